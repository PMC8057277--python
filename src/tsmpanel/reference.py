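"""Transcript models, somatic SNVs, clinical records, and coding-context mapping.

The analyses in this package are defined on the coding (non-transcribed)
strand of a transcript, read 5'→3'.  Every somatic single-nucleotide variant
is therefore projected from genomic coordinates into a spliced-CDS coordinate
system before any motif or codon-context logic runs: the mapping yields the
coding-strand alleles, the 1-based CDS offset, the codon index and the
position of the mutated base within its codon (1, 2 or 3), plus a short
coding-strand flanking window used for motif matching.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FLANK_RADIUS = 3  # ±3 bases → 7-base window, wide enough for every shipped motif


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware CDS: genomic intervals plus the spliced coding sequence.

    ``cds_sequence`` is given 5'→3' on the coding (non-transcribed) strand;
    for minus-strand transcripts it is the reverse complement of the genomic
    slice.  ``cds_intervals`` are 1-based inclusive and ascend by genomic
    position regardless of strand.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        total = sum(e - s + 1 for s, e in self.cds_intervals)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"transcript {self.transcript_id}: interval length {total} != "
                f"sequence length {len(self.cds_sequence)}"
            )
        prev_end = 0
        for s, e in self.cds_intervals:
            if s > e or s <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: intervals must be ascending "
                    "and non-overlapping"
                )
            prev_end = e

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def genomic_to_cds(self, position: int) -> int | None:
        """1-based spliced CDS offset in transcription order, or None if outside."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= position <= e:
                plus_offset = offset + (position - s + 1)
                if self.strand == "+":
                    return plus_offset
                return self.cds_length - plus_offset + 1
            offset += e - s + 1
        return None


@dataclass(frozen=True)
class SomaticSNV:
    patient_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        for b in (self.ref, self.alt):
            if b not in "ACGT":
                raise ValueError(f"allele must be a single base in ACGT, got {b!r}")


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    cancer_type: str
    pfs_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be non-negative")


@dataclass(frozen=True)
class MutationContext:
    """A somatic SNV annotated in its transcript's coding frame."""

    snv: SomaticSNV
    transcript_id: str
    coding_ref: str
    coding_alt: str
    cds_position: int
    codon_index: int
    codon_position: int
    ref_codon: str
    alt_codon: str
    synonymous: bool
    flank: str


# ---------------------------------------------------------------------------
# Transcript loading
# ---------------------------------------------------------------------------


def _validate_transcript(
    tx: TranscriptModel, genome: "pyfaidx.Fasta | None"  # noqa: F821
) -> bool:
    """Check frame and (when a genome is given) sequence agreement.

    Returns False (with a logged warning) for out-of-frame transcripts;
    raises for interval/sequence mismatches, which indicate corrupt input.
    """
    if tx.cds_length % 3 != 0:
        logger.warning(
            "transcript %s: CDS length %d not divisible by 3; skipped",
            tx.transcript_id,
            tx.cds_length,
        )
        return False
    if genome is not None:
        pieces = [str(genome[tx.chromosome][s - 1 : e]) for s, e in tx.cds_intervals]
        genomic = "".join(pieces).upper()
        expected = genomic if tx.strand == "+" else reverse_complement(genomic)
        if expected != tx.cds_sequence:
            raise ValueError(
                f"transcript {tx.transcript_id}: cds_sequence disagrees with genome"
            )
    return True


def _canonical_per_gene(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """One transcript per gene: longest CDS, ties by smallest transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for tx in transcripts:
        cur = best.get(tx.gene_id)
        if (
            cur is None
            or tx.cds_length > cur.cds_length
            or (tx.cds_length == cur.cds_length and tx.transcript_id < cur.transcript_id)
        ):
            best[tx.gene_id] = tx
    return sorted(best.values(), key=lambda t: t.transcript_id)


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for chunk in text.split(";"):
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def load_transcripts_tsv(path: str | Path) -> list[TranscriptModel]:
    """Read the simplified transcript TSV (embedded spliced CDS sequence).

    Columns: transcript_id, gene_id, chrom, strand, intervals
    (``start-end[;start-end...]``, 1-based inclusive), cds_sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "gene_id", "chrom", "strand", "intervals", "cds_sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        tx = TranscriptModel(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            chromosome=row.chrom,
            strand=row.strand,
            cds_intervals=_parse_intervals(row.intervals),
            cds_sequence=row.cds_sequence.upper(),
        )
        if _validate_transcript(tx, None):
            out.append(tx)
    return _canonical_per_gene(out)


def load_transcripts_gff3(gff3_path: str | Path, fasta_path: str | Path) -> list[TranscriptModel]:
    """Read CDS features from a GFF3 file, splicing sequence from the genome.

    CDS features are grouped by their ``transcript_id`` attribute (falling
    back to ``Parent``); the gene comes from ``gene_id`` (falling back to the
    transcript id).
    """
    import gffutils
    import pyfaidx

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome = pyfaidx.Fasta(str(fasta_path))
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes.get("transcript_id", feat.attributes.get("Parent", [feat.id]))[0]
        grouped.setdefault(tid, []).append(feat)
    out = []
    for tid, feats in grouped.items():
        feats.sort(key=lambda f: f.start)
        chrom = feats[0].seqid
        strand = feats[0].strand
        gene = feats[0].attributes.get("gene_id", [tid])[0]
        intervals = tuple((f.start, f.end) for f in feats)
        genomic = "".join(str(genome[chrom][s - 1 : e]) for s, e in intervals).upper()
        seq = genomic if strand == "+" else reverse_complement(genomic)
        tx = TranscriptModel(tid, gene, chrom, strand, intervals, seq)
        if _validate_transcript(tx, genome):
            out.append(tx)
    return _canonical_per_gene(out)


def load_transcripts(
    annotation_source: str | Path, genome_source: str | Path | None = None
) -> list[TranscriptModel]:
    """Dispatch on annotation format: GFF3 (needs a genome FASTA) or TSV."""
    path = Path(annotation_source)
    if path.suffix.lower() in {".gff", ".gff3"}:
        if genome_source is None:
            raise ValueError("GFF3 annotation requires a genome FASTA")
        return load_transcripts_gff3(path, genome_source)
    return load_transcripts_tsv(path)


# ---------------------------------------------------------------------------
# Variant loading / writing
# ---------------------------------------------------------------------------


def load_snvs_vcf(path: str | Path, default_patient: str | None = None) -> tuple[list[SomaticSNV], int]:
    """Parse a VCF v4.x file into somatic SNVs.

    Multi-allelic records are split; indels, MNVs and symbolic alleles are
    dropped and counted.  Patient and cancer-type labels are taken from the
    ``PATIENT`` / ``CTYPE`` INFO tags when present, else from
    ``default_patient`` (default: the file stem).

    Returns (snvs, n_dropped).
    """
    import pysam

    path = Path(path)
    patient_fallback = default_patient if default_patient is not None else path.stem
    snvs: list[SomaticSNV] = []
    dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        has_patient = "PATIENT" in vcf.header.info
        has_ctype = "CTYPE" in vcf.header.info
        for rec in vcf:
            patient = rec.info.get("PATIENT", patient_fallback) if has_patient else patient_fallback
            ctype = rec.info.get("CTYPE", "") if has_ctype else ""
            ref = rec.ref or ""
            for alt in rec.alts or ():
                if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                    dropped += 1
                    continue
                if ref == alt:
                    logger.warning("record at %s:%d has ref==alt; dropped", rec.chrom, rec.pos)
                    dropped += 1
                    continue
                snvs.append(SomaticSNV(patient, rec.chrom, rec.pos, ref, alt, ctype))
    if dropped:
        logger.info("%s: dropped %d non-SNV or invalid allele records", path.name, dropped)
    return snvs, dropped


def load_snvs_maf(path: str | Path) -> tuple[list[SomaticSNV], int]:
    """Parse a MAF-like TSV; only Variant_Type == SNP rows are kept."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {
        "Chromosome",
        "Start_Position",
        "Reference_Allele",
        "Tumor_Seq_Allele2",
        "Variant_Type",
        "Tumor_Sample_Barcode",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAF missing columns: {sorted(missing)}")
    snvs: list[SomaticSNV] = []
    dropped = 0
    for row in df.itertuples(index=False):
        ref, alt = row.Reference_Allele, row.Tumor_Seq_Allele2
        if (
            row.Variant_Type != "SNP"
            or len(ref) != 1
            or len(alt) != 1
            or ref not in "ACGT"
            or alt not in "ACGT"
            or ref == alt
        ):
            dropped += 1
            continue
        ctype = getattr(row, "Cancer_Type", "") if hasattr(row, "Cancer_Type") else ""
        snvs.append(
            SomaticSNV(
                row.Tumor_Sample_Barcode,
                str(row.Chromosome),
                int(row.Start_Position),
                ref,
                alt,
                ctype if isinstance(ctype, str) else "",
            )
        )
    if dropped:
        logger.info("%s: dropped %d non-SNP records", Path(path).name, dropped)
    return snvs, dropped


def load_snvs(
    variant_source: str | Path, format: str = "vcf", default_patient: str | None = None
) -> tuple[list[SomaticSNV], int]:
    if format == "vcf":
        return load_snvs_vcf(variant_source, default_patient)
    if format == "maf":
        return load_snvs_maf(variant_source)
    raise ValueError(f"unknown variant format {format!r}")


def write_vcf(snvs: Sequence[SomaticSNV], path: str | Path, contig_length: int = 10**7) -> None:
    """Write SNVs to an uncompressed VCF with PATIENT/CTYPE INFO tags."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("INFO", items=[("ID", "PATIENT"), ("Number", "1"), ("Type", "String"), ("Description", "Patient identifier")])
    header.add_meta("INFO", items=[("ID", "CTYPE"), ("Number", "1"), ("Type", "String"), ("Description", "Cancer type code")])
    for chrom in sorted({s.chromosome for s in snvs}):
        header.contigs.add(chrom, length=contig_length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for snv in sorted(snvs, key=lambda s: (s.chromosome, s.position, s.patient_id, s.alt)):
            rec = out.new_record(
                contig=snv.chromosome,
                start=snv.position - 1,
                stop=snv.position,
                alleles=(snv.ref, snv.alt),
            )
            rec.info["PATIENT"] = snv.patient_id
            if snv.cancer_type:
                rec.info["CTYPE"] = snv.cancer_type
            out.write(rec)


def write_maf(snvs: Sequence[SomaticSNV], path: str | Path) -> None:
    rows = [
        {
            "Hugo_Symbol": ".",
            "Chromosome": s.chromosome,
            "Start_Position": s.position,
            "Reference_Allele": s.ref,
            "Tumor_Seq_Allele2": s.alt,
            "Variant_Type": "SNP",
            "Tumor_Sample_Barcode": s.patient_id,
            "Cancer_Type": s.cancer_type,
        }
        for s in snvs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


def load_clinical(table_source: str | Path) -> tuple[list[ClinicalRecord], list[tuple[str, str]]]:
    """Read the per-patient clinical TSV.

    Returns (records, excluded) where excluded is a list of
    (patient_id, reason) for rows lacking a valid progression-free survival.
    Duplicate patient ids are a hard error.
    """
    df = pd.read_csv(table_source, sep="\t", dtype={"patient_id": str, "cancer_type": str})
    required = {"patient_id", "cancer_type", "pfs_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    dupes = df["patient_id"][df["patient_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dupes))}")
    records: list[ClinicalRecord] = []
    excluded: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        pfs = pd.to_numeric(pd.Series([row.pfs_months]), errors="coerce").iloc[0]
        if pd.isna(pfs) or pfs < 0:
            excluded.append((row.patient_id, "invalid PFS"))
            continue
        records.append(
            ClinicalRecord(row.patient_id, row.cancer_type, float(pfs), bool(int(row.event)))
        )
    for pid, reason in excluded:
        logger.info("patient %s excluded: %s", pid, reason)
    return records, excluded


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "cancer_type": r.cancer_type,
                "pfs_months": r.pfs_months,
                "event": int(r.event),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNV → coding context mapping
# ---------------------------------------------------------------------------


class TranscriptIndex:
    """Per-chromosome interval index over a canonical transcript set.

    When a position falls inside more than one gene's CDS, the transcript
    with the longest CDS wins, ties broken by smallest gene_id (logged).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._by_chrom: dict[str, list[tuple[int, int, TranscriptModel]]] = {}
        for tx in transcripts:
            lst = self._by_chrom.setdefault(tx.chromosome, [])
            for s, e in tx.cds_intervals:
                lst.append((s, e, tx))
        for lst in self._by_chrom.values():
            lst.sort(key=lambda t: t[0])
        self._starts = {c: [s for s, _, _ in lst] for c, lst in self._by_chrom.items()}

    def lookup(self, chromosome: str, position: int) -> TranscriptModel | None:
        lst = self._by_chrom.get(chromosome)
        if not lst:
            return None
        hi = bisect_right(self._starts[chromosome], position)
        hits = [tx for s, e, tx in lst[:hi] if s <= position <= e]
        if not hits:
            return None
        if len({t.gene_id for t in hits}) > 1:
            logger.info("position %s:%d overlaps %d genes; canonical rule applied", chromosome, position, len(hits))
        return min(hits, key=lambda t: (-t.cds_length, t.gene_id))


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def map_to_cds(
    snv: SomaticSNV, index: TranscriptIndex | Iterable[TranscriptModel]
) -> MutationContext | None:
    """Project one SNV into its transcript's coding frame.

    Returns None when the position is in no CDS.  Raises ValueError when the
    genomic reference allele disagrees with the transcript sequence (callers
    doing bulk mapping count these via :func:`map_cohort`).
    """
    if not isinstance(index, TranscriptIndex):
        index = TranscriptIndex(index)
    tx = index.lookup(snv.chromosome, snv.position)
    if tx is None:
        return None
    cds_pos = tx.genomic_to_cds(snv.position)
    assert cds_pos is not None
    if tx.strand == "+":
        coding_ref, coding_alt = snv.ref, snv.alt
    else:
        coding_ref, coding_alt = complement(snv.ref), complement(snv.alt)
    if tx.cds_sequence[cds_pos - 1] != coding_ref:
        raise ValueError(
            f"ref mismatch at {snv.chromosome}:{snv.position} in {tx.transcript_id}: "
            f"expected {tx.cds_sequence[cds_pos - 1]}, VCF says {coding_ref}"
        )
    codon_index = (cds_pos - 1) // 3 + 1
    codon_position = (cds_pos - 1) % 3 + 1
    codon_start = (codon_index - 1) * 3
    ref_codon = tx.cds_sequence[codon_start : codon_start + 3]
    alt_codon = ref_codon[: codon_position - 1] + coding_alt + ref_codon[codon_position:]
    lo = cds_pos - 1 - FLANK_RADIUS
    hi = cds_pos + FLANK_RADIUS
    padded = "N" * FLANK_RADIUS + tx.cds_sequence + "N" * FLANK_RADIUS
    flank = padded[lo + FLANK_RADIUS : hi + FLANK_RADIUS]
    return MutationContext(
        snv=snv,
        transcript_id=tx.transcript_id,
        coding_ref=coding_ref,
        coding_alt=coding_alt,
        cds_position=cds_pos,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        synonymous=_translate(ref_codon) == _translate(alt_codon),
        flank=flank,
    )


@dataclass
class MappingSummary:
    n_input: int = 0
    n_mapped: int = 0
    n_noncds: int = 0
    n_ref_mismatch: int = 0
    contexts: list[MutationContext] = field(default_factory=list)


def map_cohort(snvs: Iterable[SomaticSNV], transcripts: Iterable[TranscriptModel]) -> MappingSummary:
    """Map a batch of SNVs, tallying non-CDS positions and reference mismatches."""
    index = TranscriptIndex(transcripts)
    summary = MappingSummary()
    for snv in snvs:
        summary.n_input += 1
        try:
            ctx = map_to_cds(snv, index)
        except ValueError as exc:
            logger.warning("%s", exc)
            summary.n_ref_mismatch += 1
            continue
        if ctx is None:
            summary.n_noncds += 1
        else:
            summary.n_mapped += 1
            summary.contexts.append(ctx)
    return summary
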