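"""Transcript/variant parsing and coding-context mapping."""

import numpy as np
import pandas as pd
import pytest

from tsmpanel.reference import (
    ClinicalRecord,
    SomaticSNV,
    TranscriptModel,
    TranscriptIndex,
    load_clinical,
    load_snvs,
    load_transcripts,
    map_cohort,
    map_to_cds,
    reverse_complement,
    write_vcf,
    write_maf,
)

from conftest import TOY_CDS


# ---------------------------------------------------------------------------
# Transcript loading
# ---------------------------------------------------------------------------


def _write_transcript_tsv(path, rows):
    pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "chrom", "strand", "intervals", "cds_sequence"],
    ).to_csv(path, sep="\t", index=False)


def test_simplified_tsv_loads_single_transcript(tmp_path):
    p = tmp_path / "tx.tsv"
    _write_transcript_tsv(p, [["T1", "G1", "chr1", "+", "101-112", TOY_CDS]])
    (tx,) = load_transcripts(p)
    assert tx.cds_length == 12
    assert tx.cds_sequence == TOY_CDS
    assert tx.cds_intervals == ((101, 112),)


def test_out_of_frame_transcript_skipped_with_warning(tmp_path, caplog):
    p = tmp_path / "tx.tsv"
    _write_transcript_tsv(
        p,
        [
            ["T1", "G1", "chr1", "+", "101-112", TOY_CDS],
            ["T2", "G2", "chr1", "+", "201-213", "A" * 13],
        ],
    )
    with caplog.at_level("WARNING"):
        txs = load_transcripts(p)
    assert [t.transcript_id for t in txs] == ["T1"]
    assert "not divisible by 3" in caplog.text


def test_interval_sequence_length_mismatch_is_hard_error():
    with pytest.raises(ValueError, match="length"):
        TranscriptModel("T1", "G1", "chr1", "+", ((101, 110),), TOY_CDS)


def test_minus_strand_gff3_reverse_complements_genomic_slice(tmp_path, toy_genome):
    fasta = tmp_path / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(">chr1\n" + toy_genome["chr1"] + "\n")
    gff = tmp_path / "ann.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            "chr1\ttest\tCDS\t131\t142\t.\t-\t0\t"
            "ID=cds2;transcript_id=T2;gene_id=G2\n"
        )
    (tx,) = load_transcripts(gff, fasta)
    assert tx.strand == "-"
    assert tx.cds_sequence == reverse_complement(toy_genome["chr1"][130:142])


def test_canonical_transcript_longest_cds_then_smallest_id(tmp_path):
    p = tmp_path / "tx.tsv"
    _write_transcript_tsv(
        p,
        [
            ["T9", "G1", "chr1", "+", "101-112", TOY_CDS],
            ["T2", "G1", "chr1", "+", "201-215", "ATGCCTTCATGATGA"],
            ["T5", "G1", "chr1", "+", "301-315", "ATGCCTTCATGATGA"],
        ],
    )
    (tx,) = load_transcripts(p)
    assert tx.transcript_id == "T2"  # longest CDS, tie broken by id


# ---------------------------------------------------------------------------
# Variant loading
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.1\n"
    "##contig=<ID=chr1,length=1000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def test_empty_vcf_yields_empty_set(tmp_path):
    p = tmp_path / "empty.vcf"
    p.write_text(VCF_HEADER)
    snvs, dropped = load_snvs(p, "vcf")
    assert snvs == [] and dropped == 0


def test_vcf_filters_non_snvs_and_counts_drops(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(
        VCF_HEADER
        + "chr1\t105\t.\tC\tT\t.\t.\t.\n"
        + "chr1\t106\t.\tT\tA\t.\t.\t.\n"
        + "chr1\t110\t.\tTG\tT\t.\t.\t.\n"
    )
    snvs, dropped = load_snvs(p, "vcf", default_patient="P1")
    assert len(snvs) == 2 and dropped == 1
    assert {(s.ref, s.alt) for s in snvs} == {("C", "T"), ("T", "A")}


def test_multiallelic_vcf_record_is_split(tmp_path):
    p = tmp_path / "ma.vcf"
    p.write_text(VCF_HEADER + "chr1\t105\t.\tC\tT,G\t.\t.\t.\n")
    snvs, dropped = load_snvs(p, "vcf")
    assert sorted(s.alt for s in snvs) == ["G", "T"] and dropped == 0


def test_maf_snp_row_parses_and_indel_dropped(tmp_path):
    p = tmp_path / "toy.maf"
    p.write_text(
        "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
        "Tumor_Seq_Allele2\tVariant_Type\tTumor_Sample_Barcode\n"
        "X\tchr1\t105\tC\tT\tSNP\tP7\n"
        "X\tchr1\t110\tTG\tT\tDEL\tP7\n"
    )
    snvs, dropped = load_snvs(p, "maf")
    assert len(snvs) == 1 and dropped == 1
    assert snvs[0].patient_id == "P7" and snvs[0].ref == "C" and snvs[0].alt == "T"


def test_vcf_round_trip_preserves_snv_multiset(tmp_path):
    rng = np.random.default_rng(11)
    snvs = []
    for i in range(50):
        ref, alt = (str(b) for b in rng.choice(list("ACGT"), size=2, replace=False))
        snvs.append(SomaticSNV(f"P{i % 5}", "chr1", int(rng.integers(1, 900)), ref, alt, "SYN"))
    path = tmp_path / "rt.vcf"
    write_vcf(snvs, path, contig_length=1000)
    reloaded, dropped = load_snvs(path, "vcf")
    assert dropped == 0
    assert sorted(map(repr, reloaded)) == sorted(map(repr, snvs))


def test_maf_round_trip_preserves_snv_multiset(tmp_path):
    snvs = [SomaticSNV("P1", "chr1", 105, "C", "T", "SYN"),
            SomaticSNV("P2", "chr2", 9, "G", "A", "SYN")]
    path = tmp_path / "rt.maf"
    write_maf(snvs, path)
    reloaded, _ = load_snvs(path, "maf")
    assert sorted(map(repr, reloaded)) == sorted(map(repr, snvs))


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


def test_clinical_rows_with_invalid_pfs_are_excluded(tmp_path):
    p = tmp_path / "clin.tsv"
    p.write_text(
        "patient_id\tcancer_type\tpfs_months\tevent\n"
        "P1\tSYN\t12.0\t1\n"
        "P2\tSYN\t\t1\n"
    )
    records, excluded = load_clinical(p)
    assert [r.patient_id for r in records] == ["P1"]
    assert records[0].pfs_months == 12.0 and records[0].event is True
    assert excluded == [("P2", "invalid PFS")]


def test_duplicate_patient_id_is_hard_error(tmp_path):
    p = tmp_path / "clin.tsv"
    p.write_text(
        "patient_id\tcancer_type\tpfs_months\tevent\n"
        "P1\tSYN\t12.0\t1\nP1\tSYN\t13.0\t0\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        load_clinical(p)


# ---------------------------------------------------------------------------
# Mapping SNVs into coding context
# ---------------------------------------------------------------------------


def test_map_plus_strand_second_codon(toy_transcript):
    # ATG CCT TCA TGA; genomic 105 is CDS position 5 (middle of codon 2).
    snv = SomaticSNV("P1", "chr1", 105, "C", "T")
    ctx = map_to_cds(snv, [toy_transcript])
    assert ctx.cds_position == 5
    assert ctx.codon_index == 2 and ctx.codon_position == 2
    assert ctx.ref_codon == "CCT" and ctx.alt_codon == "CTT"
    assert not ctx.synonymous  # Pro -> Leu


def test_map_synonymous_third_position(toy_transcript):
    snv = SomaticSNV("P1", "chr1", 106, "T", "A")
    ctx = map_to_cds(snv, [toy_transcript])
    assert ctx.codon_position == 3
    assert ctx.ref_codon == "CCT" and ctx.alt_codon == "CCA"
    assert ctx.synonymous  # Pro -> Pro


def test_map_minus_strand_complements_alleles(toy_minus_transcript, toy_genome):
    # Pick a minus-strand CDS position whose genomic base is G -> coding C.
    chrom_seq = toy_genome["chr1"]
    pos = next(p for p in range(131, 143) if chrom_seq[p - 1] == "G")
    snv = SomaticSNV("P1", "chr1", pos, "G", "A")
    ctx = map_to_cds(snv, [toy_minus_transcript])
    assert ctx.coding_ref == "C" and ctx.coding_alt == "T"
    # cds_position counts from the genomic 3' end on minus strand
    assert ctx.cds_position == 142 - pos + 1


def test_position_outside_cds_maps_to_none(toy_transcript):
    assert map_to_cds(SomaticSNV("P1", "chr1", 100, "A", "C"), [toy_transcript]) is None
    assert map_to_cds(SomaticSNV("P1", "chr1", 113, "A", "C"), [toy_transcript]) is None


def test_ref_mismatch_counted_not_mapped(toy_transcript):
    # Genomic 105 is C on the coding strand; claim it is A.
    bad = SomaticSNV("P1", "chr1", 105, "A", "G")
    good = SomaticSNV("P1", "chr1", 106, "T", "A")
    summary = map_cohort([bad, good], [toy_transcript])
    assert summary.n_ref_mismatch == 1 and summary.n_mapped == 1


def test_count_conservation_mapped_noncds_mismatch(toy_transcript):
    rng = np.random.default_rng(5)
    snvs = []
    for _ in range(200):
        pos = int(rng.integers(90, 125))
        ref = rng.choice(list("ACGT"))
        alt = rng.choice([b for b in "ACGT" if b != ref])
        snvs.append(SomaticSNV("P1", "chr1", pos, str(ref), str(alt)))
    summary = map_cohort(snvs, [toy_transcript])
    assert summary.n_input == len(snvs)
    assert summary.n_mapped + summary.n_noncds + summary.n_ref_mismatch == summary.n_input
    assert len(summary.contexts) == summary.n_mapped


def test_flank_padded_with_n_at_cds_edges(toy_transcript):
    ctx = map_to_cds(SomaticSNV("P1", "chr1", 101, "A", "G"), [toy_transcript])
    assert ctx.flank == "NNNATGC"
    ctx = map_to_cds(SomaticSNV("P1", "chr1", 112, "A", "C"), [toy_transcript])
    assert ctx.flank == "ATGANNN"


def test_translation_reproduces_synonymous_flag(toy_transcript, toy_minus_transcript):
    from Bio.Seq import Seq

    rng = np.random.default_rng(9)
    index = TranscriptIndex([toy_transcript, toy_minus_transcript])
    for _ in range(100):
        tx = toy_transcript if rng.random() < 0.5 else toy_minus_transcript
        lo, hi = tx.cds_intervals[0]
        pos = int(rng.integers(lo, hi + 1))
        cds_pos = tx.genomic_to_cds(pos)
        coding_ref = tx.cds_sequence[cds_pos - 1]
        genomic_ref = coding_ref if tx.strand == "+" else str(Seq(coding_ref).complement())
        genomic_alt = rng.choice([b for b in "ACGT" if b != genomic_ref])
        ctx = map_to_cds(SomaticSNV("P1", "chr1", pos, genomic_ref, str(genomic_alt)), index)
        assert ctx.synonymous == (
            str(Seq(ctx.ref_codon).translate()) == str(Seq(ctx.alt_codon).translate())
        )


def test_strand_equivalence_under_genome_reverse_complement(toy_genome):
    """Reverse-complementing the genome and flipping every transcript's strand
    and interval orientation must leave every mapped context unchanged."""
    chrom = toy_genome["chr1"]
    L = len(chrom)
    fwd_tx = TranscriptModel("T1", "G1", "chr1", "+", ((101, 112),), TOY_CDS)
    # Same CDS, expressed on the minus strand of the reverse-complemented genome.
    rc_chrom = reverse_complement(chrom)
    s, e = L - 112 + 1, L - 101 + 1
    rev_tx = TranscriptModel("T1", "G1", "chr1", "-", ((s, e),), TOY_CDS)
    assert reverse_complement(rc_chrom[s - 1 : e]) == TOY_CDS

    rng = np.random.default_rng(21)
    for _ in range(50):
        pos = int(rng.integers(101, 113))
        ref = chrom[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        ctx_fwd = map_to_cds(SomaticSNV("P1", "chr1", pos, ref, alt), [fwd_tx])
        rc_pos = L - pos + 1
        ctx_rev = map_to_cds(
            SomaticSNV("P1", "chr1", rc_pos, reverse_complement(ref), reverse_complement(alt)),
            [rev_tx],
        )
        assert ctx_fwd.coding_ref == ctx_rev.coding_ref
        assert ctx_fwd.coding_alt == ctx_rev.coding_alt
        assert ctx_fwd.codon_position == ctx_rev.codon_position
        assert ctx_fwd.flank == ctx_rev.flank


def test_snv_in_overlapping_genes_uses_canonical_rule():
    t_small = TranscriptModel("TA", "GA", "chr1", "+", ((101, 112),), TOY_CDS)
    t_big = TranscriptModel("TB", "GB", "chr1", "+", ((95, 115),), "ATG" + TOY_CDS + "TGATGA")
    ctx = map_to_cds(SomaticSNV("P1", "chr1", 105, "C", "T"), [t_small, t_big])
    assert ctx.transcript_id == "TB"  # longer CDS wins


def test_clinical_record_rejects_negative_pfs():
    with pytest.raises(ValueError):
        ClinicalRecord("P1", "SYN", -1.0, True)
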