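"""Synthetic cohorts with planted deaminase-signature structure.

The generator produces (i) a toy reference — random-sequence single-exon
CDS transcripts on alternating strands of one chromosome, (ii) per-patient
somatic SNV sets whose placement is enriched at deaminase motif sites in
proportion to a latent per-patient signature intensity ``z``, with
controllable codon-position and strand bias, and (iii) progression-free
survival times whose exponential hazard scales as ``exp(beta * z)``, so
that signature-high patients progress earlier.

Default conditions emulate the data the pipeline targets: per-patient CDS
mutation burden is log-normal with a >10-fold spread between the 10th and
90th percentile patient, cohorts contain a mixture of signature-carrying
and signature-free patients (z = Bernoulli(1/2) × half-normal), and the
planted High/Low PFS structure sits at a 24-month threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import CORE_MOTIFS, DEAMINATION_PRODUCT, iupac_match
from .reference import (
    ClinicalRecord,
    SomaticSNV,
    TranscriptModel,
    complement,
    reverse_complement,
    write_clinical,
    write_maf,
    write_vcf,
)

logger = logging.getLogger(__name__)

SPACER = 20  # bases of intergenic padding between toy transcripts


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 10
    cds_length_codons: int = 100
    n_patients: int = 300
    burden_log_mean: float = float(np.log(50.0))
    burden_log_sigma: float = 1.0
    motif_enrichment: dict[str, float] = field(default_factory=lambda: {"A3G": 10.0})
    strand_bias_factor: float = 0.8
    codon_position_weights: tuple[float, float, float] = (0.2, 0.2, 0.6)
    outcome_link_beta: float = 1.0
    z_sigma: float = 2.5
    baseline_median_factor: float = 4.0
    censoring_rate: float = 0.1
    threshold_months: int = 24
    cancer_type: str = "SYN"

    def __post_init__(self) -> None:
        if abs(sum(self.codon_position_weights) - 1.0) > 1e-9:
            raise ValueError("codon_position_weights must sum to 1")
        if any(rho < 0 for rho in self.motif_enrichment.values()):
            raise ValueError("enrichment factors must be non-negative")


@dataclass(frozen=True)
class MotifSite:
    """A motif placement on a transcript's coding strand.

    ``strand_mode`` 'coding' sites mutate the deamination base itself
    (e.g. C>T); 'reverse_complement' sites carry the mirrored substitution
    on the coding strand (e.g. G>A).
    """

    transcript_id: str
    cds_position: int  # 1-based position of the mutated base
    motif: str
    strand_mode: str
    coding_ref: str
    coding_alt: str

    @property
    def codon_position(self) -> int:
        return (self.cds_position - 1) % 3 + 1


def make_reference(config: SimulationConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random toy genome plus single-exon transcripts on alternating strands."""
    rng = np.random.default_rng(config.seed)
    cds_len = 3 * config.cds_length_codons
    chrom = "chr1"
    genome_parts: list[str] = []
    transcripts: list[TranscriptModel] = []
    cursor = 1
    bases = np.array(list("ACGT"))
    for i in range(config.n_transcripts):
        spacer = "".join(rng.choice(bases, SPACER))
        genome_parts.append(spacer)
        cursor += SPACER
        cds = "".join(rng.choice(bases, cds_len))
        strand = "+" if i % 2 == 0 else "-"
        start, end = cursor, cursor + cds_len - 1
        genome_parts.append(cds if strand == "+" else reverse_complement(cds))
        cursor = end + 1
        transcripts.append(
            TranscriptModel(
                transcript_id=f"T{i:03d}",
                gene_id=f"G{i:03d}",
                chromosome=chrom,
                strand=strand,
                cds_intervals=((start, end),),
                cds_sequence=cds,
            )
        )
    genome_parts.append("".join(rng.choice(bases, SPACER)))
    return {chrom: "".join(genome_parts)}, transcripts


def write_reference(
    genome: dict[str, str], transcripts: Sequence[TranscriptModel], outdir: str | Path
) -> tuple[Path, Path]:
    """Write genome FASTA and the simplified transcript TSV."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    tsv = outdir / "transcripts.tsv"
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chromosome,
                "strand": t.strand,
                "intervals": ";".join(f"{s}-{e}" for s, e in t.cds_intervals),
                "cds_sequence": t.cds_sequence,
            }
            for t in transcripts
        ]
    ).to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


def enumerate_motif_sites(
    transcripts: Sequence[TranscriptModel], motif_names: Sequence[str]
) -> list[MotifSite]:
    """All placements of the named core motifs, both strand modes."""
    sites: list[MotifSite] = []
    for name in motif_names:
        pattern, site_index = CORE_MOTIFS[name]
        ref, alt = DEAMINATION_PRODUCT[name]
        rc_pattern = "".join(complement(b) for b in pattern)[::-1]
        rc_site = len(pattern) - site_index + 1
        for tx in transcripts:
            seq = tx.cds_sequence
            for mode, pat, si, cref, calt in (
                ("coding", pattern, site_index, ref, alt),
                ("reverse_complement", rc_pattern, rc_site, complement(ref), complement(alt)),
            ):
                for start in range(len(seq) - len(pat) + 1):
                    window = seq[start : start + len(pat)]
                    if all(iupac_match(c, b) for c, b in zip(pat, window)):
                        sites.append(
                            MotifSite(tx.transcript_id, start + si, name, mode, cref, calt)
                        )
    return sites


def _to_genomic(tx: TranscriptModel, cds_position: int, coding_ref: str, coding_alt: str):
    (start, end), = tx.cds_intervals
    if tx.strand == "+":
        return start + cds_position - 1, coding_ref, coding_alt
    return end - (cds_position - 1), complement(coding_ref), complement(coding_alt)


def simulate_patient_snvs(
    config: SimulationConfig,
    transcripts: Sequence[TranscriptModel],
    z: float,
    rng: np.random.Generator,
    patient_id: str,
    sites: list[MotifSite] | None = None,
) -> list[SomaticSNV]:
    """One patient's somatic SNV set.

    Every CDS position carries sampling weight 1; each placement of an
    enriched motif adds weight rho * z at its mutated site, so an SNV lands
    on a motif-m site with probability
    S_m * rho_m * z / (L + sum_m S_m * rho_m * z) — i.e. motif sites are
    hit with probability proportional to 1 + rho*z.  A motif hit draws its
    site with strand mode per ``strand_bias_factor`` and codon position per
    ``codon_position_weights``, and carries the motif's deamination
    substitution; background SNVs fall uniformly on the CDS with a uniform
    alternate base.  Burden is log-normal, truncated at 1.
    """
    if z < 0:
        raise ValueError("latent intensity must be non-negative")
    enriched = {m: r for m, r in config.motif_enrichment.items() if r > 0}
    if sites is None:
        sites = enumerate_motif_sites(transcripts, sorted(enriched))
    by_tx = {t.transcript_id: t for t in transcripts}
    # Bucket sites by (motif, strand_mode, codon_position) for biased draws.
    buckets: dict[tuple[str, str, int], list[MotifSite]] = {}
    n_sites: dict[str, int] = {m: 0 for m in enriched}
    for s in sites:
        if s.motif in enriched:
            buckets.setdefault((s.motif, s.strand_mode, s.codon_position), []).append(s)
            n_sites[s.motif] += 1
    for m in enriched:
        if n_sites[m] == 0:
            raise ValueError(f"reference has no sites for enriched motif {m}")

    cds_len = 3 * config.cds_length_codons
    total_positions = cds_len * len(transcripts)
    extra = {m: n_sites[m] * enriched[m] * z for m in enriched}
    extra_tot = sum(extra.values())
    p_motif = extra_tot / (total_positions + extra_tot) if enriched else 0.0
    burden = max(1, int(round(rng.lognormal(config.burden_log_mean, config.burden_log_sigma))))

    tx_list = list(transcripts)
    motif_names = sorted(enriched)
    motif_probs = (
        np.array([extra[m] for m in motif_names]) / extra_tot if extra_tot > 0 else None
    )
    w = np.asarray(config.codon_position_weights)

    snvs: list[SomaticSNV] = []
    for _ in range(burden):
        if enriched and rng.random() < p_motif:
            motif = motif_names[rng.choice(len(motif_names), p=motif_probs)] if len(motif_names) > 1 else motif_names[0]
            mode = "coding" if rng.random() < config.strand_bias_factor else "reverse_complement"
            avail = [k for k in ((motif, mode, mc) for mc in (1, 2, 3)) if k in buckets]
            if not avail:  # no placement on the drawn strand mode; use the other
                mode = "reverse_complement" if mode == "coding" else "coding"
                avail = [k for k in ((motif, mode, mc) for mc in (1, 2, 3)) if k in buckets]
            probs = np.array([w[k[2] - 1] for k in avail])
            probs = probs / probs.sum()
            key = avail[rng.choice(len(avail), p=probs)]
            site = buckets[key][rng.integers(len(buckets[key]))]
            tx = by_tx[site.transcript_id]
            pos, ref, alt = _to_genomic(tx, site.cds_position, site.coding_ref, site.coding_alt)
        else:
            tx = tx_list[rng.integers(len(tx_list))]
            cds_pos = int(rng.integers(1, cds_len + 1))
            coding_ref = tx.cds_sequence[cds_pos - 1]
            coding_alt = rng.choice([b for b in "ACGT" if b != coding_ref])
            pos, ref, alt = _to_genomic(tx, cds_pos, coding_ref, str(coding_alt))
        snvs.append(SomaticSNV(patient_id, tx.chromosome, int(pos), ref, alt, config.cancer_type))
    return snvs


@dataclass
class CohortTruth:
    z: dict[str, float]
    hazard: dict[str, float]
    signature_carrier: dict[str, bool]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel], list[SomaticSNV], list[ClinicalRecord], CohortTruth]:
    """Full synthetic cohort: reference, variants, clinical outcomes, truth.

    Latent intensity z ~ Bernoulli(1/2) × |N(0, z_sigma)|; PFS ~ Exponential
    with rate lam0 * exp(beta * z) where lam0 puts a z=0 patient's median
    PFS at ``baseline_median_factor`` × the threshold, so signature-free
    patients progress late and carriers progress earlier in proportion to
    their intensity.  A ``censoring_rate`` fraction of patients is censored
    uniformly before their progression time.
    """
    genome, transcripts = make_reference(config)
    rng = np.random.default_rng(config.seed + 1)
    sites = enumerate_motif_sites(
        transcripts, sorted(m for m, r in config.motif_enrichment.items() if r > 0)
    )
    lam0 = np.log(2.0) / (config.baseline_median_factor * config.threshold_months)
    snvs: list[SomaticSNV] = []
    records: list[ClinicalRecord] = []
    truth = CohortTruth({}, {}, {})
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        z = float(rng.integers(0, 2) * abs(rng.normal(0.0, config.z_sigma)))
        lam = lam0 * float(np.exp(config.outcome_link_beta * z))
        pfs = float(rng.exponential(1.0 / lam))
        event = True
        if rng.random() < config.censoring_rate:
            event = False
            pfs *= float(rng.random())
        snvs.extend(simulate_patient_snvs(config, transcripts, z, rng, pid, sites))
        records.append(ClinicalRecord(pid, config.cancer_type, pfs, event))
        truth.z[pid] = z
        truth.hazard[pid] = lam
        truth.signature_carrier[pid] = z > 0
    return genome, transcripts, snvs, records, truth


def write_cohort(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Simulate and write every artefact in the formats the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, snvs, records, truth = simulate_cohort(config)
    fasta, tsv = write_reference(genome, transcripts, outdir)
    paths = {
        "genome": fasta,
        "transcripts": tsv,
        "vcf": outdir / "somatic.vcf",
        "maf": outdir / "somatic.maf",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(snvs, paths["vcf"], contig_length=max(len(s) for s in genome.values()) + 1)
    write_maf(snvs, paths["maf"])
    write_clinical(records, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "z": truth.z,
                "hazard": truth.hazard,
                "signature_carrier": truth.signature_carrier,
            },
            fh,
            indent=1,
        )
    return paths
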