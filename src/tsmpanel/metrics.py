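"""Deaminase-associated mutation metric panel.

Each metric counts a patient's coding-region SNVs that satisfy a motif
placement plus optional substitution, codon-position, synonymy and
transition/transversion filters, normalised either by the patient's total
CDS SNV count or by the count of SNVs sitting in the metric's motif.

Motifs are short IUPAC patterns with one designated mutated site, matched on
the coding strand 5'→3'.  A ``reverse_complement`` strand mode matches the
pattern on the transcribed strand instead (implemented by matching the
reverse complement of the pattern on the coding-strand flank), which is how
strand-bias metrics such as "G>A inside a TCW motif" are expressed: a G>A on
the coding strand mirrors a C>T deamination on the opposite strand.

The shipped default catalog holds 142 metrics generated combinatorially from
the four documented deaminase motifs (AID WRC, APOBEC3G CC, APOBEC3B TCW,
ADAR WA), their strand modes, codon-position and synonymy qualifiers, and a
set of global burden / transition-transversion / codon-position summaries.
Users can substitute any catalog via the YAML schema below.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .reference import FLANK_RADIUS, MutationContext, reverse_complement

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

PURINES = frozenset("AG")

TRANSITION = "transition"
TRANSVERSION = "transversion"


def iupac_match(code: str, base: str) -> bool:
    """True when ``base`` (A/C/G/T) is among the bases the IUPAC code denotes.

    An 'N' *in the sequence* (flank padding) matches no code.
    """
    return base in IUPAC[code]


def iupac_reverse_complement(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifSpec:
    """An enzyme's target motif with the mutated site marked.

    ``strand_mode`` 'coding' places the pattern on the coding strand;
    'reverse_complement' places it on the transcribed strand.
    """

    name: str
    pattern: str
    site_index: int
    strand_mode: str = "coding"

    def __post_init__(self) -> None:
        if not 1 <= self.site_index <= len(self.pattern):
            raise ValueError("site_index outside pattern")
        if len(self.pattern) > 2 * FLANK_RADIUS + 1:
            raise ValueError("pattern wider than the flank window")
        if self.strand_mode not in ("coding", "reverse_complement"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)} in pattern")


@dataclass(frozen=True)
class MetricSpec:
    metric_id: str
    display_name: str
    motif: MotifSpec | None = None
    ref_class: str = "N"
    alt_class: str = "N"
    codon_position_filter: frozenset[int] | str = "any"
    synonymy_filter: str = "any"          # synonymous | non-synonymous | any
    substitution_class_filter: str = "any"  # transition | transversion | any
    denominator: str = "total_cds_snvs"   # total_cds_snvs | motif_site_snvs | none
    unit: str = "percent"                 # percent | count | ratio

    def __post_init__(self) -> None:
        if self.unit == "percent" and self.denominator == "none":
            raise ValueError(f"{self.metric_id}: percent unit needs a denominator")
        if self.denominator == "motif_site_snvs" and self.motif is None:
            raise ValueError(f"{self.metric_id}: motif_site_snvs denominator needs a motif")
        if self.synonymy_filter not in ("synonymous", "non-synonymous", "any"):
            raise ValueError(f"{self.metric_id}: bad synonymy_filter")
        if self.substitution_class_filter not in (TRANSITION, TRANSVERSION, "any"):
            raise ValueError(f"{self.metric_id}: bad substitution_class_filter")
        if self.codon_position_filter != "any":
            if not isinstance(self.codon_position_filter, frozenset):
                object.__setattr__(
                    self, "codon_position_filter", frozenset(self.codon_position_filter)
                )
            if not self.codon_position_filter <= {1, 2, 3}:
                raise ValueError(f"{self.metric_id}: codon positions must be within 1..3")


@dataclass
class PatientProfile:
    patient_id: str
    cancer_type: str
    values: dict[str, float]
    total_cds_snvs: int
    undefined_flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Matching and classification
# ---------------------------------------------------------------------------


def match_motif(context: MutationContext, motif: MotifSpec) -> bool:
    """Does the motif sit on this SNV, the marked site on the mutated base?

    The pattern (or its reverse complement, in 'reverse_complement' mode) is
    aligned so the site position covers the mutated coding-strand base, and
    every pattern position must match the flank under IUPAC semantics.  'N'
    padding in the flank matches nothing, so placements running off a CDS
    edge fail.
    """
    return _match_flank(context.flank, motif)


@lru_cache(maxsize=65536)
def _match_flank(flank: str, motif: MotifSpec) -> bool:
    pattern, site = motif.pattern, motif.site_index
    if motif.strand_mode == "reverse_complement":
        pattern = iupac_reverse_complement(pattern)
        site = len(pattern) - site + 1
    center = FLANK_RADIUS  # 0-based index of the mutated base in the flank
    start = center - (site - 1)
    if start < 0 or start + len(pattern) > len(flank):
        logger.warning("motif %s placement exceeds flank window", motif.name)
        return False
    window = flank[start : start + len(pattern)]
    return all(b != "N" and iupac_match(c, b) for c, b in zip(pattern, window))


def classify_substitution(coding_ref: str, coding_alt: str) -> str:
    """Transition (purine↔purine / pyrimidine↔pyrimidine) or transversion."""
    if coding_ref == coding_alt:
        raise ValueError("ref == alt")
    return TRANSITION if (coding_ref in PURINES) == (coding_alt in PURINES) else TRANSVERSION


def _passes(ctx: MutationContext, spec: MetricSpec) -> bool:
    if spec.motif is not None and not match_motif(ctx, spec.motif):
        return False
    if not iupac_match(spec.ref_class, ctx.coding_ref):
        return False
    if not iupac_match(spec.alt_class, ctx.coding_alt):
        return False
    if spec.codon_position_filter != "any" and ctx.codon_position not in spec.codon_position_filter:
        return False
    if spec.synonymy_filter != "any":
        want = spec.synonymy_filter == "synonymous"
        if ctx.synonymous != want:
            return False
    if spec.substitution_class_filter != "any":
        if classify_substitution(ctx.coding_ref, ctx.coding_alt) != spec.substitution_class_filter:
            return False
    return True


def evaluate_metric(
    contexts: Sequence[MutationContext], spec: MetricSpec
) -> tuple[float, bool]:
    """Evaluate one metric for one patient's mapped contexts.

    Returns (value, defined).  A zero denominator yields (0.0, False) so
    downstream feature matrices stay complete.
    """
    numerator = sum(1 for c in contexts if _passes(c, spec))
    if spec.denominator == "none":
        return float(numerator), True
    if spec.denominator == "total_cds_snvs":
        den = len(contexts)
    else:  # motif_site_snvs: motif placement only, other filters ignored
        assert spec.motif is not None
        den = sum(1 for c in contexts if match_motif(c, spec.motif))
    if den == 0:
        return 0.0, False
    if spec.unit == "percent":
        return 100.0 * numerator / den, True
    return numerator / den, True


def build_profile(
    patient_id: str,
    contexts: Sequence[MutationContext],
    catalog: Sequence[MetricSpec],
    cancer_type: str = "",
) -> PatientProfile:
    """Evaluate every catalog metric for one patient."""
    ids = [s.metric_id for s in catalog]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate metric_id(s) in catalog: {dupes}")
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for spec in catalog:
        value, defined = evaluate_metric(contexts, spec)
        values[spec.metric_id] = value
        if not defined:
            undefined.add(spec.metric_id)
    if not cancer_type and contexts:
        cancer_type = contexts[0].snv.cancer_type
    return PatientProfile(patient_id, cancer_type, values, len(contexts), undefined)


def profiles_to_frame(profiles: Iterable[PatientProfile]):
    """Patients × metrics matrix with cancer_type and total_cds_snvs columns."""
    import pandas as pd

    rows = []
    for p in profiles:
        row = {"patient_id": p.patient_id, "cancer_type": p.cancer_type,
               "total_cds_snvs": p.total_cds_snvs}
        row.update(p.values)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

#: The four deaminase motifs the panel is built around.  Site bases:
#: AID deaminates the C of WRC; APOBEC3G the second C of CC; APOBEC3B the C
#: of TCW; ADAR edits the A of WA.
CORE_MOTIFS: dict[str, tuple[str, int]] = {
    "AID": ("WRC", 3),
    "A3G": ("CC", 2),
    "A3B": ("TCW", 2),
    "ADAR": ("WA", 2),
}

#: Deamination products on the strand carrying the motif: C>T for the
#: cytidine deaminases, A>G for ADAR.
DEAMINATION_PRODUCT: dict[str, tuple[str, str]] = {
    "AID": ("C", "T"),
    "A3G": ("C", "T"),
    "A3B": ("C", "T"),
    "ADAR": ("A", "G"),
}

_SUBSTITUTIONS = [
    (r, a) for r in "ACGT" for a in "ACGT" if r != a
]


def _display_motif(pattern: str) -> str:
    return "-".join(pattern) + "-"


def _motif_mode_specs(enzyme: str, strand_mode: str) -> list[MetricSpec]:
    pattern, site = CORE_MOTIFS[enzyme]
    motif = MotifSpec(enzyme, pattern, site, strand_mode)
    ref, alt = DEAMINATION_PRODUCT[enzyme]
    if strand_mode == "reverse_complement":
        shown_ref, shown_alt = reverse_complement(ref), reverse_complement(alt)
    else:
        shown_ref, shown_alt = ref, alt
    sub = f"{shown_ref}>{shown_alt}"
    tag = f"{enzyme}_{_display_motif(pattern)}"
    mode_tag = "" if strand_mode == "coding" else ".rc"
    base_id = f"{enzyme.lower()}{mode_tag}"
    specs: list[MetricSpec] = []

    def add(metric_id, display, **kw):
        specs.append(MetricSpec(metric_id=metric_id, display_name=display,
                                motif=motif, **kw))

    # Deamination-product substitution at the motif site.
    add(f"{base_id}.pct", f"cds:{tag} {sub} %",
        ref_class=shown_ref, alt_class=shown_alt)
    for mc in (1, 2, 3):
        add(f"{base_id}.mc{mc}.pct", f"cds:{tag} {sub} MC{mc}%",
            ref_class=shown_ref, alt_class=shown_alt,
            codon_position_filter=frozenset({mc}))
    add(f"{base_id}.motif_pct", f"cds:{tag} {sub} motif %",
        ref_class=shown_ref, alt_class=shown_alt, denominator="motif_site_snvs")
    for mc in (1, 2, 3):
        add(f"{base_id}.mc{mc}.motif_pct", f"cds:{tag} {sub} MC{mc} motif %",
            ref_class=shown_ref, alt_class=shown_alt,
            codon_position_filter=frozenset({mc}), denominator="motif_site_snvs")
    for syn, label in (("synonymous", "syn"), ("non-synonymous", "nonsyn")):
        add(f"{base_id}.{label}.pct", f"cds:{tag} {sub} {label} %",
            ref_class=shown_ref, alt_class=shown_alt, synonymy_filter=syn)
    # Any substitution at the motif site (site base fixed by the pattern).
    add(f"{base_id}.anysub.pct", f"cds:{tag} {shown_ref}>N %",
        ref_class=shown_ref, alt_class="N")
    for mc in (1, 2, 3):
        add(f"{base_id}.anysub.mc{mc}.pct", f"cds:{tag} {shown_ref}>N MC{mc}%",
            ref_class=shown_ref, alt_class="N",
            codon_position_filter=frozenset({mc}))
    return specs


def _global_specs() -> list[MetricSpec]:
    specs = [
        MetricSpec("burden.count", "cds:total SNV count", denominator="none", unit="count"),
        MetricSpec("ti.pct", "cds:transitions %", substitution_class_filter=TRANSITION),
        MetricSpec("tv.pct", "cds:transversions %", substitution_class_filter=TRANSVERSION),
        MetricSpec("syn.pct", "cds:synonymous %", synonymy_filter="synonymous"),
        MetricSpec("nonsyn.pct", "cds:non-synonymous %", synonymy_filter="non-synonymous"),
    ]
    for mc in (1, 2, 3):
        specs.append(MetricSpec(f"mc{mc}.pct", f"cds:MC{mc}%",
                                codon_position_filter=frozenset({mc})))
        specs.append(MetricSpec(f"ti.mc{mc}.pct", f"cds:transitions MC{mc}%",
                                substitution_class_filter=TRANSITION,
                                codon_position_filter=frozenset({mc})))
        specs.append(MetricSpec(f"tv.mc{mc}.pct", f"cds:transversions MC{mc}%",
                                substitution_class_filter=TRANSVERSION,
                                codon_position_filter=frozenset({mc})))
        specs.append(MetricSpec(f"syn.mc{mc}.pct", f"cds:synonymous MC{mc}%",
                                synonymy_filter="synonymous",
                                codon_position_filter=frozenset({mc})))
    for ref, alt in _SUBSTITUTIONS:
        specs.append(MetricSpec(f"sub.{ref}{alt}.pct", f"cds:{ref}>{alt} %",
                                ref_class=ref, alt_class=alt))
    specs.append(MetricSpec("ti.fraction", "cds:transition fraction",
                            substitution_class_filter=TRANSITION,
                            denominator="total_cds_snvs", unit="ratio"))
    return specs


def default_catalog() -> list[MetricSpec]:
    """The shipped 142-metric panel.

    8 motif/strand-mode blocks × 14 qualifier combinations (112) plus 30
    global burden / substitution-spectrum / codon-position / synonymy
    summaries.
    """
    specs: list[MetricSpec] = []
    for enzyme in CORE_MOTIFS:
        for mode in ("coding", "reverse_complement"):
            specs.extend(_motif_mode_specs(enzyme, mode))
    specs.extend(_global_specs())
    assert len(specs) == 142, len(specs)
    return specs


# ---------------------------------------------------------------------------
# Catalog (de)serialisation
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: MetricSpec) -> dict:
    d: dict = {"metric_id": spec.metric_id, "display_name": spec.display_name}
    if spec.motif is not None:
        d["motif"] = {
            "name": spec.motif.name,
            "pattern": spec.motif.pattern,
            "site_index": spec.motif.site_index,
            "strand_mode": spec.motif.strand_mode,
        }
    d.update(
        ref_class=spec.ref_class,
        alt_class=spec.alt_class,
        codon_position_filter=(
            "any" if spec.codon_position_filter == "any"
            else sorted(spec.codon_position_filter)
        ),
        synonymy_filter=spec.synonymy_filter,
        substitution_class_filter=spec.substitution_class_filter,
        denominator=spec.denominator,
        unit=spec.unit,
    )
    return d


def save_catalog(catalog: Sequence[MetricSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"metrics": [_spec_to_dict(s) for s in catalog]}, fh, sort_keys=False)


def load_catalog(config_source: str | Path) -> list[MetricSpec]:
    """Load and validate a metric catalog from its YAML schema.

    Schema: top-level mapping with a ``metrics`` list; each entry carries the
    MetricSpec fields, with ``motif`` an optional nested mapping
    (name/pattern/site_index/strand_mode) and ``codon_position_filter``
    either "any" or a list drawn from [1, 2, 3].
    """
    with open(config_source) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "metrics" not in doc:
        raise ValueError("catalog config must be a mapping with a 'metrics' list")
    specs: list[MetricSpec] = []
    for i, entry in enumerate(doc["metrics"]):
        if not isinstance(entry, dict):
            raise ValueError(f"metrics[{i}] is not a mapping")
        for key in ("metric_id", "display_name"):
            if key not in entry:
                raise ValueError(f"metrics[{i}] missing required field '{key}'")
        motif = None
        if entry.get("motif") is not None:
            m = entry["motif"]
            for key in ("name", "pattern", "site_index"):
                if key not in m:
                    raise ValueError(
                        f"metrics[{i}].motif missing required field '{key}'"
                    )
            motif = MotifSpec(m["name"], m["pattern"], int(m["site_index"]),
                              m.get("strand_mode", "coding"))
        cpf = entry.get("codon_position_filter", "any")
        if cpf != "any":
            cpf = frozenset(int(x) for x in cpf)
        specs.append(MetricSpec(
            metric_id=str(entry["metric_id"]),
            display_name=str(entry["display_name"]),
            motif=motif,
            ref_class=entry.get("ref_class", "N"),
            alt_class=entry.get("alt_class", "N"),
            codon_position_filter=cpf,
            synonymy_filter=entry.get("synonymy_filter", "any"),
            substitution_class_filter=entry.get("substitution_class_filter", "any"),
            denominator=entry.get("denominator", "total_cds_snvs"),
            unit=entry.get("unit", "percent"),
        ))
    ids = [s.metric_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate metric_id in catalog config")
    return specs
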