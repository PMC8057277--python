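"""Cohort construction: PFS thresholding, High/Low labelling, stratified splits.

Patients are binarised per cancer type against a threshold derived from the
cohort's median progression-free survival (PFS) rounded to the nearest
6-month increment, with optional per-cancer overrides.  Splits into
training / tuning / validation partitions are stratified by label and use
deterministic largest-remainder allocation on a seeded shuffle, so a seed
fully reproduces an assignment.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import ClinicalRecord

logger = logging.getLogger(__name__)

HIGH = "High"
LOW = "Low"

PARTITIONS = ("train", "tune", "validation")
DEFAULT_FRACTIONS = (0.75, 0.10, 0.15)


@dataclass(frozen=True)
class CohortSummary:
    cancer_type: str
    median_pfs_months: float
    pfs_threshold_months: int
    n_included: int
    n_above: int
    n_below: int


@dataclass(frozen=True)
class SplitAssignment:
    cancer_type: str
    seed: int
    fractions: tuple[float, float, float]
    assignment: Mapping[str, str]  # patient_id -> partition
    eligible: bool

    def partition(self, name: str) -> list[str]:
        return [p for p, part in self.assignment.items() if part == name]


def compute_threshold(median_pfs_months: float, override: int | None = None) -> int:
    """PFS threshold in months: nearest multiple of 6, ties rounded up.

    An explicit ``override`` (e.g. a literature-derived threshold) wins.
    The result is clamped to a minimum of 6 months.
    """
    if override is not None:
        return int(override)
    if median_pfs_months <= 0:
        raise ValueError("median PFS must be positive")
    rounded = 6 * int(np.floor(median_pfs_months / 6 + 0.5))
    return max(6, rounded)


def label_pfs(record: ClinicalRecord, threshold_months: int) -> str:
    """Low iff progression occurred strictly before the threshold."""
    return LOW if record.pfs_months < threshold_months else HIGH


def summarize_cohort(
    records: Sequence[ClinicalRecord], threshold_months: int
) -> CohortSummary:
    if not records:
        raise ValueError("empty cohort")
    types = {r.cancer_type for r in records}
    if len(types) != 1:
        raise ValueError(f"records span multiple cancer types: {sorted(types)}")
    labels = [label_pfs(r, threshold_months) for r in records]
    n_above = labels.count(HIGH)
    return CohortSummary(
        cancer_type=types.pop(),
        median_pfs_months=float(np.median([r.pfs_months for r in records])),
        pfs_threshold_months=threshold_months,
        n_included=len(records),
        n_above=n_above,
        n_below=len(records) - n_above,
    )


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n items to len(fractions) bins, preserving order ties
    by largest fractional remainder (earlier bin wins exact ties)."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def stratified_split(
    labels: Mapping[str, str],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    cancer_type: str = "",
) -> SplitAssignment:
    """Partition patients into train/tune/validation, stratified by label.

    Within each label class, patients are shuffled with a NumPy generator
    seeded by ``seed`` and allocated to partitions by largest-remainder
    rounding of fraction × class size, so per-class counts differ from exact
    proportionality by at most one patient.  ``eligible`` is False when any
    class is absent from the tune or validation partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    eligible = True
    for cls in sorted(set(labels.values())):
        members = sorted(p for p, l in labels.items() if l == cls)
        rng.shuffle(members)
        counts = _largest_remainder(len(members), fractions)
        if counts[1] == 0 or counts[2] == 0:
            eligible = False
        idx = 0
        for part, k in zip(PARTITIONS, counts):
            for p in members[idx : idx + k]:
                assignment[p] = part
            idx += k
    return SplitAssignment(
        cancer_type=cancer_type,
        seed=seed,
        fractions=tuple(fractions),
        assignment=assignment,
        eligible=eligible,
    )


def apply_eligibility(
    splits: Mapping[str, SplitAssignment]
) -> tuple[list[str], list[tuple[str, str]]]:
    """Retain cohorts whose splits are viable; exclude the rest with reasons."""
    retained, excluded = [], []
    for ctype in sorted(splits):
        if splits[ctype].eligible:
            retained.append(ctype)
        else:
            excluded.append((ctype, "empty tune/validation class"))
            logger.info("cohort %s excluded: empty tune/validation class", ctype)
    return retained, excluded


# ---------------------------------------------------------------------------
# Reference cohort-parameter fixture
# ---------------------------------------------------------------------------


def load_reference_cohorts() -> pd.DataFrame:
    """The packaged per-cancer cohort parameter table.

    Columns: cancer_type, abbreviation, median_pfs_months,
    pfs_threshold_months, n_included, n_above, n_below.  The printed
    thresholds serve as the per-cancer override table; a handful were set
    from the literature rather than the rounding rule.
    """
    ref = importlib.resources.files("tsmpanel.data") / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def threshold_overrides() -> dict[str, int]:
    """abbreviation -> printed PFS threshold, for use as compute_threshold overrides."""
    df = load_reference_cohorts()
    return dict(zip(df["abbreviation"], df["pfs_threshold_months"].astype(int)))
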