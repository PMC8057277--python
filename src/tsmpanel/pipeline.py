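"""End-to-end orchestration: profile → cohort → cross-validate → survival → sweep.

``run_full`` wires the stage modules together for every cancer type present
in the clinical table, records an auditable manifest (seeds, per-stage
counts, exclusions with reasons, output paths), and writes per-stage TSV/JSON
artefacts.  Per-cancer-type seeds are derived as
``base_seed + crc32(cancer_type)`` (mod 2^31) so adding a cohort never
perturbs another cohort's results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import metrics as metrics_mod
from . import models as models_mod
from . import reference as ref_mod
from . import survival as surv_mod

logger = logging.getLogger(__name__)

DEFAULT_GRID = (6, 12, 24, 36, 48, 60)


@dataclass
class RunConfig:
    transcripts: str
    variants: str
    clinical: str
    outdir: str
    genome: str | None = None
    variant_format: str = "vcf"
    catalog: str | None = None
    fractions: tuple[float, float, float] = cohort_mod.DEFAULT_FRACTIONS
    n_iterations: int = 20
    base_seed: int = 0
    threshold_overrides: dict[str, int] = field(default_factory=dict)
    threshold_grid: tuple[int, ...] = DEFAULT_GRID
    sweep_folds: int = 10
    run_sweep: bool = True
    search_budget: int = 30
    log_level: str = "INFO"


def cohort_seed(base_seed: int, cancer_type: str) -> int:
    return int((base_seed + zlib.crc32(cancer_type.encode())) % 2**31)


def build_profiles(
    transcripts: Sequence[ref_mod.TranscriptModel],
    snvs: Sequence[ref_mod.SomaticSNV],
    catalog: Sequence[metrics_mod.MetricSpec],
) -> tuple[pd.DataFrame, ref_mod.MappingSummary]:
    """Map all SNVs and evaluate the catalog per patient."""
    summary = ref_mod.map_cohort(snvs, transcripts)
    by_patient: dict[str, list[ref_mod.MutationContext]] = {}
    for ctx in summary.contexts:
        by_patient.setdefault(ctx.snv.patient_id, []).append(ctx)
    profiles = [
        metrics_mod.build_profile(pid, ctxs, catalog)
        for pid, ctxs in sorted(by_patient.items())
    ]
    return metrics_mod.profiles_to_frame(profiles), summary


def threshold_sweep(
    records: Sequence[ref_mod.ClinicalRecord],
    profiles: pd.DataFrame,
    feature_cols: Sequence[str],
    grid: Sequence[int] = DEFAULT_GRID,
    folds: int = 10,
    fractions: Sequence[float] = cohort_mod.DEFAULT_FRACTIONS,
    space: models_mod.HyperparameterSpace | None = None,
    base_seed: int = 0,
    cancer_type: str = "",
) -> pd.DataFrame:
    """Re-label the cohort at each grid threshold and cross-validate.

    Grid points whose relabelling yields an ineligible cohort (an empty
    class, or an empty tune/validation partition at every seed) are reported
    absent.  Returns a table (threshold_months, n_models, mean_kappa,
    mean_accuracy), absent points excluded.
    """
    rows = []
    for threshold in grid:
        labels = {r.patient_id: cohort_mod.label_pfs(r, threshold) for r in records}
        if len(set(labels.values())) < 2:
            logger.info("%s: threshold %d gives a single class; absent", cancer_type, threshold)
            continue
        probe = cohort_mod.stratified_split(labels, fractions, seed=base_seed)
        if not probe.eligible:
            logger.info("%s: threshold %d ineligible; absent", cancer_type, threshold)
            continue
        results, _ = models_mod.cross_validate(
            profiles, labels, feature_cols,
            n_iterations=folds, fractions=fractions, space=space,
            base_seed=base_seed + threshold, cancer_type=cancer_type,
        )
        if not results:
            continue
        rows.append({
            "threshold_months": threshold,
            "n_models": len(results),
            "mean_kappa": float(np.mean([r.kappa for r in results])),
            "mean_accuracy": float(np.mean([r.accuracy for r in results])),
        })
    if not rows:
        logger.warning("%s: every grid threshold was ineligible", cancer_type)
        return pd.DataFrame(columns=["threshold_months", "n_models", "mean_kappa", "mean_accuracy"])
    return pd.DataFrame(rows)


def run_full(config: RunConfig) -> dict:
    """Execute every stage per cancer type; return (and write) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": [],
        "cohorts": {},
        "excluded": [],
    }

    def stage(name: str, **info) -> None:
        manifest["stages"].append({"stage": name, **info})

    # -- load ---------------------------------------------------------------
    transcripts = ref_mod.load_transcripts(config.transcripts, config.genome)
    snvs, n_dropped = ref_mod.load_snvs(config.variants, config.variant_format)
    records, excluded_clinical = ref_mod.load_clinical(config.clinical)
    manifest["excluded"].extend(
        {"patient_id": pid, "reason": reason} for pid, reason in excluded_clinical
    )
    stage("load", n_transcripts=len(transcripts), n_snvs=len(snvs),
          n_dropped_records=n_dropped, n_patients=len(records))

    # -- profile ------------------------------------------------------------
    catalog = (metrics_mod.load_catalog(config.catalog) if config.catalog
               else metrics_mod.default_catalog())
    profiles, mapping = build_profiles(transcripts, snvs, catalog)
    profiles_path = outdir / "profiles.tsv"
    profiles.to_csv(profiles_path, sep="\t")
    stage("profile", n_metrics=len(catalog), n_profiled=len(profiles),
          n_mapped=mapping.n_mapped, n_noncds=mapping.n_noncds,
          n_ref_mismatch=mapping.n_ref_mismatch, output=str(profiles_path))

    # Patients with no mapped CDS SNVs are excluded from modelling.
    with_snvs = set(profiles.index)
    for r in records:
        if r.patient_id not in with_snvs:
            manifest["excluded"].append(
                {"patient_id": r.patient_id, "reason": "no CDS somatic mutations"}
            )
    records = [r for r in records if r.patient_id in with_snvs]

    # -- cohort -------------------------------------------------------------
    by_type: dict[str, list[ref_mod.ClinicalRecord]] = {}
    for r in records:
        by_type.setdefault(r.cancer_type, []).append(r)
    feature_cols = [s.metric_id for s in catalog]
    space = models_mod.HyperparameterSpace(search_budget=config.search_budget)
    summaries, labels_by_type, splits = [], {}, {}
    for ctype, recs in sorted(by_type.items()):
        median = float(np.median([r.pfs_months for r in recs]))
        threshold = cohort_mod.compute_threshold(
            median, config.threshold_overrides.get(ctype)
        )
        summaries.append(cohort_mod.summarize_cohort(recs, threshold))
        labels = {r.patient_id: cohort_mod.label_pfs(r, threshold) for r in recs}
        labels_by_type[ctype] = (threshold, labels)
        if len(set(labels.values())) < 2:
            splits[ctype] = cohort_mod.SplitAssignment(ctype, 0, config.fractions, {}, False)
        else:
            splits[ctype] = cohort_mod.stratified_split(
                labels, config.fractions, seed=cohort_seed(config.base_seed, ctype),
                cancer_type=ctype,
            )
    summary_path = outdir / "cohort_summary.tsv"
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        summary_path, sep="\t", index=False
    )
    retained, excluded_cohorts = cohort_mod.apply_eligibility(splits)
    manifest["excluded"].extend(
        {"cancer_type": c, "reason": reason} for c, reason in excluded_cohorts
    )
    stage("cohort", n_cohorts=len(by_type), n_retained=len(retained), output=str(summary_path))

    # -- cross-validate -----------------------------------------------------
    rec_by_id = {r.patient_id: r for r in records}
    cv_rows = []
    for ctype in retained:
        threshold, labels = labels_by_type[ctype]
        seed = cohort_seed(config.base_seed, ctype)
        results, best = models_mod.cross_validate(
            profiles, labels, feature_cols,
            n_iterations=config.n_iterations, fractions=config.fractions,
            space=space, base_seed=seed, cancer_type=ctype,
        )
        entry: dict = {
            "seed": seed,
            "threshold_months": threshold,
            "n_iterations_run": len(results),
            "mean_accuracy": float(np.mean([r.accuracy for r in results])) if results else None,
            "sd_accuracy": float(np.std([r.accuracy for r in results], ddof=1)) if len(results) > 1 else None,
            "mean_kappa": float(np.mean([r.kappa for r in results])) if results else None,
        }
        for r in results:
            cv_rows.append({
                "cancer_type": ctype, "iteration": r.iteration,
                "accuracy": r.accuracy, "kappa": r.kappa,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "balanced_accuracy": r.balanced_accuracy,
                "agreement": models_mod.interpret_kappa(r.kappa),
            })
        # -- survival validation on the best model's validation predictions --
        if best is not None:
            best_result = results[best]
            entry["best_iteration"] = best_result.iteration
            entry["best_accuracy"] = best_result.accuracy
            entry["best_kappa"] = best_result.kappa
            predicted = {pid: lab for pid, (_, lab) in best_result.predictions.items()}
            curves, lr, significant = surv_mod.validate_predictions(predicted, rec_by_id)
            entry["logrank_statistic"] = lr.statistic
            entry["logrank_p"] = lr.p_value
            entry["logrank_evaluable"] = lr.evaluable
            entry["logrank_significant"] = significant
            if curves:
                km_frames = []
                for label, curve in curves.items():
                    frame = curve.to_frame()
                    frame.insert(0, "group", label)
                    km_frames.append(frame)
                pd.concat(km_frames).to_csv(outdir / f"km_{ctype}.tsv", sep="\t", index=False)
        manifest["cohorts"][ctype] = entry
    cv_path = outdir / "cross_validation.tsv"
    pd.DataFrame(cv_rows).to_csv(cv_path, sep="\t", index=False)
    stage("cross_validate", n_cohorts=len(retained), output=str(cv_path))
    stage("survival", n_evaluated=sum(1 for e in manifest["cohorts"].values()
                                      if "logrank_p" in e))

    # -- threshold sweep ----------------------------------------------------
    if config.run_sweep:
        sweep_frames = []
        for ctype in retained:
            table = threshold_sweep(
                by_type[ctype], profiles, feature_cols,
                grid=config.threshold_grid, folds=config.sweep_folds,
                fractions=config.fractions, space=space,
                base_seed=cohort_seed(config.base_seed, ctype), cancer_type=ctype,
            )
            table.insert(0, "cancer_type", ctype)
            sweep_frames.append(table)
        sweep_path = outdir / "threshold_sweep.tsv"
        if sweep_frames:
            pd.concat(sweep_frames).to_csv(sweep_path, sep="\t", index=False)
        stage("sweep", grid=list(config.threshold_grid), output=str(sweep_path))
    else:
        stage("sweep", skipped=True)

    stage("manifest")
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
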