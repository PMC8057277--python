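"""Gradient-boosted-tree outcome models and their evaluation.

Per cancer type, a binary classifier (gradient-boosted trees, logistic
objective) learns High/Low PFS labels from the patient metric profiles.
Hyperparameters are tuned by seeded random search against a tuning
partition with early stopping, and performance is reported on a held-out
validation partition over repeated stratified splits.  Agreement beyond
chance is summarised with Cohen's kappa:

    kappa = (po - pe) / (1 - pe)

where ``po`` is observed accuracy and ``pe`` the accuracy expected from the
confusion-matrix marginals alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .cohort import DEFAULT_FRACTIONS, HIGH, stratified_split

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperparameterSpace:
    """Random-search space for the booster; fixed values are sampled as-is."""

    eta: tuple[float, float] = (0.1, 0.3)
    gamma: float = 0.0
    subsample: float = 0.8
    max_depth: tuple[int, int] = (4, 12)
    min_child_weight: tuple[int, int] = (2, 8)
    colsample_bytree: tuple[float, float] = (0.5, 1.0)
    max_rounds: int = 250
    early_stopping_rounds: int = 50
    search_budget: int = 30

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "eta": float(rng.uniform(*self.eta)),
            "gamma": self.gamma,
            "subsample": self.subsample,
            "max_depth": int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            "min_child_weight": int(
                rng.integers(self.min_child_weight[0], self.min_child_weight[1] + 1)
            ),
            "colsample_bytree": float(rng.uniform(*self.colsample_bytree)),
        }


@dataclass
class ModelResult:
    cancer_type: str
    iteration: int
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN; High = positive
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    balanced_accuracy: float
    accuracy: float
    kappa: float
    predictions: dict[str, tuple[float, str]] = field(default_factory=dict)


def cohens_kappa(confusion: tuple[int, int, int, int]) -> float:
    """Chance-corrected agreement from a 2×2 confusion matrix (TP, FP, FN, TN)."""
    tp, fp, fn, tn = confusion
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


_KAPPA_BANDS = [
    (0.00, "slight agreement"),
    (0.21, "fair agreement"),
    (0.41, "moderate agreement"),
    (0.61, "substantial agreement"),
    (0.81, "almost perfect agreement"),
]


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch agreement band for a kappa value."""
    if kappa > 1:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0:
        return "not different to random chance"
    label = _KAPPA_BANDS[0][1]
    for lo, name in _KAPPA_BANDS:
        if kappa >= lo:
            label = name
    return label


def _to_matrix(profiles: pd.DataFrame, feature_cols: Sequence[str]) -> np.ndarray:
    return profiles[list(feature_cols)].to_numpy(dtype=float)


def tune_and_train(
    train_X: np.ndarray,
    train_y: np.ndarray,
    tune_X: np.ndarray,
    tune_y: np.ndarray,
    space: HyperparameterSpace | None = None,
    seed: int = 0,
) -> tuple[xgb.Booster, dict, float]:
    """Random-search the space; each candidate early-stops on tune error.

    Labels are 1 = High, 0 = Low.  Returns (booster, params, tune_error) for
    the candidate with the lowest tune-partition classification error (ties
    go to the earlier draw).
    """
    if len(set(train_y)) < 2:
        raise ValueError("training partition has a single class")
    space = space or HyperparameterSpace()
    rng = np.random.default_rng(seed)
    dtrain = xgb.DMatrix(train_X, label=train_y)
    dtune = xgb.DMatrix(tune_X, label=tune_y)
    best: tuple[float, int, xgb.Booster, dict] | None = None
    for i in range(space.search_budget):
        params = space.sample(rng)
        params.update(
            booster="gbtree",
            objective="binary:logistic",
            eval_metric="error",
            seed=int(rng.integers(0, 2**31 - 1)),
            nthread=1,
        )
        evals_result: dict = {}
        booster = xgb.train(
            params,
            dtrain,
            num_boost_round=space.max_rounds,
            evals=[(dtune, "tune")],
            early_stopping_rounds=space.early_stopping_rounds,
            evals_result=evals_result,
            verbose_eval=False,
        )
        err = float(min(evals_result["tune"]["error"]))
        if best is None or err < best[0]:
            best = (err, i, booster, params)
    assert best is not None
    return best[2], best[3], best[0]


def predict_labels(booster: xgb.Booster, X: np.ndarray, cutoff: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (score >= cutoff → High = 1)."""
    dm = xgb.DMatrix(X)
    iteration = (0, booster.best_iteration + 1) if hasattr(booster, "best_iteration") else None
    scores = booster.predict(dm, iteration_range=iteration)
    return scores, (scores >= cutoff).astype(int)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def _safe_div(a: float, b: float) -> float:
    return a / b if b else float("nan")


def evaluate_confusion(
    confusion: tuple[int, int, int, int], cancer_type: str = "", iteration: int = 0
) -> ModelResult:
    tp, fp, fn, tn = confusion
    n = tp + fp + fn + tn
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    return ModelResult(
        cancer_type=cancer_type,
        iteration=iteration,
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        balanced_accuracy=(sens + spec) / 2,
        accuracy=(tp + tn) / n,
        kappa=cohens_kappa(confusion),
    )


def cross_validate(
    profiles: pd.DataFrame,
    labels: Mapping[str, str],
    feature_cols: Sequence[str],
    n_iterations: int = 20,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    space: HyperparameterSpace | None = None,
    base_seed: int = 0,
    cancer_type: str = "",
) -> tuple[list[ModelResult], int | None]:
    """Repeated stratified-split cross-validation.

    Each iteration draws a fresh seeded train/tune/validation split, tunes
    and trains a booster, and evaluates it on the validation partition.
    Iterations whose validation partition loses a class are skipped with a
    warning.  Returns (results, best_iteration_index) where the best model
    has the highest accuracy, ties broken by kappa then by earliest
    iteration.
    """
    space = space or HyperparameterSpace()
    results: list[ModelResult] = []
    for it in range(n_iterations):
        seed = base_seed + it
        split = stratified_split(dict(labels), fractions, seed=seed, cancer_type=cancer_type)
        parts = {name: split.partition(name) for name in ("train", "tune", "validation")}
        y = {name: np.array([1 if labels[p] == HIGH else 0 for p in ids])
             for name, ids in parts.items()}
        if any(len(set(y[name])) < 2 for name in ("train", "tune", "validation")):
            logger.warning(
                "%s iteration %d skipped: partition with a single class", cancer_type, it
            )
            continue
        X = {name: _to_matrix(profiles.loc[ids], feature_cols) for name, ids in parts.items()}
        booster, _, _ = tune_and_train(
            X["train"], y["train"], X["tune"], y["tune"], space, seed=seed
        )
        scores, preds = predict_labels(booster, X["validation"])
        result = evaluate_confusion(
            confusion_counts(y["validation"], preds), cancer_type, it
        )
        result.predictions = {
            pid: (float(s), HIGH if p else "Low")
            for pid, s, p in zip(parts["validation"], scores, preds)
        }
        results.append(result)
    best = None
    if results:
        best = max(
            range(len(results)),
            key=lambda i: (results[i].accuracy, results[i].kappa, -results[i].iteration),
        )
    return results, best


def compare_burden(
    burden: Mapping[str, float], labels: Mapping[str, str]
) -> tuple[float, float]:
    """Welch two-sample t-test of total CDS SNV burden between High and Low.

    Degenerate zero-variance groups with equal means return (0.0, 1.0).
    """
    high = np.array([b for p, b in burden.items() if labels[p] == HIGH], dtype=float)
    low = np.array([b for p, b in burden.items() if labels[p] != HIGH], dtype=float)
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least two patients")
    if high.var(ddof=1) == 0 and low.var(ddof=1) == 0:
        if high.mean() == low.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(high, low, equal_var=False)
    return float(t), float(p)
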