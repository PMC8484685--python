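"""Prediction tables, ROC/PRC metrics with bootstrap CIs, and the
hypothesis-testing procedures used to compare models.

Predictions live in a tidy table with one row per tile set (a Panoptes tile
set counts as a single tile for all statistics).  Per-patient scores are the
arithmetic mean of a patient's tile-set scores; patient-level metrics treat
each patient as one sample point.  Confidence intervals are percentile
bootstrap over patients (per-patient level) or tile sets (per-tile level);
architecture comparisons use the 50-resample / 80%-subsample AUROC scheme
with a one-sided unpaired t-test.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import UndefinedMetricError

PRED_COLUMNS = ("patient_id", "slide_id", "tile_set_id", "score", "true_label")


def validate_predictions(preds: pd.DataFrame, check_unique: bool = True) -> pd.DataFrame:
    for c in PRED_COLUMNS:
        if c not in preds.columns:
            raise ValueError(f"prediction table missing column {c!r}")
    if len(preds) and (preds["score"].min() < 0 or preds["score"].max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    # bootstrap resamples legitimately repeat tile sets; uniqueness is only
    # demanded of user-facing tables
    if check_unique and preds["tile_set_id"].duplicated().any():
        raise ValueError("one row per tile set required")
    return preds


def predictions_from_model(model, dataset, batch_size: int = 64) -> pd.DataFrame:
    """Score a dataset with a trained model into a prediction table."""
    scores = []
    use_clin = getattr(model, "clinical", None) is not None
    for i in range(0, len(dataset), batch_size):
        idx = np.arange(i, min(i + batch_size, len(dataset)))
        p = model.predict_proba(dataset.batch(idx, clinical=use_clin))[:, 1]
        scores.append(p)
    return pd.DataFrame(
        {
            "patient_id": dataset.patient_ids,
            "slide_id": dataset.slide_ids,
            "tile_set_id": dataset.tile_set_ids,
            "score": np.concatenate(scores) if scores else np.empty(0),
            "true_label": dataset.labels,
        }
    )


def patient_scores(preds: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: mean tile-set score and the patient's label."""
    validate_predictions(preds, check_unique=False)
    if preds.empty:
        raise ValueError("empty prediction table")
    out = (
        preds.groupby("patient_id")
        .agg(score=("score", "mean"), true_label=("true_label", "first"))
        .reset_index()
    )
    return out


def classify(score: float | np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Positive iff score strictly exceeds the cutoff."""
    return (np.asarray(score) > cutoff).astype(int)


def _check_two_class(y) -> None:
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("metric undefined with a single class present")


def auroc(table: pd.DataFrame) -> float:
    """Area under the ROC curve (Mann-Whitney probability, ties count 1/2)."""
    _check_two_class(table["true_label"])
    return float(roc_auc_score(table["true_label"], table["score"]))


def aupr(table: pd.DataFrame) -> float:
    """Average precision over recall steps."""
    _check_two_class(table["true_label"])
    return float(average_precision_score(table["true_label"], table["score"]))


def accuracy(table: pd.DataFrame, cutoff: float = 0.5) -> float:
    return float((classify(table["score"].values, cutoff) == table["true_label"].values).mean())


def confusion_metrics(table: pd.DataFrame, cutoff: float = 0.5) -> dict[str, float]:
    y = table["true_label"].values
    yhat = classify(table["score"].values, cutoff)
    tp = int(((y == 1) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())

    def _safe(a, b):
        return float(a / b) if b else float("nan")

    precision = _safe(tp, tp + fp)
    recall = _safe(tp, tp + fn)
    return {
        "sensitivity": recall,
        "specificity": _safe(tn, tn + fp),
        "precision": precision,
        "recall": recall,
        "f1": _safe(2 * precision * recall, precision + recall)
        if not (np.isnan(precision) or np.isnan(recall))
        else float("nan"),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def bootstrap_ci(
    table: pd.DataFrame,
    metric: Callable[[pd.DataFrame], float],
    level: str = "per_patient",
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI of a metric.

    Resampling is with replacement over patients (``per_patient``) or tile
    sets (``per_tile``); resamples containing a single class are redrawn.
    """
    rng = np.random.default_rng(seed)
    if level == "per_patient":
        units = table["patient_id"].unique()
        grouped = {p: g for p, g in table.groupby("patient_id")}
    elif level == "per_tile":
        units = np.arange(len(table))
    else:
        raise ValueError(f"unknown level {level!r}")
    vals = []
    redraws = 0
    while len(vals) < n_boot:
        pick = rng.choice(len(units), len(units), replace=True)
        if level == "per_patient":
            sub = pd.concat([grouped[units[i]] for i in pick], ignore_index=True)
        else:
            sub = table.iloc[pick]
        if sub["true_label"].nunique() < 2:
            redraws += 1
            if redraws > max_redraws:
                raise UndefinedMetricError(
                    "bootstrap cannot find two-class resamples"
                )
            continue
        vals.append(metric(sub))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class MetricsReport:
    """Point metrics with bootstrap CIs at one aggregation level."""

    level: str
    n_pos: int
    n_neg: int
    auroc: Optional[float]
    auroc_ci: Optional[tuple[float, float]]
    aupr: Optional[float]
    aupr_ci: Optional[tuple[float, float]]
    accuracy: float
    accuracy_ci: Optional[tuple[float, float]]
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    preds: pd.DataFrame,
    level: str = "per_patient",
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Full MetricsReport at the requested level.

    ``per_patient`` first averages each patient's tile-set scores; CIs are
    bootstrapped over the corresponding sampling unit.  Metrics undefined for
    a single-class table are reported as missing rather than zero.
    """
    validate_predictions(preds)
    table = patient_scores(preds) if level == "per_patient" else preds
    # CI resampling always operates on the tile-level table so patient
    # resamples recompute the patient means from their tiles
    def _lifted(metric):
        def f(sub):
            t = patient_scores(sub) if level == "per_patient" else sub
            return metric(t)

        return f

    y = table["true_label"].values
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    cm = confusion_metrics(table)
    try:
        auc = auroc(table)
        auc_ci = bootstrap_ci(preds, _lifted(auroc), level, n_boot, seed)
        ap = aupr(table)
        ap_ci = bootstrap_ci(preds, _lifted(aupr), level, n_boot, seed + 1)
    except UndefinedMetricError:
        auc = auc_ci = ap = ap_ci = None
    acc = accuracy(table)
    acc_ci = bootstrap_ci(preds, _lifted(accuracy), level, n_boot, seed + 2) if auc is not None else None
    return MetricsReport(
        level=level,
        n_pos=n_pos,
        n_neg=n_neg,
        auroc=auc,
        auroc_ci=auc_ci,
        aupr=ap,
        aupr_ci=ap_ci,
        accuracy=acc,
        accuracy_ci=acc_ci,
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        precision=cm["precision"],
        recall=cm["recall"],
        f1=cm["f1"],
    )


def wilcoxon_tiles(preds: pd.DataFrame) -> float:
    """One-sided rank-sum p-value: positive tiles score higher.

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise (the unpaired Mann-Whitney form; the two tile
    groups have unequal sizes).
    """
    validate_predictions(preds, check_unique=False)
    _check_two_class(preds["true_label"])
    pos = preds.loc[preds["true_label"] == 1, "score"].values
    neg = preds.loc[preds["true_label"] == 0, "score"].values
    small = max(len(pos), len(neg)) <= 20
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < len(pos) + len(neg)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(pos, neg, alternative="greater", method=method)
    return float(res.pvalue)


def compare_architectures(
    preds_a: pd.DataFrame,
    preds_b: pd.DataFrame,
    level: str = "per_patient",
    n_resamples: int = 50,
    sample_rate: float = 0.8,
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One-sided test that model A outranks model B on the same test split.

    Each model's table is subsampled 50 times at an 80% rate *without*
    replacement (over patients or tile sets per ``level``); the AUROC of each
    subsample feeds an unpaired one-sided two-sample t-test of A > B.
    Returns (p_value, aurocs_a, aurocs_b).
    """

    def _resample_aurocs(preds, rng):
        validate_predictions(preds, check_unique=False)
        table = patient_scores(preds) if level == "per_patient" else preds
        n = len(table)
        k = max(int(round(sample_rate * n)), 2)
        vals = []
        guard = 0
        while len(vals) < n_resamples:
            idx = rng.choice(n, k, replace=False)
            sub = table.iloc[idx]
            if sub["true_label"].nunique() < 2:
                guard += 1
                if guard > 1000:
                    raise UndefinedMetricError("cannot draw two-class subsamples")
                continue
            vals.append(auroc(sub))
        return np.asarray(vals)

    a = _resample_aurocs(preds_a, np.random.default_rng(seed))
    b = _resample_aurocs(preds_b, np.random.default_rng(seed + 1))
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
        p = 0.5 if np.isclose(a.mean(), b.mean()) else (0.0 if a.mean() > b.mean() else 1.0)
    else:
        p = float(sp_stats.ttest_ind(a, b, alternative="greater", equal_var=False).pvalue)
    return p, a, b
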