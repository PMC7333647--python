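"""Class-weighted logistic prediction with repeated stratified-split
evaluation, averaged ROC/PR curves, corner-distance cutoffs, feature
importance, U-test highlighting, and exemplar selection.

The 95% interval reported for each aggregate metric is the
normal-approximation confidence interval of the *mean* across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from .assoc_stats import mann_whitney_u

__all__ = [
    "LogisticModel",
    "AveragedCurve",
    "EvaluationResult",
    "zscore_columns",
    "class_weights",
    "fit_weighted_logistic",
    "repeated_split_evaluate",
    "average_curves",
    "optimal_cutoff",
    "u_test_and_top_third",
    "select_exemplars",
]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def zscore_columns(X: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Standardize every column to mean 0, SD 1 (population SD).

    Raises a ValueError naming the first zero-variance column.
    """
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=float)
        names = list(X.columns)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"column {j}" for j in range(arr.shape[1])]
    sd = arr.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance column: {names[bad[0]]}")
    out = (arr - arr.mean(axis=0)) / sd
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


def class_weights(y: Sequence[int]) -> dict[int, float]:
    """Per-class weight = n_samples / (n_classes * n_in_class)."""
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    n = y.size
    return {int(c): float(n / (classes.size * k)) for c, k in zip(classes, counts)}


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision(X)
        return 1.0 / (1.0 + np.exp(-z))


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: Optional[Mapping[int, float]] = None,
    ridge_c: float = 1000.0,
) -> LogisticModel:
    """Maximum weighted likelihood with weak L2 stabilization (C=1000)."""
    clf = LogisticRegression(
        C=ridge_c,
        class_weight=dict(weights) if weights is not None else None,
        solver="lbfgs",
        max_iter=5000,
    )
    clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return LogisticModel(
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0].astype(float),
    )


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------


@dataclass
class AveragedCurve:
    kind: str  # "ROC" or "PR"
    x: np.ndarray  # FPR (ROC) or recall (PR) grid
    y: np.ndarray  # mean TPR or mean precision
    thresholds: np.ndarray  # mean decision threshold at each grid point

    def auc(self) -> float:
        return float(np.trapezoid(self.y, self.x))


def _step_interp(
    grid: np.ndarray, x: np.ndarray, y: np.ndarray, thr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous step interpolation of (x, y, threshold) onto grid.

    ``x`` must be sorted ascending; for each grid point the value at the
    largest x <= grid point is taken.
    """
    idx = np.searchsorted(x, grid, side="right") - 1
    idx = np.clip(idx, 0, x.size - 1)
    return y[idx], thr[idx]


def average_curves(
    curves: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    kind: str,
    grid_points: int = 101,
) -> AveragedCurve:
    """Vertically average (x, y, threshold) curves on a fixed x grid."""
    if kind not in ("ROC", "PR"):
        raise ValueError("kind must be 'ROC' or 'PR'")
    if len(curves) == 0:
        raise ValueError("no curves to average")
    grid = np.linspace(0.0, 1.0, grid_points)
    ys = np.empty((len(curves), grid_points))
    ts = np.empty((len(curves), grid_points))
    for i, (x, y, thr) in enumerate(curves):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        thr = np.asarray(thr, dtype=float)
        order = np.argsort(x, kind="stable")
        ys[i], ts[i] = _step_interp(grid, x[order], y[order], thr[order])
    return AveragedCurve(kind=kind, x=grid, y=ys.mean(axis=0), thresholds=ts.mean(axis=0))


def optimal_cutoff(curve: AveragedCurve) -> tuple[float, tuple[float, float]]:
    """Corner-distance optimal operating point.

    ROC: point closest to (0, 1); PR: point closest to (1, 1).  Ties break
    toward the lower threshold.  Returns (threshold, (x, y)).
    """
    corner = (0.0, 1.0) if curve.kind == "ROC" else (1.0, 1.0)
    d = np.hypot(curve.x - corner[0], curve.y - corner[1])
    best = np.flatnonzero(d == d.min())
    idx = best[np.argmin(curve.thresholds[best])]
    return float(curve.thresholds[idx]), (float(curve.x[idx]), float(curve.y[idx]))


# ---------------------------------------------------------------------------
# Repeated-split evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    metrics: pd.DataFrame  # per-repetition accuracy/sensitivity/specificity/AUCs
    summary: dict  # mean and 95% CI of the mean per metric
    importance: pd.Series  # per-feature coefficient sums over repetitions
    mean_probability: pd.Series  # per-sample mean held-out probability
    roc_curve: AveragedCurve
    pr_curve: AveragedCurve
    roc_cutoff: tuple[float, tuple[float, float]]
    pr_cutoff: tuple[float, tuple[float, float]]
    repetitions: int = 0


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    m = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return m, m - 1.96 * se, m + 1.96 * se


def repeated_split_evaluate(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    repetitions: int = 1000,
    test_fraction: float = 0.2,
    master_seed: int = 0,
    ridge_c: float = 1000.0,
    grid_points: int = 101,
) -> EvaluationResult:
    """Stratified 80/20 split, weighted-logistic fit, score; repeated.

    Per repetition the test metrics (accuracy, sensitivity, specificity,
    ROC-AUC, PR-AUC) and fitted coefficients are recorded; aggregates are
    means with normal-approximation 95% CIs, coefficient-sum importances,
    averaged ROC/PR curves with corner-distance cutoffs, and per-sample
    mean probability over the repetitions in which the sample was held out.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        index = list(X.index)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(arr.shape[1])]
        index = list(range(arr.shape[0]))
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 members to stratify")

    splitter = StratifiedShuffleSplit(
        n_splits=repetitions, test_size=test_fraction, random_state=master_seed
    )
    records = []
    coef_sum = np.zeros(arr.shape[1])
    prob_sum = np.zeros(arr.shape[0])
    prob_n = np.zeros(arr.shape[0])
    roc_curves, pr_curves = [], []
    from sklearn.metrics import auc as _auc

    for train_idx, test_idx in splitter.split(arr, y):
        Xtr, ytr = arr[train_idx], y[train_idx]
        Xte, yte = arr[test_idx], y[test_idx]
        model = fit_weighted_logistic(
            Xtr, ytr, weights=class_weights(ytr), ridge_c=ridge_c
        )
        probs = model.predict_proba(Xte)
        pred = (probs >= 0.5).astype(int)
        tp = int(((pred == 1) & (yte == 1)).sum())
        tn = int(((pred == 0) & (yte == 0)).sum())
        fp = int(((pred == 1) & (yte == 0)).sum())
        fn = int(((pred == 0) & (yte == 1)).sum())
        n_pos, n_neg = tp + fn, tn + fp
        fpr, tpr, roc_thr = roc_curve(yte, probs)
        roc_thr = np.clip(roc_thr, 0.0, 1.0)
        prec, rec, pr_thr = precision_recall_curve(yte, probs)
        # align threshold arrays with curve points
        pr_thr = np.concatenate([pr_thr, [1.0]])
        records.append(
            {
                "accuracy": (tp + tn) / yte.size,
                "sensitivity": tp / n_pos if n_pos else np.nan,
                "specificity": tn / n_neg if n_neg else np.nan,
                "roc_auc": _auc(fpr, tpr),
                "pr_auc": float(np.trapezoid(prec[::-1], rec[::-1])),
            }
        )
        coef_sum += model.coefficients
        prob_sum[test_idx] += probs
        prob_n[test_idx] += 1
        roc_curves.append((fpr, tpr, roc_thr))
        pr_curves.append((rec, prec, pr_thr))

    metrics = pd.DataFrame(records)
    summary = {}
    for col in metrics.columns:
        m, lo, hi = _mean_ci(metrics[col].to_numpy())
        summary[col] = {"mean": m, "ci95": [lo, hi]}
    mean_prob = np.divide(
        prob_sum, prob_n, out=np.full_like(prob_sum, np.nan), where=prob_n > 0
    )
    roc_avg = average_curves(roc_curves, "ROC", grid_points)
    pr_avg = average_curves(pr_curves, "PR", grid_points)
    return EvaluationResult(
        metrics=metrics,
        summary=summary,
        importance=pd.Series(coef_sum, index=names, name="importance"),
        mean_probability=pd.Series(mean_prob, index=index, name="mean_probability"),
        roc_curve=roc_avg,
        pr_curve=pr_avg,
        roc_cutoff=optimal_cutoff(roc_avg),
        pr_cutoff=optimal_cutoff(pr_avg),
        repetitions=repetitions,
    )


# ---------------------------------------------------------------------------
# Feature highlighting and exemplars
# ---------------------------------------------------------------------------


def u_test_and_top_third(
    importances: pd.Series,
    X: pd.DataFrame,
    y: Sequence[int],
    alpha: float = 0.05,
) -> list[str]:
    """Features significant in the two-sided U-test AND ranked in the top
    third by |importance| (quota = floor(k/3))."""
    y = np.asarray(y, dtype=int)
    k = len(importances)
    quota = k // 3
    ranked = importances.abs().sort_values(ascending=False)
    top = set(ranked.index[:quota])
    out = []
    for feat in importances.index:
        if feat not in top:
            continue
        _, p = mann_whitney_u(
            X.loc[y == 1, feat].to_numpy(), X.loc[y == 0, feat].to_numpy()
        )
        if p < alpha:
            out.append(feat)
    return out


def best_slice(mask: np.ndarray) -> int:
    """Axial (last-axis) slice index maximizing in-slice ROI area; lowest
    index on ties."""
    areas = np.asarray(mask, dtype=bool).sum(axis=(0, 1))
    return int(np.argmax(areas))


def select_exemplars(
    features: pd.DataFrame,
    highlighted: Sequence[str],
    mean_probability: pd.Series,
    masks: Mapping[str, np.ndarray],
) -> dict:
    """Exemplar descriptors: per highlighted feature the patients attaining
    its max/min value, and for the model the patients with max/min mean
    held-out probability, each with its best axial slice index."""
    if len(features) == 0:
        raise ValueError("empty cohort")

    def descriptor(pid: str, value: float) -> dict:
        return {
            "patient_id": str(pid),
            "value": float(value),
            "slice_index": best_slice(masks[pid]) if pid in masks else None,
        }

    out: dict = {"features": {}, "model": {}}
    for feat in highlighted:
        col = features[feat]
        out["features"][feat] = {
            "max": descriptor(col.idxmax(), col.max()),
            "min": descriptor(col.idxmin(), col.min()),
        }
    probs = mean_probability.dropna()
    out["model"] = {
        "max": descriptor(probs.idxmax(), probs.max()),
        "min": descriptor(probs.idxmin(), probs.min()),
    }
    return out
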