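"""Stability feature selection via repeated cross-validated Lasso.

Each repetition runs a linear-response Lasso on the 0/1 label with the
penalty chosen by stratified, shuffled 5-fold CV over a 100-point
log-spaced path from ``lambda_max = max|X'(y - ybar)| / n`` down to
``lambda_max * 1e-3``.  Features are ranked by how often they receive a
nonzero coefficient across repetitions; the final subset keeps the top
``round(sqrt(n))`` of them.

Rows are put into a canonical order (sorted by label then feature values)
before fold splitting, so results are invariant to the order patients are
supplied in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "lasso_cv_once",
    "repeat_selection",
    "truncate_top_sqrt_n",
    "feature_correlation_map",
]


@dataclass
class SelectionResult:
    """Per-feature selection counts and coefficient sums over repetitions."""

    table: pd.DataFrame  # columns: feature, selection_count, coefficient_sum
    repetitions: int

    def ranked(self) -> pd.DataFrame:
        t = self.table.copy()
        t["abs_coefficient_sum"] = t["coefficient_sum"].abs()
        t = t.sort_values(
            by=["selection_count", "abs_coefficient_sum", "feature"],
            ascending=[False, False, True],
            kind="stable",
        ).drop(columns="abs_coefficient_sum")
        t["rank"] = np.arange(1, len(t) + 1)
        return t.reset_index(drop=True)


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)] + [y]
    return np.lexsort(keys)


def _alpha_path(
    X: np.ndarray, y: np.ndarray, n_alphas: int, min_ratio: float
) -> np.ndarray:
    n = X.shape[0]
    alpha_max = np.abs(X.T @ (y - y.mean())).max() / n
    if alpha_max <= 0:
        return np.array([])
    return np.logspace(
        np.log10(alpha_max), np.log10(alpha_max * min_ratio), n_alphas
    )


def lasso_cv_once(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    feature_names: list[str] | None = None,
) -> dict[str, float]:
    """One cross-validated Lasso run; returns {feature: nonzero coefficient}.

    ``X`` must be column-standardized.  A constant label yields an empty
    selection (the penalty path degenerates at lambda_max = 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]

    classes, counts = np.unique(y, return_counts=True)
    if classes.size > 1 and counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= {folds} folds"
        )

    order = _canonical_order(X, y)
    X, y = X[order], y[order]

    alphas = _alpha_path(X, y, n_alphas, alpha_min_ratio)
    if alphas.size == 0:
        return {}

    cv_err = np.zeros(alphas.size)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # the small-alpha end of the path may stop at max_iter; it almost
        # never wins CV and the duality gap there is immaterial
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, val_idx in splitter.split(X, y):
            Xtr, ytr = X[train_idx], y[train_idx]
            Xval, yval = X[val_idx], y[val_idx]
            x_mean, y_mean = Xtr.mean(axis=0), ytr.mean()
            _, coefs, _ = lasso_path(
                Xtr - x_mean, ytr - y_mean, alphas=alphas, max_iter=5000
            )
            preds = (Xval - x_mean) @ coefs + y_mean  # (n_val, n_alphas)
            cv_err += ((preds - yval[:, None]) ** 2).sum(axis=0)
    best_alpha = float(alphas[np.argmin(cv_err)])

    model = Lasso(alpha=best_alpha, fit_intercept=True, max_iter=50_000)
    model.fit(X, y)
    # coordinate descent can leave coefficients at rounding-noise level
    return {
        feature_names[j]: float(c)
        for j, c in enumerate(model.coef_)
        if abs(c) > 1e-10
    }


def repeat_selection(
    X: np.ndarray,
    y: np.ndarray,
    repetitions: int = 100,
    master_seed: int = 0,
    folds: int = 5,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Repeat :func:`lasso_cv_once` with reshuffled folds; accumulate counts
    and coefficient sums per feature."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    counts = dict.fromkeys(feature_names, 0)
    sums = dict.fromkeys(feature_names, 0.0)
    seeds = np.random.SeedSequence(master_seed).generate_state(repetitions)
    for rep in range(repetitions):
        selected = lasso_cv_once(
            X,
            y,
            folds=folds,
            seed=int(seeds[rep] % (2**31 - 1)),
            n_alphas=n_alphas,
            alpha_min_ratio=alpha_min_ratio,
            feature_names=feature_names,
        )
        for name, coef in selected.items():
            counts[name] += 1
            sums[name] += coef
    table = pd.DataFrame(
        {
            "feature": feature_names,
            "selection_count": [counts[f] for f in feature_names],
            "coefficient_sum": [sums[f] for f in feature_names],
        }
    )
    return SelectionResult(table=table, repetitions=repetitions)


def truncation_quota(n: int) -> int:
    """round(sqrt(n)) with nearest-integer rounding."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(np.rint(np.sqrt(n)))


def truncate_top_sqrt_n(result: SelectionResult, n: int) -> list[str]:
    """Keep the top round(sqrt(n)) features by selection count.

    Only features whose coefficient sum is nonzero are eligible; boundary
    ties break by |coefficient sum| descending, then feature name.  If
    fewer eligible features exist than the quota, all are returned with a
    warning.
    """
    quota = truncation_quota(n)
    ranked = result.ranked()
    eligible = ranked[
        (ranked["selection_count"] > 0) & (ranked["coefficient_sum"] != 0.0)
    ]
    if len(eligible) < quota:
        logger.warning(
            "only %d eligible features for quota %d; returning all",
            len(eligible),
            quota,
        )
        return eligible["feature"].tolist()
    return eligible["feature"].head(quota).tolist()


def feature_correlation_map(
    X: pd.DataFrame | np.ndarray,
) -> tuple[pd.DataFrame, list[int]]:
    """Pearson correlation matrix, hierarchically ordered.

    Ordering uses average linkage on ``1 - |r|``.  Zero-variance columns
    correlate 0 with everything (flagged via a warning).  Returns the
    reordered correlation matrix and the leaf order.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(arr.shape[1])]
    if arr.shape[1] < 2:
        raise ValueError("need at least two features")
    sd = arr.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "zero-variance feature(s): %s; correlations set to 0",
            [names[j] for j in np.flatnonzero(degenerate)],
        )
    safe = arr.copy()
    safe[:, degenerate] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(safe, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)

    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(linkage).tolist()
    ordered = pd.DataFrame(
        corr[np.ix_(order, order)],
        index=[names[i] for i in order],
        columns=[names[i] for i in order],
    )
    return ordered, order
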