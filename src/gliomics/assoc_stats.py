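"""Association and survival statistics.

Chi-square on contingency tables (uncorrected by default), Mann-Whitney U
with an exact-enumeration path for small samples, Kaplan-Meier with median
survival, the log-rank test, and multivariate Cox proportional hazards with
Efron tie handling (delegated to lifelines).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "ContingencyTable",
    "CoxResult",
    "CollinearityError",
    "pearson_chi2",
    "mann_whitney_u",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]

#: Total pooled sample size at or below which the U-test enumerates exactly.
EXACT_U_LIMIT = 20


class CollinearityError(ValueError):
    """Covariates are collinear to working precision."""


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: Sequence[str] = ()
    col_labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


def pearson_chi2(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    correction: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence.

    No continuity correction by default (matches the reference recomputation
    of all printed 2x2 p-values); Yates correction available behind the flag.

    Returns ``(statistic, df, p)``.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=correction)
    return float(stat), int(df), float(p)


def _u_statistic(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all group assignments when the pooled size is at
    most ``EXACT_U_LIMIT`` (handles ties exactly); otherwise the
    tie-corrected normal approximation with continuity correction.
    The p-value is capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n1], n1)

    if n1 + n2 <= EXACT_U_LIMIT:
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        total = 0
        extreme = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                extreme += 1
        p = min(1.0, extreme / total)
        return u_obs, p

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), min(1.0, float(res.pvalue))


@dataclass
class KMCurve:
    times: np.ndarray  # event times where the curve drops
    survival: np.ndarray  # S(t) just after each time
    median: Optional[float]  # earliest time with S <= 0.5, None if never


def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> KMCurve:
    """Product-limit survival estimate and median survival time.

    ``median`` is the earliest time at which survival drops to <= 0.5
    (None when the curve never reaches 0.5, e.g. all-censored data).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("at least one record required")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    surv = 1.0
    out_t, out_s = [], []
    median: Optional[float] = None
    for ti in uniq:
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        out_t.append(ti)
        out_s.append(surv)
        if median is None and surv <= 0.5 + 1e-12:
            median = float(ti)
    return KMCurve(np.asarray(out_t), np.asarray(out_s), median)


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> tuple[float, int, float]:
    """Log-rank chi-square across >= 2 groups; returns (statistic, df, p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)


@dataclass
class CoxResult:
    coefficients: "pd.Series"
    hazard_ratios: "pd.Series"
    p_values: "pd.Series"
    summary: "pd.DataFrame"
    converged: bool = True


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: Optional[Sequence[str]] = None,
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Raises :class:`CollinearityError` when the covariate matrix is rank
    deficient to working precision.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    covariates = list(covariates)
    X = data[covariates].to_numpy(dtype=float)
    if X.shape[0] < 2 or len(np.unique(data.loc[data[event_col] == 1, duration_col])) < 2:
        raise ValueError("need at least two distinct event times")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max())) < len(covariates):
        raise CollinearityError(
            f"covariates {covariates} are collinear to working precision"
        )

    cph = CoxPHFitter()
    cph.fit(
        data[[duration_col, event_col] + covariates],
        duration_col=duration_col,
        event_col=event_col,
    )
    summary = cph.summary
    return CoxResult(
        coefficients=summary["coef"],
        hazard_ratios=summary["exp(coef)"],
        p_values=summary["p"],
        summary=summary,
        converged=True,
    )
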