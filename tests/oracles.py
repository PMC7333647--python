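"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (pure-Python loops, exhaustive
enumeration) and shares no code with the package implementations it
cross-checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def brute_glcm(gray, roi, ng, direction, delta=1):
    """Symmetrized, normalized co-occurrence matrix by voxel-pair scan."""
    gray = np.asarray(gray)
    roi = np.asarray(roi, dtype=bool)
    off = tuple(delta * c for c in direction)
    mat = np.zeros((ng, ng))
    for idx in np.ndindex(gray.shape):
        if not roi[idx]:
            continue
        nbr = tuple(i + o for i, o in zip(idx, off))
        if _in_bounds(nbr, gray.shape) and roi[nbr]:
            mat[gray[idx] - 1, gray[nbr] - 1] += 1
    mat = mat + mat.T
    total = mat.sum()
    return mat / total if total > 0 else None


def brute_glszm(gray, roi, ng):
    """Zone inventory by breadth-first flood fill (26-connectivity)."""
    gray = np.asarray(gray)
    roi = np.asarray(roi, dtype=bool)
    seen = np.zeros(gray.shape, dtype=bool)
    max_size = int(roi.sum())
    mat = np.zeros((ng, max_size))
    neighbors = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in np.ndindex(gray.shape):
        if not roi[start] or seen[start]:
            continue
        level = gray[start]
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            cur = queue.pop()
            size += 1
            for d in neighbors:
                nbr = tuple(c + o for c, o in zip(cur, d))
                if (
                    _in_bounds(nbr, gray.shape)
                    and roi[nbr]
                    and not seen[nbr]
                    and gray[nbr] == level
                ):
                    seen[nbr] = True
                    queue.append(nbr)
        mat[level - 1, size - 1] += 1
    return mat


def brute_gldm(gray, roi, ng, delta=1, alpha=0):
    """Gray level x dependence count by per-voxel neighbor scan."""
    gray = np.asarray(gray)
    roi = np.asarray(roi, dtype=bool)
    offsets = [
        (i, j, k)
        for i in range(-delta, delta + 1)
        for j in range(-delta, delta + 1)
        for k in range(-delta, delta + 1)
        if (i, j, k) != (0, 0, 0)
    ]
    mat = np.zeros((ng, len(offsets) + 1))
    for idx in np.ndindex(gray.shape):
        if not roi[idx]:
            continue
        dep = 0
        for d in offsets:
            nbr = tuple(c + o for c, o in zip(idx, d))
            if (
                _in_bounds(nbr, gray.shape)
                and roi[nbr]
                and abs(int(gray[idx]) - int(gray[nbr])) <= alpha
            ):
                dep += 1
        mat[gray[idx] - 1, dep] += 1
    return mat


def brute_ngtdm(gray, roi, ng):
    """Per-level (n_g, s_g) by per-voxel 26-neighborhood means."""
    gray = np.asarray(gray)
    roi = np.asarray(roi, dtype=bool)
    neighbors = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    n_g = np.zeros(ng)
    s_g = np.zeros(ng)
    for idx in np.ndindex(gray.shape):
        if not roi[idx]:
            continue
        vals = []
        for d in neighbors:
            nbr = tuple(c + o for c, o in zip(idx, d))
            if _in_bounds(nbr, gray.shape) and roi[nbr]:
                vals.append(int(gray[nbr]))
        g = int(gray[idx])
        n_g[g - 1] += 1
        if vals:
            s_g[g - 1] += abs(g - sum(vals) / len(vals))
    return n_g, s_g


def exact_u_pvalue(x, y):
    """Two-sided exact U-test p by enumerating all group assignments.

    U computed from pairwise comparisons (ties count 1/2), independent of
    any ranking code.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(sample_x, sample_y):
        u = 0.0
        for a in sample_x:
            for b in sample_y:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    mu = n1 * len(y) / 2.0
    dev = abs(u_of(x, y) - mu)
    total = 0
    extreme = 0
    indices = range(len(pooled))
    for combo in itertools.combinations(indices, n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in indices if i not in combo]
        total += 1
        if abs(u_of(xs, ys) - mu) >= dev - 1e-12:
            extreme += 1
    return min(1.0, extreme / total)


def cox_two_group_loglik(beta, times, events, group):
    """Breslow partial log-likelihood for a single binary covariate
    (valid exactly when event times are untied)."""
    ll = 0.0
    for t, e, g in zip(times, events, group):
        if not e:
            continue
        risk = [gj for tj, gj in zip(times, group) if tj >= t]
        denom = sum(math.exp(beta * gj) for gj in risk)
        ll += beta * g - math.log(denom)
    return ll


def km_survival_at(times, events, t_query):
    """Hand product-limit estimate of S(t_query)."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    surv = 1.0
    for i in order:
        if times[i] > t_query:
            break
        if events[i]:
            at_risk = sum(1 for tj in times if tj >= times[i])
            d = sum(
                1 for tj, ej in zip(times, events) if tj == times[i] and ej
            )
            # count each tied event time once
            if any(
                times[j] == times[i] and events[j] and j < i for j in order
            ):
                continue
            surv *= 1 - d / at_risk
    return surv
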