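"""Radiomics texture features from masked, discretized volumes.

Implements first-order statistics and the GLCM, GLSZM, GLDM, and NGTDM
families.  Matrix builders operate on integer gray-level volumes produced by
:func:`gliomics.imgproc.discretize` and are restricted to the ROI bounding
box for speed; every feature is invariant to voxels outside the ROI.

Degenerate-case conventions (documented, fixed):

- GLCM Correlation on a zero-variance matrix is 1; Imc1/Imc2 are 0.
- NGTDM Busyness/Strength/Contrast/Coarseness return 0 when their
  denominator vanishes.
- First-order Kurtosis (Pearson, non-excess) returns 0 on zero variance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import TransformBankConfig
from .imgproc import ImageVolume, discretize, transform_bank

logger = logging.getLogger(__name__)

__all__ = [
    "SEQUENCES",
    "FAMILIES",
    "FeatureName",
    "encode_feature_name",
    "parse_feature_name",
    "firstorder_features",
    "glcm_matrices",
    "glcm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
    "feature_manifest",
    "extract_feature_table",
]

SEQUENCES = ("T1pre", "T1post", "T2", "FLAIR")
FAMILIES = ("firstorder", "glcm", "glszm", "gldm", "ngtdm")

# 13 unique 3D directions at Chebyshev distance 1 (half of the 26-neighborhood).
GLCM_DIRECTIONS = tuple(
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) > (0, 0, 0)
)

_OFFSETS_26 = tuple(
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
)


# ---------------------------------------------------------------------------
# Feature names
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureName:
    """Structured feature name: sequence, transform label, family, feature."""

    sequence: str
    transform: str
    family: str
    feature: str

    def __str__(self) -> str:
        return f"{self.sequence}-{self.transform}_{self.family}_{self.feature}"


_NAME_RE = re.compile(
    r"^(?P<seq>T1pre|T1post|T2|FLAIR)-(?P<transform>[A-Za-z0-9\-]+)"
    r"_(?P<family>firstorder|glcm|glszm|gldm|ngtdm)_(?P<feature>\w+)$"
)


def encode_feature_name(
    sequence: str, transform: str, family: str, feature: str
) -> str:
    if sequence not in SEQUENCES:
        raise ValueError(f"unknown sequence {sequence!r}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    return str(FeatureName(sequence, transform, family, feature))


def parse_feature_name(name: str) -> FeatureName:
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse feature name {name!r}")
    return FeatureName(
        m.group("seq"), m.group("transform"), m.group("family"), m.group("feature")
    )


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _bbox_crop(gray: np.ndarray, roi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Crop both arrays to the ROI bounding box (pure speedup)."""
    idx = np.nonzero(roi)
    slices = tuple(slice(a.min(), a.max() + 1) for a in idx)
    return gray[slices], roi[slices]


def _check_roi(roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return roi


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------


def firstorder_features(
    values: np.ndarray, roi: np.ndarray, bin_width: float = 0.25
) -> dict[str, float]:
    """First-order intensity statistics over ROI voxels only.

    Kurtosis is the non-excess (Pearson) form; zero-variance ROIs report the
    sentinel 0.0 for Skewness and Kurtosis.  Entropy is computed on the
    fixed-bin-width discretization of the ROI.
    """
    roi = _check_roi(roi)
    v = np.asarray(values, dtype=float)[roi]
    var = float(v.var())
    if var > 0:
        skewness = float(stats.skew(v))
        kurtosis = float(stats.kurtosis(v, fisher=False))
    else:
        skewness = 0.0
        kurtosis = 0.0
    _, ng = discretize(np.asarray(values, dtype=float), roi, bin_width)
    levels = np.floor((v - v.min()) / bin_width).astype(int)
    p = np.bincount(levels) / v.size
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    q25, q75 = np.percentile(v, [25, 75])
    return {
        "Mean": float(v.mean()),
        "Median": float(np.median(v)),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(np.ptp(v)),
        "Variance": var,
        "StandardDeviation": float(v.std()),
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Energy": float((v**2).sum()),
        "Entropy": entropy,
        "Percentile10": float(np.percentile(v, 10)),
        "Percentile90": float(np.percentile(v, 90)),
        "InterquartileRange": float(q75 - q25),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(v - v.mean()).mean()),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrices(
    gray: np.ndarray,
    roi: np.ndarray,
    ng: int,
    delta: int = 1,
    directions: Sequence[tuple[int, int, int]] = GLCM_DIRECTIONS,
) -> list[np.ndarray]:
    """Symmetrized, normalized co-occurrence matrix per direction.

    Directions whose co-occurrence count is zero are dropped.
    """
    roi = _check_roi(roi)
    gray, roi = _bbox_crop(np.asarray(gray), roi)
    mats: list[np.ndarray] = []
    for d in directions:
        off = tuple(int(delta) * c for c in d)
        sl_a, sl_b = [], []
        ok = True
        for o, n in zip(off, gray.shape):
            if abs(o) >= n:
                ok = False
                break
            if o >= 0:
                sl_a.append(slice(0, n - o))
                sl_b.append(slice(o, n))
            else:
                sl_a.append(slice(-o, n))
                sl_b.append(slice(0, n + o))
        if not ok:
            continue
        a = gray[tuple(sl_a)]
        b = gray[tuple(sl_b)]
        valid = roi[tuple(sl_a)] & roi[tuple(sl_b)]
        if not valid.any():
            continue
        ia = a[valid] - 1
        ib = b[valid] - 1
        mat = np.bincount(ia * ng + ib, minlength=ng * ng).reshape(ng, ng).astype(float)
        mat = mat + mat.T
        mats.append(mat / mat.sum())
    return mats


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    autocorr = float((ii * jj * p).sum())
    if sigma2 > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 1.0
    nz = p[p > 0]
    hxy = float(-(nz * np.log2(nz)).sum())
    px_nz = px[px > 0]
    hx = float(-(px_nz * np.log2(px_nz)).sum())
    pxy = np.outer(px, px)
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
    mask2 = pxy > 0
    hxy2 = float(-(pxy[mask2] * np.log2(pxy[mask2])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(arg)) if arg > 0 else 0.0
    return {
        "Autocorrelation": autocorr,
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
    }


def glcm_features(
    gray: np.ndarray,
    roi: np.ndarray,
    ng: int,
    delta: int = 1,
    directions: Sequence[tuple[int, int, int]] = GLCM_DIRECTIONS,
) -> dict[str, float]:
    """Per-direction GLCM features averaged over the direction set."""
    mats = glcm_matrices(gray, roi, ng, delta=delta, directions=directions)
    if not mats:
        # single-voxel ROI: no co-occurring pairs in any direction
        return {k: v for k, v in _glcm_features_one(np.ones((1, 1))).items()}
    per_dir = [_glcm_features_one(m) for m in mats]
    return {
        k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(
    gray: np.ndarray, roi: np.ndarray, ng: int
) -> np.ndarray:
    """Gray level x zone size counts; zones are maximal 26-connected
    components of equal level within the ROI."""
    roi = _check_roi(roi)
    gray, roi = _bbox_crop(np.asarray(gray), roi)
    max_size = int(roi.sum())
    mat = np.zeros((ng, max_size), dtype=float)
    for g in range(1, ng + 1):
        comp = (gray == g) & roi
        if not comp.any():
            continue
        labels, n_comp = ndimage.label(comp, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            mat[g - 1, s - 1] += 1
    return mat


def glszm_features(gray: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    mat = glszm_matrix(gray, roi, ng)
    nz_total = mat.sum()
    n_vox = int(np.asarray(roi, dtype=bool).sum())
    g = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    pg = mat.sum(axis=1)
    ps = mat.sum(axis=0)
    p = mat / nz_total
    p_nz = p[p > 0]
    mu_g = float((g[:, 0] * pg).sum() / nz_total)
    return {
        "SmallAreaEmphasis": float((mat / s**2).sum() / nz_total),
        "LargeAreaEmphasis": float((mat * s**2).sum() / nz_total),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz_total),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz_total**2),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz_total),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz_total**2),
        "ZonePercentage": float(nz_total / n_vox),
        "GrayLevelVariance": float((((g[:, 0] - mu_g) ** 2) * pg).sum() / nz_total),
        "LowGrayLevelZoneEmphasis": float((mat / g**2).sum() / nz_total),
        "HighGrayLevelZoneEmphasis": float((mat * g**2).sum() / nz_total),
        "SmallAreaLowGrayLevelEmphasis": float((mat / (g**2 * s**2)).sum() / nz_total),
        "SmallAreaHighGrayLevelEmphasis": float((mat * g**2 / s**2).sum() / nz_total),
        "LargeAreaLowGrayLevelEmphasis": float((mat * s**2 / g**2).sum() / nz_total),
        "LargeAreaHighGrayLevelEmphasis": float((mat * s**2 * g**2).sum() / nz_total),
        "ZoneEntropy": float(-(p_nz * np.log2(p_nz)).sum()),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_matrix(
    gray: np.ndarray,
    roi: np.ndarray,
    ng: int,
    delta: int = 1,
    alpha: int = 0,
) -> np.ndarray:
    """Gray level x dependence-count matrix.

    The dependence of a voxel is the number of in-ROI neighbors within
    Chebyshev distance ``delta`` whose |level difference| <= ``alpha``
    (the center itself is not counted).
    """
    roi = _check_roi(roi)
    gray, roi = _bbox_crop(np.asarray(gray), roi)
    dep = np.zeros(gray.shape, dtype=np.int64)
    offsets = [
        (i, j, k)
        for i in range(-delta, delta + 1)
        for j in range(-delta, delta + 1)
        for k in range(-delta, delta + 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for off in offsets:
        sl_a, sl_b = [], []
        ok = True
        for o, n in zip(off, gray.shape):
            if abs(o) >= n:
                ok = False
                break
            if o >= 0:
                sl_a.append(slice(0, n - o))
                sl_b.append(slice(o, n))
            else:
                sl_a.append(slice(-o, n))
                sl_b.append(slice(0, n + o))
        if not ok:
            continue
        a, b = gray[tuple(sl_a)], gray[tuple(sl_b)]
        dependent = (
            roi[tuple(sl_a)]
            & roi[tuple(sl_b)]
            & (np.abs(a - b) <= alpha)
        )
        dep[tuple(sl_a)] += dependent
    max_dep = len(offsets)
    mat = np.zeros((ng, max_dep + 1), dtype=float)
    gl = gray[roi] - 1
    dp = dep[roi]
    np.add.at(mat, (gl, dp), 1.0)
    return mat


def gldm_features(
    gray: np.ndarray,
    roi: np.ndarray,
    ng: int,
    delta: int = 1,
    alpha: int = 0,
) -> dict[str, float]:
    mat = gldm_matrix(gray, roi, ng, delta=delta, alpha=alpha)
    n = mat.sum()  # = ROI voxel count
    g = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    # dependence-size weight uses d+1 so the zero-dependence bin is legal
    d = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    pg = mat.sum(axis=1)
    pd_ = mat.sum(axis=0)
    p = mat / n
    p_nz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((mat / d**2).sum() / n),
        "LargeDependenceEmphasis": float((mat * d**2).sum() / n),
        "GrayLevelNonUniformity": float((pg**2).sum() / n),
        "DependenceNonUniformity": float((pd_**2).sum() / n),
        "DependenceNonUniformityNormalized": float((pd_**2).sum() / n**2),
        "LowGrayLevelEmphasis": float((mat / g**2).sum() / n),
        "HighGrayLevelEmphasis": float((mat * g**2).sum() / n),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (mat / (g**2 * d**2)).sum() / n
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (mat * g**2 * d**2).sum() / n
        ),
        "DependenceEntropy": float(-(p_nz * np.log2(p_nz)).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_table(
    gray: np.ndarray, roi: np.ndarray, ng: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level counts n_g and summed gray-tone differences s_g.

    s_g sums |g - mean level of in-ROI 26-neighbors| over ROI voxels of
    level g; voxels without in-ROI neighbors contribute 0.
    """
    roi = _check_roi(roi)
    gray, roi = _bbox_crop(np.asarray(gray), roi)
    lvl = gray.astype(float) * roi
    nb_sum = np.zeros(gray.shape, dtype=float)
    nb_cnt = np.zeros(gray.shape, dtype=float)
    for off in _OFFSETS_26:
        sl_a, sl_b = [], []
        ok = True
        for o, n in zip(off, gray.shape):
            if abs(o) >= n:
                ok = False
                break
            if o >= 0:
                sl_a.append(slice(0, n - o))
                sl_b.append(slice(o, n))
            else:
                sl_a.append(slice(-o, n))
                sl_b.append(slice(0, n + o))
        if not ok:
            continue
        nb_sum[tuple(sl_a)] += lvl[tuple(sl_b)]
        nb_cnt[tuple(sl_a)] += roi[tuple(sl_b)]
    diff = np.zeros(gray.shape, dtype=float)
    has_nb = roi & (nb_cnt > 0)
    diff[has_nb] = np.abs(
        gray[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb]
    )
    n_g = np.zeros(ng, dtype=float)
    s_g = np.zeros(ng, dtype=float)
    gl = gray[roi] - 1
    np.add.at(n_g, gl, 1.0)
    np.add.at(s_g, gl, diff[roi])
    return n_g, s_g


def ngtdm_features(gray: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    n_g, s_g = ngtdm_table(gray, roi, ng)
    n = n_g.sum()
    p = n_g / n
    present = p > 0
    i = np.arange(1, ng + 1, dtype=float)
    ngp = int(present.sum())

    coarse_den = float((p * s_g).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 0.0

    if ngp > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        ii = i[present][:, None]
        jj = i[present][None, :]
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (ngp * (ngp - 1))
            * s_g.sum()
            / n
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        si = s_g[present][:, None]
        sj = s_g[present][None, :]
        complexity = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / n
        )
        s_total = float(s_g.sum())
        strength = (
            float(((pi + pj) * (ii - jj) ** 2).sum()) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# Cohort extraction
# ---------------------------------------------------------------------------

_FAMILY_FEATURES: dict[str, list[str]] = {
    "firstorder": sorted(
        [
            "Mean", "Median", "Minimum", "Maximum", "Range", "Variance",
            "StandardDeviation", "Skewness", "Kurtosis", "Energy", "Entropy",
            "Percentile10", "Percentile90", "InterquartileRange",
            "RootMeanSquared", "MeanAbsoluteDeviation",
        ]
    ),
    "glcm": sorted(
        [
            "Autocorrelation", "Contrast", "Correlation", "Idm", "Imc1",
            "Imc2", "JointEnergy", "JointEntropy",
        ]
    ),
    "glszm": sorted(
        [
            "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
            "SizeZoneNonUniformityNormalized", "ZonePercentage",
            "GrayLevelVariance", "LowGrayLevelZoneEmphasis",
            "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
            "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
            "LargeAreaHighGrayLevelEmphasis", "ZoneEntropy",
        ]
    ),
    "gldm": sorted(
        [
            "SmallDependenceEmphasis", "LargeDependenceEmphasis",
            "GrayLevelNonUniformity", "DependenceNonUniformity",
            "DependenceNonUniformityNormalized", "LowGrayLevelEmphasis",
            "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
            "LargeDependenceHighGrayLevelEmphasis", "DependenceEntropy",
        ]
    ),
    "ngtdm": sorted(["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]),
}


def feature_manifest(
    transforms: TransformBankConfig | None = None,
    families: Sequence[str] = FAMILIES,
    features_by_family: Mapping[str, Sequence[str]] | None = None,
    sequences: Sequence[str] = SEQUENCES,
) -> list[str]:
    """Deterministic list of feature-table column names for a config."""
    if transforms is None:
        transforms = TransformBankConfig()
    if features_by_family is None:
        features_by_family = _FAMILY_FEATURES
    cols = []
    for seq in sequences:
        for label in transforms.transform_labels():
            for family in families:
                for feat in features_by_family[family]:
                    cols.append(encode_feature_name(seq, label, family, feat))
    return cols


def _features_for_volume(
    values: np.ndarray,
    roi: np.ndarray,
    bin_width: float,
    families: Sequence[str],
) -> dict[str, float]:
    out: dict[str, float] = {}
    need_gray = any(f in families for f in ("glcm", "glszm", "gldm", "ngtdm"))
    if need_gray:
        gray, ng = discretize(values, roi, bin_width)
    for family in families:
        if family == "firstorder":
            feats = firstorder_features(values, roi, bin_width)
        elif family == "glcm":
            feats = glcm_features(gray, roi, ng)
        elif family == "glszm":
            feats = glszm_features(gray, roi, ng)
        elif family == "gldm":
            feats = gldm_features(gray, roi, ng)
        elif family == "ngtdm":
            feats = ngtdm_features(gray, roi, ng)
        else:
            raise ValueError(f"unknown family {family!r}")
        for feat in _FAMILY_FEATURES[family]:
            out[f"{family}_{feat}"] = feats[feat]
    return out


def extract_feature_table(
    volumes: Mapping[str, Mapping[str, ImageVolume]],
    masks: Mapping[str, np.ndarray],
    transforms: TransformBankConfig | None = None,
    bin_width: float = 0.25,
    families: Sequence[str] = FAMILIES,
    sequences: Sequence[str] = SEQUENCES,
) -> pd.DataFrame:
    """Patients x named-features table.

    ``volumes`` maps patient id -> sequence name -> :class:`ImageVolume`;
    ``masks`` maps patient id -> boolean ROI array (the single mask serves
    every sequence and transform).  Patients missing any sequence or mask
    are skipped with a logged reason.
    """
    if transforms is None:
        transforms = TransformBankConfig()
    rows: dict[str, dict[str, float]] = {}
    for pid in volumes:
        patient_vols = volumes[pid]
        missing = [s for s in sequences if s not in patient_vols]
        if missing:
            logger.warning("patient %s skipped: missing sequence(s) %s", pid, missing)
            continue
        if pid not in masks:
            logger.warning("patient %s skipped: missing ROI mask", pid)
            continue
        roi = np.asarray(masks[pid], dtype=bool)
        row: dict[str, float] = {}
        for seq in sequences:
            vol = patient_vols[seq]
            derived = transform_bank(vol.values, vol.spacing, transforms)
            for label, dvals in derived.items():
                feats = _features_for_volume(dvals, roi, bin_width, families)
                for key, value in feats.items():
                    row[f"{seq}-{label}_{key}"] = value
        rows[pid] = row
        logger.info("patient %s: %d features extracted", pid, len(row))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
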