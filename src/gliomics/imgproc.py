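"""Intensity normalization, discretization, and the image-transform bank.

All transforms return a volume on the input lattice, so a single ROI mask
serves every derived image.  The wavelet decomposition is one-level and
separable; the default is the stationary (undecimated) variant so sub-bands
share the input lattice, with an orthogonal decimated variant retained for
energy-conservation checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern

from .config import TransformBankConfig

__all__ = [
    "ImageVolume",
    "NormalizationError",
    "whitestripe_normalize",
    "discretize",
    "wavelet_subbands",
    "pointwise_transform",
    "gradient_magnitude",
    "lbp2d",
    "lbp3d",
    "transform_bank",
    "WAVELET_BANDS",
]

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

# Coiflet-1 orthogonal scaling (decomposition low-pass) filter.
_COIF1_DEC_LO = np.array(
    [
        -0.015655728135464787,
        -0.07273261951252645,
        0.3848648468648578,
        0.8525720202116004,
        0.3378976624574818,
        -0.07273261951252645,
    ]
)
# Haar kept as a short alternative for tiny volumes.
_HAAR_DEC_LO = np.array([0.7071067811865476, 0.7071067811865476])

_FILTERS = {"coif1": _COIF1_DEC_LO, "haar": _HAAR_DEC_LO}


class NormalizationError(ValueError):
    pass


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing in millimetres."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        if not np.isfinite(self.values).all():
            raise ValueError("ImageVolume values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


# ---------------------------------------------------------------------------
# White-stripe intensity normalization
# ---------------------------------------------------------------------------


def locate_upper_mode(v: np.ndarray, n_bins: int = 128) -> float:
    """Dominant mode of the smoothed histogram among intensities at or
    above the sample median (bandwidth: two histogram bins)."""
    v = np.asarray(v, dtype=float).ravel()
    counts, edges = np.histogram(v, bins=n_bins)
    smoothed = ndimage.gaussian_filter1d(counts.astype(float), sigma=2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.flatnonzero(centers >= np.median(v))
    return float(centers[idx[np.argmax(smoothed[idx])]])


def whitestripe_normalize(
    values: np.ndarray,
    brain_mask: np.ndarray,
    tau: float = 0.05,
    n_bins: int = 128,
    min_stripe_voxels: int = 50,
) -> np.ndarray:
    """Normalize intensities against the dominant upper-histogram mode.

    The "stripe" is the set of intensities within +-``tau`` quantile-width
    of the mode located by :func:`locate_upper_mode`; the output is
    ``(x - mode) / SD(stripe)``.  A stripe smaller than
    ``min_stripe_voxels`` falls back to a whole-brain z-score.
    """
    values = np.asarray(values, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    v = values[brain_mask]
    if v.size == 0:
        raise NormalizationError("brain mask is empty")
    if np.ptp(v) == 0:
        raise NormalizationError("constant image cannot be normalized")

    mode = locate_upper_mode(v, n_bins=n_bins)
    q_mode = float(np.mean(v <= mode))
    lo = np.quantile(v, max(0.0, q_mode - tau))
    hi = np.quantile(v, min(1.0, q_mode + tau))
    stripe = v[(v >= lo) & (v <= hi)]
    if stripe.size < min_stripe_voxels:
        warnings.warn(
            f"white stripe has only {stripe.size} voxels; "
            "falling back to whole-brain z-score",
            stacklevel=2,
        )
        return (values - v.mean()) / v.std()
    sd = stripe.std()
    if sd == 0:
        sd = v.std()
    return (values - mode) / sd


# ---------------------------------------------------------------------------
# Gray-level discretization
# ---------------------------------------------------------------------------


def discretize(
    values: np.ndarray, roi: np.ndarray, bin_width: float
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width discretization of ROI voxels to levels 1..Ng.

    Voxels outside the ROI are assigned level 0.  Returns the gray-level
    volume and the number of levels Ng.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    out = np.zeros(values.shape, dtype=np.int64)
    v = values[roi]
    levels = np.floor((v - v.min()) / bin_width).astype(np.int64) + 1
    ng = int(levels.max())
    out[roi] = levels
    return out, ng


# ---------------------------------------------------------------------------
# Wavelet sub-bands
# ---------------------------------------------------------------------------


def _qmf(dec_lo: np.ndarray) -> np.ndarray:
    hi = dec_lo[::-1].copy()
    hi[1::2] *= -1.0
    return hi


def _stationary_axis(x: np.ndarray, weights: np.ndarray, axis: int) -> np.ndarray:
    return ndimage.correlate1d(x, weights, axis=axis, mode="wrap")


def _decimated_axis(x: np.ndarray, weights: np.ndarray, axis: int) -> np.ndarray:
    n = x.shape[axis]
    if n % 2 != 0:
        raise ValueError("decimated transform requires even axis lengths")
    mat = np.zeros((n // 2, n))
    for m in range(n // 2):
        for k, w in enumerate(weights):
            mat[m, (k + 2 * m) % n] += w
    moved = np.moveaxis(x, axis, -1)
    out = moved @ mat.T
    return np.moveaxis(out, -1, axis)


def wavelet_subbands(
    values: np.ndarray,
    wavelet: str = "coif1",
    stationary: bool = True,
) -> dict[str, np.ndarray]:
    """One-level separable 3D wavelet decomposition into 8 sub-bands.

    Band labels read high/low per axis in array-axis order, e.g. ``LLH`` is
    low-pass on axes 0 and 1 and high-pass on axis 2.  The stationary
    variant (default) keeps every sub-band on the input lattice; the
    decimated variant is orthogonal with periodization and conserves energy.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected a 3D volume")
    try:
        lo = _FILTERS[wavelet]
    except KeyError:
        raise ValueError(f"unknown wavelet {wavelet!r}") from None
    if min(values.shape) < lo.size:
        raise ValueError(
            f"volume dims {values.shape} smaller than filter length {lo.size}"
        )
    hi = _qmf(lo)
    apply_axis = _stationary_axis if stationary else _decimated_axis

    bands: dict[str, np.ndarray] = {}
    for label in WAVELET_BANDS:
        out = values
        for axis, ch in enumerate(label):
            out = apply_axis(out, lo if ch == "L" else hi, axis)
        bands[label] = out
    return bands


# ---------------------------------------------------------------------------
# Pointwise transforms
# ---------------------------------------------------------------------------

_POINTWISE_KINDS = ("square", "squareroot", "logarithm", "exponential")


def pointwise_transform(values: np.ndarray, kind: str) -> np.ndarray:
    """Monotone pointwise intensity map with range-preserving rescale.

    Intensities are first shifted to be nonnegative (s = x - min), then

    - square:      s^2 / R
    - squareroot:  sqrt(s * R)
    - logarithm:   log(s + 1) * R / log(R + 1)
    - exponential: exp(s * log(R + 1) / R) - 1

    where R is the input range (max - min), so every output spans [0, R].
    A constant input maps to zeros.
    """
    if kind not in _POINTWISE_KINDS:
        raise ValueError(f"unknown pointwise transform {kind!r}")
    values = np.asarray(values, dtype=float)
    rng = float(np.ptp(values))
    if rng == 0:
        return np.zeros_like(values)
    s = values - values.min()
    if kind == "square":
        return s**2 / rng
    if kind == "squareroot":
        return np.sqrt(s * rng)
    if kind == "logarithm":
        return np.log1p(s) * rng / np.log1p(rng)
    return np.expm1(s * np.log1p(rng) / rng)


def gradient_magnitude(
    values: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> np.ndarray:
    """Euclidean norm of central-difference partials scaled by spacing."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or min(values.shape) < 2:
        raise ValueError("gradient requires a 3D volume with dims >= 2")
    grads = np.gradient(values, *[float(s) for s in spacing])
    return np.sqrt(sum(g**2 for g in grads))


# ---------------------------------------------------------------------------
# Local binary patterns
# ---------------------------------------------------------------------------


def lbp2d(values: np.ndarray, radius: int = 1, n_samples: int = 8) -> np.ndarray:
    """Slice-wise rotation-invariant uniform LBP codes (transverse plane).

    Intensities are quantized to 256 levels relative to the volume range
    before coding, which makes the codes exactly invariant to global
    intensity offsets (LBP thresholds against the center value only).
    """
    values = np.asarray(values, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if min(values.shape[0], values.shape[1]) <= 2 * radius:
        raise ValueError("radius exceeds slice extent")
    rng_ = np.ptp(values)
    if rng_ > 0:
        quant = np.rint((values - values.min()) / rng_ * 255.0).astype(np.int64)
    else:
        quant = np.zeros(values.shape, dtype=np.int64)
    out = np.empty(values.shape, dtype=float)
    for k in range(values.shape[2]):
        out[:, :, k] = local_binary_pattern(
            quant[:, :, k], P=n_samples, R=radius, method="uniform"
        )
    return out


_OFFSETS_26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def lbp3d(
    values: np.ndarray, radii: Sequence[int] = (1, 2, 3)
) -> dict[int, np.ndarray]:
    """Simplified rotation-invariant 3D local-pattern response per radius.

    For each radius r, neighbors are sampled at the 26 integer offsets
    scaled by r (periodic boundary); the response at a voxel is the count
    of neighbors >= the center value.  The count is invariant to global
    intensity offsets and to permutations of the sampling directions.
    """
    values = np.asarray(values, dtype=float)
    out: dict[int, np.ndarray] = {}
    for r in radii:
        r = int(r)
        if r < 1:
            raise ValueError("radius must be >= 1")
        if 2 * r >= min(values.shape):
            raise ValueError(f"radius {r} exceeds volume extent {values.shape}")
        count = np.zeros(values.shape, dtype=float)
        for off in _OFFSETS_26 * r:
            neighbor = np.roll(values, shift=tuple(-off), axis=(0, 1, 2))
            count += neighbor >= values
        out[r] = count
    return out


# ---------------------------------------------------------------------------
# Transform bank
# ---------------------------------------------------------------------------


def transform_bank(
    values: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    config: TransformBankConfig | None = None,
) -> dict[str, np.ndarray]:
    """Apply the configured transforms; returns label -> derived volume.

    Labels follow the feature-name convention: ``original``,
    ``wavelet-LLL`` ... ``wavelet-HHH``, ``square``, ``squareroot``,
    ``logarithm``, ``exponential``, ``gradient``, ``lbp-2D``,
    ``lbp-3D-m1`` ... (one per configured radius).
    """
    if config is None:
        config = TransformBankConfig()
    values = np.asarray(values, dtype=float)
    out: dict[str, np.ndarray] = {}
    if config.original:
        out["original"] = values
    if config.wavelet_bands:
        bands = wavelet_subbands(values, wavelet=config.wavelet_name, stationary=True)
        for b in config.wavelet_bands:
            out[f"wavelet-{b}"] = bands[b]
    for flag, kind in (
        (config.square, "square"),
        (config.squareroot, "squareroot"),
        (config.logarithm, "logarithm"),
        (config.exponential, "exponential"),
    ):
        if flag:
            out[kind] = pointwise_transform(values, kind)
    if config.gradient:
        out["gradient"] = gradient_magnitude(values, spacing)
    if config.lbp2d:
        out["lbp-2D"] = lbp2d(values)
    if config.lbp3d_radii:
        responses = lbp3d(values, config.lbp3d_radii)
        for i, r in enumerate(config.lbp3d_radii, start=1):
            out[f"lbp-3D-m{i}"] = responses[int(r)]
    return out
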