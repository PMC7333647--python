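"""Fully synthetic radiogenomic cohort generator.

Produces, with no external data: per-patient genomic tables (variant rows,
copy-number segments), a clinical/survival cohort table, and co-registered
4-sequence MR-like volumes with a tumor ROI mask.  The statistical structure
mirrors the cohort the downstream analysis assumes:

- mutation prevalence ~ ``cic_prevalence`` with near-containment inside
  IDH-mutant AND 1p/19q-codeleted patients,
- exponential proportional-hazards survival with a configurable hazard
  ratio for mutants and independent exponential censoring,
- label-dependent image texture: mutant ROIs are larger and carry
  multi-scale heterogeneous blob texture; wild-type ROIs are compact with a
  dark necrotic core and a bright rim.

Reproducibility: every patient draws from a sub-seed derived from the
master seed by a fixed counter scheme (``SeedSequence([seed, stage, i])``),
so a cohort can be extended without reshuffling earlier patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ConfigurationError, SimulationConfig
from .genomics import CNVSegment, VariantRecord
from .imgproc import ImageVolume
from .texture import SEQUENCES

__all__ = [
    "GroundTruth",
    "generate_genomic_cohort",
    "generate_image_cohort",
    "write_cohort_tables",
    "write_image_cohort",
]

# stage codes for the per-patient sub-seed counter scheme
_STAGE_GENOMIC = 1
_STAGE_IMAGE = 2

#: feature-table columns the image generator is designed to make informative
INFORMATIVE_FEATURES = [
    "T2-original_glszm_SizeZoneNonUniformityNormalized",
    "T1post-original_ngtdm_Busyness",
    "T1pre-original_gldm_DependenceNonUniformityNormalized",
    "FLAIR-original_firstorder_Variance",
]


@dataclass
class GroundTruth:
    patient_ids: list[str]
    cic_label: np.ndarray
    idh_label: np.ndarray
    codel_label: np.ndarray
    true_hazard: np.ndarray
    informative_feature_ids: list[str] = field(
        default_factory=lambda: list(INFORMATIVE_FEATURES)
    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patient_ids": self.patient_ids,
            "cic_label": self.cic_label.astype(int).tolist(),
            "idh_label": self.idh_label.astype(int).tolist(),
            "codel_label": self.codel_label.astype(int).tolist(),
            "true_hazard": self.true_hazard.tolist(),
            "informative_feature_ids": self.informative_feature_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _patient_rng(seed: int, stage: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage, index]))


def _patient_id(index: int) -> str:
    return f"SYN-{index:04d}"


# ---------------------------------------------------------------------------
# Genomic / clinical cohort
# ---------------------------------------------------------------------------

_QUALIFYING = ("missense", "frameshift", "nonsense")


def _joint_rate_given_wildtype(config: SimulationConfig) -> float:
    """P(IDH-mut AND codel | no mutation) implied by the configured
    P(mutation | IDH-mut AND codel) via Bayes."""
    prev = config.cic_prevalence
    a = prev * config.p_idh_given_cic * config.p_codel_given_cic
    r = config.cic_rate_in_codel_idh
    if r <= 0 or prev >= 1:
        return 0.0
    return float(np.clip(a * (1 - r) / (r * (1 - prev)), 0.0, 1.0))


def generate_genomic_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[VariantRecord], list[CNVSegment], GroundTruth]:
    """Draw labels, clinical covariates, survival, and genomic tables.

    Returns ``(cohort, variants, segments, truth)``.  Survival times come
    from an exponential proportional-hazards model with per-patient hazard
    ``baseline_hazard * hazard_ratio_cic**cic``; censoring is independent
    exponential calibrated so the expected censored fraction equals
    ``censor_rate``.
    """
    n = config.n_patients
    p_both_wt = _joint_rate_given_wildtype(config)

    ids, rows = [], []
    variants: list[VariantRecord] = []
    segments: list[CNVSegment] = []
    cic = np.zeros(n, dtype=int)
    idh = np.zeros(n, dtype=int)
    codel = np.zeros(n, dtype=int)
    hazards = np.zeros(n, dtype=float)

    for i in range(n):
        rng = _patient_rng(config.seed, _STAGE_GENOMIC, i)
        pid = _patient_id(i)
        ids.append(pid)

        cic_i = int(rng.random() < config.cic_prevalence)
        if cic_i:
            idh_i = int(rng.random() < config.p_idh_given_cic)
            codel_i = int(rng.random() < config.p_codel_given_cic)
        elif rng.random() < p_both_wt:
            idh_i, codel_i = 1, 1
        else:
            idh_i = int(rng.random() < config.p_idh_given_nothing)
            codel_i = 0
        cic[i], idh[i], codel[i] = cic_i, idh_i, codel_i

        fubp1_i = int(rng.random() < (0.35 if cic_i else 0.03))

        if cic_i:
            variants.append(
                VariantRecord(pid, "CIC", _QUALIFYING[rng.integers(3)])
            )
        elif rng.random() < 0.05:
            # non-qualifying decoy record; must never trigger a call
            variants.append(VariantRecord(pid, "CIC", "silent"))
        if idh_i:
            variants.append(
                VariantRecord(pid, "IDH1", _QUALIFYING[rng.integers(3)])
            )
        if fubp1_i:
            variants.append(
                VariantRecord(pid, "FUBP1", _QUALIFYING[rng.integers(3)])
            )
        if rng.random() < 0.3:
            variants.append(VariantRecord(pid, "TTN", "other"))

        segments.extend(_patient_segments(pid, codel_i, rng))

        hazard = config.baseline_hazard * config.hazard_ratio_cic**cic_i
        hazards[i] = hazard
        t_event = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0:
            censor_hazard = hazard * config.censor_rate / (1.0 - config.censor_rate)
            t_censor = rng.exponential(1.0 / censor_hazard)
        else:
            t_censor = np.inf
        time = max(min(t_event, t_censor), 1.0)
        event = int(t_event <= t_censor)

        rows.append(
            {
                "patient_id": pid,
                "age": float(np.clip(rng.normal(45.0, 12.0), 18.0, 90.0)),
                "gender": "female" if rng.random() < 0.5 else "male",
                "grade": "G2" if rng.random() < 0.55 else "G3",
                "cic_mutant": cic_i,
                "idh_mutant": idh_i,
                "codeletion_1p19q": codel_i,
                "fubp1_mutant": fubp1_i,
                "time": float(time),
                "event": event,
            }
        )

    cohort = pd.DataFrame(rows)
    truth = GroundTruth(
        patient_ids=ids,
        cic_label=cic,
        idh_label=idh,
        codel_label=codel,
        true_hazard=hazards,
    )
    return cohort, variants, segments, truth


_ARM_SPANS = {"1p": ("1", 1, 121_500_000), "19q": ("19", 26_500_000, 58_600_000)}


def _patient_segments(
    pid: str, codel: int, rng: np.random.Generator
) -> list[CNVSegment]:
    """Two segments per target arm (exercises length weighting) plus a
    neutral control arm."""
    segs: list[CNVSegment] = []
    for arm, (chrom, start, end) in _ARM_SPANS.items():
        mid = (start + end) // 2
        for s, e in ((start, mid), (mid + 1, end)):
            if codel:
                mean = float(np.clip(rng.normal(-0.5, 0.1), -0.9, -0.25))
            else:
                mean = float(np.clip(rng.normal(0.0, 0.05), -0.15, 0.15))
            segs.append(CNVSegment(pid, chrom, arm, s, e, mean))
    segs.append(
        CNVSegment(
            pid, "7", "other", 1, 159_000_000,
            float(np.clip(rng.normal(0.0, 0.05), -0.15, 0.15)),
        )
    )
    return segs


# ---------------------------------------------------------------------------
# Image cohort
# ---------------------------------------------------------------------------


def _multiscale_noise(
    shape: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-SD blob texture mixing three spatial scales."""
    out = np.zeros(shape)
    for sigma, weight in ((1.0, 1.0), (2.0, 1.5), (4.0, 2.0)):
        layer = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        sd = layer.std()
        if sd > 0:
            out += weight * layer / sd
    return out / np.sqrt(1.0**2 + 1.5**2 + 2.0**2)


def generate_image_cohort(
    config: SimulationConfig,
    labels: Sequence[int],
) -> tuple[dict[str, dict[str, ImageVolume]], dict[str, np.ndarray]]:
    """Generate 4 co-registered volumes plus one ROI mask per patient.

    ``labels`` are the per-patient binary mutation labels (length must be
    ``n_patients``).  Mutant ROIs use the larger configured radius and
    blob texture blended in with weight ``texture_contrast``; wild-type
    ROIs are compact with a dark core and bright rim.  Sequences share one
    anatomy through different monotone contrast transfer functions, so
    registration is exact by construction.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != config.n_patients:
        raise ConfigurationError(
            f"labels length {labels.size} != n_patients {config.n_patients}"
        )
    shape = config.image_shape
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    grid = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
    )
    center_vox = (np.asarray(shape) - 1) / 2.0
    brain_semi = 0.46 * np.asarray(shape) * spacing
    contrast = float(np.clip(config.texture_contrast, 0.0, 1.0))

    volumes: dict[str, dict[str, ImageVolume]] = {}
    masks: dict[str, np.ndarray] = {}
    for i, label in enumerate(labels):
        rng = _patient_rng(config.seed, _STAGE_IMAGE, i)
        pid = _patient_id(i)
        radius = config.roi_radius_by_label[int(label)]

        # brain ellipsoid + smooth parenchyma variation
        rel = (grid - center_vox[:, None, None, None]) * spacing[:, None, None, None]
        brain = (rel**2 / (brain_semi**2)[:, None, None, None]).sum(axis=0) <= 1.0
        base = 1.0 + 0.1 * ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)

        # ROI sphere placed so it fits within the brain ellipsoid
        max_shift = np.maximum(brain_semi * 0.5 - radius, 0.0)
        offset = rng.uniform(-max_shift, max_shift)
        tumor_center = center_vox * spacing + offset
        dist = np.sqrt(
            ((grid * spacing[:, None, None, None]
              - tumor_center[:, None, None, None]) ** 2).sum(axis=0)
        )
        roi = dist <= radius
        if not roi.any():  # pragma: no cover - guarded by config validation
            raise ConfigurationError("ROI radius produced an empty mask")

        # wild-type regime: dark necrotic core, bright rim
        core = dist <= 0.5 * radius
        rim = roi & ~core
        wt_pattern = np.where(core, 0.45, np.where(rim, 1.6, 0.0))
        wt_pattern += 0.05 * rng.standard_normal(shape)

        # mutant regime: fragmented multi-scale blob texture
        mut_pattern = 1.0 + 0.9 * _multiscale_noise(shape, rng)

        blend = contrast * label
        tumor = (1.0 - blend) * wt_pattern + blend * mut_pattern

        anatomy = np.where(brain, base, 0.0)
        anatomy = np.where(roi, tumor, anatomy)
        anatomy += config.noise_sd * rng.standard_normal(shape)

        rim_boost = 0.3 * rim.astype(float)
        seq_values = {
            "T1pre": anatomy,
            "T1post": anatomy + rim_boost,
            "T2": 2.2 - anatomy,
            "FLAIR": 0.5 + 0.7 * anatomy,
        }
        volumes[pid] = {
            seq: ImageVolume(vals, tuple(spacing)) for seq, vals in seq_values.items()
        }
        masks[pid] = roi
    return volumes, masks


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_cohort_tables(
    outdir: str | Path,
    cohort: pd.DataFrame,
    variants: Sequence[VariantRecord],
    segments: Sequence[CNVSegment],
    truth: GroundTruth,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "variants": outdir / "variants.maf.tsv",
        "segments": outdir / "segments.seg.tsv",
        "truth": outdir / "ground_truth.json",
    }
    cohort.to_csv(paths["cohort"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "gene": v.gene,
                "variant_classification": v.variant_classification,
            }
            for v in variants
        ]
    ).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "chrom": s.chrom,
                "arm": s.arm,
                "start": s.start,
                "end": s.end,
                "seg_mean": s.seg_mean,
            }
            for s in segments
        ]
    ).to_csv(paths["segments"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths


def write_image_cohort(
    outdir: str | Path,
    volumes: Mapping[str, Mapping[str, ImageVolume]],
    masks: Mapping[str, np.ndarray],
) -> list[Path]:
    """Write one NIfTI file per sequence per patient plus the mask."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for pid, seqs in volumes.items():
        for seq, vol in seqs.items():
            affine = np.diag(list(vol.spacing) + [1.0])
            path = outdir / f"{pid}_{seq}.nii.gz"
            nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), path)
            written.append(path)
        mask = masks[pid]
        affine = np.diag(list(seqs[SEQUENCES[0]].spacing) + [1.0])
        path = outdir / f"{pid}_mask.nii.gz"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)
        written.append(path)
    return written
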