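"""Configuration objects for the pipeline.

Every numeric constant used by the analysis lives here exactly once, so a
full pipeline profile is a single serializable object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "TransformBankConfig",
    "SelectionConfig",
    "EvaluationConfig",
    "ThresholdConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its documented range."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic radiogenomic cohort generator.

    The defaults emulate the marginal/conditional rates of the reference
    cohort: ~22.8% mutation prevalence, near-containment of the mutation
    within IDH-mutant AND 1p/19q-codeleted patients, and a protective
    proportional hazard for mutants.
    """

    n_patients: int = 120
    cic_prevalence: float = 0.228
    p_idh_given_cic: float = 0.991
    p_codel_given_cic: float = 0.931
    cic_rate_in_codel_idh: float = 0.659
    p_idh_given_nothing: float = 0.70
    hazard_ratio_cic: float = 0.30
    baseline_hazard: float = 1.0 / 2000.0  # events per day
    censor_rate: float = 0.45
    image_shape: tuple[int, int, int] = (40, 40, 28)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_radius_by_label: tuple[float, float] = (6.0, 9.0)  # (wild-type, mutant) mm
    texture_contrast: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cic_prevalence",
            "p_idh_given_cic",
            "p_codel_given_cic",
            "cic_rate_in_codel_idh",
            "p_idh_given_nothing",
            "censor_rate",
        ):
            _check_fraction(name, getattr(self, name))
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.hazard_ratio_cic <= 0:
            raise ConfigurationError("hazard_ratio_cic must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        self.image_shape = tuple(int(v) for v in self.image_shape)  # type: ignore[assignment]
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)  # type: ignore[assignment]
        self.roi_radius_by_label = tuple(float(v) for v in self.roi_radius_by_label)  # type: ignore[assignment]
        if len(self.image_shape) != 3 or any(d < 8 for d in self.image_shape):
            raise ConfigurationError("image_shape must be a triple with all dims >= 8")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel_spacing must be positive")
        max_radius = max(self.roi_radius_by_label)
        half_extent = min(
            d * s / 2.0 for d, s in zip(self.image_shape, self.voxel_spacing)
        )
        if max_radius >= half_extent:
            raise ConfigurationError(
                f"roi radius {max_radius} exceeds half the smallest image extent "
                f"({half_extent})"
            )
        if self.texture_contrast < 0:
            raise ConfigurationError("texture_contrast must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class TransformBankConfig:
    """Which derived images to compute before texture extraction.

    ``wavelet_bands`` lists sub-band labels from the 8 combinations
    LLL ... HHH; ``lbp3d_radii`` are voxel radii for the 3D local-pattern
    operator.
    """

    original: bool = True
    wavelet_bands: tuple[str, ...] = (
        "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
    )
    square: bool = True
    squareroot: bool = True
    logarithm: bool = True
    exponential: bool = True
    gradient: bool = True
    lbp2d: bool = True
    lbp3d_radii: tuple[int, ...] = (1, 2, 3)
    wavelet_name: str = "coif1"

    _VALID_BANDS = frozenset(
        {"LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"}
    )

    def __post_init__(self) -> None:
        self.wavelet_bands = tuple(str(b) for b in self.wavelet_bands)  # type: ignore[assignment]
        self.lbp3d_radii = tuple(int(r) for r in self.lbp3d_radii)  # type: ignore[assignment]
        bad = set(self.wavelet_bands) - self._VALID_BANDS
        if bad:
            raise ConfigurationError(f"unknown wavelet sub-band label(s): {sorted(bad)}")

    def transform_labels(self) -> list[str]:
        labels: list[str] = []
        if self.original:
            labels.append("original")
        labels.extend(f"wavelet-{b}" for b in self.wavelet_bands)
        for flag, label in (
            (self.square, "square"),
            (self.squareroot, "squareroot"),
            (self.logarithm, "logarithm"),
            (self.exponential, "exponential"),
            (self.gradient, "gradient"),
            (self.lbp2d, "lbp-2D"),
        ):
            if flag:
                labels.append(label)
        labels.extend(f"lbp-3D-m{i}" for i, _ in enumerate(self.lbp3d_radii, start=1))
        return labels


@dataclass
class SelectionConfig:
    folds: int = 5
    repetitions: int = 100
    n_alphas: int = 100
    alpha_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")


@dataclass
class EvaluationConfig:
    repetitions: int = 1000
    test_fraction: float = 0.2
    alpha: float = 0.05
    ridge_c: float = 1000.0  # weak L2 stabilization of the logistic fit
    curve_grid_points: int = 101

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must be in (0, 1)")
        _check_fraction("alpha", self.alpha)


@dataclass
class ThresholdConfig:
    segment_mean_deletion: float = -0.2
    arm_deleted_fraction: float = 0.5
    gene_frequency_genomic: float = 0.05
    gene_frequency_imaging: float = 0.10
    p_significant: float = 0.05
    p_survival_screen: float = 0.1
    discretization_bin_width: float = 0.25


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run; round-trips through YAML."""

    output_dir: str = "pipeline_output"
    master_seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    transforms: TransformBankConfig = field(default_factory=TransformBankConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        for fld, sub_cls in (
            ("simulation", SimulationConfig),
            ("transforms", TransformBankConfig),
            ("selection", SelectionConfig),
            ("evaluation", EvaluationConfig),
            ("thresholds", ThresholdConfig),
        ):
            if fld in data:
                sub = data.pop(fld)
                kwargs[fld] = sub_cls(**sub) if isinstance(sub, dict) else sub
        kwargs.update(data)
        return cls(**kwargs)


def _tuples_to_lists(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_tuples_to_lists(config.to_dict()), fh, sort_keys=False)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)
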