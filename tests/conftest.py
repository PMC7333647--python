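import numpy as np
import pytest

from gliomics.config import SimulationConfig, TransformBankConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_config():
    """Small, fast cohort configuration shared across tests."""
    return SimulationConfig(
        n_patients=16,
        image_shape=(24, 24, 16),
        roi_radius_by_label=(4.0, 6.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def minimal_transforms():
    """Original-image-only transform bank (fast extraction)."""
    return TransformBankConfig(
        original=True,
        wavelet_bands=(),
        square=False,
        squareroot=False,
        logarithm=False,
        exponential=False,
        gradient=False,
        lbp2d=False,
        lbp3d_radii=(),
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    from gliomics import synthcohort

    cohort, variants, segments, truth = synthcohort.generate_genomic_cohort(
        small_sim_config
    )
    return cohort, variants, segments, truth


@pytest.fixture(scope="session")
def small_images(small_sim_config, small_cohort):
    from gliomics import synthcohort

    _, _, _, truth = small_cohort
    return synthcohort.generate_image_cohort(small_sim_config, truth.cic_label)
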