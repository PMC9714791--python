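import numpy as np
import pytest

from phenorev.simulate import (
    BehaviorSimConfig,
    DESimConfig,
    ImageSimConfig,
    simulate_behavior,
    simulate_de_tables,
    simulate_images,
)


@pytest.fixture(scope="session")
def full_rescue_sim():
    """Small DE simulation where every dysregulated gene is exactly
    reversed (alpha = -1) with tiny standard errors."""
    cfg = DESimConfig(
        n_genes=400,
        frac_dysregulated=0.5,
        alpha_by_scenario={"rescue": -1.0},
        effect_mean=2.0,
        effect_sd=0.3,
        se_low=0.01,
        se_high=0.02,
        seed=11,
    )
    disease, treatment, truth = simulate_de_tables(cfg)
    return cfg, disease, treatment, truth


@pytest.fixture(scope="session")
def two_group_behavior():
    cfg = BehaviorSimConfig(
        groups=[("a", 30), ("b", 30)],
        n_features=5,
        mean_shift={"b": 2.0},
        feature_correlation=0.4,
        seed=5,
    )
    return simulate_behavior(cfg)


@pytest.fixture(scope="session")
def spot_image_sim():
    cfg = ImageSimConfig(
        image_shape=(256, 256),
        n_nuclei=8,
        nuclear_spot_rate=1.5,
        extranuclear_spot_rate=1200.0,
        spot_sigma_px=2.0,
        background_level=0.05,
        noise_sd=0.005,
        seed=7,
    )
    return cfg, simulate_images(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
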