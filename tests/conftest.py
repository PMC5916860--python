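"""Shared fixtures: small rendered leaves and analytic cohorts.

Everything is generated at call time from seeds; no stored data.  Render
resolution is kept at 40-80 dpi so the whole suite stays fast — the oracle
comparisons are against ground truth computed from the very same rendered
masks, so they are resolution-honest.
"""

import numpy as np
import pytest

from leafdyn.dynamics import build_interval_scheme, dynamic_features
from leafdyn.synthetic import (
    DEFAULT_PROFILES,
    ExperimentConfig,
    render_leaf_image,
    sample_plant_parameters,
    simulate_features,
)

DEFAULT_SCHEDULE = tuple(range(20, 45, 3))


@pytest.fixture(scope="session")
def render_cfg():
    return ExperimentConfig(dpi=60.0, master_seed=0)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return ExperimentConfig(dpi=60.0, noise_sigma=0.0, master_seed=0)


@pytest.fixture(scope="session")
def third_leaf():
    """One rendered 3rd leaf mid-experiment, with ground truth.

    Rendered at 100 dpi: the tip-third divider is pixel-quantized, so
    colour-fidelity checks need enough resolution that region-convention
    differences of a pixel or two stop dominating the region mean.
    """
    cfg = ExperimentConfig(dpi=100.0, master_seed=0)
    params = sample_plant_parameters(DEFAULT_PROFILES["N2"], seed=3, cv=0.1,
                                     plant_id="fx-N2")
    img, truth = render_leaf_image(params, 32, "3rd", cfg)
    return img, truth


@pytest.fixture(scope="session")
def scheme3():
    return build_interval_scheme(DEFAULT_SCHEDULE, 3)


@pytest.fixture(scope="session")
def scheme6():
    return build_interval_scheme(DEFAULT_SCHEDULE, 6)


@pytest.fixture(scope="session")
def analytic_cohort():
    """Default-condition feature table via the analytic fast path."""
    cfg = ExperimentConfig(master_seed=7)
    return cfg, simulate_features(cfg)


@pytest.fixture(scope="session")
def analytic_dyn3(analytic_cohort, scheme3):
    _, feats = analytic_cohort
    return dynamic_features(feats, scheme3)


@pytest.fixture(scope="session")
def analytic_dyn6(analytic_cohort, scheme6):
    _, feats = analytic_cohort
    return dynamic_features(feats, scheme6)
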