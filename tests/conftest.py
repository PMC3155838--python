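"""Shared fixtures: small models and designs built programmatically."""

import numpy as np
import pytest

from popkdesign import (
    BATEMAN,
    DOST,
    Design,
    DesignConstraints,
    Group,
    build_competing_set,
    build_population_model,
)
from popkdesign.presets import get_design_preset, get_model_preset


@pytest.fixture(scope="session")
def adult_model():
    """Central adult Bateman-with-lag population model."""
    pm, ci = get_model_preset("adult_bateman_lag")
    return pm


@pytest.fixture(scope="session")
def adult_ci():
    return get_model_preset("adult_bateman_lag")[1]


@pytest.fixture(scope="session")
def dost_model():
    return get_model_preset("adult_dost_lag")[0]


@pytest.fixture(scope="session")
def adult_design():
    """Published-style adult design: 60 subjects, 4 samples."""
    g = Group(n_subjects=60, times=np.array([20 / 60, 35 / 60, 3.0, 6.2]))
    return Design(groups=[g], constraints=DesignConstraints())


@pytest.fixture(scope="session")
def adult_preset():
    return get_design_preset("adult")


@pytest.fixture()
def tiny_toy_set():
    """Single-member competing set over a Dost model without lag (small and
    fast for optimizer brute-force checks)."""
    pm = build_population_model(
        DOST,
        theta={"k": 1.0, "v_f": 40.0, "tlag": 0.0},
        bsv_cv={"k": 20.0, "v_f": 30.0},
        sigma_prop=0.2, sigma_add=0.02,
        fixed_theta=("tlag",),
        label="toy_dost",
    )
    return build_competing_set([(pm, {})], central_weight=1.0)
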