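"""Shared fixtures.

The expensive synthetic experiments and preset fields are session-scoped
so the unit, property and acceptance tests all reuse one computation.
"""

import warnings

import numpy as np
import pytest

from brinkswim.brinkman_core import GridSpec, swimmer_preset, synthesize_flow
from brinkswim.ptv_pipeline import records_from_tracks, reconstruct_field
from brinkswim.synthetic_data import advect_tracers, scenario_config


@pytest.fixture(scope="session")
def two_gaussian_field():
    """Two-Gaussian H10 preset on the standard 90 um, 1 um grid."""
    model = swimmer_preset("two_gaussian", H=10.0)
    return synthesize_flow(model, GridSpec.centered(90.0, 1.0))


@pytest.fixture(scope="session")
def preset_fields():
    """All four preset fields at H = 10 um on the 90 um grid."""
    grid = GridSpec.centered(90.0, 1.0)
    return {
        name: synthesize_flow(swimmer_preset(name, H=10.0), grid)
        for name in ("two_stokeslet", "two_gaussian", "three_stokeslet", "three_gaussian")
    }


@pytest.fixture(scope="session")
def three_gaussian_h30_field():
    model = swimmer_preset("three_gaussian", H=30.0)
    return synthesize_flow(model, GridSpec.centered(90.0, 1.0))


@pytest.fixture(scope="session")
def h10_experiment():
    """Full-scale synthetic H10 experiment (500 tracers, 8.2 s)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return advect_tracers(scenario_config("H10", seed=3), truth_window=90.0)


@pytest.fixture(scope="session")
def h30_experiment():
    """Full-scale synthetic H30 experiment (fast straight swimmer)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return advect_tracers(scenario_config("H30", seed=3), truth_window=90.0)


@pytest.fixture(scope="session")
def h10_recovered(h10_experiment):
    """PTV-chain reconstruction of the synthetic H10 flow field."""
    exp = h10_experiment
    records = records_from_tracks(exp.tracks, exp.pose, frame_gap=exp.config.dt)
    return reconstruct_field(records, window=90.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
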