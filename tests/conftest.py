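"""Shared fixtures: small phantoms and toy volumes sized for fast tests."""

import numpy as np
import pytest

import arcplan as ap


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse 4-phase phantom config used by most planning tests."""
    return ap.PhantomConfig(
        shape=(40, 40, 40), spacing=(4.0, 4.0, 4.0), n_phases=4,
        gtv_radius_mm=8.0, amplitude_mm=8.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return ap.build_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_setup(small_cfg):
    """Phantom + CTVexp + machine + default 84-scenario grid (coarse grid)."""
    return ap.default_setup(small_cfg)


@pytest.fixture(scope="session")
def water_64():
    """Uniform unit-density cube, 64^3 at 2.5 mm."""
    return ap.VoxelVolume(np.ones((64, 64, 64)), (2.5, 2.5, 2.5))


@pytest.fixture(scope="session")
def optimized_small_plan(small_setup):
    """One IMPT plan optimized on a reduced scenario set, then normalized."""
    plan = ap.make_plan(small_setup, "IMPT", lateral_spacing_mm=8.0)
    scen = ap.enumerate_scenarios(5.0, 0.03, [0])
    return ap.optimize_and_normalize(
        small_setup, plan, scenarios=scen, max_iter=60, max_points_per_roi=1200
    )
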