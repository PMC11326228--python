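"""Shared fixtures: the desk-scale study conditions, computed once.

The expensive session fixtures (periodic flow solutions, delivery runs)
represent the default study conditions — a 1-kHz, 80-dB-SPL traveling wave
on the 12-mm gerbil two-layer domain — and are reused by both the unit and
the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cochstream import driftflow, transport, travelwave
from cochstream.driftflow import SolverConfig, solve_drift, two_layer_grid
from cochstream.transport import TransportConfig, run_delivery
from cochstream.travelwave import (CochlearGeometry, TravelingWaveParams,
                                   WallMotionField, wall_motion)


@pytest.fixture(scope="session")
def geometry() -> CochlearGeometry:
    return CochlearGeometry()


@pytest.fixture(scope="session")
def wave_params() -> TravelingWaveParams:
    return TravelingWaveParams()


@pytest.fixture(scope="session")
def grid():
    return two_layer_grid()


@pytest.fixture(scope="session")
def tail_region(geometry, wave_params):
    """(x_lo, x_hi) of the traveling-wave tail: 2-4 mm basal of the peak."""
    x_cf = wave_params.cf_place(geometry)
    return (x_cf - 4e-3, x_cf - 2e-3)


def _drift(grid, geometry, params):
    wm = wall_motion(geometry, params)
    return solve_drift(grid, wm, config=SolverConfig(store_last_cycle=False))


@pytest.fixture(scope="session")
def flow_default(grid, geometry, wave_params):
    """Periodic flow + drift for the default traveling wave."""
    return _drift(grid, geometry, wave_params)


@pytest.fixture(scope="session")
def flow_half_amplitude(grid, geometry, wave_params):
    from dataclasses import replace
    return _drift(grid, geometry, replace(wave_params,
                                          a_peak=wave_params.a_peak / 2))


@pytest.fixture(scope="session")
def flow_standing(grid, geometry, wave_params):
    """Standing-wave forcing: same envelope, no phase propagation."""
    wm = wall_motion(geometry, wave_params)
    standing = WallMotionField(x=wm.x, envelope=wm.envelope,
                               phase=np.zeros_like(wm.phase),
                               frequency=wm.frequency)
    return solve_drift(grid, standing,
                       config=SolverConfig(store_last_cycle=False))


@pytest.fixture(scope="session")
def flow_silent(grid, geometry, wave_params):
    """active_gain -> 0: stationary walls (salicylate emulation)."""
    return _drift(grid, geometry, wave_params.with_gain(0.0))


@pytest.fixture(scope="session")
def delivery_silence(grid):
    return run_delivery(grid, TransportConfig(horizon=7200.0), None)


@pytest.fixture(scope="session")
def delivery_sound(grid, flow_default):
    return run_delivery(grid, TransportConfig(horizon=7200.0),
                        flow_default.drift)


@pytest.fixture(scope="session")
def delivery_salicylate(grid, flow_silent):
    return run_delivery(grid, TransportConfig(horizon=7200.0),
                        flow_silent.drift)


@pytest.fixture(scope="session")
def delivery_1d_oracle(grid):
    """Silence case with the patch on the whole basal end wall: exactly the
    1-D erfc configuration."""
    cfg = TransportConfig(patch_on_end_wall=True, patch_extent=np.inf,
                          horizon=3600.0)
    return cfg, run_delivery(grid, cfg, None)
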