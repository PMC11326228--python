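"""Advection–diffusion transport: conservation, oracles, effect times."""

import numpy as np
import pytest

from cochstream.driftflow import DriftField, two_layer_grid
from cochstream.transport import (TransportConfig, TransportSolver,
                                  advance_concentration, diffusion_effect_time,
                                  effect_time_map, run_delivery)


def two_cell_drift(grid, strength=2.5e-9, x_lo=2e-3, x_b=5e-3, x_hi=8e-3):
    """Synthetic divergence-free drift: two counter-rotating cells in the
    scala meeting at ``x_b`` (a transport barrier), built from a stream
    function so the discrete divergence vanishes exactly."""
    h_s = grid.y_faces[grid.membrane_j]
    xn = np.arange(grid.nx + 1) * grid.dx
    g = np.zeros_like(xn)
    m1 = (xn > x_lo) & (xn < x_b)
    m2 = (xn >= x_b) & (xn < x_hi)
    g[m1] = np.sin(np.pi * (xn[m1] - x_lo) / (x_b - x_lo))
    g[m2] = -np.sin(np.pi * (xn[m2] - x_b) / (x_hi - x_b))
    sy = np.where(grid.y_faces <= h_s,
                  np.sin(np.pi * np.clip(grid.y_faces, 0, h_s) / h_s), 0.0)
    psi = strength * g[:, None] * sy[None, :]
    u = (psi[:, 1:] - psi[:, :-1]) / grid.dy[None, :]
    v = -(psi[1:, :] - psi[:-1, :]) / grid.dx
    return DriftField(u=u, v=v, grid=grid, period=1.0, converged=True,
                      n_cycles=0, periodicity_metric=0.0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"diffusivity": 0.0}, {"c0": -1.0}, {"f_thr": 0.0}, {"f_thr": 1.0},
        {"horizon": -10.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TransportConfig(**kwargs)


class TestConservation:
    def test_uniform_field_unchanged_sealed(self, grid):
        cfg = TransportConfig(patch_extent=0.0)       # sealed domain
        solver = TransportSolver(grid, cfg, None)
        solver.c[:] = 3.0
        for _ in range(5):
            advance_concentration(solver, 5.0)
        np.testing.assert_allclose(solver.c, 3.0, rtol=1e-12)

    def test_uniform_field_unchanged_under_solver_drift(self, grid,
                                                        flow_default):
        # the MAC drift field is discretely divergence-free up to the
        # pressure-solve residual (~1e-9 /s), so a uniform concentration is
        # steady to that level per unit time
        cfg = TransportConfig(patch_extent=0.0)
        solver = TransportSolver(grid, cfg, flow_default.drift)
        solver.c[:] = 1.0
        for _ in range(5):
            solver.step(min(2.0, solver.cfl_dt()[0]))
        np.testing.assert_allclose(solver.c, 1.0, rtol=1e-7)

    def test_sealed_mass_conserved(self, grid):
        cfg = TransportConfig(patch_extent=0.0)
        solver = TransportSolver(grid, cfg, None)
        rng = np.random.default_rng(1)
        solver.c[:] = rng.uniform(0, 10, solver.c.shape)
        m0 = solver.total_mass()
        for _ in range(1000):
            solver.step(5.0)
        assert abs(solver.total_mass() - m0) / m0 < 1e-10

    def test_mass_budget_closes_with_source(self, delivery_silence):
        assert delivery_silence.mass_closure < 1e-3

    def test_cfl_violation_names_limiting_cell(self, grid):
        d = two_cell_drift(grid, strength=2.5e-9)
        solver = TransportSolver(grid, TransportConfig(), d)
        dt_max, where = solver.cfl_dt()
        with pytest.raises(ValueError, match="CFL"):
            solver.step(dt_max * 2)


class TestMaximumPrinciple:
    def test_bounds_hold_through_delivery(self, delivery_sound):
        cfg_c0 = 10.0
        for snap in delivery_sound.snapshots:
            assert snap.c.min() >= -1e-6 * cfg_c0
            assert snap.c.max() <= cfg_c0 * (1 + 1e-6)
        assert delivery_sound.final.c.min() >= -1e-6 * cfg_c0
        assert delivery_sound.final.c.max() <= cfg_c0 * (1 + 1e-6)


class TestDiffusionOracle:
    def test_silence_matches_erfc_closed_form(self, delivery_1d_oracle):
        cfg, res = delivery_1d_oracle
        etm = res.effect_times
        sel = (etm.x > 2e-3) & etm.reached
        assert sel.sum() > 20
        exact = diffusion_effect_time(etm.x[sel], cfg.diffusivity, cfg.f_thr)
        rel = np.abs(etm.t_e[sel] - exact) / exact
        assert rel.max() < 0.05

    def test_monotone_front(self, delivery_silence):
        etm = delivery_silence.effect_times
        te = etm.t_e[etm.reached]
        assert te.size > 10
        assert np.all(np.diff(te) > 0)

    def test_grid_refinement_changes_t_e_little(self, delivery_1d_oracle):
        cfg, coarse = delivery_1d_oracle
        fine_grid = two_layer_grid(dx=50e-6, ny_corti=12, ny_scala=50)
        fine = run_delivery(fine_grid, cfg, None)
        ec, ef = coarse.effect_times, fine.effect_times
        sel = (ec.x > 2e-3) & ec.reached
        t_f = np.interp(ec.x[sel], ef.x[ef.reached], ef.t_e[ef.reached])
        assert np.max(np.abs(ec.t_e[sel] - t_f) / t_f) < 0.02


class TestEffectTimeMap:
    def test_linear_history_crossing(self):
        cfg = TransportConfig()
        t1 = 100.0
        times = np.linspace(0, t1, 101)
        conc = cfg.c0 * times[:, None] / t1
        etm = effect_time_map(times, conc, np.array([1e-3]), cfg)
        assert etm.t_e[0] == pytest.approx(cfg.f_thr * t1, rel=1e-9)

    def test_point_at_threshold_from_start(self):
        cfg = TransportConfig()
        conc = np.full((10, 1), cfg.c0)
        etm = effect_time_map(np.arange(10.0), conc, np.array([0.0]), cfg)
        assert etm.t_e[0] == 0.0 and etm.reached[0]

    def test_never_crossing_flagged(self):
        cfg = TransportConfig()
        conc = np.full((10, 1), 0.5 * cfg.threshold)
        etm = effect_time_map(np.arange(10.0), conc, np.array([1e-3]), cfg)
        assert not etm.reached[0]
        assert np.isnan(etm.t_e[0])

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            effect_time_map(np.array([]), np.zeros((0, 3)),
                            np.zeros(3), TransportConfig())


class TestAdvectiveFacilitation:
    def test_sound_speeds_up_tail_delivery(self, delivery_silence,
                                           delivery_sound, tail_region):
        es, ed = delivery_silence.effect_times, delivery_sound.effect_times
        sel = ((es.x > tail_region[0]) & (es.x < tail_region[1])
               & es.reached & ed.reached)
        assert sel.sum() >= 15
        assert np.all(ed.t_e[sel] < es.t_e[sel])

    def test_silencing_the_wave_recovers_diffusion(self, delivery_silence,
                                                   delivery_salicylate):
        es = delivery_silence.effect_times
        ea = delivery_salicylate.effect_times
        sel = es.reached & ea.reached
        rel = np.abs(ea.t_e[sel] - es.t_e[sel]) / es.t_e[sel]
        assert rel.max() < 0.02

    def test_stalling_point_at_circulation_boundary(self, grid):
        # two counter-rotating cells meeting at x_b: fast track basal of it
        # (flattened t_E), contour stacking (steep t_E rise) across it
        x_b = 5e-3
        d = two_cell_drift(grid, x_b=x_b)
        cfg = TransportConfig(horizon=5400.0, observation=5)
        adv = run_delivery(grid, cfg, d)
        sil = run_delivery(grid, cfg, None)

        def slope(etm, a, b):
            m = (etm.x >= a) & (etm.x <= b) & etm.reached
            return np.polyfit(etm.x[m], etm.t_e[m], 1)[0]

        fast = slope(adv.effect_times, 3e-3, 4.5e-3)
        stall = slope(adv.effect_times, x_b - 0.4e-3, x_b + 0.6e-3)
        diffusive = slope(sil.effect_times, 3e-3, 4.5e-3)
        assert fast < 0.5 * diffusive      # fast track flattens the curve
        assert stall > 3.0 * fast          # plateau ends in a steep rise
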