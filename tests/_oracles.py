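"""Closed-form flow oracles shared by the solver and acceptance tests."""

import numpy as np

from cochstream.driftflow import (CortiFlowSolver, FluidProperties, Grid2D,
                                  SolverConfig)


def oscillating_plate_error(ny: int, periods: int = 12,
                            steps_per_period: int = 200) -> float:
    """Relative L2 error against Stokes' second problem:
    u(y,t) = U0 exp(-y/delta) cos(w t - y/delta), delta = sqrt(2 nu / w)."""
    nu, f, u0 = 7e-5, 100.0, 1e-3
    om = 2 * np.pi * f
    delta = np.sqrt(2 * nu / om)
    height = 7 * delta
    grid = Grid2D(nx=4, dx=height / 4, y_faces=np.linspace(0, height, ny + 1),
                  periodic_x=True)
    solver = CortiFlowSolver(
        grid, FluidProperties(nu=nu), None, period=1 / f,
        config=SolverConfig(steps_per_period=steps_per_period,
                            store_last_cycle=False),
        bottom_tangential=lambda t: u0 * np.cos(om * t))
    for _ in range(periods * steps_per_period):
        solver.step()
    y = grid.y_centers
    exact = u0 * np.exp(-y / delta) * np.cos(om * solver.t - y / delta)
    num = solver.u.mean(axis=0)
    return float(np.linalg.norm(num - exact) / np.linalg.norm(exact))


def poiseuille_error(ny: int) -> float:
    """Relative L2 error against the body-force-driven channel profile
    u(y) = f/(2 nu) y (h - y) in a periodic channel."""
    nu, h, fx = 7e-5, 0.5e-3, 1e-2
    grid = Grid2D(nx=4, dx=h, y_faces=np.linspace(0, h, ny + 1),
                  periodic_x=True)
    solver = CortiFlowSolver(
        grid, FluidProperties(nu=nu), None, period=1e-2,
        config=SolverConfig(store_last_cycle=False), body_force=(fx, 0.0))
    for _ in range(800):        # ~20 viscous times: fully developed
        solver.step()
    y = grid.y_centers
    exact = fx / (2 * nu) * y * (h - y)
    num = solver.u.mean(axis=0)
    return float(np.linalg.norm(num - exact) / np.linalg.norm(exact))
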