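"""Solver correctness: boundary conditions, oracles, conservation, stability."""

import numpy as np
import pytest

import oxychip as oc
from oxychip.rd_solver import ConvergenceError

from conftest import make_slab_grid


def explicit_reference(C0, spacing, dt_sub, n_sub, p, dirichlet_value):
    """Independent brute-force oracle: explicit Euler on a 1-D planar slab
    with Dirichlet ends, consumption law written out directly."""
    C = C0.copy()
    for _ in range(n_sub):
        lap = np.zeros_like(C)
        lap[1:-1] = (C[:-2] - 2 * C[1:-1] + C[2:]) / spacing**2
        t = np.clip(
            (C - p.Ccr + p.smooth_width) / (2 * p.smooth_width), 0.0, 1.0
        )
        R = p.Rmax_bulk * C / (C + p.kMM) * t * t * (3 - 2 * t)
        C = C + dt_sub * (p.D * lap - R)
        C[0] = C[-1] = dirichlet_value
    return C


class TestBoundaryConditions:
    def test_atmosphere_nodes_fixed_at_normoxic_level(self, default_grid,
                                                      default_params):
        f = oc.uniform_field(default_grid, 0.05)
        f2 = oc.apply_boundary_conditions(f, default_grid, default_params)
        assert np.all(f2.C[default_grid.dirichlet] == 0.2)
        interior = default_grid.free & ~default_grid.dirichlet
        assert np.all(f2.C[interior] == 0.05)

    def test_all_solid_geometry_is_ill_posed(self, default_params):
        labels = np.full((8, 8), int(oc.Region.BARRIER_SOLID), dtype=np.int8)
        grid = oc.RegionGrid(labels=labels, spacing=25e-6)
        f = oc.OxygenField(grid, np.full((8, 8), np.nan))
        with pytest.raises(ValueError, match="atmosphere"):
            oc.apply_boundary_conditions(f, grid, default_params)

    def test_no_dirichlet_nodes_rejected_by_solver(self, default_params):
        grid = make_slab_grid(20, 20e-6)
        grid.dirichlet[:] = False
        with pytest.raises(ValueError, match="atmosphere"):
            oc.solve_steady_state(grid, default_params)


class TestTransientStep:
    def test_pure_diffusion_equilibrium_is_fixed_point(self, default_grid):
        p = oc.KineticsParams(Rmax_cell=0.0)
        f = oc.uniform_field(default_grid, p.C_atm)
        f2 = oc.step_transient(f, 500.0, p)
        assert np.allclose(f2.C[default_grid.free], p.C_atm, atol=1e-12)

    def test_diffusion_dissipates_perturbation(self):
        grid = make_slab_grid(40, 20e-6)
        p = oc.KineticsParams(Rmax_cell=0.0)
        f = oc.uniform_field(grid, p.C_atm)
        f.C[15:25, 0] = 0.5 * p.C_atm  # interior dip
        f = oc.apply_boundary_conditions(f, grid, p)
        dev = [np.abs(f.C[grid.free] - p.C_atm).sum()]
        for _ in range(5):
            f = oc.step_transient(f, 0.05, p)
            dev.append(np.abs(f.C[grid.free] - p.C_atm).sum())
        assert np.all(np.diff(dev) < 0)

    def test_implicit_matches_fine_step_explicit_oracle(self):
        # three random kinetic parameter draws on a 50-node slab
        rng = np.random.default_rng(20240917)
        n, h, dt, n_steps = 50, 20e-6, 0.1, 10
        grid = make_slab_grid(n, h)
        for _ in range(3):
            p = oc.KineticsParams(
                Rmax_cell=rng.uniform(0.01, 0.04),
                kMM=rng.uniform(0.002, 0.01),
                Ccr=rng.uniform(2e-4, 8e-4),
                smooth_width=2e-4,
            )
            x = np.linspace(0, 1, n)
            C0 = p.C_atm * (1 - 0.3 * np.sin(np.pi * x))
            f = oc.OxygenField(grid, C0[:, None].copy())
            f = oc.apply_boundary_conditions(f, grid, p)
            for _ in range(n_steps):
                f = oc.step_transient(f, dt, p, tol=1e-10)
            ref = explicit_reference(
                C0.copy(), h, dt / 1000, n_steps * 1000, p, p.C_atm
            )
            assert np.max(np.abs(f.C[:, 0] - ref)) < 1e-4

    def test_rejects_nonpositive_dt(self, default_grid, default_params):
        f = oc.uniform_field(default_grid, 0.2)
        with pytest.raises(ValueError):
            oc.step_transient(f, 0.0, default_params)

    def test_nonconvergence_is_reported(self, default_grid, default_params):
        f = oc.uniform_field(default_grid, 0.2)
        with pytest.raises(ConvergenceError):
            oc.step_transient(f, 1.0, default_params, tol=0.0, max_iter=2)


class TestSteadyState:
    def test_no_sink_gives_uniform_normoxic_field(self, default_grid):
        p = oc.KineticsParams(Rmax_cell=0.0)
        ss, rep = oc.solve_steady_state(default_grid, p)
        assert rep.converged
        assert np.allclose(ss.C[default_grid.free], p.C_atm, atol=1e-12)

    def test_slab_matches_closed_form_parabola(self):
        # zeroth-order consumption (kMM and the critical band negligible)
        # between two normoxic Dirichlet planes: C = C_atm - R0/(2D) x (L - x)
        n, h = 200, 5e-6
        grid = make_slab_grid(n, h)
        p = oc.KineticsParams(kMM=1e-8, Ccr=1e-9, smooth_width=1e-9)
        ss, rep = oc.solve_steady_state(grid, p)
        assert rep.converged
        x = grid.r - grid.r[0]
        L = x[-1]
        closed = p.C_atm - p.Rmax_bulk / (2 * p.D) * x * (L - x)
        err = np.abs(ss.C[:, 0] - closed) / closed
        assert err.max() < 0.005

    def test_maximum_principle_on_default_device(self, steady_with,
                                                 default_params):
        assert oc.max_principle_violation(steady_with[0], default_params) == 0.0

    def test_mass_balance_closes(self, steady_with):
        rep = steady_with[1]
        assert rep.converged
        assert rep.influx > 0
        assert rep.mass_balance_error < 0.01

    def test_center_concentration_grid_converged(self, default_geom,
                                                 default_params, steady_with):
        fine = oc.rasterize(default_geom, 12.5e-6)
        ss_f, rep = oc.solve_steady_state(fine, default_params)
        c_coarse = oc.radial_profile(steady_with[0]).C
        c_fine = oc.radial_profile(ss_f).C
        # compare at matching radii; absolute tolerance 2% of C_atm covers
        # the near-zero center where a relative test is ill-conditioned
        interp = np.interp(
            oc.radial_profile(steady_with[0]).r, oc.radial_profile(ss_f).r, c_fine
        )
        assert np.max(np.abs(interp - c_coarse)) < 0.02 * default_params.C_atm


class TestTransientApproach:
    def test_transient_converges_to_steady_state(self, transient_default,
                                                 steady_with, default_grid):
        ss = steady_with[0]
        free = default_grid.free
        dist = [
            float(np.max(np.abs(f.C[free] - ss.C[free])))
            for f in transient_default.fields
        ]
        # monotone decay after the onset, and small at the end of 30 min
        assert np.all(np.diff(dist[2:]) <= 1e-12)
        assert dist[-1] < 5e-4

    def test_maximum_principle_all_recorded_steps(self, transient_default,
                                                  default_params):
        for f in transient_default.fields:
            assert oc.max_principle_violation(f, default_params) == 0.0
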