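"""Sweeps, nullclines, the awareness surface and basins of attraction."""

import numpy as np
import pytest

from earlydetect import (
    DomainError,
    SimulationSettings,
    awareness_surface,
    basin_of_attraction,
    bifurcation_sweep,
    find_coexistence,
    nullclines,
    phase_portrait,
    rhs_nondim,
    simulate,
)

from conftest import DEFAULT_IC


def nearest_flip_distance(result):
    assert result.threshold_estimates, "no regime change found"
    return min(abs(e - result.analytic_threshold) for e in result.threshold_estimates)


class TestBifurcationSweep:
    def test_detection_sweep_controls_above_threshold(self, table2):
        grid = np.linspace(0.05, 3.0, 201)
        res = bifurcation_sweep(table2, "kappa", grid, t_end=200.0)
        above = grid > table2.alpha
        assert np.all(res.longrun_x[above] < 1e-6)
        assert res.analytic_threshold == table2.alpha
        # near the threshold the attractor is a small limit cycle, so the
        # terminal-snapshot classifier can flip one grid point early
        step = grid[1] - grid[0]
        assert nearest_flip_distance(res) <= 2 * step
        assert not res.failures

    def test_alpha_sweep_regime_change_at_kappa(self, benchmark):
        grid = np.linspace(0.1, 2.0, 77)
        res = bifurcation_sweep(benchmark, "alpha", grid, t_end=200.0)
        assert res.analytic_threshold == benchmark.kappa
        step = grid[1] - grid[0]
        assert nearest_flip_distance(res) <= 2 * step
        below = grid < benchmark.kappa - 2 * step
        assert np.all(res.longrun_x[np.where(below)] < 1e-6)

    def test_stronger_immune_kill_cannot_raise_longrun_tumor(self, benchmark):
        grid = np.linspace(0.05, 2.0, 50)
        res = bifurcation_sweep(benchmark, "beta", grid, t_end=200.0)
        # slack covers phase-dependent snapshots in the oscillatory window
        assert np.all(np.diff(res.longrun_x) <= 5e-3)
        assert res.longrun_x[-1] < res.longrun_x[0]

    def test_longrun_states_match_equilibria(self, table2):
        grid = np.array([0.05, 0.1, 0.2, 0.3])
        res = bifurcation_sweep(table2, "kappa", grid, t_end=200.0)
        for i, kappa in enumerate(grid):
            roots = find_coexistence(table2.replace(kappa=float(kappa)))
            stable = [r for r in roots if r.locally_stable]
            assert len(stable) == 1
            assert res.longrun_x[i] == pytest.approx(stable[0].location[0], abs=1e-4)
            assert res.longrun_y[i] == pytest.approx(stable[0].location[1], abs=1e-4)

    def test_unknown_parameter_rejected(self, table2):
        with pytest.raises(DomainError):
            bifurcation_sweep(table2, "zeta", [0.1, 0.2])

    def test_sweep_frame_shape(self, table2):
        res = bifurcation_sweep(table2, "kappa", [0.1, 3.0], t_end=50.0)
        df = res.to_frame()
        assert list(df.columns) == ["param_value", "longrun_x", "longrun_y", "regime"]
        assert set(df["regime"]) <= {"controlled", "persistent", "failed"}


class TestAwarenessSurface:
    def test_rows_are_bounded_trajectories(self, benchmark):
        times = np.linspace(0.0, 30.0, 61)
        surf = awareness_surface(benchmark, [0.2, 0.65, 1.5], times)
        assert surf.shape == (3, 61)
        assert np.all(np.isfinite(surf))
        assert np.all(surf >= -1e-9) and np.all(surf <= 1 + 1e-9)

    def test_weaker_detection_means_larger_tumor(self, benchmark):
        """Rows are ordered in alpha: the detection term weakens as alpha
        grows, so the tumor can only be (weakly) larger pointwise."""
        times = np.linspace(0.0, 30.0, 61)
        surf = awareness_surface(benchmark, [0.2, 0.65, 1.5], times)
        assert np.all(np.diff(surf, axis=0) >= -1e-6)

    def test_single_alpha_reduces_to_simulation(self, benchmark):
        times = np.linspace(0.0, 10.0, 21)
        surf = awareness_surface(benchmark, [benchmark.alpha], times)
        traj = simulate(benchmark, *DEFAULT_IC, SimulationSettings(t_end=10.0, n_out=21))
        np.testing.assert_allclose(surf[0], traj.x, atol=1e-7)


class TestNullclines:
    def test_immune_nullcline_hand_value(self, table2):
        data = nullclines(table2, x_grid=np.array([0.25]))
        assert data.immune_nullcline[1][0] == pytest.approx(0.755, rel=1e-12)

    def test_tumor_nullcline_hand_value(self, table2):
        p = table2.replace(kappa=0.0)
        data = nullclines(p, x_grid=np.array([0.6]))
        # g = 1 - 0.6 = 0.4; y = 0.1*0.4/(0.5-0.4)
        assert data.tumor_nullcline[1][0] == pytest.approx(0.4, rel=1e-12)

    @pytest.mark.parametrize("kappa", [0.0, 0.1, 0.3])
    def test_intersections_are_equilibria(self, table2, kappa):
        p = table2.replace(kappa=kappa)
        inter = nullclines(p).intersections
        roots = [r.location for r in find_coexistence(p)]
        assert len(inter) == len(roots) == 1
        assert inter[0][0] == pytest.approx(roots[0][0], abs=1e-6)
        assert inter[0][1] == pytest.approx(roots[0][1], abs=1e-6)
        # both nullcline equations hold at the reported point
        x, y = inter[0]
        assert abs(1 - x - p.beta * y / (p.gamma + y) - p.kappa / (p.alpha + p.delta * x)) < 1e-8
        assert abs(p.rho * (1 - y) * x / (p.mu + x) - p.sigma * x - p.eta) < 1e-8

    def test_strong_detection_has_no_intersection(self, table2):
        assert nullclines(table2).intersections == []

    def test_grid_outside_unit_interval_rejected(self, table2):
        with pytest.raises(DomainError):
            nullclines(table2, x_grid=np.array([0.0, 0.5]))


class TestPhasePortrait:
    def test_field_arrows_are_normalized(self, benchmark):
        port = phase_portrait(benchmark, n_field=10, t_end=20.0)
        norms = np.hypot(port.arrows_u, port.arrows_v)
        np.testing.assert_allclose(norms[port.magnitude > 0], 1.0, rtol=1e-12)
        raw_u = port.arrows_u * np.where(port.magnitude > 0, port.magnitude, 1.0)
        dx, _ = rhs_nondim((port.field_x[3, 4], port.field_y[3, 4]), benchmark)
        assert raw_u[3, 4] == pytest.approx(dx, rel=1e-12)

    def test_trajectory_bundle_converges_to_attractor(self, benchmark):
        port = phase_portrait(benchmark, t_end=300.0)
        (x_star, y_star) = find_coexistence(benchmark)[0].location
        for traj in port.trajectories:
            assert traj.terminal_state[0] == pytest.approx(x_star, abs=1e-4)
            assert traj.terminal_state[1] == pytest.approx(y_star, abs=1e-4)


class TestBasinOfAttraction:
    def test_default_regime_fully_controlled(self, table2):
        g = np.linspace(0.25, 1.0, 4)
        basin = basin_of_attraction(table2, g, g, t_end=200.0)
        assert basin.controlled_fraction == 1.0
        assert basin.n_failed == 0

    def test_weak_detection_has_persistent_cells(self, benchmark):
        g = np.linspace(0.2, 1.0, 5)
        basin = basin_of_attraction(benchmark, g, g, t_end=200.0)
        assert np.any(basin.outcome == "persistent")

    def test_labels_stable_under_doubling_horizon(self, benchmark):
        g = np.linspace(0.2, 1.0, 5)
        b1 = basin_of_attraction(benchmark, g, g, t_end=200.0)
        b2 = basin_of_attraction(benchmark, g, g, t_end=400.0)
        assert np.array_equal(b1.outcome, b2.outcome)

    def test_single_cell_reduces_to_threshold_test(self, table2):
        basin = basin_of_attraction(table2, [0.35], [0.08], t_end=50.0)
        traj = simulate(table2, 0.35, 0.08, SimulationSettings(t_end=50.0, abs_tol=1e-12))
        assert basin.final_x[0, 0] == pytest.approx(traj.terminal_state[0], abs=1e-9)
        assert basin.outcome[0, 0] == "controlled"

    def test_consistency_of_labels_and_values(self, benchmark):
        g = np.linspace(0.2, 1.0, 3)
        basin = basin_of_attraction(benchmark, g, g, t_end=100.0)
        controlled = basin.outcome == "controlled"
        assert np.array_equal(controlled, basin.final_x < basin.threshold)

    def test_out_of_box_grid_rejected(self, table2):
        with pytest.raises(DomainError):
            basin_of_attraction(table2, [0.0, 0.5], [0.5], t_end=10.0)
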