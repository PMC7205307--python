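"""Fixed points, stability, 2D reduction, trajectories, bifurcations."""

import numpy as np
import pytest

from xapswitch import (CircuitVariant, bifurcation_diagram, bistable_range,
                       find_fixed_points, integrate, jacobian, mean_mrna,
                       reduce_mrna_qss, rhs_nondimensional, table1)
from xapswitch.interface import fixture_scenarios

from conftest import random_table1_draws

WT = CircuitVariant()


def scenario_cases():
    fx = fixture_scenarios()
    # (params, variant, expected fixed-point count, expected branch)
    return [
        pytest.param(table1(), WT, 3, "both", id="reference-bistable"),
        pytest.param(table1(c_a=7.0), WT, 1, "low", id="low-inducer"),
        pytest.param(table1(c_a=40.0), WT, 1, "high", id="high-inducer"),
        pytest.param(table1(), CircuitVariant(xapB_removed=True), 1, "low",
                     id="no-transporter"),
        pytest.param(table1(), CircuitVariant(xapA_removed=True), 3, "both",
                     id="no-degradation-enzyme"),
        pytest.param(fx["fig8a"].params, fx["fig8a"].variant, 3, "both",
                     id="single-inducer-site-retuned"),
        pytest.param(fx["fig8b"].params, fx["fig8b"].variant, 3, "both",
                     id="single-promoter-site-retuned"),
        pytest.param(fx["fig8c"].params, fx["fig8c"].variant, 1, "any",
                     id="no-cooperativity-anywhere"),
    ]


@pytest.mark.parametrize("params,variant,n_expected,branch", scenario_cases())
def test_fixed_point_structure(params, variant, n_expected, branch):
    fps = find_fixed_points(params, variant)
    assert len(fps) == n_expected
    if n_expected == 3:
        assert [fp.stability for fp in fps] == ["stable", "unstable", "stable"]
    else:
        assert fps[0].stability == "stable"
        if branch == "low":
            assert fps[0].state.p_a < 1e-3
        elif branch == "high":
            assert fps[0].state.p_a > 1e-3


def test_roots_verified_separated_and_ordered(t1):
    fps = find_fixed_points(t1)
    for fp in fps:
        resid = np.max(np.abs(rhs_nondimensional(fp.state.as_array(), t1)))
        assert resid < 1e-9 * max(1.0, fp.state.x_a)
    for a, b in zip(fps, fps[1:]):
        assert (b.state.p_a - a.state.p_a) > 1e-6 * b.state.p_a
        # lower/middle/upper order holds simultaneously in all coordinates
        assert b.state.m_a > a.state.m_a and b.state.x_a > a.state.x_a


def test_scalar_reduction_matches_full_rhs_sweep(t1):
    """Brute-force oracle: the xanthosine balance evaluated through the
    full 3D RHS (with mRNA and protein at their conditional steady states)
    changes sign exactly where the fixed-point search found roots."""
    xs = np.geomspace(1e-6, 1e8, 100_000)
    g = np.empty_like(xs)
    for i, x in enumerate(xs):
        m = mean_mrna(t1, x)
        g[i] = rhs_nondimensional((m, t1.rho_p * m, x), t1)[2]
    sign_changes = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)
    roots = sorted(fp.state.x_a for fp in find_fixed_points(t1))
    assert len(sign_changes) == len(roots) == 3
    for i, root in zip(sign_changes, roots):
        assert xs[i] <= root <= xs[i + 1]


class TestJacobian:
    def test_linear_rows_are_exact(self, t1):
        J = jacobian((1e-4, 1e-2, 50.0), t1)
        assert J[1, 0] == t1.rho_p
        assert J[1, 1] == -1.0
        assert J[1, 2] == 0.0

    def test_matches_finite_differences(self, t1, rng):
        for _ in range(100):
            y = 10 ** rng.uniform(-5, 3, size=3)
            J = jacobian(y, t1)
            Jfd = np.zeros((3, 3))
            for j in range(3):
                h = 1e-5 * max(abs(y[j]), 1.0)
                yp, ym = y.copy(), y.copy()
                yp[j] += h
                ym[j] -= h
                Jfd[:, j] = (rhs_nondimensional(yp, t1)
                             - rhs_nondimensional(ym, t1)) / (2 * h)
            # finite differences lose precision through cancellation when
            # entries span many decades; scale the floor to the row size
            floor = 1e-7 * np.abs(J).max(axis=1, keepdims=True)
            assert np.all(np.abs(J - Jfd)
                          <= 1e-4 * np.abs(J) + floor + 1e-12)

    def test_middle_fixed_point_is_a_saddle(self, t1):
        mid = find_fixed_points(t1)[1]
        assert max(ev.real for ev in mid.eigenvalues) > 0


class TestReduction:
    def test_fixed_points_project_onto_2d(self, t1):
        red = reduce_mrna_qss(t1)
        fps2 = red.fixed_points()
        fps3 = find_fixed_points(t1)
        assert len(fps2) == len(fps3) == 3
        for f2, f3 in zip(fps2, fps3):
            y = (f3.state.p_a, f3.state.x_a)
            assert np.max(np.abs(red.rhs(y))) < 1e-9 * max(1.0, f3.state.x_a)

    def test_protein_nullcline_is_rho_times_activity(self, t1):
        red = reduce_mrna_qss(t1)
        xs = np.geomspace(1e-3, 1e4, 50)
        laws = red.laws
        assert np.allclose(red.protein_nullcline(xs),
                           t1.rho * laws.p_active(xs), rtol=1e-13)

    def test_stability_classes_agree_with_3d(self, t1):
        pattern2 = [fp.stability for fp in reduce_mrna_qss(t1).fixed_points()]
        pattern3 = [fp.stability for fp in find_fixed_points(t1)]
        assert pattern2 == pattern3 == ["stable", "unstable", "stable"]


class TestTrajectories:
    def test_origin_converges_high_when_monostable_high(self, t1):
        p = t1.with_(c_a=40.0)
        fp = find_fixed_points(p)[0]
        _, traj = integrate(p, (0, 0, 0), 400.0)
        assert traj[-1] == pytest.approx(fp.state.as_array(), rel=1e-5)

    def test_origin_lies_in_low_basin_when_bistable(self, t1):
        low = find_fixed_points(t1)[0]
        _, traj = integrate(t1, (0, 0, 0), 400.0)
        assert traj[-1] == pytest.approx(low.state.as_array(), rel=1e-5)

    def test_protein_relaxation_is_non_oscillatory(self, t1):
        _, traj = integrate(t1.with_(c_a=25.0), (0, 0, 0), 400.0,
                            n_points=2000)
        dp = np.diff(traj[:, 1])
        moving = dp[np.abs(dp) > 1e-8 * traj[:, 1].max()]
        flips = np.sum(np.diff(np.sign(moving)) != 0)
        assert flips <= 1

    def test_trapping_region_all_starts_converge(self, t1, rng):
        stable = [fp.state.as_array() for fp in find_fixed_points(t1)
                  if fp.is_stable]
        for _ in range(50):
            y0 = 10 ** rng.uniform(-5, 3, size=3)
            _, traj = integrate(t1, y0, 600.0, n_points=50)
            err = min(np.max(np.abs(traj[-1] - s) / np.maximum(s, 1e-12))
                      for s in stable)
            assert err < 1e-4

    def test_rejects_negative_initial_state(self, t1):
        with pytest.raises(ValueError):
            integrate(t1, (-1.0, 0, 0), 1.0)


class TestBifurcation:
    def test_branch_pattern_and_window(self, t1):
        grid = np.geomspace(1.0, 100.0, 81)
        diag = bifurcation_diagram(t1, "c_a", grid)
        counts = diag.branch_counts()
        assert set(counts) == {1, 3}
        # pattern 1 -> 3 -> 1 along increasing c_a
        changes = np.flatnonzero(np.diff(counts != 1))
        assert counts[0] == 1 and counts[-1] == 1 and len(changes) == 2
        lo, hi = diag.bistable_window()
        assert lo < 12 and hi > 18.5
        assert lo > 7 and hi < 25
        assert len(diag.folds) == 2
        assert 7 < diag.folds[0] < 12 and 18.5 < diag.folds[1] < 25

    def test_single_point_grid_degenerates(self, t1):
        diag = bifurcation_diagram(t1, "c_a", [13.0])
        assert len(diag.points) == 1 and len(diag.points[0]) == 3
        assert diag.folds == []

    def test_tidy_frame_round_trips_through_csv(self, t1, tmp_path):
        diag = bifurcation_diagram(t1, "c_a", [10.0, 13.0], refine_folds=False)
        from xapswitch.interface import RunRecord, write_results
        from xapswitch.interface import fixture_scenarios

        df = diag.to_frame()
        write_results(RunRecord(fixture_scenarios()["fig5_bistable"]),
                      {"bif.csv": df}, tmp_path)
        import pandas as pd

        back = pd.read_csv(tmp_path / "bif.csv", float_precision="round_trip")
        assert np.allclose(back["p_a"], df["p_a"], rtol=0, atol=0)


class TestBistableRange:
    def test_degradation_threshold_location(self, t1):
        res = bistable_range(t1, "k_alpha", (1e2, 1e5))
        assert res["verdict"] == "transition(s) found"
        assert len(res["critical_values"]) == 1
        # bistability survives two decades above the default turnover and
        # is lost only near 1e4
        crit = res["critical_values"][0]
        assert 1e3 < crit < 3e4

    def test_no_transporter_never_bistable(self, t1):
        res = bistable_range(t1, "c_a", (1.0, 1e3),
                             variant=CircuitVariant(xapB_removed=True))
        assert res["verdict"] == "monostable throughout"
        assert res["critical_values"] == []

    def test_rejects_bad_bounds(self, t1):
        with pytest.raises(ValueError):
            bistable_range(t1, "k_alpha", (1e3, 1e2))


def test_random_parameter_draws_have_one_or_three_roots(rng):
    """Across the estimated parameter ranges the steady-state balance has
    an odd root count (the quintic structure admits at most three
    nonnegative roots in practice)."""
    for draw in random_table1_draws(rng, 25):
        from xapswitch import NondimParams

        fps = find_fixed_points(NondimParams(**draw))
        assert len(fps) in (1, 3)
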