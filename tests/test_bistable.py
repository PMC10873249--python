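import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutorder.bistable import (
    COUPLED_PRESET,
    REGULATION_PRESETS,
    AutoregCubic,
    CoupledModelSpec,
    ExpressionTable,
    MonostableError,
    MutationState,
    RegulationSpec,
    classify_observation,
    coupled_steady_states,
    drift,
    eval_autoregulation,
    find_fixed_points,
    follow_branch,
    mutation_trajectory_steady_states,
    potential,
    production_rate,
    saddle_node_thresholds,
)
from oracles import bisect_roots, integrate_to_steady_state

# Frozen bisection-oracle roots of lam + f(x) - x = 0 for the default cubic.
ROOT_LAM3 = 3.324717957245011
ROOT_LAM0 = 0.4786202931954178


class TestAutoregCubic:
    def test_default_values(self, cubic):
        assert eval_autoregulation(2.0, cubic) == 0.0
        assert eval_autoregulation(3.0, cubic) == pytest.approx(1.0)
        assert eval_autoregulation(1.0, cubic) == pytest.approx(-1.0)

    def test_rejects_positive_leading_coefficient(self):
        with pytest.raises(ValueError, match="leading"):
            AutoregCubic((1.0, 0.0, 0.0, 0.0))

    def test_rejects_wrong_degree(self):
        with pytest.raises(ValueError):
            AutoregCubic((-1.0, 0.0, 0.0))


class TestDrift:
    @pytest.mark.parametrize(
        "x, lam, expected", [(1.0, 2.0, 0.0), (3.0, 2.0, 0.0), (2.0, 0.0, -2.0)]
    )
    def test_examples(self, cubic, x, lam, expected):
        assert drift(x, lam, cubic) == pytest.approx(expected, abs=1e-12)


class TestPotential:
    def test_zero_at_origin(self, cubic):
        for lam in (0.0, 1.3, 2.0, 4.0):
            assert potential(0.0, lam, cubic) == 0.0

    def test_gradient_is_minus_drift(self, cubic):
        h = 1e-6
        x, lam = 1.7, 2.0
        num = -(potential(x + h, lam, cubic) - potential(x - h, lam, cubic)) / (2 * h)
        assert num == pytest.approx(drift(x, lam, cubic), abs=1e-8)

    def test_extrema_at_lam2(self, cubic):
        # at lam=2 the drift zeros are 1, 2, 3; U'' = -(f'(x) - 1)
        for x, kind in ((1.0, "min"), (2.0, "max"), (3.0, "min")):
            curvature = -(cubic.derivative(x) - 1.0)
            if kind == "min":
                assert curvature > 0
            else:
                assert curvature < 0
            h = 1e-4
            u = potential(x, 2.0, cubic)
            sides = (potential(x - h, 2.0, cubic), potential(x + h, 2.0, cubic))
            if kind == "min":
                assert all(s > u for s in sides)
            else:
                assert all(s < u for s in sides)


class TestFixedPoints:
    def test_lam2_exact(self, cubic):
        fps = find_fixed_points(2.0, cubic)
        assert fps.values == pytest.approx((1.0, 2.0, 3.0), abs=1e-9)
        assert [p.stable for p in fps] == [True, False, True]

    def test_lam3_single_root_matches_bisection(self, cubic):
        fps = find_fixed_points(3.0, cubic)
        assert len(fps) == 1
        assert fps.points[0].stable
        assert fps.values[0] == pytest.approx(ROOT_LAM3, abs=1e-9)

    def test_lam0_single_root_matches_bisection(self, cubic):
        fps = find_fixed_points(0.0, cubic)
        assert len(fps) == 1
        assert fps.values[0] == pytest.approx(ROOT_LAM0, abs=1e-9)

    def test_residuals_small_on_grid(self, cubic):
        for lam in np.linspace(0.0, 4.0, 81):
            for p in find_fixed_points(lam, cubic):
                assert abs(drift(p.x, lam, cubic)) < 1e-9

    def test_rejects_bad_tol(self, cubic):
        with pytest.raises(ValueError):
            find_fixed_points(2.0, cubic, tol=0.0)


class TestThresholds:
    def test_closed_form(self, cubic):
        thr = saddle_node_thresholds(cubic)
        delta = 2.0 / (3.0 * math.sqrt(3.0))
        assert thr.lam_low == pytest.approx(2.0 - delta, abs=1e-14)
        assert thr.lam_high == pytest.approx(2.0 + delta, abs=1e-14)
        assert round(thr.lam_low, 1) == 1.6
        assert round(thr.lam_high, 1) == 2.4

    def test_monostable_raises(self):
        # x - f(x) has derivative 3x^2 + 0.5 > 0: no critical points
        with pytest.raises(MonostableError):
            saddle_node_thresholds(AutoregCubic((-1.0, 0.0, 0.5, 0.0)))

    def test_root_count_flips_at_threshold(self, cubic):
        thr = saddle_node_thresholds(cubic)
        assert len(find_fixed_points(thr.lam_low + 1e-6, cubic)) == 3
        assert len(find_fixed_points(thr.lam_low - 1e-6, cubic)) == 1
        assert len(find_fixed_points(thr.lam_high - 1e-6, cubic)) == 3
        assert len(find_fixed_points(thr.lam_high + 1e-6, cubic)) == 1

    def test_root_count_law_on_grid(self, cubic):
        thr = saddle_node_thresholds(cubic)
        for lam in np.linspace(0.0, 4.0, 161):
            k = len(find_fixed_points(lam, cubic))
            if thr.lam_low + 1e-6 < lam < thr.lam_high - 1e-6:
                assert k == 3, lam
            elif lam < thr.lam_low - 1e-6 or lam > thr.lam_high + 1e-6:
                assert k == 1, lam


class TestProductionRate:
    def test_examples(self):
        spec = RegulationSpec(0.5, 1.0, 1.0)
        assert production_rate(spec, MutationState.JT) == 2.5
        assert production_rate(RegulationSpec(3.5, -1.0, -1.0), MutationState.O) == 3.5
        assert production_rate(RegulationSpec(1.2, 0.7, -0.3), MutationState.O) == 1.2

    def test_both_orders_share_rate(self):
        spec = RegulationSpec(0.7, 0.9, -0.4)
        assert production_rate(spec, MutationState.JT) == production_rate(
            spec, MutationState.TJ
        )

    def test_indicators(self):
        assert (MutationState.O.has_jak2, MutationState.O.has_tet2) == (0, 0)
        assert (MutationState.J.has_jak2, MutationState.J.has_tet2) == (1, 0)
        assert (MutationState.T.has_jak2, MutationState.T.has_tet2) == (0, 1)
        for s in (MutationState.JT, MutationState.TJ):
            assert (s.has_jak2, s.has_tet2) == (1, 1)


class TestFollowBranch:
    def test_hysteresis_up_then_down(self, cubic):
        assert follow_branch([2.0, 3.0, 2.0], 1.0, cubic) == pytest.approx(3.0, abs=1e-9)

    def test_hysteresis_down_then_up(self, cubic):
        assert follow_branch([2.0, 1.0, 2.0], 1.0, cubic) == pytest.approx(1.0, abs=1e-9)

    def test_single_rate_is_identity_on_branch(self, cubic):
        assert follow_branch([2.0], 1.0, cubic) == pytest.approx(1.0, abs=1e-12)

    def test_empty_path_rejected(self, cubic):
        with pytest.raises(ValueError):
            follow_branch([], 1.0, cubic)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_time_integration(self, cubic, seed):
        rng = np.random.default_rng(seed)
        path = rng.uniform(0.2, 3.8, size=4)
        x0 = rng.uniform(0.0, 4.0)
        expected = integrate_to_steady_state(x0, path, cubic, horizon=120.0)
        assert follow_branch(path, x0, cubic) == pytest.approx(expected, abs=1e-6)

    def test_no_branch_change_inside_window(self, cubic):
        # a path that never leaves the bistable window keeps its branch
        thr = saddle_node_thresholds(cubic)
        inner = np.linspace(thr.lam_low + 0.01, thr.lam_high - 0.01, 7)
        path = list(inner) + list(inner[::-1])
        low_start = find_fixed_points(path[0], cubic).values[0]
        end = follow_branch(path, low_start, cubic)
        final_fps = find_fixed_points(path[-1], cubic)
        assert end == pytest.approx(final_fps.values[0], abs=1e-9)


class TestMutationTrajectories:
    def test_order_dependent_preset(self, cubic):
        table = mutation_trajectory_steady_states(REGULATION_PRESETS["fig4a"], cubic)
        assert table.j == pytest.approx(ROOT_LAM3, abs=1e-9)
        assert table.jt == pytest.approx(3.0, abs=1e-9)
        assert table.tj == pytest.approx(1.0, abs=1e-9)
        assert round(table.t, 1) == 0.7

    def test_gate_up_preset_one_decimal(self, cubic):
        table = mutation_trajectory_steady_states(REGULATION_PRESETS["fig2a"], cubic)
        assert [round(v, 1) for v in (table.o, table.j, table.t, table.jt, table.tj)] == [
            0.6,
            0.8,
            0.8,
            3.2,
            3.2,
        ]

    def test_gate_down_preset_one_decimal(self, cubic):
        table = mutation_trajectory_steady_states(REGULATION_PRESETS["fig2b"], cubic)
        assert [round(v, 1) for v in (table.o, table.j, table.t, table.jt, table.tj)] == [
            3.4,
            3.2,
            3.2,
            0.8,
            0.8,
        ]

    def test_levels_positive_for_presets(self, cubic):
        for spec in REGULATION_PRESETS.values():
            table = mutation_trajectory_steady_states(spec, cubic)
            assert all(v > 0 for v in table.as_dict().values())


class TestCoupledModel:
    def test_reference_cascade(self):
        y, x = coupled_steady_states(COUPLED_PRESET)
        assert [round(v, 1) for v in (y.o, y.j, y.t, y.tj)] == [0.8, 3.2, 0.6, 0.8]
        assert [round(v, 1) for v in (x.o, x.j, x.t, x.tj)] == [1.8, 3.2, 1.6, 0.8]

    def test_decoupled_linear_gene_is_flat(self):
        model = CoupledModelSpec(
            regulation=RegulationSpec(1.5, 1.0, -1.0),
            basal=2.0,
            direct_jak2=0.0,
            coupling=0.0,
        )
        _, x = coupled_steady_states(model)
        assert set(x.as_dict().values()) == {2.0}

    def test_affine_relation_exact(self):
        model = COUPLED_PRESET
        y, x = coupled_steady_states(model)
        assert x.j - x.tj == pytest.approx(model.coupling * (y.j - y.tj), abs=1e-12)
        assert x.o == pytest.approx(model.basal + model.coupling * y.o, abs=1e-12)


class TestClassification:
    def test_gate_up_pattern(self):
        table = ExpressionTable(o=0.6, j=0.8, t=0.8, jt=3.2, tj=3.2)
        flags = classify_observation(table, tol=0.25)
        assert flags.pattern == 2
        assert flags.non_additive and not flags.non_commutative

    def test_inversion_pattern(self):
        table = ExpressionTable(o=1.8, j=3.2, t=1.6, jt=0.8, tj=0.8)
        flags = classify_observation(table, tol=0.25)
        assert flags.pattern == 3

    def test_order_pattern(self):
        table = ExpressionTable(o=1.0, j=3.3, t=0.7, jt=3.0, tj=1.0)
        flags = classify_observation(table, tol=0.25)
        assert flags.pattern == 4
        assert flags.non_commutative

    def test_additive_table_has_no_flags(self):
        o, j, t = 1.0, 1.7, 2.1
        table = ExpressionTable(o=o, j=j, t=t, jt=j + t - o, tj=j + t - o)
        flags = classify_observation(table, tol=0.05)
        assert not flags.non_additive
        assert not flags.non_commutative
        assert flags.pattern is None

    def test_rejects_bad_tol(self):
        with pytest.raises(ValueError):
            classify_observation(ExpressionTable(1, 1, 1, 1, 1), tol=0.0)

    @given(
        o=st.floats(-5, 5),
        j=st.floats(-5, 5),
        t=st.floats(-5, 5),
        a=st.floats(-0.05, 0.05),
        b=st.floats(-0.05, 0.05),
    )
    @settings(max_examples=200, deadline=None)
    def test_additivity_implies_commutativity(self, o, j, t, a, b):
        # build a table whose two additivity defects are a and b (|.| <= tol)
        tol = 0.05
        table = ExpressionTable(o=o, j=j, t=t, jt=j + t - o + a, tj=j + t - o + b)
        assert abs((table.j - table.o) - (table.tj - table.t)) <= tol + 1e-12
        assert abs((table.t - table.o) - (table.jt - table.j)) <= tol + 1e-12
        assert abs(table.jt - table.tj) <= 2 * tol + 1e-12
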