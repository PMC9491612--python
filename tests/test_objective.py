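"""The three BSR objective components and the acceptance filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_linear_model, make_repeller_model, make_rotation_model
from teaps.models import build_builtin_model
from teaps.objective import (
    BatchObjective,
    BSRSpec,
    ObjectiveVector,
    ObservationSet,
    accept_bsr,
    combined_objective,
    o_basin,
    o_fix,
    o_relax,
    sample_observation_points,
)

T1_STEADY = {"k1": 1.0, "v2": 2.0, "km2": 1.0, "k3": 1.0, "k4": 1.0}


def obs_at(points):
    return ObservationSet(points=np.atleast_2d(points), half_width=0.1)


class TestObservationSampling:
    def test_points_within_box(self, t1, spec):
        rng = np.random.default_rng(0)
        obs = sample_observation_points(spec, 0.1, rng, t1)
        assert obs.points.shape == (spec.n_obs, 3)
        assert np.all(obs.points >= 0.9) and np.all(obs.points <= 1.1)

    def test_degenerate_halfwidth_limit(self, t1, spec):
        rng = np.random.default_rng(0)
        obs = sample_observation_points(spec, 1e-12, rng, t1)
        np.testing.assert_allclose(obs.points, 1.0, atol=1e-11)

    def test_same_seed_reproduces_points(self, t1, spec):
        a = sample_observation_points(spec, 0.05, np.random.default_rng(7), t1)
        b = sample_observation_points(spec, 0.05, np.random.default_rng(7), t1)
        np.testing.assert_array_equal(a.points, b.points)

    def test_rejects_nonpositive_halfwidth(self, t1, spec):
        with pytest.raises(ValueError):
            sample_observation_points(spec, 0.0, np.random.default_rng(0), t1)


class TestOFix:
    def test_zero_at_constrained_parameters(self, t1):
        assert o_fix(t1, T1_STEADY, np.ones(3)) == 0.0

    def test_hand_value(self, t1):
        mu = {"k1": 1.0, "v2": 1.0, "km2": 1.0, "k3": 0.5, "k4": 0.5}
        assert o_fix(t1, mu, np.ones(3)) == pytest.approx(0.5)

    def test_norm_homogeneity_on_linear_model(self):
        m = make_linear_model()
        base = o_fix(m, {"k1": 1.0}, np.array([3.0]))
        assert o_fix(m, {"k1": 2.5}, np.array([3.0])) == pytest.approx(2.5 * base)


class TestOBasin:
    def test_contracting_linear_model_is_zero(self):
        m = make_linear_model()
        pts = np.linspace(0.5, 1.5, 7)[:, None]
        assert o_basin(m, {"k1": 3.0}, obs_at(pts)) == 0.0

    def test_expanding_model_value(self):
        m = make_repeller_model()
        assert o_basin(m, {"k1": 1.0}, obs_at([[1.05]])) == pytest.approx(2.0)

    def test_antisymmetric_jacobian_gives_zero(self):
        m = make_rotation_model()
        pts = 1 + np.random.default_rng(0).uniform(-0.1, 0.1, (10, 2))
        assert o_basin(m, {"w": 2.0}, obs_at(pts)) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_point_reordering(self, t1, spec):
        rng = np.random.default_rng(3)
        pts = 1 + rng.uniform(-0.1, 0.1, (12, 3))
        mu = {"k1": 1.0, "v2": 5.0, "km2": 0.3, "k3": 1.0, "k4": 2.0}
        a = o_basin(t1, mu, obs_at(pts))
        b = o_basin(t1, mu, obs_at(pts[::-1]))
        assert a == b

    def test_non_increasing_when_point_removed(self, t1):
        rng = np.random.default_rng(4)
        pts = 1 + rng.uniform(-0.1, 0.1, (12, 3))
        mu = {"k1": 1.0, "v2": 5.0, "km2": 0.3, "k3": 1.0, "k4": 2.0}
        full = o_basin(t1, mu, obs_at(pts))
        for i in range(len(pts)):
            reduced = o_basin(t1, mu, obs_at(np.delete(pts, i, axis=0)))
            assert reduced <= full + 1e-15


class TestORelax:
    def test_fast_linear_relaxation_is_zero(self, spec):
        m = make_linear_model()
        assert o_relax(m, {"k1": 1.0}, spec) == 0.0

    def test_slow_relaxation_penalized(self, spec):
        m = make_linear_model()
        assert o_relax(m, {"k1": 0.1}, spec) == pytest.approx(0.2)

    def test_zero_eigenvalue_excluded(self, spec):
        # conserved pair in T6: two structural zero eigenvalues at any point
        m = build_builtin_model("T6")
        mu = {"k1": 1.0, "k2": 1.0, "v3": 2.0, "km3": 1.0, "k4": 1.0}
        val = o_relax(m, mu, spec)
        # nonzero eigenvalues of the block system are -2 and -(a + k4)
        assert val == 0.0


class TestCombinedAndAcceptance:
    def test_all_zero_components(self):
        ov = ObjectiveVector(0.0, 0.0, 0.0, weight_w=2.0)
        assert ov.combined_scalar == 0.0
        np.testing.assert_array_equal(ov.residual_vector, [0, 0, 0])

    def test_weighted_sum_arithmetic(self):
        ov = ObjectiveVector(0.5, 0.0, 0.0, weight_w=2.0)
        assert ov.combined_scalar == pytest.approx(0.25)

    @given(
        st.floats(0, 10),
        st.floats(0, 10),
        st.floats(0, 10),
        st.floats(0, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_component(self, a, b, c, bump):
        w = 1.5
        base = ObjectiveVector(a, b, c, weight_w=w).combined_scalar
        assert ObjectiveVector(a + bump, b, c, weight_w=w).combined_scalar >= base
        assert ObjectiveVector(a, b + bump, c, weight_w=w).combined_scalar >= base
        assert ObjectiveVector(a, b, c + bump, weight_w=w).combined_scalar >= base

    def test_combined_objective_fills_fields(self, t1, spec):
        rng = np.random.default_rng(0)
        obs = sample_observation_points(spec, 0.1, rng, t1)
        ov = combined_objective(t1, T1_STEADY, spec, obs)
        assert ov.o_fix == 0.0
        assert ov.o_basin >= 0.0 and ov.o_relax >= 0.0
        assert ov.combined_scalar == pytest.approx(
            ov.o_fix**2 + ov.o_basin**spec.weight_w + ov.o_relax**spec.weight_w
        )

    def test_accept_linear_attractor(self, spec):
        ok, diag = accept_bsr(make_linear_model(), {"k1": 1.0}, spec)
        assert ok and diag["max_re_nonzero"] == pytest.approx(-1.0)

    def test_reject_repeller(self, spec):
        ok, diag = accept_bsr(make_repeller_model(), {"k1": 1.0}, spec)
        assert not ok

    def test_t1_acceptance_decided_by_eigenvalues(self, t1, spec):
        # eigenvalues of the hand-checked Jacobian decide membership
        J = np.array([[-0.5, 0, -1], [0.5, -1, 1], [0, 1, -1]])
        expected = np.linalg.eigvals(J).real.max() < 0
        ok, _ = accept_bsr(t1, T1_STEADY, spec)
        assert ok == expected

    def test_all_zero_eigenvalues_not_accepted(self, spec):
        # pure rotation: eigenvalues +-i w, real parts zero-classified
        ok, _ = accept_bsr(make_rotation_model(), {"w": 1.0}, spec)
        assert not ok


class TestBatchObjective:
    def test_matches_scalar_components(self, t1, spec):
        rng = np.random.default_rng(1)
        obs = sample_observation_points(spec, 0.1, rng, t1)
        bo = BatchObjective(t1, spec, obs)
        mus = [
            T1_STEADY,
            {"k1": 1.0, "v2": 1.0, "km2": 1.0, "k3": 0.5, "k4": 0.5},
            {"k1": 0.2, "v2": 30.0, "km2": 7.0, "k3": 2.0, "k4": 0.1},
        ]
        th = np.log10([[mu[p] for p in t1.parameter_names] for mu in mus])
        comps = bo.components(th)
        for row, mu in zip(comps, mus):
            assert row[0] == pytest.approx(o_fix(t1, mu, np.ones(3)), abs=1e-12)
            assert row[1] == pytest.approx(o_basin(t1, mu, obs), abs=1e-12)
            assert row[2] == pytest.approx(o_relax(t1, mu, spec), abs=1e-12)

    def test_components_continuous_in_parameters(self, t1, spec):
        rng = np.random.default_rng(2)
        obs = sample_observation_points(spec, 0.1, rng, t1)
        bo = BatchObjective(t1, spec, obs)
        th0 = np.log10([1.0, 5.0, 0.5, 1.0, 2.0])
        eps = 1e-7
        base = bo.components(th0[None, :])[0]
        for j in range(5):
            th = th0.copy()
            th[j] += eps
            pert = bo.components(th[None, :])[0]
            assert np.all(np.abs(pert - base) < 1e-4)


class TestBSRSpecValidation:
    def test_rejects_positive_lambda_target(self):
        with pytest.raises(ValueError):
            BSRSpec(lambda_target=0.1)

    def test_rejects_non_increasing_schedule(self):
        with pytest.raises(ValueError):
            BSRSpec(d_schedule=(0.1, 0.05))

    def test_default_slack_is_half_target_rate(self):
        assert BSRSpec().effective_basin_tol == pytest.approx(0.15)
        assert BSRSpec(basin_tol=0.02).effective_basin_tol == 0.02
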