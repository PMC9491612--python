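"""The staged search: cloud, CNM collection, m-LBFGS, stopping rule."""

import numpy as np
import pytest

from conftest import make_linear_model
from teaps._rng import stream
from teaps.models import ParameterSpace, build_builtin_model
from teaps.objective import BSRSpec
from teaps.search import (
    TEAPSConfig,
    cnm_stage,
    init_parameter_cloud,
    m_lbfgs_optimize,
    run_teaps,
    stopping_check,
)


def small_config(model, **kw):
    defaults = dict(
        n_initial=60,
        n_collect=25,
        n_noise_loops=1,
        max_pool=120,
        lbfgs_maxiter=25,
        max_outer_iters=1,
        seed=3,
    )
    defaults.update(kw)
    return TEAPSConfig(space=ParameterSpace.for_model(model), spec=BSRSpec(), **defaults)


class TestInitialCloud:
    def test_within_box_and_seeded(self, t1):
        cfg = small_config(t1)
        cloud = init_parameter_cloud(cfg, stream(3, "cloud"))
        assert cloud.shape == (60, 5)
        assert np.all(cloud >= cfg.space.log10_lower) and np.all(cloud <= cfg.space.log10_upper)
        cloud2 = init_parameter_cloud(cfg, stream(3, "cloud"))
        np.testing.assert_array_equal(cloud, cloud2)

    def test_custom_cloud_size(self, t1):
        cfg = small_config(t1, n_initial=123)
        assert init_parameter_cloud(cfg, stream(0, "c")).shape[0] == 123


class TestCNMStage:
    def test_presolved_cloud_collected_immediately(self, t1):
        cfg = small_config(t1, n_collect=10)
        # exact BSR solutions: k = v2/(km2+1) with km2 large, k ~ 1
        rng = np.random.default_rng(0)
        km2 = 10 ** rng.uniform(3, 4.5, 10)
        k = rng.uniform(0.95, 1.2, 10)
        v2 = k * (km2 + 1)
        cloud = np.log10(np.column_stack([k, v2, km2, k, k]))
        pool, reached = cnm_stage(t1, cfg, cloud, np.random.default_rng(1))
        assert reached
        np.testing.assert_allclose(np.sort(pool, axis=0), np.sort(cloud, axis=0))

    def test_pool_size_contract_and_box(self, t1):
        cfg = small_config(t1)
        cloud = init_parameter_cloud(cfg, stream(9, "cloud"))
        pool, _reached = cnm_stage(t1, cfg, cloud, np.random.default_rng(2))
        assert len(pool) >= min(cfg.n_collect, len(cloud))
        assert np.all(pool >= cfg.space.log10_lower - 1e-12)
        assert np.all(pool <= cfg.space.log10_upper + 1e-12)


class TestMLBFGS:
    def test_linear_model_converges_to_certified_minimum(self):
        m = make_linear_model()
        cfg = TEAPSConfig(
            space=ParameterSpace(("k1",), np.array([1e-3]), np.array([1e3])),
            spec=BSRSpec(),
            n_initial=2,
            seed=0,
        )
        theta, comps, ok = m_lbfgs_optimize(
            m, cfg, np.array([-2.5]), d=0.1, rng=np.random.default_rng(0)
        )
        # certified as soon as the relaxation bound |k| >= 0.3 is met
        assert comps[2] == 0.0 and comps[1] == 0.0
        assert 10 ** theta[0] >= 0.3

    def test_objective_never_increases(self, t1):
        cfg = small_config(t1)
        rng = np.random.default_rng(5)
        from teaps.objective import BatchObjective, sample_observation_points

        obs = sample_observation_points(cfg.spec, 0.1, rng, t1)
        bo = BatchObjective(t1, cfg.spec, obs)
        for _ in range(3):
            th0 = rng.uniform(cfg.space.log10_lower, cfg.space.log10_upper)
            f0 = bo.combined_single(th0)
            theta, comps, _ok = m_lbfgs_optimize(
                t1, cfg, th0, d=0.1, rng=np.random.default_rng(1), obs=obs
            )
            w = cfg.spec.weight_w
            f1 = comps[0] ** 2 + comps[1] ** w + comps[2] ** w
            assert f1 <= f0 + 1e-12

    def test_zero_twist_is_deterministic(self, t1):
        cfg = small_config(t1)
        from teaps.objective import sample_observation_points

        rng = np.random.default_rng(8)
        obs = sample_observation_points(cfg.spec, 0.1, rng, t1)
        th0 = np.log10([0.8, 50.0, 20.0, 0.9, 1.1])
        outs = [
            m_lbfgs_optimize(
                t1, cfg, th0, d=0.1, rng=np.random.default_rng(123), obs=obs, twist=False
            )[0]
            for _ in range(2)
        ]
        np.testing.assert_array_equal(outs[0], outs[1])


class TestStoppingRule:
    def test_identical_distributions_stop(self, t1):
        cfg = small_config(t1)
        h = np.random.default_rng(0).normal(0, 1, (200, 5))
        stop, details = stopping_check(cfg, h, h.copy())
        assert stop and all(d["p"] >= cfg.wilcoxon_alpha for d in details)

    def test_shifted_distribution_continues(self, t1):
        # a +10 log10 shift is rejected by the rank-sum test (for fully
        # separated samples of size 20 the exact two-sided p-value is
        # 2 / C(40, 20) ~ 1.5e-11, far below any alpha)
        cfg = small_config(t1)
        h = np.random.default_rng(1).normal(0, 1, (20, 5))
        stop, details = stopping_check(cfg, h, h + 10.0)
        assert not stop
        assert all(d["p"] < 0.05 for d in details)

    def test_single_outlier_within_containment(self, t1):
        cfg = small_config(t1)
        rng = np.random.default_rng(2)
        h = rng.uniform(0, 1, (400, 2))
        new = rng.uniform(0.1, 0.9, (200, 2))
        new[0, 0] = 5.0  # 1 of 200 outside the seen range -> 99.5% inside
        stop, details = stopping_check(cfg, h, new)
        assert details[0]["containment"] == pytest.approx(0.995)
        assert stop

    def test_empty_inputs_rejected(self, t1):
        cfg = small_config(t1)
        with pytest.raises(ValueError):
            stopping_check(cfg, np.empty((0, 2)), np.ones((5, 2)))


@pytest.fixture(scope="module")
def t1_result(t1):
    cfg = small_config(t1, max_outer_iters=2, seed=21)
    return cfg, run_teaps(t1, cfg)


class TestRunTeaps:
    def test_nonempty_accepted_ensemble(self, t1_result):
        _cfg, res = t1_result
        assert res.warning is None
        assert len(res.accepted) > 0

    def test_final_sets_satisfy_acceptance(self, t1, t1_result, spec):
        from teaps.objective import accept_bsr

        _cfg, res = t1_result
        acc = res.accepted
        assert np.all(acc.objectives[:, 0] < spec.fix_tol)
        for mu in acc.subset(np.arange(min(20, len(acc)))).sets:
            ok, diag = accept_bsr(t1, mu, spec)
            assert ok and diag["max_re_nonzero"] < 0

    def test_no_set_outside_box(self, t1_result):
        cfg, res = t1_result
        ens = res.ensemble
        assert np.all(ens.log10_values >= cfg.space.log10_lower - 1e-9)
        assert np.all(ens.log10_values <= cfg.space.log10_upper + 1e-9)

    def test_reproducible_from_seed(self, t1, t1_result):
        cfg, res = t1_result
        res2 = run_teaps(t1, cfg)
        np.testing.assert_array_equal(res.ensemble.log10_values, res2.ensemble.log10_values)
        np.testing.assert_array_equal(res.ensemble.accepted, res2.ensemble.accepted)

    def test_snapshots_cover_stages(self, t1_result):
        _cfg, res = t1_result
        labels = [lab for lab, _ in res.snapshots]
        assert labels[0] == "cnm"
        assert any(lab.startswith("g-lbfgs-") for lab in labels)
        assert labels[-1] == "final"


class TestDegenerateConfigs:
    def test_single_d_no_noise_reduces_to_one_sweep(self, t1):
        spec1 = BSRSpec(d_schedule=(0.1,))
        cfg = TEAPSConfig(
            space=ParameterSpace.for_model(t1),
            spec=spec1,
            n_initial=20,
            n_collect=8,
            n_noise_loops=0,
            max_pool=40,
            lbfgs_maxiter=15,
            max_outer_iters=1,
            seed=4,
        )
        res = run_teaps(t1, cfg)
        labels = [lab for lab, _ in res.snapshots]
        assert labels == ["cnm", "g-lbfgs-1", "final"]

    def test_validation(self, t1):
        with pytest.raises(ValueError):
            TEAPSConfig(space=ParameterSpace.for_model(t1), wilcoxon_alpha=1.5)
        with pytest.raises(ValueError):
            TEAPSConfig(space=ParameterSpace.for_model(t1), n_initial=1)
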