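"""KDE densities, similarity indices, PCA shape analysis and PCI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teaps.density import (
    DensityGrid,
    PCAReport,
    cosine_similarity,
    js_divergence,
    kde_density,
    pca_full,
    pci,
    random_comparator_ci,
    silverman_bandwidths,
)
from teaps.ensemble import ParameterEnsemble


def ens_from(log10_values, names=None):
    arr = np.atleast_2d(np.asarray(log10_values, dtype=float))
    names = names or tuple(f"p{i}" for i in range(arr.shape[1]))
    return ParameterEnsemble(parameter_names=tuple(names), log10_values=arr)


class TestSilverman:
    def test_one_dimensional_closed_form(self):
        # independent closed form: h = (4 / (3 n))^(1/5) * sigma
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, (500, 1))
        sigma = x.std(ddof=1)
        expected = (4.0 / (3 * 500)) ** 0.2 * sigma
        assert silverman_bandwidths(x)[0] == pytest.approx(expected)

    def test_zero_variance_floored_with_warning(self):
        x = np.ones((50, 2))
        with pytest.warns(UserWarning, match="floored"):
            h = silverman_bandwidths(x)
        assert np.all(h == 1e-3)


class TestKDE:
    def test_density_normalized(self):
        rng = np.random.default_rng(1)
        ens = ens_from(rng.uniform(-2, 2, (200, 2)))
        grid = DensityGrid.regular(ens.parameter_names, 1e-3, 1e3, resolution=15)
        prof = kde_density(ens, grid)
        assert prof.density.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(prof.density >= 0)

    def test_repeated_point_concentrates_at_nearest_cell(self):
        with pytest.warns(UserWarning):
            ens = ens_from(np.tile([[0.55, -1.2]], (20, 1)))
            grid = DensityGrid.regular(ens.parameter_names, 1e-3, 1e3, resolution=13)
            prof = kde_density(ens, grid)
        dens = prof.density.reshape(grid.shape)
        i, j = np.unravel_index(dens.argmax(), grid.shape)
        assert grid.axes[0][i] == pytest.approx(0.55, abs=np.diff(grid.axes[0])[0])
        assert grid.axes[1][j] == pytest.approx(-1.2, abs=np.diff(grid.axes[1])[0])

    def test_grid_resolution_shrinks_with_dimension(self):
        g2 = DensityGrid.regular(("a", "b"), 1e-3, 1e3)
        g5 = DensityGrid.regular(tuple("abcde"), 1e-3, 1e3)
        assert g2.shape == (20, 20)
        assert g5.n_points <= 200_000


class TestSimilarityIndices:
    def test_cosine_identical_vectors(self):
        v = np.array([0.2, 0.3, 0.5])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_cosine_disjoint_supports(self):
        assert cosine_similarity([1, 0], [0, 1]) == 0.0

    def test_cosine_hand_value(self):
        assert cosine_similarity([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_js_identical_is_zero(self):
        v = np.array([0.25, 0.75])
        assert js_divergence(v, v) == 0.0

    def test_js_disjoint_is_log2(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.log(2))

    def test_js_base2_option(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0], base=2) == pytest.approx(1.0)

    def test_js_symmetry(self):
        a = np.array([0.1, 0.2, 0.7])
        b = np.array([0.3, 0.3, 0.4])
        assert js_divergence(a, b) == pytest.approx(js_divergence(b, a))

    def test_js_requires_normalized_inputs(self):
        with pytest.raises(ValueError):
            js_divergence([0.5, 0.2], [0.5, 0.5])


class TestRandomComparator:
    @staticmethod
    def _profiles():
        rng = np.random.default_rng(2)
        ens_a = ens_from(rng.normal(0, 0.5, (300, 2)))
        ens_b = ens_from(rng.normal(0.1, 0.5, (300, 2)))
        grid = DensityGrid.regular(("p0", "p1"), 1e-3, 1e3, resolution=15)
        return kde_density(ens_a, grid), kde_density(ens_b, grid)

    def test_self_comparison_ratio_positive(self):
        da, db = self._profiles()
        rep = random_comparator_ci(da, db, n_reps=50, rng=np.random.default_rng(3))
        # a structured match beats value-shuffled comparators
        assert rep["cosine_ratio"]["log10_ratio"] > 0
        assert rep["js_ratio"]["log10_ratio"] < 0

    def test_ci_brackets_point_estimate(self):
        da, db = self._profiles()
        rep = random_comparator_ci(da, db, n_reps=50, rng=np.random.default_rng(4))
        for key in ("cosine_ratio", "js_ratio"):
            lo, hi = rep[key]["ci"]
            assert lo <= rep[key]["log10_ratio"] <= hi

    def test_grid_mismatch_rejected(self):
        da, _ = self._profiles()
        grid = DensityGrid.regular(("p0", "p1"), 1e-3, 1e3, resolution=9)
        other = kde_density(ens_from(np.zeros((5, 2)) + 0.3), grid)
        with pytest.raises(ValueError, match="grid"):
            random_comparator_ci(da, other)


class TestPCA:
    def test_isotropic_cloud_has_comparable_axis_ranges(self):
        rng = np.random.default_rng(5)
        rep = pca_full(ens_from(rng.normal(0, 1, (2000, 3))))
        assert rep.axis_ranges.max() / rep.axis_ranges.min() < 1.6

    def test_line_cloud_has_dominant_axis(self):
        rng = np.random.default_rng(6)
        t = rng.normal(0, 1, 500)
        X = np.column_stack([t, 2 * t, -t]) + rng.normal(0, 0.01, (500, 3))
        rep = pca_full(ens_from(X))
        assert rep.axis_ranges[0] / rep.axis_ranges[1] > 20

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(7)
        rep = pca_full(ens_from(rng.normal(0, 1, (100, 4))))
        np.testing.assert_allclose(rep.loadings @ rep.loadings.T, np.eye(4), atol=1e-10)

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning, match="rank"):
            pca_full(ens_from(rng.normal(0, 1, (3, 5))))


class TestPCI:
    @staticmethod
    def _report(loadings):
        L = np.asarray(loadings, dtype=float)
        return PCAReport(
            parameter_names=tuple(f"p{i}" for i in range(L.shape[1])),
            loadings=L,
            scores=np.zeros((1, L.shape[0])),
            axis_ranges=np.ones(L.shape[0]),
            explained_variance=np.ones(L.shape[0]),
        )

    def test_single_axis_loading_collapses_to_axis_index(self):
        L = np.zeros((4, 4))
        L[[0, 1, 2, 3], [1, 2, 0, 3]] = 1.0  # parameter p0 loads only on axis 3
        vals = pci(self._report(L))
        assert vals[0] == pytest.approx(3.0)

    def test_uniform_loadings_give_midpoint(self):
        n = 5
        L = np.full((n, n), 1.0 / np.sqrt(n))
        vals = pci(self._report(L))
        np.testing.assert_allclose(vals, (n + 1) / 2)

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_pci_bounded_by_axis_range(self, n, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(0, 1, (n, n))
        vals = pci(self._report(L))
        assert np.all(vals >= 1 - 1e-12) and np.all(vals <= n + 1e-12)
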