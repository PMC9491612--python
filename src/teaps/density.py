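"""Distribution comparison and ensemble-shape analysis.

Parameter ensembles are compared as normalized kernel-density vectors on a
shared lattice in log10 parameter space: a product-Gaussian KDE with
per-dimension Silverman bandwidths is evaluated at every lattice point,
the density tensor is flattened in a preset (row-major) order and
normalized to sum 1, and two such vectors are compared by cosine
similarity and Jensen-Shannon divergence.  A "random comparator" vector —
components resampled from the empirical value distribution of the
reference density — calibrates how much of the similarity is structural.

Ensemble shape is characterized by full-rank PCA in log10 space and the
principal central axis index (PCI): the per-parameter average of PCA axis
indices weighted by normalized absolute loadings.  A small PCI means the
parameter varies mainly along the broad directions of the BSR set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ensemble import ParameterEnsemble

__all__ = [
    "DensityGrid",
    "DensityProfile",
    "silverman_bandwidths",
    "kde_density",
    "cosine_similarity",
    "js_divergence",
    "random_comparator_ci",
    "PCAReport",
    "pca_full",
    "pci",
]

_BANDWIDTH_FLOOR = 1e-3  # log10 units; guards zero-variance dimensions


@dataclass(frozen=True)
class DensityGrid:
    """Shared evaluation lattice in log10 space, one axis per compared
    parameter, flattened in row-major order."""

    parameter_names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]

    @property
    def n_points(self) -> int:
        return int(np.prod([len(a) for a in self.axes]))

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.axes)

    @classmethod
    def regular(
        cls,
        parameter_names: Sequence[str],
        lower: float,
        upper: float,
        resolution: Optional[int] = None,
        max_points: int = 200_000,
    ) -> "DensityGrid":
        """Log-uniform lattice over [lower, upper] (linear-scale bounds).

        Resolution defaults to 20 points per axis, reduced so the full
        tensor stays within ``max_points`` lattice points for
        higher-dimensional comparisons.
        """
        dim = len(parameter_names)
        if resolution is None:
            resolution = min(20, max(3, int(max_points ** (1.0 / dim))))
        ax = np.linspace(math.log10(lower), math.log10(upper), resolution)
        return cls(tuple(parameter_names), tuple(ax.copy() for _ in range(dim)))


@dataclass(frozen=True)
class DensityProfile:
    grid: DensityGrid
    density: np.ndarray            # flattened, sums to 1
    bandwidths: np.ndarray         # per-dimension Silverman bandwidths

    def __post_init__(self) -> None:
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if self.density.shape != (self.grid.n_points,):
            raise ValueError("density length must match grid")
        if abs(self.density.sum() - 1.0) > 1e-12:
            raise ValueError("density must be normalized to sum 1")


def silverman_bandwidths(samples: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman plug-in bandwidths for a product-Gaussian
    kernel: h_j = sigma_j * (4 / ((d + 2) n))^(1/(d+4)).

    Reduces to (4/(3n))^(1/5) sigma in one dimension.  Dimensions with
    (numerically) zero dispersion fall back to a floor of 1e-3 log10 units.
    """
    samples = np.atleast_2d(samples)
    n, dim = samples.shape
    sigma = samples.std(axis=0, ddof=1) if n > 1 else np.zeros(samples.shape[1])
    factor = (4.0 / ((dim + 2) * n)) ** (1.0 / (dim + 4))
    h = sigma * factor
    if np.any(h < _BANDWIDTH_FLOOR):
        warnings.warn("zero-dispersion dimension: bandwidth floored at 1e-3 log10 units")
        h = np.maximum(h, _BANDWIDTH_FLOOR)
    return h


def kde_density(
    ensemble: ParameterEnsemble,
    grid: DensityGrid,
    chunk: int = 512,
) -> DensityProfile:
    """Product-Gaussian KDE of the ensemble (log10 scale) on the grid,
    normalized by the total sum.

    The kernel is separable, so the density tensor is accumulated as a sum
    of outer products of per-axis kernel evaluations — no explicit
    (samples x grid points) distance matrix.
    """
    if len(ensemble) < 1:
        raise ValueError("need at least one sample")
    cols = [ensemble.parameter_names.index(p) for p in grid.parameter_names]
    X = ensemble.log10_values[:, cols]
    h = silverman_bandwidths(X)
    dim = X.shape[1]
    shape = grid.shape
    dens = np.zeros(shape)
    letters = "abcdefghijklmnop"[:dim]
    subscript = ",".join(f"m{c}" for c in letters) + "->" + letters
    for start in range(0, X.shape[0], chunk):
        blk = X[start : start + chunk]
        Ks = [
            np.exp(-0.5 * ((grid.axes[j][None, :] - blk[:, j : j + 1]) / h[j]) ** 2)
            for j in range(dim)
        ]
        if dim == 1:
            dens += Ks[0].sum(axis=0)
        else:
            dens += np.einsum(subscript, *Ks, optimize=True)
    flat = dens.reshape(-1)
    total = flat.sum()
    if total <= 0:
        # kernels narrower than the lattice spacing underflow between grid
        # points; fall back to nearest-cell mass assignment
        dens = np.zeros(shape)
        idx = tuple(
            np.argmin(np.abs(grid.axes[j][None, :] - X[:, j : j + 1]), axis=1)
            for j in range(dim)
        )
        np.add.at(dens, idx, 1.0)
        flat = dens.reshape(-1)
        total = flat.sum()
    flat = flat / total
    flat = flat / flat.sum()  # renormalize against rounding
    return DensityProfile(grid=grid, density=flat, bandwidths=h)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """sum(A_i B_i) / sqrt(sum A_i^2) sqrt(sum B_i^2); 1 for identical
    directions, 0 for disjoint supports."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def js_divergence(a: np.ndarray, b: np.ndarray, base: Optional[float] = None) -> float:
    """Jensen-Shannon divergence (natural log by default, 0*log0 = 0)
    between two normalized density vectors:
    1/2 sum A_i log(A_i / m_i) + 1/2 sum B_i log(B_i / m_i), m = (A+B)/2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if abs(a.sum() - 1.0) > 1e-8 or abs(b.sum() - 1.0) > 1e-8:
        raise ValueError("inputs must each be normalized to sum 1")
    m = 0.5 * (a + b)
    # log-space form avoids underflow of a/m for subnormal densities
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(a > 0, a * (np.log(np.maximum(a, 1e-300)) - np.log(np.maximum(m, 1e-300))), 0.0)
        tb = np.where(b > 0, b * (np.log(np.maximum(b, 1e-300)) - np.log(np.maximum(m, 1e-300))), 0.0)
    val = 0.5 * (ta.sum() + tb.sum())
    if base is not None:
        val /= math.log(base)
    return float(max(val, 0.0))


def random_comparator_ci(
    bf_density: DensityProfile,
    other_density: DensityProfile,
    n_reps: int = 200,
    rng: Optional[np.random.Generator] = None,
    ci: float = 0.95,
) -> dict:
    """Calibrate similarity indices against a random comparator.

    Comparator vectors have components resampled (with replacement) from
    the value histogram of the reference (brute-force) density vector and
    are renormalized.  Reported per index: log10 of the ratio of the
    search-vs-reference value to the random-vs-reference value, with a
    percentile confidence interval over ``n_reps`` comparators.  A positive
    cosine ratio and a negative JS ratio mean the search ensemble matches
    the reference better than random sampling does.
    """
    if bf_density.grid.shape != other_density.grid.shape:
        raise ValueError("densities must share a grid")
    if rng is None:
        rng = np.random.default_rng(0)
    A = bf_density.density
    B = other_density.density
    cos_ab = cosine_similarity(A, B)
    js_ab = js_divergence(A, B)
    log_cos, log_js = [], []
    g = A.size
    for _ in range(n_reps):
        comp = rng.choice(A, size=g, replace=True)
        s = comp.sum()
        if s <= 0:
            continue
        comp = comp / s
        cos_r = cosine_similarity(A, comp)
        js_r = js_divergence(A, comp)
        if cos_r > 0:
            log_cos.append(math.log10(cos_ab / cos_r))
        if js_ab > 0 and js_r > 0:
            log_js.append(math.log10(js_ab / js_r))
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2

    def summarize(vals: list) -> dict:
        v = np.asarray(vals)
        return {
            "log10_ratio": float(np.median(v)),
            "ci": (float(np.quantile(v, lo_q)), float(np.quantile(v, hi_q))),
        }

    return {
        "cosine": cos_ab,
        "js": js_ab,
        "cosine_ratio": summarize(log_cos),
        "js_ratio": summarize(log_js),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Ensemble shape: full-rank PCA and the principal central axis index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAReport:
    parameter_names: tuple[str, ...]
    loadings: np.ndarray       # (n_axes, n_params), rows orthonormal
    scores: np.ndarray         # (n_samples, n_axes)
    axis_ranges: np.ndarray    # per-axis score max - min
    explained_variance: np.ndarray


def pca_full(ensemble: ParameterEnsemble) -> PCAReport:
    """Centered PCA of the ensemble in log10 space with all components
    retained (axis count equals the parameter-space dimension), so both the
    widest and the narrowest directions of the found set are visible.

    With fewer samples than parameters the decomposition is rank-truncated
    (with a warning); PCI is then computed over the available axes.
    """
    X = ensemble.log10_values
    n, p = X.shape
    if n <= p:
        warnings.warn(f"only {n} samples for {p} parameters: PCA rank-truncated")
    Xc = X - X.mean(axis=0)
    _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt.T
    return PCAReport(
        parameter_names=tuple(ensemble.parameter_names),
        loadings=vt,
        scores=scores,
        axis_ranges=scores.max(axis=0) - scores.min(axis=0),
        explained_variance=s**2 / max(n - 1, 1),
    )


def pci(report: PCAReport) -> np.ndarray:
    """Principal central axis index per parameter:
    PCI(i) = sum_k c_{k,i} k / sum_k c_{k,i}, with
    c_{k,i} = |l_{k,i}| / sum_m |l_{k,m}| (per-axis normalized absolute
    loadings).  Bounded by [1, n_axes]; small values mean the parameter
    loads on the leading (broad) axes.
    """
    L = np.abs(report.loadings)
    row_sums = L.sum(axis=1, keepdims=True)
    c = L / np.where(row_sums > 0, row_sums, 1.0)
    k = np.arange(1, L.shape[0] + 1, dtype=float)[:, None]
    denom = c.sum(axis=0)
    return (c * k).sum(axis=0) / np.where(denom > 0, denom, 1.0)
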