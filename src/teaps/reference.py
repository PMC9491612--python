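"""Ground-truth searches of the BSR parameter set.

For the built-in models the fixed-point condition f(1,...,1; mu) = 0 can be
solved symbolically for a subset of the parameters, which shrinks the
search to the remaining free parameters (every sampled point then has
O_fix = 0 exactly).  The brute-force search enumerates a log-uniform grid
(or log-uniform random draws) over the free parameters and keeps the
points whose relaxation condition holds exactly (O_relax = 0, i.e. the
largest nonzero eigenvalue real part at the fixed point is at most
lambda_target) and whose local contraction is certified on a deterministic
observation lattice of the d = 0.1 box — the largest eigenvalue of
M = D_f + D_f^T stays within the expansion-rate slack ``basin_tol``
(see the methods note; an exact nonpositive maximum is structurally
impossible for conserved-moiety models, so certification carries a bounded
slack, by default |lambda_target|).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import sympy as sp

from .ensemble import ParameterEnsemble
from .models import ODESystem, compiled
from .objective import BSRSpec, ObservationSet

__all__ = [
    "GridSpec",
    "Reduction",
    "analytic_fixed_point_reduction",
    "brute_force_search",
    "observation_lattice",
    "UnsupportedModelError",
]


class UnsupportedModelError(ValueError):
    """The fixed-point constraints could not be solved symbolically."""


@dataclass(frozen=True)
class GridSpec:
    """Budget and bounds for the reference search.

    The reference bounds default to [5e-4, 5e4] (one decade below the
    staged search's lower bound, as used for the reference runs);
    ``points_total`` is the number of sampled free-parameter points.
    """

    lower: float = 5e-4
    upper: float = 5e4
    points_total: int = 100_000
    mode: str = "random"  # "grid" | "random"
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.points_total < 1:
            raise ValueError("points_total >= 1 required")
        if not (0 < self.lower < self.upper):
            raise ValueError("bounds must be positive with lower < upper")
        if self.mode not in ("grid", "random"):
            raise ValueError("mode must be 'grid' or 'random'")


@dataclass(frozen=True)
class Reduction:
    """Symbolic solution of f(x*, mu) = 0 for a subset of the parameters."""

    model: ODESystem
    free_names: tuple[str, ...]
    constrained_names: tuple[str, ...]
    constrained_exprs: dict[str, sp.Expr]

    def full_params(self, free_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (m, n_free) free-parameter values (linear scale) to full
        (m, n_params) vectors plus a feasibility mask (all parameters
        strictly positive and finite)."""
        free_values = np.atleast_2d(np.asarray(free_values, dtype=float))
        syms = [sp.Symbol(n) for n in self.free_names]
        fn = sp.lambdify(syms, [self.constrained_exprs[c] for c in self.constrained_names],
                         modules="numpy")
        cols = [free_values[:, j] for j in range(free_values.shape[1])]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            cons = fn(*cols)
        m = free_values.shape[0]
        out = np.empty((m, self.model.n_params))
        for j, name in enumerate(self.model.parameter_names):
            if name in self.free_names:
                out[:, j] = free_values[:, self.free_names.index(name)]
            else:
                out[:, j] = np.broadcast_to(
                    np.asarray(cons[self.constrained_names.index(name)], dtype=float), (m,)
                )
        feasible = np.all(np.isfinite(out) & (out > 0), axis=1)
        return out, feasible


def analytic_fixed_point_reduction(
    model: ODESystem, x_star: Optional[np.ndarray] = None
) -> Reduction:
    """Solve the fixed-point constraints symbolically, expressing the
    model's designated constrained parameters in terms of the rest."""
    if not model.reduction_constrained:
        raise UnsupportedModelError(
            f"model {model.name} declares no fixed-point reduction"
        )
    x = np.ones(model.n_phase) if x_star is None else np.asarray(x_star, dtype=float)
    subs = {
        sp.Symbol(s): sp.Integer(int(v)) if float(v).is_integer() else sp.Float(v)
        for s, v in zip(model.species_names, x)
    }
    eqs = []
    for expr in model.rhs:
        e = sp.simplify(expr.subs(subs))
        if e != 0:
            eqs.append(sp.Eq(e, 0))
    unknowns = [sp.Symbol(n) for n in model.reduction_constrained]
    sols = sp.solve(eqs, unknowns, dict=True)
    if not sols:
        raise UnsupportedModelError(
            f"fixed-point constraints of {model.name} not symbolically solvable "
            f"for {model.reduction_constrained}"
        )
    sol = sols[0]
    constrained = {str(k): sp.simplify(v) for k, v in sol.items()}
    if set(constrained) != set(model.reduction_constrained):
        raise UnsupportedModelError(
            f"incomplete reduction for {model.name}: solved {set(constrained)}"
        )
    free = tuple(n for n in model.parameter_names if n not in constrained)
    return Reduction(
        model=model,
        free_names=free,
        constrained_names=tuple(model.reduction_constrained),
        constrained_exprs=constrained,
    )


def observation_lattice(model: ODESystem, spec: BSRSpec, d: float) -> ObservationSet:
    """Deterministic 3-per-axis lattice {x*-d, x*, x*+d}^n_phase, so that
    brute-force membership is reproducible."""
    x_star = spec.x_star_for(model)
    axes = [np.array([x - d, x, x + d]) for x in x_star]
    pts = np.array(list(itertools.product(*axes)))
    return ObservationSet(points=pts, half_width=d)


def _free_samples(
    gridspec: GridSpec, n_free: int, rng: Optional[np.random.Generator]
) -> np.ndarray:
    lo, hi = np.log10(gridspec.lower), np.log10(gridspec.upper)
    n = gridspec.points_total
    if gridspec.mode == "random":
        if rng is None:
            rng = np.random.default_rng(0)
        return rng.uniform(lo, hi, size=(n, n_free))
    # grid mode: smallest full lattice covering the budget, truncated to
    # exactly points_total points in the preset (row-major) order
    r = int(np.ceil(n ** (1.0 / n_free)))
    axis = np.linspace(lo, hi, r)
    out = np.empty((n, n_free))
    filled = 0
    for combo in itertools.product(*[axis] * n_free):
        out[filled] = combo
        filled += 1
        if filled == n:
            break
    return out


def brute_force_search(
    model: ODESystem,
    gridspec: GridSpec,
    spec: BSRSpec,
    rng: Optional[np.random.Generator] = None,
    keep_all: bool = False,
    chunk: int = 50_000,
) -> ParameterEnsemble:
    """Enumerate the reduced free-parameter space and keep the BSR points.

    ``keep_all=True`` disables the BSR judgement and returns every feasible
    sampled point (useful for auditing the sampling itself).
    """
    red = analytic_fixed_point_reduction(model, spec.x_star)
    fixed = dict(gridspec.fixed_params)
    unknown = set(fixed) - set(red.free_names)
    if unknown:
        raise ValueError(f"fixed_params {sorted(unknown)} are not free parameters of {model.name}")
    free = tuple(n for n in red.free_names if n not in fixed)
    if not free:
        raise ValueError("no free parameters left to search")
    theta_free = _free_samples(gridspec, len(free), rng)

    cm = compiled(model)
    x_star = spec.x_star_for(model)
    lattice = observation_lattice(model, spec, spec.d_schedule[-1])
    pts = lattice.points
    k = pts.shape[0]
    tol = spec.effective_basin_tol
    kept: list[np.ndarray] = []
    kept_obj: list[np.ndarray] = []
    for start in range(0, theta_free.shape[0], chunk):
        block = 10.0 ** theta_free[start : start + chunk]
        full_free = np.empty((block.shape[0], len(red.free_names)))
        for j, name in enumerate(red.free_names):
            full_free[:, j] = fixed[name] if name in fixed else block[:, free.index(name)]
        P, feasible = red.full_params(full_free)
        P = P[feasible]
        if not P.shape[0]:
            continue
        if keep_all:
            kept.append(P)
            kept_obj.append(np.zeros((P.shape[0], 3)))
            continue
        m = P.shape[0]
        # relaxation condition at the fixed point (exact O_relax = 0)
        J = cm.jac(np.broadcast_to(x_star, (m, model.n_phase)), P)
        re = np.linalg.eigvals(J).real
        max_re = np.where(np.abs(re) > spec.zero_eig_tol, re, -np.inf).max(axis=1)
        with np.errstate(invalid="ignore"):
            relax_ok = np.isfinite(max_re) & (max_re <= spec.lambda_target)
        P = P[relax_ok]
        max_re = max_re[relax_ok]
        if not P.shape[0]:
            continue
        # contraction certificate on the deterministic lattice
        m = P.shape[0]
        Xb = np.tile(pts, (m, 1))
        Pb = np.repeat(P, k, axis=0)
        Jb = cm.jac(Xb, Pb)
        M = Jb + np.swapaxes(Jb, -1, -2)
        lam = np.linalg.eigvalsh(M)[..., -1].reshape(m, k).max(axis=1)
        basin_ok = np.isfinite(lam) & (lam <= tol)
        P = P[basin_ok]
        if P.shape[0]:
            o_basin = np.maximum(lam[basin_ok], 0.0)
            o_relax = np.maximum(max_re[basin_ok] - spec.lambda_target, 0.0)
            kept.append(P)
            kept_obj.append(
                np.column_stack([np.zeros(P.shape[0]), o_basin, o_relax])
            )
    if kept:
        P_all = np.vstack(kept)
        obj = np.vstack(kept_obj)
    else:
        P_all = np.empty((0, model.n_params))
        obj = np.empty((0, 3))
    return ParameterEnsemble(
        parameter_names=tuple(model.parameter_names),
        log10_values=np.log10(P_all) if P_all.size else P_all,
        stage_found=["brute-force"] * P_all.shape[0],
        objectives=obj,
        accepted=np.ones(P_all.shape[0], dtype=bool),
    )
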