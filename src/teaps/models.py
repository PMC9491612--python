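"""Symbolic ODE systems and the built-in sample models.

An :class:`ODESystem` holds the right-hand side of ``dx/dt = f(x, mu)``
symbolically (sympy), together with an analytically differentiated Jacobian.
Models are small mass-action / Michaelis-Menten reaction networks; each
right-hand side is a signed sum of named reaction rates, which lets
evaluation errors point at the offending reaction.

Eight built-in models (T1..T8) cover the common wiring motifs of cellular
networks: positive and negative feedback, reversible reactions with a
conserved regulator, pathway switching, signaling cascades and
multi-factor regulation of a single reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "ODESystem",
    "ParameterSet",
    "ParameterSpace",
    "BUILTIN_MODEL_IDS",
    "build_builtin_model",
    "rhs_eval",
    "jacobian_eval",
    "EvaluationError",
]


class EvaluationError(ValueError):
    """A rate law could not be evaluated (e.g. vanishing denominator)."""


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic parameter values in linear scale, with a log10 view.

    All values must be strictly positive; ``log10_values`` is derived and
    kept consistent by construction.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be positive and finite, got {v}")

    @property
    def log10_values(self) -> dict[str, float]:
        return {k: math.log10(v) for k, v in self.values.items()}

    @classmethod
    def from_log10(cls, log10_values: Mapping[str, float]) -> "ParameterSet":
        return cls({k: 10.0 ** v for k, v in log10_values.items()})

    def to_array(self, parameter_names: Sequence[str]) -> np.ndarray:
        return np.array([self.values[n] for n in parameter_names], dtype=float)

    @classmethod
    def from_array(cls, parameter_names: Sequence[str], arr: Sequence[float]) -> "ParameterSet":
        return cls(dict(zip(parameter_names, (float(v) for v in arr))))


@dataclass(frozen=True)
class ParameterSpace:
    """A positive box in parameter space (per-parameter bounds, linear scale)."""

    parameter_names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (len(self.parameter_names),) or hi.shape != lo.shape:
            raise ValueError("bounds must align with parameter_names")
        if not np.all((lo > 0) & (lo < hi)):
            raise ValueError("require 0 < lower < upper per parameter")

    @property
    def log10_lower(self) -> np.ndarray:
        return np.log10(self.lower)

    @property
    def log10_upper(self) -> np.ndarray:
        return np.log10(self.upper)

    def contains(self, values: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        v = np.atleast_2d(np.asarray(values, dtype=float))
        return np.all((v >= self.lower - atol) & (v <= self.upper + atol), axis=1)

    @classmethod
    def for_model(
        cls,
        model: "ODESystem",
        lower: float = 5e-3,
        upper: float = 5e4,
        flux_lower: float = 5e-1,
    ) -> "ParameterSpace":
        """Default search box: [5e-3, 5e4], input-flux parameters [5e-1, 5e4]."""
        lo = np.full(model.n_params, lower)
        for i, name in enumerate(model.parameter_names):
            if name in model.input_flux_params:
                lo[i] = flux_lower
        return cls(tuple(model.parameter_names), lo, np.full(model.n_params, upper))


@dataclass(frozen=True)
class ODESystem:
    """A parametric ODE system dx/dt = f(x, mu) with symbolic rate laws."""

    name: str
    species_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    reactions: dict[str, sp.Expr]          # rate-law expressions by reaction id
    rhs: tuple[sp.Expr, ...]               # one expression per species
    input_flux_params: frozenset[str] = frozenset()
    # parameters constrained by the fixed-point reduction (reference_search)
    reduction_constrained: tuple[str, ...] = ()
    # net stoichiometric coefficient of each reaction in each species'
    # balance (n_phase x n_reactions, aligned with `reactions` order);
    # None for models not built from a reaction composition
    stoichiometry: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.rhs) != len(self.species_names):
            raise ValueError("rhs length must equal number of species")
        allowed = {sp.Symbol(n) for n in self.species_names} | {
            sp.Symbol(n) for n in self.parameter_names
        }
        for expr in self.rhs:
            extra = expr.free_symbols - allowed
            if extra:
                raise ValueError(f"unknown symbols in rhs: {extra}")

    @property
    def n_phase(self) -> int:
        return len(self.species_names)

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def constant_mask(self) -> tuple[bool, ...]:
        return tuple(sp.simplify(e) == 0 for e in self.rhs)

    @property
    def species_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(n) for n in self.species_names)

    @property
    def parameter_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(n) for n in self.parameter_names)

    def jacobian_expr(self) -> sp.Matrix:
        return sp.Matrix(self.rhs).jacobian(sp.Matrix(self.species_symbols))


# ---------------------------------------------------------------------------
# Compiled numeric evaluation
# ---------------------------------------------------------------------------


class _BatchFunc:
    """Lambdified expression list evaluated over batches of (x, mu) rows."""

    def __init__(self, model: ODESystem, exprs: Sequence[sp.Expr], out_shape: tuple[int, ...]):
        args = list(model.species_symbols) + list(model.parameter_symbols)
        self._f = sp.lambdify(args, list(exprs), modules="numpy")
        self._n_phase = model.n_phase
        self._out_shape = out_shape

    def __call__(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """x: (m, n_phase), p: (m, n_params) or (n_params,) -> (m, *out_shape)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p = np.asarray(p, dtype=float)
        if p.ndim == 1:
            p = np.broadcast_to(p, (x.shape[0], p.shape[0]))
        cols = [x[:, i] for i in range(self._n_phase)] + [p[:, j] for j in range(p.shape[1])]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            vals = self._f(*cols)
        m = x.shape[0]
        out = np.empty((len(vals), m), dtype=float)
        for i, v in enumerate(vals):
            out[i] = np.broadcast_to(np.asarray(v, dtype=float), (m,))
        return np.ascontiguousarray(out.T).reshape((m, *self._out_shape))


class CompiledModel:
    """Vectorized numeric evaluators for a model's rhs, rates and Jacobian."""

    def __init__(self, model: ODESystem):
        self.model = model
        n = model.n_phase
        self.rhs = _BatchFunc(model, model.rhs, (n,))
        self.jac = _BatchFunc(model, list(model.jacobian_expr()), (n, n))
        self._rate_names = list(model.reactions)
        self.rates = _BatchFunc(model, [model.reactions[r] for r in self._rate_names], (len(self._rate_names),))
        # Jacobian of the rhs with respect to the parameters (for
        # Gauss-Newton solves of the fixed-point condition)
        param_jac = sp.Matrix(model.rhs).jacobian(sp.Matrix(model.parameter_symbols))
        self.jac_params = _BatchFunc(model, list(param_jac), (n, model.n_params))

    def rhs_single(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        out = self.rhs(np.asarray(x, dtype=float)[None, :], np.asarray(p, dtype=float))[0]
        if not np.all(np.isfinite(out)):
            rates = self.rates(np.asarray(x, dtype=float)[None, :], np.asarray(p, dtype=float))[0]
            bad = [r for r, v in zip(self._rate_names, rates) if not np.isfinite(v)]
            raise EvaluationError(
                f"model {self.model.name}: rate law(s) {bad or ['<composition>']} "
                f"not finite at x={np.asarray(x).tolist()}"
            )
        return out

    def jac_single(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        out = self.jac(np.asarray(x, dtype=float)[None, :], np.asarray(p, dtype=float))[0]
        if not np.all(np.isfinite(out)):
            raise EvaluationError(
                f"model {self.model.name}: Jacobian not finite at x={np.asarray(x).tolist()}"
            )
        return out


_COMPILED: dict[int, CompiledModel] = {}


def compiled(model: ODESystem) -> CompiledModel:
    """Return (and cache) the vectorized evaluators for *model*."""
    key = id(model)
    cm = _COMPILED.get(key)
    if cm is None or cm.model is not model:
        cm = CompiledModel(model)
        _COMPILED[key] = cm
    return cm


def _as_param_array(model: ODESystem, mu) -> np.ndarray:
    if isinstance(mu, ParameterSet):
        return mu.to_array(model.parameter_names)
    if isinstance(mu, Mapping):
        return np.array([mu[n] for n in model.parameter_names], dtype=float)
    return np.asarray(mu, dtype=float)


def rhs_eval(model: ODESystem, x, mu) -> np.ndarray:
    """Evaluate f(x, mu) numerically. Raises :class:`EvaluationError` on a
    non-finite rate law (naming the reaction)."""
    return compiled(model).rhs_single(np.asarray(x, dtype=float), _as_param_array(model, mu))


def jacobian_eval(model: ODESystem, x, mu) -> np.ndarray:
    """Evaluate the analytic Jacobian D_f(x) numerically."""
    return compiled(model).jac_single(np.asarray(x, dtype=float), _as_param_array(model, mu))


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------

# Each entry: species, parameters, input-flux parameters, rate laws,
# ODE composition (strings over reaction ids), and the parameters that the
# fixed-point reduction solves for (the rest remain free).
_BUILTIN_DEFS: dict[str, dict] = {
    "T1": dict(
        species=("s1", "s2", "s3"),
        params=("k1", "v2", "km2", "k3", "k4"),
        flux=("k1",),
        rates={
            "re1": "k1",
            "re2": "v2*s3*s1/(km2 + s1)",
            "re3": "k3*s2",
            "re4": "k4*s3",
        },
        odes=("re1 - re2", "re2 - re3", "re3 - re4"),
        constrained=("k1", "k3", "k4"),
    ),
    "T2": dict(
        species=("s1", "s2", "s3"),
        params=("k1", "v2", "ki2", "k3", "k4"),
        flux=("k1",),
        rates={
            "re1": "k1",
            "re2": "v2*s1/(1 + s3/ki2)",
            "re3": "k3*s2",
            "re4": "k4*s3",
        },
        # corrected composition; the as-printed variant is handled below
        odes=("re1 - re2", "re2 - re3", "re3 - re4"),
        constrained=("k1", "k3", "k4"),
    ),
    "T3": dict(
        species=("s1", "s2", "s3"),
        params=("k1", "k2", "v3", "km3", "k4"),
        flux=("k1",),
        rates={
            "re1": "k1",
            "re2": "k2*s1",
            "re3": "v3*s3*s2/(km3 + s2)",
            "re4": "k4*s2",
        },
        odes=("re1 + re3 - re2", "re2 - re3 - re4", "0"),
        constrained=("k1", "k4"),
    ),
    "T4": dict(
        species=("s1", "s2", "s3"),
        params=("k1", "v2", "ki2", "v3", "ki3", "k4", "k5"),
        flux=("k1",),
        rates={
            "re1": "k1",
            "re2": "v2*s1/(1 + s3/ki2)",
            "re3": "v3*s1/(1 + s2/ki3)",
            "re4": "k4*s2",
            "re5": "k5*s3",
        },
        odes=("re1 - re2 - re3", "re2 - re4", "re3 - re5"),
        constrained=("k1", "k4", "k5"),
    ),
    "T5": dict(
        species=("s1", "s2", "s3"),
        params=("k1", "k2", "v3", "ki3", "k4", "k5"),
        flux=("k1",),
        rates={
            "re1": "k1",
            "re2": "k2*s1*s3",
            "re3": "v3*s1/(1 + s2/ki3)",
            "re4": "k4*s2",
            "re5": "k5*s3",
        },
        odes=("re1 - re2 - re3", "re2 - re4", "re3 - re5"),
        constrained=("k1", "k4", "k5"),
    ),
    "T6": dict(
        species=("s1", "s2", "s3", "s4"),
        params=("k1", "k2", "v3", "km3", "k4"),
        flux=(),
        rates={
            "re1": "k1*s1",
            "re2": "k2*s2",
            "re3": "v3*s2*s3/(km3 + s3)",
            "re4": "k4*s4",
        },
        odes=("re2 - re1", "re1 - re2", "re4 - re3", "re3 - re4"),
        constrained=("k1", "k4"),
    ),
    "T7": dict(
        species=("s1", "s2", "s3", "s4"),
        params=("k1", "v2", "km2", "v3", "km3", "k4"),
        flux=(),
        rates={
            "re1": "k1*s1",
            "re2": "v2*s4*s2/(km2 + s2)",
            "re3": "v3*s2*s3/(km3 + s3)",
            "re4": "k4*s4",
        },
        odes=("re2 - re1", "re1 - re2", "re4 - re3", "re3 - re4"),
        constrained=("k1", "k4"),
    ),
    "T8": dict(
        species=("s1", "s2", "s3", "s4"),
        params=("k0", "v1", "km1", "fb3", "fb4", "v2", "km2", "v3", "km3"),
        flux=("k0",),
        rates={
            "re0": "k0",
            "re1": "v1*(s1/(km1 + s1))*(1/(1 + fb3*s3 - fb4*s4))",
            "re2": "v2*s2/(km2 + s2)",
            "re3": "v3*s3/(km3 + s3)",
        },
        odes=("re0 - re1", "re1 - re2", "re2 - re3", "0"),
        constrained=("v1", "v2", "v3"),
    ),
}

BUILTIN_MODEL_IDS: tuple[str, ...] = tuple(_BUILTIN_DEFS)


def _assemble(name: str, spec: dict, odes: Sequence[str]) -> ODESystem:
    ns = {s: sp.Symbol(s) for s in spec["species"]}
    ns.update({p: sp.Symbol(p) for p in spec["params"]})
    rates = {rid: sp.sympify(expr, locals=ns) for rid, expr in spec["rates"].items()}
    # compose the balances with reaction-id placeholders first, to extract
    # the stoichiometric coefficients, then substitute the rate laws
    placeholders = {rid: sp.Symbol(f"__{rid}") for rid in rates}
    comp_ns = dict(ns)
    comp_ns.update(placeholders)
    rids = list(rates)
    stoich = []
    rhs = []
    for o in odes:
        comp = sp.expand(sp.sympify(o, locals=comp_ns))
        row = tuple(float(comp.coeff(placeholders[r])) for r in rids)
        stoich.append(row)
        rhs.append(sp.expand(comp.subs({placeholders[r]: rates[r] for r in rids})))
    return ODESystem(
        name=name,
        species_names=tuple(spec["species"]),
        parameter_names=tuple(spec["params"]),
        reactions=rates,
        rhs=tuple(rhs),
        input_flux_params=frozenset(spec["flux"]),
        reduction_constrained=tuple(spec["constrained"]),
        stoichiometry=tuple(stoich),
    )


@lru_cache(maxsize=32)
def build_builtin_model(model_id: str, t2_as_printed: bool = False) -> ODESystem:
    """Return one of the built-in sample models T1..T8.

    T2's s2 balance is returned in the corrected form ``re2 - re3`` by
    default; the literally published form ``re2 - re1`` (which decouples s2
    from its consumption reaction) is available with ``t2_as_printed=True``.
    """
    if model_id not in _BUILTIN_DEFS:
        raise KeyError(f"unknown model id {model_id!r}; known: {', '.join(BUILTIN_MODEL_IDS)}")
    spec = _BUILTIN_DEFS[model_id]
    odes = list(spec["odes"])
    constrained = spec["constrained"]
    if model_id == "T2" and t2_as_printed:
        odes[1] = "re2 - re1"
        constrained = ("k1", "k4")
    sysm = _assemble(model_id, spec, odes)
    if constrained != spec["constrained"]:
        sysm = ODESystem(
            name=sysm.name,
            species_names=sysm.species_names,
            parameter_names=sysm.parameter_names,
            reactions=sysm.reactions,
            rhs=sysm.rhs,
            input_flux_params=sysm.input_flux_params,
            reduction_constrained=tuple(constrained),
            stoichiometry=sysm.stoichiometry,
        )
    return sysm
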