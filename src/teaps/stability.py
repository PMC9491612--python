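"""Monte-Carlo basin-stability estimation.

Basin stability of a parameter set is the probability that a trajectory
started from a random initial state around the target fixed point returns
to (a neighborhood of) it: initial states are drawn coordinate-wise as
target * (1 + Uniform(-h, h)), each is integrated with a stiff solver to
t_end, the endpoint is refined by a root solve of f(x) = 0, and the start
counts as stable when every component of the located fixed point lies
within the return window (90-110% of the target by default).  The
ensemble estimate aggregates the per-set stable fractions into a mean and
its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, optimize

from ._rng import stream
from .ensemble import ParameterEnsemble
from .models import ODESystem, _as_param_array, compiled

__all__ = [
    "BasinConfig",
    "BasinEstimate",
    "converge_to_fixed_point",
    "estimate_basin_stability",
    "basin_trace",
]


@dataclass(frozen=True)
class BasinConfig:
    """Sampling sizes and judgement windows for the basin estimate.

    ``perturb_half_width`` is the relative half-width of the initial-state
    box (0.15 for the small sample models; larger state dimensions use
    smaller widths, e.g. 0.105 / 0.101 for the pathway-scale models).
    """

    n_param_samples: int = 500
    n_initial_states: int = 500
    perturb_half_width: float = 0.15
    t_end: float = 100.0
    return_window: tuple[float, float] = (0.9, 1.1)
    rtol: float = 1e-6
    atol: float = 1e-9
    root_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perturb_half_width <= 0:
            raise ValueError("perturb_half_width must be positive")
        lo, hi = self.return_window
        if not (0 < lo < 1 < hi):
            raise ValueError("return_window must bracket 1")


@dataclass(frozen=True)
class BasinEstimate:
    per_set_ratio: np.ndarray
    mean: float
    sem: float

    def __post_init__(self) -> None:
        r = np.asarray(self.per_set_ratio, dtype=float)
        object.__setattr__(self, "per_set_ratio", r)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("ratios must lie in [0, 1]")


def converge_to_fixed_point(
    model: ODESystem,
    mu,
    x0: np.ndarray,
    config: BasinConfig,
    target: Optional[np.ndarray] = None,
) -> tuple[Optional[np.ndarray], bool]:
    """Integrate from x0 to t_end (stiff solver), then root-solve f(x) = 0
    from the endpoint.

    Returns ``(fixed_point_estimate, stable)``; the estimate is None when
    the trajectory blew up or the root solve failed.  ``stable`` means the
    located fixed point has every component inside the return window
    relative to *target* (all-ones by default).
    """
    cm = compiled(model)
    p = _as_param_array(model, mu)
    if target is None:
        target = np.ones(model.n_phase)

    def f(_t, x):
        return cm.rhs(x[None, :], p)[0]

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        sol = integrate.solve_ivp(
            f,
            (0.0, config.t_end),
            np.asarray(x0, dtype=float),
            method="LSODA",
            rtol=config.rtol,
            atol=config.atol,
            dense_output=False,
        )
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        return None, False
    x_end = sol.y[:, -1]

    def froot(x):
        return cm.rhs(x[None, :], p)[0]

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        root = optimize.root(froot, x_end, method="hybr")
    if not np.all(np.isfinite(root.x)):
        return None, False
    resid = np.max(np.abs(froot(root.x)))
    if not root.success and resid > config.root_tol:
        return None, False
    if resid > config.root_tol:
        return root.x, False
    lo, hi = config.return_window
    in_window = bool(np.all((root.x >= lo * target) & (root.x <= hi * target)))
    # the trajectory itself must have returned: a persistent oscillation
    # leaves x(t_end) on the cycle even though the root solve can fall
    # back onto the enclosed (unstable) fixed point
    returned = bool(np.all((x_end >= lo * target) & (x_end <= hi * target)))
    return root.x, in_window and returned


def estimate_basin_stability(
    model: ODESystem,
    ensemble: ParameterEnsemble,
    config: BasinConfig,
    rng: Optional[np.random.Generator] = None,
    target: Optional[np.ndarray] = None,
) -> BasinEstimate:
    """Stable-fraction estimate over a random subsample of the ensemble.

    Samples min(n_param_samples, |ensemble|) parameter sets without
    replacement; per set, draws n_initial_states initial states as
    target * (1 + Uniform(-h, h)) and computes the fraction judged stable
    by :func:`converge_to_fixed_point`.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    if rng is None:
        rng = stream(config.seed, "basin")
    if target is None:
        target = np.ones(model.n_phase)
    n_sets = min(config.n_param_samples, len(ensemble))
    chosen = (
        rng.choice(len(ensemble), size=n_sets, replace=False)
        if n_sets < len(ensemble)
        else np.arange(len(ensemble))
    )
    h = config.perturb_half_width
    ratios = np.empty(n_sets)
    P = ensemble.values
    for i, idx in enumerate(chosen):
        p = P[idx]
        stable = 0
        for _j in range(config.n_initial_states):
            x0 = target * (1.0 + rng.uniform(-h, h, size=model.n_phase))
            _x, ok = converge_to_fixed_point(model, p, x0, config, target=target)
            stable += ok
        ratios[i] = stable / config.n_initial_states
    mean = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / np.sqrt(n_sets)) if n_sets > 1 else 0.0
    return BasinEstimate(per_set_ratio=ratios, mean=mean, sem=sem)


def basin_trace(
    model: ODESystem,
    snapshots: Sequence[tuple[str, np.ndarray]],
    config: BasinConfig,
    parameter_names: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[dict]:
    """Basin-stability estimate after each search stage (the data behind
    stage-progression plots): one (label, mean, sem) record per snapshot."""
    if parameter_names is None:
        parameter_names = tuple(model.parameter_names)
    if rng is None:
        rng = stream(config.seed, "basin-trace")
    out = []
    for label, log10_sets in snapshots:
        if log10_sets.shape[0] == 0:
            out.append({"stage": label, "mean": float("nan"), "sem": float("nan"), "n_sets": 0})
            continue
        ens = ParameterEnsemble(
            parameter_names=tuple(parameter_names), log10_values=log10_sets
        )
        est = estimate_basin_stability(model, ens, config, rng=rng)
        out.append(
            {
                "stage": label,
                "mean": est.mean,
                "sem": est.sem,
                "n_sets": len(est.per_set_ratio),
            }
        )
    return out
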