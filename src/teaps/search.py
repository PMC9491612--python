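"""The staged global search for the BSR parameter set (TEAPS).

The scheme wraps a globalized cluster-Newton method around the BSR
objective:

1. a cluster-Newton (CNM) stage moves a log-uniform cloud of parameter
   points toward the zero of the residual vector (O_fix, O_basin, O_relax)
   using a shared linear surrogate, harvesting points that reach a moderate
   objective level;
2. a globalized quasi-Newton stage (g-LBFGS) refines every harvested point
   by box-constrained L-BFGS whose descent direction is randomly "twisted"
   for global reach (m-LBFGS), interleaved with noise-addition /
   re-optimization loops that expand the collection, repeated over a
   growing schedule of observation-box half-widths d;
3. the whole cycle repeats with fresh clouds until the found parameter
   distribution stops shifting (per-parameter rank-sum test plus a range
   containment condition).

Finally each candidate is polished by a bounded least-squares solve of the
fixed-point residual and filtered by the acceptance rule
(||f(x*,mu)||_2 < 1e-6 and a strictly negative largest nonzero eigenvalue
real part at the fixed point).

All optimization happens in log10 parameter space: the search boxes span
seven decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from ._rng import stream
from .ensemble import ParameterEnsemble
from .models import ODESystem, ParameterSpace, compiled
from .objective import BatchObjective, BSRSpec, ObservationSet, sample_observation_points

__all__ = [
    "TEAPSConfig",
    "TEAPSResult",
    "init_parameter_cloud",
    "cnm_stage",
    "m_lbfgs_optimize",
    "g_lbfgs_stage",
    "stopping_check",
    "run_teaps",
]


@dataclass(frozen=True)
class TEAPSConfig:
    space: ParameterSpace
    spec: BSRSpec = field(default_factory=BSRSpec)
    n_initial: int = 500
    n_collect: int = 100
    cnm_threshold: float = 0.1
    max_cnm_iters: int = 30
    n_noise_loops: int = 3
    noise_sigma_log10: float = 1.0
    lbfgs_maxiter: int = 60
    twist_theta_max: float = math.pi / 6
    max_pool: int = 2000
    wilcoxon_alpha: float = 0.1
    containment_frac: float = 0.99
    max_outer_iters: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.wilcoxon_alpha < 1):
            raise ValueError("wilcoxon_alpha in (0,1) required")
        if not (0 < self.containment_frac < 1):
            raise ValueError("containment_frac in (0,1) required")
        if self.n_initial < 2:
            raise ValueError("n_initial >= 2 required")


@dataclass
class TEAPSResult:
    ensemble: ParameterEnsemble                       # all final candidates, flagged
    snapshots: list[tuple[str, np.ndarray]]           # (stage label, log10 sets)
    stopping_trace: list[dict]
    n_outer_iters: int = 0
    warning: Optional[str] = None

    @property
    def accepted(self) -> ParameterEnsemble:
        return self.ensemble.accepted_subset


# ---------------------------------------------------------------------------
# Stage 0: initial cloud
# ---------------------------------------------------------------------------


def init_parameter_cloud(config: TEAPSConfig, rng: np.random.Generator) -> np.ndarray:
    """Log10-uniform cloud of n_initial points inside the search box."""
    lo, hi = config.space.log10_lower, config.space.log10_upper
    return rng.uniform(lo, hi, size=(config.n_initial, len(lo)))


# ---------------------------------------------------------------------------
# Stage 1: cluster-Newton collection
# ---------------------------------------------------------------------------


def cnm_stage(
    model: ODESystem,
    config: TEAPSConfig,
    cloud: np.ndarray,
    rng: np.random.Generator,
    max_step: float = 1.5,
) -> tuple[np.ndarray, bool]:
    """Iterate shared-surrogate Newton steps over the cloud, harvesting
    points whose combined objective drops below ``cnm_threshold``.

    Per iteration a linear model ``r(theta) ~ W0 + A theta`` of the residual
    vector is fitted over the whole cloud by least squares, and every point
    takes the minimum-norm (ridge-regularized) step solving ``A step = -r``.
    Steps are clipped to ``max_step`` log10 units and projected into the
    box.  Returns ``(pool, reached_target)``; if the harvest target is not
    reached within ``max_cnm_iters`` the pool is topped up with the current
    best cloud points so the next stage always has material to refine.
    """
    lo, hi = config.space.log10_lower, config.space.log10_upper
    spec = config.spec
    cloud = np.clip(np.array(cloud, dtype=float), lo, hi)
    # solve the O_fix component of the residual exactly up front (analytic
    # Gauss-Newton, minimal movement): the linear surrogate alone needs
    # many iterations for it and walks the cloud off its initial coverage
    cloud = polish_fixed_point(model, config, cloud, mode="anchor")
    pool: list[np.ndarray] = []
    d0 = spec.d_schedule[0]
    reached = False
    for _ in range(config.max_cnm_iters):
        obs = sample_observation_points(spec, d0, rng, model)
        bo = BatchObjective(model, spec, obs)
        R = bo.components(cloud)
        w = spec.weight_w
        combined = R[:, 0] ** 2 + R[:, 1] ** w + R[:, 2] ** w
        hit = combined < config.cnm_threshold
        if hit.any():
            pool.extend(cloud[hit])
            cloud = cloud[~hit]
            R = R[~hit]
        if len(pool) >= config.n_collect or cloud.shape[0] < 2:
            reached = len(pool) >= config.n_collect
            break
        # shared linear surrogate of the residual over the cloud
        D = np.column_stack([np.ones(cloud.shape[0]), cloud])
        W, *_ = np.linalg.lstsq(D, np.log1p(R), rcond=None)
        A = W[1:].T                                   # (3, n_params)
        target = -np.log1p(R)                         # drive residuals to 0
        G = A @ A.T
        G += 1e-8 * np.trace(G) / 3 * np.eye(3) + 1e-12 * np.eye(3)
        step = (A.T @ np.linalg.solve(G, target.T)).T
        norms = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * np.minimum(1.0, max_step / np.maximum(norms, 1e-30))
        # per-point random under-relaxation: the shared surrogate would
        # otherwise contract the whole cloud onto one trajectory, and the
        # harvest would lose its spread over the target set
        step *= rng.uniform(0.1, 1.0, size=(cloud.shape[0], 1))
        cloud = np.clip(cloud + step, lo, hi)
        # walk on the fixed-point manifold: off it, the surrogate descent
        # systematically shears the cloud along the box before any harvest
        cloud = polish_fixed_point(model, config, cloud, max_iters=10, mode="anchor")
    if len(pool) < config.n_collect and cloud.shape[0]:
        # top up with a random (seeded) draw of the remaining points; a
        # best-by-objective selection would bias the pool toward the
        # objective's deepest basin and erase the cloud's coverage
        need = config.n_collect - len(pool)
        take = rng.permutation(cloud.shape[0])[:need]
        pool.extend(cloud[take])
    return np.array(pool), reached


# ---------------------------------------------------------------------------
# Stage 2: globalized L-BFGS
# ---------------------------------------------------------------------------

_FD_STEP = 1e-4  # central-difference step in log10 units


def _batch_value_grad(
    bo: BatchObjective, theta: np.ndarray, active: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combined objective, central-difference gradient and objective
    components for the active rows of *theta*, in one batched evaluation."""
    m, n = theta.shape
    idx = np.flatnonzero(active)
    ma = idx.size
    batch = np.repeat(theta[idx], 2 * n + 1, axis=0).reshape(ma, 2 * n + 1, n)
    for i in range(n):
        batch[:, 1 + 2 * i, i] += _FD_STEP
        batch[:, 2 + 2 * i, i] -= _FD_STEP
    comps = bo.components(batch.reshape(-1, n))
    w = bo.spec.weight_w
    vals = (comps[:, 0] ** 2 + comps[:, 1] ** w + comps[:, 2] ** w).reshape(ma, 2 * n + 1)
    f = np.full(m, np.nan)
    g = np.zeros((m, n))
    c = np.full((m, 3), np.nan)
    f[idx] = vals[:, 0]
    g[idx] = (vals[:, 1::2] - vals[:, 2::2]) / (2 * _FD_STEP)
    c[idx] = comps.reshape(ma, 2 * n + 1, 3)[:, 0, :]
    return f, g, c


# a point is "certified" when it already satisfies the BSR conditions under
# the sweep's observation set (fixed-point residual within the catchment of
# the final least-squares polish, contraction within the slack, relaxation
# bound met); optimization past certification only slides points along the
# certified band and is stopped.  The polish corrects parameters by
# ~o_fix / |df/dmu|, negligible at this level.
_CERT_FIX = 1e-2


def _certified(comps: np.ndarray, spec: BSRSpec) -> np.ndarray:
    return (
        (comps[:, 0] <= _CERT_FIX)
        & (comps[:, 1] <= spec.effective_basin_tol)
        & (comps[:, 2] <= 1e-12)
    )


def m_lbfgs_batch(
    model: ODESystem,
    config: TEAPSConfig,
    theta0: np.ndarray,
    d: float,
    rng: np.random.Generator,
    obs: Optional[ObservationSet] = None,
    twist: bool = True,
    memory: int = 8,
    max_step_norm: float = 0.5,
    project: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Box-constrained L-BFGS on the combined objective, run in lock-step
    over a whole batch of starting points (one vectorized objective call
    per iteration for the entire batch).

    Each point keeps its own limited memory and backtracking line search;
    the globalizing twist rotates each point's quasi-Newton direction
    toward an independent random vector by an angle drawn uniformly from
    [0, theta_max], theta_max halving per iteration (``twist=False`` gives
    plain projected L-BFGS).  Returns ``(best_theta, best_f, ls_ok)``;
    the best iterate per point is returned even on line-search failure, so
    the objective never increases.
    """
    lo, hi = config.space.log10_lower, config.space.log10_upper
    spec = config.spec
    if obs is None:
        obs = sample_observation_points(spec, d, rng, model)
    bo = BatchObjective(model, spec, obs)

    theta = np.clip(np.atleast_2d(np.asarray(theta0, dtype=float)), lo, hi)
    m, n = theta.shape
    active = np.ones(m, dtype=bool)
    f, g, comps = _batch_value_grad(bo, theta, active)
    active &= ~_certified(comps, spec)
    best_theta, best_f = theta.copy(), f.copy()
    S = np.zeros((memory, m, n))
    Y = np.zeros((memory, m, n))
    n_mem = np.zeros(m, dtype=int)
    head = np.zeros(m, dtype=int)          # ring-buffer write position
    stall = np.zeros(m, dtype=int)
    ls_ok = np.ones(m, dtype=bool)
    theta_max = config.twist_theta_max if twist else 0.0

    for _ in range(config.lbfgs_maxiter):
        if not active.any():
            break
        # two-loop recursion, vectorized over points (per-point ring buffer)
        q = g.copy()
        alpha = np.zeros((memory, m))
        for back in range(memory):
            j = (head - 1 - back) % memory
            use = active & (n_mem > back)
            if not use.any():
                break
            s = S[j, np.arange(m)]
            y = Y[j, np.arange(m)]
            ys = np.einsum("ij,ij->i", y, s)
            a = np.where(use, np.einsum("ij,ij->i", s, q) / np.where(ys != 0, ys, 1.0), 0.0)
            alpha[back] = a
            q -= (a * use)[:, None] * y
        jlast = (head - 1) % memory
        slast = S[jlast, np.arange(m)]
        ylast = Y[jlast, np.arange(m)]
        yy = np.einsum("ij,ij->i", ylast, ylast)
        gamma = np.where(
            (n_mem > 0) & (yy > 0), np.einsum("ij,ij->i", slast, ylast) / np.where(yy > 0, yy, 1.0), 1.0
        )
        q *= gamma[:, None]
        for back in range(memory - 1, -1, -1):
            j = (head - 1 - back) % memory
            use = active & (n_mem > back)
            if not use.any():
                continue
            s = S[j, np.arange(m)]
            y = Y[j, np.arange(m)]
            ys = np.einsum("ij,ij->i", y, s)
            b = np.where(use, np.einsum("ij,ij->i", y, q) / np.where(ys != 0, ys, 1.0), 0.0)
            q += ((alpha[back] - b) * use)[:, None] * s
        direction = -q
        bad = np.einsum("ij,ij->i", direction, g) >= 0
        direction[bad] = -g[bad]
        if theta_max > 0:
            nrm = np.linalg.norm(direction, axis=1, keepdims=True)
            d_hat = direction / np.where(nrm > 0, nrm, 1.0)
            r = rng.standard_normal((m, n))
            r -= np.einsum("ij,ij->i", r, d_hat)[:, None] * d_hat
            r_nrm = np.linalg.norm(r, axis=1, keepdims=True)
            r = r / np.where(r_nrm > 1e-12, r_nrm, 1.0)
            ang = rng.uniform(0.0, theta_max, size=(m, 1))
            direction = np.where(
                (nrm > 0) & (r_nrm > 1e-12),
                nrm * (np.cos(ang) * d_hat + np.sin(ang) * r),
                direction,
            )
            theta_max *= 0.5
        # step-length control: clip to max_step_norm so the search certifies
        # points where they enter the BSR set instead of leaping along its
        # flat interior; with an empty memory (no curvature information,
        # e.g. on one-sided ReLU slopes where s'y <= 0) the raw gradient can
        # also be arbitrarily small, so scale it up to the cap as well
        dn = np.linalg.norm(direction, axis=1, keepdims=True)
        factor = np.minimum(1.0, max_step_norm / np.maximum(dn, 1e-30))
        empty = (n_mem == 0)[:, None]
        boost = np.where(
            empty & (dn < max_step_norm) & (dn > 0), max_step_norm / np.maximum(dn, 1e-30), factor
        )
        direction = direction * np.where(empty, boost, factor)
        # vectorized backtracking line search with box projection
        step = np.where(active, 1.0, 0.0)
        accepted = np.zeros(m, dtype=bool)
        hold = np.zeros(m, dtype=bool)      # trial certified: freeze there
        cand = theta.copy()
        f_cand = f.copy()
        searching = active.copy()
        for _ls in range(25):
            if not searching.any():
                break
            trial = np.clip(theta + step[:, None] * direction, lo, hi)
            delta = trial - theta
            tiny = np.linalg.norm(delta, axis=1) < 1e-14
            searching &= ~tiny
            idx = np.flatnonzero(searching)
            if not idx.size:
                break
            comps_t = bo.components(trial[idx])
            w_ = bo.spec.weight_w
            f_trial = comps_t[:, 0] ** 2 + comps_t[:, 1] ** w_ + comps_t[:, 2] ** w_
            armijo = f_trial <= f[idx] + 1e-4 * np.einsum(
                "ij,ij->i", g[idx], delta[idx]
            )
            # a trial that certifies BSR is taken outright: descent would
            # otherwise step across the (narrow) certified set and carry
            # the point further along the objective's flat valley
            cert_t = _certified(comps_t, spec)
            good = armijo | (f_trial < f[idx] - 1e-16) | cert_t
            hold[idx[cert_t]] = True
            gi = idx[good]
            cand[gi] = trial[gi]
            f_cand[gi] = f_trial[good]
            accepted[gi] = True
            searching[gi] = False
            step[searching] *= 0.5
        ls_ok &= accepted | ~active
        progressed = accepted & active
        theta_old, g_old = theta.copy(), g.copy()
        theta = np.where(progressed[:, None], cand, theta)
        if project:
            # keep the path on the fixed-point manifold: descend the
            # contraction/relaxation components subject to f(x*, mu) = 0
            # (Gauss-Newton projection after every accepted step).  Off
            # the manifold the certification test can never fire and
            # points cross the BSR set unrecorded.
            idxp = np.flatnonzero(progressed)
            if idxp.size:
                theta[idxp] = polish_fixed_point(
                    model, config, theta[idxp], max_iters=8, mode="project"
                )
        f_new, g_new, comps_new = _batch_value_grad(bo, theta, progressed)
        f = np.where(progressed, f_new, f)
        g = np.where(progressed[:, None], g_new, g)
        better = progressed & (f < best_f)
        best_f = np.where(better, f, best_f)
        best_theta[better] = theta[better]
        stall = np.where(better, 0, stall + 1)
        # memory update where curvature condition holds
        s_vec = theta - theta_old
        y_vec = g - g_old
        sy = np.einsum("ij,ij->i", s_vec, y_vec)
        upd = progressed & (sy > 1e-12)
        if upd.any():
            S[head[upd], np.flatnonzero(upd)] = s_vec[upd]
            Y[head[upd], np.flatnonzero(upd)] = y_vec[upd]
            head[upd] = (head[upd] + 1) % memory
            n_mem[upd] = np.minimum(n_mem[upd] + 1, memory)
        active &= progressed
        newly_certified = progressed & _certified(np.nan_to_num(comps_new, nan=np.inf), spec)
        if newly_certified.any():
            best_f[newly_certified] = f[newly_certified]
            best_theta[newly_certified] = theta[newly_certified]
            active &= ~newly_certified
        active &= ~(best_f < 1e-16)
        active &= ~(np.max(np.abs(g), axis=1) < 1e-10)
        active &= stall < 5
    return best_theta, best_f, ls_ok


def m_lbfgs_optimize(
    model: ODESystem,
    config: TEAPSConfig,
    theta0: np.ndarray,
    d: float,
    rng: np.random.Generator,
    obs: Optional[ObservationSet] = None,
    twist: bool = True,
    memory: int = 8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Single-start m-LBFGS: the batch optimizer applied to one point.

    Returns ``(best_theta, objective_components_at_best, line_search_ok)``.
    """
    spec = config.spec
    if obs is None:
        obs = sample_observation_points(spec, d, rng, model)
    best, _f, ok = m_lbfgs_batch(
        model, config, np.atleast_2d(theta0), d, rng, obs=obs, twist=twist, memory=memory
    )
    comps = BatchObjective(model, spec, obs).components(best)[0]
    return best[0], comps, bool(ok[0])


def g_lbfgs_stage(
    model: ODESystem,
    config: TEAPSConfig,
    pool: np.ndarray,
    rng: np.random.Generator,
    snapshots: Optional[list] = None,
    snapshot_prefix: str = "",
) -> np.ndarray:
    """Refine and expand the pool over the d schedule.

    For each half-width d: one m-LBFGS sweep over the pool, then
    ``n_noise_loops`` rounds of {log10-Gaussian noise (sigma halving per
    round), re-optimization, keep parents plus improved children}.  After
    the schedule a plain (untwisted) L-BFGS pass runs at the largest d.
    The pool is capped at ``max_pool`` by seeded subsampling.
    """
    spec = config.spec
    # re-anchor the collected points on the fixed-point manifold first: a
    # first-order descent of ||f||^2 in log coordinates drifts down the
    # overall rate scale (||f|| is ~degree-1 homogeneous in it) before
    # converging, which would collapse the pool onto the slowest permitted
    # timescale; the Gauss-Newton polish restores f(x*) = 0 with minimal
    # parameter movement instead
    pool = polish_fixed_point(model, config, np.array(pool, dtype=float), mode="project")

    def sweep(P: np.ndarray, d: float, twist: bool) -> tuple[np.ndarray, np.ndarray]:
        obs = sample_observation_points(spec, d, rng, model)
        out, fs, _ok = m_lbfgs_batch(model, config, P, d, rng, obs=obs, twist=twist)
        return out, fs

    for stage_idx, d in enumerate(spec.d_schedule, start=1):
        pool, f_pool = sweep(pool, d, twist=True)
        for loop in range(config.n_noise_loops):
            sigma = config.noise_sigma_log10 * 0.5**loop
            noised = pool + rng.normal(0.0, sigma, size=pool.shape)
            noised = np.clip(noised, config.space.log10_lower, config.space.log10_upper)
            noised = polish_fixed_point(model, config, noised, mode="project")
            children, f_child = sweep(noised, d, twist=True)
            improved = (f_child <= f_pool) | (f_child < config.cnm_threshold)
            pool = np.vstack([pool, children[improved]])
            f_pool = np.concatenate([f_pool, f_child[improved]])
            if pool.shape[0] > config.max_pool:
                keep = rng.choice(pool.shape[0], config.max_pool, replace=False)
                pool, f_pool = pool[keep], f_pool[keep]
        if snapshots is not None:
            snapshots.append((f"{snapshot_prefix}g-lbfgs-{stage_idx}", pool.copy()))
    # final plain quasi-Newton pass at the widest observation box
    pool, _ = sweep(pool, spec.d_schedule[-1], twist=False)
    return pool


# ---------------------------------------------------------------------------
# Finalization: fixed-point polish and acceptance filter
# ---------------------------------------------------------------------------


def polish_fixed_point(
    model: ODESystem,
    config: TEAPSConfig,
    pool: np.ndarray,
    max_iters: int = 40,
    resid_tol: float = 1e-10,
    mode: str = "anchor",
) -> np.ndarray:
    """Drive ||f(x*, mu)|| to solver precision by damped Gauss-Newton on
    the fixed-point residual in log10 space, batched over the whole pool.

    The parameter Jacobian is analytic; the minimum-norm step solves the
    small n_phase x n_phase normal system, so the correction moves each
    point as little as possible.  Two weightings: ``mode="anchor"``
    (iteratively reweighted, fewest-coordinates — for far-from-manifold
    points whose free-coordinate coverage must be preserved, with a
    Euclidean fallback pass) and ``mode="project"`` (plain Euclidean
    min-norm — for near-manifold points, where the step approximates the
    orthogonal projection onto the manifold and retains the tangent
    component of a preceding noise displacement).  Steps are projected
    into the box; points that stop improving keep their best iterate.
    """
    cm = compiled(model)
    x_star = config.spec.x_star_for(model)
    lo, hi = config.space.log10_lower, config.space.log10_upper
    n = model.n_phase
    ln10 = math.log(10.0)

    theta = np.clip(np.atleast_2d(np.array(pool, dtype=float)), lo, hi)
    theta0 = theta.copy()
    m = theta.shape[0]
    xs = np.broadcast_to(x_star, (m, n))

    def resid(th: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            F = cm.rhs(xs[: th.shape[0]], 10.0**th)
        F[~np.isfinite(F)] = 1e30
        return F

    F = resid(theta)
    norm = np.linalg.norm(F, axis=1)
    best_theta, best_norm = theta.copy(), norm.copy()
    active = norm > resid_tol
    damping = np.full(m, 1e-12)
    reweight = mode == "anchor"
    for _pass in range(2 if mode == "anchor" else 1):
        if _pass == 1:
            # fallback: plain Euclidean min-norm for points the
            # reweighted pass failed to converge (a wrong early weight
            # lock-in can starve a direction the solve needs)
            theta = best_theta.copy()
            F = resid(theta)
            norm = np.linalg.norm(F, axis=1)
            active = norm > resid_tol
            damping = np.full(m, 1e-12)
            reweight = False
            if not active.any():
                break
        _polish_loop(
            resid, theta, theta0, F, norm, best_theta, best_norm, active,
            damping, cm, xs, lo, hi, max_iters, resid_tol, reweight, ln10,
        )
    return best_theta


def _polish_loop(
    resid, theta, theta0, F, norm, best_theta, best_norm, active, damping,
    cm, xs, lo, hi, max_iters, resid_tol, reweight, ln10,
) -> None:
    n = xs.shape[1]
    for _ in range(max_iters):
        idx = np.flatnonzero(active)
        if not idx.size:
            break
        P = 10.0 ** theta[idx]
        with np.errstate(all="ignore"):
            Jp = cm.jac_params(xs[: idx.size], P)
        # chain rule to log10 coordinates: d f / d theta_j = df/dmu_j mu_j ln10
        J = Jp * (P[:, None, :] * ln10)
        J[~np.isfinite(J)] = 0.0
        # fewest-coordinates minimum-norm step (iteratively reweighted):
        # the fixed-point system determines a subset of the parameters
        # from the rest, so the correction should move only that subset.
        # A plain Euclidean min-norm step instead spreads the move over
        # every coordinate — including one-way "ratchet" directions
        # (saturating denominators, the overall rate scale) that shear
        # the pool across the box.  Reweighting by the accumulated
        # per-coordinate movement (L1 flavor) concentrates the correction
        # on the coordinates that have to move and leaves the rest alone.
        if reweight:
            Wgt = (np.abs(theta[idx] - theta0[idx]) + 1e-2)[:, None, :]
        else:
            Wgt = np.ones((idx.size, 1, J.shape[2]))
        JW = J * Wgt
        A = JW @ np.swapaxes(J, 1, 2)
        lam = (damping[idx] + 1e-14 * np.einsum("mii->m", A))[:, None]
        A = A + lam[..., None] * np.eye(n)
        try:
            y = np.linalg.solve(A, -F[idx][..., None])
        except np.linalg.LinAlgError:
            y = np.linalg.lstsq(
                A.reshape(-1, n), -F[idx].reshape(-1, 1), rcond=None
            )[0].reshape(idx.size, n, 1)
        delta = (np.swapaxes(JW, 1, 2) @ y)[..., 0]
        # backtracking on the batched step
        scale = np.ones(idx.size)
        improved = np.zeros(idx.size, dtype=bool)
        trial_theta = theta[idx].copy()
        trial_norm = norm[idx].copy()
        for _bt in range(6):
            open_ = ~improved
            if not open_.any():
                break
            cand = np.clip(theta[idx][open_] + scale[open_, None] * delta[open_], lo, hi)
            Fc = resid(cand)
            nc = np.linalg.norm(Fc, axis=1)
            good = nc < trial_norm[open_]
            sub = np.flatnonzero(open_)[good]
            trial_theta[sub] = cand[good]
            trial_norm[sub] = nc[good]
            improved[sub] = True
            scale[~improved] *= 0.25
        damping[idx[~improved]] *= 100.0
        damping[idx[improved]] = np.maximum(damping[idx[improved]] * 0.1, 1e-12)
        theta[idx] = trial_theta
        norm[idx] = trial_norm
        better = norm[idx] < best_norm[idx]
        bi = idx[better]
        best_theta[bi] = theta[bi]
        best_norm[bi] = norm[bi]
        F[idx] = resid(theta[idx])
        active[idx] = (norm[idx] > resid_tol) & (damping[idx] < 1e8)
    return best_theta


def _finalize(
    model: ODESystem, config: TEAPSConfig, pool: np.ndarray
) -> ParameterEnsemble:
    spec = config.spec
    polished = polish_fixed_point(model, config, pool, mode="project")
    obs_lattice = _acceptance_observations(model, spec)
    bo = BatchObjective(model, spec, obs_lattice)
    comps = bo.components(polished)
    cm = compiled(model)
    m = polished.shape[0]
    xs = np.broadcast_to(spec.x_star_for(model), (m, model.n_phase))
    J = cm.jac(xs, 10.0**polished)
    re = np.linalg.eigvals(J).real
    max_re = np.where(np.abs(re) > spec.zero_eig_tol, re, -np.inf).max(axis=1)
    accepted = (comps[:, 0] < spec.fix_tol) & (max_re < 0) & np.isfinite(max_re)
    return ParameterEnsemble(
        parameter_names=tuple(model.parameter_names),
        log10_values=polished,
        stage_found=["final"] * m,
        objectives=comps,
        accepted=accepted,
    )


def _acceptance_observations(model: ODESystem, spec: BSRSpec) -> ObservationSet:
    """Deterministic 3-per-axis lattice at the widest d, for diagnostics."""
    from .reference import observation_lattice

    return observation_lattice(model, spec, spec.d_schedule[-1])


# ---------------------------------------------------------------------------
# Stopping rule
# ---------------------------------------------------------------------------


def stopping_check(
    config: TEAPSConfig, history_values: np.ndarray, new_values: np.ndarray
) -> tuple[bool, list[dict]]:
    """Two-condition convergence test on the found parameter distribution.

    For every parameter: (1) a Wilcoxon rank-sum test between the values
    found up to the previous cycle and the pooled values including the
    latest cycle must not reject (p >= alpha, no multiplicity correction),
    and (2) at least ``containment_frac`` of the latest cycle's values must
    lie within the [min, max] range already found.  Stop only if both hold
    for all parameters.
    """
    history_values = np.atleast_2d(history_values)
    new_values = np.atleast_2d(new_values)
    if not history_values.size or not new_values.size:
        raise ValueError("both value collections must be nonempty")
    details = []
    stop = True
    for j in range(history_values.shape[1]):
        h, w = history_values[:, j], new_values[:, j]
        pooled = np.concatenate([h, w])
        p = float(stats.ranksums(h, pooled).pvalue)
        inside = float(np.mean((w >= h.min()) & (w <= h.max())))
        ok = (p >= config.wilcoxon_alpha) and (inside >= config.containment_frac)
        details.append({"param": j, "p": p, "containment": inside, "ok": ok})
        stop &= ok
    return stop, details


# ---------------------------------------------------------------------------
# Outer loop
# ---------------------------------------------------------------------------


def run_teaps(model: ODESystem, config: TEAPSConfig) -> TEAPSResult:
    """Full search: repeat {cloud -> CNM -> g-LBFGS -> polish/filter} with
    fresh clouds until the accepted distribution stops shifting.

    Reproducible from (config, seed): every random component draws from a
    named substream of the run seed.  Returns all final candidates; the
    ``accepted`` flags mark the sets passing the acceptance filter.  An
    empty accepted set after ``max_outer_iters`` is reported via the
    ``warning`` field, not an exception.
    """
    snapshots: list[tuple[str, np.ndarray]] = []
    stopping_trace: list[dict] = []
    parts: list[ParameterEnsemble] = []
    accepted_hist: Optional[np.ndarray] = None
    n_outer = 0
    for outer in range(config.max_outer_iters):
        n_outer = outer + 1
        prefix = "" if outer == 0 else f"iter{outer + 1}:"
        r_cloud = stream(config.seed, "cloud", outer)
        r_cnm = stream(config.seed, "cnm", outer)
        r_opt = stream(config.seed, "optimize", outer)
        cloud = init_parameter_cloud(config, r_cloud)
        pool, _ = cnm_stage(model, config, cloud, r_cnm)
        if snapshots is not None:
            snapshots.append((f"{prefix}cnm", pool.copy()))
        pool = g_lbfgs_stage(
            model, config, pool, r_opt, snapshots=snapshots, snapshot_prefix=prefix
        )
        ens = _finalize(model, config, pool)
        parts.append(ens)
        acc_new = ens.log10_values[ens.accepted]
        if accepted_hist is None:
            accepted_hist = acc_new
            continue
        if len(acc_new) and len(accepted_hist):
            stop, details = stopping_check(config, accepted_hist, acc_new)
            stopping_trace.append(
                {"outer_iter": outer + 1, "stop": stop, "per_param": details}
            )
            accepted_hist = np.vstack([accepted_hist, acc_new])
            if stop:
                break
        else:
            accepted_hist = np.vstack([accepted_hist, acc_new]) if len(acc_new) else accepted_hist
    merged = ParameterEnsemble.concatenate(parts)
    warning = None
    if merged.accepted is None or not merged.accepted.any():
        warning = "no parameter set passed the acceptance filter"
    snapshots.append(
        ("final", merged.log10_values[merged.accepted] if merged.accepted is not None else merged.log10_values)
    )
    return TEAPSResult(
        ensemble=merged,
        snapshots=snapshots,
        stopping_trace=stopping_trace,
        n_outer_iters=n_outer,
        warning=warning,
    )
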