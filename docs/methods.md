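# Methods

## The BSR property

The package works with ODE models of biochemical networks,
`dx/dt = f(x, μ)`, where `x ∈ R^N` collects the amounts of the model's
species and `μ ∈ R^Np` its kinetic parameters (rate constants,
Michaelis–Menten constants, inhibition constants, input fluxes). A
parameter set is called **biologically stable and resilient (BSR)** for a
prescribed state `x*` when three conditions hold:

1. **Fixed point** — `f(x*, μ) = 0`. The built-in models use
   `x* = (1, …, 1)`: absolute amounts depend on the unit chosen, so only
   relative deviations are meaningful and the steady state can be
   normalized to one.
2. **Local contraction around `x*`** — in a box of relative half-width
   `d` around the fixed point, the symmetrized Jacobian
   `M(x) = D_f(x) + D_f(x)^T` should not expand the distance between
   neighboring orbits. `λ_max(M(x))/2` bounds the instantaneous growth
   rate of `‖δx‖`; if `M ≺ 0` throughout a neighborhood, every orbit in it
   converges exponentially to `x*`.
3. **Bounded relaxation time** — the slowest nonzero mode at the fixed
   point must relax at least at rate `|λ*_target|`:
   `max_{Re λ ≠ 0} Re λ(D_f(x*)) ≤ λ*_target < 0`. Exact zero eigenvalues
   are tolerated: conservation laws (e.g. the `s1 + s2` and `s3 + s4`
   moieties of the cascade models T6/T7) produce structural zero modes
   that are neutral rather than unstable, and they are excluded from the
   maximum (an eigenvalue is zero-classified when `|Re λ| ≤ 1e-8`).

The three conditions are scored by nonnegative objective components

    O_fix(μ)   = ‖f(x*, μ)‖₂
    O_basin(μ) = ReLU( max over observation points X^(k) of λ_max(M(x)) )
    O_relax(μ) = ReLU( max_{|Re λ*|>1e-8} Re λ*(D_f(x*)) − λ*_target )

with observation points drawn coordinate-wise as `x*_j + U(−d, d)`.
The scalar search objective is `O_fix² + O_basin^w + O_relax^w`; the
cluster-Newton stage instead drives the concatenated residual vector
`(O_fix, O_basin, O_relax)` to zero.

### The weight w

`w ∈ [1, 2]` is admissible; the package defaults to `w = 1`. The reason
is geometric: with `w = 2` the combined objective trades a small positive
`O_relax` against a smaller `O_basin`, so its unconstrained minimum lies
slightly *outside* the BSR set (for T1 the stationary rate scale sits a
few percent below the relaxation bound). With `w = 1` the piecewise-linear
tradeoff pins the minimum exactly on the `O_relax = 0` kink — on the
boundary of the BSR set — so optimized points are BSR members rather than
near-members.

### The contraction slack

Demanding `O_basin = 0` exactly is structurally impossible for several
model classes. For the conserved-moiety models the proof is one line:
with a conservation vector `u` (`uᵀ D_f ≡ 0`), `uᵀ M u = 0` while
`M u ≠ 0`, so `M` always has a strictly positive eigenvalue. Dense scans
show strictly positive floors for the non-conserved models T1
(`λ_max(M) ≥ ~0.101` anywhere the relaxation bound holds), T3 and T8 as
well. Contraction is therefore *certified with a slack*: a parameter set
counts as contracting when `O_basin ≤ basin_tol`, i.e. when transient
local distance growth is no faster than `basin_tol/2`. The default is

    basin_tol = |λ*_target| / 2        (0.15 at the default target)

half the prescribed relaxation-rate scale — the only rate scale the
problem supplies. The same slack bounds the log-width of the constrained
rate constants of T1 to ≈0.22 decades (between the relaxation bound
0.89 ≈ |λ*_target|/0.34 and the contraction cap `basin_tol/0.101`),
consistent with the narrow (<0.3 decade) marginals the reference search
produces. The slack enters only the membership judgement (brute-force
acceptance and the optimizer's early-stop certificate); the objective
itself and the final acceptance filter are unchanged.

## The staged search

The search (`teaps.search.run_teaps`) repeats three stages with fresh
random clouds until the found distribution stops moving:

1. **Cluster-Newton harvest.** A log₁₀-uniform cloud (default 500 points)
   is first placed on the fixed-point manifold (see *polish* below) and
   then moved toward zero residual with a shared linear surrogate: per
   iteration, `log1p` of the residual vector is regressed on the cloud
   coordinates, each point takes the ridge-regularized minimum-norm
   Newton step toward zero (clipped to 1.5 log₁₀ units, projected into
   the box, re-anchored on the manifold), scaled by a per-point random
   factor `U(0.1, 1)`. The random under-relaxation is essential:
   deterministic shared steps contract the entire cloud onto one
   trajectory. Points whose combined objective drops below the
   *moderate* level `cnm_threshold` are harvested each iteration until
   `n_collect` are in hand; if the iteration cap is reached first, the
   pool is topped up with a random draw of the remaining cloud.
   The default level 0.1 is a calibrated compromise (level tuning is
   part of applying the method): certified sets themselves carry
   combined objective up to `basin_tol` ≈ 0.15, so 0.1 defers some of
   them to the optimizer's certification test, but looser levels inject
   near-certified mass across the whole box that later drifts along the
   objective's flat valley and distorts the found distribution.
2. **Globalized quasi-Newton refinement (g-LBFGS).** For each half-width
   `d` in the schedule (0.004, 0.036, 0.1): every pool member is
   optimized by box-constrained L-BFGS in log₁₀ space with a frozen
   observation set, then `n_noise_loops` rounds of {add log₁₀-Gaussian
   noise (σ = 1 decade, halving per round), re-anchor, re-optimize, keep
   parents and improved children} expand the pool. The growing `d`
   schedule lets easy (small-box) contraction guide the search before the
   full 10% box is enforced. A final untwisted L-BFGS pass runs at the
   largest `d`.
3. **Finalization.** Candidates are polished by a bounded trust-region
   least-squares solve of `f(x*, μ) = 0` in log₁₀ space and filtered by
   the acceptance rule `‖f(x*, μ)‖₂ < 1e-6` and
   `max_{nonzero} Re λ*(D_f(x*)) < 0`.

The outer loop stops when, for every parameter, (a) a Wilcoxon rank-sum
test between the values accepted so far and the pooled values including
the latest cycle does not reject at α = 0.1 (no multiplicity
correction), and (b) at least 99% of the latest cycle's values lie within
the range already seen.

### m-LBFGS details

* Gradients are central finite differences in log₁₀ space (step 1e-4):
  the max-eigenvalue terms are non-smooth and analytic eigen-derivatives
  break at crossings.
* The globalizing **twist** rotates the quasi-Newton direction within the
  span of (direction, fresh Gaussian vector) by an angle
  `U(0, θ_max)`, `θ_max = 30°` halving per iteration; the final pass uses
  `θ_max = 0`.
* Steps are norm-clipped to 0.5 log₁₀ units and projected onto the box;
  when the L-BFGS memory is empty (no curvature information — the pair
  update is skipped where `sᵀy ≤ 0`, which happens throughout the
  one-sided ReLU pieces of the objective) the raw gradient direction is
  scaled *up* to the step cap, since it can otherwise be arbitrarily
  small and the iteration would crawl. A greedy step-expansion phase was
  tried for the same purpose and rejected: it amplifies the objective's
  weak tilt along the BSR set's flat interior directions into a
  many-decade slide that piles the ensemble onto a box edge.
* **Certification capture**: a point stops optimizing once it satisfies
  `O_fix ≤ 1e-2` (within the catchment of the final polish),
  `O_basin ≤ basin_tol` and `O_relax = 0` under the sweep's own
  observation set — and the test is applied to every line-search trial,
  with a certified trial accepted outright. Past certification the
  objective only ranks certified members against each other, and since
  it decreases monotonically along the set's flat interior directions,
  unchecked minimization provably collapses the ensemble onto one edge
  of the box; and without the per-trial test, descent steps across the
  narrow certified band unrecorded. Accepted iterates are also
  re-projected onto the fixed-point manifold each iteration, so the
  `O_fix` part of the certificate stays satisfied along the whole path.
* **The fixed-point polish** (damped Gauss-Newton on `f(x*, μ) = 0` in
  log₁₀ coordinates, batched, analytic parameter Jacobian) comes in two
  weightings chosen by role. Far from the manifold (the CNM cloud) the
  minimum-norm metric matters: a plain Euclidean step exploits the
  rate laws' approximate degree-1 homogeneity and one-way "ratchet"
  directions (saturating denominators) to shear the whole cloud across
  the box, so there the step is iteratively reweighted by accumulated
  per-coordinate movement (an L1 flavor that concentrates the correction
  on the coordinates that must move, with a Euclidean fallback pass for
  points it fails to converge). Near the manifold (noise children,
  in-sweep projection, finalization) the plain Euclidean step is used:
  there it approximates the orthogonal projection onto the manifold and
  retains the tangent component of the preceding noise displacement —
  the mechanism by which the noise loops explore the BSR set's flat
  directions.
* The pool is capped (`max_pool`, default 2000) by seeded random
  subsampling; the keep-parents rule would otherwise double it per noise
  loop.

## Reference searches

For the built-in models the fixed-point condition is solved symbolically
(`analytic_fixed_point_reduction`), e.g. for T1
`k1 = k3 = k4 = v2/(km2 + 1)` with `(v2, km2)` free; every sampled point
then has `O_fix = 0` exactly. The brute-force search enumerates a
log-uniform grid or log-uniform random draws over the free parameters
(bounds 5e-4..5e4, the reference-search range; the staged search uses
5e-3..5e4 with 5e-1 as the input-flux floor — both kept as printed per
mode) and keeps points with `O_relax = 0` and the contraction certificate
on a deterministic 3-per-axis lattice `{x*−d, x*, x*+d}^N` at `d = 0.1`.
The lattice replaces random observation points so that membership is
reproducible; its corners are the worst case of the box, making the
brute-force judgement slightly stricter than the search's random-point
certificate. For T8 the input flux is pinned to 0.5 and the remaining
eight parameters are compared.

## Basin stability

Basin stability of a parameter set is estimated by Monte Carlo: initial
states `x_j = target_j (1 + U(−h, h))` (default `h = 0.15`), stiff
integration (LSODA, rtol 1e-6, atol 1e-9) to `t = 100`, then a root solve
of `f(x) = 0` from the endpoint (`‖f‖∞ ≤ 1e-10`). A start counts as
stable when every component of the located fixed point *and of the
endpoint itself* lies within 90–110% of the target. The endpoint
condition is needed for honesty about oscillations: an undamped
oscillation leaves the state on its cycle, but a Newton solve from the
cycle can land on the enclosed unstable fixed point; without the endpoint
check such a system would be scored as returned. For genuinely relaxing
systems (rate ≥ 0.3 over a horizon of 100) the trajectory has decayed by
e⁻³⁰ and the extra condition never changes the score. Ensemble estimates
sample parameter sets without replacement (all sets when the ensemble is
smaller than the requested sample) and report the mean stable fraction
with its standard error.

## Density comparison

Ensembles are compared in the *reduced free-parameter space* in log₁₀
scale. Both the search ensemble (projected to the free coordinates) and
the brute-force set live on the fixed-point manifold; comparing in the
full parameter space would put both on a measure-zero sheet that no
tensor-product lattice can resolve. Densities are product-Gaussian KDEs
with per-dimension Silverman bandwidths
`h_j = σ_j (4/((dim+2) n))^(1/(dim+4))` (floor 1e-3 log₁₀ units for
degenerate dimensions), evaluated on a shared log-uniform lattice
(20 points per axis, reduced for higher-dimensional comparisons to keep
the tensor under 2×10⁵ points), flattened in row-major order and
normalized to sum 1. Similarity is scored by cosine similarity and
Jensen–Shannon divergence (natural log, `0·log 0 = 0`; base-2 available).
The random-comparator calibration resamples density-vector components
from the reference vector's empirical value distribution and reports
`log₁₀` ratios with percentile confidence intervals: positive cosine
ratios and negative JS ratios mean the search matches the reference
better than value-shuffled vectors do.

PCA of an ensemble retains all components (axis count = parameter count)
so both the widest and narrowest directions of the BSR set are visible;
the principal central axis index
`PCI(i) = Σ_k c_{k,i} k / Σ_k c_{k,i}` with
`c_{k,i} = |l_{k,i}| / Σ_m |l_{k,m}|` summarizes, per parameter, which
axes it loads on — small PCI means the parameter varies along the broad
directions of the set.

## Problem sizes

The package's default study conditions are the reference settings
(`x* = 1`, `λ*_target = −0.3`, `d` schedule 0.004/0.036/0.1, 20
observation points, `w = 1`, acceptance `‖f‖ < 1e-6`). The bundled
validation suite and the results script run the pipeline at desk scale:
search clouds of 300 points, harvest target 120, pool cap 800, up to 5
outer cycles, and 2–4×10⁵ reference points per model — sizes chosen so
a full four-model comparison completes in minutes on one CPU while
leaving the density comparisons' similarity structure intact (at 10⁵
reference points the reference itself becomes the noise floor for the
sparser models: two independent references for the four-variable
cascade agree only to cosine ≈ 0.95). Basin-stability estimates in the
validation suite use 40 parameter sets × 40 initial states per stage.
Published full-scale analyses of this kind use 10²–10⁴× larger budgets
(reference grids of 3×10⁸–3×10⁹ points). At desk scale the banded
models (narrow rate-constant windows: T1, T6, T7) reproduce the
full-scale similarity values within a few percent; models whose BSR set
contains multi-decade scale-flat directions (T2, and T8 whose
comparison conditions the reference on a pinned input flux) are
diffusion-limited — the search reaches the whole set but cannot
equilibrate its occupancy within desk-scale noise-loop counts, and
their desk-scale similarity values are substantially below the
full-scale ones. This is a coverage-rate limitation of the budget, not
a membership error: every reported set satisfies the BSR conditions
exactly.

## What the built-in models do and do not cover

T1–T8 span the canonical wiring motifs (positive/negative feedback,
reversible regulation, pathway switching, cascades with conservation,
multi-factor regulation) with 3–4 species and 5–9 parameters. They are
fixtures for validating the search machinery, not stand-ins for
pathway-scale models: real networks add high dimensionality (dozens of
species, 10²+ parameters), stiffness spread over many decades, and
oscillatory regimes. The SBML reader accepts such models (reaction
networks with content-MathML kinetic laws; rules, events and function
definitions are rejected explicitly), but pathway-scale searches need
correspondingly larger budgets than the bundled desk-scale settings.

## Known limitations

* The contraction certificate is sufficient-with-slack, not necessary:
  systems whose basin is large but whose symmetrized Jacobian is
  indefinite on the 10% box (common for strongly non-normal Jacobians)
  are under-counted relative to simulation-based basin stability.
* The CNM surrogate is a single global linear model per iteration; its
  harvest is biased toward the regions its descent paths cross first.
  Coverage of the BSR set therefore leans on the noise/re-optimize loops
  and on repeated outer cycles, and very wide flat regions (T2's
  four-decade rate-scale direction) equilibrate slowly at small budgets.
* `analytic_fixed_point_reduction` handles the built-ins' fixed-point
  systems (linear in the constrained parameters); imported SBML models
  fall back to search-only use (`UnsupportedModelError` from the
  reference pipeline).
* Determinism is per-platform: identical seeds reproduce results
  bit-for-bit on the same NumPy/SciPy builds, but eigen- and ODE-solver
  differences across platforms can flip borderline certificates.
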