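# Methods

## Model and geometry

A constraint-based metabolic model is the triple (S, lb, ub) with an
optional linear objective c. The steady-state flux space

    F = { v ∈ R^n : S v = 0, lb ≤ v ≤ ub }

is a bounded convex polytope but almost never full-dimensional in flux
coordinates. All samplers in polyflux operate on its full-dimensional
restatement, obtained by `build_polytope` in four steps:

1. **Bound tightening.** For each reaction the minimum and maximum flux
   over F is computed by LP (this is FVA at γ = 0). Bounds are replaced by
   that range. Reactions whose range is narrower than `tol = 1e-7` are
   *fixed*: they are pinned at the interval midpoint and become implicit
   equalities. The midpoint is chosen (rather than either bound) so the
   pinned value is the center of the residual numerical interval; any point
   of an interval this narrow is equivalent at sampling accuracy.
2. **Null-space projection.** The augmented system S_aug (S stacked with a
   unit row per fixed reaction) is factored by SVD; the numerical rank uses
   the standard cutoff σ_max · max(m, n) · 1e-12, and the orthonormal basis
   N of its null space gives the sampling dimension d = n − rank(S_aug).
3. **Interior particular solution.** The shift of the affine map
   v = N x + shift is the v-component of a Chebyshev-style LP in flux space
   (maximize the margin to all free bounds subject to the equalities).
   Unlike a least-squares particular solution this is strictly interior,
   so the polytope origin is a valid walk start and no facet is active at
   x = 0.
4. **Facet cleanup.** The box constraints on free fluxes become
   A x ≤ b; rows are normalized to unit norm (so slacks are distances and
   billiard normals are unit vectors) and redundant facets are removed by
   one LP per facet: the facet's own bound is relaxed by 1 and the row is
   dropped when its maximum over the remaining constraints cannot exceed
   the original bound (+1e-7). Testing against the *remaining* set with the
   own-bound relaxation removes exact duplicates one copy at a time and
   makes the operation idempotent.

Full-dimensionality is certified by the Chebyshev-center LP: radius
≥ 1e-7, else construction fails with an explicit error.

All LPs go through a single solver-agnostic function (`polyflux.lp.solve_lp`),
currently backed by HiGHS via `scipy.optimize.linprog`. Any LP solver with
~1e-9 feasibility tolerance can be substituted there without touching the
rest of the code.

## Random walks

All walks share one seeded `numpy.random.Generator` per chain (sphere
directions are normalized Gaussians; every uniform comes from the same
stream), so a chain is a pure function of (polytope, walk, parameters,
seed, start). The default start is the Chebyshev center.

* **CDHR / RDHR** (hit-and-run): choose a coordinate axis / uniform sphere
  direction, then a uniform point on the chord through the current point.
  Exact and rejection-free; the workhorse for low dimensions.
* **Ball walk**: propose uniformly in a ball of radius δ
  (default 4·r_cheb/√d), accept iff feasible (lazy Metropolis on the
  uniform target).
* **Billiard walk**: trajectory length L = −τ ln η with η ~ U(0, 1),
  specular reflection u ← u − 2(u·n̂)n̂ at each facet, stop at length L;
  if more than R reflections occur (default R = 10·d) the step is rejected
  and the chain stays put. τ defaults to the axis-aligned bounding-box
  diagonal (2d LPs) — a diameter proxy; MMCS re-derives τ per phase as
  6·√λ_max of the current sample covariance, the scale at which a
  trajectory crosses the body a few times. A trajectory escaping the body
  by more than 1e-8 raises a geometry error (it indicates un-normalized
  rows).
* **Dikin walk**: proposal uniform in the log-barrier Hessian ellipsoid
  {z : (z−x)ᵀH(x)(z−x) ≤ r²}, H(x) = Σ A_iᵀA_i/(b_i − A_i·x)², with
  r = 0.5 (guaranteeing the proposal stays interior); the move is rejected
  when x lies outside the same-radius ellipsoid at y and otherwise accepted
  with probability min(1, √(det H(y)/det H(x))), which makes the uniform
  law stationary.
* **John and Vaidya walks**: names reserved in the interface; they raise
  `NotImplementedError`.

Default thinning (`walk_length`) is 1 for the billiard walk — its long
reflected trajectories decorrelate within a step — and ⌈d/2⌉ for the local
walks. Every recorded point satisfies A x ≤ b + 1e-9; this is asserted
across the test suite.

## Rounding and the two sampling regimes

Flux polytopes are anisotropic (condition numbers of 10^4 and far beyond),
which throttles every local walk. Rounding estimates an affine map that
makes the body near-isotropic:

* a pilot chain of max(500, 20·d) samples is drawn;
* the sample covariance C is factored (symmetric square root L = C^{1/2});
* the polytope is mapped through x = L y + mean and rows re-normalized;
* iterate until the ratio of extreme singular values of the pilot
  covariance is ≤ 3, up to 20 iterations (non-convergence is an error
  carrying the last condition number).

The roundness threshold 3 and the pilot size follow common multiphase
Monte Carlo practice; both are exposed as arguments.

**MMCS** interleaves this with production sampling in one pass: while the
phase covariance condition exceeds 3, phases only refine the transform and
their samples are *discarded* — they follow a changing kernel and would
bias the chain. Once round, the transform is frozen and batches (of
`ess_target` samples, capped at 50 000 per batch) accumulate, each batch
mapped back to original coordinates through the composed transform. After
every batch the full accumulated chain is re-scored; termination requires
min-coordinate ESS ≥ `ess_target` (default 1000) *and* max-coordinate
PSRF ≤ `psrf_limit` (default 1.1). The returned report is reproducible by
an independent diagnostics pass over the returned chain — the gates are a
property of the output, not of internal state. A phase cap (100) and an
optional wall-clock budget turn unreachable gates into clean errors that
carry partial diagnostics.

**BWR** runs the same rounding to completion first, then billiard batches
on the rounded polytope under the same gates. The two regimes must agree in
distribution; the tests compare their coordinate means on reference
fixtures within three combined Monte-Carlo standard errors.

Because the rounding map is invertible and affine, uniformity is preserved
exactly by the coordinate change; the measure-preservation tests verify the
analytic cube moments after sampling a random invertible skew of the cube.

## Diagnostics

* **ESS** (single chain): n / (1 + 2 Σ ρ̂_t) with the autocorrelation sum
  truncated by Geyer's initial monotone positive sequence (pair sums
  Γ_k = ρ̂_2k + ρ̂_2k+1 kept while positive, forced non-increasing).
  Autocovariances are computed by FFT. The estimate is capped at 2n to
  bound antithetic chains. Calibration: an AR(1) chain with coefficient φ
  has ESS/n = (1−φ)/(1+φ); the tests check φ = 0.5 at n = 10^5 within 15%.
* **PSRF** (split chain): the single returned chain is split in half and
  R̂ = √(((h−1)/h · W + B/h)/W) with W the mean within-half variance and
  B = h · var(half means). Identical halves give R̂ = √((h−1)/h) ≤ 1.
  Rank-normalization is not applied: uniform targets are bounded and
  light-tailed, where the plain estimator is already well-behaved.
* Gates are evaluated per coordinate with min/max aggregation.
  Zero-variance coordinates (fixed fluxes that survived preprocessing) are
  excluded from gating and listed in the report.

## Copulas

`compute_copula` maps two flux series to normalized ranks (r − 0.5)/n
(average ranks on ties — continuous samplers are tie-free, but file
round-tripping can introduce ties) and histograms the rank pairs on an
m×m grid (default m = 10). Marginals are uniform by construction; the grid
is invariant under strictly monotone transforms of either series. The
`dependence_indicator` is the ratio of mass within `band` of the diagonal
to mass within `band` of the anti-diagonal: ≈1 for independence, > 1 for
positive dependence, `inf` (sentinel) when the anti-diagonal band is
empty. Note that for odd m the central cell lies in both bands, so perfect
rank correlation yields m (not infinity) at band 0.

## Fixtures and what the tests do (and do not) show

The reference generators produce: linear pathway ("chain") models where
steady state forces all fluxes equal; a branched pathway with a
2-dimensional flux polytope whose vertices are enumerable by hand; and
geometric bodies (cube, standard simplex, stretched box, seeded random
skew of the cube) with exact uniform moments. These capture the two
failure modes that matter for samplers — dimension and anisotropy — in a
regime where ground truth is analytic. They do *not* reproduce other
features of genome-scale networks: thousands of reactions, highly sparse
and degenerate stoichiometry, and near-redundant constraint families.
Passing tests therefore certify algorithmic correctness and the gate
contract, not genome-scale wall-clock performance.

Problem sizes used in the checked-in tests (chosen to exercise the
contracts at analytic ground truth): gate contract on a 20-dimensional
stretched box with axis conditioning 100; uniformity oracles on the cube
(d = 6) and simplex (d = 5) for all five walks at min ESS ≥ 500;
cross-method consistency on the cube (d = 6) and a stretched box (d = 10).

## Degenerate inputs and numerical choices

* Infinite bounds are clamped to ±1000 (COBRA convention, configurable);
  the polytope is therefore always bounded.
* Infeasible models fail at the first LP with the solver message as
  certificate; models with every flux fixed fail as not-full-dimensional.
* γ = 1 optimality restriction is rejected (the optimal face is lower-
  dimensional); use γ < 1 or rebuild the polytope on the face.
* Constant series are rejected by ESS/PSRF (exact-range check, not a
  floating-point variance threshold, so a constant stored with round-off
  is still detected).
* The billiard reflection loop treats the facet currently being left as
  non-blocking (its slack is clamped at 0 and the reflected direction
  points inward), so corner chatter is bounded by the reflection budget.

## Known limitations

* Single-threaded by design; reproducibility is guaranteed for a given
  seed regardless of machine.
* Rounding is sampling-based whitening; a maximum-volume-ellipsoid variant
  is a possible extension point but not implemented.
* No non-uniform targets (e.g. Gaussian-restricted sampling), no loopless
  FVA, no gene–protein–reaction logic, no `.mat` writing.
* ESS/PSRF are univariate per coordinate; no multivariate ESS.
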