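# Methods

## Model

The global (MNR) model writes the response at spatial unit *i* as a sum of
per-predictor components plus iid Normal(0, σ²) error:

- spline-role predictor *x_p*: a degree-*M* truncated power spline,
  `Σ_{j=1}^{M} β_{pj} x_p^j + Σ_{r=1}^{R} β_{p,M+r} (x_p − t_{pr})₊^M`.
  The truncated power `(x − t)₊^M` is zero below the knot and `(x − t)^M`
  above it, continuous with M−1 continuous derivatives at *t*, so the fit
  can change slope (or curvature) at each knot.
- fourier-role predictor *z_q*: a linear term plus cosine harmonics,
  `½θ_{q0} + γ_q z_q + Σ_{h=1}^{H} θ_{qh} cos(h z_q)`, the standard
  cosine-series estimator for components with an oscillating pattern.
  The free constant is carried by an explicit all-½ design column.

The geographically weighted (GWNR) model keeps the same basis but lets the
full coefficient vector vary by location, estimated at each *(uᵢ, vᵢ)* by
weighted least squares with kernel weights decaying in distance. Both
models share the n × m design Q\*, m = 2 + P(M+R) + Q(1+H).

### Structural aliasing of the two constant columns

Q\* contains an all-ones intercept column (spline side) and an all-½
constant column (Fourier side). These are exactly collinear, so
rank(Q\*) = m − 1 *by construction* and only the combination β₀ + ½θ₀ is
identifiable; the literal inverse in the weighted least-squares formula
does not exist. This package resolves the aliasing explicitly rather than
reparameterizing the model away from its published form:

- Hat matrices are projections onto the column span, which is unaffected
  by the aliasing: L = Q\*(Q\*ᵀQ\*)⁺Q\*ᵀ is the unique orthogonal projector,
  and each row of G is `qᵢᵀ(Q*ᵀWᵢQ*)⁺Q*ᵀWᵢ` with the Moore–Penrose
  pseudo-inverse, likewise unique. SSEs, traces and the F test are
  therefore well defined.
- Reported coefficient vectors are the minimum-norm solutions, which
  splits the aliased pair deterministically (the ½-column coefficient is
  half the intercept coefficient). The synthetic generator stores its true
  coefficients in the same minimum-norm representative, so noiseless
  recovery is exact.
- Any rank loss *beyond* this single structural aliasing (duplicated
  predictors, a knot outside the data range producing a zero column, a
  bandwidth so small a local fit sees too few points) is a hard error
  naming the dependent columns or the failing location — never a silent
  pseudo-inverse. Rank decisions use an SVD cutoff at a relative
  tolerance of 1e-10.

Consequently tr(L) = m − 1, and "residual degrees of freedom" below always
means n minus the number of identifiable parameters.

## The goodness-of-fit test

With A = (I−G)ᵀ(I−G) and B = (I−L) − A,

```
F₁* = (yᵀBy / τ₁) / (yᵀAy / γ₁),   γᵢ = tr(Aⁱ), τᵢ = tr(Bⁱ),
df₁ = τ₁²/τ₂,  df₂ = γ₁²/γ₂.
```

Since L is a symmetric projection, yᵀBy = SSE_MNR − SSE_GWNR; the
implementation computes both routes and verifies their agreement at run
time instead of assuming it. γ₁ = n − 2tr(G) + tr(GᵀG) (the trace of the
symmetric product; the sign of the tr(GᵀG) term follows from expanding
tr((I−G)ᵀ(I−G)) directly). The error-variance estimate is σ̂² = SSE/γ₁,
which is unbiased because E(SSE) = σ²γ₁ under the model assumptions.

The reference distribution comes from Satterthwaite moment matching: a
quadratic form εᵀAε in iid standard normals has mean tr(A) and variance
2tr(A²); matching both moments of c·χ²_r gives c = γ₂/γ₁ and r = γ₁²/γ₂
(exact when A is idempotent — the uniform-weight limit, where G = L,
γ₁ = n − (m−1) and (c, r) = (1, n − (m−1))). Degrees of freedom are used
as continuous (non-integer) values throughout; a p-value is reported
alongside the critical-value decision.

Degenerate situations are explicit errors, not NaNs: τ₁ ≤ 0 (the local fit
does not dominate the global one — e.g. uniform weights leave nothing to
test) and SSE_GWNR = 0 (saturated fit) both raise with remediation hints.

### Known limitation: the test is conservative

F₁* treats the numerator and denominator chi-square approximations as
independent, but both are quadratic forms in the *same* error vector and
are positively correlated (correlation `2tr(BA)/√(4tr(B²)tr(A²))`,
typically 0.3–0.45 at the default study conditions). The ratio is
therefore under-dispersed relative to an F distribution, and the actual
type-I error at nominal α = 0.05 sits near 0.01–0.02 across every kernel
and bandwidth we examined (verified both by Monte Carlo over full refits
and by direct simulation of the two quadratic forms at fixed L, G). The
diagnostic `sse_chi2_approx_check` shows the *marginal* scaled-chi-square
approximation of SSE is excellent (KS distance ≈ 0.01), so the
conservatism comes from the ignored dependence, not from Satterthwaite
matching itself. Users should read a rejection as strong evidence of
spatial heterogeneity, and a non-rejection as weaker evidence of
homogeneity than the nominal level suggests. Power against smoothly
varying coefficient surfaces is nonetheless high (essentially 1 at
amplitude 2, n = 60 in the default scenario).

## Spatial weights

- Kernels: gaussian `exp(−½(d/b)²)` (default), bisquare and tricube
  (compact support; weights vanish at d ≥ b). Gaussian is the default
  because it cannot produce all-zero weight rows at small n.
- Bandwidth: fixed distance, or adaptive (b resolved per location as the
  distance of the k-th nearest neighbour). When no bandwidth is known,
  `select_bandwidth` minimizes the leave-one-out CV score Σᵢ(yᵢ − ŷ₍₋ᵢ₎)²
  with wᵢᵢ forced to 0, breaking ties toward the larger (smoother)
  bandwidth.
- Distances: euclidean (default) on planar coordinates, or haversine
  great-circle km (Earth radius 6371 km) for lon/lat input. Euclidean
  weights are invariant under translation and rotation of the coordinate
  frame.

## Synthetic data generator

The generator emulates the kind of data the method targets: n spatial
units (default 60) on the unit square (near-regular grid or uniform
random), two spline-role predictors drawn uniform on [0, 3] with degree 1
and one interior quantile knot each, and two periodic-role predictors
drawn uniform on [0, 2π] with one cosine harmonic each — a 10-column
design matching the structure used in the method's applications. The mean
is built from the same basis, errors are iid Normal(0, σ²) with σ = 1 by
default, and everything is reproducible from one integer seed
(replicate seeds in the Monte-Carlo harness are counter-based, so
replicates are order-independent).

Under H₁ each coefficient drifts as a fixed linear-plus-interaction
surface in the centred coordinates, scaled by `surface_amplitude` — the
simplest smooth nonstationarity. Amplitude 2 roughly doubles-to-triples
the coefficient spread across the unit square relative to the O(1) base
coefficients.

What the generator does *not* emulate: spatially correlated errors
(excluded by the model's independence assumption), non-Gaussian errors,
irregular real-world geography (islands, road distances), measurement
error in predictors, and model misspecification (the fitted basis family
always contains the truth). Passing tests therefore demonstrate internal
correctness and the statistical properties of the procedure *under its own
assumptions*, not robustness on real survey data.

## Numerical choices

- Default study conditions: n = 60 units, gaussian kernel with fixed
  bandwidth 0.5 on the unit square (weights ≈ 0.02 at the far corner —
  genuinely local but never degenerate), α = 0.05, 500 Monte-Carlo
  replicates for operating-characteristic checks. These sizes keep the
  full test suite and the acceptance script in the tens of seconds on one
  CPU while leaving binomial standard errors near 0.01.
- Quantile knot rule: R knots at levels 1/(R+1), …, R/(R+1) of each spline
  predictor's empirical distribution; explicit knots override. A knot
  outside the open data range is allowed but warned about.
- Fourier predictors are used in raw radians by default; an optional
  `rescale_fourier` flag maps them affinely onto [0, 2π] first.
- Hat matrices are materialized densely; the implementation targets
  n up to a few thousand, not raster-scale problems.
- Machine-readable reports fix floats to 10 significant digits, making
  identical runs byte-identical; the per-location coefficient CSV is
  written at full precision (%.17g) and read back with round-trip float
  parsing, so serialization is lossless.
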