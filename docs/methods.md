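# Methods

## Model and conventions

The data matrix `X` is n samples × p features and is column-mean-centered
before any fit (`center_columns`; re-applied after subsampling, which breaks
centering). A fitted component is a rank-one triplet `(d, u, v)` with unit
`u ∈ ℝⁿ` (scores) and unit `v ∈ ℝᵖ` (loadings), `d = uᵀXv`. Some
presentations of the alternating algorithm write the score/loading roles
with transposed symbols; this package fixes one convention throughout:
thresholding always acts on the p-vector of regression coefficients
`z = Xᵀu`, and the score update is the normalized projection `Xv`.

Singular vectors are defined only up to sign; every fitting routine forces
the largest-magnitude loading positive (ties broken by lowest index), which
makes all outputs — including benchmark tables — bit-reproducible.

Subsequent components are obtained by deflation: the *sparse* rank-one
approximation itself is subtracted from the current matrix. Because the
sparse `v` is not an exact singular vector, later components are only
approximately orthogonal to earlier ones; this is inherent to the
procedure and deliberately not "corrected". The residual is not re-centered
before the next fit: deflation preserves the column means of a centered
matrix up to numerical noise, since `u` is a normalized combination of
centered columns.

## Thresholding operators

With `z = Xᵀu` and penalty strength λ ≥ 0:

* lasso: `sign(z)(|z| − λ)₊`;
* adaptive lasso: `sign(z)(|z| − ŵλ)₊`, `ŵ = 1/|z|^γ` (γ = 1 default,
  meaningful range (0, 2]); a coefficient with `z = 0` is set to zero
  without evaluating the infinite weight. Weights are recomputed from the
  current `z` at every alternating step by default (the operator is then
  stateless); `alasso_weights="initial"` freezes them at the warm-start
  coefficients instead.
* SCAD (a = 3.7): the thresholding rule induced by the SCAD penalty — a
  quadratic spline with knots at λ and aλ. The rule is soft-thresholding
  for `|z| ≤ 2λ`, `((a−1)z − sign(z)aλ)/(a−2)` for `2λ < |z| ≤ aλ`, and the
  identity beyond `aλ` (large coefficients are unbiased). It is continuous
  in `z` and is verified in the tests against a brute-force minimizer of
  `½(z−θ)² + SCAD(θ)`. Beware that a frequently reprinted variant of the
  middle branch with boundary at λ instead of 2λ is discontinuous and does
  not minimize the objective.
* randomized lasso: `sign(z)(|z| − λwᵢ)₊` with `wᵢ ~ U(κ, 1)`; weakness
  κ = 0.2 by default. Each coefficient's effective penalty is in
  `[κλ, λ]` — equivalently a random penalty in `[λ, λ/κ]` for the
  unweighted parameterization. One weight vector is drawn per
  stability-selection subsample, not per alternating step.

All operators reduce to the identity at λ = 0, shrink toward zero without
crossing it, and are monotone in `z` (property-tested).

## Alternating algorithm and penalty selection (RSPCA)

`fit_rank_one_penalized` warm-starts at the leading unpenalized score
vector and alternates thresholded loadings updates with score projections
until the loadings change by less than `tol = 1e-6` in max-norm (after
sign alignment) or 200 iterations. If thresholding zeroes every
coefficient, the *empty fit* (d = 0, v = 0, flagged) is returned.

The penalty grid is geometric, 50 points spanning
`[10⁻³·λ_max, λ_max]` with `λ_max = max|Xᵀu₀|` (which empties the model on
the first pass). Every grid point is fitted in full and scored by GIC
(default) or BIC; empty fits compete as df = 0 models. Ties in the
criterion resolve toward the larger λ, i.e. the sparser model. The error
variance `σ̂² = ||X − d₁u₁v₁ᵀ||²_F/(np)` comes from the unpenalized
rank-one (OLS) model of the matrix currently being fitted — re-estimated
after deflation for later components. An exactly rank-one input would give
`σ̂² = 0`; the criteria then use a machine-epsilon-scaled floor (with a
warning) instead of dividing by zero.

## Stability selection (S4VDPCA)

Per subsample (B = 500; pilot scans use B_pilot = 100): draw
`⌊n/2⌋` rows without replacement, re-center, draw one randomized-lasso
weight vector, and run the full alternating algorithm at the fixed λ.
The subsample fraction 0.5 is the customary stability-selection choice
and is configurable.

The single λ for probability estimation is chosen by *point-wise control*:
20 candidates, geometric over the upper half (in log scale) of the full
grid range, i.e. `[10⁻¹·⁵·λ_max, λ_max]` — large penalties keep the
per-subsample fits sparse and cheap. For each candidate the pilot
probabilities are computed and the number of *ties* counted, defined as
`p − (#distinct probability values)`; this definition is monotone in the
number of coincident values and is maximal for degenerate all-zero or
all-one profiles. The candidate with the fewest ties wins (ties between
candidates resolve to the larger λ), and its profile is re-estimated at
the full B.

Forward selection then ranks features by probability (ties broken by the
full-data unpenalized coefficient magnitude `|Xᵀu₁|`, then by index — the
magnitude tie-break prevents index-order artifacts at small B), evaluates
the GIC of the plain SVD restricted to each prefix of the ranking, and
returns the minimizing prefix (ties toward the smaller model). The number
of prefixes evaluated is capped at the number of positive-probability
features and a configurable budget of 5000 criterion evaluations.

RNG contract: a single `numpy.random.Generator` drives the whole analysis;
each subsample consumes first its row indices, then its weight vector, in
a fixed order over candidates, so a master seed reproduces everything.

## Simulator

`Σ = (d−1)vvᵀ + I` with `d = p^α` and `⌊p^β⌋` equal nonzero loadings
`1/√⌊p^β⌋` (the square root is required for `||v|| = 1`; equal-value
loadings without it would not be a unit vector). Sampling uses the
structured identity `X = E + √(d−1)·z vᵀ` (E standard normal n×p, z
standard normal n-vector), which has covariance exactly Σ without forming
the p×p matrix; rows are then column-centered, since the estimators assume
centered data and the population mean is zero. The support occupies the
first `⌊p^β⌋` indices by default — the estimators are
permutation-equivariant (verified by a permutation test) — with seeded
random placement available.

Benchmark grids derive one child seed per (α-index, β-index, replicate)
via `SeedSequence(master, spawn_key=...)`, so methods are compared on
identical matrices (paired) and grids are reproducible under any execution
order. A failing method in one replicate records missing values rather
than aborting the grid.

What the simulator does *not* emulate: correlated noise between features,
heavy tails or skewness, multiple interacting spikes, batch structure.
Passing benchmarks therefore demonstrate behaviour under an isotropic
single-spike Gaussian, not under arbitrary real molecular data.

## Evaluation

Angle `arccos |⟨v̂, v⟩|` in degrees (sign-invariant, clamped before
arccos); FDR `|supp̂ \ supp|/|supp̂|` (0 for an empty estimate); TPR
`|supp̂ ∩ supp|/|supp|`. Empty fits score angle 90°, FDR 0, TPR 0, so
medians stay defined in weak-signal corners where sparse fits collapse.
Medians use the midpoint convention for even counts. The consistency
classifier (below 10° / 10–45° / above 45° at the largest scale) is an
explicitly finite-sample proxy for the asymptotic taxonomy
(angle → 0 / limit in (0°, 90°) / limit 90°), which is not observable at
any finite p.

## Problem sizes

Operator and algebra tests run at toy sizes. The quantitative benchmark
checks run at full feature dimension p = 1000, n = 50 with 25–50
replicates per cell; the S4VDPCA recovery and method-comparison checks run
at p = 300, n = 50 with 10–20 replicates — sizes at which the medians are
stable for the strong contrasts being asserted, while a full test run
stays in the minutes range on one CPU.

## Known limitations

* Multi-component fits are only approximately orthogonal (deflation of a
  sparse fit); no orthogonality-enforced multi-PC variant is provided.
* No cross-validated penalty selection; the criteria assume the rank-one
  residual is a reasonable noise estimate.
* The alternating algorithm is nonconvex; the criterion path in λ is
  monotone in practice with an SVD warm start but is not guaranteed to be.
* No error-rate control via the stability-selection bound; the method uses
  ranking plus GIC, and the full stability path is intentionally not
  computed.
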