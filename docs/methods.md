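# Methods

## Model and simulation

The synthetic data generator is a reduced Wong–Wang mean-field model of
N coupled neural populations.  Each population carries a synaptic gating
variable S ∈ [0, 1] with dynamics

    dS/dt = −S/τ_s + γ (1 − S) ⊙ R(x) + σ η(t),
    R(x)  = (a x − b) / (1 − exp(−d (a x − b))),
    x     = w J_N S + G J_N C S + I_0,

where R is the population firing rate (Hz), x the total synaptic input
(nA), C the structural connectivity, and η independent white noise per
population with common amplitude σ.  Defaults (τ_s = 0.1 s, γ = 0.641,
a = 270 /nC, b = 108 Hz, d = 0.154 s) are the standard values for this
model family.  Two two-population presets are built in:

| preset | w | J_N (nA) | G | I_0 (nA) | stable fixed points |
|---|---|---|---|---|---|
| `two_attractor` | 0.90 | 0.2609 | 0.32 | 0.30 | 2 |
| `four_attractor` | 1.07 | 0.29 | 0.03 | 0.30 | 4 |

both with C = [[0,1],[1,0]].  An N-population preset (w = 0.95,
J_N = 0.2609 nA, I_0 = 0.32 nA, G free) runs on any user-supplied
connectome or on the package's surrogate generator (random symmetric
nonnegative matrix, zero diagonal, O(1) row sums).  The surrogate is a
stand-in for empirical structural connectivity: it reproduces scale and
symmetry but none of the topology of a measured connectome, so
high-dimensional results here are qualitative only.

Integration uses the stochastic Heun predictor–corrector with a shared
Wiener increment per step (for additive noise the Itô and Stratonovich
readings coincide), a 0.1 ms step (τ_s/1000), and output downsampled to
2 ms (two populations) or 5 ms (networks).  Two-population runs last
120 s with no burn-in; network presets drop the first 10 s.  The
transfer function is evaluated through `expm1` with a first-order series
below |d(ax−b)| < 1e-8, which makes it smooth through the removable
singularity at a·x = b.  States are not clipped to [0, 1]; a guard
aborts integration (naming the step) if any |S| exceeds 10.  The initial
state defaults to uniform random in [0, 1]^N from the run seed; a run is
bit-reproducible given its seed.

Noise enters the gating equation directly as σ·dW with σ treated as a
unitless amplitude in the range 0.3–1; at the top of that range the
gating nonlinearity visibly compresses fluctuations relative to the
linearized theory (relevant to the error-law comparison below).

## Attractor landscape

Stable fixed points are found by integrating the noiseless field from
Latin-hypercube starts in [0, 1]^N until max|dS/dt| < 1e-6 s⁻¹ (the
convergence reading of "derivative two orders of magnitude below the
integration step" with dt = 1e-4; the unit comparison is ambiguous, so
the threshold is a documented choice), then refining each candidate by a
damped Newton solve with a central-difference Jacobian to
max|drift| < 1e-8.  Roots closer than 1e-4 (Euclidean) merge; unstable
roots reached by Newton are kept but flagged and excluded from all
labeling.  Stability and eigenvalues come from the exact analytic
Jacobian (chain rule through the transfer function, with the a/2 limit
slope at the singularity), which the tests check against central
differences.

Ground-truth regime labels: each sample is assigned to the nearest
stable fixed point (Euclidean), each analysis window to the attractor
closest on average over its samples; ties resolve to the lowest index.
The mean inter-transition interval is (span between first and last label
change)/(changes − 1); no debouncing or minimum-dwell rule is applied,
so at low noise the statistic is dominated by rare crossing events and
is heavy-tailed across seeds — the acceptance machinery therefore pools
the spans and counts over many seeds (25 in the reproduction script)
rather than averaging per-seed ratios, which would be dominated by runs
containing a single flickery crossing or none at all.  Because basin
escapes are Kramers-like, the interval at the lowest noise is
exponentially sensitive to the effective noise amplitude and to the
counting rule: counting every label flip versus merged crossing events
changes the answer by more than an order of magnitude at σ = 0.3.

## Time-varying autoregression with a low-rank tensor (TVART)

The trajectory is cut into T disjoint windows of M samples.  Window k is
an affine autoregression at prediction delay Δt samples,
x(t+Δt) ≈ A_k x(t) + b_k, with predictors in [kM, (k+1)M) and responses
shifted by Δt (the trailing remainder is dropped).  Offsets are
implemented by appending a constant-1 row to the predictors, so the
stack of [A_k | b_k] matrices is one third-order tensor constrained to a
rank-R canonical polyadic decomposition [A_k|b_k] = U1 diag(u3_k) U2ᵀ
with spatial modes U1 (N×R), U2 ((N+1)×R) and temporal modes U3 (T×R).
The cost is

    C = ½ Σ_k ‖Y_k − A_k X_k‖²_F
        + 1/(2η) (‖U1‖²_F + ‖U2‖²_F + ‖U3‖²_F) + β Rg(U3),

so smaller η or larger β regularizes harder.  Rg is either the spline
penalty (squared 2-norm of second differences of U3 rows; linear trends
free, favoring smooth temporal variation) or total variation (1-norm of
first differences, favoring piecewise-constant modes).

Optimization is exact block-coordinate descent: the U1 update is a ridge
solve against Z_k = D_k U2ᵀ X_k; the U2 update couples left and right
Grams per window and is solved as one (N+1)R system; the U3 update
solves the sparse block-tridiagonal system formed by per-window Grams
plus the temporal penalty.  Total variation is handled by one
iteratively-reweighted majorizer step per sweep on the ε-smoothed 1-norm
(ε = 1e-6); the cost reported for TV is the smoothed value, so every
sweep is still non-increasing.  Everything the solver needs reduces to
per-window Gram matrices, so the cost of a sweep is independent of M
after windowing.

Factors initialize i.i.d. Normal(0, 1/R) from the config seed.  After
each sweep, U1 and U2 columns are rebalanced to equal norms — the exact
minimizer of the Tikhonov term over that rescaling, hence monotone —
while U3 is left untouched so the temporal penalty is unaffected; the
returned factors apply the conventional unit-norm-spatial-modes scaling
(magnitudes absorbed into U3) once, for clustering.  Iteration stops
when the relative cost decrease falls below 1e-6 (default cap 60
sweeps); hitting the cap returns the fit with `converged=False`.

Prediction error is reported per dimension: mse = SSE/(T·M·N), directly
comparable to the per-eigenvalue analytic law; R² uses the total sum of
squares about the per-dimension global response mean.  "Full rank" means
R = N+1, the unconstrained affine model.

Defaults follow the study conditions: M = 100, spline, η = β = 0.5 for
two-population data; η = 10, β = 0.1 (spline) or η = 90, β = 1 (TV) for
networks.

## Regime identification

Rows of U3 are clustered with a full-covariance Gaussian mixture (10
restarts, 500 iterations, covariance floor 1e-6 — unstated upstream,
declared here), giving labels, per-window maximum posterior
probabilities and total log-likelihood; ΔL_n is the likelihood gain of
an n-component mixture over a single Gaussian.  Cluster labels are
matched to attractor indices by the best permutation (brute force for
k ≤ 6, Hungarian assignment above) and accuracy is the percent of
windows agreeing after relabeling; windows, not samples, are the
classification unit.  Chance levels come from 1000 uniform label
shuffles (median, 5th/95th percentiles); note that best-permutation
matching inflates the nominal 1/k level by a few points (a maximum over
permutations of binomial fluctuations).  High-dimensional fits use
agglomerative clustering (Manhattan distance, average linkage —
configurable; only the metric is prescribed upstream) and report cluster
counts per dendrogram cutoff.  Davies–Bouldin (centroid form) and Dunn
(min inter-point separation / max intra-cluster diameter, infinite when
all clusters are degenerate) summarize cluster quality.

### What the delay experiment does and does not show

With this exact solver, the temporal modes of two-population fits carry
the attractor *position* (through the offset channel b_k ≈
(I − e^{JΔt})·S*) at every delay: per-window ridge estimation resolves
that channel above its noise floor already at a 1-sample delay, so
classification accuracy for the two-attractor preset is high (~96–97%)
at short *and* long delays, and the benefit of a longer horizon shows
mainly in the four-attractor preset (~70% at 1 step vs ~89% at 31
steps).  Published figures for the same conditions report a much
stronger short-delay degradation (≈60% at 1 step); that behavior could
not be reproduced with any exact alternating-least-squares variant we
tried (initialization, penalty form and scale, centering, rank), and
depends on solver details of the original implementation that its
description does not pin down.  The acceptance suite states both
expectations and reports our measured values; the discrepancy is
confined to the short-delay points.

## Error-scaling law

Linearizing at a stable fixed point gives a multivariate
Ornstein–Uhlenbeck process whose conditional covariance over a horizon
dt is σ²∫₀^dt e^{Js}e^{Jᵀs}ds — computed in closed form through the
unitary eigendecomposition when J is normal and by adaptive `quad_vec`
quadrature with matrix exponentials otherwise.  Its trace gives

    MSE(dt) = −(σ²/2) Σ_i (1/λ_i) (1 − exp(2 λ_i dt)),

with the single-rate per-dimension form −σ²/(2λ̄)(1 − e^{2λ̄dt}).
Eigenvalues pool over stable fixed points only, using real parts (a
declared choice; a flag admits unstable points).  Delay sweeps fit one
full-rank TVART model per delay over {1, 6, 11, 16, 21, 26, 31} samples
and record per-dimension MSE; the error law (or an ordinary linear
trend, whichever has higher R²) is fitted by bounded nonlinear least
squares with c > 0, λ < 0.

Two caveats the tests account for.  First, at the shortest horizon the
measured error sits above the analytic curve because ridge shrinkage of
A_k contributes an estimation bias comparable to the (vanishing)
stochastic term; band comparisons against the λ_min/λ_max curves are
therefore made on a logarithmic scale (factor-2 band) at horizons of
≥ 6 samples.  Second, when windows are not much longer than the
correlation time 1/|λ|, the in-sample per-window offsets absorb part of
the slow state fluctuation and pull the measured error *below* the
Markov conditional-variance curve at long horizons; the rate-recovery
test on a pure linear OU system uses 2 s windows (≫ 1/|λ|) for this
reason.  At σ near 1 the gating nonlinearity additionally compresses
fluctuations below the linearized prediction.

## Pipeline and reproducibility

`ExperimentConfig` resolves a preset plus overrides into concrete model,
simulation and TVART parameters; YAML configs are validated strictly
(unknown keys rejected, offending keys listed).  `run_experiment` chains
simulate → fixed points → TVART → clustering (plus an optional delay
sweep), writes CSV/JSON artifacts with a MANIFEST, and derives every
stage seed from the master seed by hashing the stage name, so reruns are
byte-identical and stages can be reproduced independently.  There is no
command-line entry point: the package is a library, and the `examples/`
scripts are the runnable surface.

## Problem sizes

Tests and the acceptance script use the study's two-population
conditions unchanged (120 s, 0.1 ms step, 2 ms sampling, M = 100,
delays up to 31 samples).  Headline quantities average 3 seeds
(classification) or pool 5 seeds (hopping intervals); the
hyperparameter study uses a 5×5 log-spaced η×β grid with 2 repeats per
cell; network-scale checks run N = 12 surrogate connectomes for 120 s at
5 ms sampling.  These sizes are the package's defaults for its own
verification and scale linearly if enlarged.

## Known limitations

- No hemodynamic forward model, no fitting of G to empirical functional
  connectivity, no bifurcation tracking, and no basin-volume estimation.
- Single-lag autoregression only; no missing data, no streaming.
- The TV subproblem is solved by smoothed IRLS, an approximation to the
  exact proximal step (documented ε = 1e-6).
- Published numbers that depend on the measured human connectome (its
  equilibrium counts and eigenvalue scales) are out of reach by
  construction; the surrogate reproduces trends, not values.
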