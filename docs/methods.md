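# Methods

This note records the models, estimators, numerical conventions and
design choices behind `edmchaos`, and what the synthetic-data tests do
and do not establish about real data.

## Problem setting

The package analyzes sets of replicated multi-species abundance time
series — the canonical case is a two-species predator–prey microcosm
run many times with identical conditions but different initial
abundances. The question it answers is *why* forecasts of such dynamics
fail: because of process noise (stochasticity), because the dynamics
are state-dependent in a way no single linear model captures
(nonlinearity), or because nearby trajectories diverge exponentially
(chaos). Replication across initial conditions is what makes the
question answerable: cross-predicting between replicates probes whether
the same dynamical rule governs different regions of phase space.

## Regularization

Delay embeddings require a constant sampling step, so irregular series
are interpolated with a cubic spline (`scipy.interpolate.CubicSpline`)
onto a grid anchored at the first observation; the last grid point never
passes the last observation (no extrapolation). Boundary condition is
not-a-knot, chosen over natural (zero end curvature) because not-a-knot
reproduces smooth trends exactly — in particular any cubic — while a
natural spline visibly flattens the ends of short series. Interpolated
abundances are clipped at zero from below; abundances cannot be
negative, and re-fitting under a positivity constraint would distort the
interpolant elsewhere for no practical gain. The spline is fit on the
raw scale (not log), matching the intent of treating the series as
abundances; a log-scale option was considered and rejected because zero
abundances (extinctions) are legitimate data here. Time is carried in
days throughout.

## Embedding and forecasters

Two embedding modes are exposed because both are used in practice and
are equivalent in theory (Takens):

* **univariate** — delay coordinates `(x(t), x(t−τ), …, x(t−(E−1)τ))`
  of one species, with τ = 1 grid step by default;
* **multivariate (block)** — the simultaneous abundances of all species
  as coordinates, so E equals the species count (2 for a predator–prey
  pair). E-selection is skipped in this mode since the dimension is
  fixed by the data.

**Simplex projection.** For each query the E + 1 nearest library states
(Euclidean distance) vote on the future of the target species with
weights `w_i = exp(−d_i/d_1)`. If the nearest distance is exactly zero,
all zero-distance neighbors get unit weight and the rest zero — the
limit of the weight formula. Distance ties are broken by library order
(stable sort), so results are deterministic.

**S-map.** For each query, all library states are weighted
`w_i = exp(−θ·d_i/d̄)` with d̄ the mean distance from the query to the
whole library (the classic convention, not mean-to-neighbors), and the
target is regressed on the state coordinates plus an intercept by
weighted least squares. The solve is `numpy.linalg.lstsq` with relative
singular-value cutoff 1e−10: rank-deficient neighborhoods get the
minimum-norm pseudo-inverse solution rather than an exception; only a
library whose states are all identical is rejected outright. At θ = 0
every weight is 1 and the S-map is exactly one global OLS model — this
identity (asserted to 1e−10 in tests) is what makes the θ = 0 fit a
meaningful "total variation" reference for the partition below.

**Cross-validation and selection.** Self-prediction always uses
leave-one-out: library rows sharing the query's time stamp are excluded.
No wider Theiler window is applied; for the short, noisy series this
package targets, temporal autocorrelation at lag ≥ 1 step is part of
the dynamics being modeled. E is chosen to minimize leave-one-out
simplex MAE over a default grid 1–8; θ minimizes leave-one-out S-map
MAE over a default grid {0, 1e−4, …, 8} (18 values). Exact ties go to
the smaller parameter, so linear data select θ = 0. Series are not
normalized before embedding; with a single target species the distance
metric is scale-consistent, but multivariate embeddings mix species
units, and users with wildly different scales should rescale first.

**Multi-step forecasts are direct, not iterated**: each horizon tp is a
separate projection/regression onto the target shifted by tp. Direct
forecasts measure how predictability decays with horizon without
compounding one-step model error, which is exactly what the Lyapunov
regression needs.

## Cross-replicate prediction

`cross_predict(source, target)` embeds both series identically
(default E = 2 block mode for a two-species system), selects θ by
leave-one-out on the *source* (train-on-source semantics; the fitted
hyperparameter travels with the trained model), then forecasts the
target's states at horizons 1–10. With multiple species the error pairs
are pooled per horizon. Horizons for which a series is too short are
recorded as skipped, never silently dropped. Both orderings of each
pair are retained. The initial-abundance distance
ΔN0 = ‖N0_A − N0_B‖₂ is attached to every record; it is a true metric
on initial-state space (property-tested).

## Lyapunov estimation

Two estimators, one validation oracle:

1. **Regression over horizons**: λ is the OLS slope of log(MAE) against
   tp (1–10 by default), with the standard two-sided p-value for the
   slope (`scipy.stats.linregress`). Zero-MAE horizons are dropped with
   a warning. A perfectly flat profile returns λ = 0, p = 1.
2. **Stepwise rate**: λest = log(RMSE(tp+1)/RMSE(tp)) per adjacent
   pair, averaged when more than two horizons are supplied. The sign
   convention is growth ⇒ positive; the partition uses tp = 1 vs 2 by
   default (configurable to 1…5) because later horizons saturate at the
   attractor size and bias λest toward zero.
3. **Two-trajectory oracle** (synthetic maps only): iterate twin
   trajectories separated by δ0 = 1e−8 for 15 steps from 1000 settled
   starting points and average `log(|Δ|/δ0)/T`. Fifteen steps keeps the
   separation far below attractor size even at growth log 2 per step
   (1e−8·2¹⁵ ≈ 3e−4). The oracle reproduces the analytic exponent
   log 2 of the quadratic logistic map at r = 4 within 0.05 and
   anchors the error-growth estimators in tests.

p-values are reported raw; the upstream practice of filtering pairwise
λ at p < .05 is supported downstream, and Benjamini–Hochberg adjustment
is deliberately not applied by default (available to users via
`scipy.stats.false_discovery_control` on the reported column).

## Error partition

With `mse_total` the leave-one-out MSE of the θ = 0 fit at horizon 1,
`mse_best` the same at the selected θ, and λest as above:

* nonlinearity (raw) = `mse_total − mse_best`, floored at 0 (flagged if
  a finite sample puts the best θ above θ = 0);
* chaos (raw) = `mse_best · (1 − e^{−2·λest})` if λest > 0, else 0.
  The factor follows from writing the non-chaotic error as
  RMSE₀ = RMSE_bestθ·e^{−λest} and subtracting its square:
  MSE_chaos = MSE_bestθ − RMSE₀². A single-exponent variant
  (1 − e^{−λest}) is exposed as `chaos_formula='printed'` for
  comparison with analyses that used it; it is not the default because
  it is not algebraically consistent with the RMSE₀ definition, and it
  sets the chaos-dominance threshold at λest > log 2 — above the true
  exponent (≈ 0.385, by the oracle) of the canonical chaotic Ricker map
  at r = 3, which would misplace a textbook chaotic system as
  noise-dominated;
* stochasticity (raw) = the remainder.

All three are divided by `mse_total`; fractions are clamped to [0, 1]
and renormalized (with a flag) only if finite-sample noise pushed a
term outside. The invariants — fractions in [0, 1], sum 1 within 1e−9,
chaos exactly 0 when λest < 0, chaos nondecreasing in λest — are
property-tested on every run.

**Known limitation.** Any stochastic process has growing multi-step
forecast error (`RMSE(2)/RMSE(1) = √(1 + c·ρ²) > 1` for an AR process
with persistence ρ, independent of the noise scale), so λest > 0 and a
nonzero chaos share appear even for linear noise-driven dynamics
(≈ 0.15–0.4 depending on persistence, in our fixtures). The partition
separates regimes *relatively* — deterministic chaos yields
chaos > stochasticity, noise-dominated dynamics yield a large
stochasticity share — but the chaos fraction is not an unbiased zero
for non-chaotic stochastic systems. Conclusions should rest on
comparisons across systems or conditions, not on a small chaos fraction
in isolation.

The rule-of-thumb fit classification (`good` iff MAE < sd(observed)/2,
strict at the boundary) and the standardized MAE are provided for
summary plots.

## Grouping

Replicates are assigned to two groups by a straight line in
initial-abundance space supplied by the analyst
(`N0·normal < offset` → group 1, else group 2; the ≥ side includes the
boundary). Automatic discovery of dynamical regimes is out of scope:
a declarative boundary keeps the grouping reproducible. Group
comparisons cover (a) mean ± SE trajectories of the off-diagonal S-map
coefficients (effect of predator on prey and vice versa), trimmed to
time steps present for every group member, and (b) mean cross-
prediction MAE within each group versus between groups, self-pairs
excluded.

## Synthetic data

The generators define the study conditions the tests run under:

* **Ricker map** `x' = x·exp(r(1−x))·exp(σζ)` — the default discrete
  growth model, chaotic for r ≳ 2.69; log-normal multiplicative noise
  keeps states positive. The quadratic logistic map
  `x' = rx(1−x) + σζ` (clipped to [0, 1], r ≤ 4) is kept as an option
  and for the analytic r = 4 oracle. Default series length 100 steps.
* **Replicated Lotka–Volterra** — Euler–Maruyama (internal dt = 0.01 d,
  output step 0.5 d, 20 d span) with shared parameters
  (a = 1, b = 0.5, c = 0.5, m = 0.5 per day; equilibrium (2, 2), cycle
  ≈ 9 d) and only N0 varying, on a deterministic low-discrepancy grid
  around the equilibrium — many distinct phase-space starting points,
  like a microcosm experiment with 19 replicates. Multiplicative
  process noise sd σ = 0.05 per unit time by default; trajectories are
  floored at 0 and extinct replicates are retained. A two-regime
  variant (doubled prey growth, halved predation in regime 2) provides
  ground-truth group labels.
* **VAR(1)** `x(t+1) = A·x(t) + ζ` (spectral radius < 1 enforced,
  100-step burn-in) — the linear benchmark for S-map coefficient
  recovery; an affine shift makes it a valid abundance container
  without changing coefficients.

All generators are byte-deterministic under a fixed seed
(`numpy.random.default_rng`), and σ = 0 yields exactly deterministic
trajectories. What the generators do **not** emulate: observation error
(off by default), irregular real-world sampling gaps, demographic
discreteness at low abundance, and the specific functional forms of any
real microcosm. Passing tests therefore demonstrate correctness of the
estimators under known dynamics, not that any particular real system is
chaotic.

## Problem sizes in tests

The test suite and the acceptance script size their simulations for a
single CPU: growth-map partitions use 100-step series and 20-replicate
medians; the Lyapunov regression check uses one 1000-step series; VAR
recovery averages 12 realizations of 500 steps; cross-prediction checks
use 4–6 replicates of 21–41 grid points with horizons 1–5. For the
deterministic (σ = 0) map conditions, replicate runs vary the initial
state rather than the (inert) noise seed. These sizes reproduce every
qualitative contrast stably across seeds; users analyzing real data are
not bound by them.
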