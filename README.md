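# edmchaos

**Attributing prediction error in replicated ecological time series to
stochasticity, nonlinearity, and chaos with empirical dynamic modeling.**

Population forecasts fail for different reasons: intrinsic randomness
(process noise), state-dependent dynamics that a single linear model
cannot capture (nonlinearity), and exponential sensitivity to initial
conditions (chaos). When an experiment provides *replicates that differ
only in their initial abundances* — the classic design of predator–prey
microcosms — these three causes leave distinguishable signatures in how
forecast error behaves across replicates and across prediction horizons.
`edmchaos` implements that analysis end to end for ecologists working
with replicated multi-species abundance series.

## What it computes

The core machinery is empirical dynamic modeling (EDM), which forecasts
from the reconstructed attractor instead of a parametric model:

- **Simplex projection** — the forecast for a query state is the
  weighted average of the futures of its E + 1 nearest neighbors in the
  delay-embedded state space, with weights `w_i = exp(−d_i/d_1)`.
  Leave-one-out skill over a grid of embedding dimensions selects E.
- **S-map** — a locally weighted linear regression over all library
  states with weights `w_i = exp(−θ·d_i/d̄)`. At θ = 0 this is one
  global linear (vector-autoregressive) model; skill improving for
  θ > 0 is the standard nonlinearity test. In a multivariate (block)
  embedding the regression coefficients are time-varying interaction
  coefficients (effect of predator on prey and vice versa).
- **Cross-prediction** — train the S-map on replicate A, forecast
  replicate B, for all ordered pairs, at horizons tp = 1…10, together
  with the initial-abundance distance ΔN0 = ‖N0_A − N0_B‖.
- **Lyapunov exponents from error growth** — treating the forecast as a
  twin trajectory started next to the observation, ε(t) ≈ ε0·e^{λt}, so
  λ is the OLS slope of log(MAE) against horizon (with a p-value for
  the slope).
- **Error partitioning** — with MSE_total the θ = 0 fit ("total
  variation") and MSE_bestθ the fit at the cross-validated θ:
  nonlinearity = MSE_total − MSE_bestθ; chaos =
  MSE_bestθ·(1 − e^{−2λest}) for λest > 0 (zero otherwise), where λest
  is the per-step growth rate of the best-θ RMSE across horizons; the
  remainder is stochasticity. Divided by MSE_total the three fractions
  sum to one.

A synthetic-data module generates the study designs this analysis
expects — replicated Lotka–Volterra predator–prey systems differing
only in N0, Ricker/logistic growth maps with tunable chaos (r) and
process noise (σ), VAR(1) linear benchmarks — plus a brute-force
two-trajectory Lyapunov oracle for validation.

## Worked example

```python
import numpy as np
from edmchaos import synthetic_data, partition_series

# a chaotic Ricker map, no process noise
s = synthetic_data.simulate_map("ricker", r=3.0, sigma=0.0, n_steps=150, seed=0)
p = partition_series(s)
print(f"E={p.E_used} theta={p.theta_best} lambda_est={p.lambda_est:.3f}")
print(f"nonlinearity={p.frac_nonlinearity:.3f} chaos={p.frac_chaos:.3f} "
      f"stochasticity={p.frac_stochasticity:.3f}")
```

prints

```
E=1 theta=8.0 lambda_est=0.429
nonlinearity=0.925 chaos=0.043 stochasticity=0.032
```

Read: a strongly localized S-map (θ = 8) beats the global linear model
by a wide margin (93% of the θ = 0 error is nonlinearity), the forecast
error grows exponentially across horizons (λest > 0, so this series is
flagged chaotic), and of the error that remains at the best θ, the
chaos share exceeds the noise share — as it must for a deterministic
chaotic map.

The same analysis runs from the shell on a config file:

```bash
edmchaos all --config docs/example_config.yaml --seed 1 --outdir results/run1
```

writing `dataset.csv`, `fits.csv` (per-replicate E/θ selection and
self-fit skill), `pairs.csv` (all ordered cross-predictions with ΔN0, λ
and per-horizon errors), `partition.csv`, optional grouping tables, and
a `manifest.json` recording every parameter and version. Runs with the
same seed are byte-identical.

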