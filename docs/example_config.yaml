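# Example pipeline configuration.
#
# Either point `dataset.path` at a wide CSV
# (replicate_id, time, <one column per species>) or describe a synthetic
# experiment under `dataset.synthetic`.

dataset:
  name: lv-demo
  step_days: 0.5          # regular grid step (days); CSV input is
                          # spline-regularized onto this grid
  synthetic:
    kind: lotka-volterra
    n_replicates: 6
    sigma: 0.05           # process-noise sd per unit time
    t_max: 20.0
  # path: data/microcosms.csv
  # roles: {prey: prey, predator: predator}

edm:
  mode: multivariate      # or: univariate
  tau: 1                  # delay in grid steps
  horizons: 10            # forecast horizons 1..10
  E_grid: [1, 2, 3, 4, 5, 6, 7, 8]
  theta_grid: [0.0, 1.0e-4, 3.0e-4, 1.0e-3, 3.0e-3, 0.01, 0.03, 0.1,
               0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]

cross:
  E_fixed: 2              # embedding dimension for cross-predictions

partition:
  lambda_horizons: [1, 2]     # horizons for the stepwise lambda estimate
  chaos_formula: squared      # or: printed

# optional: enables the grouping stage
# grouping:
#   boundary: {normal: [1.0, 0.0], offset: 2.0}

seed: 1
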