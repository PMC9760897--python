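"""Lyapunov estimation from forecast-error growth, and error partitioning.

The Lyapunov exponent λ measures the exponential rate at which nearby
trajectories diverge; λ > 0 is the operational signature of chaos,
λ < 0 of local convergence toward a stable equilibrium.  Treating the
forecast as a second trajectory started next to the observation, the
growth of forecast error with the prediction horizon estimates that
rate: ε(t) ≈ ε0·exp(λ·t), so λ is the slope of an ordinary
least-squares regression of log(error) on horizon.

The partitioning splits total prediction error into three fractions:

* **nonlinearity** — the skill gained by localizing the S-map
  (MSE at θ = 0, a single global linear model, minus MSE at the best θ);
* **chaos** — the part of the best-θ error attributable to exponential
  divergence.  Writing the non-chaotic error as RMSE0 = RMSE_bestθ·e^{−λest},
  MSE_chaos = MSE_bestθ − RMSE0² = MSE_bestθ·(1 − exp(−2·λest)), clamped
  to zero when λest < 0 (an alternative single-exponent factor is
  exposed as ``chaos_formula='printed'``);
* **stochasticity** — the remainder.

Each term is divided by the θ = 0 MSE ("total variation") so the three
fractions sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from edmchaos.errors import InsufficientDataError, ValidationError

__all__ = [
    "LyapunovEstimate",
    "ErrorPartition",
    "FitClassification",
    "lyapunov_from_horizons",
    "lyapunov_stepwise",
    "lyapunov_stepwise_mean",
    "partition_error",
    "partition_series",
    "classify_fit",
]


@dataclass(frozen=True)
class LyapunovEstimate:
    """Slope of log(error) against prediction horizon.

    ``lam`` is per grid step; ``intercept`` is log ε0; ``p_value`` is
    the two-sided test of zero slope.
    """

    lam: float
    intercept: float
    p_value: float
    n_horizons: int


@dataclass(frozen=True)
class ErrorPartition:
    """MSE decomposition into nonlinearity / chaos / stochasticity.

    ``mse_total`` is the θ = 0 fit ("total variation"), ``mse_best`` the
    best-θ fit.  Fractions live in [0, 1] and sum to 1; ``flags``
    records any clamping that was needed (e.g. ``mse_best`` above
    ``mse_total`` on a finite sample).
    """

    mse_total: float
    mse_best: float
    lambda_est: float
    rmse0: float
    frac_nonlinearity: float
    frac_chaos: float
    frac_stochasticity: float
    flags: tuple[str, ...] = ()
    theta_best: float | None = None
    E_used: int | None = None


@dataclass(frozen=True)
class FitClassification:
    """Rule-of-thumb forecast quality: good iff MAE < sd(observed)/2."""

    label: str                 # 'good' | 'poor' | 'undefined'
    standardized_mae: float    # MAE / sd(observed)


def lyapunov_from_horizons(mae_by_tp, times=None) -> LyapunovEstimate:
    """Estimate λ as the OLS slope of log(MAE) on the forecast horizon.

    Horizons with zero MAE are dropped with a warning (their log is
    undefined); at least two must remain.  A perfectly constant error
    profile gives λ = 0 with p = 1.
    """
    mae = np.asarray(mae_by_tp, dtype=float)
    t = (np.arange(1, len(mae) + 1, dtype=float) if times is None
         else np.asarray(times, dtype=float))
    if len(mae) != len(t):
        raise ValidationError("mae_by_tp and times must align")
    if np.any(mae < 0):
        raise ValidationError("MAE values must be nonnegative")
    keep = mae > 0
    if not np.all(keep):
        warnings.warn("dropping horizons with zero MAE (log undefined)")
        mae, t = mae[keep], t[keep]
    if len(mae) < 2:
        raise InsufficientDataError("need >= 2 horizons with positive MAE")
    res = stats.linregress(t, np.log(mae))
    p = float(res.pvalue)
    if np.isnan(p):   # zero residual variance (exactly collinear points)
        p = 1.0 if res.slope == 0 else 0.0
    return LyapunovEstimate(
        lam=float(res.slope),
        intercept=float(res.intercept),
        p_value=p,
        n_horizons=len(mae),
    )


def lyapunov_stepwise(rmse_ti: float, rmse_tnext: float, dt: float = 1.0) -> float:
    """λest from one pair of adjacent horizons.

    Solves RMSE(t+dt) = RMSE(t)·exp(λest·dt): growing error gives
    λest > 0, shrinking error (converging trajectories, a locally stable
    equilibrium) gives λest < 0.
    """
    if rmse_ti <= 0 or rmse_tnext <= 0:
        raise ValidationError("RMSE values must be positive")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    return float(np.log(rmse_tnext / rmse_ti) / dt)


def lyapunov_stepwise_mean(rmse_seq, dt: float = 1.0) -> float:
    """Mean of per-step λest over a sequence of adjacent-horizon RMSEs."""
    rmse_seq = np.asarray(rmse_seq, dtype=float)
    if len(rmse_seq) < 2:
        raise InsufficientDataError("need >= 2 horizons")
    rates = [
        lyapunov_stepwise(rmse_seq[i], rmse_seq[i + 1], dt)
        for i in range(len(rmse_seq) - 1)
    ]
    return float(np.mean(rates))


def partition_error(
    mse_total: float,
    mse_best: float,
    lambda_est: float,
    *,
    chaos_formula: str = "squared",
    theta_best: float | None = None,
    E_used: int | None = None,
) -> ErrorPartition:
    """Split total prediction error into its three fractions.

    ``chaos_formula='printed'`` uses MSE_chaos = MSE_bestθ·(1 − e^{−λ});
    ``'squared'`` uses the algebraically consistent (1 − e^{−2λ}) that
    follows from RMSE0 = RMSE_bestθ·e^{−λ} (see docs/methods.md for why
    both are exposed).  λest < 0 forces the chaos fraction to exactly
    zero.  Fractions are clamped to [0, 1] and renormalized (flagged) if
    finite-sample noise pushed any term outside.
    """
    if mse_total <= 0:
        raise ValidationError("mse_total must be positive")
    if mse_best < 0:
        raise ValidationError("mse_best must be nonnegative")
    if chaos_formula not in ("printed", "squared"):
        raise ValidationError(f"unknown chaos_formula {chaos_formula!r}")
    flags = []
    nonlin_raw = mse_total - mse_best
    if nonlin_raw < 0:
        flags.append("best_exceeds_total")
        nonlin_raw = 0.0
    if lambda_est > 0:
        k = 1.0 if chaos_formula == "printed" else 2.0
        chaos_raw = mse_best * (1.0 - np.exp(-k * lambda_est))
        rmse0 = float(np.sqrt(mse_best) * np.exp(-lambda_est))
    else:
        chaos_raw = 0.0
        rmse0 = float(np.sqrt(mse_best))
    stoch_raw = mse_total - nonlin_raw - chaos_raw
    fracs = np.array([nonlin_raw, chaos_raw, stoch_raw]) / mse_total
    if np.any(fracs < 0) or np.any(fracs > 1):
        flags.append("clamped")
        fracs = np.clip(fracs, 0.0, 1.0)
        fracs = fracs / fracs.sum()
    return ErrorPartition(
        mse_total=float(mse_total),
        mse_best=float(mse_best),
        lambda_est=float(lambda_est),
        rmse0=rmse0,
        frac_nonlinearity=float(fracs[0]),
        frac_chaos=float(fracs[1]),
        frac_stochasticity=float(fracs[2]),
        flags=tuple(flags),
        theta_best=theta_best,
        E_used=E_used,
    )


def partition_series(
    series,
    *,
    E: int | None = None,
    theta: float | None = None,
    tau: int = 1,
    mode: str = "univariate",
    target_species: str | None = None,
    E_grid=None,
    theta_grid=None,
    lambda_horizons=(1, 2),
    chaos_formula: str = "squared",
) -> ErrorPartition:
    """End-to-end partition for one series.

    Selects ``E`` (simplex) and ``theta`` (S-map) by leave-one-out
    cross-validation unless given, measures the θ = 0 and best-θ MSE at
    horizon 1, estimates λest from the growth of the best-θ RMSE across
    ``lambda_horizons`` (adjacent pairs averaged), and partitions.
    """
    from edmchaos.edm_core import (
        DEFAULT_E_GRID, DEFAULT_THETA_GRID, EmbeddingSpec, embed,
        select_E, select_theta, smap_forecast,
    )
    if E is None:
        if mode == "multivariate":
            E = len(series.species)   # block embedding: one dim per species
        else:
            E, _ = select_E(
                series, E_grid if E_grid is not None else DEFAULT_E_GRID,
                tau=tau, tp=1, mode=mode, target_species=target_species,
            )
    if theta is None:
        theta, _ = select_theta(
            series, E,
            theta_grid if theta_grid is not None else DEFAULT_THETA_GRID,
            tau=tau, tp=1, mode=mode, target_species=target_species,
        )
    def best_fit_at(tp):
        spec = EmbeddingSpec(E=E, tau=tau, tp=tp, mode=mode,
                             target_species=target_species)
        block = embed(series, spec)
        return smap_forecast(block, block, theta, exclude_same_time=True)

    rmses = [best_fit_at(tp).diagnostics.rmse for tp in sorted(lambda_horizons)]
    fit1 = best_fit_at(1)
    mse_best = fit1.diagnostics.mse
    spec1 = EmbeddingSpec(E=E, tau=tau, tp=1, mode=mode,
                          target_species=target_species)
    block1 = embed(series, spec1)
    fit0 = smap_forecast(block1, block1, 0.0, exclude_same_time=True)
    mse_total = fit0.diagnostics.mse
    if any(r <= 0 for r in rmses):
        lam = 0.0   # perfect fit at some horizon: no measurable divergence
    else:
        lam = lyapunov_stepwise_mean(rmses)
    return partition_error(
        mse_total, mse_best, lam,
        chaos_formula=chaos_formula, theta_best=theta, E_used=E,
    )


def classify_fit(mae: float, observed_sd: float) -> FitClassification:
    """Rule-of-thumb skill class: 'good' iff MAE < sd/2 (strict).

    The standardized MAE (mae/sd) is returned for contour plots; a
    nonpositive sd makes the classification 'undefined'.
    """
    if mae < 0:
        raise ValidationError("mae must be nonnegative")
    if observed_sd <= 0:
        return FitClassification("undefined", float("nan"))
    std = mae / observed_sd
    return FitClassification("good" if mae < observed_sd / 2 else "poor", std)
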