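"""Synthetic data generators with known dynamical character.

Three families of fixtures, all deterministic under a fixed seed:

* **discrete growth maps** (Ricker and the quadratic logistic map) with
  tunable growth rate ``r`` and per-step process noise ``sigma`` —
  series whose position on the stochasticity/nonlinearity/chaos
  spectrum is controlled by construction.  The Ricker map
  ``x' = x·exp(r(1-x))`` is the default "May-type" model because it is
  chaotic at r = 3 (the quadratic map is merely periodic there) and
  tolerates multiplicative noise without leaving the positive axis;
* **replicated Lotka-Volterra predator-prey systems** sharing all
  parameters and differing only in initial abundances, emulating a
  microcosm experiment with many replicates started at different
  points in phase space;
* **VAR(1) linear benchmarks** for coefficient-recovery oracles.

A brute-force two-trajectory Lyapunov oracle for the deterministic maps
closes the loop: the forecast-error-based λ estimators can be checked
against direct divergence of nearby trajectories (analytically log 2
for the quadratic logistic map at r = 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from edmchaos.errors import ValidationError
from edmchaos.io_model import Dataset, ReplicateSeries, SpeciesInfo

__all__ = [
    "SyntheticConfig",
    "simulate_map",
    "simulate_lv_replicates",
    "simulate_var1",
    "lyapunov_oracle",
    "two_regime_dataset",
    "DEFAULT_LV_PARAMS",
]

#: shared Lotka-Volterra parameters (per day): prey growth a, predation b,
#: conversion efficiency c, predator mortality d.  Equilibrium at
#: (prey, predator) = (d/(c·b), a/b) = (2, 2); cycle period ≈ 8.9 d.
DEFAULT_LV_PARAMS: dict[str, float] = dict(
    prey_growth=1.0, predation=0.5, conversion=0.5, predator_mortality=0.5,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Declarative description of a synthetic experiment."""

    model: str = "ricker"
    r: float = 3.0
    sigma: float = 0.0
    n_steps: int = 100
    n_replicates: int = 1
    N0: tuple | None = None
    seed: int = 0
    observation_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.n_steps < 10:
            raise ValidationError("n_steps must be >= 10")


def _map_step(model: str, r: float, x: float, noise: float, sigma: float) -> float:
    if model == "ricker":
        return x * np.exp(r * (1.0 - x)) * np.exp(sigma * noise)
    # quadratic logistic: additive noise, clipped back into [0, 1]
    return float(np.clip(r * x * (1.0 - x) + sigma * noise, 0.0, 1.0))


def simulate_map(
    model: str = "ricker",
    *,
    r: float = 3.0,
    sigma: float = 0.0,
    n_steps: int = 100,
    x0: float = 0.5,
    seed: int = 0,
    observation_noise_sd: float = 0.0,
    replicate_id: str = "sim",
) -> ReplicateSeries:
    """Simulate a single-species discrete growth map.

    Ricker: ``x' = x·exp(r(1-x))·exp(sigma·ζ)`` (log-normal
    multiplicative noise keeps abundances positive).  Quadratic
    logistic: ``x' = r·x·(1-x) + sigma·ζ`` clipped to [0, 1]; ``r > 4``
    is rejected because the deterministic map then escapes the unit
    interval.  Optional observation noise is additive Gaussian applied
    after simulation, floored at 0.
    """
    if model not in ("ricker", "quadratic-logistic"):
        raise ValidationError(f"unknown map model {model!r}")
    if model == "quadratic-logistic" and r > 4:
        raise ValidationError("quadratic logistic map needs r <= 4")
    rng = np.random.default_rng(seed)
    x = np.empty(n_steps)
    x[0] = x0
    noise = rng.standard_normal(n_steps - 1)
    for t in range(n_steps - 1):
        x[t + 1] = _map_step(model, r, x[t], noise[t], sigma)
    if observation_noise_sd > 0:
        x = np.clip(x + rng.normal(0, observation_noise_sd, n_steps), 0.0, None)
    return ReplicateSeries(
        replicate_id=replicate_id,
        species=(SpeciesInfo("x", "other", "dimensionless"),),
        times=np.arange(n_steps, dtype=float),
        abundances=x[:, None],
    )


def _lv_derivs(prey, pred, p):
    dprey = prey * (p["prey_growth"] - p["predation"] * pred)
    dpred = pred * (p["conversion"] * p["predation"] * prey
                    - p["predator_mortality"])
    return dprey, dpred


def simulate_lv_replicates(
    n_replicates: int = 19,
    *,
    N0_list=None,
    params: dict[str, float] | None = None,
    sigma: float = 0.05,
    t_max: float = 20.0,
    step: float = 0.5,
    dt: float = 0.01,
    seed: int = 0,
    observation_noise_sd: float = 0.0,
    name: str = "lv",
) -> Dataset:
    """Replicated predator-prey dynamics differing only in N0.

    Euler-Maruyama integration of the Lotka-Volterra equations with
    multiplicative process noise (sd ``sigma`` per unit time on each
    species, scaled by abundance so trajectories stay nonnegative);
    abundances are floored at 0 and extinct trajectories are retained.
    If ``N0_list`` is omitted, initial abundances are spread on a
    deterministic grid around the coexistence equilibrium — many
    distinct starting points in phase space, as in a microcosm
    experiment.
    """
    p = dict(DEFAULT_LV_PARAMS)
    if params:
        p.update(params)
    if step <= 0 or dt <= 0 or t_max <= 0:
        raise ValidationError("step, dt and t_max must be positive")
    if any(v <= 0 for v in p.values()):
        raise ValidationError("LV parameters must be positive")
    if N0_list is None:
        # deterministic low-discrepancy grid around the equilibrium (2, 2)
        golden = 0.6180339887498949
        N0_list = [
            (0.8 + 2.4 * ((i * golden) % 1.0),
             0.8 + 2.4 * ((i * golden + 0.5) % 1.0))
            for i in range(n_replicates)
        ]
    rng = np.random.default_rng(seed)
    species = (
        SpeciesInfo("prey", "prey", "individuals"),
        SpeciesInfo("predator", "predator", "individuals"),
    )
    n_sub = int(round(step / dt))
    n_out = int(np.floor(t_max / step + 1e-9)) + 1
    reps = []
    for i, n0 in enumerate(N0_list):
        prey, pred = float(n0[0]), float(n0[1])
        out = np.empty((n_out, 2))
        out[0] = (prey, pred)
        for k in range(1, n_out):
            for _ in range(n_sub):
                dprey, dpred = _lv_derivs(prey, pred, p)
                z = rng.standard_normal(2)
                prey = max(prey + dprey * dt
                           + sigma * prey * np.sqrt(dt) * z[0], 0.0)
                pred = max(pred + dpred * dt
                           + sigma * pred * np.sqrt(dt) * z[1], 0.0)
            out[k] = (prey, pred)
        if observation_noise_sd > 0:
            out = np.clip(
                out + rng.normal(0, observation_noise_sd, out.shape), 0.0, None
            )
        reps.append(
            ReplicateSeries(
                replicate_id=f"r{i + 1:02d}",
                species=species,
                times=step * np.arange(n_out),
                abundances=out,
            )
        )
    return Dataset(name=name, replicates=tuple(reps), step=step)


def two_regime_dataset(
    *,
    n_per_regime: int = 2,
    sigma: float = 0.02,
    t_max: float = 15.0,
    step: float = 0.5,
    seed: int = 0,
) -> tuple[Dataset, dict[str, int]]:
    """Dataset with two dynamical regimes plus the true regime labels.

    Regime 1 is the default Lotka-Volterra parameterization; regime 2
    doubles prey growth and halves predation — same species, same
    grid, genuinely different dynamics.  Used to test that
    between-group cross-prediction error exceeds within-group error.
    """
    p2 = dict(DEFAULT_LV_PARAMS)
    p2["prey_growth"] *= 2.0
    p2["predation"] *= 0.5
    n01 = [(1.5 + 0.3 * i, 1.5) for i in range(n_per_regime)]
    n02 = [(3.5 + 0.3 * i, 1.5) for i in range(n_per_regime)]
    d1 = simulate_lv_replicates(
        N0_list=n01, sigma=sigma, t_max=t_max, step=step, seed=seed,
    )
    d2 = simulate_lv_replicates(
        N0_list=n02, params=p2, sigma=sigma, t_max=t_max, step=step,
        seed=seed + 1,
    )
    reps, labels = [], {}
    for g, d in ((1, d1), (2, d2)):
        for r in d.replicates:
            rid = f"g{g}_{r.replicate_id}"
            reps.append(ReplicateSeries(rid, r.species, r.times, r.abundances))
            labels[rid] = g
    return Dataset("two_regime", tuple(reps), step=step), labels


def simulate_var1(
    A,
    *,
    noise_sd: float = 0.01,
    n: int = 500,
    seed: int = 0,
    burn_in: int = 100,
    replicate_id: str = "var1",
) -> ReplicateSeries:
    """Stationary first-order vector autoregression x(t+1) = A·x(t) + ζ.

    The first ``burn_in`` steps are discarded.  ``A`` must have spectral
    radius < 1 (otherwise the process diverges and is rejected).  Values
    may be negative — this is a linear benchmark, not an abundance
    series, so no flooring is applied.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    k = A.shape[0]
    if A.shape != (k, k):
        raise ValidationError("A must be square")
    rho = float(np.max(np.abs(np.linalg.eigvals(A))))
    if rho >= 1.0:
        raise ValidationError(f"unstable A (spectral radius {rho:.3f} >= 1)")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    x = np.zeros((total, k))
    noise = rng.normal(0.0, noise_sd, (total - 1, k))
    for t in range(total - 1):
        x[t + 1] = A @ x[t] + noise[t]
    x = x[burn_in:]
    species = tuple(SpeciesInfo(f"x{j + 1}", "other", "a.u.") for j in range(k))
    # shift into the nonnegative orthant so the series is a valid abundance
    # container; an affine shift changes neither VAR coefficients nor EDM
    shift = max(0.0, -float(x.min()))
    return ReplicateSeries(
        replicate_id=replicate_id,
        species=species,
        times=np.arange(n, dtype=float),
        abundances=x + shift,
    )


def lyapunov_oracle(
    model: str = "quadratic-logistic",
    *,
    r: float = 4.0,
    n_pairs: int = 1000,
    delta0: float = 1e-8,
    n_steps: int = 15,
    burn_in: int = 100,
    seed: int = 0,
    sigma: float = 0.0,
) -> float:
    """Brute-force Lyapunov exponent by direct trajectory divergence.

    For each of ``n_pairs`` starting points on the attractor (random
    start, ``burn_in`` iterations discarded), a twin trajectory offset
    by ``delta0`` is iterated ``n_steps`` steps and the mean of
    ``log(|x_T - x'_T| / delta0) / T`` is returned.  ``n_steps`` is kept
    short so the separation stays far below attractor size (no
    saturation).  Only deterministic maps are admissible: the notion of
    trajectory divergence is undefined under process noise.

    For the quadratic logistic map at r = 4 the analytic value is
    log 2 ≈ 0.693.
    """
    if sigma != 0.0:
        raise ValidationError("lyapunov_oracle requires a deterministic map")
    if model not in ("ricker", "quadratic-logistic"):
        raise ValidationError(f"unknown map model {model!r}")
    if model == "quadratic-logistic" and r > 4:
        raise ValidationError("quadratic logistic map needs r <= 4")
    rng = np.random.default_rng(seed)
    lams = np.empty(n_pairs)
    i = 0
    while i < n_pairs:
        x = rng.uniform(0.05, 0.95)
        for _ in range(burn_in):
            x = _map_step(model, r, x, 0.0, 0.0)
        xp = x + delta0
        ok = True
        for _ in range(n_steps):
            x = _map_step(model, r, x, 0.0, 0.0)
            xp = _map_step(model, r, xp, 0.0, 0.0)
            if x == xp:          # separation annihilated (clip or underflow)
                ok = False
                break
        if not ok:
            continue             # redraw; keeps the log defined
        lams[i] = np.log(abs(x - xp) / delta0) / n_steps
        i += 1
    return float(lams.mean())
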