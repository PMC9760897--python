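"""Cross-replicate prediction.

Train the S-map on one replicate and predict another: if two replicates
obey the same underlying dynamics, a model fitted to either should
forecast both.  How cross-prediction skill decays with the distance
between initial abundances, and how forecast error grows with the
prediction horizon, carry the signatures of stochasticity, nonlinearity
and chaos that the partitioning module quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from edmchaos.chaos_partition import lyapunov_from_horizons
from edmchaos.edm_core import (
    EmbeddingSpec,
    ForecastDiagnostics,
    embed,
    goodness_of_fit,
    select_theta,
    smap_forecast,
)
from edmchaos.errors import InsufficientDataError, ValidationError
from edmchaos.io_model import Dataset, ReplicateSeries

__all__ = [
    "CrossPredictionRecord",
    "initial_distance",
    "cross_predict",
    "pairwise_table",
    "records_to_frame",
    "DEFAULT_HORIZONS",
]

#: forecast horizons used for the error-growth (Lyapunov) regression
DEFAULT_HORIZONS: tuple[int, ...] = tuple(range(1, 11))


@dataclass(frozen=True)
class CrossPredictionRecord:
    """One ordered (source -> target) cross-prediction.

    ``delta_N0`` is the Euclidean distance between the two replicates'
    initial abundance vectors; ``per_horizon`` maps each forecast
    horizon to its diagnostics (``None`` where the pair had too few
    usable rows — recorded, never silently dropped); ``lyapunov`` is the
    slope of log(MAE) against horizon with its p-value.
    """

    source_id: str
    target_id: str
    delta_N0: float
    per_horizon: dict[int, ForecastDiagnostics | None]
    lyapunov: float
    lyapunov_p: float
    E_used: int
    theta_used: float

    @property
    def mean_mae(self) -> float:
        """MAE averaged over horizons with defined diagnostics."""
        vals = [d.mae for d in self.per_horizon.values() if d is not None]
        return float(np.mean(vals)) if vals else float("nan")


def initial_distance(repA: ReplicateSeries, repB: ReplicateSeries) -> float:
    """Euclidean distance between initial abundance vectors (ΔN0).

    Zero iff the two replicates started from identical abundances; a
    larger value means a greater divergence in initial predator and/or
    prey abundances.
    """
    if repA.species_labels != repB.species_labels:
        raise ValidationError(
            f"species mismatch: {repA.species_labels} vs {repB.species_labels}"
        )
    return float(np.linalg.norm(repA.N0 - repB.N0))


def cross_predict(
    source: ReplicateSeries,
    target: ReplicateSeries,
    *,
    E: int = 2,
    theta: float | None = None,
    horizons=DEFAULT_HORIZONS,
    tau: int = 1,
    mode: str = "multivariate",
    target_species: str | None = None,
    theta_grid=None,
    leave_one_out: bool = False,
) -> CrossPredictionRecord:
    """Fit the S-map to ``source``, forecast ``target`` at each horizon.

    ``E`` defaults to 2, the theoretically expected dimension for a
    two-species system.  If ``theta`` is None it is selected on the
    source replicate by leave-one-out cross-validation and then applied
    unchanged to the target (train-on-source semantics).  In
    multivariate mode with no ``target_species`` every species is
    forecast in turn and the error pairs are pooled per horizon.  With
    ``leave_one_out=True`` library rows sharing a query's time stamp are
    excluded — predicting a replicate from itself then reproduces
    ordinary self-prediction diagnostics exactly.

    Horizons for which either series is too short are recorded with
    ``None`` diagnostics.  The Lyapunov exponent is the log(MAE)-vs-
    horizon regression slope over the usable horizons.
    """
    if source.species_labels != target.species_labels:
        raise ValidationError("source and target species lists differ")
    step_s = np.diff(source.times)
    step_t = np.diff(target.times)
    if len(step_s) and len(step_t) and not np.allclose(step_s[0], step_t[0]):
        raise ValidationError("source and target must share the grid step")
    if mode == "univariate" and target_species is None:
        target_species = source.species_labels[0]
    species_list = (
        [target_species] if target_species is not None
        else list(source.species_labels)
    )
    if theta is None:
        from edmchaos.edm_core import DEFAULT_THETA_GRID
        grid = theta_grid if theta_grid is not None else DEFAULT_THETA_GRID
        # selection target: first species in the list, on the source itself
        theta, _ = select_theta(
            source, E, grid, tau=tau, tp=1, mode=mode,
            target_species=species_list[0],
        )
    per_horizon: dict[int, ForecastDiagnostics | None] = {}
    for tp in horizons:
        obs_all, pred_all = [], []
        try:
            for sp in species_list:
                spec = EmbeddingSpec(E=E, tau=tau, tp=tp, mode=mode,
                                     target_species=sp)
                lib = embed(source, spec)
                q = embed(target, spec)
                fit = smap_forecast(lib, q, theta,
                                    exclude_same_time=leave_one_out)
                obs_all.append(q.targets)
                pred_all.append(fit.forecasts)
            per_horizon[tp] = goodness_of_fit(
                np.concatenate(obs_all), np.concatenate(pred_all)
            )
        except InsufficientDataError:
            per_horizon[tp] = None
    maes = {tp: d.mae for tp, d in per_horizon.items() if d is not None}
    try:
        lam = lyapunov_from_horizons(list(maes.values()), list(maes.keys()))
        lam_val, lam_p = lam.lam, lam.p_value
    except (InsufficientDataError, ValidationError):
        lam_val, lam_p = float("nan"), float("nan")
    return CrossPredictionRecord(
        source_id=source.replicate_id,
        target_id=target.replicate_id,
        delta_N0=initial_distance(source, target),
        per_horizon=per_horizon,
        lyapunov=lam_val,
        lyapunov_p=lam_p,
        E_used=E,
        theta_used=float(theta),
    )


def pairwise_table(
    dataset: Dataset,
    *,
    E: int = 2,
    horizons=DEFAULT_HORIZONS,
    tau: int = 1,
    mode: str = "multivariate",
    target_species: str | None = None,
    theta_grid=None,
    include_self: bool = False,
) -> list[CrossPredictionRecord]:
    """All ordered cross-predictions in a dataset: n·(n−1) records.

    theta is selected once per source replicate (leave-one-out on the
    source) and reused for all of its targets.  Self-pairs are excluded
    unless ``include_self`` is set, in which case they run in
    leave-one-out mode and are flagged by ``source_id == target_id``.
    """
    if len(dataset) < 2:
        raise ValidationError("cross-prediction needs at least 2 replicates")
    from edmchaos.edm_core import DEFAULT_THETA_GRID
    grid = theta_grid if theta_grid is not None else DEFAULT_THETA_GRID
    sel_target = (
        target_species if target_species is not None
        else dataset.species_labels[0]
    )
    thetas = {}
    for rep in dataset.replicates:
        thetas[rep.replicate_id], _ = select_theta(
            rep, E, grid, tau=tau, tp=1, mode=mode, target_species=sel_target
        )
    records = []
    for src in dataset.replicates:
        for tgt in dataset.replicates:
            self_pair = src.replicate_id == tgt.replicate_id
            if self_pair and not include_self:
                continue
            records.append(
                cross_predict(
                    src, tgt, E=E, theta=thetas[src.replicate_id],
                    horizons=horizons, tau=tau, mode=mode,
                    target_species=target_species,
                    leave_one_out=self_pair,
                )
            )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tidy long table: one row per (source, target, horizon)."""
    rows = []
    for r in records:
        for tp, d in r.per_horizon.items():
            rows.append(
                dict(
                    source_id=r.source_id,
                    target_id=r.target_id,
                    delta_N0=r.delta_N0,
                    tp=tp,
                    mae=d.mae if d else float("nan"),
                    mse=d.mse if d else float("nan"),
                    rmse=d.rmse if d else float("nan"),
                    e2=d.e2 if d else float("nan"),
                    n=d.n if d else 0,
                    skipped=d is None,
                    **{"lambda": r.lyapunov},
                    lambda_p=r.lyapunov_p,
                    E=r.E_used,
                    theta=r.theta_used,
                )
            )
    return pd.DataFrame(rows)
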