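"""State-space embedding and the two EDM forecasters.

Empirical dynamic modeling (EDM) forecasts a time series from the
geometry of its reconstructed attractor rather than from a parametric
model.  Two forecasters are provided:

* **simplex projection** — the forecast for a query state is the
  exponentially weighted average of the futures of its ``E + 1`` nearest
  neighbors in embedded state space;
* **S-map** (sequential locally weighted global linear map) — the
  forecast is a locally weighted linear regression over *all* library
  states, with weights decaying in state-space distance at rate
  ``theta``.  ``theta = 0`` gives equal weights and reduces the S-map to
  one global linear (autoregressive) model; larger ``theta`` localizes
  the fit, which pays off exactly when the dynamics are nonlinear.

Embedding dimension ``E`` and ``theta`` are chosen by leave-one-out
cross-validation, minimizing the mean absolute error (MAE) between
observed and predicted values.  The S-map regression coefficients of a
multivariate (block) embedding are interpretable as time-varying
interaction coefficients: the weight the local model gives species *j*
when predicting species *i*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from edmchaos.errors import InsufficientDataError, SingularFitError, ValidationError
from edmchaos.io_model import ReplicateSeries

__all__ = [
    "EmbeddingSpec",
    "EmbeddedBlock",
    "ForecastDiagnostics",
    "SMapFit",
    "embed",
    "simplex_forecast",
    "smap_forecast",
    "select_E",
    "select_theta",
    "goodness_of_fit",
    "DEFAULT_E_GRID",
    "DEFAULT_THETA_GRID",
]

#: default candidate embedding dimensions
DEFAULT_E_GRID: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)

#: default candidate S-map localization exponents (0 = global linear model)
DEFAULT_THETA_GRID: tuple[float, ...] = (
    0.0, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 0.5,
    0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
)

# relative singular-value cutoff for the weighted least-squares solve
_SVD_RCOND = 1e-10


@dataclass(frozen=True)
class EmbeddingSpec:
    """How to turn a series into a block of state vectors.

    ``mode='univariate'`` builds classic delay coordinates
    ``(x(t), x(t-tau), ..., x(t-(E-1)tau))`` of the target species;
    ``mode='multivariate'`` uses the simultaneous abundances of all
    species as coordinates (one dimension per species), which is
    equivalent to a delay embedding by Takens' theorem.  ``tp`` is the
    forecast horizon in grid steps.
    """

    E: int = 2
    tau: int = 1
    tp: int = 1
    mode: str = "univariate"
    target_species: str | None = None

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ValidationError("E must be >= 1")
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if self.tp < 1:
            raise ValidationError("tp must be >= 1")
        if self.mode not in ("univariate", "multivariate"):
            raise ValidationError(f"unknown embedding mode {self.mode!r}")


@dataclass(frozen=True)
class EmbeddedBlock:
    """Lagged/multivariate state matrix with aligned forecast targets.

    ``rows[i]`` is the state at ``row_times[i]``; ``targets[i]`` is the
    target species' value ``tp`` steps later.
    """

    rows: np.ndarray          # (n, dim)
    targets: np.ndarray       # (n,)
    row_times: np.ndarray     # (n,)
    spec: EmbeddingSpec | None = None

    def __post_init__(self) -> None:
        rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        targets = np.asarray(self.targets, dtype=float)
        row_times = np.asarray(self.row_times, dtype=float)
        if not (len(rows) == len(targets) == len(row_times)):
            raise ValidationError("rows, targets and row_times must align")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "row_times", row_times)

    @property
    def dim(self) -> int:
        return self.rows.shape[1]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class ForecastDiagnostics:
    """Forecast skill summary.

    ``e2`` is the coefficient of efficiency,
    ``1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2)`` — like R^2 but
    measuring scatter around the 1:1 line; 1 is a perfect forecast, 0
    matches predicting the observed mean, negative is worse than the
    mean.  ``e2`` is NaN (flagged) when the observations have zero
    variance.
    """

    mae: float
    mse: float
    rmse: float
    e2: float
    n: int
    e2_defined: bool = True


@dataclass(frozen=True)
class SMapFit:
    """Result of an S-map forecast at one ``theta``.

    ``coefficients`` has one row per query and one column per embedding
    dimension plus a trailing intercept column; in a multivariate
    embedding the column for species *j* is the local-model estimate of
    the effect of species *j* on the target species.
    """

    theta: float
    coefficients: np.ndarray   # (n_queries, dim + 1), intercept last
    forecasts: np.ndarray      # (n_queries,)
    diagnostics: ForecastDiagnostics
    query_times: np.ndarray | None = None
    dim_labels: tuple[str, ...] | None = None


def embed(series: ReplicateSeries, spec: EmbeddingSpec) -> EmbeddedBlock:
    """Build the embedded state block and aligned targets for a series.

    The series must already sit on a regular grid.  Rows with any
    undefined lag (start of the series) or undefined target (end of the
    series) are excluded, so a univariate embedding of ``n`` points has
    ``n - (E-1)*tau - tp`` rows.
    """
    labels = series.species_labels
    target = spec.target_species or labels[0]
    y = series.column(target)
    n = len(y)
    if spec.mode == "univariate":
        first = (spec.E - 1) * spec.tau
        n_rows = n - first - spec.tp
        if n_rows < 1:
            raise InsufficientDataError(
                f"series of length {n} too short for E={spec.E}, "
                f"tau={spec.tau}, tp={spec.tp}"
            )
        idx = np.arange(first, n - spec.tp)
        lags = [y[idx - k * spec.tau] for k in range(spec.E)]
        rows = np.column_stack(lags)
    else:
        n_rows = n - spec.tp
        if n_rows < 1:
            raise InsufficientDataError(
                f"series of length {n} too short for tp={spec.tp}"
            )
        idx = np.arange(0, n - spec.tp)
        rows = series.abundances[idx]
    targets = y[idx + spec.tp]
    return EmbeddedBlock(
        rows=rows, targets=targets, row_times=series.times[idx], spec=spec
    )


def _usable_mask(library: EmbeddedBlock, query_time: float, exclude_same_time: bool):
    if not exclude_same_time:
        return None
    return library.row_times != query_time


def simplex_forecast(
    library: EmbeddedBlock,
    queries: EmbeddedBlock,
    *,
    exclude_same_time: bool = False,
) -> tuple[np.ndarray, ForecastDiagnostics]:
    """Nearest-neighbor (simplex projection) forecasts for each query row.

    For each query the ``dim + 1`` nearest library rows (Euclidean
    distance) are found and the forecast is the weighted mean of their
    targets, ``w_i = exp(-d_i / d_1)`` with ``d_1`` the distance to the
    nearest neighbor.  If ``d_1 = 0`` every zero-distance neighbor gets
    unit weight and the rest get zero (their targets are averaged
    equally).  With ``exclude_same_time=True`` library rows sharing a
    query's time stamp are removed first — leave-one-out
    cross-validation when library and queries are the same block.
    """
    if len(library) == 0:
        raise InsufficientDataError("empty library")
    if library.dim != queries.dim:
        raise ValidationError("library and query dimensions differ")
    k = library.dim + 1
    dists = cdist(queries.rows, library.rows)
    forecasts = np.empty(len(queries))
    for i in range(len(queries)):
        d = dists[i]
        mask = _usable_mask(library, queries.row_times[i], exclude_same_time)
        if mask is not None:
            usable = np.nonzero(mask)[0]
        else:
            usable = np.arange(len(library))
        if len(usable) < k:
            raise InsufficientDataError(
                f"need {k} usable library rows, have {len(usable)}"
            )
        du = d[usable]
        order = usable[np.argsort(du, kind="stable")[:k]]
        dn = d[order]
        if dn[0] == 0.0:
            w = (dn == 0.0).astype(float)
        else:
            w = np.exp(-dn / dn[0])
        forecasts[i] = np.dot(w, library.targets[order]) / w.sum()
    return forecasts, _maybe_diagnostics(queries.targets, forecasts)


def smap_forecast(
    library: EmbeddedBlock,
    queries: EmbeddedBlock,
    theta: float,
    *,
    exclude_same_time: bool = False,
) -> SMapFit:
    """Locally weighted linear (S-map) forecasts for each query row.

    For a query ``y`` every library row is weighted
    ``w_i = exp(-theta * d_i / dbar)`` where ``dbar`` is the mean
    distance from ``y`` to all usable library rows, and the target is
    regressed on the states (with intercept) by weighted least squares.
    The solve uses an SVD pseudo-inverse with relative cutoff 1e-10, so
    rank-deficient neighborhoods get the minimum-norm solution rather
    than failing.
    """
    if theta < 0:
        raise ValidationError("theta must be >= 0")
    if library.dim != queries.dim:
        raise ValidationError("library and query dimensions differ")
    dim = library.dim
    if len(library) <= dim + 1:
        raise InsufficientDataError(
            f"S-map needs more than dim + 1 = {dim + 1} library rows"
        )
    dists = cdist(queries.rows, library.rows)
    nq = len(queries)
    forecasts = np.empty(nq)
    coefs = np.empty((nq, dim + 1))
    for i in range(nq):
        mask = _usable_mask(library, queries.row_times[i], exclude_same_time)
        if mask is not None:
            usable = np.nonzero(mask)[0]
        else:
            usable = np.arange(len(library))
        if len(usable) <= dim + 1:
            raise InsufficientDataError(
                f"need more than {dim + 1} usable library rows, "
                f"have {len(usable)}"
            )
        X = library.rows[usable]
        if np.all(X == X[0]):
            raise SingularFitError("all library states identical")
        d = dists[i, usable]
        if theta == 0.0:
            w = np.ones(len(usable))
        else:
            dbar = d.mean()
            if dbar == 0.0:
                raise SingularFitError("zero mean distance to library")
            w = np.exp(-theta * d / dbar)
        sw = np.sqrt(w)
        A = np.column_stack([X, np.ones(len(usable))]) * sw[:, None]
        b = library.targets[usable] * sw
        beta, *_ = np.linalg.lstsq(A, b, rcond=_SVD_RCOND)
        coefs[i] = beta
        forecasts[i] = np.dot(queries.rows[i], beta[:dim]) + beta[dim]
    diag = _maybe_diagnostics(queries.targets, forecasts)
    return SMapFit(
        theta=float(theta),
        coefficients=coefs,
        forecasts=forecasts,
        diagnostics=diag,
        query_times=queries.row_times.copy(),
    )


def _maybe_diagnostics(observed, predicted) -> ForecastDiagnostics | None:
    """Diagnostics, or None when there are too few pairs to summarize."""
    try:
        return goodness_of_fit(observed, predicted)
    except InsufficientDataError:
        return None


def _loo_diagnostics_simplex(series, spec) -> ForecastDiagnostics:
    block = embed(series, spec)
    _, diag = simplex_forecast(block, block, exclude_same_time=True)
    return diag


def select_E(
    series: ReplicateSeries,
    E_grid=DEFAULT_E_GRID,
    *,
    tau: int = 1,
    tp: int = 1,
    mode: str = "univariate",
    target_species: str | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the embedding dimension by leave-one-out simplex skill.

    Returns the ``E`` minimizing cross-validated MAE (ties broken toward
    smaller ``E``) together with the full per-``E`` diagnostics table.
    Candidates the series is too short for are skipped with a warning.
    """
    if not len(E_grid):
        raise ValidationError("E_grid is empty")
    records = []
    for E in E_grid:
        spec = EmbeddingSpec(E=E, tau=tau, tp=tp, mode=mode,
                             target_species=target_species)
        try:
            diag = _loo_diagnostics_simplex(series, spec)
        except InsufficientDataError:
            warnings.warn(f"E={E}: series too short, candidate skipped")
            continue
        records.append(
            dict(E=E, mae=diag.mae, mse=diag.mse, rmse=diag.rmse,
                 e2=diag.e2, n=diag.n)
        )
    if not records:
        raise InsufficientDataError("series too short for every E candidate")
    table = pd.DataFrame(records)
    best = int(table.loc[table["mae"].idxmin(), "E"])  # idxmin keeps first tie
    return best, table


def select_theta(
    series: ReplicateSeries,
    E: int,
    theta_grid=DEFAULT_THETA_GRID,
    *,
    tau: int = 1,
    tp: int = 1,
    mode: str = "univariate",
    target_species: str | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the S-map localization ``theta`` by leave-one-out skill.

    The returned MAE-vs-theta profile is the standard nonlinearity
    diagnostic: skill improving for ``theta > 0`` indicates state-
    dependent (nonlinear) dynamics.  Exact ties go to the smaller
    ``theta``, so purely linear series select ``theta = 0``.
    """
    if not len(theta_grid):
        raise ValidationError("theta_grid is empty")
    spec = EmbeddingSpec(E=E, tau=tau, tp=tp, mode=mode,
                         target_species=target_species)
    block = embed(series, spec)
    records = []
    for theta in sorted(theta_grid):
        fit = smap_forecast(block, block, theta, exclude_same_time=True)
        d = fit.diagnostics
        records.append(
            dict(theta=theta, mae=d.mae, mse=d.mse, rmse=d.rmse, e2=d.e2, n=d.n)
        )
    table = pd.DataFrame(records)
    best = float(table.loc[table["mae"].idxmin(), "theta"])
    return best, table


def goodness_of_fit(observed, predicted) -> ForecastDiagnostics:
    """MAE / MSE / RMSE and coefficient of efficiency for paired values.

    Pairs with undefined (NaN) entries are dropped.  Zero observed
    variance leaves ``e2`` NaN with ``e2_defined=False``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must have equal length")
    keep = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[keep], pred[keep]
    n = len(obs)
    if n < 2:
        raise InsufficientDataError("need at least 2 defined pairs")
    err = obs - pred
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_obs = float(np.sum((obs - obs.mean()) ** 2))
    if ss_obs == 0.0:
        return ForecastDiagnostics(mae, mse, rmse, float("nan"), n,
                                   e2_defined=False)
    e2 = 1.0 - float(np.sum(err**2)) / ss_obs
    return ForecastDiagnostics(mae, mse, rmse, e2, n)
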