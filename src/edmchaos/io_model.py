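"""Domain types, CSV I/O, and spline regularization of irregular series.

A :class:`ReplicateSeries` holds one experimental replicate of a
multi-species abundance time series; a :class:`Dataset` collects the
replicates of one experiment (e.g. a set of predator-prey microcosms that
differ only in initial abundances).  Irregularly sampled observations are
brought onto a regular grid with a cubic spline before any state-space
embedding, because delay embeddings require a constant step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from edmchaos.errors import FormatError, InsufficientDataError, ValidationError

__all__ = [
    "SpeciesInfo",
    "ReplicateSeries",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "spline_regularize",
    "regularize_dataset",
]

#: recognised ecological roles for a species column
ROLES = ("prey", "predator", "other")


@dataclass(frozen=True)
class SpeciesInfo:
    """A species column: label, ecological role, and abundance unit."""

    label: str
    role: str = "other"
    unit: str = "individuals"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r} for species {self.label!r}; "
                f"expected one of {ROLES}"
            )


@dataclass(frozen=True)
class ReplicateSeries:
    """One experimental replicate: a time grid plus per-species abundances.

    Parameters
    ----------
    replicate_id
        Unique identifier within the dataset.
    species
        Ordered species descriptors; order fixes the column order of
        ``abundances`` and of the initial-abundance vector ``N0``.
    times
        Observation times in days, strictly increasing.
    abundances
        ``(n_times, n_species)`` array of nonnegative abundances.
    """

    replicate_id: str
    species: tuple[SpeciesInfo, ...]
    times: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        abund = np.asarray(self.abundances, dtype=float)
        if abund.ndim != 2:
            raise ValidationError("abundances must be a 2-D (time x species) array")
        if times.ndim != 1 or len(times) != abund.shape[0]:
            raise ValidationError("times and abundance rows must align")
        if abund.shape[1] != len(self.species):
            raise ValidationError("abundance columns must match the species list")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"replicate {self.replicate_id!r}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(abund)):
            raise ValidationError(
                f"replicate {self.replicate_id!r}: non-finite abundance"
            )
        if np.any(abund < 0):
            raise ValidationError(
                f"replicate {self.replicate_id!r}: negative abundance"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "abundances", abund)

    @property
    def N0(self) -> np.ndarray:
        """Initial abundance vector (first abundance row)."""
        return self.abundances[0].copy()

    @property
    def species_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.species)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def column(self, label: str) -> np.ndarray:
        """Abundance series for one species."""
        try:
            j = self.species_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"species {label!r} not in replicate {self.replicate_id!r}"
            ) from None
        return self.abundances[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundances, columns=list(self.species_labels))
        df.insert(0, "time", self.times)
        df.insert(0, "replicate_id", self.replicate_id)
        return df


@dataclass(frozen=True)
class Dataset:
    """A named collection of replicates sharing species list and units.

    ``step`` is the target interpolation step in days (0.5 d for the
    short ciliate-yeast series, 1 d for the mite system, in the study
    design this package emulates).
    """

    name: str
    replicates: tuple[ReplicateSeries, ...]
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("step must be positive")
        if not self.replicates:
            raise ValidationError("dataset has no replicates")
        ids = [r.replicate_id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate replicate ids")
        ref = self.replicates[0].species
        for r in self.replicates[1:]:
            if r.species != ref:
                raise ValidationError(
                    f"replicate {r.replicate_id!r} has a different species list"
                )
        object.__setattr__(self, "replicates", tuple(self.replicates))

    @property
    def species(self) -> tuple[SpeciesInfo, ...]:
        return self.replicates[0].species

    @property
    def species_labels(self) -> tuple[str, ...]:
        return self.replicates[0].species_labels

    def __len__(self) -> int:
        return len(self.replicates)

    def __getitem__(self, replicate_id: str) -> ReplicateSeries:
        for r in self.replicates:
            if r.replicate_id == replicate_id:
                return r
        raise KeyError(replicate_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.replicates], ignore_index=True)


def read_dataset(
    path,
    *,
    name: str = "dataset",
    step: float = 1.0,
    roles: dict[str, str] | None = None,
    units: dict[str, str] | None = None,
) -> Dataset:
    """Read a wide CSV (``replicate_id, time, <species>...``) into a Dataset.

    Rows are sorted by time within each replicate; duplicate
    ``(replicate_id, time)`` rows are rejected.  Species roles and units
    come from config (``roles`` / ``units`` maps keyed by column label).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"replicate_id", "time"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    sp_cols = [c for c in df.columns if c not in required]
    if not sp_cols:
        raise FormatError("no species columns found")
    roles = roles or {}
    units = units or {}
    species = tuple(
        SpeciesInfo(c, roles.get(c, "other"), units.get(c, "individuals"))
        for c in sp_cols
    )
    reps = []
    for rid, grp in df.groupby("replicate_id", sort=True):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy(dtype=float)
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"replicate {rid!r}: duplicate or non-increasing time stamps"
            )
        reps.append(
            ReplicateSeries(
                replicate_id=str(rid),
                species=species,
                times=t,
                abundances=grp[sp_cols].to_numpy(dtype=float),
            )
        )
    return Dataset(name=name, replicates=tuple(reps), step=step)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a Dataset as a wide CSV, canonical ``repr`` number formatting.

    ``read_dataset(write_dataset(x))`` round-trips numeric content
    bit-for-bit (floats are written with shortest-repr precision).
    """
    df = dataset.to_frame()
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def spline_regularize(series: ReplicateSeries, step: float) -> ReplicateSeries:
    """Resample a series onto a regular grid with a natural cubic spline.

    The grid is anchored at the first observation and extends to the last
    grid point that does not pass the final observation (no
    extrapolation).  Interpolated abundances are clipped at zero from
    below, since negative abundances are meaningless.  Not-a-knot
    boundary conditions are used so the interpolant reproduces smooth
    trends (any cubic exactly) instead of forcing zero curvature at the
    series ends.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 observations (cubic minimum).
    ValidationError
        ``step`` nonpositive or larger than the observed span.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    if series.n_times < 4:
        raise InsufficientDataError(
            f"replicate {series.replicate_id!r}: cubic spline needs >= 4 points, "
            f"got {series.n_times}"
        )
    t0, t1 = series.times[0], series.times[-1]
    span = t1 - t0
    if step > span:
        raise ValidationError(f"step {step} exceeds the series span {span}")
    n_grid = int(np.floor(span / step + 1e-9)) + 1
    grid = t0 + step * np.arange(n_grid)
    cols = []
    for j in range(series.abundances.shape[1]):
        cs = CubicSpline(series.times, series.abundances[:, j], bc_type="not-a-knot")
        cols.append(np.clip(cs(grid), 0.0, None))
    return replace(series, times=grid, abundances=np.column_stack(cols))


def regularize_dataset(dataset: Dataset, step: float | None = None) -> Dataset:
    """Spline-regularize every replicate at the dataset step."""
    step = dataset.step if step is None else step
    reps = tuple(spline_regularize(r, step) for r in dataset.replicates)
    return Dataset(name=dataset.name, replicates=reps, step=step)
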