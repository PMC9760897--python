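"""Phase-space grouping of replicates.

Replicated predator-prey experiments can fall into distinct dynamical
regimes depending on where in (prey, predator) abundance space they
start — e.g. one group with strongly negative and one with positive
effects of predators on prey.  The group boundary is a straight line in
initial-abundance space, supplied declaratively by the analyst; the
module compares S-map interaction-coefficient trajectories between
groups and cross-prediction error within versus between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from edmchaos.errors import ValidationError
from edmchaos.io_model import Dataset

__all__ = [
    "GroupAssignment",
    "assign_groups",
    "mean_interaction_trajectories",
    "within_between_mae",
]


@dataclass(frozen=True)
class GroupAssignment:
    """replicate_id -> group (1 or 2), plus the line that divides them.

    The boundary is the set ``N0 · normal = offset``; group 1 is the
    side with ``N0 · normal < offset``, group 2 the side with
    ``N0 · normal >= offset`` (boundary points go to group 2).
    """

    labels: dict[str, int]
    normal: np.ndarray
    offset: float

    def group_ids(self, g: int) -> list[str]:
        return [rid for rid, lab in self.labels.items() if lab == g]


def assign_groups(dataset: Dataset, normal, offset: float) -> GroupAssignment:
    """Assign every replicate to a side of a line in N0 space.

    ``normal`` has one entry per species.  A vertical boundary at
    prey = c is ``normal=(1, 0), offset=c``: replicates starting with
    fewer prey than c form group 1, the rest group 2.  If every
    replicate lands on one side a warning is raised (the grouping is
    then uninformative but not an error).
    """
    normal = np.asarray(normal, dtype=float)
    if normal.shape != (len(dataset.species_labels),):
        raise ValidationError(
            f"normal must have {len(dataset.species_labels)} entries"
        )
    if np.all(normal == 0):
        raise ValidationError("boundary normal must be nonzero")
    labels = {}
    for rep in dataset.replicates:
        value = float(np.dot(rep.N0, normal)) - offset
        labels[rep.replicate_id] = 1 if value < 0 else 2
    present = set(labels.values())
    if len(present) == 1:
        warnings.warn(
            f"all replicates fall in group {present.pop()}; "
            "boundary separates nothing"
        )
    return GroupAssignment(labels=labels, normal=normal, offset=float(offset))


def mean_interaction_trajectories(
    fits: dict[str, dict[str, "SMapFit"]],
    assignment: GroupAssignment,
    species_labels,
) -> pd.DataFrame:
    """Per-group mean ± SE of S-map interaction coefficients over time.

    ``fits[replicate_id][target_species]`` is a multivariate-block
    S-map fit; its coefficient column for species *j* estimates the
    effect of *j* on the target.  For every ordered species pair
    (driver -> target, driver ≠ target) and every time step shared by
    all members of a group, the group mean and standard error of that
    coefficient are returned.  Groups with fewer than two members get
    NaN SE (flagged via the ``n`` column).
    """
    species_labels = list(species_labels)
    rows = []
    for g in (1, 2):
        members = [rid for rid in assignment.group_ids(g) if rid in fits]
        if not members:
            continue
        if len(members) < 2:
            warnings.warn(f"group {g} has < 2 replicates; SE undefined")
        for target in species_labels:
            # common time grid: intersection over group members
            times = None
            for rid in members:
                ft = fits[rid][target]
                t = set(np.round(ft.query_times, 9))
                times = t if times is None else times & t
            common = np.array(sorted(times))
            for driver in species_labels:
                if driver == target:
                    continue
                j = species_labels.index(driver)
                for t in common:
                    vals = []
                    for rid in members:
                        ft = fits[rid][target]
                        i = int(np.argmin(np.abs(ft.query_times - t)))
                        vals.append(ft.coefficients[i, j])
                    vals = np.asarray(vals)
                    n = len(vals)
                    se = (float(np.std(vals, ddof=1) / np.sqrt(n))
                          if n >= 2 else float("nan"))
                    rows.append(
                        dict(group=g, time=float(t),
                             effect=f"{driver}->{target}",
                             mean=float(vals.mean()), se=se, n=n)
                    )
    return pd.DataFrame(rows)


def within_between_mae(records, assignment: GroupAssignment) -> pd.DataFrame:
    """Mean cross-prediction MAE within each group and between groups.

    Each record's MAE is first averaged over its horizons; self-pairs
    are excluded.  Empty categories are kept with NaN mean and a
    warning, so downstream code sees them explicitly.
    """
    sums = {"within_1": [], "within_2": [], "between": []}
    for r in records:
        if r.source_id == r.target_id:
            continue
        gs = assignment.labels.get(r.source_id)
        gt = assignment.labels.get(r.target_id)
        if gs is None or gt is None:
            raise ValidationError(
                f"record ({r.source_id}, {r.target_id}) has unassigned replicate"
            )
        key = f"within_{gs}" if gs == gt else "between"
        sums[key].append(r.mean_mae)
    rows = []
    for key, vals in sums.items():
        if not vals:
            warnings.warn(f"category {key!r} has no pairs")
        rows.append(
            dict(category=key,
                 mean_mae=float(np.mean(vals)) if vals else float("nan"),
                 n_pairs=len(vals))
        )
    return pd.DataFrame(rows)
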