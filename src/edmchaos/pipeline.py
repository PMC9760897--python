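"""Config-driven orchestration of the full analysis.

Stages, in order: load or simulate the dataset, spline-regularize,
per-replicate embedding-dimension and theta selection with self-fit
diagnostics, pairwise cross-prediction, Lyapunov estimation and error
partitioning, and (optionally) phase-space grouping.  Every run writes
tidy CSV tables plus a manifest recording all parameters, the seed, and
software versions; fixed seed implies byte-identical outputs.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

import edmchaos
from edmchaos.chaos_partition import partition_series
from edmchaos.cross_prediction import pairwise_table, records_to_frame
from edmchaos.edm_core import (
    DEFAULT_E_GRID,
    DEFAULT_THETA_GRID,
    EmbeddingSpec,
    embed,
    select_E,
    select_theta,
    smap_forecast,
)
from edmchaos.errors import EdmChaosError
from edmchaos.grouping import (
    assign_groups,
    mean_interaction_trajectories,
    within_between_mae,
)
from edmchaos.io_model import read_dataset, regularize_dataset, write_dataset
from edmchaos import synthetic_data

__all__ = ["run_pipeline", "load_config", "PipelineError"]

ALL_STAGES = ("simulate", "fit", "crosspredict", "partition", "group")

DEFAULT_CONFIG = {
    "dataset": {"name": "synthetic", "step_days": 0.5},
    "edm": {
        "E_grid": list(DEFAULT_E_GRID),
        "theta_grid": list(DEFAULT_THETA_GRID),
        "tau": 1,
        "horizons": 10,
        "mode": "multivariate",
    },
    "cross": {"E_fixed": 2},
    "partition": {"lambda_horizons": [1, 2], "chaos_formula": "squared"},
    "seed": 0,
}


class PipelineError(EdmChaosError):
    """A stage failed; message names the stage and offending item."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _float_fmt(x) -> str:
    return repr(float(x))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_float_fmt)


def _get_dataset(cfg, seed):
    ds_cfg = cfg.get("dataset", {})
    if "path" in ds_cfg:
        return read_dataset(
            ds_cfg["path"],
            name=ds_cfg.get("name", "dataset"),
            step=float(ds_cfg.get("step_days", 1.0)),
            roles=ds_cfg.get("roles"),
            units=ds_cfg.get("units"),
        )
    syn = ds_cfg.get("synthetic", {})
    kind = syn.get("kind", "lotka-volterra")
    if kind == "lotka-volterra":
        return synthetic_data.simulate_lv_replicates(
            n_replicates=int(syn.get("n_replicates", 6)),
            sigma=float(syn.get("sigma", 0.05)),
            t_max=float(syn.get("t_max", 20.0)),
            step=float(ds_cfg.get("step_days", 0.5)),
            seed=seed,
            name=ds_cfg.get("name", "lv"),
        )
    raise PipelineError(f"stage simulate: unknown synthetic kind {kind!r}")


def run_pipeline(
    config: dict | str | Path,
    outdir,
    *,
    seed: int | None = None,
    stages=ALL_STAGES,
) -> Path:
    """Run the requested stages and write result tables under ``outdir``.

    Returns the output directory.  Any stage failure raises
    :class:`PipelineError` naming the stage and the replicate or pair
    that caused it.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    edm = cfg["edm"]
    tau = int(edm["tau"])
    horizons = tuple(range(1, int(edm["horizons"]) + 1))
    mode = edm["mode"]
    E_grid = tuple(edm["E_grid"])
    theta_grid = tuple(edm["theta_grid"])

    # --- simulate / load + regularize -----------------------------------
    try:
        dataset = _get_dataset(cfg, seed)
        if "path" in cfg.get("dataset", {}):
            dataset = regularize_dataset(dataset)
    except EdmChaosError as exc:
        raise PipelineError(f"stage simulate: {exc}") from exc
    write_dataset(dataset, outdir / "dataset.csv")
    if stages == ("simulate",):
        _write_manifest(cfg, seed, outdir, stages)
        return outdir

    # --- per-replicate fits ---------------------------------------------
    fits_rows = []
    self_fits: dict[str, dict] = {}
    if "fit" in stages or "group" in stages:
        for rep in dataset.replicates:
            self_fits[rep.replicate_id] = {}
            for sp in dataset.species_labels:
                try:
                    if mode == "multivariate":
                        # block embedding: one dimension per species
                        E = len(dataset.species_labels)
                    else:
                        E, _ = select_E(rep, E_grid, tau=tau, tp=1,
                                        mode=mode, target_species=sp)
                    theta, _ = select_theta(rep, E, theta_grid, tau=tau,
                                            tp=1, mode=mode,
                                            target_species=sp)
                    spec = EmbeddingSpec(E=E, tau=tau, tp=1, mode=mode,
                                         target_species=sp)
                    block = embed(rep, spec)
                    fit = smap_forecast(block, block, theta,
                                        exclude_same_time=True)
                except EdmChaosError as exc:
                    raise PipelineError(
                        f"stage fit: replicate {rep.replicate_id!r}, "
                        f"species {sp!r}: {exc}"
                    ) from exc
                self_fits[rep.replicate_id][sp] = fit
                d = fit.diagnostics
                fits_rows.append(
                    dict(replicate_id=rep.replicate_id, species=sp,
                         mode=mode, E=E, theta=theta, mae=d.mae, mse=d.mse,
                         rmse=d.rmse, e2=d.e2, n=d.n)
                )
        _write_csv(pd.DataFrame(fits_rows), outdir / "fits.csv")

    # --- pairwise cross-prediction --------------------------------------
    records = []
    if "crosspredict" in stages or "group" in stages:
        try:
            records = pairwise_table(
                dataset, E=int(cfg["cross"]["E_fixed"]), horizons=horizons,
                tau=tau, mode=mode, theta_grid=theta_grid,
            )
        except EdmChaosError as exc:
            raise PipelineError(f"stage crosspredict: {exc}") from exc
        _write_csv(records_to_frame(records), outdir / "pairs.csv")

    # --- partitioning ----------------------------------------------------
    if "partition" in stages:
        part_rows = []
        pcfg = cfg["partition"]
        for rep in dataset.replicates:
            for sp in dataset.species_labels:
                try:
                    part = partition_series(
                        rep, tau=tau, mode=mode, target_species=sp,
                        E_grid=E_grid, theta_grid=theta_grid,
                        lambda_horizons=tuple(pcfg["lambda_horizons"]),
                        chaos_formula=pcfg["chaos_formula"],
                    )
                except EdmChaosError as exc:
                    raise PipelineError(
                        f"stage partition: replicate {rep.replicate_id!r}, "
                        f"species {sp!r}: {exc}"
                    ) from exc
                part_rows.append(
                    dict(dataset=dataset.name,
                         replicate_id=rep.replicate_id, species=sp,
                         mse_total=part.mse_total, mse_best=part.mse_best,
                         lambda_est=part.lambda_est,
                         frac_nonlinearity=part.frac_nonlinearity,
                         frac_chaos=part.frac_chaos,
                         frac_stochasticity=part.frac_stochasticity,
                         E=part.E_used, theta=part.theta_best,
                         flags=";".join(part.flags))
                )
        _write_csv(pd.DataFrame(part_rows), outdir / "partition.csv")

    # --- grouping (optional: needs a configured boundary) ----------------
    gcfg = cfg.get("grouping") or {}
    if "group" in stages and gcfg.get("boundary"):
        b = gcfg["boundary"]
        try:
            assignment = assign_groups(dataset, b["normal"], b["offset"])
            wb = within_between_mae(records, assignment)
            traj = mean_interaction_trajectories(
                self_fits, assignment, dataset.species_labels
            )
        except EdmChaosError as exc:
            raise PipelineError(f"stage group: {exc}") from exc
        groups_df = pd.DataFrame(
            [dict(replicate_id=rid, group=g)
             for rid, g in sorted(assignment.labels.items())]
        )
        _write_csv(groups_df, outdir / "groups.csv")
        _write_csv(wb, outdir / "group_mae.csv")
        _write_csv(traj, outdir / "group_trajectories.csv")

    _write_manifest(cfg, seed, outdir, stages)
    return outdir


def _write_manifest(cfg, seed, outdir: Path, stages) -> None:
    manifest = {
        "config": cfg,
        "seed": seed,
        "stages": list(stages),
        "versions": {
            "edmchaos": edmchaos.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
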