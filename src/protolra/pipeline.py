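"""End-to-end workflow: titrate -> pK_half (-> split) -> pool -> HH -> LRA.

The pipeline consumes the two fixed-protonation frame sets (P and D),
computes per-frame titration curves of the target site, optionally restricts
each ensemble to a pK_half population, pools the curves, applies the
Henderson-Hasselbalch transform and the two-endpoint average, intersects
with y = x, and attaches a delete-one jackknife standard error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from protolra import __version__
from protolra.errors import InputError, PipelineStageError
from protolra.io import (
    FrameRecord,
    read_frames,
    write_ensemble_curves,
    write_lra_report,
    write_pkhalf_table,
)
from protolra.lra import (
    EnsembleCurve,
    Intersection,
    LRAResult,
    hh_transform,
    jackknife_se,
    lra_average,
    macroscopic_pka,
    split_pkhalf_populations,
)
from protolra.titration import (
    PhGrid,
    PkHalfRecord,
    exact_titration,
    mc_titration,
    pkhalf,
)

log = logging.getLogger("protolra")


@dataclass
class PipelineConfig:
    """Configuration of one LRA run (defaults mirror the standard protocol)."""

    site: str = "Asp2.50"
    ph_min: float = -10.0
    ph_max: float = 20.0
    ph_step: float = 0.25
    method: str = "exact"  # "exact" | "mc"
    mc_steps: int = 100_000
    mc_burn_in: int | None = None
    pair_move_fraction: float = 0.1
    seed: int = 1
    epsilon: float = 1e-6
    population: str = "all"  # "all" | "high" | "low"
    split_method: str = "kmeans2"  # "kmeans2" | "fixed"
    split_threshold: float | None = None
    split_ensembles: tuple[str, ...] = ("P",)
    jackknife_mode: str = "auto"  # "auto" | "by-replicate" | "thirds"
    prot_path: str | None = None
    deprot_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.method not in ("exact", "mc"):
            raise InputError(f"method must be 'exact' or 'mc', got {self.method!r}")
        if self.population not in ("all", "high", "low"):
            raise InputError("population must be 'all', 'high' or 'low'")
        if self.jackknife_mode not in ("auto", "by-replicate", "thirds"):
            raise InputError("jackknife_mode must be 'auto', 'by-replicate' or 'thirds'")

    @property
    def grid(self) -> PhGrid:
        return PhGrid(self.ph_min, self.ph_max, self.ph_step)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "split_ensembles" in obj:
            obj["split_ensembles"] = tuple(obj["split_ensembles"])
        return cls(**obj)


@dataclass
class EnsembleData:
    """Target-site protonation of every frame of one ensemble, as a matrix."""

    label: str
    grid: PhGrid
    frame_ids: list[str]
    replicates: list[str]
    times_ps: list[float]
    prot: np.ndarray  # (n_frames, n_ph)
    pkhalf_records: list[PkHalfRecord]

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)


def titrate_frames(
    records: Sequence[FrameRecord], config: PipelineConfig, label: str
) -> EnsembleData:
    """Per-frame titration of the target site over all frames of one ensemble."""
    if not records:
        raise InputError(f"ensemble {label}: no frames")
    grid = config.grid
    rows, pk_records = [], []
    frame_ids, replicates, times = [], [], []
    for k, rec in enumerate(records):
        if rec.ensemble != label:
            raise InputError(
                f"frame {rec.frame_id!r} is labelled {rec.ensemble!r}, expected {label!r}"
            )
        if config.method == "exact":
            curve = exact_titration(rec.model, grid)
        else:
            curve = mc_titration(
                rec.model, grid, steps=config.mc_steps, burn_in=config.mc_burn_in,
                pair_move_fraction=config.pair_move_fraction,
                seed=config.seed + 7919 * k,
            )
        idx = rec.model.site_index(config.site)
        rows.append(curve.protonation[idx])
        pk = pkhalf(curve, idx)
        pk_records.append(PkHalfRecord(
            frame_id=rec.frame_id, replicate_id=rec.replicate,
            time_ps=rec.time_ps, pkhalf=pk.value,
        ))
        frame_ids.append(rec.frame_id)
        replicates.append(rec.replicate)
        times.append(rec.time_ps)
    return EnsembleData(
        label=label, grid=grid, frame_ids=frame_ids, replicates=replicates,
        times_ps=times, prot=np.array(rows), pkhalf_records=pk_records,
    )


def _population_mask(data: EnsembleData, config: PipelineConfig) -> np.ndarray:
    """Frames of one ensemble retained after pK_half population filtering."""
    if config.population == "all" or data.label not in config.split_ensembles:
        return np.ones(data.n_frames, dtype=bool)
    split = split_pkhalf_populations(
        data.pkhalf_records, method=config.split_method,
        fixed_threshold=config.split_threshold,
    )
    wanted = set(split.high_frames if config.population == "high" else split.low_frames)
    mask = np.array([fid in wanted for fid in data.frame_ids])
    if not mask.any():
        raise InputError(
            f"ensemble {data.label}: population {config.population!r} is empty"
        )
    log.info(
        "ensemble %s: population %s keeps %d / %d frames (threshold %.3f)",
        data.label, config.population, int(mask.sum()), data.n_frames, split.threshold,
    )
    return mask


def _ensemble_curve(
    data: EnsembleData, rows: np.ndarray, config: PipelineConfig
) -> EnsembleCurve:
    pooled = data.prot[rows].mean(axis=0)
    return hh_transform(pooled, data.grid, ensemble_label=data.label,
                        n_frames=int(len(rows)), epsilon=config.epsilon)


def _estimate(
    data_P: EnsembleData, data_D: EnsembleData,
    rows_P: np.ndarray, rows_D: np.ndarray, config: PipelineConfig,
) -> Intersection:
    curve_P = _ensemble_curve(data_P, rows_P, config)
    curve_D = _ensemble_curve(data_D, rows_D, config)
    return macroscopic_pka(lra_average(curve_P, curve_D))


def _partitions(
    data_P: EnsembleData, data_D: EnsembleData,
    rows_P: np.ndarray, rows_D: np.ndarray, mode: str,
) -> list[tuple[str, list[tuple[str, int]]]]:
    """Jackknife partitions as (id, [(ensemble label, row index), ...])."""
    if mode == "by-replicate":
        rep_ids = sorted(
            {data_P.replicates[i] for i in rows_P}
            | {data_D.replicates[i] for i in rows_D}
        )
        parts = []
        for rep in rep_ids:
            members = [("P", int(i)) for i in rows_P if data_P.replicates[i] == rep]
            members += [("D", int(i)) for i in rows_D if data_D.replicates[i] == rep]
            parts.append((rep, members))
        return parts
    # contiguous time-ordered thirds of the retained frames, per ensemble
    parts = [(f"third{k + 1}", []) for k in range(3)]
    for label, rows in (("P", rows_P), ("D", rows_D)):
        splits = np.array_split(np.asarray(rows), 3)
        for k, chunk in enumerate(splits):
            parts[k][1].extend((label, int(i)) for i in chunk)
    return parts


def run_pipeline(
    config: PipelineConfig,
    frames_P: Sequence[FrameRecord] | None = None,
    frames_D: Sequence[FrameRecord] | None = None,
) -> LRAResult:
    """Execute the full workflow; optionally write artifacts to ``out_dir``.

    Frames may be passed in memory; otherwise ``prot_path``/``deprot_path``
    are read.  Artifacts: curves.tsv (P/D/LRA ensemble pKa curves),
    pkhalf_P.tsv, pkhalf_D.tsv, lra_report.json and run_info.json.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, str(exc)) from exc

    if frames_P is None:
        if config.prot_path is None:
            raise PipelineStageError("read", "no protonated-ensemble frames given")
        frames_P = stage("read", read_frames, config.prot_path)
    if frames_D is None:
        if config.deprot_path is None:
            raise PipelineStageError("read", "no deprotonated-ensemble frames given")
        frames_D = stage("read", read_frames, config.deprot_path)

    data_P = stage("titrate", titrate_frames, frames_P, config, "P")
    data_D = stage("titrate", titrate_frames, frames_D, config, "D")
    log.info("titrated %d P frames, %d D frames", data_P.n_frames, data_D.n_frames)

    mask_P = stage("split", _population_mask, data_P, config)
    mask_D = stage("split", _population_mask, data_D, config)
    rows_P = np.flatnonzero(mask_P)
    rows_D = np.flatnonzero(mask_D)

    curve_P = stage("pool+hh", _ensemble_curve, data_P, rows_P, config)
    curve_D = stage("pool+hh", _ensemble_curve, data_D, rows_D, config)
    curve_lra = stage("lra", lra_average, curve_P, curve_D)
    inter = stage("intersect", macroscopic_pka, curve_lra)

    mode = config.jackknife_mode
    if mode == "auto":
        mode = "thirds" if config.population != "all" else "by-replicate"
    parts = _partitions(data_P, data_D, rows_P, rows_D, mode)

    def estimator(kept: list[tuple[str, int]]) -> float:
        kp = np.array([i for lab, i in kept if lab == "P"], dtype=int)
        kd = np.array([i for lab, i in kept if lab == "D"], dtype=int)
        return _estimate(data_P, data_D, kp, kd, config).pka_macro

    se, loo = stage("jackknife", jackknife_se, parts, estimator)

    result = LRAResult(
        pka_macro=inter.pka_macro, ph_star=inter.ph_star, se=se,
        leave_one_out=loo, n_frames_P=int(len(rows_P)), n_frames_D=int(len(rows_D)),
        boundary_flag=inter.boundary, multiple_flag=inter.multiple,
        population=config.population,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stage("write", write_ensemble_curves,
              {"P": curve_P, "D": curve_D, "LRA": curve_lra}, out / "curves.tsv")
        stage("write", write_pkhalf_table, data_P.pkhalf_records,
              out / "pkhalf_P.tsv", "P")
        stage("write", write_pkhalf_table, data_D.pkhalf_records,
              out / "pkhalf_D.tsv", "D")
        stage("write", write_lra_report, result, out / "lra_report.json")
        run_info = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "method": config.method,
            "site": config.site,
            "grid": {"ph_min": config.ph_min, "ph_max": config.ph_max,
                     "step": config.ph_step},
            "population": config.population,
            "jackknife_mode": mode,
            "n_frames_total": data_P.n_frames + data_D.n_frames,
            "n_frames_retained": int(len(rows_P) + len(rows_D)),
            "n_undefined_hh_points": {
                "P": int(np.isnan(curve_P.pka_values).sum()),
                "D": int(np.isnan(curve_D.pka_values).sum()),
                "LRA": int(np.isnan(curve_lra.pka_values).sum()),
            },
        }
        with open(out / "run_info.json", "w") as fh:
            json.dump(run_info, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
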