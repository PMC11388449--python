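"""Readers and writers for the package's plain-text interchange formats.

Frames (per-conformation titration models) travel as JSON-lines; curves and
pK_half series as TSV with 6-decimal floats; reports as JSON; residue maps
and activation-index configuration as YAML.  Structure/trajectory loading is
delegated to MDAnalysis and imported lazily so the numeric pipeline has no
hard dependency on it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from protolra.errors import InputError, ParseError
from protolra.geometry import A100Config, BWMap, StructureFrame
from protolra.lra import EnsembleCurve, LRAResult
from protolra.titration import (
    PhGrid,
    PkHalfRecord,
    TitrationCurve,
    TitrationModel,
    TitrationSite,
)

FLOAT_FMT = "{:.6f}"


@dataclass
class FrameRecord:
    """One trajectory frame: metadata plus its titration model."""

    frame_id: str
    replicate: str
    time_ps: float
    ensemble: str  # "P" | "D"
    model: TitrationModel

    def __post_init__(self):
        if self.ensemble not in ("P", "D"):
            raise InputError(f"ensemble must be 'P' or 'D', got {self.ensemble!r}")


# ---------------------------------------------------------------------------
# frames (JSON-lines)
# ---------------------------------------------------------------------------

def _model_to_obj(rec: FrameRecord) -> dict:
    triplets = []
    w = rec.model.w
    for i in range(rec.model.n_sites):
        for j in range(i + 1, rec.model.n_sites):
            if w[i, j] != 0.0:
                triplets.append([i, j, w[i, j]])
    return {
        "frame_id": rec.frame_id,
        "replicate": rec.replicate,
        "time_ps": rec.time_ps,
        "ensemble": rec.ensemble,
        "sites": [
            {"id": s.id, "pkint": s.pkint, "polarity": s.polarity}
            for s in rec.model.sites
        ],
        "w": triplets,
    }


def write_frames(records: Iterable[FrameRecord], path: str | Path) -> None:
    """Write frame records as JSON-lines (one object per frame)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(_model_to_obj(rec), sort_keys=True) + "\n")


def read_frames(path: str | Path) -> list[FrameRecord]:
    """Read and validate a JSON-lines frame file.

    Coupling triplets are sparse upper-triangle ``[i, j, value]`` entries
    (0-based); giving both (i, j) and (j, i) with different values is a
    symmetry violation.  Parse errors carry the 1-based line number.
    """
    records: list[FrameRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"malformed JSON: {exc}", line=lineno) from None
            try:
                records.append(_obj_to_record(obj))
            except (InputError, KeyError, TypeError) as exc:
                raise ParseError(str(exc), line=lineno) from None
    if not records:
        warnings.warn(f"{path}: empty frame file", UserWarning, stacklevel=2)
    return records


def _obj_to_record(obj: dict) -> FrameRecord:
    sites = [
        TitrationSite(id=str(s["id"]), pkint=float(s["pkint"]),
                      polarity=str(s["polarity"]))
        for s in obj["sites"]
    ]
    n = len(sites)
    w = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for trip in obj.get("w", []):
        i, j, val = int(trip[0]), int(trip[1]), float(trip[2])
        if i == j:
            raise InputError(f"diagonal coupling ({i}, {j}) not allowed")
        if not (0 <= i < n and 0 <= j < n):
            raise InputError(f"coupling indices ({i}, {j}) out of range for {n} sites")
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != val:
            raise InputError(
                f"asymmetric couplings for pair {key}: {seen[key]} vs {val}"
            )
        seen[key] = val
        w[key[0], key[1]] = w[key[1], key[0]] = val
    return FrameRecord(
        frame_id=str(obj["frame_id"]),
        replicate=str(obj["replicate"]),
        time_ps=float(obj["time_ps"]),
        ensemble=str(obj["ensemble"]),
        model=TitrationModel(sites=sites, w=w),
    )


# ---------------------------------------------------------------------------
# titration curves (TSV)
# ---------------------------------------------------------------------------

def write_curve(curve: TitrationCurve, path: str | Path) -> None:
    """TSV: header ``ph`` then one column per site id, 6-decimal floats."""
    with open(path, "w") as fh:
        fh.write("ph\t" + "\t".join(curve.site_ids) + "\n")
        for k, ph in enumerate(curve.grid.values):
            row = [FLOAT_FMT.format(ph)]
            row += [FLOAT_FMT.format(curve.protonation[i, k])
                    for i in range(len(curve.site_ids))]
            fh.write("\t".join(row) + "\n")


def read_curve(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Return (ph values, site ids, protonation matrix of shape (sites, ph))."""
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if not header or header[0] != "ph":
            raise ParseError("curve TSV must start with a 'ph' column", line=1)
        site_ids = header[1:]
        ph, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.strip().split("\t")
            if len(parts) != len(header):
                raise ParseError(f"expected {len(header)} columns", line=lineno)
            ph.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    return np.array(ph), site_ids, np.array(rows).T


# ---------------------------------------------------------------------------
# pK_half tables (TSV)
# ---------------------------------------------------------------------------

def write_pkhalf_table(
    records: Sequence[PkHalfRecord], path: str | Path, system: str = "system"
) -> None:
    """TSV columns: system, replicate, time_ps, pkhalf (empty = undefined)."""
    with open(path, "w") as fh:
        fh.write("system\treplicate\ttime_ps\tpkhalf\n")
        for r in records:
            pk = "" if r.pkhalf is None else FLOAT_FMT.format(r.pkhalf)
            fh.write(f"{system}\t{r.replicate_id}\t{FLOAT_FMT.format(r.time_ps)}\t{pk}\n")


def read_pkhalf_table(path: str | Path) -> list[PkHalfRecord]:
    records: list[PkHalfRecord] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["system", "replicate", "time_ps", "pkhalf"]
        if header != expected:
            raise ParseError(f"pkhalf TSV header must be {expected}, got {header}", line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError("expected 4 columns", line=lineno)
            _, replicate, time_ps, pk = parts
            records.append(PkHalfRecord(
                frame_id=f"{replicate}:{time_ps}",
                replicate_id=replicate,
                time_ps=float(time_ps),
                pkhalf=float(pk) if pk.strip() else None,
            ))
    return records


# ---------------------------------------------------------------------------
# LRA report (JSON + curves TSV)
# ---------------------------------------------------------------------------

def write_lra_report(result: LRAResult, path: str | Path) -> None:
    obj = {
        "pka_macro": result.pka_macro,
        "ph_star": result.ph_star,
        "se": result.se,
        "leave_one_out": [[pid, theta] for pid, theta in result.leave_one_out],
        "n_frames_P": result.n_frames_P,
        "n_frames_D": result.n_frames_D,
        "flags": {
            "boundary": result.boundary_flag,
            "multiple_intersections": result.multiple_flag,
            "population": result.population,
        },
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_ensemble_curves(
    curves: dict[str, EnsembleCurve], path: str | Path
) -> None:
    """TSV of the P, D and LRA ensemble pKa curves (empty cell = undefined)."""
    labels = ["P", "D", "LRA"]
    grid = next(iter(curves.values())).grid
    with open(path, "w") as fh:
        fh.write("ph\tpka_P\tpka_D\tpka_LRA\n")
        for k, ph in enumerate(grid.values):
            row = [FLOAT_FMT.format(ph)]
            for lab in labels:
                v = curves[lab].pka_values[k]
                row.append("" if math.isnan(v) else FLOAT_FMT.format(v))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# YAML configuration (BW map, A100)
# ---------------------------------------------------------------------------

def read_bw_map(path: str | Path) -> BWMap:
    """YAML: ``receptor: <name>`` and ``entries: {code: {chain, resid}}``."""
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    try:
        entries = {
            str(code): (str(spec["chain"]), int(spec["resid"]))
            for code, spec in obj["entries"].items()
        }
        return BWMap(receptor=str(obj.get("receptor", "receptor")), entries=entries)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"invalid BW map: {exc}") from None


def write_bw_map(bw_map: BWMap, path: str | Path) -> None:
    obj = {
        "receptor": bw_map.receptor,
        "entries": {
            code: {"chain": chain, "resid": resid}
            for code, (chain, resid) in bw_map.entries.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_a100_config(path: str | Path) -> A100Config:
    """YAML: distance_pairs (5 two-code lists), coefficients, intercept, thresholds."""
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    try:
        thresholds = obj.get("thresholds", {})
        return A100Config(
            distance_pairs=[tuple(p) for p in obj["distance_pairs"]],
            coefficients=[float(c) for c in obj["coefficients"]],
            intercept=float(obj.get("intercept", 0.0)),
            inactive_below=float(thresholds.get("inactive_below", 0.0)),
            active_above=float(thresholds.get("active_above", 55.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"invalid A100 config: {exc}") from None


# ---------------------------------------------------------------------------
# structures and trajectories (via MDAnalysis, lazy)
# ---------------------------------------------------------------------------

def _require_mda():
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "structure/trajectory I/O requires the optional MDAnalysis dependency"
        ) from exc
    return mda


def _universe_to_frame(universe, frame_id: str, time_ps: float) -> StructureFrame:
    atoms = universe.atoms
    chains = getattr(atoms, "chainIDs", None)
    if chains is None or all(not str(c).strip() for c in chains):
        chains = atoms.segids
    return StructureFrame(
        names=[str(n) for n in atoms.names],
        resnames=[str(r) for r in atoms.resnames],
        resids=atoms.resids,
        chains=[str(c).strip() or "A" for c in chains],
        coords=atoms.positions.astype(float),
        masses=atoms.masses.astype(float),
        frame_id=frame_id,
        time_ps=time_ps,
    )


def load_structure(path: str | Path) -> StructureFrame:
    """Load a single-model structure file (PDB/GRO/...) into a StructureFrame."""
    mda = _require_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(str(path))
    return _universe_to_frame(u, frame_id=Path(path).stem, time_ps=0.0)


def iter_trajectory(
    topology: str | Path, trajectory: str | Path | None = None
) -> Iterator[StructureFrame]:
    """Yield one StructureFrame per saved snapshot of a trajectory."""
    mda = _require_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory is None:
            u = mda.Universe(str(topology))
        else:
            u = mda.Universe(str(topology), str(trajectory))
    for k, ts in enumerate(u.trajectory):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            time_ps = float(getattr(ts, "time", 0.0) or 0.0)
        yield _universe_to_frame(u, frame_id=f"frame{k:06d}", time_ps=time_ps)


def write_pdb(frame: StructureFrame, path: str | Path) -> None:
    """Write a StructureFrame as a minimal PDB file (via MDAnalysis)."""
    mda = _require_mda()
    n = frame.n_atoms
    resid_keys = list(dict.fromkeys(
        (str(c), int(r)) for c, r in zip(frame.chains, frame.resids)
    ))
    res_index = {key: i for i, key in enumerate(resid_keys)}
    atom_res = [res_index[(str(c), int(r))] for c, r in zip(frame.chains, frame.resids)]
    seg_keys = list(dict.fromkeys(str(c) for c, _ in resid_keys))
    seg_index = {key: i for i, key in enumerate(seg_keys)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n, n_residues=len(resid_keys), n_segments=len(seg_keys),
            atom_resindex=atom_res,
            residue_segindex=[seg_index[c] for c, _ in resid_keys],
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(x) for x in frame.names])
        u.add_TopologyAttr("masses", frame.masses)
        res_names, res_ids = [], []
        for c, r in resid_keys:
            sel = [(str(cc), int(rr)) == (c, r)
                   for cc, rr in zip(frame.chains, frame.resids)]
            res_names.append(str(frame.resnames[np.flatnonzero(sel)[0]]))
            res_ids.append(r)
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", res_ids)
        u.add_TopologyAttr("segids", seg_keys)
        u.add_TopologyAttr("chainIDs", [str(c) for c in frame.chains])
        u.atoms.positions = frame.coords
        u.atoms.write(str(path))
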