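"""Activation-state metrics on structures addressed by Ballesteros-Weinstein codes.

All coordinates are Angstrom, residue numbers are 1-based as in the source
files, and a :class:`BWMap` translates generic helix.position codes (e.g.
``"2.50"``) to (chain, residue number) pairs for a specific receptor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from protolra.errors import BWLookupError, InputError, StructureError

BACKBONE_ATOMS = ("N", "CA", "C", "O")
NPXXY_CODES = ("7.49", "7.50", "7.51", "7.52", "7.53")

#: second side-chain dihedral (chi2) atom quadruples by residue name
CHI2_ATOMS = {
    "ASP": ("CA", "CB", "CG", "OD1"),
    "ASN": ("CA", "CB", "CG", "OD1"),
    "GLU": ("CA", "CB", "CG", "CD"),
    "GLN": ("CA", "CB", "CG", "CD"),
    "LYS": ("CA", "CB", "CG", "CD"),
    "ARG": ("CA", "CB", "CG", "CD"),
    "PRO": ("CA", "CB", "CG", "CD"),
    "MET": ("CA", "CB", "CG", "SD"),
    "LEU": ("CA", "CB", "CG", "CD1"),
    "PHE": ("CA", "CB", "CG", "CD1"),
    "TYR": ("CA", "CB", "CG", "CD1"),
    "TRP": ("CA", "CB", "CG", "CD1"),
    "HIS": ("CA", "CB", "CG", "ND1"),
    "HSD": ("CA", "CB", "CG", "ND1"),
    "HSE": ("CA", "CB", "CG", "ND1"),
    "ILE": ("CA", "CB", "CG1", "CD1"),
}


def _is_hydrogen(name: str) -> bool:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() == "H"


@dataclass
class StructureFrame:
    """One structure snapshot as flat per-atom arrays."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    masses: np.ndarray
    frame_id: str = "frame"
    time_ps: float = 0.0

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.names)
        if self.coords.shape != (n, 3):
            raise InputError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise InputError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue(self, chain: str, resid: int) -> "ResidueView":
        mask = (self.chains == chain) & (self.resids == resid)
        if not mask.any():
            raise StructureError(
                f"residue {chain}/{resid} absent from frame {self.frame_id!r}"
            )
        return ResidueView(self, np.flatnonzero(mask))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureFrame":
        """Copy with coordinates mapped through x -> R x + t."""
        out = StructureFrame(
            names=self.names, resnames=self.resnames, resids=self.resids,
            chains=self.chains, coords=self.coords @ np.asarray(rotation).T + translation,
            masses=self.masses, frame_id=self.frame_id, time_ps=self.time_ps,
        )
        return out


@dataclass
class ResidueView:
    """Atoms of one residue inside a :class:`StructureFrame`."""

    frame: StructureFrame
    indices: np.ndarray

    @property
    def resname(self) -> str:
        return str(self.frame.resnames[self.indices[0]])

    @property
    def chain(self) -> str:
        return str(self.frame.chains[self.indices[0]])

    @property
    def resid(self) -> int:
        return int(self.frame.resids[self.indices[0]])

    @property
    def atom_names(self) -> list[str]:
        return [str(self.frame.names[i]) for i in self.indices]

    def atom(self, name: str) -> np.ndarray:
        for i in self.indices:
            if self.frame.names[i] == name:
                return self.frame.coords[i]
        raise StructureError(
            f"atom {name!r} missing in residue {self.chain}/{self.resid} "
            f"({self.resname})"
        )

    def has_atom(self, name: str) -> bool:
        return any(self.frame.names[i] == name for i in self.indices)

    def sidechain_indices(self) -> np.ndarray:
        keep = [
            i for i in self.indices
            if self.frame.names[i] not in ("N", "CA", "C", "O", "OXT")
            and not _is_hydrogen(str(self.frame.names[i]))
        ]
        return np.array(keep, dtype=int)


@dataclass
class BWMap:
    """Ballesteros-Weinstein code -> (chain, residue number) for one receptor."""

    receptor: str
    entries: dict[str, tuple[str, int]]

    def __post_init__(self):
        self.entries = {
            str(code): (str(chain), int(resid))
            for code, (chain, resid) in self.entries.items()
        }

    def codes(self) -> list[str]:
        return list(self.entries)

    def lookup(self, code: str) -> tuple[str, int]:
        try:
            return self.entries[code]
        except KeyError:
            raise BWLookupError(
                f"BW code {code!r} not in map for receptor {self.receptor!r}"
            ) from None


@dataclass
class A100Config:
    """Five-distance linear activation index with classification thresholds.

    The five interhelical distance pairs and their weights are receptor
    calibration data and must be supplied (e.g. via YAML); only the
    classification thresholds have universal defaults: values below
    ``inactive_below`` are inactive, values above ``active_above`` are
    active, and everything in between (inclusive) is intermediate.
    """

    distance_pairs: list[tuple[str, str]]
    coefficients: list[float]
    intercept: float = 0.0
    inactive_below: float = 0.0
    active_above: float = 55.0

    def __post_init__(self):
        if len(self.distance_pairs) != 5 or len(self.coefficients) != 5:
            raise InputError(
                "A100 config requires exactly five distance pairs and coefficients"
            )
        if not self.inactive_below < self.active_above:
            raise InputError("inactive_below must be < active_above")


@dataclass
class ActivationMetrics:
    """Per-frame activation metrics (distances in A, areas in A^2)."""

    frame_id: str
    time_ps: float
    tm3_tm6_A: float
    tm3_tm7_ca_A: float
    npxxy_rmsd_A: float
    a100: float
    state: str
    ts_d1_A: float
    ts_d2_A: float
    na_pocket_area_A2: float
    hlock_area_A2: float
    tm3_tm7_sc_A: float
    chi2_deg: float


def resolve_bw(bw_map: BWMap, frame: StructureFrame, code: str) -> ResidueView:
    """Residue addressed by a BW code; fails loudly when absent."""
    chain, resid = bw_map.lookup(code)
    return frame.residue(chain, resid)


def ca_distance(frame: StructureFrame, code_i: str, code_j: str, bw_map: BWMap) -> float:
    """Euclidean distance between the Calpha atoms of two mapped residues."""
    a = resolve_bw(bw_map, frame, code_i).atom("CA")
    b = resolve_bw(bw_map, frame, code_j).atom("CA")
    return float(np.linalg.norm(a - b))


def sidechain_com(frame: StructureFrame, residue: ResidueView) -> np.ndarray:
    """Mass-weighted centre of the heavy side-chain atoms (beyond Calpha)."""
    idx = residue.sidechain_indices()
    if len(idx) == 0:
        raise StructureError(
            f"residue {residue.chain}/{residue.resid} ({residue.resname}) has no "
            "heavy side-chain atoms (glycine?)"
        )
    m = frame.masses[idx]
    return (frame.coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def heron_area(a: float, b: float, c: float, tol: float = 1e-9) -> float:
    """Triangle area from its three side lengths (Heron's formula)."""
    if a < 0 or b < 0 or c < 0:
        raise InputError("side lengths must be non-negative")
    for x, y, z in ((a, b, c), (b, c, a), (c, a, b)):
        if x > y + z + tol:
            raise InputError(
                f"side lengths ({a}, {b}, {c}) violate the triangle inequality"
            )
    s = 0.5 * (a + b + c)
    radicand = s * (s - a) * (s - b) * (s - c)
    return math.sqrt(max(radicand, 0.0))


def pocket_area(frame: StructureFrame, codes: Sequence[str], bw_map: BWMap) -> float:
    """Heron area of the triangle spanned by three side-chain centres of mass."""
    if len(codes) != 3:
        raise InputError(f"pocket_area needs exactly three BW codes, got {len(codes)}")
    coms = [sidechain_com(frame, resolve_bw(bw_map, frame, c)) for c in codes]
    d01 = float(np.linalg.norm(coms[0] - coms[1]))
    d02 = float(np.linalg.norm(coms[0] - coms[2]))
    d12 = float(np.linalg.norm(coms[1] - coms[2]))
    return heron_area(d01, d02, d12)


def _backbone_coords(frame: StructureFrame, bw_map: BWMap, codes: Iterable[str]) -> np.ndarray:
    rows = []
    for code in codes:
        res = resolve_bw(bw_map, frame, code)
        for name in BACKBONE_ATOMS:
            rows.append(res.atom(name))
    return np.array(rows)


def npxxy_rmsd(
    frame: StructureFrame,
    reference: StructureFrame,
    bw_map: BWMap,
    fit_codes: Sequence[str] | None = None,
    motif_codes: Sequence[str] = NPXXY_CODES,
) -> float:
    """Backbone RMSD of the NPxxY motif after superposition on ``fit_codes``.

    The frame is least-squares fitted onto the reference over the backbone
    atoms of ``fit_codes`` (default: every code in the map), then the RMSD is
    taken over the motif backbone atoms only.  Fitting on the surrounding
    helices rather than the motif itself keeps the motif displacement visible.
    """
    if fit_codes is None:
        fit_codes = bw_map.codes()
    mov_fit = _backbone_coords(frame, bw_map, fit_codes)
    ref_fit = _backbone_coords(reference, bw_map, fit_codes)
    if mov_fit.shape != ref_fit.shape:
        raise StructureError("fit selections differ in atom count")
    mov_centroid = mov_fit.mean(axis=0)
    ref_centroid = ref_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_fit - ref_centroid, mov_fit - mov_centroid)
    mov_motif = _backbone_coords(frame, bw_map, motif_codes)
    ref_motif = _backbone_coords(reference, bw_map, motif_codes)
    moved = rot.apply(mov_motif - mov_centroid) + ref_centroid
    return float(np.sqrt(np.mean(np.sum((moved - ref_motif) ** 2, axis=1))))


def a100_index(
    frame: StructureFrame, cfg: A100Config, bw_map: BWMap
) -> tuple[float, str]:
    """Linear activation index over five interhelical Calpha distances.

    Classification: value < ``inactive_below`` -> ``inactive``;
    value > ``active_above`` -> ``active``; otherwise ``intermediate``
    (both thresholds inclusive on the intermediate side).
    """
    value = cfg.intercept
    for (ci, cj), coeff in zip(cfg.distance_pairs, cfg.coefficients):
        value += coeff * ca_distance(frame, ci, cj, bw_map)
    return float(value), classify_a100(value, cfg)


def classify_a100(value: float, cfg: A100Config | None = None) -> str:
    lo = cfg.inactive_below if cfg is not None else 0.0
    hi = cfg.active_above if cfg is not None else 55.0
    if value < lo:
        return "inactive"
    if value > hi:
        return "active"
    return "intermediate"


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, IUPAC convention, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0 or not n1.any() or not n2.any():
        raise InputError("degenerate dihedral: collinear atoms")
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    ang = math.degrees(math.atan2(y, float(np.dot(n1, n2))))
    if ang <= -180.0:
        ang += 360.0
    return ang


def chi2_torsion(frame: StructureFrame, residue: ResidueView) -> float:
    """Second side-chain torsion (for Asp: CA-CB-CG-OD1), degrees in (-180, 180]."""
    resname = residue.resname.upper()
    try:
        atoms = CHI2_ATOMS[resname]
    except KeyError:
        raise StructureError(f"no chi2 definition for residue type {resname!r}") from None
    coords = [residue.atom(name) for name in atoms]
    return dihedral(*coords)


def frame_count(
    duration_ps: float, interval_ps: float, replicates: int = 1, include_t0: bool = True
) -> int:
    """Number of snapshots saved at a fixed interval over a trajectory.

    For example, 100 ns sampled every 100 ps with the initial frame included
    gives 1001 snapshots per replicate.
    """
    if interval_ps <= 0:
        raise InputError("interval_ps must be positive")
    if duration_ps < 0:
        raise InputError("duration_ps must be >= 0")
    ratio = duration_ps / interval_ps
    n = round(ratio)
    if abs(ratio - n) > 1e-9:
        raise InputError(
            f"interval {interval_ps} ps does not divide duration {duration_ps} ps"
        )
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    return int(replicates * (n + 1 if include_t0 else n))


def compute_metrics(
    frame: StructureFrame,
    reference: StructureFrame,
    bw_map: BWMap,
    a100_cfg: A100Config,
    chi2_code: str = "2.50",
    fit_codes: Sequence[str] | None = None,
) -> ActivationMetrics:
    """All activation metrics for one frame (one output row of ``metrics``)."""
    value, state = a100_index(frame, a100_cfg, bw_map)
    return ActivationMetrics(
        frame_id=frame.frame_id,
        time_ps=frame.time_ps,
        tm3_tm6_A=ca_distance(frame, "3.50", "6.34", bw_map),
        tm3_tm7_ca_A=ca_distance(frame, "3.50", "7.53", bw_map),
        npxxy_rmsd_A=npxxy_rmsd(frame, reference, bw_map, fit_codes=fit_codes),
        a100=value,
        state=state,
        ts_d1_A=ca_distance(frame, "3.40", "6.48", bw_map),
        ts_d2_A=ca_distance(frame, "5.51", "6.44", bw_map),
        na_pocket_area_A2=pocket_area(frame, ("2.50", "3.39", "7.49"), bw_map),
        hlock_area_A2=pocket_area(frame, ("3.43", "6.40", "6.41"), bw_map),
        tm3_tm7_sc_A=float(np.linalg.norm(
            sidechain_com(frame, resolve_bw(bw_map, frame, "3.43"))
            - sidechain_com(frame, resolve_bw(bw_map, frame, "7.53"))
        )),
        chi2_deg=chi2_torsion(frame, resolve_bw(bw_map, frame, chi2_code)),
    )
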