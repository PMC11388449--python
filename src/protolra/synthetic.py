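"""Synthetic conformational-titration ensembles and toy structures.

``simulate_ensemble`` emulates the statistical structure of fixed-protonation
MD output: per replicate, a Markov chain over conformational substates with
tunable persistence, a per-frame intrinsic pKa of the target site drawn
around the substate mean, and fixed neighbour sites coupled to the target.
The generator's parameters define a joint (substate x protonation-microstate)
partition function whose exact half-titration point is the ground truth that
the LRA pipeline is expected to approximate; that brute-force reference is
``oracle_macroscopic_pka``.

Consistency note: for an equilibrium interpretation, the substate occupancies
of the protonated ensemble are determined by the deprotonated occupancies and
the substate pKas (occ_P ∝ occ_D * 10**pk).  ``occupancy_P="consistent"``
(the default) derives them; explicit occupancies are allowed to emulate
non-equilibrium or under-sampled MD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from protolra.errors import InputError, ProtolraError
from protolra.geometry import BWMap, StructureFrame
from protolra.io import FrameRecord
from protolra.titration import (
    ANIONIC,
    LN10,
    PhGrid,
    PkHalfRecord,
    TitrationModel,
    TitrationSite,
    _enumerate_states,
)


@dataclass(frozen=True)
class NeighborSite:
    """A fixed titratable neighbour coupled to the target site."""

    id: str
    pkint: float
    polarity: str = ANIONIC
    coupling: float = 0.0  # w(target, neighbour), pK units


@dataclass
class SubstateSpec:
    """One conformational substate of the generator."""

    label: str
    pkint_mean: float
    pkint_sigma: float = 0.0
    neighbors: list[NeighborSite] = field(default_factory=list)

    def __post_init__(self):
        if self.pkint_sigma < 0:
            raise InputError("pkint_sigma must be >= 0")


@dataclass
class SyntheticEnsembleSpec:
    """Parameters of a two-ensemble (P and D) synthetic trajectory set."""

    states: list[SubstateSpec]
    occupancy_D: Sequence[float]
    occupancy_P: Sequence[float] | str = "consistent"
    markov_persistence: float = 0.0
    n_replicates: int = 3
    frames_per_replicate: int = 1001
    interval_ps: float = 100.0
    target_site_id: str = "Asp2.50"
    target_polarity: str = ANIONIC
    seed: int = 0

    def __post_init__(self):
        if not self.states:
            raise InputError("need at least one substate")
        if not (0.0 <= self.markov_persistence <= 1.0):
            raise InputError("markov_persistence must be in [0, 1]")
        self.occupancy_D = self._check_occ(self.occupancy_D, "occupancy_D")
        if isinstance(self.occupancy_P, str):
            if self.occupancy_P != "consistent":
                raise InputError("occupancy_P must be probabilities or 'consistent'")
            self.occupancy_P = consistent_occupancy_P(
                self.occupancy_D, [s.pkint_mean for s in self.states]
            )
        else:
            self.occupancy_P = self._check_occ(self.occupancy_P, "occupancy_P")
        if self.n_replicates < 1 or self.frames_per_replicate < 1:
            raise InputError("need >= 1 replicate and >= 1 frame per replicate")

    def _check_occ(self, occ, name) -> np.ndarray:
        occ = np.asarray(occ, dtype=float)
        if occ.shape != (len(self.states),):
            raise InputError(f"{name} length must match number of substates")
        if np.any(occ < 0) or not math.isclose(occ.sum(), 1.0, abs_tol=1e-9):
            raise InputError(f"{name} must be non-negative and sum to 1")
        return occ


def consistent_occupancy_P(occupancy_D, pkints) -> np.ndarray:
    """Protonated-ensemble occupancies implied by equilibrium: occ_D * 10**pk."""
    occ_D = np.asarray(occupancy_D, dtype=float)
    pk = np.asarray(pkints, dtype=float)
    logw = np.where(occ_D > 0, np.log10(np.maximum(occ_D, 1e-300)) + pk, -np.inf)
    w = 10.0 ** (logw - logw.max())
    return w / w.sum()


@dataclass
class JointModelOracle:
    """Ground-truth joint (substate, microstate) model for the target site.

    ``energies_D`` are substate conformational free energies with the target
    deprotonated (pK units); the protonated-side energies are fixed by
    thermodynamic consistency, E_P = E_D - pkint, and stored for reference.
    """

    substate_labels: list[str]
    energies_D: list[float]
    target_pkints: list[float]
    target_polarity: str = ANIONIC
    neighbors: list[list[NeighborSite]] = field(default_factory=list)

    def __post_init__(self):
        k = len(self.substate_labels)
        if not (len(self.energies_D) == len(self.target_pkints) == k):
            raise InputError("oracle fields must have one entry per substate")
        if not all(np.isfinite(self.energies_D)) or not all(
            np.isfinite(self.target_pkints)
        ):
            raise InputError("oracle energies and pkints must be finite")
        if not self.neighbors:
            self.neighbors = [[] for _ in range(k)]

    @property
    def energies_P(self) -> list[float]:
        return [e - pk for e, pk in zip(self.energies_D, self.target_pkints)]

    def substate_model(self, idx: int, target_site_id: str = "target") -> TitrationModel:
        neigh = self.neighbors[idx]
        sites = [TitrationSite(target_site_id, self.target_pkints[idx],
                               self.target_polarity)]
        n = len(neigh) + 1
        w = np.zeros((n, n))
        for j, nb in enumerate(neigh, start=1):
            sites.append(TitrationSite(nb.id, nb.pkint, nb.polarity))
            w[0, j] = w[j, 0] = nb.coupling
        return TitrationModel(sites=sites, w=w)


def oracle_from_spec(spec: SyntheticEnsembleSpec) -> JointModelOracle:
    """Ground-truth oracle implied by a generator spec (D-side occupancies)."""
    occ = np.asarray(spec.occupancy_D, dtype=float)
    if np.any(occ <= 0):
        raise InputError("oracle requires strictly positive occupancy_D")
    energies = (-np.log10(occ)).tolist()
    return JointModelOracle(
        substate_labels=[s.label for s in spec.states],
        energies_D=energies,
        target_pkints=[s.pkint_mean for s in spec.states],
        target_polarity=spec.target_polarity,
        neighbors=[list(s.neighbors) for s in spec.states],
    )


def oracle_macroscopic_pka(
    oracle: JointModelOracle, grid: PhGrid, max_substates: int = 4
) -> float:
    """Exact macroscopic pKa of the target site by joint enumeration.

    Builds the Boltzmann sum over every (substate, protonation microstate)
    pair at each grid pH — weight 10**-(E_D(substate) + G_micro) — takes the
    exact average protonation of the target site, and interpolates the pH
    where it crosses one half.
    """
    n_sub = len(oracle.substate_labels)
    if n_sub > max_substates:
        raise InputError(f"{n_sub} substates exceeds oracle cap {max_substates}")
    ph = grid.values
    log_terms = []   # log10 weights, rows: (substate, state) pairs
    target_prot = []  # target-site protonation per row
    for idx in range(n_sub):
        model = oracle.substate_model(idx)
        states = _enumerate_states(model.n_sites)
        q = states + model.charge_offsets[None, :]
        pair = 0.5 * np.einsum("si,ij,sj->s", q, model.w, q)
        base = oracle.energies_D[idx] + pair - states @ model.pkints
        n_prot = states.sum(axis=1)
        # log10 weight = -(base + n_prot * pH)
        log_terms.append(-(base[:, None] + n_prot[:, None] * ph[None, :]))
        target_prot.append(states[:, 0])
    logw = np.concatenate(log_terms, axis=0) * LN10
    s_t = np.concatenate(target_prot)
    log_z = logsumexp(logw, axis=0)
    # average protonation; where no protonated state contributes, b-sum is -inf
    with np.errstate(divide="ignore"):
        log_num = logsumexp(logw, axis=0, b=s_t[:, None])
    p = np.exp(log_num - log_z)
    d = p - 0.5
    for k in range(len(ph)):
        if d[k] == 0.0:
            return float(ph[k])
        if k + 1 < len(ph) and d[k] * d[k + 1] < 0.0:
            frac = d[k] / (d[k] - d[k + 1])
            return float(ph[k] + frac * (ph[k + 1] - ph[k]))
    raise ProtolraError(
        "target-site protonation does not cross 0.5 within the pH grid"
    )


@dataclass
class SyntheticEnsemble:
    """Output of :func:`simulate_ensemble`: frames plus ground-truth sidecar."""

    spec: SyntheticEnsembleSpec
    frames_P: list[FrameRecord]
    frames_D: list[FrameRecord]
    substates_P: dict[str, list[str]]  # replicate -> per-frame substate labels
    substates_D: dict[str, list[str]]
    oracle: JointModelOracle | None

    def sidecar(self) -> dict:
        obj = {
            "seed": self.spec.seed,
            "target_site_id": self.spec.target_site_id,
            "markov_persistence": self.spec.markov_persistence,
            "occupancy_P": list(map(float, self.spec.occupancy_P)),
            "occupancy_D": list(map(float, self.spec.occupancy_D)),
            "substates": {
                "P": self.substates_P,
                "D": self.substates_D,
            },
            "states": [
                {
                    "label": s.label,
                    "pkint_mean": s.pkint_mean,
                    "pkint_sigma": s.pkint_sigma,
                    "neighbors": [
                        {"id": nb.id, "pkint": nb.pkint, "polarity": nb.polarity,
                         "coupling": nb.coupling}
                        for nb in s.neighbors
                    ],
                }
                for s in self.spec.states
            ],
        }
        if self.oracle is not None:
            obj["oracle"] = {
                "substate_labels": self.oracle.substate_labels,
                "energies_D": self.oracle.energies_D,
                "energies_P": self.oracle.energies_P,
                "target_pkints": self.oracle.target_pkints,
            }
        return obj


def _markov_labels(rng, occ: np.ndarray, persistence: float, n: int) -> np.ndarray:
    """Stationary chain: stay w.p. rho, else resample from the occupancies."""
    labels = np.empty(n, dtype=int)
    labels[0] = rng.choice(len(occ), p=occ)
    for t in range(1, n):
        if rng.random() < persistence:
            labels[t] = labels[t - 1]
        else:
            labels[t] = rng.choice(len(occ), p=occ)
    return labels


def simulate_ensemble(spec: SyntheticEnsembleSpec) -> SyntheticEnsemble:
    """Generate the P and D frame sets of one synthetic system.

    Deterministic under ``spec.seed``.  The oracle sidecar is derived from
    the D-ensemble occupancies and substate mean pKas; it is omitted when an
    explicit (possibly inconsistent) ``occupancy_P`` was supplied.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * spec.n_replicates)
    frames: dict[str, list[FrameRecord]] = {"P": [], "D": []}
    substates: dict[str, dict[str, list[str]]] = {"P": {}, "D": {}}
    occ = {"P": np.asarray(spec.occupancy_P, float),
           "D": np.asarray(spec.occupancy_D, float)}
    for e_idx, ensemble in enumerate(("P", "D")):
        for rep in range(spec.n_replicates):
            rng = np.random.Generator(
                np.random.PCG64(children[e_idx * spec.n_replicates + rep])
            )
            rep_id = f"rep{rep + 1}"
            labels = _markov_labels(
                rng, occ[ensemble], spec.markov_persistence, spec.frames_per_replicate
            )
            substates[ensemble][rep_id] = [spec.states[i].label for i in labels]
            for t, sub_idx in enumerate(labels):
                sub = spec.states[sub_idx]
                pk = sub.pkint_mean + sub.pkint_sigma * rng.standard_normal()
                sites = [TitrationSite(spec.target_site_id, pk, spec.target_polarity)]
                n = len(sub.neighbors) + 1
                w = np.zeros((n, n))
                for j, nb in enumerate(sub.neighbors, start=1):
                    sites.append(TitrationSite(nb.id, nb.pkint, nb.polarity))
                    w[0, j] = w[j, 0] = nb.coupling
                frames[ensemble].append(FrameRecord(
                    frame_id=f"{ensemble}:{rep_id}:{t}",
                    replicate=rep_id,
                    time_ps=t * spec.interval_ps,
                    ensemble=ensemble,
                    model=TitrationModel(sites=sites, w=w),
                ))
    try:
        oracle = oracle_from_spec(spec)
    except InputError:
        oracle = None
    return SyntheticEnsemble(
        spec=spec, frames_P=frames["P"], frames_D=frames["D"],
        substates_P=substates["P"], substates_D=substates["D"], oracle=oracle,
    )


def simulate_pkhalf_series(
    base_level: float = 7.5,
    shift: float = -2.0,
    sigma: float = 0.2,
    n_replicates: int = 3,
    frames_per_replicate: int = 1001,
    interval_ps: float = 100.0,
    switch_frame: int = 500,
    shifted_replicates: Sequence[int] = (0, 1),
    seed: int = 0,
) -> tuple[list[PkHalfRecord], dict[str, str]]:
    """Per-replicate pK_half time series with a sustained level shift.

    Replicates listed in ``shifted_replicates`` jump from ``base_level`` to
    ``base_level + shift`` at ``switch_frame`` and stay there; Gaussian noise
    of width ``sigma`` is added throughout.  Returns the records and a
    ground-truth map frame_id -> "high"/"low" (by generating level).
    """
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[PkHalfRecord] = []
    truth: dict[str, str] = {}
    high_level = max(base_level, base_level + shift)
    for rep in range(n_replicates):
        rep_id = f"rep{rep + 1}"
        for t in range(frames_per_replicate):
            level = base_level
            if rep in shifted_replicates and t >= switch_frame:
                level = base_level + shift
            fid = f"{rep_id}:{t}"
            records.append(PkHalfRecord(
                frame_id=fid, replicate_id=rep_id, time_ps=t * interval_ps,
                pkhalf=level + sigma * rng.standard_normal(),
            ))
            truth[fid] = "high" if level == high_level else "low"
    return records, truth


# ---------------------------------------------------------------------------
# toy structures with analytically known metrics
# ---------------------------------------------------------------------------

_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}


def _mass_of(name: str) -> float:
    stripped = name.strip().lstrip("0123456789")
    return _MASS.get(stripped[:1].upper(), 12.011)


def _frame(atoms, frame_id="toy", time_ps=0.0) -> StructureFrame:
    """atoms: sequence of (chain, resid, resname, atom name, (x, y, z))."""
    return StructureFrame(
        names=[a[3] for a in atoms],
        resnames=[a[2] for a in atoms],
        resids=[a[1] for a in atoms],
        chains=[a[0] for a in atoms],
        coords=[a[4] for a in atoms],
        masses=[_mass_of(a[3]) for a in atoms],
        frame_id=frame_id,
        time_ps=time_ps,
    )


@dataclass
class ToyStructure:
    """A named fixture: frame (+ optional reference), residue map, known values."""

    name: str
    frame: StructureFrame
    bw_map: BWMap | None = None
    reference: StructureFrame | None = None
    expected: dict[str, float] = field(default_factory=dict)
    fit_codes: list[str] | None = None


def _ala(chain, resid, cb_xyz, offset=(0.0, 0.0, -5.0)):
    """Alanine whose only side-chain heavy atom (CB) sits at ``cb_xyz``."""
    base = np.asarray(cb_xyz, float) + np.asarray(offset, float)
    return [
        (chain, resid, "ALA", "N", tuple(base + (0.0, 1.0, 0.0))),
        (chain, resid, "ALA", "CA", tuple(base)),
        (chain, resid, "ALA", "C", tuple(base + (1.2, 0.0, 0.0))),
        (chain, resid, "ALA", "O", tuple(base + (1.8, 1.0, 0.0))),
        (chain, resid, "ALA", "CB", tuple(cb_xyz)),
    ]


def _asp_dihedral(od1_xyz):
    return [
        ("A", 1, "ASP", "N", (-1.0, 1.5, 0.0)),
        ("A", 1, "ASP", "CA", (0.0, 1.0, 0.0)),
        ("A", 1, "ASP", "C", (-1.0, 2.0, 1.0)),
        ("A", 1, "ASP", "O", (-1.5, 3.0, 1.0)),
        ("A", 1, "ASP", "CB", (0.0, 0.0, 0.0)),
        ("A", 1, "ASP", "CG", (1.0, 0.0, 0.0)),
        ("A", 1, "ASP", "OD1", od1_xyz),
    ]


def _backbone_res(chain, resid, resname, origin):
    o = np.asarray(origin, float)
    return [
        (chain, resid, resname, "N", tuple(o + (0.0, 1.4, 0.0))),
        (chain, resid, resname, "CA", tuple(o)),
        (chain, resid, resname, "C", tuple(o + (1.4, 0.0, 0.3))),
        (chain, resid, resname, "O", tuple(o + (1.9, 1.0, 0.8))),
    ]


def generate_toy_structure(name: str) -> ToyStructure:
    """Small structure fixtures with analytically known metric values."""
    if name == "triangle345":
        atoms = (
            _ala("A", 1, (0.0, 0.0, 0.0))
            + _ala("A", 2, (3.0, 0.0, 0.0))
            + _ala("A", 3, (0.0, 4.0, 0.0))
        )
        bw_map = BWMap("toy", {"2.50": ("A", 1), "3.39": ("A", 2), "7.49": ("A", 3)})
        return ToyStructure(name, _frame(atoms), bw_map=bw_map,
                            expected={"area_A2": 6.0})
    if name == "ca_pair_5A":
        atoms = (
            _backbone_res("A", 1, "ALA", (0.0, 0.0, 0.0))
            + _backbone_res("A", 2, "ALA", (3.0, 4.0, 0.0))
        )
        bw_map = BWMap("toy", {"3.50": ("A", 1), "6.34": ("A", 2)})
        return ToyStructure(name, _frame(atoms), bw_map=bw_map,
                            expected={"distance_A": 5.0})
    if name == "dihedral_cis":
        return ToyStructure(name, _frame(_asp_dihedral((1.0, 1.0, 0.0))),
                            expected={"chi2_deg": 0.0})
    if name == "dihedral_trans":
        return ToyStructure(name, _frame(_asp_dihedral((1.0, -1.0, 0.0))),
                            expected={"chi2_deg": 180.0})
    if name == "dihedral_90":
        return ToyStructure(name, _frame(_asp_dihedral((1.0, 0.0, 1.0))),
                            expected={"chi2_deg": 90.0})
    if name == "npxxy_shift_1A":
        scaffold_codes = ["1.50", "2.50", "3.50", "5.51", "6.30"]
        motif_codes = ["7.49", "7.50", "7.51", "7.52", "7.53"]
        origins = [(0, 0, 0), (8, 0, 2), (0, 9, 1), (7, 8, 6), (-4, 4, 9)]
        atoms = []
        entries = {}
        for i, (code, origin) in enumerate(zip(scaffold_codes, origins), start=1):
            atoms += _backbone_res("A", i, "ALA", origin)
            entries[code] = ("A", i)
        motif_origin = np.array([3.0, 3.0, 15.0])
        for j, code in enumerate(motif_codes):
            resid = 10 + j
            atoms += _backbone_res("A", resid, "ALA",
                                   motif_origin + (3.0 * j, 0.5 * j, 0.0))
            entries[code] = ("A", resid)
        reference = _frame(atoms, frame_id="reference")
        moved = _frame(atoms, frame_id="shifted")
        motif_mask = np.isin(moved.resids, np.arange(10, 10 + len(motif_codes)))
        coords = moved.coords.copy()
        coords[motif_mask] += np.array([1.0, 0.0, 0.0])
        moved.coords = coords
        return ToyStructure(
            name, moved, bw_map=BWMap("toy", entries), reference=reference,
            expected={"npxxy_rmsd_A": 1.0}, fit_codes=scaffold_codes,
        )
    if name == "toy_receptor":
        return _toy_receptor()
    raise InputError(f"unknown toy structure {name!r}")


def _asp_residue(chain, resid, cb_xyz):
    """Aspartate with a planar carboxylate; chi2 (CA-CB-CG-OD1) is 0 degrees."""
    b = np.asarray(cb_xyz, float)
    return [
        (chain, resid, "ASP", "N", tuple(b + (-1.0, 2.0, 0.0))),
        (chain, resid, "ASP", "CA", tuple(b + (0.0, 1.5, 0.0))),
        (chain, resid, "ASP", "C", tuple(b + (1.2, 2.2, 0.0))),
        (chain, resid, "ASP", "O", tuple(b + (1.4, 3.4, 0.0))),
        (chain, resid, "ASP", "CB", tuple(b)),
        (chain, resid, "ASP", "CG", tuple(b + (1.5, 0.0, 0.0))),
        (chain, resid, "ASP", "OD1", tuple(b + (2.2, 1.1, 0.0))),
        (chain, resid, "ASP", "OD2", tuple(b + (2.0, -1.2, 0.0))),
    ]


def _toy_receptor() -> ToyStructure:
    """A 14-residue pseudo-receptor carrying every code the metrics need."""
    codes = ["1.50", "2.50", "3.39", "3.40", "3.43", "3.50", "5.51",
             "6.34", "6.40", "6.41", "6.44", "6.48",
             "7.49", "7.50", "7.51", "7.52", "7.53"]
    rng = np.random.default_rng(20240817)
    atoms: list = []
    entries: dict[str, tuple[str, int]] = {}
    for i, code in enumerate(codes, start=1):
        origin = rng.uniform(-12.0, 12.0, size=3)
        if code == "2.50":
            atoms += _asp_residue("A", i, origin)
        else:
            atoms += _ala("A", i, tuple(origin))
        entries[code] = ("A", i)
    frame = _frame(atoms, frame_id="toy_receptor")
    reference = _frame(atoms, frame_id="toy_receptor_ref")
    return ToyStructure(
        "toy_receptor", frame, bw_map=BWMap("toy_receptor", entries),
        reference=reference, expected={"chi2_deg": 0.0, "npxxy_rmsd_A": 0.0},
    )
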