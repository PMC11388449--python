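"""Macroscopic pKa from two fixed-protonation ensembles.

Per-frame titration curves from the protonated (P) and deprotonated (D)
ensembles are pooled into a grand-mean protonation per pH, transformed with
the Henderson-Hasselbalch relation into pH-dependent ensemble pKa curves,
averaged point-wise across the two endpoints (the linear-response average),
and intersected with the y = x line to yield the macroscopic pKa.  Errors
come from delete-one jackknife resampling over frame partitions; bimodal
per-frame pK_half series can be split into high/low conformational
populations beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from protolra.errors import InputError
from protolra.titration import PhGrid, PkHalfRecord, TitrationCurve

ENSEMBLE_LABELS = ("P", "D", "LRA")


@dataclass
class EnsembleCurve:
    """pH-dependent ensemble pKa values; NaN marks undefined points."""

    grid: PhGrid
    pka_values: np.ndarray
    ensemble_label: str
    n_frames: int

    def __post_init__(self):
        self.pka_values = np.asarray(self.pka_values, dtype=float)
        if self.pka_values.shape != (len(self.grid),):
            raise InputError(
                f"pka_values length {self.pka_values.shape} != grid length {len(self.grid)}"
            )
        if self.ensemble_label not in ENSEMBLE_LABELS:
            raise InputError(f"ensemble_label must be one of {ENSEMBLE_LABELS}")
        if np.any(np.isinf(self.pka_values)):
            raise InputError("defined pka values must be finite (use NaN for undefined)")
        if self.n_frames <= 0:
            raise InputError("n_frames must be positive")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.pka_values)


@dataclass
class Intersection:
    """Result of intersecting an ensemble pKa curve with y = x."""

    pka_macro: float
    ph_star: float
    boundary: bool = False
    multiple: bool = False


@dataclass
class LRAResult:
    """Macroscopic pKa with jackknife error and bookkeeping."""

    pka_macro: float
    ph_star: float
    se: float
    leave_one_out: list[tuple[str, float]]
    n_frames_P: int
    n_frames_D: int
    boundary_flag: bool = False
    multiple_flag: bool = False
    population: str = "all"

    def __post_init__(self):
        if self.se < 0:
            raise InputError("se must be >= 0")


@dataclass
class PopulationSplit:
    """Two-way partition of per-frame pK_half values."""

    threshold: float
    high_frames: list[str]
    low_frames: list[str]
    method: str
    separation: float
    n_undefined: int = 0

    @property
    def unimodal_suspect(self) -> bool:
        return self.separation < 1.0


def pool_protonation(
    curves: Sequence[TitrationCurve],
    site: str,
    replicate_ids: Sequence[str] | None = None,
    weighting: str = "frames",
) -> tuple[np.ndarray, int]:
    """Pooled average protonation of ``site`` over frames, per pH point.

    The default is the grand mean with equal frame weights.  With
    ``weighting="replicates"`` (requires ``replicate_ids``) replicate means
    are averaged instead; the two coincide for equal-length replicates.
    Returns the pooled curve and the number of frames pooled.
    """
    if len(curves) == 0:
        raise InputError("cannot pool an empty list of curves")
    grid = curves[0].grid
    rows = []
    for c in curves:
        if c.grid != grid:
            raise InputError(f"grid mismatch: {c.grid} != {grid}")
        rows.append(c.site_protonation(site))
    if weighting == "frames":
        return np.mean(rows, axis=0), len(curves)
    if weighting != "replicates":
        raise InputError("weighting must be 'frames' or 'replicates'")
    if replicate_ids is None or len(replicate_ids) != len(curves):
        raise InputError("weighting='replicates' needs one replicate id per curve")
    rows = np.asarray(rows)
    rep_means = [
        rows[[i for i, r in enumerate(replicate_ids) if r == rep]].mean(axis=0)
        for rep in dict.fromkeys(replicate_ids)
    ]
    return np.mean(rep_means, axis=0), len(curves)


def hh_transform(
    pooled: np.ndarray,
    grid: PhGrid,
    ensemble_label: str,
    n_frames: int,
    epsilon: float = 1e-6,
) -> EnsembleCurve:
    """Henderson-Hasselbalch transform: pKa(pH) = pH + log10(p / (1 - p)).

    Points with pooled protonation below ``epsilon`` or above ``1 - epsilon``
    are undefined (NaN) rather than clamped, so the divergent tails never
    enter the LRA average.
    """
    p = np.asarray(pooled, dtype=float)
    if p.shape != (len(grid),):
        raise InputError(f"pooled length {p.shape} != grid length {len(grid)}")
    if np.any((p < 0) | (p > 1)):
        raise InputError("pooled protonation must lie in [0, 1]")
    ok = (p >= epsilon) & (p <= 1.0 - epsilon)
    pka = np.full(len(grid), np.nan)
    pka[ok] = grid.values[ok] + np.log10(p[ok] / (1.0 - p[ok]))
    return EnsembleCurve(grid=grid, pka_values=pka, ensemble_label=ensemble_label,
                         n_frames=n_frames)


def lra_average(curve_P: EnsembleCurve, curve_D: EnsembleCurve) -> EnsembleCurve:
    """Two-endpoint average: point-wise mean of the P and D ensemble curves.

    Undefined wherever either input is undefined (NaN propagates).
    """
    if curve_P.grid != curve_D.grid:
        raise InputError("P and D curves are on different grids")
    labels = {curve_P.ensemble_label, curve_D.ensemble_label}
    if labels != {"P", "D"}:
        raise InputError(f"expected one P and one D curve, got labels {labels}")
    pka = 0.5 * (curve_P.pka_values + curve_D.pka_values)
    return EnsembleCurve(
        grid=curve_P.grid, pka_values=pka, ensemble_label="LRA",
        n_frames=curve_P.n_frames + curve_D.n_frames,
    )


def macroscopic_pka(curve: EnsembleCurve) -> Intersection:
    """Intersection of the ensemble pKa curve with the y = x line.

    Finds a sign change of f(pH) = pKa(pH) - pH between consecutive defined
    grid points and interpolates the root linearly.  With no sign change the
    defined point minimizing |f| is returned with ``boundary`` set; with
    several sign changes the root bracketed by the smallest |f| values wins
    and ``multiple`` is set.
    """
    defined = np.flatnonzero(curve.defined)
    if len(defined) < 2:
        raise InputError("need at least 2 defined points to intersect with y = x")
    ph = curve.grid.values[defined]
    f = curve.pka_values[defined] - ph
    roots: list[tuple[float, float]] = []  # (bracket score, root)
    for k in range(len(ph) - 1):
        if f[k] == 0.0:
            roots.append((0.0, float(ph[k])))
        elif f[k] * f[k + 1] < 0.0:
            frac = f[k] / (f[k] - f[k + 1])
            root = float(ph[k] + frac * (ph[k + 1] - ph[k]))
            roots.append((min(abs(f[k]), abs(f[k + 1])), root))
    if f[-1] == 0.0:
        roots.append((0.0, float(ph[-1])))
    if not roots:
        k = int(np.argmin(np.abs(f)))
        return Intersection(
            pka_macro=float(curve.pka_values[defined][k]),
            ph_star=float(ph[k]), boundary=True,
        )
    roots.sort(key=lambda t: (t[0], t[1]))
    best = roots[0][1]
    return Intersection(pka_macro=best, ph_star=best, multiple=len(roots) > 1)


def jackknife_se(
    partitions: Sequence[tuple[str, Sequence]],
    estimator: Callable[[list], float],
) -> tuple[float, list[tuple[str, float]]]:
    """Delete-one jackknife standard error over frame partitions.

    ``partitions`` is a list of ``(partition_id, frames)`` pairs; the
    estimator maps a flat frame list to a pKa value.  Returns
    ``SE = sqrt(((n-1)/n) * sum_i (theta_i - theta_bar)**2)`` together with
    the leave-one-out values.
    """
    n = len(partitions)
    if n < 2:
        raise InputError(f"jackknife needs >= 2 partitions, got {n}")
    leave_one_out: list[tuple[str, float]] = []
    for i, (pid, _) in enumerate(partitions):
        kept: list = []
        for j, (_, frames) in enumerate(partitions):
            if j != i:
                kept.extend(frames)
        try:
            theta = float(estimator(kept))
        except Exception as exc:
            raise InputError(
                f"estimator failed with partition {pid!r} left out: {exc}"
            ) from exc
        leave_one_out.append((pid, theta))
    thetas = np.array([t for _, t in leave_one_out])
    se = float(np.sqrt((n - 1) / n * np.sum((thetas - thetas.mean()) ** 2)))
    return se, leave_one_out


def _kmeans2_1d(values: np.ndarray) -> float:
    """Deterministic 1-D two-means threshold (Lloyd, min/max init)."""
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    m_low, m_high = lo, hi
    assign = values >= 0.5 * (m_low + m_high)
    for _ in range(200):
        m_high = float(values[assign].mean())
        m_low = float(values[~assign].mean())
        new_assign = values >= 0.5 * (m_low + m_high)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return 0.5 * (m_low + m_high)


def split_pkhalf_populations(
    records: Sequence[PkHalfRecord],
    method: str = "kmeans2",
    fixed_threshold: float | None = None,
) -> PopulationSplit:
    """Partition frames into high/low pK_half conformational populations.

    ``kmeans2`` clusters the defined pK_half values into two groups and puts
    the threshold midway between the cluster means (requires >= 10 defined
    records); ``fixed`` uses the supplied threshold.  Records with undefined
    pK_half are excluded and counted.  A warning is emitted when the
    population means are closer than 1 pK unit (likely unimodal).
    """
    if method not in ("kmeans2", "fixed"):
        raise InputError(f"unknown split method {method!r}")
    if method == "fixed" and fixed_threshold is None:
        raise InputError("method 'fixed' requires fixed_threshold")
    defined = [r for r in records if r.pkhalf is not None]
    n_undefined = len(records) - len(defined)
    if not defined:
        raise InputError("no defined pkhalf records to split")
    values = np.array([r.pkhalf for r in defined])
    if method == "kmeans2":
        if len(defined) < 10:
            raise InputError(
                f"kmeans2 split needs >= 10 defined records, got {len(defined)}"
            )
        threshold = _kmeans2_1d(values)
    else:
        threshold = float(fixed_threshold)
    high = values >= threshold
    high_frames = [r.frame_id for r, h in zip(defined, high) if h]
    low_frames = [r.frame_id for r, h in zip(defined, high) if not h]
    if high.all() or not high.any():
        separation = 0.0
    else:
        separation = float(values[high].mean() - values[~high].mean())
    if separation < 1.0:
        warnings.warn(
            f"pkhalf population separation {separation:.3f} pK < 1; "
            "the series may be unimodal", UserWarning, stacklevel=2,
        )
    return PopulationSplit(
        threshold=threshold, high_frames=high_frames, low_frames=low_frames,
        method=method, separation=separation, n_undefined=n_undefined,
    )
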