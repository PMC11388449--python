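"""Equilibrium protonation of interacting titratable sites in one conformation.

A conformation is summarised by a :class:`TitrationModel`: a list of sites,
each with an intrinsic pKa, plus a symmetric matrix of pairwise charge-charge
couplings expressed in pK units (energy divided by kT*ln10).  A protonation
microstate assigns 0/1 (deprotonated/protonated) to every site; its reduced
free energy at a given pH is

    G(state; pH) = sum_i s_i * (pH - pkint_i) + sum_{i<j} w_ij * q_i * q_j

with q_i = s_i - 1 for anionic sites and q_i = s_i for cationic sites, and
Boltzmann weight 10**(-G).  Average protonations over a pH grid are computed
either by exact enumeration of all 2**n microstates or by Metropolis Monte
Carlo; the half-titration point (pK_half) of a site is read off the resulting
curve by linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from protolra.errors import CapacityError, InputError

LN10 = math.log(10.0)

ANIONIC = "anionic"
CATIONIC = "cationic"
_POLARITIES = (ANIONIC, CATIONIC)

#: hard cap on exact enumeration (2**20 microstates)
ENUMERATION_CAP = 20


@dataclass(frozen=True)
class TitrationSite:
    """One titratable site: label, intrinsic pKa and charge polarity.

    ``anionic`` sites carry charge -1 when deprotonated (e.g. Asp, Glu);
    ``cationic`` sites carry +1 when protonated (e.g. Lys, Arg, His).
    """

    id: str
    pkint: float
    polarity: str = ANIONIC

    def __post_init__(self):
        if not np.isfinite(self.pkint):
            raise InputError(f"site {self.id!r}: pkint must be finite, got {self.pkint}")
        if self.polarity not in _POLARITIES:
            raise InputError(
                f"site {self.id!r}: polarity must be one of {_POLARITIES}, got {self.polarity!r}"
            )

    @property
    def charge_offset(self) -> int:
        """q_i = s_i + charge_offset."""
        return -1 if self.polarity == ANIONIC else 0


@dataclass
class TitrationModel:
    """Sites plus a symmetric pairwise coupling matrix in pK units."""

    sites: list[TitrationSite]
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.sites)
        if self.w.shape != (n, n):
            raise InputError(f"coupling matrix shape {self.w.shape} != ({n}, {n})")
        if not np.array_equal(self.w, self.w.T):
            raise InputError("coupling matrix is not symmetric")
        if np.any(np.diagonal(self.w) != 0.0):
            raise InputError("coupling matrix diagonal must be exactly zero")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    @property
    def pkints(self) -> np.ndarray:
        return np.array([s.pkint for s in self.sites], dtype=float)

    @property
    def charge_offsets(self) -> np.ndarray:
        return np.array([s.charge_offset for s in self.sites], dtype=float)

    def site_index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise InputError(f"site {site_id!r} not in model") from None


@dataclass(frozen=True)
class PhGrid:
    """Uniform pH grid ``ph_min + k*step``, inclusive of an exactly-reached end."""

    ph_min: float = -10.0
    ph_max: float = 20.0
    step: float = 0.25

    def __post_init__(self):
        if not (self.ph_min < self.ph_max):
            raise InputError(f"ph_min ({self.ph_min}) must be < ph_max ({self.ph_max})")
        if not (self.step > 0):
            raise InputError(f"step must be positive, got {self.step}")

    @property
    def values(self) -> np.ndarray:
        # ph_max included when it lies on the grid to within float tolerance
        n = int(math.floor((self.ph_max - self.ph_min) / self.step + 1e-9)) + 1
        return self.ph_min + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TitrationCurve:
    """Per-site average protonation on a pH grid.

    ``protonation`` has shape (n_sites, n_ph); ``mc_error`` (same shape) is a
    batch-mean standard error and is only present for the ``mc`` method.
    """

    grid: PhGrid
    site_ids: list[str]
    protonation: np.ndarray
    method: str = "exact"
    mc_error: np.ndarray | None = None

    def __post_init__(self):
        self.protonation = np.asarray(self.protonation, dtype=float)
        expected = (len(self.site_ids), len(self.grid))
        if self.protonation.shape != expected:
            raise InputError(
                f"protonation shape {self.protonation.shape} != {expected}"
            )
        if np.any((self.protonation < -1e-12) | (self.protonation > 1 + 1e-12)):
            raise InputError("protonation values must lie in [0, 1]")

    def site_index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise InputError(f"site {site_id!r} not in curve") from None

    def site_protonation(self, site_id: str) -> np.ndarray:
        return self.protonation[self.site_index(site_id)]


@dataclass
class PkHalf:
    """Half-titration point of one site; ``value`` is None when undefined."""

    value: float | None
    multiple: bool = False
    boundary: bool = False

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class PkHalfRecord:
    """pK_half of the target site in one trajectory frame."""

    frame_id: str
    replicate_id: str
    time_ps: float
    pkhalf: float | None = None

    def __post_init__(self):
        if self.time_ps < 0:
            raise InputError(f"time_ps must be >= 0, got {self.time_ps}")
        if self.pkhalf is not None and not np.isfinite(self.pkhalf):
            raise InputError("pkhalf must be finite when defined (use None otherwise)")


def _validate_state(state, model: TitrationModel) -> np.ndarray:
    state = np.asarray(state)
    if state.shape != (model.n_sites,):
        raise InputError(
            f"state length {state.shape} does not match site count {model.n_sites}"
        )
    if not np.all((state == 0) | (state == 1)):
        raise InputError("state entries must be 0 or 1")
    return state.astype(float)


def microstate_energy(state, model: TitrationModel, ph: float) -> float:
    """Reduced free energy (pK units) of one protonation microstate at ``ph``.

    The Boltzmann weight of the state is ``10**(-G)``.  The all-deprotonated
    state of an all-cationic model is the zero of energy at every pH.
    """
    s = _validate_state(state, model)
    q = s + model.charge_offsets
    prot_term = float(np.dot(s, ph - model.pkints))
    pair_term = 0.5 * float(q @ model.w @ q)  # diagonal is zero
    return prot_term + pair_term


def _enumerate_states(n: int) -> np.ndarray:
    """All 2**n binary vectors, shape (2**n, n); column i is bit i."""
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def exact_titration(
    model: TitrationModel,
    grid: PhGrid,
    cap: int = ENUMERATION_CAP,
) -> TitrationCurve:
    """Average protonation per site by Boltzmann sum over all microstates.

    Raises :class:`CapacityError` above ``cap`` sites (default 20); use
    :func:`mc_titration` for larger models.
    """
    n = model.n_sites
    if n == 0:
        raise InputError("model has no sites")
    if n > cap:
        raise CapacityError(
            f"{n} sites exceeds enumeration cap {cap}; use mc_titration instead"
        )
    states = _enumerate_states(n)
    q = states + model.charge_offsets[None, :]
    pair = 0.5 * np.einsum("si,ij,sj->s", q, model.w, q)
    base = pair - states @ model.pkints  # pH-independent part of G
    n_prot = states.sum(axis=1)
    ph = grid.values
    prot = np.empty((n, len(ph)))
    # chunk over pH so the (2**n, chunk) intermediate stays small
    chunk = max(1, int(4_000_000 // max(1, 2**n)))
    for lo in range(0, len(ph), chunk):
        ph_c = ph[lo : lo + chunk]
        log_w = -LN10 * (base[:, None] + n_prot[:, None] * ph_c[None, :])
        log_z = logsumexp(log_w, axis=0)
        for i in range(n):
            num = logsumexp(log_w, axis=0, b=states[:, i : i + 1])
            with np.errstate(over="ignore"):
                prot[i, lo : lo + chunk] = np.exp(num - log_z)
    prot = np.clip(prot, 0.0, 1.0)
    return TitrationCurve(grid=grid, site_ids=model.site_ids, protonation=prot, method="exact")


def _mc_chain(pkints, qoff, w, partner, has_partner, ph, steps,
              pair_fraction, burn_in, seed, batch_sums, batch_len):
    """One Metropolis chain at fixed pH; one step = one sweep over all sites."""
    np.random.seed(seed)
    n = pkints.shape[0]
    n_batches = batch_sums.shape[0]
    s = np.zeros(n, dtype=np.int8)
    q = np.empty(n)
    for i in range(n):
        if pkints[i] > ph:
            s[i] = 1
        q[i] = s[i] + qoff[i]
    for t in range(steps):
        for i in range(n):
            ds_i = 1 - 2 * s[i]
            field_i = 0.0
            for k in range(n):
                field_i += w[i, k] * q[k]
            pair = (
                has_partner[i]
                and pair_fraction > 0.0
                and np.random.random() < pair_fraction
            )
            if pair:
                j = partner[i]
                ds_j = 1 - 2 * s[j]
                field_j = 0.0
                for k in range(n):
                    field_j += w[j, k] * q[k]
                dg = (
                    ds_i * (ph - pkints[i])
                    + ds_j * (ph - pkints[j])
                    + ds_i * field_i
                    + ds_j * field_j
                    + w[i, j] * ds_i * ds_j
                )
                if dg <= 0.0 or np.random.random() < math.exp(-LN10 * dg):
                    s[i] += ds_i
                    s[j] += ds_j
                    q[i] += ds_i
                    q[j] += ds_j
            else:
                dg = ds_i * (ph - pkints[i]) + ds_i * field_i
                if dg <= 0.0 or np.random.random() < math.exp(-LN10 * dg):
                    s[i] += ds_i
                    q[i] += ds_i
        if t >= burn_in:
            b = (t - burn_in) // batch_len
            if b >= n_batches:
                b = n_batches - 1
            for i2 in range(n):
                batch_sums[b, i2] += s[i2]


try:  # pragma: no cover - exercised implicitly whenever numba is present
    from numba import njit

    _mc_chain = njit(cache=False)(_mc_chain)
except ImportError:  # pragma: no cover
    pass


def mc_titration(
    model: TitrationModel,
    grid: PhGrid,
    steps: int = 100_000,
    burn_in: int | None = None,
    pair_move_fraction: float = 0.1,
    seed: int | None = None,
) -> TitrationCurve:
    """Metropolis Monte Carlo titration, one independent chain per pH point.

    One MC step is a full sweep: each site in turn receives one proposal, a
    single protonation flip or -- with probability ``pair_move_fraction`` --
    a simultaneous flip together with its most strongly coupled partner
    (helps strongly coupled pairs).  Averages are taken after ``burn_in``
    sweeps (default 10% of ``steps``) and carry a batch-mean standard error.
    Identical seeds give identical output.
    """
    if steps <= 0:
        raise InputError(f"steps must be positive, got {steps}")
    if burn_in is None:
        burn_in = steps // 10
    if not (steps > burn_in >= 0):
        raise InputError(f"need steps > burn_in >= 0, got steps={steps}, burn_in={burn_in}")
    if seed is None:
        raise InputError("mc_titration requires an explicit seed")
    if not (0.0 <= pair_move_fraction <= 1.0):
        raise InputError("pair_move_fraction must be in [0, 1]")

    n = model.n_sites
    if n == 0:
        raise InputError("model has no sites")
    w = np.ascontiguousarray(model.w)
    abs_w = np.abs(w)
    partner = np.argmax(abs_w, axis=1).astype(np.int64)
    has_partner = (abs_w.max(axis=1) > 0.0) & (n > 1)

    ph_values = grid.values
    sample_steps = steps - burn_in
    n_batches = min(20, sample_steps)
    batch_len = sample_steps // n_batches

    prot = np.empty((n, len(ph_values)))
    err = np.empty((n, len(ph_values)))
    chain_seeds = np.random.SeedSequence(seed).generate_state(len(ph_values), np.uint32)
    pkints = model.pkints
    qoff = model.charge_offsets
    for k, ph in enumerate(ph_values):
        batch_sums = np.zeros((n_batches, n))
        _mc_chain(pkints, qoff, w, partner, has_partner, float(ph), int(steps),
                  float(pair_move_fraction), int(burn_in), int(chain_seeds[k]),
                  batch_sums, int(batch_len))
        counts = np.full(n_batches, batch_len, dtype=float)
        counts[-1] += sample_steps - n_batches * batch_len
        batch_means = batch_sums / counts[:, None]
        prot[:, k] = batch_sums.sum(axis=0) / sample_steps
        if n_batches > 1:
            err[:, k] = batch_means.std(axis=0, ddof=1) / math.sqrt(n_batches)
        else:
            err[:, k] = np.nan
    return TitrationCurve(
        grid=grid, site_ids=model.site_ids, protonation=np.clip(prot, 0, 1),
        method="mc", mc_error=err,
    )


def pkhalf(curve: TitrationCurve, site_index: int) -> PkHalf:
    """pH at which a site's protonation crosses 0.5 (linear interpolation).

    Several crossings -> the median one, with ``multiple`` set; no crossing
    within the grid -> undefined with ``boundary`` set.
    """
    if not (0 <= site_index < len(curve.site_ids)):
        raise InputError(
            f"site_index {site_index} out of range for {len(curve.site_ids)} sites"
        )
    ph = curve.grid.values
    d = curve.protonation[site_index] - 0.5
    crossings: list[float] = []
    for k in range(len(ph)):
        if d[k] == 0.0:
            crossings.append(float(ph[k]))
        elif k + 1 < len(ph) and d[k] * d[k + 1] < 0.0:
            frac = d[k] / (d[k] - d[k + 1])
            crossings.append(float(ph[k] + frac * (ph[k + 1] - ph[k])))
    if not crossings:
        return PkHalf(value=None, boundary=True)
    crossings.sort()
    value = crossings[(len(crossings) - 1) // 2]  # lower median: an actual crossing
    return PkHalf(value=value, multiple=len(crossings) > 1)
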