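"""Contact detection and age-stratified contact statistics.

A contact is an epidemiologically motivated event: two pedestrians whose
center distance stays below a safety radius (default 1.8 m) for a
sustained dwell time (default 30 s).  Once a pair has made contact, later
episodes between the same two people are not counted again (unique-pair
rule); per-episode counting and cumulative (non-continuous) dwell are
available behind configuration switches for pathogens with different
exposure profiles.

Registered pairs aggregate into the raw symmetric count matrix C_ij over
the sixteen five-year age bins; dividing row i by the group size n_i
yields the per-capita matrix m_ij (mean contacts a bin-i individual has
with bin-j individuals), which satisfies the reciprocity identity
C_ij = m_ij n_i = m_ji n_j.  Row-normalizing any per-capita matrix K
gives the mixing matrix P and the assortativity index
Q = (Tr(P) - 1)/(n - 1), 0 for proportionate and 1 for fully
within-group mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .population import N_AGE_BINS, AGE_BIN_LABELS, PedestrianProfile

__all__ = [
    "ContactDefinition",
    "DwellState",
    "ContactMatrix",
    "MixingMatrix",
    "update_dwell",
    "build_contact_matrix",
    "assortativity_q",
    "mixing_matrix",
    "average_matrix",
    "duration_scaling",
    "merge_bins",
]

_DWELL_EPS = 1e-9  # guards float accumulation at the dwell threshold


@dataclass(frozen=True)
class ContactDefinition:
    """Distance + dwell-time contact criterion.

    ``radius`` is the proximity threshold in metres, ``dwell`` the
    continuous time in seconds a pair must stay within it.  With
    ``cumulative`` the dwell accumulator survives separations instead of
    resetting; with ``unique_pairs`` off a pair can register once per
    proximity episode.
    """

    radius: float = 1.8
    dwell: float = 30.0
    unique_pairs: bool = True
    cumulative: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.dwell < 0:
            raise ValueError("contact radius must be positive and dwell non-negative")


class DwellState:
    """Pairwise dwell accumulators and the registered-contact set."""

    def __init__(self, n: int):
        self.n = n
        self.acc = np.zeros((n, n))
        self.registered = np.zeros((n, n), dtype=bool)
        self.counts = np.zeros((n, n), dtype=np.int64)


def update_dwell(
    positions: np.ndarray,
    profiles: list[PedestrianProfile] | None,
    dt: float,
    definition: ContactDefinition,
    state: DwellState,
) -> list[tuple[int, int]]:
    """Advance the dwell accumulators by one observation of the crowd.

    Every pair currently within the contact radius gains ``dt`` of dwell;
    under the default continuous rule a pair that separates resets to
    zero.  Pairs whose accumulator crosses the dwell threshold on this
    observation are returned (and, with unique-pair counting, never
    again).
    """
    x = np.asarray(positions)
    diff = x[:, None, :] - x[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    within = d < definition.radius
    np.fill_diagonal(within, False)

    prev = state.acc
    acc = np.where(within, prev + dt, prev if definition.cumulative else 0.0)
    state.acc = acc

    threshold = definition.dwell - _DWELL_EPS
    crossing = within & (acc >= threshold) & (prev < threshold)
    if definition.unique_pairs:
        crossing &= ~state.registered
    iu, ju = np.nonzero(np.triu(crossing, k=1))
    new_pairs = [(int(i), int(j)) for i, j in zip(iu, ju)]
    for i, j in new_pairs:
        state.registered[i, j] = state.registered[j, i] = True
        state.counts[i, j] += 1
        state.counts[j, i] += 1
    return new_pairs


@dataclass
class ContactMatrix:
    """Raw counts C_ij, group sizes n_i and the per-capita matrix m_ij."""

    C: np.ndarray
    n: np.ndarray
    labels: tuple[str, ...] = tuple(AGE_BIN_LABELS)
    extrapolated: bool = False

    m: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.n = np.asarray(self.n)
        if self.C.shape != (len(self.n), len(self.n)):
            raise ValueError("count matrix and group sizes disagree in size")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("contact counts must be symmetric")
        self.m = _per_capita(self.C, self.n)

    @property
    def total_contacts(self) -> float:
        """Total registered pair contacts (each pair counted once)."""
        return float(self.C.sum()) / 2.0

    @property
    def mean_contacts_per_person(self) -> float:
        n_tot = int(self.n.sum())
        return float(self.C.sum()) / n_tot if n_tot else 0.0


def _per_capita(C: np.ndarray, n: np.ndarray) -> np.ndarray:
    m = np.zeros_like(C, dtype=float)
    nz = n > 0
    if not np.all(nz) and C[~nz].any():
        raise ValueError("contacts recorded for an age bin with zero members")
    if not np.all(nz):
        warnings.warn("empty age bins: their per-capita rows are reported as zero")
    m[nz] = C[nz] / np.asarray(n, dtype=float)[nz, None]
    return m


def build_contact_matrix(
    pairs: list[tuple[int, int]],
    profiles: list[PedestrianProfile],
    n_bins: int = N_AGE_BINS,
) -> ContactMatrix:
    """Tally registered pairs into the age-binned contact matrix.

    Each pair (a, b) increments C[bin(a), bin(b)] and C[bin(b), bin(a)]
    once each, so a same-bin pair adds 2 to the diagonal — each
    participant reports one contact, which is what makes the reciprocity
    identity hold on the diagonal.  Group sizes come from the population
    census.
    """
    if not profiles:
        raise ValueError("cannot build a contact matrix for an empty population")
    bins = np.array([p.age_bin.index for p in profiles])
    if bins.max(initial=0) >= n_bins:
        raise ValueError("profile age bin outside the matrix size")
    C = np.zeros((n_bins, n_bins))
    for a, b in pairs:
        C[bins[a], bins[b]] += 1
        C[bins[b], bins[a]] += 1
    n = np.bincount(bins, minlength=n_bins)
    labels = tuple(AGE_BIN_LABELS[:n_bins]) if n_bins == N_AGE_BINS else tuple(
        f"bin{i}" for i in range(n_bins)
    )
    return ContactMatrix(C=C, n=n, labels=labels)


@dataclass(frozen=True)
class MixingMatrix:
    """Row-stochastic mixing fractions P and the assortativity index Q."""

    P: np.ndarray
    Q: float


def mixing_matrix(K: np.ndarray) -> MixingMatrix:
    """Row-normalize a contact-rate matrix and compute Q.

    p_ij = K_ij / sum_j K_ij; rows with zero total stay zero and
    contribute nothing to the trace.  Q = (Tr(P) - 1)/(n - 1) ranges from
    0 (proportionate mixing) to 1 (fully assortative).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("mixing requires a square matrix")
    if np.any(K < 0):
        raise ValueError("contact rates must be non-negative")
    totals = K.sum(axis=1)
    if not np.any(totals > 0):
        raise ValueError("assortativity is undefined for an all-zero matrix")
    P = np.zeros_like(K)
    nz = totals > 0
    P[nz] = K[nz] / totals[nz, None]
    n = K.shape[0]
    Q = (float(np.trace(P)) - 1.0) / (n - 1)
    return MixingMatrix(P=P, Q=Q)


def assortativity_q(K: np.ndarray) -> float:
    """Assortativity index Q = (Tr(P) - 1)/(n - 1) of a per-capita matrix."""
    return mixing_matrix(K).Q


def average_matrix(matrices: list[ContactMatrix] | list[np.ndarray]) -> np.ndarray:
    """Unweighted element-wise mean of per-capita matrices across areas."""
    if not matrices:
        raise ValueError("nothing to average")
    arrays = [m.m if isinstance(m, ContactMatrix) else np.asarray(m, dtype=float) for m in matrices]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("matrices must share the same age-bin structure")
    return np.mean(arrays, axis=0)


def duration_scaling(
    matrix: ContactMatrix,
    t_sim: float,
    t_activity: float,
) -> ContactMatrix:
    """Extrapolate a short simulated window to the full activity duration.

    Per-capita contact rates scale linearly by ``t_activity / t_sim`` (an
    identity when the run already covers the activity); the result is
    flagged as extrapolated for the run manifest.  Raw counts are scaled
    alongside so the reciprocity identity keeps holding.
    """
    if t_sim <= 0:
        raise ValueError("simulated duration must be positive")
    ratio = t_activity / t_sim
    if ratio == 1.0:
        return matrix
    return ContactMatrix(
        C=matrix.C * ratio, n=matrix.n, labels=matrix.labels, extrapolated=True
    )


def merge_bins(K: np.ndarray, groups: list[list[int]], sizes: np.ndarray | None = None) -> np.ndarray:
    """Coarsen a per-capita matrix onto merged age bins.

    ``groups`` lists the fine-bin indices composing each coarse bin.
    Columns add; rows combine as size-weighted means (uniform when sizes
    are not given), matching how per-capita rates aggregate.
    """
    K = np.asarray(K, dtype=float)
    g = len(groups)
    w = np.ones(K.shape[0]) if sizes is None else np.asarray(sizes, dtype=float)
    out = np.zeros((g, g))
    for a, rows in enumerate(groups):
        rw = w[rows]
        tot = rw.sum()
        for b, cols in enumerate(groups):
            block = K[np.ix_(rows, cols)].sum(axis=1)
            out[a, b] = (rw * block).sum() / tot if tot > 0 else 0.0
    return out
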