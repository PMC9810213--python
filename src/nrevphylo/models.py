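"""Nucleotide substitution rate matrices: GTR, NREV6 and NREV12.

The three families differ in how much directional (strand-specific)
substitution bias they can express:

* **GTR** — time-reversible: off-diagonal rates ``q_ij = r_ij * pi_j`` with
  symmetric exchangeabilities ``r_ij = r_ji``, so detailed balance
  ``pi_i q_ij = pi_j q_ji`` holds by construction.
* **NREV6** — strand-symmetric non-reversible: each substitution shares its
  rate with the complementary substitution on the opposite strand
  (``A->C`` with ``T->G``, ``C->T`` with ``G->A``, ...), the natural model
  for double-stranded genomes with no strand bias.
* **NREV12** — fully general (UNREST-like): all twelve substitution types
  have independent rates, appropriate when one genome strand is exposed to
  mutagenic processes for longer than the other.

For the non-reversible families the off-diagonal entries are the rate
parameters themselves; equilibrium base frequencies are *induced* by the
matrix through ``pi Q = 0`` rather than supplied.  All constructors return
matrices normalized to one expected substitution per site per unit time.

The degree of non-reversibility (DNR) of a 12-rate parameterization is, for
each unordered nucleotide pair, the absolute difference between the forward
and reverse relative rates; a dataset-level DNR is the mean of the six pair
values.  Rates are on the shared relative scale with A->G fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "NREV12_RATE_ORDER",
    "PAIR_ORDER",
    "Family",
    "RateMatrix",
    "FrequencyVector",
    "DNRProfile",
    "IrreversibilityIndices",
    "build_gtr",
    "build_nrev6",
    "build_nrev12",
    "stationary_distribution",
    "normalize",
    "compute_dnr",
    "is_reversible",
    "irreversibility_indices",
    "matrix_to_text",
    "matrix_from_text",
    "rates_to_text",
    "rates_from_text",
]

#: Fixed state order used for every 4x4 matrix in the package.
NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")
_IDX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: Canonical ordering of the 12 directed rates (matches the keyed text format:
#: C-A, A-C, G-A, A-G, A-T, T-A, G-C, C-G, T-G, G-T, C-T, T-C).
NREV12_RATE_ORDER: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("A", "C"), ("G", "A"), ("A", "G"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("T", "G"), ("G", "T"), ("C", "T"), ("T", "C"),
)

#: The six unordered nucleotide pairs, in canonical order.
PAIR_ORDER: tuple[tuple[str, str], ...] = (
    ("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"),
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Family(str, Enum):
    GTR = "GTR"
    NREV6 = "NREV6"
    NREV12 = "NREV12"
    NREV12F = "NREV12F"


class ModelError(ValueError):
    """Invalid rate-matrix parameterization."""


@dataclass(frozen=True)
class FrequencyVector:
    """Probability distribution over (A, C, G, T)."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,):
            raise ModelError(f"frequency vector must have 4 entries, got {pi.shape}")
        if np.any(pi < 0):
            raise ModelError("frequencies must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ModelError(f"frequencies must sum to 1 (got {pi.sum()!r})")
        object.__setattr__(self, "pi", pi)

    def __getitem__(self, nuc: str | int) -> float:
        return float(self.pi[_IDX[nuc] if isinstance(nuc, str) else nuc])


@dataclass(frozen=True)
class RateMatrix:
    """A 4x4 instantaneous rate matrix (rows = from-state, order A,C,G,T)."""

    q: np.ndarray
    family: Family
    normalized: bool = False

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4, 4):
            raise ModelError("rate matrix must be 4x4")
        off = q[~np.eye(4, dtype=bool)]
        if np.any(off < 0):
            raise ModelError("off-diagonal rates must be non-negative")
        if np.any(np.abs(q.sum(axis=1)) > 1e-10):
            raise ModelError("rate-matrix rows must sum to 0")
        object.__setattr__(self, "q", q)

    def rate(self, i: str, j: str) -> float:
        return float(self.q[_IDX[i], _IDX[j]])


@dataclass(frozen=True)
class DNRProfile:
    """Per-pair and average degree of non-reversibility."""

    pair_dnr: dict[tuple[str, str], float]
    average_dnr: float = field(init=False)

    def __post_init__(self) -> None:
        if set(self.pair_dnr) != set(PAIR_ORDER):
            raise ModelError("DNR profile requires all six nucleotide pairs")
        object.__setattr__(
            self, "average_dnr", float(np.mean([self.pair_dnr[p] for p in PAIR_ORDER]))
        )


@dataclass(frozen=True)
class IrreversibilityIndices:
    """Kolmogorov 3-cycle product differences for the cycles
    (A,C,G), (A,C,T), (A,G,T)."""

    iri: tuple[float, float, float]

    def all_zero(self, tol: float = 1e-10) -> bool:
        return all(abs(v) < tol for v in self.iri)


def _rowfix(q: np.ndarray) -> np.ndarray:
    q = q.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _as_positive_rates(rates: Sequence[float], n: int, what: str) -> np.ndarray:
    arr = np.asarray(list(rates), dtype=float)
    if arr.shape != (n,):
        raise ModelError(f"{what} requires exactly {n} rates, got {arr.shape}")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ModelError(f"{what} rates must be positive and finite")
    return arr


def build_gtr(rates: Sequence[float], freqs: FrequencyVector | Sequence[float]) -> RateMatrix:
    """Build a normalized GTR matrix from six exchangeabilities and frequencies.

    ``rates`` are keyed by :data:`PAIR_ORDER` (AC, AG, AT, CG, CT, GT); the
    off-diagonal entries are ``q_ij = r_{ij} * pi_j``, which satisfies detailed
    balance ``pi_i q_ij = pi_j q_ji`` identically.
    """
    r = _as_positive_rates(rates, 6, "GTR")
    if not isinstance(freqs, FrequencyVector):
        freqs = FrequencyVector(np.asarray(freqs, dtype=float))
    if np.any(freqs.pi <= 0):
        raise ModelError("GTR requires strictly positive frequencies")
    q = np.zeros((4, 4))
    for (x, y), rate in zip(PAIR_ORDER, r):
        i, j = _IDX[x], _IDX[y]
        q[i, j] = rate * freqs.pi[j]
        q[j, i] = rate * freqs.pi[i]
    q = _rowfix(q)
    return normalize(RateMatrix(q, Family.GTR), freqs)


def build_nrev6(rates: Sequence[float]) -> RateMatrix:
    """Build a normalized strand-symmetric NREV6 matrix from six rates.

    ``rates[k]`` is the rate of ``x -> y`` for ``(x, y)`` the k-th pair in
    :data:`PAIR_ORDER`; the complementary substitution gets the same rate
    (``q[comp(x) -> comp(y)] = q[x -> y]``), giving the six equalities
    ``q_AC=q_TG, q_AG=q_TC, q_AT=q_TA, q_CG=q_GC, q_CT=q_GA, q_GT=q_CA``.
    """
    r = _as_positive_rates(rates, 6, "NREV6")
    q = np.zeros((4, 4))
    for (x, y), rate in zip(PAIR_ORDER, r):
        q[_IDX[x], _IDX[y]] = rate
        q[_IDX[_COMPLEMENT[x]], _IDX[_COMPLEMENT[y]]] = rate
    q = _rowfix(q)
    m = RateMatrix(q, Family.NREV6)
    return normalize(m, stationary_distribution(m))


def build_nrev12(rates: Sequence[float] | Mapping[tuple[str, str], float]) -> RateMatrix:
    """Build a normalized NREV12 matrix: each off-diagonal is its own rate.

    ``rates`` is either a length-12 sequence in :data:`NREV12_RATE_ORDER`
    (the C-A, A-C, G-A, A-G, ... keyed order) or a mapping from directed
    ``(from, to)`` pairs to rates.
    """
    if isinstance(rates, Mapping):
        if set(rates) != set(NREV12_RATE_ORDER):
            raise ModelError("NREV12 mapping must cover all 12 directed pairs")
        rates = [rates[k] for k in NREV12_RATE_ORDER]
    r = _as_positive_rates(rates, 12, "NREV12")
    q = np.zeros((4, 4))
    for (x, y), rate in zip(NREV12_RATE_ORDER, r):
        q[_IDX[x], _IDX[y]] = rate
    q = _rowfix(q)
    m = RateMatrix(q, Family.NREV12)
    return normalize(m, stationary_distribution(m))


def stationary_distribution(q: RateMatrix | np.ndarray) -> FrequencyVector:
    """Solve ``pi Q = 0`` with ``sum(pi) = 1``.

    Raises :class:`ModelError` for reducible/degenerate matrices (null space
    of dimension != 1 or a non-positive solution).
    """
    mat = q.q if isinstance(q, RateMatrix) else np.asarray(q, dtype=float)
    a = np.vstack([mat.T, np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise ModelError("rate matrix is reducible: stationary distribution not unique")
    scale = max(np.max(np.abs(mat)), 1.0)
    resid = np.max(np.abs(pi @ mat)) / scale
    if resid > 1e-10 or np.any(pi < -1e-12):
        raise ModelError(f"no valid stationary distribution (residual {resid:.2e})")
    pi = np.clip(pi, 0.0, None)
    return FrequencyVector(pi / pi.sum())


def normalize(q: RateMatrix, pi: FrequencyVector | None = None) -> RateMatrix:
    """Rescale so the expected substitution rate ``-sum_i pi_i q_ii`` is 1."""
    if pi is None:
        pi = stationary_distribution(q)
    c = -float(pi.pi @ np.diag(q.q))
    if c <= 0:
        raise ModelError("expected rate must be positive to normalize")
    return RateMatrix(q.q / c, q.family, normalized=True)


def compute_dnr(rates: Sequence[float] | Mapping[tuple[str, str], float]) -> DNRProfile:
    """Degree of non-reversibility of a 12-rate set.

    For each unordered pair ``{x, y}``, ``pair_dnr = |rate(x->y) - rate(y->x)|``
    on the shared relative scale (reference rate A->G = 1); ``average_dnr`` is
    the mean of the six pair values.
    """
    if isinstance(rates, Mapping):
        if set(rates) != set(NREV12_RATE_ORDER):
            raise ModelError("DNR mapping must cover all 12 directed pairs")
        lookup = dict(rates)
    else:
        r = _as_positive_rates(rates, 12, "DNR")
        lookup = dict(zip(NREV12_RATE_ORDER, (float(v) for v in r)))
    pair_dnr = {
        (x, y): abs(lookup[(x, y)] - lookup[(y, x)]) for x, y in PAIR_ORDER
    }
    return DNRProfile(pair_dnr)


def dnr_of_matrix(q: RateMatrix) -> DNRProfile:
    """DNR profile of a rate matrix rescaled so the A->G entry is 1."""
    ag = q.rate("A", "G")
    if ag <= 0:
        raise ModelError("A->G rate must be positive to set the relative scale")
    return compute_dnr([q.rate(x, y) / ag for x, y in NREV12_RATE_ORDER])


def is_reversible(q: RateMatrix, tol: float = 1e-8) -> bool:
    """True iff detailed balance ``pi_i q_ij = pi_j q_ji`` holds within ``tol``
    for the matrix's own stationary distribution."""
    pi = stationary_distribution(q).pi
    flux = pi[:, None] * q.q
    return bool(np.max(np.abs(flux - flux.T)) < tol)


_CYCLES = (("A", "C", "G"), ("A", "C", "T"), ("A", "G", "T"))


def irreversibility_indices(q: RateMatrix) -> IrreversibilityIndices:
    """Kolmogorov cycle criterion over the three independent 3-cycles.

    For cycle (i, j, k): ``IRI = q_ij q_jk q_ki - q_ik q_kj q_ji``, evaluated
    on the normalized matrix.  A chain is reversible iff every cycle's forward
    and backward rate products agree, so reversible matrices yield all zeros.
    """
    m = q if q.normalized else normalize(q)
    vals = []
    for a, b, c in _CYCLES:
        i, j, k = _IDX[a], _IDX[b], _IDX[c]
        fwd = m.q[i, j] * m.q[j, k] * m.q[k, i]
        bwd = m.q[i, k] * m.q[k, j] * m.q[j, i]
        vals.append(float(fwd - bwd))
    return IrreversibilityIndices(tuple(vals))


# ---------------------------------------------------------------------------
# plain-text serialization

def matrix_to_text(q: RateMatrix) -> str:
    """4x4 whitespace-delimited table, rows/columns in A,C,G,T order."""
    lines = ["\t".join(f"{v:.12g}" for v in row) for row in q.q]
    return "\n".join(lines) + "\n"


def matrix_from_text(text: str, family: Family = Family.NREV12) -> RateMatrix:
    rows = [ln.split() for ln in text.strip().splitlines() if ln.strip()]
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise ModelError("matrix text must contain 4 rows of 4 numbers")
    q = np.array([[float(v) for v in r] for r in rows])
    return RateMatrix(q, family)


def rates_to_text(rates: Sequence[float] | Mapping[tuple[str, str], float]) -> str:
    """Keyed text block, one ``X-Y<TAB>rate`` line per directed substitution."""
    if not isinstance(rates, Mapping):
        r = _as_positive_rates(rates, 12, "rates")
        rates = dict(zip(NREV12_RATE_ORDER, (float(v) for v in r)))
    return "".join(f"{x}-{y}\t{rates[(x, y)]:.12g}\n" for x, y in NREV12_RATE_ORDER)


def rates_from_text(text: str) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for ln in text.strip().splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        key, val = ln.split()
        x, _, y = key.partition("-")
        if x not in _IDX or y not in _IDX or x == y:
            raise ModelError(f"bad rate key {key!r}")
        out[(x, y)] = float(val)
    if set(out) != set(NREV12_RATE_ORDER):
        raise ModelError("rate block must name all 12 directed substitutions")
    return out
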