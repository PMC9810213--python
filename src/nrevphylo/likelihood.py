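"""Felsenstein pruning likelihoods and maximum-likelihood model fitting.

The likelihood of an alignment on a rooted tree under a (possibly
non-reversible) rate matrix Q is computed by the pruning algorithm over
compressed site patterns, with per-node rescaling against underflow and an
optional discrete-gamma mixture of among-site rate categories.  Because Q
need not be reversible the root placement matters: per-site likelihoods are
``sum_i root_freq_i * L_i(root)`` and there is no pulley principle.

Model fitting maximizes the log-likelihood over the free relative rates
(A->G fixed at 1 as the reference), the gamma shape, optionally the branch
lengths, and — for the +F variant — the three free root frequencies.
Equilibrium frequencies of NREV6/NREV12 are induced by the matrix through
``pi Q = 0``; GTR uses empirical alignment frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .alignment import Alignment
from .models import (
    NREV12_RATE_ORDER,
    NUCLEOTIDES,
    PAIR_ORDER,
    Family,
    FrequencyVector,
    RateMatrix,
    build_gtr,
    build_nrev6,
    build_nrev12,
    stationary_distribution,
)
from .trees import RootedTree, TreeError, TreeNode

__all__ = [
    "transition_matrix",
    "discretize_gamma",
    "GammaCategories",
    "ModelFit",
    "FitOptions",
    "PruningEngine",
    "log_likelihood",
    "fit_model",
]

_IDX = {n: i for i, n in enumerate(NUCLEOTIDES)}

RATE_BOUNDS = (1e-6, 100.0)
SHAPE_BOUNDS = (0.01, 100.0)
BRANCH_BOUNDS = (0.0, 10.0)


# ---------------------------------------------------------------------------
# transition probabilities

class _QExp:
    """Cached exponentiator for one rate matrix.

    Uses the complex eigendecomposition ``P(t) = V diag(e^{w t}) V^{-1}`` when
    it reconstructs Q accurately, otherwise falls back to scaling-and-squaring
    expm per branch (non-reversible Q is not guaranteed diagonalizable).
    """

    def __init__(self, q: np.ndarray):
        self.q = np.asarray(q, dtype=float)
        self._eig = None
        try:
            w, v = np.linalg.eig(self.q)
            vinv = np.linalg.inv(v)
            if np.max(np.abs((v * w) @ vinv - self.q)) < 1e-10:
                self._eig = (w, v, vinv)
        except np.linalg.LinAlgError:
            pass

    def expm(self, t: float) -> np.ndarray:
        if t == 0.0:
            return np.eye(4)
        if self._eig is not None:
            w, v, vinv = self._eig
            p = ((v * np.exp(w * t)) @ vinv).real
        else:
            p = linalg.expm(self.q * t)
        # numerical cleanup: clamp tiny excursions, renormalize rows
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=1, keepdims=True)
        return p


def transition_matrix(q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries in [0, 1]."""
    if t < 0:
        raise ValueError("branch length t must be non-negative")
    mat = q.q if isinstance(q, RateMatrix) else np.asarray(q, dtype=float)
    return _QExp(mat).expm(float(t))


# ---------------------------------------------------------------------------
# discrete gamma rates

@dataclass(frozen=True)
class GammaCategories:
    shape: float
    n_cat: int
    rates: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))


def discretize_gamma(shape: float, n_cat: int) -> GammaCategories:
    """Equal-probability discrete gamma categories with mean-of-category rates.

    The gamma has mean 1 (shape ``alpha``, rate ``alpha``); category k's rate
    is the conditional mean of the distribution between the k/n and (k+1)/n
    quantiles, so the category rates average exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_cat < 1:
        raise ValueError("need at least one category")
    if n_cat == 1:
        return GammaCategories(shape, 1, np.array([1.0]))
    edges = gamma_dist.ppf(np.linspace(0, 1, n_cat + 1), a=shape, scale=1.0 / shape)
    # conditional means via the regularized incomplete gamma of shape+1
    upper = gammainc(shape + 1.0, shape * edges[1:])
    lower = gammainc(shape + 1.0, shape * edges[:-1])
    rates = n_cat * (np.where(np.isfinite(edges[1:]), upper, 1.0) - lower)
    rates = rates / rates.mean()
    return GammaCategories(shape, n_cat, rates)


# ---------------------------------------------------------------------------
# pruning engine

class PruningEngine:
    """Pruning likelihood evaluator bound to one tree/alignment pair.

    The engine reads branch lengths from the tree at every call, so callers
    may mutate ``node.length`` (branch-length optimization, NNI scoring)
    between calls without rebuilding.  Site patterns are compressed once.
    """

    def __init__(self, tree: RootedTree, aln: Alignment):
        missing = set(tree.leaf_names()) - set(aln.taxa)
        if missing:
            raise TreeError(f"tree leaves not in alignment: {sorted(missing)}")
        self.tree = tree
        self.aln = aln
        leaf_partials, counts, _ = aln.partial_vectors()
        self._leaf_partials = leaf_partials
        self.counts = counts
        self.n_patterns = len(counts)

    def site_log_likelihoods(
        self,
        q: RateMatrix,
        root_freqs: np.ndarray,
        gamma: GammaCategories | None = None,
    ) -> np.ndarray:
        """Per-pattern log-likelihoods (gamma-averaged), shape (n_patterns,)."""
        qexp = _QExp(q.q)
        cat_rates = gamma.rates if gamma is not None else np.array([1.0])
        per_cat = np.empty((len(cat_rates), self.n_patterns))
        for c, rate in enumerate(cat_rates):
            per_cat[c] = self._one_category(qexp, root_freqs, rate)
        if len(cat_rates) == 1:
            return per_cat[0]
        return logsumexp(per_cat, axis=0) - np.log(len(cat_rates))

    def _one_category(self, qexp: _QExp, root_freqs: np.ndarray, rate: float) -> np.ndarray:
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for node in self.tree.postorder():
            if node.is_leaf:
                partials[id(node)] = self._leaf_partials[node.name]
                continue
            prod = None
            for child in node.children:
                p = qexp.expm(child.length * rate)
                contrib = partials.pop(id(child)) @ p.T
                prod = contrib if prod is None else prod * contrib
            mx = prod.max(axis=1)
            bad = mx <= 0
            if np.any(bad):
                mx = np.where(bad, 1.0, mx)
                logscale = np.where(bad, -np.inf, logscale)
            prod /= mx[:, None]
            logscale += np.log(mx)
            partials[id(node)] = prod
        root_partial = partials[id(self.tree.root)]
        site = root_partial @ root_freqs
        with np.errstate(divide="ignore"):
            return np.log(site) + logscale

    def log_likelihood(
        self,
        q: RateMatrix,
        root_freqs: np.ndarray | FrequencyVector,
        gamma: GammaCategories | None = None,
    ) -> float:
        rf = root_freqs.pi if isinstance(root_freqs, FrequencyVector) else np.asarray(root_freqs)
        return float(self.counts @ self.site_log_likelihoods(q, rf, gamma))


def log_likelihood(
    tree: RootedTree,
    aln: Alignment,
    q: RateMatrix,
    root_freqs: FrequencyVector | np.ndarray,
    gamma: GammaCategories | None = None,
) -> float:
    """Alignment log-likelihood on a rooted tree (pruning algorithm)."""
    return PruningEngine(tree, aln).log_likelihood(q, root_freqs, gamma)


# ---------------------------------------------------------------------------
# model fitting

@dataclass(frozen=True)
class FitOptions:
    gamma: bool = True
    n_cat: int = 4
    root_freq_mode: str = "empirical"  # empirical | stationary | ml
    optimize_branch_lengths: bool = True
    n_starts: int = 3
    seed: int = 0
    max_rounds: int = 10
    tol: float = 1e-6
    bl_tol: float = 1e-4


@dataclass(frozen=True)
class ModelFit:
    family: Family
    rates: dict
    q: RateMatrix
    frequencies: FrequencyVector
    root_frequencies: FrequencyVector
    gamma: GammaCategories | None
    log_likelihood: float
    k: int
    n_sites: int
    converged: bool
    tree: RootedTree
    options: FitOptions = field(default=FitOptions(), repr=False)

    @property
    def gamma_shape(self) -> float | None:
        return self.gamma.shape if self.gamma is not None else None

    def rates_nrev12_order(self) -> list[float]:
        """The 12 directed rates in the canonical keyed order."""
        return [self.q.q[_IDX[x], _IDX[y]] / self.q.q[_IDX["A"], _IDX["G"]]
                for x, y in NREV12_RATE_ORDER]


_GTR_FREE = [p for p in PAIR_ORDER if p != ("A", "G")]
_NREV12_FREE = [p for p in NREV12_RATE_ORDER if p != ("A", "G")]


def _base_k(family: Family, gamma: bool) -> int:
    base = {Family.GTR: 8, Family.NREV6: 5, Family.NREV12: 11, Family.NREV12F: 14}[family]
    return base + (1 if gamma else 0)


class _Parameterization:
    """Maps an unconstrained optimizer vector to (Q, root freqs, gamma)."""

    def __init__(self, family: Family, aln: Alignment, options: FitOptions):
        self.family = family
        self.options = options
        self.empirical = aln.empirical_frequencies()
        self.n_rates = {Family.GTR: 5, Family.NREV6: 5,
                        Family.NREV12: 11, Family.NREV12F: 11}[family]
        self.ml_root = family is Family.NREV12F or options.root_freq_mode == "ml"
        self.n_params = (self.n_rates + (1 if options.gamma else 0)
                         + (3 if self.ml_root else 0))

    def unpack(self, theta: np.ndarray):
        pos = self.n_rates
        rates = np.exp(theta[:pos])
        if self.family is Family.GTR:
            full = []
            it = iter(rates)
            for p in PAIR_ORDER:
                full.append(1.0 if p == ("A", "G") else next(it))
            q = build_gtr(full, FrequencyVector(self.empirical))
        elif self.family is Family.NREV6:
            full = []
            it = iter(rates)
            for p in PAIR_ORDER:
                full.append(1.0 if p == ("A", "G") else next(it))
            q = build_nrev6(full)
        else:
            full = []
            it = iter(rates)
            for p in NREV12_RATE_ORDER:
                full.append(1.0 if p == ("A", "G") else next(it))
            q = build_nrev12(full)

        gamma = None
        if self.options.gamma:
            gamma = discretize_gamma(float(np.exp(theta[pos])), self.options.n_cat)
            pos += 1

        if self.family is Family.GTR:
            root = self.empirical
        elif self.ml_root:
            z = np.concatenate([theta[pos:pos + 3], [0.0]])
            root = np.exp(z - logsumexp(z))
        elif self.options.root_freq_mode == "stationary":
            root = stationary_distribution(q).pi
        else:
            root = self.empirical
        return q, root, gamma

    def bounds(self) -> list[tuple[float, float]]:
        lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
        b = [(lo, hi)] * self.n_rates
        if self.options.gamma:
            b.append((np.log(SHAPE_BOUNDS[0]), np.log(SHAPE_BOUNDS[1])))
        if self.ml_root:
            b.extend([(-10.0, 10.0)] * 3)
        return b

    def starts(self, aln: Alignment) -> list[np.ndarray]:
        rng = np.random.default_rng(self.options.seed)
        base = [np.zeros(self.n_params)]
        if self.options.n_starts >= 2:
            base.append(rng.normal(0.0, 0.5, self.n_params))
        if self.options.n_starts >= 3:
            base.append(self._empirical_start(aln))
        return base[: max(1, self.options.n_starts)]

    def _empirical_start(self, aln: Alignment) -> np.ndarray:
        # pairwise mismatch counts as crude rate hints, scaled so A<->G ~ 1
        codes = aln.codes()
        counts = np.ones((4, 4))
        ref = codes[0]
        for row in codes[1:]:
            ok = (ref < 4) & (row < 4) & (ref != row)
            np.add.at(counts, (ref[ok], row[ok]), 1.0)
        counts = counts / counts[_IDX["A"], _IDX["G"]]
        theta = np.zeros(self.n_params)
        if self.family in (Family.GTR, Family.NREV6):
            sym = (counts + counts.T) / 2.0
            vals = [sym[_IDX[x], _IDX[y]] for (x, y) in _GTR_FREE]
        else:
            vals = [counts[_IDX[x], _IDX[y]] for (x, y) in _NREV12_FREE]
        theta[: self.n_rates] = np.clip(np.log(vals), np.log(1e-3), np.log(1e3))
        return theta


def _sweep_branch_lengths(
    engine: PruningEngine,
    q: RateMatrix,
    root: np.ndarray,
    gamma: GammaCategories | None,
    tol: float,
    max_sweeps: int = 10,
    nodes: list | None = None,
    maxiter: int = 50,
) -> float:
    """Coordinate-wise branch-length maximization in place; returns final lnL.

    ``nodes`` restricts the sweep to a subset of branches (used to rescore
    local rearrangements cheaply); default is every branch.
    """
    best = engine.log_likelihood(q, root, gamma)
    for _ in range(max_sweeps):
        start = best
        for node in (nodes if nodes is not None else engine.tree.branches()):
            orig = node.length

            def nll(t: float, _node=node) -> float:
                _node.length = t
                return -engine.log_likelihood(q, root, gamma)

            res = optimize.minimize_scalar(
                nll, bounds=BRANCH_BOUNDS, method="bounded",
                options={"xatol": 1e-6, "maxiter": maxiter},
            )
            if -res.fun > best:
                node.length = float(res.x)
                best = -res.fun
            else:
                node.length = orig
        if best - start < tol:
            break
    return best


def fit_model(
    tree: RootedTree,
    aln: Alignment,
    family: Family | str,
    options: FitOptions | None = None,
) -> ModelFit:
    """Fit one substitution-model family by maximum likelihood.

    Maximizes over the free relative rates (A->G = 1), the gamma shape when
    enabled, the branch lengths (default: re-optimized in alternation with
    the rates), and the 3 free root frequencies for NREV12+F.  Multi-start
    L-BFGS-B on log-transformed parameters; convergence when a full
    rates/branch-lengths round improves lnL by less than ``options.tol``.
    """
    family = Family(family)
    options = options or FitOptions()
    if family is Family.NREV12F:
        options = replace(options, root_freq_mode="ml")
    work_tree = tree.copy()
    work_tree.validate()
    engine = PruningEngine(work_tree, aln)
    param = _Parameterization(family, aln, options)

    def nll(theta: np.ndarray) -> float:
        try:
            q, root, gamma = param.unpack(theta)
        except Exception:
            return 1e12
        val = engine.log_likelihood(q, root, gamma)
        return -val if np.isfinite(val) else 1e12

    best_res = None
    for start in param.starts(aln):
        res = optimize.minimize(
            nll, start, method="L-BFGS-B", bounds=param.bounds(),
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        if best_res is None or res.fun < best_res.fun:
            best_res = res

    converged = bool(best_res.success)
    theta = best_res.x
    lnl = -best_res.fun

    if options.optimize_branch_lengths:
        rounds_converged = False
        for _ in range(options.max_rounds):
            q, root, gamma = param.unpack(theta)
            lnl_bl = _sweep_branch_lengths(engine, q, root, gamma, options.bl_tol)
            res = optimize.minimize(
                nll, theta, method="L-BFGS-B", bounds=param.bounds(),
                options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
            )
            if res.fun < -lnl_bl:
                theta = res.x
                new_lnl = -res.fun
            else:
                new_lnl = lnl_bl
            gain = new_lnl - lnl
            lnl = new_lnl
            if gain < options.tol:
                rounds_converged = True
                break
        converged = converged and rounds_converged

    if not converged:
        warnings.warn(f"{family.value} fit did not fully converge", RuntimeWarning)

    q, root, gamma = param.unpack(theta)
    if family is Family.GTR:
        rates_full = dict(zip(PAIR_ORDER, _gtr_rates_from_theta(theta, param)))
        freqs = FrequencyVector(param.empirical)
    else:
        ag = q.q[_IDX["A"], _IDX["G"]]
        rates_full = {
            k: float(q.q[_IDX[k[0]], _IDX[k[1]]] / ag) for k in NREV12_RATE_ORDER
        }
        freqs = stationary_distribution(q)
    n_branches = len(work_tree.branches()) if options.optimize_branch_lengths else 0
    return ModelFit(
        family=family,
        rates=rates_full,
        q=q,
        frequencies=freqs,
        root_frequencies=FrequencyVector(root),
        gamma=gamma,
        log_likelihood=lnl,
        k=_base_k(family, options.gamma) + n_branches,
        n_sites=aln.n_sites,
        converged=converged,
        tree=work_tree,
        options=options,
    )


def _gtr_rates_from_theta(theta: np.ndarray, param: _Parameterization) -> list[float]:
    rates = np.exp(theta[: param.n_rates])
    it = iter(rates)
    return [1.0 if p == ("A", "G") else float(next(it)) for p in PAIR_ORDER]
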