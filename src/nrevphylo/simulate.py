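"""Synthetic benchmark inputs: the DNR rate ladder, random true trees, and
sequence evolution under stationarity.

The rate ladder spans eleven degrees of non-reversibility (DNR 0 through 20
in steps of 2).  Six "reverse" rates stay fixed across levels while the six
"forward" rates (C->A, G->A, A->T, G->C, T->G, C->T) each gain the level
value, so the per-pair |forward - reverse| difference — and hence the
average DNR — equals the level exactly.  Level 0 gives a symmetric, fully
reversible matrix; every positive level fails the Kolmogorov cycle
criterion on all three 3-cycles.

Sequences are evolved under the stationarity criterion ``pi e^{Qt} = pi``:
root states are drawn from the stationary distribution of Q, so base
composition is constant in time.  True trees are random rooted bifurcations
with exponential branch lengths; branch lengths can be rescaled so that
simulated alignments hit a target average pairwise identity (API).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .alignment import Alignment
from .models import RateMatrix, stationary_distribution
from .likelihood import _QExp
from .trees import RootedTree, TreeNode

__all__ = [
    "DNR_LEVELS",
    "SimConfig",
    "DatasetManifestEntry",
    "dnr_ladder",
    "ladder_divergence_factor",
    "generate_true_tree",
    "simulate_alignment",
    "compute_api",
    "scale_tree_to_api",
    "simulation_grid",
    "derive_seed",
]

DNR_LEVELS: tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20)

#: Base relative rates at DNR 0, in the canonical keyed order
#: (C-A, A-C, G-A, A-G, A-T, T-A, G-C, C-G, T-G, G-T, C-T, T-C).
_BASE_RATES = (0.166, 0.166, 1.0, 1.0, 0.14, 0.14, 0.131, 0.131, 0.118, 0.118, 1.101, 1.101)

#: Positions of the six "forward" rates that grow with the level.
_FORWARD = (0, 2, 4, 6, 8, 10)

#: Mean of the exponential branch-length distribution for generated trees
#: (expected substitutions/site; trees are typically rescaled to an API
#: target afterwards, so only the shape of the distribution matters).
BRANCH_LENGTH_MEAN = 0.05


def dnr_ladder(level: int) -> list[float]:
    """The 12 relative rates at one rung of the non-reversibility ladder.

    Only the printed levels 0, 2, ..., 20 exist; anything else raises
    (no interpolation).
    """
    if level not in DNR_LEVELS:
        raise ValueError(f"DNR level must be one of {DNR_LEVELS}, got {level!r}")
    rates = list(_BASE_RATES)
    for i in _FORWARD:
        rates[i] += level
    return rates


def ladder_divergence_factor(level: int) -> float:
    """Relative divergence of a ladder level on the shared rate time scale.

    The printed ladder rates share one time scale: the forward rates grow
    with the level while the reverse rates stay fixed, so the raw (un-
    normalized) generator at level L produces more substitutions per unit
    time than the level-0 baseline.  This returns the ratio of expected
    substitution rates, ``E_L / E_0`` with ``E = -sum_i pi_i q_ii`` of the
    raw generator — the factor by which branch lengths calibrated under the
    baseline process must be inflated to evolve sequences at level L on the
    same time scale.  Level 0 gives exactly 1.
    """

    def raw_expected_rate(lvl: int) -> float:
        q = np.zeros((4, 4))
        idx = {n: i for i, n in enumerate("ACGT")}
        from .models import NREV12_RATE_ORDER

        for (x, y), rate in zip(NREV12_RATE_ORDER, dnr_ladder(lvl)):
            q[idx[x], idx[y]] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        pi = stationary_distribution(q).pi
        return float(-(pi * np.diag(q)).sum())

    return raw_expected_rate(level) / raw_expected_rate(0)


def generate_true_tree(n_taxa: int, seed: int) -> RootedTree:
    """Random rooted bifurcating tree with exponential branch lengths.

    Coalescent-style: lineages are merged by uniformly random pair joins
    until one remains; every branch gets an independent Exp(mean =
    ``BRANCH_LENGTH_MEAN``) length.  Deterministic per seed.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    lineages = [TreeNode(f"t{i + 1}") for i in range(n_taxa)]
    for node in lineages:
        node.length = float(rng.exponential(BRANCH_LENGTH_MEAN))
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.exponential(BRANCH_LENGTH_MEAN))
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = parent
    root = lineages[0]
    root.length = 0.0
    return RootedTree(root)


def simulate_alignment(
    tree: RootedTree, q: RateMatrix, n_sites: int, seed: int
) -> Alignment:
    """Evolve an alignment along a tree under the stationarity criterion.

    Root states are drawn from the stationary distribution of Q; each branch
    applies ``P = e^{Q t}``.  Requires a normalized Q so branch lengths are
    in expected substitutions/site.  No among-site rate heterogeneity.
    """
    if not q.normalized:
        raise ValueError("simulate_alignment requires a normalized rate matrix")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(q).pi
    qexp = _QExp(q.q)

    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, size=n_sites, p=pi)
    }
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is not tree.root:
            parent_states = states[id(node.parent)]
            p = qexp.expm(node.length)
            cum = np.cumsum(p, axis=1)
            u = rng.random(n_sites)
            states[id(node)] = (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int64)
        if node.is_leaf:
            seqs[node.name] = states[id(node)]

    nucs = np.array(list("ACGT"))
    taxa = tuple(tree.leaf_names())
    return Alignment(taxa, tuple("".join(nucs[seqs[t]]) for t in taxa))


def compute_api(aln: Alignment) -> float:
    """Average pairwise identity (%) over gap-free column pairs."""
    if aln.n_taxa < 2:
        raise ValueError("API needs at least two sequences")
    codes = aln.codes()
    idents = []
    for i, j in combinations(range(aln.n_taxa), 2):
        ok = (codes[i] < 4) & (codes[j] < 4)
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise ValueError(
                f"no comparable columns between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
            )
        idents.append(float((codes[i][ok] == codes[j][ok]).sum()) / n_ok)
    return 100.0 * float(np.mean(idents))


def _mean_api(tree: RootedTree, q: RateMatrix, seed: int, n_rep: int, n_sites: int) -> float:
    seeds = [derive_seed(seed, ("api", r)) for r in range(n_rep)]
    return float(np.mean(
        [compute_api(simulate_alignment(tree, q, n_sites, s)) for s in seeds]
    ))


def scale_tree_to_api(
    tree: RootedTree,
    q: RateMatrix,
    target_api: float,
    seed: int,
    tolerance: float = 1.0,
    n_rep: int = 3,
    n_sites: int = 5000,
) -> tuple[RootedTree, float]:
    """Find a global branch-length multiplier hitting a target API.

    Bisection on the multiplier (API is monotone decreasing in it): the
    objective is the mean API of ``n_rep`` seeded simulated alignments of
    ``n_sites`` sites.  Returns ``(scaled_tree, achieved_api)`` with the
    achieved value within ``tolerance`` percentage points of the target.
    """
    if not 0 < target_api < 100:
        raise ValueError("target API must be in (0, 100)")
    lo, hi = 1e-3, 1e3

    def api_at(mult: float) -> float:
        return _mean_api(tree.scaled(mult), q, seed, n_rep, n_sites)

    api_lo, api_hi = api_at(lo), api_at(hi)
    if not (api_hi <= target_api <= api_lo):
        raise ValueError(
            f"target API {target_api} outside reachable range "
            f"[{api_hi:.1f}, {api_lo:.1f}] for multipliers in [{lo}, {hi}]"
        )
    mult = 1.0
    for _ in range(60):
        mid = np.sqrt(lo * hi)  # bisect in log space
        api_mid = api_at(mid)
        if abs(api_mid - target_api) <= tolerance:
            return tree.scaled(mid), api_mid
        if api_mid > target_api:
            lo = mid
        else:
            hi = mid
        mult = mid
    achieved = api_at(mult)
    if abs(achieved - target_api) <= tolerance:
        return tree.scaled(mult), achieved
    raise ValueError(f"bisection failed to reach API {target_api} (got {achieved:.2f})")


# ---------------------------------------------------------------------------
# the simulation grid

@dataclass(frozen=True)
class SimConfig:
    """Design of the simulation benchmark.

    Defaults match the full design (5 API trees x 11 DNR levels x 100
    replicates = 5,500 alignments); tests and examples run scaled-down grids.
    """

    n_taxa: int = 12
    n_sites: int = 2000
    dnr_levels: tuple[int, ...] = DNR_LEVELS
    api_targets: tuple[float, ...] = (75.0, 80.0, 85.0, 90.0, 95.0)
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.dnr_levels) <= set(DNR_LEVELS):
            raise ValueError(f"dnr_levels must be drawn from {DNR_LEVELS}")
        if not all(0 < a < 100 for a in self.api_targets):
            raise ValueError("API targets must be in (0, 100)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class DatasetManifestEntry:
    tree_id: float  # the API level of the true tree
    dnr_level: int
    replicate: int
    seed: int
    tree_path: str = ""
    alignment_path: str = ""


def derive_seed(master_seed: int, key: tuple) -> int:
    """Deterministic per-entry seed below 2^31.

    Uses numpy's SeedSequence with the entry key folded into the spawn key,
    so distinct entries get statistically independent streams.
    """
    digest = [
        zlib.crc32(k.encode()) & 0x7FFFFFFF if isinstance(k, str) else int(k)
        for k in key
    ]
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(digest))
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def simulation_grid(config: SimConfig) -> list[DatasetManifestEntry]:
    """Manifest of the full benchmark grid: one entry per
    (API tree x DNR level x replicate), with per-entry derived seeds."""
    entries = []
    for t_idx, api in enumerate(config.api_targets):
        for level in config.dnr_levels:
            for rep in range(config.replicates):
                entries.append(DatasetManifestEntry(
                    tree_id=api,
                    dnr_level=level,
                    replicate=rep,
                    seed=derive_seed(config.seed, (t_idx, level, rep)),
                ))
    return entries
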