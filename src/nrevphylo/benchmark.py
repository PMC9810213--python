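"""Tree-inference benchmark: how non-reversible evolution degrades accuracy.

For each simulated dataset a tree is inferred under GTR and under NREV12 and
each inferred tree is scored against the true tree with the weighted
Robinson-Foulds (wRF) distance — the sum over the union of unrooted
bipartitions of absolute branch-length differences, where a bipartition
present in only one tree contributes its full length.  Paired t-tests per
(DNR, API) cell then ask whether the correctly specified NREV12 beats the
mis-specified GTR, with Holm adjustment across cells.

Tree inference is a deterministic small-scale ML search: neighbor-joining
start tree, then alternating model refits, coordinate-wise branch-length
optimization, and first-improvement NNI sweeps.  Trees are compared
unrooted (the two root child edges merged), since wRF operates on split
sets; the root placement used during NREV12 inference is therefore not
scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from itertools import combinations

import numpy as np
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj
from statsmodels.stats.multitest import multipletests

from .alignment import Alignment
from .likelihood import (
    FitOptions,
    ModelFit,
    PruningEngine,
    _sweep_branch_lengths,
    fit_model,
)
from .models import Family, build_nrev12
from .simulate import (
    SimConfig,
    dnr_ladder,
    derive_seed,
    generate_true_tree,
    ladder_divergence_factor,
    scale_tree_to_api,
    simulate_alignment,
    simulation_grid,
)
from .trees import RootedTree, TreeError

__all__ = [
    "BenchmarkRecord",
    "PairedTestResult",
    "build_start_tree",
    "optimize_branch_lengths",
    "infer_tree",
    "wrf_distance",
    "paired_wrf_test",
    "run_benchmark",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    api_level: float
    dnr_level: int
    replicate: int
    wrf_gtr: float
    wrf_nrev12: float


@dataclass(frozen=True)
class PairedTestResult:
    dnr_level: int
    api_level: float
    mean_difference: float
    t_statistic: float
    p_value: float
    adjusted_p_value: float
    n_pairs: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# start tree

def build_start_tree(aln: Alignment) -> RootedTree:
    """Neighbor-joining start tree on pairwise p-distances.

    Deterministic for a fixed alignment; negative NJ branch lengths are
    clamped to zero; the tree is rooted on the edge of the alphabetically
    first taxon (recorded, arbitrary).
    """
    if aln.n_taxa < 4:
        raise TreeError("need at least 4 sequences to build a tree")
    codes = aln.codes()
    n = aln.n_taxa
    dmat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ok = (codes[i] < 4) & (codes[j] < 4)
        if not ok.any():
            raise TreeError(
                f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
            )
        d = float((codes[i][ok] != codes[j][ok]).mean())
        dmat[i, j] = dmat[j, i] = d
    njt = nj(DistanceMatrix(dmat, ids=list(aln.taxa)))
    rooted = njt.root_by_outgroup([min(aln.taxa)])
    tree = RootedTree.from_newick(str(rooted))
    for node in tree.branches():
        if node.length < 0 or not np.isfinite(node.length):
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# branch lengths and tree search

def optimize_branch_lengths(tree: RootedTree, aln: Alignment, fit: ModelFit) -> RootedTree:
    """Coordinate-wise ML branch lengths under a fitted model (lnL ascent)."""
    out = tree.copy()
    engine = PruningEngine(out, aln)
    _sweep_branch_lengths(
        engine, fit.q, fit.root_frequencies.pi, fit.gamma, tol=1e-4
    )
    return out


def _nni_candidates(tree: RootedTree):
    """Yield ``(neighbor, local_nodes)`` for each NNI move in deterministic
    edge order, where ``local_nodes`` are the branches touching the swap
    (used for cheap local branch-length rescoring).

    Internal edges are (parent u, child v) with v internal and u internal;
    for the edge spanning the root the exchange happens between the root's
    two child subtrees.
    """
    index = {id(n): i for i, n in enumerate(tree.postorder())}

    def swap(tree2: RootedTree, a_id: int, b_id: int):
        by_index = {idx: n for idx, n in enumerate(tree2.postorder())}
        a, b = by_index[a_id], by_index[b_id]
        pa, pb = a.parent, b.parent
        pa.children[pa.children.index(a)] = b
        pb.children[pb.children.index(b)] = a
        a.parent, b.parent = pb, pa
        return [a, b, pa if pa is not tree2.root else b, pb if pb is not tree2.root else a]

    nodes = list(tree.postorder())
    for v in nodes:
        if v.is_leaf or v is tree.root or v.parent is None:
            continue
        u = v.parent
        if u is tree.root:
            # root-spanning edge: exchange children of v with children of the
            # root's other child (if internal); do it once, from the first child
            others = [c for c in u.children if c is not v]
            if len(others) != 1 or others[0].is_leaf:
                continue
            w = others[0]
            if index[id(v)] > index[id(w)]:
                continue  # visit each root edge pair once
            for vc in v.children:
                for wc in w.children[:1]:
                    t2 = tree.copy()
                    local = swap(t2, index[id(vc)], index[id(wc)])
                    yield t2, local
        else:
            siblings = [c for c in u.children if c is not v]
            if not siblings:
                continue
            s = siblings[0]
            for vc in v.children:
                t2 = tree.copy()
                local = swap(t2, index[id(vc)], index[id(s)])
                yield t2, local


def infer_tree(
    aln: Alignment,
    family: Family | str,
    options: FitOptions | None = None,
    max_sweeps: int = 20,
) -> tuple[RootedTree, ModelFit]:
    """ML tree inference by NNI hill-climbing.

    Starts from the NJ tree and alternates: model-parameter refit (on the
    current tree, branch lengths held), full branch-length optimization,
    then one NNI sweep accepting the first move that improves lnL by more
    than 1e-4 (moves are pre-scored by re-optimizing only the branches the
    swap touches).  Terminates when a sweep accepts nothing.  Returns the
    final tree and the model fit on it.
    """
    family = Family(family)
    base = options or FitOptions(gamma=False, n_starts=1)
    rate_opts = dc_replace(base, optimize_branch_lengths=False)
    tree = build_start_tree(aln)
    fit = fit_model(tree, aln, family, rate_opts)
    engine = PruningEngine(tree, aln)
    best_lnl = _sweep_branch_lengths(
        engine, fit.q, fit.root_frequencies.pi, fit.gamma, tol=base.bl_tol,
        max_sweeps=3,
    )
    converged = False
    for _ in range(max_sweeps):
        accepted = False
        for cand, local in _nni_candidates(tree):
            cand_engine = PruningEngine(cand, aln)
            # cheap local rescoring: only the branches touching the swap
            lnl = _sweep_branch_lengths(
                cand_engine, fit.q, fit.root_frequencies.pi, fit.gamma,
                tol=1e-3, max_sweeps=1, nodes=local, maxiter=20,
            )
            if lnl > best_lnl + 1e-4:
                tree = cand
                engine = cand_engine
                best_lnl = lnl
                accepted = True
                break
        if not accepted:
            converged = True
            break
        fit = fit_model(tree, aln, family, rate_opts)
        best_lnl = max(best_lnl, _sweep_branch_lengths(
            engine, fit.q, fit.root_frequencies.pi, fit.gamma, tol=base.bl_tol,
            max_sweeps=3,
        ))
    fit = dc_replace(fit, tree=tree, log_likelihood=best_lnl)
    if not converged:
        warnings.warn("NNI search hit the sweep limit", RuntimeWarning)
    return tree, fit


# ---------------------------------------------------------------------------
# weighted Robinson-Foulds

def _weighted_splits(tree: RootedTree) -> dict[frozenset, float]:
    """Unrooted weighted bipartitions: split -> total branch length.

    The two edges incident to the root are one unrooted edge, so their
    lengths are summed under a single split.  Splits are canonicalized as
    the side not containing the alphabetically first leaf.
    """
    leaves = frozenset(tree.leaf_names())
    ref = min(leaves)
    below: dict[int, frozenset] = {}
    splits: dict[frozenset, float] = {}
    root_children = tree.root.children
    merge_root = len(root_children) == 2
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root:
            continue
        side = below[id(node)]
        if ref in side:
            side = leaves - side
        if not side or len(side) == len(leaves):
            continue
        length = node.length
        if merge_root and node.parent is tree.root:
            if node is root_children[1]:
                continue  # counted with the first root child
            length = root_children[0].length + root_children[1].length
        splits[side] = splits.get(side, 0.0) + length
    return splits


def wrf_distance(a: RootedTree, b: RootedTree) -> float:
    """Weighted Robinson-Foulds distance between two trees (unrooted).

    ``sum over the union of bipartitions of |len_a - len_b|``; a bipartition
    absent from one tree contributes its full length in the other.
    """
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise TreeError("trees must share the same leaf set")
    sa, sb = _weighted_splits(a), _weighted_splits(b)
    total = 0.0
    for split in set(sa) | set(sb):
        total += abs(sa.get(split, 0.0) - sb.get(split, 0.0))
    return total


# ---------------------------------------------------------------------------
# paired tests and the full experiment

def paired_wrf_test(
    records: list[BenchmarkRecord], adjust: str = "holm"
) -> list[PairedTestResult]:
    """Per-(DNR, API) paired t-tests of wrf_gtr - wrf_nrev12, Holm-adjusted.

    Groups with zero variance of the differences are reported as degenerate
    (p and t are NaN) and excluded from the adjustment.
    """
    groups: dict[tuple[int, float], list[BenchmarkRecord]] = {}
    for rec in records:
        groups.setdefault((rec.dnr_level, rec.api_level), []).append(rec)
    results = []
    raw_ps = []
    for (dnr, api), recs in sorted(groups.items()):
        diffs = np.array([r.wrf_gtr - r.wrf_nrev12 for r in recs])
        if len(diffs) < 2:
            raise ValueError(f"group (DNR={dnr}, API={api}) has fewer than 2 pairs")
        if np.ptp(diffs) == 0.0:
            if diffs[0] == 0.0:
                # no difference anywhere: no evidence against the null
                results.append(PairedTestResult(
                    dnr, api, 0.0, 0.0, 1.0, 1.0, len(diffs)
                ))
                raw_ps.append(1.0)
            else:
                results.append(PairedTestResult(
                    dnr, api, float(diffs.mean()), float("nan"), float("nan"),
                    float("nan"), len(diffs), degenerate=True,
                ))
            continue
        t, p = stats.ttest_1samp(diffs, 0.0)
        results.append(PairedTestResult(
            dnr, api, float(diffs.mean()), float(t), float(p), float(p), len(diffs)
        ))
        raw_ps.append(float(p))
    if raw_ps:
        _, adj, _, _ = multipletests(raw_ps, method=adjust)
        it = iter(adj)
        results = [
            r if r.degenerate else dc_replace(r, adjusted_p_value=float(next(it)))
            for r in results
        ]
    return results


def run_benchmark(
    config: SimConfig,
    fit_options: FitOptions | None = None,
    progress=None,
) -> tuple[list[BenchmarkRecord], list[PairedTestResult]]:
    """Run the full simulate -> infer(GTR, NREV12) -> wRF experiment.

    For each API target a true tree is generated and scaled to that target;
    for each (DNR level, replicate) an alignment is simulated, trees are
    inferred under GTR and NREV12, and both are scored against the true
    tree.  Per-entry failures are logged (warnings) and skipped.
    """
    fit_options = fit_options or FitOptions(gamma=False, n_starts=1)
    level0 = build_nrev12(dnr_ladder(0))
    true_trees: dict[float, RootedTree] = {}
    for t_idx, api in enumerate(config.api_targets):
        base = generate_true_tree(config.n_taxa, derive_seed(config.seed, ("tree", t_idx)))
        scaled, _ = scale_tree_to_api(
            base, level0, api, derive_seed(config.seed, ("scale", t_idx))
        )
        true_trees[api] = scaled

    records: list[BenchmarkRecord] = []
    factors = {lvl: ladder_divergence_factor(lvl) for lvl in config.dnr_levels}
    for entry in simulation_grid(config):
        true_tree = true_trees[entry.tree_id]
        q = build_nrev12(dnr_ladder(entry.dnr_level))
        # the ladder shares one time scale: higher levels substitute faster,
        # so branch lengths calibrated under the baseline process inflate
        sim_tree = true_tree.scaled(factors[entry.dnr_level])
        aln = simulate_alignment(sim_tree, q, config.n_sites, entry.seed)
        try:
            tree_gtr, _ = infer_tree(aln, Family.GTR, fit_options)
            tree_n12, _ = infer_tree(aln, Family.NREV12, fit_options)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(
                f"entry (api={entry.tree_id}, dnr={entry.dnr_level}, "
                f"rep={entry.replicate}) failed: {exc}",
                RuntimeWarning,
            )
            continue
        rec = BenchmarkRecord(
            api_level=entry.tree_id,
            dnr_level=entry.dnr_level,
            replicate=entry.replicate,
            wrf_gtr=wrf_distance(true_tree, tree_gtr),
            wrf_nrev12=wrf_distance(true_tree, tree_n12),
        )
        records.append(rec)
        if progress is not None:
            progress(rec)
    tests = paired_wrf_test(records)
    return records, tests


def records_to_tsv(records: list[BenchmarkRecord]) -> str:
    lines = ["api\tdnr\trep\twrf_gtr\twrf_nrev12"]
    for r in records:
        lines.append(
            f"{r.api_level:g}\t{r.dnr_level}\t{r.replicate}\t"
            f"{r.wrf_gtr:.6g}\t{r.wrf_nrev12:.6g}"
        )
    return "\n".join(lines) + "\n"
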