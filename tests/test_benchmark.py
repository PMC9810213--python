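"""Start trees, branch-length optimization, NNI search, weighted
Robinson-Foulds distances, and the paired accuracy tests."""

import itertools

import numpy as np
import pytest

import dendropy

from nrevphylo import (
    Alignment,
    RootedTree,
    build_nrev12,
    build_start_tree,
    dnr_ladder,
    fit_model,
    infer_tree,
    optimize_branch_lengths,
    paired_wrf_test,
    simulate_alignment,
    wrf_distance,
)
from nrevphylo.benchmark import BenchmarkRecord, _weighted_splits
from nrevphylo.likelihood import FitOptions, PruningEngine
from nrevphylo.models import Family
from nrevphylo.simulate import generate_true_tree
from nrevphylo.trees import TreeError


# ---------------------------------------------------------------------------
# start tree

def test_start_tree_joins_close_pairs():
    aln = Alignment(
        ("a", "b", "c", "d"),
        ("AAAAAAAAAA", "AAAAAAAAAC", "GGGGGGGGGG", "GGGGGGGGGT"),
    )
    tree = build_start_tree(aln)
    splits = {frozenset(s) for s in _weighted_splits(tree)}
    assert frozenset({"c", "d"}) in splits or frozenset({"a", "b"}) in splits


def test_start_tree_deterministic(scaled_tree_api90):
    q = build_nrev12(dnr_ladder(0))
    aln = simulate_alignment(scaled_tree_api90, q, 1000, seed=3)
    assert build_start_tree(aln).to_newick() == build_start_tree(aln).to_newick()


def test_start_tree_recovers_topology_mostly(scaled_tree_api90):
    """NJ on 20 kb simulations finds the true unrooted topology >= 8/10."""
    q = build_nrev12(dnr_ladder(0))
    true_splits = {s for s in _weighted_splits(scaled_tree_api90) if len(s) > 1}
    hits = 0
    for rep in range(10):
        aln = simulate_alignment(scaled_tree_api90, q, 20000, seed=300 + rep)
        est = build_start_tree(aln)
        est_splits = {s for s in _weighted_splits(est) if len(s) > 1}
        full = frozenset(scaled_tree_api90.leaf_names())
        norm = lambda ss: {min(s, full - s, key=sorted) for s in ss}
        if norm(true_splits) == norm(est_splits):
            hits += 1
    assert hits >= 8


# ---------------------------------------------------------------------------
# branch lengths

def test_branch_length_recovery_two_taxon():
    tree = RootedTree.from_newick("(x:0.1,y:0.1);")
    q = build_nrev12(dnr_ladder(0))
    aln = simulate_alignment(tree, q, 20000, seed=5)
    fit = fit_model(tree, aln, Family.NREV12,
                    FitOptions(gamma=False, n_starts=1, optimize_branch_lengths=False))
    out = optimize_branch_lengths(tree, aln, fit)
    # only the sum of the two root edges is identifiable: true total 0.2
    total = sum(n.length for n in out.branches())
    assert 0.17 <= total <= 0.23


def test_branch_length_optimization_is_ascent(scaled_tree_api90):
    q = build_nrev12(dnr_ladder(2))
    aln = simulate_alignment(scaled_tree_api90, q, 1000, seed=8)
    fit = fit_model(scaled_tree_api90, aln, Family.NREV12,
                    FitOptions(gamma=False, n_starts=1, optimize_branch_lengths=False))
    perturbed = scaled_tree_api90.scaled(3.0)
    before = PruningEngine(perturbed, aln).log_likelihood(
        fit.q, fit.root_frequencies.pi, fit.gamma)
    out = optimize_branch_lengths(perturbed, aln, fit)
    after = PruningEngine(out, aln).log_likelihood(
        fit.q, fit.root_frequencies.pi, fit.gamma)
    assert after >= before


def test_zero_divergence_drives_lengths_to_zero():
    aln = Alignment(("a", "b", "c", "d"), ("ACGT" * 50,) * 4)
    tree = RootedTree.from_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
    q = build_nrev12(dnr_ladder(0))
    fit = fit_model(tree, aln, Family.NREV12,
                    FitOptions(gamma=False, n_starts=1, optimize_branch_lengths=False))
    out = optimize_branch_lengths(tree, aln, fit)
    assert all(n.length < 1e-4 for n in out.branches())


# ---------------------------------------------------------------------------
# wRF

def test_wrf_identical_trees_is_zero(scaled_tree_api90):
    assert wrf_distance(scaled_tree_api90, scaled_tree_api90) == 0.0


def test_wrf_single_branch_difference():
    a = RootedTree.from_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);")
    b = RootedTree.from_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.5);")
    # the two root edges merge into one unrooted edge: 0.4 vs 0.7
    assert wrf_distance(a, b) == pytest.approx(0.3)


def test_wrf_symmetric_and_leafset_checked():
    a = RootedTree.from_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);")
    b = RootedTree.from_newick("((A:0.2,C:0.1):0.1,(B:0.1,D:0.1):0.1);")
    assert wrf_distance(a, b) == pytest.approx(wrf_distance(b, a))
    c = RootedTree.from_newick("((A:0.1,B:0.1):0.2,(C:0.1,E:0.1):0.2);")
    with pytest.raises(TreeError):
        wrf_distance(a, c)


def test_wrf_five_taxon_against_enumeration_oracle():
    """Two distinct topologies with toy lengths, checked two independent ways:
    explicit bipartition enumeration and dendropy's weighted RF."""
    nwk_a = "(((A:0.1,B:0.2):0.3,C:0.4):0.05,(D:0.6,E:0.7):0.05);"
    nwk_b = "(((A:0.1,C:0.2):0.25,B:0.35):0.1,(D:0.55,E:0.75):0.1);"
    a = RootedTree.from_newick(nwk_a)
    b = RootedTree.from_newick(nwk_b)

    def oracle_splits(tree):
        leaves = frozenset(tree.leaf_names())
        out = {}
        for node in tree.postorder():
            if node is tree.root:
                continue
            below = frozenset(n.name for n in tree.postorder()
                              if n.is_leaf and _is_descendant(n, node))
            side = min(below, leaves - below, key=sorted)
            length = node.length
            if node.parent is tree.root:
                side_key = side
                out[side_key] = out.get(side_key, 0.0) + length
            else:
                out[side] = out.get(side, 0.0) + length
        return out

    def _is_descendant(leaf, node):
        cur = leaf
        while cur is not None:
            if cur is node:
                return True
            cur = cur.parent
        return False

    sa, sb = oracle_splits(a), oracle_splits(b)
    expected = sum(abs(sa.get(k, 0.0) - sb.get(k, 0.0)) for k in set(sa) | set(sb))
    assert wrf_distance(a, b) == pytest.approx(expected, abs=1e-12)

    ns = dendropy.TaxonNamespace()
    da = dendropy.Tree.get(data=nwk_a, schema="newick", taxon_namespace=ns)
    db = dendropy.Tree.get(data=nwk_b, schema="newick", taxon_namespace=ns)
    da.encode_bipartitions()
    db.encode_bipartitions()
    dd = dendropy.calculate.treecompare.weighted_robinson_foulds_distance(da, db)
    assert wrf_distance(a, b) == pytest.approx(dd, abs=1e-10)


def test_wrf_semimetric_properties():
    rng = np.random.default_rng(77)
    trees = [generate_true_tree(6, seed=int(rng.integers(1 << 30))) for _ in range(4)]
    for x, y in itertools.combinations(trees, 2):
        d = wrf_distance(x, y)
        assert d >= 0
        assert d == pytest.approx(wrf_distance(y, x))
    for x in trees:
        assert wrf_distance(x, x) == 0.0


# ---------------------------------------------------------------------------
# inference

def test_infer_tree_recovers_topology(scaled_tree_api90):
    """DNR 0, ~90% API, 5 kb: inferred unrooted topology matches truth in
    >= 7/10 replicates under both model families."""
    q = build_nrev12(dnr_ladder(0))
    full = frozenset(scaled_tree_api90.leaf_names())
    norm = lambda tree: {
        min(s, full - s, key=sorted)
        for s in _weighted_splits(tree) if 1 < len(s) < len(full) - 1
    }
    true_top = norm(scaled_tree_api90)
    for family in (Family.GTR, Family.NREV12):
        hits = 0
        for rep in range(10):
            aln = simulate_alignment(scaled_tree_api90, q, 5000, seed=700 + rep)
            tree, fit = infer_tree(aln, family)
            if norm(tree) == true_top:
                hits += 1
        assert hits >= 7, family


def test_infer_tree_improves_on_start(scaled_tree_api90):
    q = build_nrev12(dnr_ladder(8))
    aln = simulate_alignment(scaled_tree_api90, q, 2000, seed=900)
    start = build_start_tree(aln)
    tree, fit = infer_tree(aln, Family.NREV12)
    opts = FitOptions(gamma=False, n_starts=1, optimize_branch_lengths=False)
    start_fit = fit_model(start, aln, Family.NREV12, opts)
    assert fit.log_likelihood >= start_fit.log_likelihood - 1e-6


def test_infer_tree_deterministic(scaled_tree_api90):
    q = build_nrev12(dnr_ladder(0))
    aln = simulate_alignment(scaled_tree_api90, q, 1000, seed=42)
    t1, _ = infer_tree(aln, Family.GTR)
    t2, _ = infer_tree(aln, Family.GTR)
    assert t1.to_newick() == t2.to_newick()


# ---------------------------------------------------------------------------
# paired tests

def _records(diffs, dnr=8, api=90.0):
    return [
        BenchmarkRecord(api, dnr, i, wrf_gtr=1.0 + d, wrf_nrev12=1.0)
        for i, d in enumerate(diffs)
    ]


def test_paired_test_identical_vectors():
    res = paired_wrf_test(_records([0.0] * 6))
    assert res[0].t_statistic == 0.0
    assert res[0].p_value == 1.0


def test_paired_test_worked_example():
    res = paired_wrf_test(_records([1.0, 2.0, 3.0, 4.0]))[0]
    assert res.t_statistic == pytest.approx(3.873, abs=1e-3)
    assert res.mean_difference == pytest.approx(2.5)
    assert res.n_pairs == 4


def test_paired_test_degenerate_constant_nonzero():
    res = paired_wrf_test(_records([0.5] * 5))[0]
    assert res.degenerate
    assert np.isnan(res.p_value)


def test_paired_test_holm_adjustment_monotone():
    records = _records([1.0, 2.0, 3.0, 4.0], dnr=8) + _records(
        [0.1, -0.2, 0.3, -0.1], dnr=0
    )
    results = paired_wrf_test(records)
    assert len(results) == 2
    for r in results:
        assert r.adjusted_p_value >= r.p_value - 1e-15


def test_paired_test_requires_pairs():
    with pytest.raises(ValueError):
        paired_wrf_test(_records([1.0]))
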