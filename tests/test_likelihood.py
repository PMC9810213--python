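"""Pruning likelihoods against independent oracles, gamma discretization,
and maximum-likelihood fitting."""

import itertools

import numpy as np
import pytest
from scipy import integrate, linalg
from scipy.stats import gamma as gamma_dist

from nrevphylo import (
    Alignment,
    RootedTree,
    build_gtr,
    build_nrev12,
    build_nrev6,
    discretize_gamma,
    dnr_ladder,
    fit_model,
    log_likelihood,
    compute_dnr,
    simulate_alignment,
    stationary_distribution,
    transition_matrix,
)
from nrevphylo.likelihood import FitOptions
from nrevphylo.models import Family

IDX = {n: i for i, n in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# independent oracles

def taylor_expm(q: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Truncated series sum_k (Qt)^k / k!."""
    acc = np.eye(4)
    term = np.eye(4)
    for k in range(1, terms):
        term = term @ (q * t) / k
        acc = acc + term
    return acc


def enumeration_loglik(tree: RootedTree, aln: Alignment, qmat: np.ndarray,
                       root_freqs: np.ndarray) -> float:
    """Brute force: sum over all internal-node state assignments per site."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    pmats = {id(n): linalg.expm(qmat * n.length) for n in nodes if n is not tree.root}
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            states = {id(n): s for n, s in zip(internals, assign)}
            for n in nodes:
                if n.is_leaf:
                    states[id(n)] = IDX[aln.sequence(n.name)[site]]
            prob = root_freqs[states[id(tree.root)]]
            for n in nodes:
                if n is tree.root:
                    continue
                prob *= pmats[id(n)][states[id(n.parent)], states[id(n)]]
            site_lik += prob
        total += np.log(site_lik)
    return total


def random_nrev12(rng) -> "build_nrev12":
    return build_nrev12(rng.uniform(0.1, 5.0, 12))


# ---------------------------------------------------------------------------
# transition matrices

def test_transition_identity_at_zero():
    q = build_nrev12(dnr_ladder(2))
    assert np.allclose(transition_matrix(q, 0.0), np.eye(4))


def test_transition_rejects_negative_time():
    with pytest.raises(ValueError):
        transition_matrix(build_nrev12(dnr_ladder(0)), -0.1)


@pytest.mark.parametrize("level,t", [(2, 0.1), (8, 0.5), (20, 1.3)])
def test_transition_matches_taylor_series(level, t):
    q = build_nrev12(dnr_ladder(level))
    p = transition_matrix(q, t)
    assert np.max(np.abs(p - taylor_expm(q.q, t))) < 1e-10
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_transition_preserves_stationarity():
    for level in (0, 8, 20):
        q = build_nrev12(dnr_ladder(level))
        pi = stationary_distribution(q).pi
        for t in (0.05, 0.7, 3.0):
            assert np.max(np.abs(pi @ transition_matrix(q, t) - pi)) < 1e-10


# ---------------------------------------------------------------------------
# discrete gamma

def test_gamma_single_category():
    g = discretize_gamma(0.5, 1)
    assert g.rates.tolist() == [1.0]


def test_gamma_concentrates_at_large_shape():
    g = discretize_gamma(1e6, 4)
    assert np.allclose(g.rates, 1.0, atol=1e-2)


def test_gamma_category_means_match_quadrature():
    """shape=1 (exponential): quartile conditional means by numeric integration."""
    g = discretize_gamma(1.0, 4)
    edges = gamma_dist.ppf([0, 0.25, 0.5, 0.75, 1.0], a=1.0, scale=1.0)
    expected = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(lambda x: x * np.exp(-x), lo, min(hi, 200.0))
        expected.append(4.0 * val)
    assert np.allclose(g.rates, expected, atol=1e-6)
    assert abs(g.rates.mean() - 1.0) < 1e-10


def test_gamma_rejects_bad_shape():
    with pytest.raises(ValueError):
        discretize_gamma(-1.0, 4)


# ---------------------------------------------------------------------------
# pruning likelihood

def test_degenerate_tree_zero_branches():
    """Two taxa joined at the root with zero branch lengths: lnL is the log
    root-frequency of each observed (shared) state."""
    tree = RootedTree.from_newick("(A:0.0,B:0.0);")
    aln = Alignment(("A", "B"), ("ACGT", "ACGT"))
    q = build_nrev12(dnr_ladder(0))
    pi = stationary_distribution(q)
    lnl = log_likelihood(tree, aln, q, pi)
    assert lnl == pytest.approx(np.sum(np.log(pi.pi)), abs=1e-10)


def test_pruning_matches_enumeration_fixed_example(four_taxon_tree):
    rng = np.random.default_rng(7)
    q = random_nrev12(rng)
    aln = simulate_alignment(four_taxon_tree, q, 20, seed=3)
    pi = stationary_distribution(q).pi
    mine = log_likelihood(four_taxon_tree, aln, q, pi)
    oracle = enumeration_loglik(four_taxon_tree, aln, q.q, pi)
    assert mine == pytest.approx(oracle, abs=1e-10)


def test_pruning_handles_ambiguity_as_missing(four_taxon_tree):
    q = build_nrev12(dnr_ladder(2))
    pi = stationary_distribution(q)
    aln1 = Alignment(("A", "B", "C", "D"), ("ACGT", "ACGT", "ACGT", "ACGT"))
    aln2 = Alignment(("A", "B", "C", "D"), ("ACGT", "ACGT", "ACGT", "NNNN"))
    # a fully-missing sequence marginalizes out: lnL equals the 3-taxon value
    lnl_full = log_likelihood(four_taxon_tree, aln2, q, pi)
    pruned = RootedTree.from_newick("((A:0.10,B:0.20):0.05,C:0.37);")
    lnl_three = log_likelihood(pruned, Alignment(("A", "B", "C"), ("ACGT",) * 3), q, pi)
    assert lnl_full == pytest.approx(lnl_three, abs=1e-9)
    assert log_likelihood(four_taxon_tree, aln1, q, pi) < lnl_full


def test_site_order_invariance(four_taxon_tree, small_alignment):
    q = build_nrev12(dnr_ladder(2))
    pi = stationary_distribution(q)
    rng = np.random.default_rng(0)
    perm = rng.permutation(small_alignment.n_sites)
    shuffled = Alignment(
        small_alignment.taxa,
        tuple("".join(s[i] for i in perm) for s in small_alignment.sequences),
    )
    a = log_likelihood(four_taxon_tree, small_alignment, q, pi)
    b = log_likelihood(four_taxon_tree, shuffled, q, pi)
    assert a == pytest.approx(b, abs=1e-9)


def test_pulley_principle_gtr_only(small_alignment):
    """Re-rooting along the internal edge leaves GTR lnL unchanged but
    changes the non-reversible NREV12 lnL."""
    t1 = RootedTree.from_newick("((A:0.10,B:0.20):0.02,(C:0.30,D:0.15):0.10);")
    t2 = RootedTree.from_newick("((A:0.10,B:0.20):0.09,(C:0.30,D:0.15):0.03);")
    freqs = [0.1, 0.2, 0.3, 0.4]
    gtr = build_gtr([1, 2, 0.5, 1, 3, 1], freqs)
    a = log_likelihood(t1, small_alignment, gtr, np.array(freqs))
    b = log_likelihood(t2, small_alignment, gtr, np.array(freqs))
    assert a == pytest.approx(b, abs=1e-8)

    q12 = build_nrev12(dnr_ladder(2))
    pi = stationary_distribution(q12)
    a12 = log_likelihood(t1, small_alignment, q12, pi)
    b12 = log_likelihood(t2, small_alignment, q12, pi)
    assert abs(a12 - b12) > 1e-4


def test_pruning_matches_enumeration_random_trees():
    """Property: pruning == enumeration on random shapes/models (5 taxa)."""
    rng = np.random.default_rng(123)
    from nrevphylo.simulate import generate_true_tree

    for trial in range(5):
        tree = generate_true_tree(5, seed=int(rng.integers(1 << 30)))
        q = random_nrev12(rng)
        aln = simulate_alignment(tree, q, 10, seed=int(rng.integers(1 << 30)))
        pi = stationary_distribution(q).pi
        mine = log_likelihood(tree, aln, q, pi)
        oracle = enumeration_loglik(tree, aln, q.q, pi)
        assert mine == pytest.approx(oracle, abs=1e-10)


# ---------------------------------------------------------------------------
# fitting

def test_fit_nesting_inequalities(scaled_tree_api90, fast_options):
    q = build_nrev12(dnr_ladder(4))
    aln = simulate_alignment(scaled_tree_api90, q, 2000, seed=21)
    l6 = fit_model(scaled_tree_api90, aln, Family.NREV6, fast_options).log_likelihood
    lg = fit_model(scaled_tree_api90, aln, Family.GTR, fast_options).log_likelihood
    l12 = fit_model(scaled_tree_api90, aln, Family.NREV12, fast_options).log_likelihood
    assert l12 >= l6 - 1e-3
    assert l12 >= lg - 1e-3


def test_nrev12_recovers_nrev6_pair_equality(eight_taxon_tree, fast_options):
    """Data from a strand-symmetric model: the NREV12 fit should estimate
    complementary rates equal within ~10%."""
    q6 = build_nrev6([0.6, 1.0, 0.5, 0.7, 1.4, 0.8])
    aln = simulate_alignment(eight_taxon_tree, q6, 10000, seed=31)
    fit = fit_model(eight_taxon_tree, aln, Family.NREV12, fast_options)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for (x, y), rate in fit.rates.items():
        partner = fit.rates[(comp[x], comp[y])]
        assert rate == pytest.approx(partner, rel=0.10)


def test_recovery_improves_with_data(scaled_tree_api90, fast_options):
    q = build_nrev12(dnr_ladder(2))
    true = np.array(dnr_ladder(2))

    def rel_err(n_sites, seed):
        aln = simulate_alignment(scaled_tree_api90, q, n_sites, seed=seed)
        fit = fit_model(scaled_tree_api90, aln, Family.NREV12, fast_options)
        est = np.array(fit.rates_nrev12_order())
        return float(np.mean(np.abs(est - true) / true))

    assert rel_err(20000, 51) < rel_err(2000, 51)


def test_fit_dnr_recovery_2kb(scaled_tree_api90, fast_options):
    q = build_nrev12(dnr_ladder(2))
    aln = simulate_alignment(scaled_tree_api90, q, 20000, seed=61)
    fit = fit_model(scaled_tree_api90, aln, Family.NREV12, fast_options)
    assert 1.5 <= compute_dnr(fit.rates).average_dnr <= 2.5
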