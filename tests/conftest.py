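import numpy as np
import pytest

from nrevphylo import (
    Alignment,
    RootedTree,
    build_nrev12,
    dnr_ladder,
    generate_true_tree,
    scale_tree_to_api,
    simulate_alignment,
)
from nrevphylo.likelihood import FitOptions

#: Table of the rate ladder used throughout: level -> 12 rates in the
#: canonical keyed order (C-A, A-C, G-A, A-G, A-T, T-A, G-C, C-G, T-G, G-T,
#: C-T, T-C).  Levels add a constant to the six forward rates.
BASE_RATES = [0.166, 0.166, 1.0, 1.0, 0.14, 0.14, 0.131, 0.131, 0.118, 0.118, 1.101, 1.101]


@pytest.fixture(scope="session")
def four_taxon_tree() -> RootedTree:
    return RootedTree.from_newick("((A:0.10,B:0.20):0.05,(C:0.30,D:0.15):0.07);")


@pytest.fixture(scope="session")
def eight_taxon_tree() -> RootedTree:
    return generate_true_tree(8, seed=11)


@pytest.fixture(scope="session")
def scaled_tree_api90(eight_taxon_tree) -> RootedTree:
    """Eight-taxon tree scaled so level-0 simulations sit near 90% API."""
    q0 = build_nrev12(dnr_ladder(0))
    tree, _ = scale_tree_to_api(eight_taxon_tree, q0, 90.0, seed=5)
    return tree


@pytest.fixture(scope="session")
def small_alignment(four_taxon_tree) -> Alignment:
    q = build_nrev12(dnr_ladder(2))
    return simulate_alignment(four_taxon_tree, q, 200, seed=42)


@pytest.fixture(scope="session")
def fast_options() -> FitOptions:
    """Single-start, no-gamma, fixed-branch-length options for quick fits."""
    return FitOptions(gamma=False, n_starts=1, optimize_branch_lengths=False)
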