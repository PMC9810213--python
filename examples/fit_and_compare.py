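"""Fit GTR / NREV6 / NREV12 to one dataset and compare them.

Simulates an alignment under a known non-reversible model (ladder level 4)
on a random 8-taxon tree, then runs the three-family comparison: maximum-
likelihood fits, AIC-c scores, Akaike weights, the two likelihood-ratio
tests, and the DNR estimated from the NREV12 rates.  With truly
non-reversible data NREV12 should win both tests and carry most of the
Akaike weight.
"""

from nrevphylo import (
    build_nrev12,
    compare_models,
    dnr_ladder,
    generate_true_tree,
    scale_tree_to_api,
    simulate_alignment,
)
from nrevphylo.likelihood import FitOptions

TRUE_LEVEL = 4

base = generate_true_tree(8, seed=11)
tree, api = scale_tree_to_api(base, build_nrev12(dnr_ladder(0)), 90.0, seed=5)
q = build_nrev12(dnr_ladder(TRUE_LEVEL))
aln = simulate_alignment(tree, q, 5000, seed=77)
print(f"simulated 8 taxa x {aln.n_sites} sites at ~{api:.0f}% identity, "
      f"true DNR = {TRUE_LEVEL}")

options = FitOptions(gamma=False, n_starts=1, optimize_branch_lengths=False)
report = compare_models(tree, aln, options)

print("\nfamily      lnL          AIC-c        Akaike weight")
for family, fit in report.fits.items():
    print(f"{family.value:<10}  {fit.log_likelihood:>11.2f}  "
          f"{report.aicc_scores[family]:>11.2f}  {report.akaike_weights[family]:.4f}")
for pair, res in report.lrt_results.items():
    print(f"LRT {pair[0].value} vs {pair[1].value}: "
          f"statistic {res.statistic:.2f}, df {res.df}, p = {res.p_value:.3g}")
print(f"best family by AIC-c: {report.best_family.value}")
print(f"estimated average DNR: {report.dnr.average_dnr:.2f} (truth {TRUE_LEVEL})")
print("\nLow p-values mean the 12-rate non-reversible model fits significantly")
print("better than its reversible/strand-symmetric nested alternatives.")
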