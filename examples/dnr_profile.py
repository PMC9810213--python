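"""Quantify strand-specific substitution bias with the DNR statistic.

Builds NREV12 rate matrices from the benchmark rate ladder and prints, for
each, the per-pair and average degree of non-reversibility (DNR) plus the
Kolmogorov irreversibility indices.  A DNR of 0 means every substitution
type runs at the same relative rate in both directions (a reversible
process); larger values mean stronger directional bias.
"""

from nrevphylo import (
    build_nrev12,
    compute_dnr,
    dnr_ladder,
    irreversibility_indices,
    is_reversible,
)

for level in (0, 2, 10, 20):
    rates = dnr_ladder(level)
    profile = compute_dnr(rates)
    q = build_nrev12(rates)
    iri = irreversibility_indices(q)
    print(f"ladder level {level}:")
    print(f"  per-pair DNR: "
          + ", ".join(f"{x}{y}={v:g}" for (x, y), v in profile.pair_dnr.items()))
    print(f"  average DNR = {profile.average_dnr:g}")
    print(f"  reversible: {is_reversible(q)}; "
          f"irreversibility indices = ({iri.iri[0]:.3g}, {iri.iri[1]:.3g}, {iri.iri[2]:.3g})")

print()
print("Each pair value is |forward rate - reverse rate| on the relative scale")
print("with A->G = 1; the average over the six nucleotide pairs is the")
print("dataset-level DNR. Non-zero cycle indices confirm non-reversibility.")
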