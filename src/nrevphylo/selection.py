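"""Model comparison: likelihood-ratio tests, AIC-c, and Akaike weights.

Nested pairs: NREV6 and GTR are both nested in NREV12, and NREV12 in
NREV12+F (3 extra ML root frequencies).  Likelihood-ratio degrees of freedom
count dimensions the optimizer actually explores: NREV6 (5 free rates) vs
NREV12 (11 free rates) gives df 6; GTR vs NREV12 also gives df 6, because
GTR's equilibrium frequencies are moment plug-ins from the alignment rather
than ML parameters that NREV12 relaxes (empirically, the null distribution
of the statistic tracks chi-square_6, not chi-square_3).  The GTR-in-NREV12
nesting runs through the detailed-balance submanifold, so the chi-square
reference is approximate either way; the caveat is documented.

AIC-c uses the number of alignment columns as the sample size, and its k
follows the conventional count in which GTR's three empirical frequencies
are charged as estimated parameters (GTR 8, NREV6 5, NREV12 11, NREV12+F 14).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .alignment import Alignment
from .likelihood import FitOptions, ModelFit, fit_model
from .models import DNRProfile, Family, compute_dnr
from .trees import RootedTree

__all__ = [
    "LRTResult",
    "ModelComparisonReport",
    "lrt",
    "aicc",
    "akaike_weights",
    "compare_models",
]

#: Allowed (null, alternative) nestings and their degrees of freedom.
NESTED_PAIRS: dict[tuple[Family, Family], int] = {
    (Family.NREV6, Family.NREV12): 6,
    (Family.GTR, Family.NREV12): 6,
    (Family.NREV12, Family.NREV12F): 3,
}


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    null_family: Family
    alt_family: Family


@dataclass(frozen=True)
class ModelComparisonReport:
    fits: dict[Family, ModelFit]
    aicc_scores: dict[Family, float]
    akaike_weights: dict[Family, float]
    lrt_results: dict[tuple[Family, Family], LRTResult]
    best_family: Family
    dnr: DNRProfile
    n_sites: int

    def to_table_row(self, dataset: str = "-") -> str:
        """Tab-separated row: dataset, AIC-c GTR/NREV6/NREV12, the two LRT
        p-values, and the NREV12 average DNR."""
        p_gtr = self.lrt_results[(Family.GTR, Family.NREV12)].p_value
        p_n6 = self.lrt_results[(Family.NREV6, Family.NREV12)].p_value
        cells = [
            dataset,
            f"{self.aicc_scores[Family.GTR]:.1f}",
            f"{self.aicc_scores[Family.NREV6]:.1f}",
            f"{self.aicc_scores[Family.NREV12]:.1f}",
            f"{p_gtr:.4g}",
            f"{p_n6:.4g}",
            f"{self.dnr.average_dnr:.4g}",
        ]
        return "\t".join(cells)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "aicc": {f.value: s for f, s in self.aicc_scores.items()},
            "akaike_weights": {f.value: w for f, w in self.akaike_weights.items()},
            "lrt": {
                f"{a.value}_vs_{b.value}": {
                    "statistic": r.statistic, "df": r.df, "p_value": r.p_value
                }
                for (a, b), r in self.lrt_results.items()
            },
            "best_family": self.best_family.value,
            "dnr": {
                "average": self.dnr.average_dnr,
                "pairs": {f"{x}{y}": v for (x, y), v in self.dnr.pair_dnr.items()},
            },
            "log_likelihoods": {
                f.value: fit.log_likelihood for f, fit in self.fits.items()
            },
            "converged": {f.value: fit.converged for f, fit in self.fits.items()},
        }


def lrt(null_fit: ModelFit, alt_fit: ModelFit) -> LRTResult:
    """Likelihood-ratio test of two nested fits.

    ``statistic = 2 (lnL_alt - lnL_null)`` clamped at zero, referred to the
    chi-square with df equal to the parameter-count difference.
    """
    key = (null_fit.family, alt_fit.family)
    if key not in NESTED_PAIRS:
        raise ValueError(f"{key[0].value} is not nested in {key[1].value}")
    stat = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if stat < -1e-3:
        import warnings

        warnings.warn(
            f"LRT statistic {stat:.4g} < 0: the {alt_fit.family.value} "
            "optimizer likely failed to reach the nested optimum",
            RuntimeWarning,
        )
    stat = max(stat, 0.0)
    df = NESTED_PAIRS[key]
    p = float(chi2.sf(stat, df))
    return LRTResult(stat, df, p, null_fit.family, alt_fit.family)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 lnL + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AIC-c undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_scores) -> np.ndarray:
    """Akaike weights ``w_m = exp(-delta_m/2) / sum exp(-delta/2)``."""
    scores = np.asarray(list(aicc_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one AIC-c score")
    if not np.all(np.isfinite(scores)):
        raise ValueError("AIC-c scores must be finite")
    delta = scores - scores.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def compare_models(
    tree: RootedTree,
    aln: Alignment,
    options: FitOptions | None = None,
    include_nrev12f: bool = False,
) -> ModelComparisonReport:
    """Fit GTR, NREV6, NREV12 (and optionally NREV12+F), then compare.

    Produces AIC-c per family (n = alignment columns), Akaike weights, the
    NREV6-vs-NREV12 and GTR-vs-NREV12 likelihood-ratio tests, the family with
    the lowest AIC-c, and the DNR profile of the NREV12 rate estimates.
    """
    options = options or FitOptions()
    families = [Family.GTR, Family.NREV6, Family.NREV12]
    if include_nrev12f:
        families.append(Family.NREV12F)
    fits = {fam: fit_model(tree, aln, fam, options) for fam in families}

    scores = {fam: aicc(f.log_likelihood, f.k, aln.n_sites) for fam, f in fits.items()}
    weights = dict(zip(scores, akaike_weights(scores.values())))
    lrts = {
        (Family.NREV6, Family.NREV12): lrt(fits[Family.NREV6], fits[Family.NREV12]),
        (Family.GTR, Family.NREV12): lrt(fits[Family.GTR], fits[Family.NREV12]),
    }
    if include_nrev12f:
        lrts[(Family.NREV12, Family.NREV12F)] = lrt(
            fits[Family.NREV12], fits[Family.NREV12F]
        )
    best = min(scores, key=scores.get)
    dnr = compute_dnr(fits[Family.NREV12].rates)
    return ModelComparisonReport(
        fits=fits,
        aicc_scores=scores,
        akaike_weights=weights,
        lrt_results=lrts,
        best_family=best,
        dnr=dnr,
        n_sites=aln.n_sites,
    )
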