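# Methods

## Substitution models

All matrices are 4x4 continuous-time Markov generators over the state order
A, C, G, T, rows indexing the from-state.  Off-diagonals are non-negative,
rows sum to zero, and constructors return matrices normalized so that the
expected substitution rate at stationarity, `-sum_i pi_i q_ii`, equals 1 —
branch lengths are then expected substitutions per site.

* **GTR**: `q_ij = r_ij pi_j` with symmetric exchangeabilities `r_ij = r_ji`
  (six, keyed AC, AG, AT, CG, CT, GT) and supplied frequencies.  Detailed
  balance `pi_i q_ij = pi_j q_ji` holds identically.
* **NREV6**: the six rates are assigned to the off-diagonals directly, each
  shared with the complementary substitution (`q[x->y] = q[comp(x)->comp(y)]`).
  The induced stationary distribution always satisfies `pi_A = pi_T`,
  `pi_C = pi_G` (strand symmetry), which the test suite asserts.
* **NREV12**: each off-diagonal is its own rate.  For both non-reversible
  families the equilibrium frequencies are *induced* by `pi Q = 0`
  (solved by least squares on the augmented system; residual checked below
  1e-10 relative, typically ~1e-16).  Writing the off-diagonals as
  rate-times-frequency products would be circular when the frequencies are
  themselves model-induced, so the rates stand alone.

The reference rate is `A -> G = 1` throughout: builders accept any positive
rates, but ML fitting fixes `A -> G` and DNR values are reported on this
relative scale (they are scale-dependent by construction).

**Degree of non-reversibility (DNR).**  For each unordered nucleotide pair
`{x, y}`, `pair_dnr = |rate(x->y) - rate(y->x)|`; the dataset-level DNR is
the mean of the six pair values.  **Irreversibility indices** implement the
Kolmogorov cycle criterion on the normalized matrix: for each of the three
independent 3-cycles (A,C,G), (A,C,T), (A,G,T), the index is
`q_ij q_jk q_ki - q_ik q_kj q_ji`.  A chain is reversible iff all cycle
products balance, so reversible matrices give three zeros and genuinely
non-reversible ones give three non-zero indices.

## Likelihood

Felsenstein pruning on rooted trees over compressed site patterns.  Gaps
and IUPAC ambiguity codes are missing data: a leaf contributes a 0/1
partial vector over its compatible states.  Underflow is handled by
per-internal-node rescaling with accumulated log factors.  Because Q need
not be reversible there is no pulley principle: per-site likelihoods are
`sum_i root_freq_i L_i(root)` and moving the root changes the likelihood
(the suite asserts both the GTR invariance and the NREV12 non-invariance).

Transition probabilities `P(t) = e^{Qt}` use a cached complex
eigendecomposition when it reconstructs Q to 1e-10 (non-reversible
generators can have complex eigenvalues), falling back to
scaling-and-squaring `expm` otherwise; rows are clipped to [0, 1] and
renormalized against roundoff.

Among-site rate heterogeneity uses the discrete gamma with equal-probability
categories and mean-of-category rates (mean 1 by construction), 4 categories
by default; category means are computed from regularized incomplete gamma
functions and cross-checked against quadrature in the tests.

## Maximum-likelihood fitting

Free parameters: the relative rates (5 for GTR/NREV6, 11 for NREV12,
log-transformed, bounds [1e-6, 100]), the gamma shape (log-transformed,
bounds [0.01, 100]) when enabled, three root-frequency parameters
(additive log-ratio) for NREV12+F, and optionally the branch lengths
(bounds [0, 10]).  Root frequencies for the base NREV6/NREV12 models
default to the empirical alignment frequencies, with stationary-pi and ML
modes as options; GTR uses empirical frequencies as both equilibrium and
root distribution.

Optimization is multi-start L-BFGS-B (up to three starts: all-ones, a
seeded random perturbation, and a start informed by pairwise mismatch
counts), alternating with coordinate-wise (bounded Brent) branch-length
sweeps when branch lengths are free; the alternation stops when a full
round gains < 1e-6 lnL (capped at 10 rounds, with a convergence flag and a
warning otherwise).  Long-running loops in the tests and the benchmark use
single-start fits without gamma and, where the true tree is known and
given, fixed branch lengths — these are exposed `FitOptions`, chosen to
keep the default suite fast; they do not change any default.

## Model comparison

* **LRT**: `2 (lnL_alt - lnL_null)` clamped at zero against chi-square.
  Degrees of freedom count dimensions the optimizer explores: 6 for
  NREV6-vs-NREV12 and 6 for GTR-vs-NREV12 — GTR's three equilibrium
  frequencies are moment plug-ins from the alignment, not ML parameters
  that NREV12 relaxes.  This choice was validated empirically: under
  reversible data the statistic's null distribution tracks chi-square_6
  (rejection ~2% at alpha = 0.05 over 60 replicates) while chi-square_3
  over-rejects (~17%).  NREV12-vs-NREV12+F has df 3.  The GTR-in-NREV12
  nesting passes through the detailed-balance submanifold, so the
  chi-square reference is approximate regardless; the suite checks the
  calibration of the NREV6-vs-NREV12 test directly (rejection within
  [1%, 12%] over 200 nested-null replicates).
* **AIC-c**: `-2 lnL + 2k + 2k(k+1)/(n-k-1)` with `n` = alignment columns.
  `k` uses the conventional counts (GTR 8, NREV6 5, NREV12 11, NREV12+F 14,
  +1 for the gamma shape, + the branch count when branch lengths are
  re-fit; shared terms cancel in comparisons).
* **Akaike weights**: `w_m = exp(-delta_m/2) / sum exp(-delta/2)`.

## Simulation

The built-in rate ladder spans DNR 0, 2, ..., 20: six reverse rates fixed
(A->C 0.166, A->G 1, T->A 0.14, C->G 0.131, G->T 0.118, T->C 1.101), six
forward rates equal to the same base plus the level, so the per-pair
differences — and the average DNR — equal the level exactly.  Level 0 is
symmetric and fully reversible; every positive level fails the Kolmogorov
criterion on all three cycles.  Levels off the grid are rejected rather
than interpolated.

Sequences evolve under the stationarity criterion: root states are drawn
from the stationary distribution of Q and each branch applies `e^{Qt}`, so
base composition is constant in time.  `simulate_alignment` requires a
normalized matrix; no rate heterogeneity is simulated by default.  True
trees are random rooted bifurcations (uniform pair joins) with iid
exponential branch lengths (mean 0.05 substitutions/site — only the shape
matters because trees are rescaled afterwards); a global branch-length
multiplier is found by log-space bisection so that the mean average
pairwise identity (API) of three seeded 5 kb simulations hits a target
within +/-1 percentage point.  API is the mean over sequence pairs of the
fraction of identical positions among columns where neither sequence has a
gap, in percent.  Per-dataset seeds derive from the master seed through
numpy `SeedSequence` spawn keys (strings folded via CRC32), so grids are
reproducible and entries independent.

**A common time scale across the ladder.**  Normalized to one expected
substitution per unit time, every ladder level produces the same realized
divergence and inference accuracy is empirically flat in DNR.  The ladder's
printed rates, however, share one scale: the forward rates grow with the
level, so at a fixed time the level-L process generates more substitutions
(raw expected-rate ratio `E_L/E_0`: ~3.0 at L=2, ~8.9 at L=8, ~20.7 at
L=20).  The benchmark therefore multiplies branch lengths by
`ladder_divergence_factor(L)` before simulating, and scores inferred trees
against the *unscaled* true tree.  Rising DNR then degrades accuracy both
through branch-length inflation and progressive saturation — which is the
phenomenon the benchmark exists to measure.  Level 0 has factor 1, so
reversible baselines are unaffected.

## Tree-inference benchmark

Start trees are neighbor joining (scikit-bio) on pairwise p-distances,
negative NJ lengths clamped to zero, rooted deterministically on the
alphabetically first taxon (non-reversible inference needs *a* root; a
full root-position search is out of scope and the root is excluded from
scoring).  The search alternates model refits (branch lengths held),
full coordinate-wise branch-length optimization, and first-improvement NNI
sweeps in deterministic edge order; candidate moves are pre-scored by
re-optimizing only the branches touching the swap and accepted when lnL
improves by > 1e-4; the search stops when a sweep accepts nothing (cap 20
sweeps, flagged if hit).  The lnL trajectory is non-decreasing across
accepted moves.

**wRF** is computed over unrooted weighted bipartitions (the two root child
edges merge into one edge): the sum over the union of splits of
`|len_a - len_b|`, unshared splits contributing their full length; pendant
edges are included.  The implementation is cross-checked against dendropy's
weighted Robinson-Foulds and a direct bipartition enumeration.

Per (DNR, API) cell, a paired t-test on `wrf_GTR - wrf_NREV12` with Holm
adjustment across cells; all-zero differences give t = 0, p = 1, while a
constant non-zero difference vector is reported as degenerate rather than
assigned a fabricated p-value.

## Problem sizes in the test suite

The default suite runs desk-scale versions of the experiments: likelihood
correctness on 4-5-taxon trees against brute-force enumeration (50 random
cases), DNR recovery at 20 kb on 12 taxa (levels 2 and 8, +/-25%), LRT
calibration with 200 replicates of 2 kb on 8 taxa, and the accuracy trend
with one ~90%-API tree, levels {0, 8, 20}, 10 replicates of 2 kb on 8
taxa.  The full 5,500-dataset design is enumerated (and counted) through
the manifest generator and can be executed with the `benchmark`/`simulate`
CLI at full scale.

## Known limitations

* No partitioned models, invariant-sites category, codon/amino-acid models,
  or Bayesian inference; NNI-only search (no SPR/TBR), no bootstrap.
* The chi-square reference for GTR-vs-NREV12 is approximate (non-standard
  nesting); treat borderline p-values with care.
* DNR magnitudes depend on the `A -> G = 1` reference convention; values
  computed under a different reference rate are not comparable.
* Simulated data lack indels, recombination, among-lineage rate variation,
  and rate heterogeneity among sites unless requested — passing tests show
  correctness of the implemented process, not robustness to every feature
  of real virus alignments.
* At extreme divergence (high ladder levels) some reverse rates become
  nearly unidentifiable at a few kb; their estimates can hit the optimizer
  bounds and DNR estimates inflate accordingly.
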