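# Methods

## Modified Band Depth

For a sample collection **y**₁,…,**y**ₙ ∈ ℝᵈ the band of a pair
(**y**_{i₁}, **y**_{i₂}) is the region between their coordinate-wise minimum
and maximum. MBD(**y**ᵢ) is the average over all C(n,2) pairs of the
proportion of coordinates of **y**ᵢ inside the pair's band. It is a
unitless proportion; in-sample values lie in [2/n, 1] (every coordinate is
an endpoint of the n−1 bands through its own sample) and induce a
center-outward ordering whose maximizer is the most representative profile.

The production path never enumerates pairs. For each column the value
y_{i,k} has a minimal sorted-position l and multiplicity η, and the number
of pair-bands containing it at that coordinate decomposes by cases
(both band endpoints below/above/equal) into

  (l−1)(n−l−η+1) + (l−1)η + η(n−l−η+1) + C(η,2)
  = (n−l+1)(l−1+η) − η² + C(η,2).

Summing over columns and dividing by d·C(n,2) reproduces the pairwise
definition exactly; the cost is one rank computation per column,
O(d·n log n) overall. Correctness is established in the test suite by
equivalence with the brute-force implementation (max deviation ≤ 1e-12
over hundreds of random matrices with and without ties), not by the
algebra alone.

For a new observation **x** relative to a reference collection the count
uses l₁ = #{reference values < x_k}, l₂ = #{≤ x_k}, η = l₂ − l₁:

  (n − l₂)(l₁ + η) + l₁·η + C(η,2).

A point that coincides with a reference row gets exactly its in-sample
depth; a point outside the reference's coordinate-wise range at every
column gets depth exactly 0 (out-of-sample depths live in [0, 1], with no
2/n floor).

### Numerical conventions

- **Ties are exact.** Two floating-point values share a multiplicity class
  iff they compare equal (`==`). No epsilon is applied; users standardizing
  data should expect ties only where values are bit-identical.
- **Non-finite entries are rejected**, not imputed: depth has no defined
  semantics for missing coordinates.
- **Ordering ties** are broken by ascending original row index (stable
  sort), so the center-outward ordering is deterministic.
- Depth requires n ≥ 2 (the pair count must be positive); n = 2 gives both
  samples depth 1.

## Depth-derived statistics

**Retention rule.** All trimming shares one rule: for trimming proportion
α the ceil((1−α)·n) deepest samples are retained (α = 0 keeps everything);
for a central proportion p the ceil(p·n) deepest samples form the
p-central set — e.g. p = 0.25 of 25 samples selects the 7 most central.

**Trimmed mean.** Component-wise mean of the retained samples. Because the
discarded samples are the most external ones, a small number of grossly
corrupted arrays is excluded before it can drag the estimate (verified on
a 20-clean + 2-outlier fixture in the tests).

**Central bands and scale curve.** The p-central band is the per-variable
min/max envelope of the p-central set; bands for increasing p are nested
by construction. The band's "area" is computed by the trapezoidal rule
over unit-spaced variable indices — the definition of area over an
unordered gene axis is a convention, and the choice (trapezoid vs
rectangle) only rescales the curve without affecting monotonicity,
translation invariance, or between-group comparisons. Consequences:
d = 1 gives area 0 for every p (zero-width domain), and a single central
sample gives area 0. The default p-grid is {k/n : k = 1..n}, the
proportions at which the central set actually changes.

## Two-sample rank test

Given populations X (n₁×d) and Y (n₂×d), subsample sizes n and m and a
seed: n rows of X and m rows of Y are drawn without replacement; the
*non-drawn remainder of X* is the reference; all n+m drawn rows receive
out-of-sample depths with respect to it; depths are jointly ranked
(average ranks on ties) and W is the rank sum of the m Y-depths. Under
the alternative, Y's points fall outside the reference bands and W is
small, so the test is one-sided (alternative: Y stochastically less
deep). The p-value uses the normal approximation with continuity
correction and tie-corrected variance; for n + m ≤ 12 an exact
permutation enumeration over all C(n+m, m) rank splits is used instead
(and is available on request up to n + m = 20).

Design points, made here because the construction admits alternatives:

- The reference is taken from the first population, which makes the test
  asymmetric in (X, Y); both orientations control the type-I error under
  H0 (asserted by simulation), but W values differ between orientations.
- n must satisfy n₁ − n ≥ 2 so the reference spans at least one band.
- The subsampling RNG is NumPy's PCG64 (`default_rng`), so `seed=0` is
  reproducible across platforms and releases.
- Under H0 the drawn points are exchangeable, so the rank statistic is
  distribution-free; empirical size at the 0.05 level over 500 replicates
  (n₁ = n₂ = 25, d = 50, n = m = 12) sits inside the exact binomial 99%
  interval in the acceptance suite.

## DS and TAD classifiers

Both use a labeled learning set with G ≥ 2 classes, each with ≥ 2 members
(within-class depth requires it), and the shared retention rule.

- **DS**: each class is summarized by its within-class α-trimmed mean; a
  test sample goes to the class with the nearest summary. With α = 0 this
  is exactly nearest-centroid on ordinary class means.
- **TAD**: each class retains its ceil((1−α)·n_g) deepest members; the
  class score is the weighted average distance from the test sample to
  those members with weights proportional to their within-class MBD
  (normalized to sum 1); smallest score wins. The depth-proportional
  weighting is the central interpretive decision of this module: it makes
  central, well-replicated profiles dominate the score, and it reduces to
  the nearest-single-prototype rule when only one member is retained.

Distances are Euclidean by default; a metric callable can be supplied but
Euclidean is the tested configuration. Argmin ties are broken by class
order of first appearance in the learning labels. These are hard
classifiers — no posterior probabilities are produced.

## Preprocessing and gene ranking

The expression pipeline follows the classic oligonucleotide-array recipe,
in this order: (i) clip intensities to [floor, ceiling] (defaults 10 and
16000 units); (ii) drop genes whose post-clipping max/min < 5 or
max − min < 500 (either criterion excludes — logical OR); (iii) log₁₀;
(iv) standardize each sample to mean 0 and unit variance (ddof = 1, the
`scale` convention) across the surviving genes. Filtering is applied
after clipping; at least two genes must survive, since per-sample
standardization is undefined on one gene. The recipe is not idempotent
(standardization changes fold ratios), but steps (i)–(iii) applied twice
equal once for in-range inputs.

B/W gene ranking: per gene, the ratio of the sample-count-weighted
between-class sum of squares of class means about the grand mean to the
pooled within-class sum of squares. Degenerate conventions: positive
between with zero within ranks first (ratio +∞); 0/0 (a gene constant
everywhere) is defined as 0 and ranks last.

## Synthetic data generator

`simulate_two_class` draws two classes of multivariate Gaussian rows with
exchangeable within-sample correlation ρ (covariance (1−ρ)I + ρJ via a
shared latent factor), a mean shift on the first `n_informative` genes for
the second class, and an optional fraction of rows displaced by a gross
constant in every coordinate (corrupted-array contamination). Defaults —
25 samples per class, 100 genes, 10 informative genes, unit shift, ρ = 0.2,
no contamination — mirror the shape of a small standardized two-condition
(normal/tumor) microarray study. Output is fully determined by the seed.

What it does *not* emulate: heavy-tailed and gene-specific noise,
platform batch effects, correlated gene blocks beyond exchangeability, and
realistic intensity scales (rows are already standardized-like). Passing
benchmarks on these fixtures therefore demonstrates the statistical
contracts of the methods (oracle equivalence, size control, robustness to
gross contamination, separation at a given signal-to-noise ratio), not
performance on any particular real dataset.

## Benchmark problem sizes

The simulation scales used throughout tests and the acceptance script —
oracle checks at n ≤ 30, d ≤ 100; rank-test operating characteristics at
n₁ = n₂ = 25, d = 50 with 500 null and 200 per-alternative replicates;
classifier benchmarks with 20 training and 5 test samples per class over
100 splits; a 500×2000 matrix for the runtime check — are desk-scale
choices that keep a full verification run in the minutes range while
leaving each Monte-Carlo estimate enough replicates for its stated
tolerance.

## Known limitations

- MBD is invariant under strictly increasing per-column transforms; it is
  therefore blind to scale differences confined to a single column's
  values' spacing. This is a feature for rank-based robustness but means
  depth alone does not detect variance changes that preserve ranks.
- The scale-curve "area" depends on the column order only through the
  (unit) spacing; permuting genes leaves it unchanged, but it has no
  meaning as a physical area.
- The rank test's power depends on the choice of n, m: a very small
  remainder (n close to n₁ − 2) makes the reference bands noisy.
- The exact rank-test enumeration is combinatorial and restricted to
  n + m ≤ 20.
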