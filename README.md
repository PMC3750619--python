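# mbdtools

Robust, centrality-based analysis of high-dimensional expression matrices
(rows = samples, columns = genes) built on the **Modified Band Depth (MBD)**.

Classical depth notions become intractable beyond a handful of dimensions;
MBD stays feasible for thousands of variables, which makes it well suited to
bulk and single-cell transcriptomics, where one wants to know which sample
profile is most *representative* of a group, which samples are outlying, how
dispersed a group is, and whether two groups of samples plausibly come from
the same population.

## The statistic

For samples **y**₁, …, **y**ₙ ∈ ℝᵈ, the MBD of **y**ᵢ is

MBD(**y**ᵢ) = C(n,2)⁻¹ Σ_{1 ≤ i₁ < i₂ ≤ n} d⁻¹ Σ_{k=1}^{d}
𝟙{ min(y_{i₁,k}, y_{i₂,k}) ≤ y_{i,k} ≤ max(y_{i₁,k}, y_{i₂,k}) },

the average proportion of coordinates of **y**ᵢ lying inside the band
(coordinate-wise min/max envelope) of each pair of samples. Instead of
enumerating all pairs (O(d·n³)), `mbdtools` counts, per column, the minimal
rank *l* and multiplicity *η* of each value in the sorted column; the number
of bands containing the value at that coordinate is

(n − l + 1)(l − 1 + η) − η² + C(η, 2),

which gives identical depths in O(d·n log n). An analogous count with
*l₁* = #{values < x}, *l₂* = #{values ≤ x} yields the depth of *new*
observations with respect to a reference collection.

On this ordering the package builds:

- **trimmed means** — the mean of the deepest ceil((1−α)·n) samples, robust
  to outlying arrays;
- **central bands and scale curves** — the area of the envelope of the
  p·n most central samples as a function of p, a dispersion profile;
- a **two-sample rank test** — subsamples of both groups are depth-ranked
  against the remainder of the first group; the Wilcoxon rank sum *W* of the
  second group's depths tests whether it is systematically less deep;
- the **DS and TAD classifiers** — assign a sample to the class whose
  depth-trimmed mean (DS) or depth-weighted central members (TAD) it is
  closest to.

It also ships matrix CSV/TSV I/O, a microarray-style preprocessing recipe
(clip to [10, 16000], drop genes varying < 5-fold or < 500 units, log₁₀,
per-sample standardization), B/W (between/within sum-of-squares) gene
ranking, a seeded two-class Gaussian fixture generator, and
parallel-coordinate plots of depth structure.

## Worked example

```python
import numpy as np
from mbdtools import (SimulationConfig, simulate_two_class, mbd, tmean,
                      rank_test, class_ds, class_tad, scale_curve)

# two-class fixture shaped like a small tumor/normal study:
# 25 + 25 samples, 100 genes, 10 informative genes shifted by 2 units
data = simulate_two_class(SimulationConfig(n_per_class=25, d=100,
                                           n_informative=10, shift=2.0, seed=7))
normal = data.values[data.labels == "0"]
tumor  = data.values[data.labels == "1"]

res = mbd(normal)
print("deepest normal sample:", res.deepest, f"(MBD = {res.depth[res.deepest]:.3f})")
tm = tmean(normal, alpha=0.2)
print("0.2-trimmed mean uses", len(tm.retained), "of 25 samples")
rt = rank_test(normal, tumor, n=12, m=12, seed=0)
print(f"rank test: W = {rt.W:g}, p = {rt.p_value:.4g}")

rng = np.random.default_rng(1)
test = np.vstack([normal[:3] + 0.1*rng.standard_normal((3,100)),
                  tumor[:3]  + 0.1*rng.standard_normal((3,100))])
print("DS :", class_ds(data.values, data.labels, test, alpha=0.2))
print("TAD:", class_tad(data.values, data.labels, test, alpha=0.2))
```

prints

```
deepest normal sample: 1 (MBD = 0.420)
0.2-trimmed mean uses 20 of 25 samples
rank test: W = 97, p = 0.001218
DS : ['0' '0' '0' '1' '1' '1']
TAD: ['0' '0' '0' '1' '1' '1']
```

Sample 1 is the most central normal profile (an MBD of 0.42 means its
coordinates fall inside 42% of all pairwise bands on average). The rank
test rejects that the two groups share a population at p ≈ 0.001 — the
tumor subsample's depths with respect to the normal reference are
systematically small. Both classifiers recover the true class of all six
perturbed test profiles.

The same operations are available from the shell:

```bash
mbdtools simulate --config sim.yaml --out X.csv
mbdtools mbd --input X.csv --out depths.csv
mbdtools ranktest --x NORMAL.csv --y TUMOR.csv --n 12 --m 12
mbdtools classify --train TRAIN.csv --test TEST.csv --method tad --alpha 0.2 --out preds.csv
mbdtools plot --input X.csv --kind bands --out bands.png
```

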