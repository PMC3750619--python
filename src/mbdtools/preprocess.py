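"""Microarray-style expression preprocessing and B/W gene ranking.

The preprocessing recipe mirrors a standard oligonucleotide-array pipeline:
clip intensities to a floor/ceiling, drop genes with too little variation
(relative fold change or absolute range), log10-transform, and standardize
each sample (row) to zero mean and unit variance across the surviving
genes.  Gene ranking uses the B/W criterion: the per-gene ratio of
between-class to within-class sums of squares, large when a gene separates
the classes well.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix

__all__ = ["preprocess_expression", "bw_rank_genes", "bw_statistic"]


def preprocess_expression(
    raw: ExpressionMatrix,
    floor: float = 10.0,
    ceiling: float = 16000.0,
    min_fold: float = 5.0,
    min_abs: float = 500.0,
) -> ExpressionMatrix:
    """Clip, filter uninformative genes, log10-transform and row-standardize.

    Steps, in order: (i) clip values to [floor, ceiling]; (ii) drop any gene
    whose post-clipping max/min ratio is below ``min_fold`` OR whose range
    max−min is below ``min_abs``; (iii) log10; (iv) standardize every sample
    to mean 0 and unit variance (ddof=1) across the retained genes.
    """
    if floor <= 0:
        raise ValueError("floor must be positive (values are log-transformed)")
    v = np.clip(raw.values, floor, ceiling)
    gmax = v.max(axis=0)
    gmin = v.min(axis=0)
    keep = (gmax / gmin >= min_fold) & (gmax - gmin >= min_abs)
    if keep.sum() < 2:
        # per-sample standardization needs at least two genes
        raise ValueError("empty matrix after filtering: fewer than 2 genes pass the variation filter")
    v = np.log10(v[:, keep])
    v = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=1, keepdims=True)
    return ExpressionMatrix(
        values=v,
        sample_ids=list(raw.sample_ids),
        variable_ids=[g for g, k in zip(raw.variable_ids, keep) if k],
        labels=None if raw.labels is None else raw.labels.copy(),
    )


def bw_statistic(values, labels) -> np.ndarray:
    """Per-gene B/W ratio: between-class over within-class sum of squares.

    B_j = sum_g n_g (mean_gj − grand_j)²,  W_j = sum_g sum_{i in g} (x_ij − mean_gj)².
    Conventions for degenerate genes: B/0 with B > 0 ranks first (ratio inf);
    0/0 (gene constant within every class and across classes) is defined as 0.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("B/W undefined: need at least two classes")
    for g in classes:
        if (labels == g).sum() < 2:
            raise ValueError(f"degenerate class: class {g!r} has fewer than 2 samples")
    grand = v.mean(axis=0)
    between = np.zeros(v.shape[1])
    within = np.zeros(v.shape[1])
    for g in classes:
        rows = v[labels == g]
        mu = rows.mean(axis=0)
        between += rows.shape[0] * (mu - grand) ** 2
        within += ((rows - mu) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = between / within
    ratio[(within == 0) & (between > 0)] = np.inf
    ratio[(within == 0) & (between == 0)] = 0.0
    return ratio


def bw_rank_genes(x: ExpressionMatrix) -> np.ndarray:
    """Gene indices ranked by decreasing B/W (ties by ascending index)."""
    if x.labels is None:
        raise ValueError("B/W undefined: matrix has no labels")
    ratio = bw_statistic(x.values, x.labels)
    return np.argsort(-ratio, kind="stable")
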