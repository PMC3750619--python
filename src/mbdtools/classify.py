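"""Depth-based supervised classifiers DS and TAD.

Both classifiers summarize each class of the learning set by its most
central (deepest) members and assign a test sample to the class whose
summary it is closest to:

* DS ("distance to a summary"): the summary is the within-class
  depth-trimmed mean; a test sample goes to the class with the nearest
  trimmed mean.
* TAD ("trimmed average distance"): the score for a class is a weighted
  average distance from the test sample to that class's retained deepest
  members, with weights proportional to their within-class depths; the
  class with the smallest score wins.

With ``alpha = 0`` DS reduces to the nearest-centroid rule on ordinary
class means.  Trimming makes both rules robust to gross outliers in the
learning set.  Distances are Euclidean by default; a different metric
callable ``metric(test_rows, points) -> (n_test, n_points)`` may be
supplied.  Argmin ties are broken by class order of first appearance in
the learning labels.
"""

from __future__ import annotations

import math

import numpy as np

from .depth import mbd
from .robust import tmean

__all__ = ["class_ds", "class_tad"]


def _euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # (n_a, d), (n_b, d) -> (n_a, n_b)
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))


def _check_inputs(learning, labels, test, alpha):
    xl = np.asarray(learning, dtype=float)
    xt = np.asarray(test, dtype=float)
    if xt.ndim == 1:
        xt = xt[None, :]
    labels = np.asarray(labels)
    if labels.shape[0] != xl.shape[0]:
        raise ValueError("labels length must match the number of learning samples")
    if xt.shape[1] != xl.shape[1]:
        raise ValueError(
            f"dimension mismatch: test has {xt.shape[1]} columns, learning has {xl.shape[1]}"
        )
    if not 0 <= alpha < 1:
        raise ValueError(f"invalid trimming proportion: alpha={alpha} not in [0, 1)")
    # classes ordered by first appearance, the documented tie-break order
    _, first = np.unique(labels, return_index=True)
    classes = labels[np.sort(first)]
    if len(classes) < 2:
        raise ValueError("need at least two classes in the learning set")
    for g in classes:
        if (labels == g).sum() < 2:
            raise ValueError(f"degenerate class: class {g!r} has fewer than 2 learning samples")
    return xl, labels, xt, classes


def class_ds(learning, labels, test, alpha: float = 0.2, metric=None):
    """Classify test samples by distance to within-class depth-trimmed means."""
    xl, labels, xt, classes = _check_inputs(learning, labels, test, alpha)
    dist = _euclidean if metric is None else metric
    centers = np.vstack([tmean(xl[labels == g], alpha).tm for g in classes])
    scores = dist(xt, centers)  # (n_test, G)
    return classes[np.argmin(scores, axis=1)]


def class_tad(learning, labels, test, alpha: float = 0.2, metric=None):
    """Classify test samples by trimmed, depth-weighted average distance to each class."""
    xl, labels, xt, classes = _check_inputs(learning, labels, test, alpha)
    dist = _euclidean if metric is None else metric
    scores = np.empty((xt.shape[0], len(classes)))
    for j, g in enumerate(classes):
        rows = xl[labels == g]
        dres = mbd(rows)
        keep = math.ceil((1.0 - alpha) * rows.shape[0])
        retained = dres.ordering[:keep]
        w = dres.depth[retained]
        w = w / w.sum()
        scores[:, j] = dist(xt, rows[retained]) @ w
    return classes[np.argmin(scores, axis=1)]
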