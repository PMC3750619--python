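"""Depth-derived descriptive statistics: trimmed means, central bands, scale curves.

All statistics here share the same retention rule: for a trimming
proportion ``alpha`` the ``ceil((1 − alpha)·n)`` deepest samples are kept,
and for a central proportion ``p`` the ``ceil(p·n)`` deepest samples form
the p-central set (so p = 0.25 of 25 samples selects the 7 most central
ones).  Depths are computed with the fast in-sample MBD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .depth import DepthResult, mbd

__all__ = [
    "TrimmedMeanResult",
    "BandEnvelope",
    "ScaleCurve",
    "tmean",
    "central_band",
    "central_partition",
    "scale_curve",
]


@dataclass(frozen=True)
class TrimmedMeanResult:
    """Deep-sample subset retained after trimming and its component-wise mean."""

    retained: np.ndarray  # indices of retained samples, deepest first
    tm: np.ndarray  # d-vector, mean of the retained rows
    alpha: float
    depth: DepthResult


@dataclass(frozen=True)
class BandEnvelope:
    """Coordinate-wise min/max envelope of the p-central sample set."""

    lower: np.ndarray
    upper: np.ndarray
    proportion: float
    members: np.ndarray  # indices of the central samples, deepest first

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass(frozen=True)
class ScaleCurve:
    """Area of the p-central band as a function of the central proportion p.

    The slope of this curve shows how dispersion accumulates from the center
    outwards; a uniformly larger curve means a more dispersed collection.
    """

    p_grid: np.ndarray
    area: np.ndarray
    label: str | None = None


def _central_count(n: int, p: float) -> int:
    return math.ceil(p * n)


def tmean(x, alpha: float = 0.2, depth: DepthResult | None = None) -> TrimmedMeanResult:
    """Depth-based trimmed mean.

    Removes the proportion ``alpha`` of most external (least deep) samples
    and returns the ordinary component-wise mean of the rest.  ``alpha = 0``
    keeps every sample, reproducing the ordinary column mean.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"invalid trimming proportion: alpha={alpha} not in [0, 1)")
    v = np.asarray(x, dtype=float)
    dres = mbd(v) if depth is None else depth
    n = v.shape[0]
    keep = math.ceil((1.0 - alpha) * n)
    retained = dres.ordering[:keep]
    return TrimmedMeanResult(retained=retained, tm=v[retained].mean(axis=0), alpha=alpha, depth=dres)


def central_band(x, p: float, depth: DepthResult | None = None) -> BandEnvelope:
    """Envelope (per-variable min/max) of the ceil(p·n) deepest samples."""
    if not 0 < p <= 1:
        raise ValueError(f"invalid proportion: p={p} not in (0, 1]")
    v = np.asarray(x, dtype=float)
    dres = mbd(v) if depth is None else depth
    members = dres.ordering[: _central_count(v.shape[0], p)]
    central = v[members]
    return BandEnvelope(
        lower=central.min(axis=0), upper=central.max(axis=0), proportion=p, members=members
    )


def central_partition(x, proportions, depth: DepthResult | None = None) -> list[BandEnvelope]:
    """Nested envelopes for a strictly increasing list of central proportions."""
    props = list(proportions)
    if len(props) == 0 or any(b <= a for a, b in zip(props, props[1:])):
        raise ValueError("invalid band limits: proportions must be strictly increasing")
    v = np.asarray(x, dtype=float)
    dres = mbd(v) if depth is None else depth
    return [central_band(v, p, depth=dres) for p in props]


def band_area(env: BandEnvelope) -> float:
    """Area between the envelope curves, trapezoidal over unit-spaced variable index.

    With a single variable the integration domain has zero width, so the
    area is 0 by construction.
    """
    return float(np.trapezoid(env.width))


def scale_curve(x, p_grid=None, depth: DepthResult | None = None, label: str | None = None) -> ScaleCurve:
    """Scale curve: p-central band area for each proportion p.

    The default grid is ``{k/n : k = 1..n}``, the proportions at which the
    central-set size actually changes.  The area is non-decreasing in p
    because the p-central sets are nested.
    """
    v = np.asarray(x, dtype=float)
    n = v.shape[0]
    if p_grid is None:
        p_grid = np.arange(1, n + 1) / n
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size == 0 or (p_grid <= 0).any() or (p_grid > 1).any():
        raise ValueError("invalid proportion: p_grid values must lie in (0, 1]")
    dres = mbd(v) if depth is None else depth
    area = np.array([band_area(central_band(v, p, depth=dres)) for p in p_grid])
    return ScaleCurve(p_grid=p_grid, area=area, label=label)
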