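"""Parallel-coordinate visualizations of depth structure.

Every function renders to a file and returns its path; all statistics are
computed by the depth/robust modules, never inside plotting code.  Plots:

* :func:`plot_depth` — all samples as polylines, deepest highlighted, or a
  grayscale gradient following the center-outward ordering.
* :func:`plot_bands` — nested envelopes of increasing central proportions,
  optionally against a reference collection (depths then computed with
  respect to the reference, whose curves are overlaid).
* :func:`plot_tmeans` — trimmed means across a sequence of trimming levels,
  colored from a user color (least trimmed) to gray (most trimmed).
* :func:`plot_central` — the p-central curves highlighted, optionally with
  a depth-gradient palette, external curves dashed gray.
* :func:`plot_scalecurve` — one or more scale curves on a common axis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap, to_rgb

from .depth import mbd, mbd_ref
from .robust import ScaleCurve, central_partition, scale_curve, tmean

__all__ = ["plot_depth", "plot_bands", "plot_tmeans", "plot_central", "plot_scalecurve"]


def _finish(fig, path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _xaxis(d):
    return np.arange(1, d + 1)


def plot_depth(x, path, mode: str = "deepest") -> Path:
    """Parallel-coordinate plot; ``mode`` is 'deepest' or 'grayscale'."""
    v = np.asarray(x, dtype=float)
    res = mbd(v)
    g = _xaxis(v.shape[1])
    fig, ax = plt.subplots(figsize=(8, 4.5))
    if mode == "grayscale":
        # light gray = deepest, dark = most external
        shades = np.linspace(0.75, 0.1, v.shape[0])
        for pos, i in enumerate(res.ordering):
            ax.plot(g, v[i], color=str(shades[pos]), lw=0.8)
    elif mode == "deepest":
        for i in range(v.shape[0]):
            if i != res.deepest:
                ax.plot(g, v[i], color="0.6", lw=0.8)
        ax.plot(g, v[res.deepest], color="red", lw=1.6, label="deepest sample")
        ax.legend(loc="upper right")
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    ax.set_xlabel("variable index")
    ax.set_ylabel("expression")
    return _finish(fig, path)


def plot_bands(x, path, proportions=(0.25, 0.5, 0.75, 1.0), ref=None) -> Path:
    """Nested central-band envelopes; with ``ref``, depths are taken w.r.t. it."""
    v = np.asarray(x, dtype=float)
    depth = None if ref is None else mbd_ref(v, ref)
    envs = central_partition(v, proportions, depth=depth)
    g = _xaxis(v.shape[1])
    fig, ax = plt.subplots(figsize=(8, 4.5))
    shades = np.linspace(0.45, 0.85, len(envs))
    for env, shade in zip(reversed(envs), reversed(shades)):
        ax.fill_between(g, env.lower, env.upper, color=str(shade),
                        label=f"{env.proportion:.0%} central")
    if ref is not None:
        refv = np.asarray(ref, dtype=float)
        for row in refv:
            ax.plot(g, row, color="tab:blue", lw=0.6, alpha=0.7)
        deepest = envs[-1].members[0] if depth is None else depth.deepest
        ax.plot(g, v[deepest], color="red", lw=1.4)
    ax.set_xlabel("variable index")
    ax.set_ylabel("expression")
    ax.legend(loc="upper right", fontsize=8)
    return _finish(fig, path)


def plot_tmeans(x, path, alphas=(0.25,), base_color="tab:blue") -> Path:
    """Trimmed means for one or several trimming proportions.

    A single alpha also shows the retained samples (colored) and the
    trimmed-out ones (gray); a sequence shows only the means, colored from
    ``base_color`` (smallest alpha) to gray (largest).
    """
    v = np.asarray(x, dtype=float)
    alphas = sorted(np.atleast_1d(np.asarray(alphas, dtype=float)))
    g = _xaxis(v.shape[1])
    fig, ax = plt.subplots(figsize=(8, 4.5))
    if len(alphas) == 1:
        res = tmean(v, alphas[0])
        kept = set(res.retained.tolist())
        for i in range(v.shape[0]):
            ax.plot(g, v[i], color=base_color if i in kept else "0.75", lw=0.7)
        ax.plot(g, res.tm, color="black", lw=1.8, label=f"{alphas[0]:g}-trimmed mean")
    else:
        cmap = LinearSegmentedColormap.from_list("tm", [to_rgb(base_color), (0.6, 0.6, 0.6)])
        for j, a in enumerate(alphas):
            res = tmean(v, a)
            ax.plot(g, res.tm, color=cmap(j / (len(alphas) - 1)), lw=1.2,
                    label=f"alpha={a:g}")
    ax.set_xlabel("variable index")
    ax.set_ylabel("expression")
    ax.legend(loc="upper right", fontsize=8)
    return _finish(fig, path)


def plot_central(x, path, p: float = 0.25, gradient: bool = False,
                 gradient_ramp=("red", "yellow")) -> Path:
    """Highlight the p-central curves; optionally color them by depth rank."""
    v = np.asarray(x, dtype=float)
    res = mbd(v)
    import math

    k = math.ceil(p * v.shape[0])
    central = res.ordering[:k]
    g = _xaxis(v.shape[1])
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for i in np.setdiff1d(np.arange(v.shape[0]), central):
        ax.plot(g, v[i], color="0.7", lw=0.7, ls="--")
    if gradient:
        cmap = LinearSegmentedColormap.from_list(
            "central", [to_rgb(gradient_ramp[0]), to_rgb(gradient_ramp[1])]
        )
        for pos, i in enumerate(central):
            ax.plot(g, v[i], color=cmap(pos / max(1, k - 1)), lw=1.2)
    else:
        for i in central:
            ax.plot(g, v[i], color="red", lw=1.2)
    ax.set_xlabel("variable index")
    ax.set_ylabel("expression")
    ax.set_title(f"{k} most central samples ({p:.0%})")
    return _finish(fig, path)


def plot_scalecurve(curves, path) -> Path:
    """Plot one scale curve or a sequence of them (e.g. one per class)."""
    if isinstance(curves, ScaleCurve):
        curves = [curves]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    styles = ["-", "--", ":", "-."]
    for j, c in enumerate(curves):
        ax.plot(c.p_grid, c.area, styles[j % len(styles)],
                label=c.label if c.label is not None else f"group {j + 1}")
    ax.set_xlabel("central proportion p")
    ax.set_ylabel("band area")
    ax.legend(loc="upper left")
    return _finish(fig, path)


def scale_curves_by_class(x, labels):
    """Convenience: one scale curve per class, for plot_scalecurve."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    classes = labels[np.sort(first)]
    v = np.asarray(x, dtype=float)
    return [scale_curve(v[labels == g], label=str(g)) for g in classes]
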