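"""Synthetic two-class expression fixtures.

Generates standardizable two-class Gaussian matrices that emulate a small
two-condition microarray study (e.g. 25 normal + 25 tumor samples over 100
genes): rows are multivariate normal with exchangeable within-sample
correlation ``rho``, the second class is shifted by ``shift`` on the first
``n_informative`` genes, and an optional fraction of rows is displaced by a
gross constant in every coordinate to emulate corrupted arrays.  Output is
fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import ExpressionMatrix

__all__ = ["SimulationConfig", "simulate_two_class"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-class Gaussian generator.

    Defaults mirror the shape of a small two-condition prostate-style study:
    two classes of 25 samples over 100 standardized genes, 10 informative
    genes with a unit mean shift, mild exchangeable correlation, and no
    contamination.
    """

    n_per_class: int = 25
    d: int = 100
    n_informative: int = 10
    shift: float = 1.0  # mean difference on informative genes, expression units
    rho: float = 0.2  # exchangeable within-sample correlation
    outlier_frac: float = 0.0
    outlier_magnitude: float = 50.0  # added to every coordinate of an outlier row
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not 0 <= self.n_informative <= self.d:
            raise ValueError("n_informative must lie in [0, d]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.outlier_frac < 0.5:
            raise ValueError("outlier_frac must lie in [0, 0.5)")


def simulate_two_class(config: SimulationConfig) -> ExpressionMatrix:
    """Draw a labeled two-class matrix according to ``config``.

    Rows are N(mu_g, (1−rho)·I + rho·J): a shared latent factor per sample
    produces the exchangeable correlation.  Class labels are "0" and "1";
    class "1" carries the mean shift on the informative genes.  Outlier rows
    (chosen uniformly over all rows) get ``outlier_magnitude`` added to every
    coordinate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, d = config.n_per_class, config.d
    total = 2 * n

    shared = rng.standard_normal((total, 1))
    noise = rng.standard_normal((total, d))
    v = np.sqrt(config.rho) * shared + np.sqrt(1.0 - config.rho) * noise

    mu = np.zeros(d)
    mu[: config.n_informative] = config.shift
    v[n:] += mu  # second class shifted

    n_out = int(round(config.outlier_frac * total))
    if n_out:
        rows = rng.choice(total, size=n_out, replace=False)
        v[rows] += config.outlier_magnitude

    labels = np.array(["0"] * n + ["1"] * n)
    return ExpressionMatrix(values=v, labels=labels)


def config_summary(config: SimulationConfig) -> dict:
    return asdict(config)
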