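"""Discretised distributions used by the message-passing engine.

Continuous parameters (activities, popularities, preference and
reciprocity entries) are carried as weights on a regular grid spanning
their admissible interval; class labels are carried as categorical
weight vectors.  Grid quadrature keeps every message exactly
normalisable and makes the engine directly comparable with exhaustive
summation over the discretised parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "GridDistribution",
    "CategoricalDistribution",
    "Priors",
    "posterior_moments",
]

_NORM_TOL = 1e-12


@dataclass
class GridDistribution:
    """Nonnegative weights on ``B ≥ 2`` equally spaced support points."""

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.support.ndim != 1 or len(self.support) < 2:
            raise ValueError("support must be 1-D with B ≥ 2 points")
        if self.weights.shape != self.support.shape:
            raise ValueError("weights and support must match")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        s = self.weights.sum()
        if abs(s - 1.0) > _NORM_TOL:
            raise ValueError(f"weights must sum to 1 (got {s})")

    @classmethod
    def from_unnormalized(cls, support, weights) -> "GridDistribution":
        w = np.asarray(weights, dtype=float)
        s = w.sum()
        if s <= 0:
            raise ValueError("cannot normalise all-zero weights")
        return cls(np.asarray(support, dtype=float), w / s)

    @classmethod
    def uniform(cls, lo: float, hi: float, size: int) -> "GridDistribution":
        g = np.linspace(lo, hi, size)
        return cls(g, np.full(size, 1.0 / size))

    @classmethod
    def point_mass(cls, support, value) -> "GridDistribution":
        g = np.asarray(support, dtype=float)
        idx = int(np.argmin(np.abs(g - value)))
        w = np.zeros_like(g)
        w[idx] = 1.0
        return cls(g, w)

    @classmethod
    def beta_shaped(cls, alpha: float, beta: float, lo: float, hi: float,
                    size: int) -> "GridDistribution":
        """Beta(α, β) density evaluated on the grid and renormalised.

        Endpoint densities that diverge (α < 1 or β < 1) are replaced by
        the neighbouring finite value before renormalisation.
        """
        g = np.linspace(lo, hi, size)
        t = (g - lo) / (hi - lo)
        d = stats.beta.pdf(t, alpha, beta)
        finite = np.isfinite(d)
        if not finite.all():
            d[~finite] = d[finite].max() if finite.any() else 1.0
        return cls.from_unnormalized(g, d)

    def mean(self) -> float:
        return float(self.weights @ self.support)

    def std(self) -> float:
        m = self.mean()
        var = float(self.weights @ (self.support - m) ** 2)
        return float(np.sqrt(max(var, 0.0)))

    def map_point(self) -> float:
        """Grid point of maximal weight (lowest value on ties)."""
        return float(self.support[int(np.argmax(self.weights))])


@dataclass
class CategoricalDistribution:
    """Probability vector over class labels ``0..k−1``."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or len(self.weights) < 1:
            raise ValueError("weights must be a nonempty vector")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > _NORM_TOL:
            raise ValueError("weights must sum to 1")

    @classmethod
    def uniform(cls, k: int) -> "CategoricalDistribution":
        return cls(np.full(k, 1.0 / k))

    @classmethod
    def from_unnormalized(cls, weights) -> "CategoricalDistribution":
        w = np.asarray(weights, dtype=float)
        s = w.sum()
        if s <= 0:
            raise ValueError("cannot normalise all-zero weights")
        return cls(w / s)

    def argmax(self) -> int:
        return int(np.argmax(self.weights))


@dataclass
class Priors:
    """Prior distributions for every parameter family.

    Continuous families are Beta-shaped densities renormalised on the
    grid (``(1, 1)`` = uniform, the default); class labels get uniform
    categorical priors.  The reciprocity prior lives on ``[0, ρ_max]``.
    """

    grid_size: int = 25
    activity: Tuple[float, float] = (1.0, 1.0)
    popularity: Tuple[float, float] = (1.0, 1.0)
    preference: Tuple[float, float] = (1.0, 1.0)
    reciprocity: Tuple[float, float] = (1.0, 1.0)
    rho_max: float = 10.0

    def grid(self) -> np.ndarray:
        """Shared [0, 1] support for a, b and π."""
        return np.linspace(0.0, 1.0, self.grid_size)

    def rho_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.rho_max, self.grid_size)

    def _family(self, shape: Tuple[float, float], lo: float, hi: float) -> GridDistribution:
        if shape == (1.0, 1.0):
            return GridDistribution.uniform(lo, hi, self.grid_size)
        return GridDistribution.beta_shaped(*shape, lo, hi, self.grid_size)

    def activity_prior(self) -> GridDistribution:
        return self._family(self.activity, 0.0, 1.0)

    def popularity_prior(self) -> GridDistribution:
        return self._family(self.popularity, 0.0, 1.0)

    def preference_prior(self) -> GridDistribution:
        return self._family(self.preference, 0.0, 1.0)

    def reciprocity_prior(self) -> GridDistribution:
        return self._family(self.reciprocity, 0.0, self.rho_max)

    def class_prior(self, k: int) -> CategoricalDistribution:
        return CategoricalDistribution.uniform(k)


def posterior_moments(dist: GridDistribution) -> Tuple[float, float]:
    """Grid-weighted (mean, standard deviation) of a posterior."""
    return dist.mean(), dist.std()
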