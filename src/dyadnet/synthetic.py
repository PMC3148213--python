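"""Planted-model generators with known ground truth.

Every test surface of the package can be driven from here: networks
are drawn from the generative dyadic model itself, so the planted
classes, activities/popularities, preference matrix and (directed)
reciprocities are returned alongside the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .ensembles import sample_network
from .model import ModelParameters
from .networks import BipartiteNetwork, DirectedNetwork

__all__ = ["PlantedSpec", "plant_bipartite", "plant_directed", "davis_shape_fixture"]


@dataclass
class PlantedSpec:
    """Ground-truth specification for a planted network.

    Activities/popularities are drawn uniformly on the given interval
    (use a degenerate interval for fixed values).  Class labels are
    assigned deterministically by proportions, in blocks.
    """

    variant: str = "bipartite"
    n_actors: int = 60
    n_events: int = 40
    preference: Sequence[Sequence[float]] = ((0.9, 0.05), (0.05, 0.9))
    activity_range: Tuple[float, float] = (0.3, 1.0)
    popularity_range: Tuple[float, float] = (0.3, 1.0)
    actor_proportions: Optional[Sequence[float]] = None
    event_proportions: Optional[Sequence[float]] = None
    reciprocity: Optional[Sequence[Sequence[float]]] = None
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("bipartite", "directed"):
            raise ValueError(f"unsupported variant {self.variant!r}")
        pref = np.atleast_2d(np.asarray(self.preference, dtype=float))
        if np.any(pref < 0) or np.any(pref > 1):
            raise ValueError("preference entries must lie in [0, 1]")
        self.preference = pref
        for name in ("activity_range", "popularity_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} must be within [0, 1] with lo ≤ hi")
        for name, k in (("actor_proportions", pref.shape[0]),
                        ("event_proportions", pref.shape[1])):
            pr = getattr(self, name)
            if pr is None:
                setattr(self, name, np.full(k, 1.0 / k))
            else:
                pr = np.asarray(pr, dtype=float)
                if len(pr) != k or abs(pr.sum() - 1.0) > 1e-9 or np.any(pr < 0):
                    raise ValueError(f"{name} must be {k} nonnegative values summing to 1")
                setattr(self, name, pr)
        if self.reciprocity is not None:
            rho = np.atleast_2d(np.asarray(self.reciprocity, dtype=float))
            if np.any(rho < 0) or not np.allclose(rho, rho.T):
                raise ValueError("reciprocity must be symmetric and ≥ 0")
            self.reciprocity = rho


def _block_labels(n: int, proportions: np.ndarray) -> np.ndarray:
    """Deterministic class labels in contiguous blocks by proportion."""
    bounds = np.round(np.cumsum(proportions) * n).astype(int)
    labels = np.zeros(n, dtype=int)
    start = 0
    for k, end in enumerate(bounds):
        labels[start:end] = k
        start = end
    return labels


def plant_bipartite(spec: PlantedSpec) -> Tuple[BipartiteNetwork, ModelParameters]:
    """Draw a bipartite network and return it with its ground truth."""
    if spec.variant != "bipartite":
        raise ValueError("spec.variant must be 'bipartite'")
    rng = np.random.default_rng(spec.seed)
    c = _block_labels(spec.n_actors, spec.actor_proportions)
    d = _block_labels(spec.n_events, spec.event_proportions)
    a = rng.uniform(*spec.activity_range, size=spec.n_actors)
    b = rng.uniform(*spec.popularity_range, size=spec.n_events)
    params = ModelParameters(a, b, c, spec.preference, event_classes=d)
    net_seed = int(rng.integers(0, 2**31 - 1))
    net = sample_network(params, "bipartite", seed=net_seed)
    return net, params


def plant_directed(spec: PlantedSpec) -> Tuple[DirectedNetwork, ModelParameters]:
    """Draw a directed network (4-state dyads) with its ground truth."""
    if spec.variant != "directed":
        raise ValueError("spec.variant must be 'directed'")
    q = spec.preference.shape[0]
    if spec.preference.shape != (q, q):
        raise ValueError("directed variant needs a square preference matrix")
    rng = np.random.default_rng(spec.seed)
    c = _block_labels(spec.n_actors, spec.actor_proportions)
    a = rng.uniform(*spec.activity_range, size=spec.n_actors)
    b = rng.uniform(*spec.popularity_range, size=spec.n_actors)
    rho = spec.reciprocity if spec.reciprocity is not None else np.ones((q, q))
    params = ModelParameters(a, b, c, spec.preference, reciprocity=rho)
    net_seed = int(rng.integers(0, 2**31 - 1))
    net = sample_network(params, "directed", seed=net_seed)
    return net, params


def davis_shape_fixture(seed: int = 0) -> Tuple[BipartiteNetwork, ModelParameters]:
    """A synthetic 18 × 14 attendance-style network.

    Emulates the structure of the classic Southern-Women attendance
    record (18 women, 14 informal social events, two social classes of
    9 women each) without shipping the real data.  Each women's class
    has its own event class (strong within-class preference), and the
    events split into sparsely attended gatherings and broadly popular
    ones — a strongly bimodal popularity profile on top of spread-out
    per-woman activities.  A plain block model tends to divide the
    events by attendance count and the women by how many events they
    attend, losing the planted 9/9 split, while the model with node
    effects absorbs the attendance heterogeneity and recovers it.
    """
    rng = np.random.default_rng(seed)
    c = np.repeat([0, 1], 9)                 # two social classes of 9 women
    d = np.repeat([0, 1], [7, 7])            # one event class per social circle
    a = rng.uniform(0.45, 1.0, size=18)
    # alternate sparsely attended and popular events within each class
    popular = np.tile([0, 1], 7).astype(bool)
    b = np.where(popular, rng.uniform(0.9, 1.0, 14), rng.uniform(0.15, 0.3, 14))
    pref = np.array([[0.95, 0.04],
                     [0.04, 0.95]])
    params = ModelParameters(a, b, c, pref, event_classes=d)
    net = sample_network(params, "bipartite", seed=int(rng.integers(0, 2**31 - 1)),
                         labels=[f"w{i+1}" for i in range(18)],
                         event_labels=[f"E{j+1}" for j in range(14)])
    return net, params
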