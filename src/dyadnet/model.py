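"""The multiscale dyadic network model.

The generative model combines two scales of structure.  Each actor
``i`` carries a global *activity* ``a_i ∈ [0, 1]`` and each event ``j``
a global *popularity* ``b_j ∈ [0, 1]`` (microscopic, node-specific
scale).  Each node additionally carries a latent class index; the
``q × l`` *preference* matrix ``π`` holds the tendency of an actor of
class ``r`` to link with an event of class ``s`` (mesoscopic, group
scale — a block model).  Dyads are conditionally independent given the
parameters, with Bernoulli probability

    p_ij = a_i · b_j · π_{c_i d_j}.

All three factors live on ``[0, 1]``, so ``p_ij`` is automatically a
valid probability; the parametrisation is equivalent, up to a bounded
reparametrisation, to an exponential random graph with additive
log-odds fields.

For directed unipartite networks every node has an activity (out-) and
popularity (in-) parameter plus a single class label; the dyad is the
4-state variable ``(x_ij, x_ji)`` and a symmetric class-pair
*reciprocity* matrix ``ρ`` reweights the mutual state.

Dropping the node-specific factors (clamping ``a ≡ b ≡ 1``) recovers
the plain stochastic block model, available throughout the package as
the "no node effects" configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .networks import BipartiteNetwork, DirectedNetwork, UndirectedNetwork

__all__ = [
    "ModelParameters",
    "dyad_probability",
    "dyad_log_likelihood",
    "directed_dyad_distribution",
    "network_log_likelihood",
    "expected_degrees",
]

Network = Union[BipartiteNetwork, DirectedNetwork, UndirectedNetwork]

#: dyad state codes for directed networks, in the fixed order
#: (x_ij, x_ji) = (0,0), (1,0), (0,1), (1,1)
DYAD_STATES = ((0, 0), (1, 0), (0, 1), (1, 1))


def _in_unit(value, name: str) -> np.ndarray:
    v = np.asarray(value, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return v


@dataclass
class ModelParameters:
    """Full parameter set θ of the dyadic model.

    Attributes
    ----------
    activities
        ``a_i ∈ [0, 1]`` per actor (per node for unipartite variants).
    popularities
        ``b_j ∈ [0, 1]`` per event; per node for the directed variant
        (in-attractiveness); ``None`` for undirected networks, where a
        single activity per node enters both ends of an edge.
    actor_classes, event_classes
        Integer class labels ``c_i ∈ {0..q-1}`` and ``d_j ∈ {0..l-1}``;
        ``event_classes`` is ``None`` for unipartite variants.
    preference
        ``q × l`` block preference matrix π with entries in [0, 1]
        (``q × q`` for unipartite variants; symmetric when undirected).
    reciprocity
        Symmetric ``q × q`` matrix ρ ≥ 0, directed variant only.
        ρ = 1 everywhere makes the two directions of a dyad independent.
    """

    activities: np.ndarray
    popularities: Optional[np.ndarray]
    actor_classes: np.ndarray
    preference: np.ndarray
    event_classes: Optional[np.ndarray] = None
    reciprocity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.activities = _in_unit(self.activities, "activities")
        if self.popularities is not None:
            self.popularities = _in_unit(self.popularities, "popularities")
        self.preference = np.atleast_2d(_in_unit(self.preference, "preference"))
        self.actor_classes = np.asarray(self.actor_classes, dtype=int)
        q, l = self.preference.shape
        if q < 1 or l < 1:
            raise ValueError("need at least one class on each side")
        if np.any(self.actor_classes < 0) or np.any(self.actor_classes >= q):
            raise ValueError("actor class labels out of range")
        if self.event_classes is not None:
            self.event_classes = np.asarray(self.event_classes, dtype=int)
            if np.any(self.event_classes < 0) or np.any(self.event_classes >= l):
                raise ValueError("event class labels out of range")
        if self.reciprocity is not None:
            rho = np.atleast_2d(np.asarray(self.reciprocity, dtype=float))
            if rho.shape != (q, q):
                raise ValueError("reciprocity must be q × q")
            if np.any(rho < 0):
                raise ValueError("reciprocity must be ≥ 0")
            if not np.allclose(rho, rho.T):
                raise ValueError("reciprocity must be symmetric")
            self.reciprocity = rho

    @property
    def q(self) -> int:
        return self.preference.shape[0]

    @property
    def l(self) -> int:
        return self.preference.shape[1]

    def probability_matrix(self, variant: str = "bipartite") -> np.ndarray:
        """Per-dyad Bernoulli/marginal link probabilities.

        Bipartite: the ``N × M`` matrix ``p_ij = a_i b_j π_{c_i d_j}``.
        Undirected: symmetric ``N × N`` with ``p_ij = a_i a_j π``,
        zero diagonal.  Directed: ``N × N`` of marginal arc
        probabilities ``P(x_ij = 1)`` under the 4-state dyad law.
        """
        a = self.activities
        if variant == "bipartite":
            b = self.popularities
            blk = self.preference[np.ix_(self.actor_classes, self.event_classes)]
            return a[:, None] * b[None, :] * blk
        if variant == "undirected":
            blk = self.preference[np.ix_(self.actor_classes, self.actor_classes)]
            p = a[:, None] * a[None, :] * blk
            np.fill_diagonal(p, 0.0)
            return p
        if variant == "directed":
            n = len(a)
            p = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    dist = self.dyad_distribution(i, j)
                    p[i, j] = dist[1] + dist[3]
            return p
        raise ValueError(f"unknown variant {variant!r}")

    def dyad_distribution(self, i: int, j: int) -> np.ndarray:
        """4-state distribution of directed dyad {i, j} (order i→j first)."""
        if self.popularities is None or self.reciprocity is None:
            raise ValueError("directed dyads need popularities and reciprocity")
        ci, cj = self.actor_classes[i], self.actor_classes[j]
        u = self.activities[i] * self.popularities[j] * self.preference[ci, cj]
        v = self.activities[j] * self.popularities[i] * self.preference[cj, ci]
        return directed_dyad_distribution(u, v, self.reciprocity[ci, cj])


def dyad_probability(activity: float, popularity: float, preference: float) -> float:
    """Bernoulli link probability ``p = a · b · π``.

    All three factors must lie in [0, 1]; the product then does too.
    Monotone nondecreasing in each argument.
    """
    a = _in_unit(activity, "activity")
    b = _in_unit(popularity, "popularity")
    pi = _in_unit(preference, "preference")
    return a * b * pi


def dyad_log_likelihood(x, p) -> float:
    """``x·ln p + (1−x)·ln(1−p)`` with −inf for impossible observations."""
    x = np.asarray(x)
    p = _in_unit(p, "p")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("x must be 0 or 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(x == 1, np.log(p), np.log1p(-p))
    return ll if ll.ndim else float(ll)


def directed_dyad_distribution(u: float, v: float, rho: float) -> np.ndarray:
    """Distribution of the 4-state dyad ``(x_ij, x_ji)``.

    The two directions are independent Bernoulli draws with means ``u``
    and ``v``; the weight of the mutual state 11 is reweighted by the
    reciprocity ``ρ ≥ 0`` and the dyad renormalised:

        w(00)=(1−u)(1−v), w(10)=u(1−v), w(01)=(1−u)v, w(11)=u·v·ρ.

    ``ρ = 1`` recovers the independent product; ``ρ > 1`` enriches,
    ``ρ < 1`` depletes reciprocated pairs.
    """
    u = float(_in_unit(u, "u"))
    v = float(_in_unit(v, "v"))
    rho = float(rho)
    if rho < 0:
        raise ValueError("rho must be ≥ 0")
    w = np.array([(1 - u) * (1 - v), u * (1 - v), (1 - u) * v, u * v * rho])
    z = w.sum()
    if z <= 0:
        raise ValueError("degenerate dyad: all four states have weight zero")
    return w / z


def network_log_likelihood(network: Network, params: ModelParameters) -> float:
    """Log-likelihood of the observed network; sums over all dyads.

    Bipartite: all ``N × M`` actor–event pairs.  Undirected: all
    unordered node pairs.  Directed: all unordered dyads, each through
    its 4-state distribution.  Dyads with probability exactly matching
    an impossible observation contribute −inf.
    """
    if isinstance(network, BipartiteNetwork):
        if len(params.activities) != network.n_actors or (
            params.popularities is None
            or len(params.popularities) != network.n_events
        ):
            raise ValueError("parameter dimensions do not match network")
        p = params.probability_matrix("bipartite")
        x = network.adjacency()
        return float(np.sum(dyad_log_likelihood(x, p)))
    if isinstance(network, UndirectedNetwork):
        if len(params.activities) != network.n_nodes:
            raise ValueError("parameter dimensions do not match network")
        p = params.probability_matrix("undirected")
        x = network.adjacency()
        iu = np.triu_indices(network.n_nodes, k=1)
        return float(np.sum(dyad_log_likelihood(x[iu], p[iu])))
    if isinstance(network, DirectedNetwork):
        if len(params.activities) != network.n_nodes:
            raise ValueError("parameter dimensions do not match network")
        total = 0.0
        for i in range(network.n_nodes):
            for j in range(i + 1, network.n_nodes):
                dist = params.dyad_distribution(i, j)
                state = DYAD_STATES.index(network.dyad_state(i, j))
                pr = dist[state]
                total += np.log(pr) if pr > 0 else -np.inf
        return float(total)
    raise TypeError(f"unsupported network type {type(network).__name__}")


def expected_degrees(params: ModelParameters, variant: str = "bipartite"):
    """Expected degrees per node under the model.

    Bipartite → ``(actor_degrees, event_degrees)``; undirected → one
    vector; directed → ``(out_degrees, in_degrees)``.  Each entry is the
    sum of link probabilities over the node's dyads.
    """
    p = params.probability_matrix(variant)
    if variant == "bipartite":
        return p.sum(axis=1), p.sum(axis=0)
    if variant == "undirected":
        return p.sum(axis=1)
    if variant == "directed":
        return p.sum(axis=1), p.sum(axis=0)
    raise ValueError(f"unknown variant {variant!r}")
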