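"""Null-model ensembles.

Two ensemble generators are provided:

* :func:`sample_network` — networks drawn from a fitted dyadic model
  (the model-based null: matches node-specific *and* group-specific
  structure in expectation).
* :func:`link_randomize` — degree-preserving link randomization of a
  directed network conserving each node's in-, out- and
  reciprocated-degree exactly (the standard motif null).

:func:`generate_ensemble` streams replicates of either kind with
per-replicate seeds derived deterministically from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Union

import numpy as np

from .model import ModelParameters
from .networks import BipartiteNetwork, DirectedNetwork, UndirectedNetwork

__all__ = ["EnsembleSpec", "sample_network", "link_randomize", "generate_ensemble"]

Network = Union[BipartiteNetwork, DirectedNetwork, UndirectedNetwork]

#: default attempted swaps per arc in link_randomize
SWAPS_PER_ARC = 10


def sample_network(params: ModelParameters, variant: str = "bipartite",
                   seed: int = 0, labels=None, event_labels=None) -> Network:
    """Draw one network from the model: independent dyads.

    Bipartite/undirected dyads are Bernoulli with ``p = a·b·π``;
    directed dyads are drawn from the 4-state distribution with
    reciprocity.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if variant == "bipartite":
        p = params.probability_matrix("bipartite")
        x = (rng.random(p.shape) < p).astype(np.int8)
        return BipartiteNetwork.from_adjacency(x, labels, event_labels)
    if variant == "undirected":
        p = params.probability_matrix("undirected")
        n = p.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        hit = rng.random(len(iu)) < p[iu, ju]
        nodes = labels or [f"n{i}" for i in range(n)]
        return UndirectedNetwork(nodes, zip(iu[hit], ju[hit]))
    if variant == "directed":
        n = len(params.activities)
        a, b = params.activities, params.popularities
        c, pref, rho = params.actor_classes, params.preference, params.reciprocity
        iu, ju = np.triu_indices(n, k=1)
        u = a[iu] * b[ju] * pref[c[iu], c[ju]]
        v = a[ju] * b[iu] * pref[c[ju], c[iu]]
        r = rho[c[iu], c[ju]]
        w = np.stack([(1 - u) * (1 - v), u * (1 - v), (1 - u) * v, u * v * r], axis=1)
        z = w.sum(axis=1, keepdims=True)
        if np.any(z <= 0):
            raise ValueError("degenerate dyad: all four states have weight zero")
        cdf = np.cumsum(w / z, axis=1)
        state = (cdf < rng.random(len(iu))[:, None]).sum(axis=1)
        arcs = [(int(i), int(j)) for i, j in zip(iu[(state == 1) | (state == 3)],
                                                 ju[(state == 1) | (state == 3)])]
        arcs += [(int(j), int(i)) for i, j in zip(iu[(state == 2) | (state == 3)],
                                                  ju[(state == 2) | (state == 3)])]
        nodes = labels or [f"n{i}" for i in range(n)]
        return DirectedNetwork(nodes, arcs)
    raise ValueError(f"unknown variant {variant!r}")


def link_randomize(network: DirectedNetwork, n_swaps: int | None = None,
                   seed: int = 0) -> DirectedNetwork:
    """Degree-preserving randomization of a directed network.

    Arcs are split into reciprocated pairs and single (asymmetric)
    arcs, and double-edge swaps are attempted *within* each category:
    two single arcs ``a→b, c→d`` become ``a→d, c→b``; two reciprocated
    pairs ``{a,b}, {c,d}`` are rewired into two new reciprocated
    pairs.  Moves creating self-loops, duplicate arcs, or converting a
    single arc into a reciprocated pair (or vice versa) are rejected,
    so every node's in-, out- and reciprocated-degree is conserved
    exactly.

    Parameters
    ----------
    n_swaps
        Number of attempted swaps (default ``10 × |arcs|``).
    """
    if n_swaps is None:
        n_swaps = SWAPS_PER_ARC * network.n_arcs
    if n_swaps < 0:
        raise ValueError("n_swaps must be ≥ 0")
    rng = np.random.default_rng(seed)

    arcs = set(network.arcs)
    singles = sorted(network.asymmetric_arcs())
    mutuals = sorted(tuple(sorted(p)) for p in network.mutual_pairs())

    n_single, n_mutual = len(singles), len(mutuals)
    can_single = n_single >= 2
    can_mutual = n_mutual >= 2
    if not (can_single or can_mutual):
        return DirectedNetwork(network.node_labels, arcs)

    for _ in range(n_swaps):
        if can_single and can_mutual:
            pick_single = rng.random() < n_single / (n_single + n_mutual)
        else:
            pick_single = can_single

        if pick_single:
            k1, k2 = rng.choice(n_single, size=2, replace=False)
            a, b = singles[k1]
            c, d = singles[k2]
            # propose a→d, c→b
            if a == d or c == b:
                continue
            new1, new2 = (a, d), (c, b)
            if new1 == new2:
                continue
            # must stay single arcs: neither new arc nor its reverse may exist
            blocked = False
            for u, v in (new1, new2):
                if (u, v) in arcs and (u, v) not in ((a, b), (c, d)):
                    blocked = True
                if (v, u) in arcs and (v, u) not in ((a, b), (c, d)):
                    blocked = True
            if blocked or (new1 == (d, a) or new2 == (b, c)):
                continue
            # reverse-of-each-other check: a→d and c→b reciprocate if (d,a)==(c,b)
            if (d, a) == new2:
                continue
            arcs.discard((a, b))
            arcs.discard((c, d))
            arcs.add(new1)
            arcs.add(new2)
            singles[k1], singles[k2] = new1, new2
        else:
            k1, k2 = rng.choice(n_mutual, size=2, replace=False)
            a, b = mutuals[k1]
            c, d = mutuals[k2]
            if len({a, b, c, d}) < 4:
                continue
            # two possible pairings; choose one at random
            if rng.random() < 0.5:
                p1, p2 = (a, c), (b, d)
            else:
                p1, p2 = (a, d), (b, c)
            new_arcs = [(p1[0], p1[1]), (p1[1], p1[0]), (p2[0], p2[1]), (p2[1], p2[0])]
            old_arcs = {(a, b), (b, a), (c, d), (d, c)}
            if any(arc in arcs and arc not in old_arcs for arc in new_arcs):
                continue
            arcs -= old_arcs
            arcs.update(new_arcs)
            mutuals[k1] = tuple(sorted(p1))
            mutuals[k2] = tuple(sorted(p2))
    return DirectedNetwork(network.node_labels, arcs)


@dataclass
class EnsembleSpec:
    """Specification of a null-model ensemble.

    ``kind`` is ``"model_sample"`` (source: :class:`ModelParameters`)
    or ``"link_randomize"`` (source: an observed
    :class:`DirectedNetwork`).
    """

    kind: str
    source: object
    n_replicates: int = 1000
    seed: int = 0
    variant: str = "directed"
    n_swaps: int | None = None

    def __post_init__(self):
        if self.kind not in ("model_sample", "link_randomize"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def generate_ensemble(spec: EnsembleSpec) -> Iterator[Network]:
    """Stream the ensemble one replicate at a time.

    Replicate ``i`` uses a seed derived deterministically from
    ``(spec.seed, i)``; identical specs yield identical ensembles.
    """
    for i in range(spec.n_replicates):
        rep_seed = np.random.SeedSequence([spec.seed, i]).generate_state(1)[0] % (2**31)
        if spec.kind == "model_sample":
            yield sample_network(spec.source, spec.variant, seed=int(rep_seed))
        else:
            yield link_randomize(spec.source, spec.n_swaps, seed=int(rep_seed))
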