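"""Partition comparison and ranked link prediction.

Inferred latent-class partitions are compared with reference
partitions via normalized mutual information,
``NMI = 2·I(X;Y) / (H(X) + H(Y))``, which is permutation-invariant —
the natural choice since latent classes are identified only up to
relabelling.

For link prediction, every dyad is scored by its model probability
``p_ij`` (posterior-mean parameters) and sorted in descending order
into a candidate list; recovery curves report which fraction of
held-out positives appears in the top fraction of the list.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .model import ModelParameters
from .networks import BipartiteNetwork

__all__ = [
    "normalized_mutual_information",
    "RankedCandidateList",
    "RecoveryCurve",
    "candidate_list",
    "recovery_curve",
]


def normalized_mutual_information(labels_x: Sequence, labels_y: Sequence) -> float:
    """NMI between two partitions of the same item set.

    Computed from the empirical contingency table with the arithmetic
    normalization ``2 I / (H_x + H_y)``.  Both partitions trivial
    (single class each) → 1 by convention; exactly one trivial → 0.
    """
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = len(x)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = xi.max() + 1, yi.max() + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (xi, yi), 1.0)
    pxy = table / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hx, hy = _entropy(px), _entropy(py)
    if hx + hy == 0.0:
        return 1.0
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz])).sum())
    return max(0.0, min(1.0, 2.0 * mi / (hx + hy)))


@dataclass
class RankedCandidateList:
    """Dyads sorted by model probability, descending.

    Ties are broken by row-major ``(actor, event)`` index order.
    ``scope`` records whether the list ranks dyads absent from the
    training network (``"unknown_pairs"``, for genuinely new links) or
    present in it (``"known_pairs"``, for repeat observations).
    """

    entries: List[Tuple[int, int, float]]
    scope: str

    def __post_init__(self):
        if self.scope not in ("unknown_pairs", "known_pairs"):
            raise ValueError(f"unknown scope {self.scope!r}")
        seen = set()
        prev = None
        for i, j, p in self.entries:
            if (i, j) in seen:
                raise ValueError(f"dyad ({i},{j}) repeated")
            seen.add((i, j))
            key = (-p, i, j)
            if prev is not None and key < prev:
                raise ValueError("entries violate the descending-probability order")
            prev = key

    def __len__(self) -> int:
        return len(self.entries)

    def dyads(self) -> List[Tuple[int, int]]:
        return [(i, j) for i, j, _ in self.entries]

    def as_table(self, actor_labels=None, event_labels=None) -> str:
        lines = ["actor\tevent\tprobability"]
        for i, j, p in self.entries:
            a = actor_labels[i] if actor_labels else str(i)
            e = event_labels[j] if event_labels else str(j)
            lines.append(f"{a}\t{e}\t{p:.10g}")
        return "\n".join(lines) + "\n"


@dataclass
class RecoveryCurve:
    """Fraction of test positives found in the top fraction of a list."""

    fractions: np.ndarray
    recovered: np.ndarray
    n_positives: int

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.recovered = np.asarray(self.recovered, dtype=float)
        if np.any(np.diff(self.recovered) < -1e-12):
            raise ValueError("recovered fraction must be nondecreasing")

    def as_table(self) -> str:
        lines = ["list_fraction\trecovered_fraction"]
        for f, r in zip(self.fractions, self.recovered):
            lines.append(f"{f:.10g}\t{r:.10g}")
        return "\n".join(lines) + "\n"


def candidate_list(params: ModelParameters, training: BipartiteNetwork,
                   scope: str = "unknown_pairs") -> RankedCandidateList:
    """Rank dyads by model probability for link prediction.

    ``scope="unknown_pairs"`` ranks the dyads *absent* from the
    training network (candidates for new links);
    ``scope="known_pairs"`` ranks the observed dyads (candidates for
    repeat observations).
    """
    p = params.probability_matrix("bipartite")
    if p.shape != training.shape:
        raise ValueError("parameters not dimensioned to the training network")
    want_known = scope == "known_pairs"
    items = []
    for i in range(training.n_actors):
        for j in range(training.n_events):
            if (training.x(i, j) == 1) == want_known:
                items.append((i, j, float(p[i, j])))
    items.sort(key=lambda t: (-t[2], t[0], t[1]))
    return RankedCandidateList(items, scope)


def recovery_curve(ranked: RankedCandidateList,
                   test_positives: Iterable[Tuple[int, int]],
                   fractions: Sequence[float] = None) -> RecoveryCurve:
    """Share of test positives within each top fraction of the list.

    At fraction ``f`` the top ``⌈f·L⌉`` entries are inspected.  Test
    positives must be a nonempty subset of the list's dyad universe.
    """
    positives = set(tuple(map(int, d)) for d in test_positives)
    if not positives:
        raise ValueError("test positive set is empty")
    universe = set(ranked.dyads())
    if not positives <= universe:
        raise ValueError("test positives must be contained in the candidate list")
    if fractions is None:
        fractions = np.linspace(0.05, 1.0, 20)
    fractions = np.asarray(sorted(fractions), dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in (0, 1]")
    L = len(ranked)
    # rank position of each positive (1-based)
    ranks = [k + 1 for k, d in enumerate(ranked.dyads()) if d in positives]
    ranks = np.asarray(sorted(ranks))
    rec = np.array([
        np.searchsorted(ranks, ceil(f * L), side="right") / len(positives)
        for f in fractions
    ])
    return RecoveryCurve(fractions, rec, len(positives))
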