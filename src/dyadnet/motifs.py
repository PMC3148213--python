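"""Triad census and motif significance statistics.

Every unordered triple of nodes in a directed network falls into one
of 16 isomorphism classes, labelled by the standard MAN coding
(counts of Mutual / Asymmetric / Null dyads plus an orientation
letter): 003, 012, 102, 021D, 021U, 021C, 111D, 111U, 030T, 030C,
201, 120D, 120U, 120C, 210, 300.

Observed counts are compared against a null ensemble (link-randomized
or model-generated, see :mod:`dyadnet.ensembles`) through Z-scores
``(observed − mean)/sd`` and mean-normalized counts, with box-plot
quartiles and whiskers exported for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Set

import networkx as nx
import numpy as np

from .networks import DirectedNetwork

__all__ = [
    "TRIAD_CLASSES",
    "TriadCensus",
    "MotifStatistics",
    "triad_census",
    "motif_zscores",
    "significant_motifs",
]

#: the 16 triad classes in conventional order
TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

#: label exchanges under arc reversal (all other classes are self-dual)
REVERSAL_DUALS = {"021D": "021U", "021U": "021D",
                  "111D": "111U", "111U": "111D",
                  "120D": "120U", "120U": "120D"}

#: infinite-Z sentinel for zero-variance ensemble classes
Z_INF = float("inf")


@dataclass(frozen=True)
class TriadCensus:
    """Counts of all node triples by triad isomorphism class."""

    counts: Dict[str, int]
    n_nodes: int

    def __post_init__(self):
        unknown = set(self.counts) - set(TRIAD_CLASSES)
        if unknown:
            raise ValueError(f"unknown triad classes {unknown}")

    def __getitem__(self, label: str) -> int:
        return self.counts.get(label, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self[k] for k in TRIAD_CLASSES], dtype=float)


@dataclass
class MotifStatistics:
    """Per-class ensemble statistics for the 16 triad classes.

    ``zscores`` uses the ensemble sample standard deviation;
    zero-variance classes get Z = 0 when the observation equals the
    ensemble constant and an infinite sentinel otherwise.
    ``normalized`` is observed ÷ ensemble mean (NaN for zero means).
    Quartiles and 1.5×IQR whisker bounds support box-plot style flags.
    """

    observed: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    zscores: np.ndarray
    normalized: np.ndarray
    q1: np.ndarray
    median: np.ndarray
    q3: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray

    def as_table(self) -> str:
        """Tab-separated table, one row per triad class."""
        lines = ["class\tobserved\tmean\tsd\tZ\tnormalized\tq1\tmedian\tq3\twhisker_lo\twhisker_hi"]
        for k, label in enumerate(TRIAD_CLASSES):
            row = [label, "%d" % self.observed[k]] + [
                "%.10g" % v for v in (
                    self.mean[k], self.sd[k], self.zscores[k], self.normalized[k],
                    self.q1[k], self.median[k], self.q3[k],
                    self.whisker_lo[k], self.whisker_hi[k])
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def whisker_outliers(self) -> Set[str]:
        """Classes whose observed count falls outside the whiskers."""
        out = set()
        for k, label in enumerate(TRIAD_CLASSES):
            if self.observed[k] < self.whisker_lo[k] or self.observed[k] > self.whisker_hi[k]:
                out.add(label)
        return out


def triad_census(network: DirectedNetwork) -> TriadCensus:
    """Classify every unordered node triple into its triad class.

    Uses the MAN-coded triadic census; the total always equals
    C(n, 3).  Networks with fewer than three nodes yield an all-zero
    census.
    """
    n = network.n_nodes
    if n < 3:
        return TriadCensus({}, n)
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    G.add_edges_from(network.arcs)
    raw = nx.triadic_census(G)
    counts = {k: int(v) for k, v in raw.items() if v}
    return TriadCensus(counts, n)


def motif_zscores(observed: TriadCensus,
                  ensemble: Iterable[TriadCensus]) -> MotifStatistics:
    """Ensemble-referenced significance statistics for the 16 classes."""
    mat = np.array([c.as_vector() for c in ensemble])
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("ensemble must contain at least two censuses")
    obs = observed.as_vector()
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    z = np.empty(len(TRIAD_CLASSES))
    for k in range(len(TRIAD_CLASSES)):
        if sd[k] > 0:
            z[k] = (obs[k] - mean[k]) / sd[k]
        else:
            z[k] = 0.0 if obs[k] == mean[k] else np.copysign(Z_INF, obs[k] - mean[k])
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(mean > 0, obs / mean, np.nan)
    q1, med, q3 = np.percentile(mat, [25, 50, 75], axis=0)
    iqr = q3 - q1
    return MotifStatistics(
        observed=obs, mean=mean, sd=sd, zscores=z, normalized=norm,
        q1=q1, median=med, q3=q3,
        whisker_lo=q1 - 1.5 * iqr, whisker_hi=q3 + 1.5 * iqr,
    )


def significant_motifs(stats: MotifStatistics, z_threshold: float = 2.0) -> Set[str]:
    """Triad classes with ``|Z|`` above the threshold (or infinite Z)."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    out = set()
    for k, label in enumerate(TRIAD_CLASSES):
        z = stats.zscores[k]
        if np.isinf(z) or abs(z) > z_threshold:
            out.add(label)
    return out
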