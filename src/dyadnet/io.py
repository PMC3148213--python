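"""Text formats: edge lists, posterior tables, statistics tables.

Edge lists are whitespace-delimited, one association per line
(``actor-label  event-label``); lines starting with ``#`` are
comments.  This matches common two-column association dumps such as
gene–disease lists.  Labels are deduplicated in first-appearance
order; duplicate lines are collapsed with a logged warning.

Posterior summaries round-trip through a sectioned tab-separated
format (class-probability rows per node, mean/sd per continuous
parameter, block matrices, convergence metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .inference import PosteriorSummary
from .networks import BipartiteNetwork, DirectedNetwork

__all__ = [
    "ParseError",
    "read_bipartite_edgelist",
    "read_directed_edgelist",
    "write_bipartite_edgelist",
    "write_directed_edgelist",
    "write_posterior",
    "read_posterior",
    "PosteriorTable",
    "read_config",
]

logger = logging.getLogger("dyadnet.io")


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _read_pairs(path) -> List[Tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(path, lineno, f"expected two labels, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
    return pairs


def read_bipartite_edgelist(path) -> BipartiteNetwork:
    """Read ``actor event`` pairs into a :class:`BipartiteNetwork`."""
    pairs = _read_pairs(path)
    if not pairs:
        raise ParseError(path, 0, "no edges")
    actors: Dict[str, int] = {}
    events: Dict[str, int] = {}
    edges = set()
    dupes = 0
    for a, e in pairs:
        i = actors.setdefault(a, len(actors))
        j = events.setdefault(e, len(events))
        if (i, j) in edges:
            dupes += 1
        edges.add((i, j))
    if dupes:
        logger.warning("%s: collapsed %d duplicate association(s)", path, dupes)
    return BipartiteNetwork(list(actors), list(events), edges)


def read_directed_edgelist(path) -> DirectedNetwork:
    """Read ``source target`` pairs into a :class:`DirectedNetwork`.

    Self-loop lines are dropped with a warning.
    """
    pairs = _read_pairs(path)
    if not pairs:
        raise ParseError(path, 0, "no edges")
    nodes: Dict[str, int] = {}
    arcs = set()
    dupes = loops = 0
    for s, t in pairs:
        if s == t:
            loops += 1
            nodes.setdefault(s, len(nodes))
            continue
        i = nodes.setdefault(s, len(nodes))
        j = nodes.setdefault(t, len(nodes))
        if (i, j) in arcs:
            dupes += 1
        arcs.add((i, j))
    if loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, loops)
    if dupes:
        logger.warning("%s: collapsed %d duplicate arc(s)", path, dupes)
    return DirectedNetwork(list(nodes), arcs)


def write_bipartite_edgelist(network: BipartiteNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# actor\tevent\n")
        for i, j in sorted(network.edges):
            fh.write(f"{network.actor_labels[i]}\t{network.event_labels[j]}\n")


def write_directed_edgelist(network: DirectedNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for i, j in sorted(network.arcs):
            fh.write(f"{network.node_labels[i]}\t{network.node_labels[j]}\n")


# ---------------------------------------------------------------------------
# posterior tables
# ---------------------------------------------------------------------------

def _moments(weights: np.ndarray, grid: np.ndarray):
    mean = weights @ grid
    var = (weights * (grid - mean[..., None]) ** 2).sum(-1)
    return mean, np.sqrt(np.maximum(var, 0.0))


def write_posterior(summary: PosteriorSummary, path,
                    actor_labels=None, event_labels=None) -> None:
    """Write class posteriors, parameter moments and metadata.

    The format round-trips through :func:`read_posterior`.
    """
    N = summary.activity.shape[0]
    q = summary.actor_class_probs.shape[1]
    actor_labels = actor_labels or [f"a{i}" for i in range(N)]
    lines = ["# dyadnet posterior v1"]
    lines.append(f"# variant\t{summary.variant}")
    meta = (f"# meta\tconverged={int(summary.converged)}\tsweeps={summary.sweeps}"
            f"\tfinal_change={summary.final_change:.10g}"
            f"\tlog_likelihood={summary.log_likelihood:.10g}")
    lines.append(meta)

    lines.append("[actor_classes]")
    lines.append("label\t" + "\t".join(f"p{r}" for r in range(q)) + "\tmap")
    amap = summary.actor_class_map()
    for i in range(N):
        probs = "\t".join(f"{p:.10g}" for p in summary.actor_class_probs[i])
        lines.append(f"{actor_labels[i]}\t{probs}\t{amap[i]}")

    if summary.event_class_probs is not None:
        M, l = summary.event_class_probs.shape
        event_labels = event_labels or [f"e{j}" for j in range(M)]
        lines.append("[event_classes]")
        lines.append("label\t" + "\t".join(f"p{s}" for s in range(l)) + "\tmap")
        emap = summary.event_class_map()
        for j in range(M):
            probs = "\t".join(f"{p:.10g}" for p in summary.event_class_probs[j])
            lines.append(f"{event_labels[j]}\t{probs}\t{emap[j]}")

    mean, sd = _moments(summary.activity, summary.grid)
    lines.append("[activity]")
    lines.append("label\tmean\tsd")
    for i in range(N):
        lines.append(f"{actor_labels[i]}\t{mean[i]:.10g}\t{sd[i]:.10g}")

    if summary.popularity is not None:
        M = summary.popularity.shape[0]
        plabels = (event_labels or [f"e{j}" for j in range(M)]) \
            if summary.variant == "bipartite" else actor_labels
        mean, sd = _moments(summary.popularity, summary.grid)
        lines.append("[popularity]")
        lines.append("label\tmean\tsd")
        for j in range(M):
            lines.append(f"{plabels[j]}\t{mean[j]:.10g}\t{sd[j]:.10g}")

    mean, sd = _moments(summary.preference, summary.grid)
    lines.append("[preference]")
    lines.append("row\tcol\tmean\tsd")
    for r in range(mean.shape[0]):
        for s in range(mean.shape[1]):
            lines.append(f"{r}\t{s}\t{mean[r, s]:.10g}\t{sd[r, s]:.10g}")

    if summary.reciprocity is not None:
        mean, sd = _moments(summary.reciprocity, summary.rho_grid)
        lines.append("[reciprocity]")
        lines.append("row\tcol\tmean\tsd")
        for r in range(mean.shape[0]):
            for s in range(mean.shape[1]):
                lines.append(f"{r}\t{s}\t{mean[r, s]:.10g}\t{sd[r, s]:.10g}")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class PosteriorTable:
    """Re-read posterior summary (point estimates, not full grids)."""

    variant: str
    converged: bool
    sweeps: int
    final_change: float
    log_likelihood: float
    actor_labels: List[str]
    actor_class_probs: np.ndarray
    actor_class_map: np.ndarray
    event_labels: Optional[List[str]]
    event_class_probs: Optional[np.ndarray]
    event_class_map: Optional[np.ndarray]
    activity_mean: np.ndarray
    activity_sd: np.ndarray
    popularity_mean: Optional[np.ndarray]
    popularity_sd: Optional[np.ndarray]
    preference_mean: np.ndarray
    preference_sd: np.ndarray
    reciprocity_mean: Optional[np.ndarray]
    reciprocity_sd: Optional[np.ndarray]


def read_posterior(path) -> PosteriorTable:
    """Round-trip reader for :func:`write_posterior` output."""
    sections: Dict[str, List[List[str]]] = {}
    meta: Dict[str, str] = {}
    variant = None
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# variant"):
                variant = line.split("\t")[1]
                continue
            if line.startswith("# meta"):
                for kv in line.split("\t")[1:]:
                    k, v = kv.split("=")
                    meta[k] = v
                continue
            if line.startswith("#"):
                continue
            if line.startswith("["):
                current = line.strip("[]")
                sections[current] = []
                continue
            sections[current].append(line.split("\t"))

    def _matrix(name):
        if name not in sections:
            return None, None
        rows = sections[name][1:]
        rr = max(int(r[0]) for r in rows) + 1
        cc = max(int(r[1]) for r in rows) + 1
        mean = np.zeros((rr, cc))
        sd = np.zeros((rr, cc))
        for r in rows:
            mean[int(r[0]), int(r[1])] = float(r[2])
            sd[int(r[0]), int(r[1])] = float(r[3])
        return mean, sd

    def _classes(name):
        if name not in sections:
            return None, None, None
        rows = sections[name][1:]
        labels = [r[0] for r in rows]
        probs = np.array([[float(x) for x in r[1:-1]] for r in rows])
        cmap = np.array([int(r[-1]) for r in rows])
        return labels, probs, cmap

    def _moment_rows(name):
        if name not in sections:
            return None, None, None
        rows = sections[name][1:]
        labels = [r[0] for r in rows]
        return labels, np.array([float(r[1]) for r in rows]), \
            np.array([float(r[2]) for r in rows])

    alabels, aprobs, amap = _classes("actor_classes")
    elabels, eprobs, emap = _classes("event_classes")
    _, amean, asd = _moment_rows("activity")
    pop = _moment_rows("popularity")
    pmean, psd = _matrix("preference")
    rmean, rsd = _matrix("reciprocity")
    return PosteriorTable(
        variant=variant,
        converged=bool(int(meta.get("converged", 0))),
        sweeps=int(meta.get("sweeps", 0)),
        final_change=float(meta.get("final_change", "nan")),
        log_likelihood=float(meta.get("log_likelihood", "nan")),
        actor_labels=alabels,
        actor_class_probs=aprobs,
        actor_class_map=amap,
        event_labels=elabels,
        event_class_probs=eprobs,
        event_class_map=emap,
        activity_mean=amean,
        activity_sd=asd,
        popularity_mean=pop[1],
        popularity_sd=pop[2],
        preference_mean=pmean,
        preference_sd=psd,
        reciprocity_mean=rmean,
        reciprocity_sd=rsd,
    )


def read_config(path) -> Dict[str, str]:
    """``key = value`` configuration file mirroring the CLI flags."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(path, lineno, "expected 'key = value'")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
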