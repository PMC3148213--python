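"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's message-passing code paths:
marginals are computed by exhaustive summation over the fully
discretised parameter space, triads by explicit isomorphism testing.
"""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np


def exhaustive_bipartite_marginals(x: np.ndarray, grid: np.ndarray,
                                   q: int, l: int) -> dict:
    """Exact marginal posteriors on the discretised parameter space.

    Enumerates every combination of class labels and π grid values;
    for each, the activity sums factorise per actor once the
    popularity configuration is fixed, which keeps the loop tractable
    for networks up to 3 × 3 with B = 5 and q = l = 2.  Priors are
    uniform on the grid and over classes.  Returns weight arrays
    keyed ``"a" (N, B)``, ``"b" (M, B)``, ``"c" (N, q)``,
    ``"d" (M, l)``, ``"pi" (q, l, B)``.
    """
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    B = len(grid)

    pi_configs = np.array(list(product(grid, repeat=q * l)))        # (K, q*l)
    K = pi_configs.shape[0]
    PI = pi_configs.reshape(K, q, l)
    b_configs = np.array(list(product(grid, repeat=m)))             # (C, m)
    C = b_configs.shape[0]

    marg = {
        "a": np.zeros((n, B)),
        "b": np.zeros((m, B)),
        "c": np.zeros((n, q)),
        "d": np.zeros((m, l)),
        "pi": np.zeros((q, l, B)),
    }

    for c_cfg in product(range(q), repeat=n):
        for d_cfg in product(range(l), repeat=m):
            d_idx = np.array(d_cfg)
            # per-actor likelihood, keeping the activity axis
            F_full = np.empty((n, K, B, C))
            for i in range(n):
                pi_sel = PI[:, c_cfg[i], d_idx]                     # (K, m)
                p = (grid[None, :, None, None]
                     * b_configs.T[None, None, :, :].transpose(0, 1, 3, 2)
                     * pi_sel[:, None, None, :])                    # (K, B, C, m)
                f = np.where(x[i] == 1, p, 1.0 - p)
                F_full[i] = f.prod(axis=-1)
            F_sum = F_full.sum(axis=2)                              # (n, K, C): Σ over a_i
            # total likelihood per (π config, b config)
            prod_all = F_sum.prod(axis=0)                           # (K, C)
            total = prod_all.sum()
            # class marginals
            for i in range(n):
                marg["c"][i, c_cfg[i]] += total
            for j in range(m):
                marg["d"][j, d_cfg[j]] += total
            # activity marginals: product over other actors × per-a term
            for i in range(n):
                others = np.ones((K, C))
                for i2 in range(n):
                    if i2 != i:
                        others *= F_sum[i2]
                marg["a"][i] += (others[:, None, :] * F_full[i]).sum(axis=(0, 2))
            # popularity marginals: group b configurations by b_j value
            for j in range(m):
                for k_val, val in enumerate(grid):
                    sel = b_configs[:, j] == val
                    marg["b"][j, k_val] += prod_all[:, sel].sum()
            # π marginals: group π configurations by entry value
            flat = prod_all.sum(axis=1)                             # (K,)
            for r in range(q):
                for s in range(l):
                    col = pi_configs[:, r * l + s]
                    for k_val, val in enumerate(grid):
                        marg["pi"][r, s, k_val] += flat[col == val].sum()

    for key, arr in marg.items():
        marg[key] = arr / arr.sum(axis=-1, keepdims=True)
    return marg


# --- triads ----------------------------------------------------------------

_TRIAD_EXEMPLARS = {
    "003": [],
    "012": [(0, 1)],
    "102": [(0, 1), (1, 0)],
    "021D": [(0, 1), (0, 2)],
    "021U": [(1, 0), (2, 0)],
    "021C": [(0, 1), (1, 2)],
    "111D": [(0, 1), (1, 0), (2, 0)],
    "111U": [(0, 1), (1, 0), (0, 2)],
    "030T": [(0, 1), (0, 2), (1, 2)],
    "030C": [(0, 1), (1, 2), (2, 0)],
    "201": [(0, 1), (1, 0), (0, 2), (2, 0)],
    "120D": [(0, 1), (1, 0), (2, 0), (2, 1)],
    "120U": [(0, 1), (1, 0), (0, 2), (1, 2)],
    "120C": [(0, 1), (1, 0), (1, 2), (2, 0)],
    "210": [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2)],
    "300": [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)],
}


def classify_triad_bruteforce(arcs_3: set) -> str:
    """Label a 3-node digraph by explicit isomorphism testing."""
    g = nx.DiGraph()
    g.add_nodes_from(range(3))
    g.add_edges_from(arcs_3)
    for label, arcs in _TRIAD_EXEMPLARS.items():
        h = nx.DiGraph()
        h.add_nodes_from(range(3))
        h.add_edges_from(arcs)
        if nx.is_isomorphic(g, h):
            return label
    raise AssertionError("unclassifiable triad")  # pragma: no cover


def census_bruteforce(network) -> dict:
    """Triad census by classifying every triple independently."""
    from itertools import combinations

    counts: dict = {}
    n = network.n_nodes
    for trio in combinations(range(n), 3):
        remap = {node: k for k, node in enumerate(trio)}
        arcs = {(remap[i], remap[j]) for i, j in network.arcs
                if i in remap and j in remap}
        label = classify_triad_bruteforce(arcs)
        counts[label] = counts.get(label, 0) + 1
    return counts
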