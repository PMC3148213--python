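"""Belief-propagation inference for the multiscale dyadic model.

The posterior over all parameters — activities ``a_i``, popularities
``b_j``, class labels ``c_i``/``d_j``, preference entries ``π_rs`` and
(directed variant) reciprocities ``ρ_rs`` — is approximated by message
passing on the factor graph of the dyad-factorised likelihood.  Each
dyad is a factor; an actor's variables are adjacent to every factor in
its row, an event's variables to every factor in its column, and the
block-level variables (π, ρ) to every factor.

Two message families circulate:

* *R-messages* (factor → variable): the expected likelihood of one
  observed dyad as a function of the target variable, with all other
  adjacent variables integrated/summed out under their incoming
  Q-messages.
* *Q-messages* (variable → factor): the posterior of one variable
  given the whole data matrix except the destination dyad — the
  normalised product of the prior and every incoming R-message except
  the one from the destination factor ("cavity" product).

At convergence the marginal posterior of each variable is the prior
times the product of *all* incoming R-messages, normalised.

Continuous parameters are carried as weights on a regular grid
(:class:`~dyadnet.distributions.GridDistribution`); class labels as
categorical weights.  Because the Bernoulli dyad likelihood is linear
in each continuous parameter separately, the grid quadrature of the
bipartite/undirected R-messages is exact given the incoming messages.
For directed dyads the per-dyad renormalisation over the four states
makes the likelihood nonlinear in the non-target parameters; there the
engine sums exactly over class pairs and over the target's grid while
evaluating the remaining continuous parameters at their incoming
Q-message means (see docs/methods.md).

Turning ``node_effects`` off clamps all activities and popularities to
point masses at 1, which reduces the model to a plain stochastic block
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import product
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .distributions import CategoricalDistribution, GridDistribution, Priors, posterior_moments
from .model import ModelParameters, network_log_likelihood
from .networks import BipartiteNetwork, DirectedNetwork, UndirectedNetwork

__all__ = [
    "InferenceConfig",
    "MessageSet",
    "PosteriorSummary",
    "MessageNormalizationError",
    "init_messages",
    "update_sweep",
    "run_inference",
    "compute_r_message",
    "compute_q_message",
    "class_map_assignment",
    "posterior_moments",
]

logger = logging.getLogger("dyadnet.inference")

_INIT_NOISE = 0.01  # relative amplitude of symmetry-breaking init noise


class MessageNormalizationError(RuntimeError):
    """A message collapsed to all-zero weight and cannot be normalised."""


@dataclass
class InferenceConfig:
    """Settings for one inference run.

    Parameters
    ----------
    q, l
        Number of actor and event classes (``l`` defaults to ``q``;
        ignored except for the bipartite variant).  The class count is
        a free resolution parameter chosen by the user.
    grid_size
        Number of grid points per continuous parameter.
    damping
        Message damping λ: ``new = (1−λ)·proposed + λ·old``.
    tolerance, max_sweeps
        Convergence is declared when the largest absolute message
        change in one sweep drops below ``tolerance``.
    seed
        Seed for the symmetry-breaking initialisation noise.
    node_effects
        ``False`` clamps a ≡ b ≡ 1 (plain stochastic block model).
    variant
        ``"bipartite"``, ``"undirected"`` or ``"directed"``; inferred
        from the network type when ``None``.
    rho_max
        Upper end of the reciprocity grid (directed variant).
    n_restarts, burn_in
        The joint posterior over class labels and block parameters has
        multiple message-passing fixed points: a label-symmetric one
        and, when the data support it, symmetry-broken ones.  Each
        restart after the first seeds the preference messages with a
        randomly oriented high/low block pattern and holds them fixed
        for ``burn_in`` sweeps while the class messages condense, then
        releases everything; the fixed point with the highest Bethe
        evidence is returned.  ``n_restarts=1`` disables the
        exploration and keeps the plain perturbed-prior start.
    """

    q: int = 2
    l: Optional[int] = None
    grid_size: int = 25
    damping: float = 0.5
    tolerance: float = 1e-6
    max_sweeps: int = 500
    seed: int = 0
    node_effects: bool = True
    variant: Optional[str] = None
    rho_max: float = 10.0
    n_restarts: int = 5
    burn_in: int = 20

    def __post_init__(self):
        if self.l is None:
            self.l = self.q
        if self.q < 1 or self.l < 1:
            raise ValueError("class counts must be ≥ 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be ≥ 2")
        if not (0.0 <= self.damping <= 1.0):
            raise ValueError("damping must lie in [0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be ≥ 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be ≥ 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be ≥ 0")
        if self.variant not in (None, "bipartite", "undirected", "directed"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class MessageSet:
    """All R- and Q-messages of one run, as dense weight arrays.

    Array layouts (``B`` = grid size, ``D`` = number of dyads):

    bipartite — ``a``/``b``: ``(N, M, B)``; ``c``: ``(N, M, q)``;
    ``d``: ``(N, M, l)``; ``pi``: ``(N, M, q, l, B)``.

    unipartite — dyads are indexed by arrays ``I < J``; node-variable
    messages have an endpoint axis: ``a``/``b``: ``(D, 2, B)``,
    ``c``: ``(D, 2, q)``; ``pi``/``rho``: ``(D, q, q, B)`` (for
    undirected π and for ρ the ``(r, s)`` and ``(s, r)`` entries are
    tied copies of one unordered-pair variable).
    """

    variant: str
    grid: np.ndarray
    rho_grid: Optional[np.ndarray]
    q_msgs: Dict[str, np.ndarray]
    r_msgs: Dict[str, np.ndarray]
    dyads: Optional[Tuple[np.ndarray, np.ndarray]] = None
    node_effects: bool = True

    def copy(self) -> "MessageSet":
        return MessageSet(
            self.variant,
            self.grid.copy(),
            None if self.rho_grid is None else self.rho_grid.copy(),
            {k: v.copy() for k, v in self.q_msgs.items()},
            {k: v.copy() for k, v in self.r_msgs.items()},
            self.dyads,
            self.node_effects,
        )


@dataclass
class PosteriorSummary:
    """Approximate marginal posteriors and run diagnostics.

    Continuous posteriors are stored as weight arrays over the stated
    grids; class posteriors as row-stochastic matrices.
    """

    variant: str
    config: InferenceConfig
    grid: np.ndarray
    activity: np.ndarray                 # (N, B)
    popularity: Optional[np.ndarray]     # (M or N, B); None if undirected
    actor_class_probs: np.ndarray        # (N, q)
    event_class_probs: Optional[np.ndarray]  # (M, l); None if unipartite
    preference: np.ndarray               # (q, l, B)
    rho_grid: Optional[np.ndarray] = None
    reciprocity: Optional[np.ndarray] = None  # (q, q, B) symmetric
    converged: bool = False
    sweeps: int = 0
    final_change: float = np.inf
    log_likelihood: float = np.nan
    bethe_evidence: float = np.nan
    restart: int = 0

    # -- point estimates -------------------------------------------------
    def activity_mean(self) -> np.ndarray:
        return self.activity @ self.grid

    def popularity_mean(self) -> Optional[np.ndarray]:
        return None if self.popularity is None else self.popularity @ self.grid

    def preference_mean(self) -> np.ndarray:
        return self.preference @ self.grid

    def preference_std(self) -> np.ndarray:
        m = self.preference_mean()[..., None]
        return np.sqrt(np.maximum((self.preference * (self.grid - m) ** 2).sum(-1), 0.0))

    def reciprocity_mean(self) -> Optional[np.ndarray]:
        if self.reciprocity is None:
            return None
        m = self.reciprocity @ self.rho_grid
        return 0.5 * (m + m.T)

    def actor_class_map(self) -> np.ndarray:
        return class_map_assignment(self.actor_class_probs)

    def event_class_map(self) -> Optional[np.ndarray]:
        if self.event_class_probs is None:
            return None
        return class_map_assignment(self.event_class_probs)

    def to_parameters(self) -> ModelParameters:
        """Posterior-mean point estimates with MAP class labels."""
        if self.variant == "bipartite":
            return ModelParameters(
                activities=self.activity_mean(),
                popularities=self.popularity_mean(),
                actor_classes=self.actor_class_map(),
                event_classes=self.event_class_map(),
                preference=self.preference_mean(),
            )
        if self.variant == "undirected":
            pref = self.preference_mean()
            return ModelParameters(
                activities=self.activity_mean(),
                popularities=None,
                actor_classes=self.actor_class_map(),
                preference=0.5 * (pref + pref.T),
            )
        return ModelParameters(
            activities=self.activity_mean(),
            popularities=self.popularity_mean(),
            actor_classes=self.actor_class_map(),
            preference=self.preference_mean(),
            reciprocity=self.reciprocity_mean(),
        )


# ---------------------------------------------------------------------------
# small numerical helpers
# ---------------------------------------------------------------------------

def _normalize_last(w: np.ndarray, what: str) -> np.ndarray:
    s = w.sum(axis=-1, keepdims=True)
    if np.any(s <= 0) or not np.isfinite(s).all():
        bad = np.argwhere(~((s > 0) & np.isfinite(s)))[0]
        raise MessageNormalizationError(
            f"{what}: message at index {tuple(bad[:-1])} has zero/invalid total weight"
        )
    return w / s


def _softmax_last(logw: np.ndarray, what: str) -> np.ndarray:
    mx = np.max(logw, axis=-1, keepdims=True)
    if not np.isfinite(mx).all():
        bad = np.argwhere(~np.isfinite(mx))[0]
        raise MessageNormalizationError(
            f"{what}: log-message at index {tuple(bad[:-1])} is −inf everywhere"
        )
    w = np.exp(logw - mx)
    return w / w.sum(axis=-1, keepdims=True)


def _cavity_logs(logR: np.ndarray, factor_axes) -> Tuple[np.ndarray, np.ndarray]:
    """Leave-one-factor-out log-sums with explicit −inf bookkeeping.

    Returns ``(cavity, total)`` where ``total`` is the log-sum over all
    factors (−inf where any factor contributes −inf) and ``cavity`` the
    per-factor leave-one-out version.  A −inf surviving in the cavity
    means *another* factor vetoed that grid point.
    """
    neg = np.isneginf(logR)
    fin = np.where(neg, 0.0, logR)
    s = fin.sum(axis=factor_axes, keepdims=True)
    cnt = neg.sum(axis=factor_axes, keepdims=True)
    cav = s - fin
    cav_cnt = cnt - neg
    cav = np.where(cav_cnt > 0, -np.inf, cav)
    total = np.where(cnt > 0, -np.inf, s)
    return cav, np.squeeze(total, axis=factor_axes)


def _log(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(w)


def _damp(new: np.ndarray, old: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * new + lam * old if lam > 0 else new


def _bernoulli_factor(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """``x p + (1−x)(1−p)`` with broadcasting."""
    return x * p + (1.0 - x) * (1.0 - p)


def _lik4(xij, xji, u, v, rho) -> np.ndarray:
    """Normalised 4-state directed dyad likelihood, broadcasting."""
    pu = xij * u + (1 - xij) * (1.0 - u)
    pv = xji * v + (1 - xji) * (1.0 - v)
    w = pu * pv * np.where((xij == 1) & (xji == 1), rho, 1.0)
    z = 1.0 + u * v * (rho - 1.0)
    if np.any(z <= 0):
        raise MessageNormalizationError("degenerate directed dyad: zero normaliser")
    return w / z


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _variant_of(network) -> str:
    if isinstance(network, BipartiteNetwork):
        return "bipartite"
    if isinstance(network, DirectedNetwork):
        return "directed"
    if isinstance(network, UndirectedNetwork):
        return "undirected"
    raise TypeError(f"unsupported network type {type(network).__name__}")


def _resolve(network, config: InferenceConfig, priors: Optional[Priors]):
    variant = config.variant or _variant_of(network)
    if config.variant is None:
        config = replace(config, variant=variant)
    elif variant != _variant_of(network):
        raise ValueError("config.variant does not match the network type")
    if priors is None:
        priors = Priors(grid_size=config.grid_size, rho_max=config.rho_max)
    if priors.grid_size != config.grid_size:
        raise ValueError("priors.grid_size must match config.grid_size")
    return variant, config, priors


def _noisy(prior_w: np.ndarray, var_shape, rng, eps: float) -> np.ndarray:
    """Per-variable beliefs ``prior × (1 + ε·noise)``, renormalised.

    All Q-messages leaving one variable start identical (they are
    copies of the same belief), so the noise is drawn once per
    variable and the caller replicates the belief onto message slots.
    Coherent per-variable noise is what allows the class-label
    symmetry to actually break; independent per-message noise would
    average out in the updates of the globally shared block
    parameters.
    """
    w = np.broadcast_to(prior_w, tuple(var_shape) + prior_w.shape).copy()
    if eps > 0:
        w *= 1.0 + eps * rng.random(w.shape)
    return _normalize_last(w, "init")


def init_messages(network, config: InferenceConfig, priors: Optional[Priors] = None,
                  noise: float = _INIT_NOISE) -> MessageSet:
    """Initialise Q-messages to perturbed priors, R-messages to uniform.

    Each Q-message starts at ``prior · (1 + ε·noise)``, renormalised,
    with ε = 0.01 by default and noise drawn from the generator seeded
    by ``config.seed`` — deterministic given the seed, and enough to
    break class-label symmetry.
    """
    variant, config, priors = _resolve(network, config, priors)
    rng = np.random.default_rng(config.seed)
    g = priors.grid()
    B = len(g)
    pa = priors.activity_prior().weights
    pb = priors.popularity_prior().weights
    pp = priors.preference_prior().weights
    q, l = config.q, config.l

    if variant == "bipartite":
        N, M = network.shape

        def _rows(belief):          # per-actor belief → (N, M, ...) messages
            return np.repeat(belief[:, None], M, axis=1)

        def _cols(belief):          # per-event belief → (N, M, ...) messages
            return np.repeat(belief[None, :], N, axis=0)

        qm = {
            "a": _rows(_noisy(pa, (N,), rng, noise)),
            "b": _cols(_noisy(pb, (M,), rng, noise)),
            "c": _rows(_noisy(np.full(q, 1.0 / q), (N,), rng, noise)),
            "d": _cols(_noisy(np.full(l, 1.0 / l), (M,), rng, noise)),
            "pi": np.broadcast_to(_noisy(pp, (q, l), rng, noise),
                                  (N, M, q, l, len(g))).copy(),
        }
        rm = {
            "a": np.full((N, M, B), 1.0 / B),
            "b": np.full((N, M, B), 1.0 / B),
            "c": np.full((N, M, q), 1.0 / q),
            "d": np.full((N, M, l), 1.0 / l),
            "pi": np.full((N, M, q, l, B), 1.0 / B),
        }
        ms = MessageSet(variant, g, None, qm, rm, None, config.node_effects)
        if not config.node_effects:
            _clamp_node_effects(ms)
        return ms

    # unipartite variants: enumerate unordered dyads i < j
    n = network.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    D = len(iu)
    ends = np.stack([iu, ju], axis=1)            # (D, 2) node index per endpoint
    qm = {
        "a": _noisy(pa, (n,), rng, noise)[ends],
        "c": _noisy(np.full(q, 1.0 / q), (n,), rng, noise)[ends],
        "pi": np.broadcast_to(_noisy(pp, (q, q), rng, noise), (D, q, q, B)).copy(),
    }
    rm = {
        "a": np.full((D, 2, B), 1.0 / B),
        "c": np.full((D, 2, q), 1.0 / q),
        "pi": np.full((D, q, q, B), 1.0 / B),
    }
    rho_grid = None
    if variant == "directed":
        qm["b"] = _noisy(pb, (n,), rng, noise)[ends]
        rm["b"] = np.full((D, 2, B), 1.0 / B)
        rho_grid = priors.rho_grid()
        pr = priors.reciprocity_prior().weights
        # tied copies of unordered-pair variables: draw for r ≤ s, mirror
        qrho = _noisy(pr, (q, q), rng, noise)
        for r in range(q):
            for s in range(r):
                qrho[r, s] = qrho[s, r]
        qm["rho"] = np.broadcast_to(qrho, (D, q, q, B)).copy()
        rm["rho"] = np.full((D, q, q, B), 1.0 / B)
    else:
        # undirected π is an unordered-pair variable: tie the copies
        sym = qm["pi"][0].copy()
        for r in range(q):
            for s in range(r):
                sym[r, s] = sym[s, r]
        qm["pi"][:] = sym
    ms = MessageSet(variant, g, rho_grid, qm, rm, (iu, ju), config.node_effects)
    if not config.node_effects:
        _clamp_node_effects(ms)
    return ms


def _clamp_node_effects(ms: MessageSet) -> None:
    """Point-mass a ≡ b ≡ 1: the plain stochastic block model."""
    delta = np.zeros_like(ms.grid)
    delta[int(np.argmin(np.abs(ms.grid - 1.0)))] = 1.0
    for key in ("a", "b"):
        if key in ms.q_msgs:
            ms.q_msgs[key][:] = delta
            ms.r_msgs[key][:] = 1.0 / len(ms.grid)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def update_sweep(message_set: MessageSet, network, priors: Priors,
                 config: InferenceConfig):
    """One synchronous sweep: all R-messages, then all Q-messages.

    Damped by ``config.damping``; returns ``(new MessageSet,
    max_abs_change)`` where the change is the largest absolute weight
    difference over every message of either family.
    """
    variant = message_set.variant
    if variant == "bipartite":
        return _sweep_bipartite(message_set, network, priors, config)
    if variant == "undirected":
        return _sweep_undirected(message_set, network, priors, config)
    return _sweep_directed(message_set, network, priors, config)


def _sweep_bipartite(ms: MessageSet, network, priors: Priors, config: InferenceConfig):
    g = ms.grid
    lam = config.damping
    X = network.adjacency().astype(float)
    N, M = X.shape
    q, l = config.q, config.l
    new = ms.copy()
    change = 0.0

    Qa, Qb = ms.q_msgs["a"], ms.q_msgs["b"]
    Qc, Qd = ms.q_msgs["c"], ms.q_msgs["d"]
    Qp = ms.q_msgs["pi"]

    ma = Qa @ g                    # (N, M) cavity means of a_i
    mb = Qb @ g
    mpi = Qp @ g                   # (N, M, q, l)
    W = Qc[:, :, :, None] * Qd[:, :, None, :]   # (N, M, q, l) class-pair probs

    X4 = X[:, :, None, None]
    P_rs = ma[:, :, None, None] * mb[:, :, None, None] * mpi
    F_rs = _bernoulli_factor(X4, P_rs)           # (N, M, q, l)

    # --- R-messages -----------------------------------------------------
    Rc = _normalize_last((Qd[:, :, None, :] * F_rs).sum(-1), "R[c]")
    Rd = _normalize_last((Qc[:, :, :, None] * F_rs).sum(-2), "R[d]")

    mpi_bar = (W * mpi).sum((-2, -1))            # (N, M)
    X3 = X[:, :, None]
    if ms.node_effects:
        Ka = (mb * mpi_bar)[:, :, None]
        Ra = _normalize_last(_bernoulli_factor(X3, g * Ka), "R[a]")
        Kb = (ma * mpi_bar)[:, :, None]
        Rb = _normalize_last(_bernoulli_factor(X3, g * Kb), "R[b]")
    else:
        Ra, Rb = ms.r_msgs["a"], ms.r_msgs["b"]

    Ftot = (W * F_rs).sum((-2, -1))              # (N, M)
    C_other = Ftot[:, :, None, None] - W * F_rs  # (N, M, q, l)
    Fg = _bernoulli_factor(X3, (ma * mb)[:, :, None] * g)   # (N, M, B)
    Rp = C_other[..., None] + W[..., None] * Fg[:, :, None, None, :]
    Rp = _normalize_last(Rp, "R[pi]")

    for key, val in (("a", Ra), ("b", Rb), ("c", Rc), ("d", Rd), ("pi", Rp)):
        if not ms.node_effects and key in ("a", "b"):
            continue
        damped = _damp(val, ms.r_msgs[key], lam)
        change = max(change, float(np.max(np.abs(damped - ms.r_msgs[key]))))
        new.r_msgs[key] = damped

    # --- Q-messages (cavity products of the fresh R-messages) ----------
    lpa = _log(priors.activity_prior().weights)
    lpb = _log(priors.popularity_prior().weights)
    lpp = _log(priors.preference_prior().weights)

    if ms.node_effects:
        cav_a, _ = _cavity_logs(_log(new.r_msgs["a"]), (1,))
        Qa_new = _softmax_last(cav_a + lpa, "Q[a]")
        cav_b, _ = _cavity_logs(_log(new.r_msgs["b"]), (0,))
        Qb_new = _softmax_last(cav_b + lpb, "Q[b]")
    else:
        Qa_new, Qb_new = ms.q_msgs["a"], ms.q_msgs["b"]
    cav_c, _ = _cavity_logs(_log(new.r_msgs["c"]), (1,))
    Qc_new = _softmax_last(cav_c - np.log(q), "Q[c]")
    cav_d, _ = _cavity_logs(_log(new.r_msgs["d"]), (0,))
    Qd_new = _softmax_last(cav_d - np.log(l), "Q[d]")
    cav_p, _ = _cavity_logs(_log(new.r_msgs["pi"]), (0, 1))
    Qp_new = _softmax_last(cav_p + lpp, "Q[pi]")

    for key, val in (("a", Qa_new), ("b", Qb_new), ("c", Qc_new),
                     ("d", Qd_new), ("pi", Qp_new)):
        if not ms.node_effects and key in ("a", "b"):
            continue
        damped = _damp(val, ms.q_msgs[key], lam)
        change = max(change, float(np.max(np.abs(damped - ms.q_msgs[key]))))
        new.q_msgs[key] = damped
    return new, change


def _sweep_undirected(ms: MessageSet, network, priors: Priors, config: InferenceConfig):
    g = ms.grid
    lam = config.damping
    q = config.q
    I, J = ms.dyads
    n = network.n_nodes
    A = network.adjacency().astype(float)
    x = A[I, J]                                   # (D,)
    new = ms.copy()
    change = 0.0

    Qa, Qc, Qp = ms.q_msgs["a"], ms.q_msgs["c"], ms.q_msgs["pi"]
    ma = Qa @ g                                   # (D, 2)
    mpi = Qp @ g                                  # (D, q, q)
    W = Qc[:, 0, :, None] * Qc[:, 1, None, :]     # (D, q, q)

    x2 = x[:, None, None]
    P_rs = (ma[:, 0] * ma[:, 1])[:, None, None] * mpi
    F_rs = _bernoulli_factor(x2, P_rs)            # (D, q, q)

    Rc0 = _normalize_last((Qc[:, 1, None, :] * F_rs).sum(-1), "R[c]")
    Rc1 = _normalize_last((Qc[:, 0, :, None] * F_rs).sum(-2), "R[c]")
    Rc = np.stack([Rc0, Rc1], axis=1)

    xg = x[:, None]
    if ms.node_effects:
        mpib = (W * mpi).sum((-2, -1))            # (D,)
        Ra0 = _bernoulli_factor(xg, g * (ma[:, 1] * mpib)[:, None])
        Ra1 = _bernoulli_factor(xg, g * (ma[:, 0] * mpib)[:, None])
        Ra = _normalize_last(np.stack([Ra0, Ra1], axis=1), "R[a]")
    else:
        Ra = ms.r_msgs["a"]

    # π: unordered-pair variables, tied (r,s)/(s,r) copies
    Ftot = (W * F_rs).sum((-2, -1))               # (D,)
    aa = (ma[:, 0] * ma[:, 1])[:, None]
    Fg = _bernoulli_factor(xg, aa * g)            # (D, B)
    Rp = np.empty_like(ms.r_msgs["pi"])
    for r in range(q):
        for s in range(r, q):
            w_pair = W[:, r, s] + (W[:, s, r] if s != r else 0.0)
            f_pair = W[:, r, s] * F_rs[:, r, s] + (W[:, s, r] * F_rs[:, s, r] if s != r else 0.0)
            msg = (Ftot - f_pair)[:, None] + w_pair[:, None] * Fg
            Rp[:, r, s] = msg
            Rp[:, s, r] = msg
    Rp = _normalize_last(Rp, "R[pi]")

    for key, val in (("a", Ra), ("c", Rc), ("pi", Rp)):
        if not ms.node_effects and key == "a":
            continue
        damped = _damp(val, ms.r_msgs[key], lam)
        change = max(change, float(np.max(np.abs(damped - ms.r_msgs[key]))))
        new.r_msgs[key] = damped

    change = max(change, _unipartite_q_update(new, ms, priors, config, n))
    return new, change


def _node_cavity(logR: np.ndarray, I: np.ndarray, J: np.ndarray, n: int,
                 logprior: np.ndarray, what: str) -> np.ndarray:
    """Cavity Q for node variables with per-dyad endpoint axis.

    ``logR`` has shape ``(D, 2, K)``; factor sums are accumulated per
    node over every dyad containing it.
    """
    neg = np.isneginf(logR)
    fin = np.where(neg, 0.0, logR)
    K = logR.shape[-1]
    s = np.zeros((n, K))
    cnt = np.zeros((n, K), dtype=int)
    np.add.at(s, I, fin[:, 0])
    np.add.at(s, J, fin[:, 1])
    np.add.at(cnt, I, neg[:, 0])
    np.add.at(cnt, J, neg[:, 1])
    nodes = np.stack([I, J], axis=1)              # (D, 2)
    cav = s[nodes] - fin
    cav_cnt = cnt[nodes] - neg
    cav = np.where(cav_cnt > 0, -np.inf, cav) + logprior
    return _softmax_last(cav, what)


def _node_posterior(logR: np.ndarray, I, J, n: int, logprior, what: str) -> np.ndarray:
    neg = np.isneginf(logR)
    fin = np.where(neg, 0.0, logR)
    K = logR.shape[-1]
    s = np.zeros((n, K))
    cnt = np.zeros((n, K), dtype=int)
    np.add.at(s, I, fin[:, 0])
    np.add.at(s, J, fin[:, 1])
    np.add.at(cnt, I, neg[:, 0])
    np.add.at(cnt, J, neg[:, 1])
    post = np.where(cnt > 0, -np.inf, s) + logprior
    return _softmax_last(post, what)


def _unipartite_q_update(new: MessageSet, ms: MessageSet, priors: Priors,
                         config: InferenceConfig, n: int) -> float:
    """Q-messages for both unipartite variants; returns max change."""
    lam = config.damping
    I, J = ms.dyads
    q = config.q
    change = 0.0
    lpa = _log(priors.activity_prior().weights)
    lpp = _log(priors.preference_prior().weights)

    updates = {}
    if ms.node_effects:
        updates["a"] = _node_cavity(_log(new.r_msgs["a"]), I, J, n, lpa, "Q[a]")
        if "b" in ms.q_msgs:
            lpb = _log(priors.popularity_prior().weights)
            updates["b"] = _node_cavity(_log(new.r_msgs["b"]), I, J, n, lpb, "Q[b]")
    updates["c"] = _node_cavity(_log(new.r_msgs["c"]), I, J, n,
                                np.full(q, -np.log(q)), "Q[c]")
    cav_p, _ = _cavity_logs(_log(new.r_msgs["pi"]), (0,))
    updates["pi"] = _softmax_last(cav_p + lpp, "Q[pi]")
    if "rho" in ms.q_msgs:
        lpr = _log(priors.reciprocity_prior().weights)
        cav_r, _ = _cavity_logs(_log(new.r_msgs["rho"]), (0,))
        updates["rho"] = _softmax_last(cav_r + lpr, "Q[rho]")

    for key, val in updates.items():
        damped = _damp(val, ms.q_msgs[key], lam)
        change = max(change, float(np.max(np.abs(damped - ms.q_msgs[key]))))
        new.q_msgs[key] = damped
    return change


def _sweep_directed(ms: MessageSet, network, priors: Priors, config: InferenceConfig):
    g = ms.grid
    rg = ms.rho_grid
    lam = config.damping
    q = config.q
    I, J = ms.dyads
    n = network.n_nodes
    A = network.adjacency()
    xij = A[I, J].astype(int)                     # (D,)
    xji = A[J, I].astype(int)
    new = ms.copy()
    change = 0.0

    Qa, Qb, Qc = ms.q_msgs["a"], ms.q_msgs["b"], ms.q_msgs["c"]
    Qp, Qr = ms.q_msgs["pi"], ms.q_msgs["rho"]
    ma = Qa @ g                                   # (D, 2)
    mb = Qb @ g
    mpi = Qp @ g                                  # (D, q, q)
    mrho = Qr @ rg                                # (D, q, q)
    W = Qc[:, 0, :, None] * Qc[:, 1, None, :]     # (D, q, q)

    # mean link probabilities per ordered class pair
    u0 = ma[:, 0, None, None] * mb[:, 1, None, None] * mpi            # i→j at (r,s)
    v0 = (ma[:, 1] * mb[:, 0])[:, None, None] * np.swapaxes(mpi, 1, 2)  # j→i at (r,s)

    x1 = xij[:, None, None]
    x2 = xji[:, None, None]
    F_rs = _lik4(x1, x2, u0, v0, mrho)            # (D, q, q)

    Rc0 = _normalize_last((Qc[:, 1, None, :] * F_rs).sum(-1), "R[c]")
    Rc1 = _normalize_last((Qc[:, 0, :, None] * F_rs).sum(-2), "R[c]")
    Rc = np.stack([Rc0, Rc1], axis=1)

    x1g = xij[:, None, None, None]
    x2g = xji[:, None, None, None]
    W4 = W[..., None]
    if ms.node_effects:
        # a_i on its grid; all other continuous parameters at cavity means
        ua = g * (mb[:, 1, None, None] * mpi)[..., None]          # (D,q,q,B)
        Ra0 = (W4 * _lik4(x1g, x2g, ua, v0[..., None], mrho[..., None])).sum((1, 2))
        ub = (ma[:, 0, None, None] * mpi)[..., None] * g           # b_j grid
        Rb1 = (W4 * _lik4(x1g, x2g, ub, v0[..., None], mrho[..., None])).sum((1, 2))
        va = g * (mb[:, 0, None, None] * np.swapaxes(mpi, 1, 2))[..., None]  # a_j
        Ra1 = (W4 * _lik4(x1g, x2g, u0[..., None], va, mrho[..., None])).sum((1, 2))
        vb = (ma[:, 1, None, None] * np.swapaxes(mpi, 1, 2))[..., None] * g  # b_i
        Rb0 = (W4 * _lik4(x1g, x2g, u0[..., None], vb, mrho[..., None])).sum((1, 2))
        Ra = _normalize_last(np.stack([Ra0, Ra1], axis=1), "R[a]")
        Rb = _normalize_last(np.stack([Rb0, Rb1], axis=1), "R[b]")
    else:
        Ra, Rb = ms.r_msgs["a"], ms.r_msgs["b"]

    # π entries: substitute the target's grid wherever that entry enters
    D, B = u0.shape[0], len(g)
    coef_u = ma[:, 0] * mb[:, 1]                                   # (D,)
    coef_v = ma[:, 1] * mb[:, 0]
    base_u = np.broadcast_to(u0[..., None], (D, q, q, B))
    base_v = np.broadcast_to(v0[..., None], (D, q, q, B))
    Rp = np.empty_like(ms.r_msgs["pi"])
    for r, s in product(range(q), repeat=2):
        umat = base_u.copy()
        vmat = base_v.copy()
        umat[:, r, s, :] = coef_u[:, None] * g                     # (D, B)
        # v at class pair (r', s') uses π[s', r']; equals target when (s',r')=(r,s)
        vmat[:, s, r, :] = coef_v[:, None] * g
        L = _lik4(x1g, x2g, umat, vmat, mrho[..., None])
        Rp[:, r, s] = (W4 * L).sum((1, 2))
    Rp = _normalize_last(Rp, "R[pi]")

    # ρ unordered-pair entries
    Rr = np.empty_like(ms.r_msgs["rho"])
    for r in range(q):
        for s in range(r, q):
            rmat = np.broadcast_to(mrho[..., None], mrho.shape + (len(rg),)).copy()
            rmat[:, r, s, :] = rg
            rmat[:, s, r, :] = rg
            L = _lik4(x1g, x2g, base_u, base_v, rmat)
            msg = (W4 * L).sum((1, 2))
            Rr[:, r, s] = msg
            Rr[:, s, r] = msg
    Rr = _normalize_last(Rr, "R[rho]")

    for key, val in (("a", Ra), ("b", Rb), ("c", Rc), ("pi", Rp), ("rho", Rr)):
        if not ms.node_effects and key in ("a", "b"):
            continue
        damped = _damp(val, ms.r_msgs[key], lam)
        change = max(change, float(np.max(np.abs(damped - ms.r_msgs[key]))))
        new.r_msgs[key] = damped

    change = max(change, _unipartite_q_update(new, ms, priors, config, n))
    return new, change


# ---------------------------------------------------------------------------
# Bethe evidence (fixed-point selection)
# ---------------------------------------------------------------------------

def _logsumexp_last(logw: np.ndarray) -> np.ndarray:
    mx = np.max(logw, axis=-1, keepdims=True)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    out = np.squeeze(safe, -1) + np.log(np.exp(logw - safe).sum(-1))
    return np.where(np.isfinite(np.squeeze(mx, -1)), out, -np.inf)


def _edge_terms(qmsg: np.ndarray, rmsg: np.ndarray) -> float:
    """Σ over edges of log Σ_x q(x)·r(x)."""
    return float(np.log((qmsg * rmsg).sum(-1)).sum())


def bethe_evidence(ms: MessageSet, network, priors: Priors,
                   config: InferenceConfig) -> float:
    """Bethe approximation of the log-evidence at the current messages.

    ``log Z ≈ Σ_factors log Z_a + Σ_variables log Z_i − Σ_edges log
    Z_ia`` with ``Z_a`` the expected dyad likelihood under incoming
    Q-messages, ``Z_i`` the normaliser of the variable posterior and
    ``Z_ia`` the overlap of the message pair on each factor–variable
    edge.  Used to rank coexisting fixed points: a symmetry-broken
    solution is preferred only when the data actually support block
    structure.  Clamped node effects are constants, not variables, and
    are excluded.
    """
    g = ms.grid
    q, l = config.q, config.l
    lpa = _log(priors.activity_prior().weights)
    lpb = _log(priors.popularity_prior().weights)
    lpp = _log(priors.preference_prior().weights)

    if ms.variant == "bipartite":
        X = network.adjacency().astype(float)
        Qa, Qb = ms.q_msgs["a"], ms.q_msgs["b"]
        Qc, Qd, Qp = ms.q_msgs["c"], ms.q_msgs["d"], ms.q_msgs["pi"]
        ma, mb = Qa @ g, Qb @ g
        mpi = Qp @ g
        W = Qc[:, :, :, None] * Qd[:, :, None, :]
        F_rs = _bernoulli_factor(X[:, :, None, None],
                                 ma[:, :, None, None] * mb[:, :, None, None] * mpi)
        log_za = float(np.log((W * F_rs).sum((-2, -1))).sum())

        log_zi = 0.0
        log_zia = 0.0
        keys = [("c", np.full(q, -np.log(q)), (1,)), ("d", np.full(l, -np.log(l)), (0,)),
                ("pi", lpp, (0, 1))]
        if ms.node_effects:
            keys += [("a", lpa, (1,)), ("b", lpb, (0,))]
        for key, lprior, axes in keys:
            _, tot = _cavity_logs(_log(ms.r_msgs[key]), axes)
            log_zi += float(_logsumexp_last(tot + lprior).sum())
            log_zia += _edge_terms(ms.q_msgs[key], ms.r_msgs[key])
        return log_za + log_zi - log_zia

    I, J = ms.dyads
    n = network.n_nodes
    A = network.adjacency()
    Qc, Qp = ms.q_msgs["c"], ms.q_msgs["pi"]
    Qa = ms.q_msgs["a"]
    ma = Qa @ g
    mpi = Qp @ g
    W = Qc[:, 0, :, None] * Qc[:, 1, None, :]
    if ms.variant == "undirected":
        x = A[I, J].astype(float)
        F_rs = _bernoulli_factor(x[:, None, None],
                                 (ma[:, 0] * ma[:, 1])[:, None, None] * mpi)
    else:
        Qb, Qr = ms.q_msgs["b"], ms.q_msgs["rho"]
        mb = Qb @ g
        mrho = Qr @ ms.rho_grid
        u0 = ma[:, 0, None, None] * mb[:, 1, None, None] * mpi
        v0 = (ma[:, 1] * mb[:, 0])[:, None, None] * np.swapaxes(mpi, 1, 2)
        F_rs = _lik4(A[I, J].astype(int)[:, None, None],
                     A[J, I].astype(int)[:, None, None], u0, v0, mrho)
    log_za = float(np.log((W * F_rs).sum((-2, -1))).sum())

    log_zi = 0.0
    log_zia = 0.0

    def _node_total(key, lprior):
        logR = _log(ms.r_msgs[key])
        neg = np.isneginf(logR)
        fin = np.where(neg, 0.0, logR)
        K = logR.shape[-1]
        s = np.zeros((n, K))
        cnt = np.zeros((n, K), dtype=int)
        np.add.at(s, I, fin[:, 0])
        np.add.at(s, J, fin[:, 1])
        np.add.at(cnt, I, neg[:, 0])
        np.add.at(cnt, J, neg[:, 1])
        return np.where(cnt > 0, -np.inf, s) + lprior

    node_keys = [("c", np.full(q, -np.log(q)))]
    if ms.node_effects:
        node_keys.append(("a", lpa))
        if "b" in ms.q_msgs:
            node_keys.append(("b", lpb))
    for key, lprior in node_keys:
        log_zi += float(_logsumexp_last(_node_total(key, lprior)).sum())
        log_zia += _edge_terms(ms.q_msgs[key], ms.r_msgs[key])

    # π entries: q² variables for directed, unordered pairs for undirected
    _, tot_p = _cavity_logs(_log(ms.r_msgs["pi"]), (0,))
    zp = _logsumexp_last(tot_p + lpp)
    zia_p = np.log((ms.q_msgs["pi"] * ms.r_msgs["pi"]).sum(-1))
    if ms.variant == "undirected":
        sel = np.triu_indices(q)
        log_zi += float(zp[sel].sum())
        log_zia += float(zia_p[:, sel[0], sel[1]].sum())
    else:
        log_zi += float(zp.sum())
        log_zia += float(zia_p.sum())
        lpr = _log(priors.reciprocity_prior().weights)
        _, tot_r = _cavity_logs(_log(ms.r_msgs["rho"]), (0,))
        zr = _logsumexp_last(tot_r + lpr)
        zia_r = np.log((ms.q_msgs["rho"] * ms.r_msgs["rho"]).sum(-1))
        sel = np.triu_indices(q)
        log_zi += float(zr[sel].sum())
        log_zia += float(zia_r[:, sel[0], sel[1]].sum())
    return log_za + log_zi - log_zia


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_PATTERN_HI = 0.85
_PATTERN_LO = 0.10
_PATTERN_WIDTH = 0.15


def _block_patterns(q: int, l: int, count: int, rng) -> list:
    """High/low seed patterns for the preference messages.

    For square class counts the first two patterns are the assortative
    and disassortative orientations; the rest are random non-constant
    binary patterns.
    """
    pats = []
    if q == l:
        eye = np.eye(q)
        pats.append(np.where(eye > 0, _PATTERN_HI, _PATTERN_LO))
        pats.append(np.where(eye > 0, _PATTERN_LO, _PATTERN_HI))
    while len(pats) < count:
        p = rng.choice([_PATTERN_LO, _PATTERN_HI], size=(q, l))
        if np.all(p == p.ravel()[0]):
            continue
        pats.append(p)
    return pats[:count]


def _seed_pi_pattern(ms: MessageSet, centers: np.ndarray) -> np.ndarray:
    """Replace π Q-messages with peaked distributions at the centers."""
    g = ms.grid
    w = np.exp(-((g[None, None, :] - centers[:, :, None]) ** 2)
               / (2.0 * _PATTERN_WIDTH ** 2))
    w /= w.sum(-1, keepdims=True)
    if ms.variant == "bipartite":
        ms.q_msgs["pi"][:] = w[None, None]
    else:
        ms.q_msgs["pi"][:] = w[None]
    return ms.q_msgs["pi"].copy()


def _class_tilt(ms: MessageSet) -> float:
    """Mean excess of the largest class weight over uniform."""
    tilts = []
    for key in ("c", "d"):
        if key in ms.q_msgs:
            w = ms.q_msgs[key]
            tilts.append(float((w.max(-1) - 1.0 / w.shape[-1]).mean()))
    return max(tilts)


def _run_single(network, config: InferenceConfig, priors: Priors,
                pattern: Optional[np.ndarray], seed: int,
                allow_abandon: bool):
    """One restart: optional pattern burn-in, then free sweeps."""
    cfg = replace(config, seed=seed)
    ms = init_messages(network, cfg, priors)
    if pattern is not None and config.burn_in > 0:
        held = _seed_pi_pattern(ms, pattern)
        for _ in range(config.burn_in):
            ms, _ = update_sweep(ms, network, priors, config)
            ms.q_msgs["pi"][:] = held
    change = np.inf
    converged = False
    abandoned = False
    sweeps = 0
    for sweeps in range(1, config.max_sweeps + 1):
        ms, change = update_sweep(ms, network, priors, config)
        logger.debug("sweep %d: max message change %.3e", sweeps, change)
        if change < config.tolerance:
            converged = True
            break
        # a pattern restart that has fallen back to the symmetric point
        # duplicates the plain restart; stop wasting sweeps on it
        if allow_abandon and sweeps % 25 == 0 and _class_tilt(ms) < 0.02:
            abandoned = True
            break
    return ms, converged, sweeps, change, abandoned


def run_inference(network, config: InferenceConfig,
                  priors: Optional[Priors] = None) -> PosteriorSummary:
    """Infer all marginal posteriors by damped message passing.

    Runs ``config.n_restarts`` restarts (a plain perturbed-prior start
    plus block-pattern burn-in starts, see :class:`InferenceConfig`),
    each swept until the largest message change falls below
    ``config.tolerance`` or ``config.max_sweeps`` is reached, and
    returns the fixed point with the highest Bethe evidence.
    Non-convergence sets ``converged=False`` on the summary rather
    than raising.  Marginal posteriors are assembled as
    ``prior × Π (all incoming R-messages)``, normalised.  Per-sweep
    cost is proportional to (number of dyads) · q · l · B.
    """
    variant, config, priors = _resolve(network, config, priors)
    n_classes = max(config.q, config.l if variant == "bipartite" else config.q)
    use_restarts = config.n_restarts > 1 and n_classes > 1
    pattern_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E37]))
    ql = config.l if variant == "bipartite" else config.q
    patterns = [None]
    if use_restarts:
        patterns += _block_patterns(config.q, ql, config.n_restarts - 1, pattern_rng)

    best = None
    for k, pattern in enumerate(patterns):
        seed = int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0]
                   % (2**31))
        ms, converged, sweeps, change, abandoned = _run_single(
            network, config, priors, pattern, seed, allow_abandon=pattern is not None)
        if abandoned:
            # fell back to the symmetric point: already covered by restart 0
            logger.debug("restart %d abandoned after %d sweeps", k, sweeps)
            continue
        ev = bethe_evidence(ms, network, priors, config)
        logger.debug("restart %d: evidence %.4f (converged=%s, %d sweeps)",
                     k, ev, converged, sweeps)
        if best is None or ev > best[0]:
            best = (ev, k, ms, converged, sweeps, change)

    ev, k, ms, converged, sweeps, change = best
    summary = _assemble_posterior(ms, network, priors, config)
    summary.converged = converged
    summary.sweeps = sweeps
    summary.final_change = float(change)
    summary.bethe_evidence = float(ev)
    summary.restart = k
    try:
        summary.log_likelihood = network_log_likelihood(network, summary.to_parameters())
    except ValueError:
        summary.log_likelihood = np.nan
    return summary


def _assemble_posterior(ms: MessageSet, network, priors: Priors,
                        config: InferenceConfig) -> PosteriorSummary:
    g = ms.grid
    q, l = config.q, config.l
    lpa = _log(priors.activity_prior().weights)
    lpb = _log(priors.popularity_prior().weights)
    lpp = _log(priors.preference_prior().weights)

    if ms.variant == "bipartite":
        N, M = network.shape
        if ms.node_effects:
            _, tot_a = _cavity_logs(_log(ms.r_msgs["a"]), (1,))
            act = _softmax_last(tot_a + lpa, "posterior[a]")
            _, tot_b = _cavity_logs(_log(ms.r_msgs["b"]), (0,))
            pop = _softmax_last(tot_b + lpb, "posterior[b]")
        else:
            act = ms.q_msgs["a"][:, 0, :].copy()
            pop = ms.q_msgs["b"][0, :, :].copy()
        _, tot_c = _cavity_logs(_log(ms.r_msgs["c"]), (1,))
        cpost = _softmax_last(tot_c - np.log(q), "posterior[c]")
        _, tot_d = _cavity_logs(_log(ms.r_msgs["d"]), (0,))
        dpost = _softmax_last(tot_d - np.log(l), "posterior[d]")
        _, tot_p = _cavity_logs(_log(ms.r_msgs["pi"]), (0, 1))
        ppost = _softmax_last(tot_p + lpp, "posterior[pi]")
        return PosteriorSummary("bipartite", config, g, act, pop, cpost, dpost, ppost)

    I, J = ms.dyads
    n = network.n_nodes
    if ms.node_effects:
        act = _node_posterior(_log(ms.r_msgs["a"]), I, J, n, lpa, "posterior[a]")
    else:
        act = ms.q_msgs["a"][:1, 0, :].repeat(n, axis=0)
    cpost = _node_posterior(_log(ms.r_msgs["c"]), I, J, n,
                            np.full(q, -np.log(q)), "posterior[c]")
    _, tot_p = _cavity_logs(_log(ms.r_msgs["pi"]), (0,))
    ppost = _softmax_last(tot_p + lpp, "posterior[pi]")

    if ms.variant == "undirected":
        return PosteriorSummary("undirected", config, g, act, None, cpost, None, ppost)

    if ms.node_effects:
        pop = _node_posterior(_log(ms.r_msgs["b"]), I, J, n, lpb, "posterior[b]")
    else:
        pop = ms.q_msgs["b"][:1, 0, :].repeat(n, axis=0)
    lpr = _log(priors.reciprocity_prior().weights)
    _, tot_r = _cavity_logs(_log(ms.r_msgs["rho"]), (0,))
    rpost = _softmax_last(tot_r + lpr, "posterior[rho]")
    return PosteriorSummary("directed", config, g, act, pop, cpost, None, ppost,
                            rho_grid=ms.rho_grid, reciprocity=rpost)


# ---------------------------------------------------------------------------
# single-message operations (reference path; used for small-scale checks)
# ---------------------------------------------------------------------------

Distribution = Union[GridDistribution, CategoricalDistribution]


def compute_r_message(dyad_observation: int, incoming: Dict[str, object],
                      target: object, support: Optional[np.ndarray] = None) -> Distribution:
    """R-message of one bipartite dyad factor to one adjacent variable.

    Parameters
    ----------
    dyad_observation
        The observed entry ``x_ij`` ∈ {0, 1}.
    incoming
        Q-messages of the *other* adjacent variables, keyed by
        ``"activity"``, ``"popularity"``, ``"actor_class"``,
        ``"event_class"`` and ``"preference"`` (the latter a ``q × l``
        object array / nested sequence of :class:`GridDistribution`).
        The target's own message must be absent.
    target
        ``"activity"``, ``"popularity"``, ``"actor_class"``,
        ``"event_class"`` or ``("preference", r, s)``.
    support
        Grid for continuous targets (defaults to the preference
        messages' support).

    Returns the expected dyad likelihood as a function of the target,
    renormalised.  Expectations are exact: the Bernoulli likelihood is
    linear in each continuous parameter, so only incoming means enter.
    """
    x = int(dyad_observation)
    if x not in (0, 1):
        raise ValueError("dyad observation must be 0 or 1")

    def _mean(key):
        return incoming[key].mean() if key in incoming else 1.0

    pi_msgs = incoming.get("preference")
    if pi_msgs is not None:
        pi_means = np.array([[d.mean() for d in row] for row in np.atleast_2d(pi_msgs)])
    else:
        pi_means = np.array([[1.0]])
    qn, ln = pi_means.shape
    wc = incoming["actor_class"].weights if "actor_class" in incoming \
        else np.full(qn, 1.0 / qn)
    wd = incoming["event_class"].weights if "event_class" in incoming \
        else np.full(ln, 1.0 / ln)

    if isinstance(target, tuple) and target[0] == "preference":
        _, r, s = target
        if support is None:
            support = np.atleast_2d(pi_msgs)[r][s].support
        ma, mb = _mean("activity"), _mean("popularity")
        f_rs = _bernoulli_factor(float(x), ma * mb * pi_means)
        wmat = np.outer(wc, wd)
        other = float((wmat * f_rs).sum() - wmat[r, s] * f_rs[r, s])
        w = other + wmat[r, s] * _bernoulli_factor(float(x), ma * mb * support)
        return GridDistribution.from_unnormalized(support, w)

    if target in ("activity", "popularity"):
        if support is None:
            support = np.atleast_2d(pi_msgs)[0][0].support
        pibar = float(np.outer(wc, wd).ravel() @ pi_means.ravel())
        k = (_mean("popularity") if target == "activity" else _mean("activity")) * pibar
        w = _bernoulli_factor(float(x), support * k)
        return GridDistribution.from_unnormalized(support, w)

    if target in ("actor_class", "event_class"):
        ma, mb = _mean("activity"), _mean("popularity")
        f_rs = _bernoulli_factor(float(x), ma * mb * pi_means)
        if target == "actor_class":
            w = f_rs @ wd
        else:
            w = wc @ f_rs
        return CategoricalDistribution.from_unnormalized(w)

    raise ValueError(f"unknown target {target!r}")


def compute_q_message(prior: Distribution, incoming_r) -> Distribution:
    """Normalised product of a prior and incoming R-messages (log space).

    ``incoming_r`` must exclude the R-message of the destination
    factor.  With no incoming messages the Q-message equals the prior.
    """
    logw = _log(np.asarray(prior.weights, dtype=float))
    for r in incoming_r:
        w = np.asarray(r.weights, dtype=float)
        if w.shape != logw.shape:
            raise ValueError("incoming R-message on a different support")
        logw = logw + _log(w)
    mx = logw.max()
    if not np.isfinite(mx):
        raise MessageNormalizationError("Q-message is zero everywhere")
    w = np.exp(logw - mx)
    if isinstance(prior, GridDistribution):
        return GridDistribution.from_unnormalized(prior.support, w)
    return CategoricalDistribution.from_unnormalized(w)


def class_map_assignment(class_posteriors: np.ndarray) -> np.ndarray:
    """Per-node MAP class; ties broken toward the lowest class index."""
    probs = np.atleast_2d(np.asarray(class_posteriors, dtype=float))
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("class posterior rows must sum to 1")
    return np.argmax(probs, axis=1)
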