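"""Mk models of discrete character evolution and stochastic character mapping.

Implements the standard machinery behind ancestral-state reconstruction of
host-use characters on a dated butterfly phylogeny: Felsenstein-pruning
likelihoods under the Mk model (ER: one symmetric rate; ARD: all rates
different), maximum-likelihood rate estimation, exact marginal ancestral
states, and SIMMAP-style stochastic character maps — full state histories
painted on every branch, sampled conditional on the tip data.

Tips without character data (species lacking host records) are treated as
missing: their partial likelihood is all-ones, so they contribute tree shape
but no state information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .ctmc import CTMCPropagator, stationary_distribution
from .trees import DatedTree

__all__ = [
    "MkModel",
    "StochasticMap",
    "er_rate_matrix",
    "mk_loglik",
    "fit_mk",
    "sample_maps",
    "summarize_root",
    "ancestral_marginals",
]

MISSING = {None, "?", "-", ""}

_RATE_BOUNDS = (1e-9, 1e3)  # events/Ma


def er_rate_matrix(k: int, rate: float) -> np.ndarray:
    """Equal-rates (ER) generator: every off-diagonal transition at ``rate``."""
    Q = np.full((k, k), float(rate))
    np.fill_diagonal(Q, -(k - 1) * float(rate))
    return Q


@dataclass
class MkModel:
    """A k-state Mk model: state labels, generator Q (1/Ma) and root prior.

    ``root_prior`` is ``"stationary"`` (default; the stationary distribution
    of Q, which is flat for ER), ``"flat"``, or an explicit probability
    vector over states.
    """

    states: tuple
    Q: np.ndarray
    model_class: str = "custom"
    root_prior: object = "stationary"

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match state count")
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < -1e-12):
            raise ValueError("negative off-diagonal rate")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-8 * max(1.0, np.abs(self.Q).max()):
            raise ValueError("rows of Q must sum to zero")
        self._index = {s: i for i, s in enumerate(self.states)}

    @property
    def k(self) -> int:
        return len(self.states)

    def state_index(self, state) -> int:
        if state not in self._index:
            raise KeyError(f"state {state!r} not in model states {self.states}")
        return self._index[state]

    def root_pi(self) -> np.ndarray:
        if isinstance(self.root_prior, str):
            if self.root_prior == "flat":
                return np.full(self.k, 1.0 / self.k)
            if self.root_prior == "stationary":
                return stationary_distribution(self.Q)
            raise ValueError(f"unknown root prior {self.root_prior!r}")
        pi = np.asarray(self.root_prior, dtype=float)
        if pi.shape != (self.k,) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("root prior must be a probability vector over states")
        return pi


# --------------------------------------------------------------------- core
def _tip_partials(tree: DatedTree, tips: Mapping, model: MkModel) -> np.ndarray:
    L = np.zeros((tree.n_nodes, model.k))
    for v in tree.tip_indices:
        lab = tree.labels[v]
        state = tips.get(lab, None)
        if state in MISSING or (isinstance(state, float) and np.isnan(state)):
            L[v, :] = 1.0
        else:
            L[v, model.state_index(state)] = 1.0
    return L


def _prune(tree: DatedTree, tips: Mapping, model: MkModel, prop: CTMCPropagator):
    """Scaled conditional likelihoods per node plus branch-top vectors.

    Returns ``(L, D, log_scale)`` where ``L[v]`` is the (rescaled) likelihood
    of data below node v given the state at v, ``D[v] = P(t_v) @ L[v]`` is
    that likelihood propagated to the top of v's branch, and ``log_scale`` is
    the accumulated log of the rescaling constants.
    """
    L = _tip_partials(tree, tips, model)
    D = np.zeros_like(L)
    P_all = prop.P_batch(tree.blen)
    log_scale = 0.0
    for v in tree.postorder:
        if tree.children[v]:
            prod = np.ones(model.k)
            for c in tree.children[v]:
                prod = prod * D[c]
            m = prod.max()
            if m <= 0:
                raise ValueError("data have zero likelihood under the model")
            log_scale += np.log(m)
            L[v] = prod / m
        if v != 0:
            D[v] = P_all[v] @ L[v]
    return L, D, log_scale


def mk_loglik(tree: DatedTree, tips: Mapping, model: MkModel) -> float:
    """Felsenstein-pruning log-likelihood of tip states under ``model``."""
    prop = CTMCPropagator(model.Q)
    L, _, log_scale = _prune(tree, tips, model, prop)
    lik = float(model.root_pi() @ L[0])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def _observed_states(tips: Mapping) -> list:
    out = []
    for s in tips.values():
        if s in MISSING or (isinstance(s, float) and np.isnan(s)):
            continue
        if s not in out:
            out.append(s)
    return sorted(out, key=str)


def fit_mk(
    tree: DatedTree,
    tips: Mapping,
    model_class: str = "ER",
    root_prior: object = "stationary",
    states: Sequence | None = None,
    n_starts: int = 3,
):
    """Maximum-likelihood Mk fit (rates on a log scale, bounded, multistart).

    Returns ``(model, loglik, info)``.  With fewer than two observed states
    the rate is unidentifiable and a boundary fit at the minimum rate is
    returned with a warning.
    """
    if states is None:
        states = _observed_states(tips)
    states = tuple(states)
    k = len(states)
    if k < 2:
        raise ValueError("need at least 2 model states")
    observed = _observed_states(tips)
    lo, hi = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])
    depth = max(tree.root_age, 1e-12)

    if len(observed) < 2:
        warnings.warn("fewer than 2 observed states; rate fixed at lower bound")
        model = MkModel(states, er_rate_matrix(k, _RATE_BOUNDS[0]), "ER", root_prior)
        return model, mk_loglik(tree, tips, model), {"converged": False, "boundary": True}

    if model_class == "ER":
        def neg(lnr: float) -> float:
            model = MkModel(states, er_rate_matrix(k, np.exp(lnr)), "ER", root_prior)
            val = mk_loglik(tree, tips, model)
            return 1e12 if not np.isfinite(val) else -val

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        rate = float(np.exp(res.x))
        model = MkModel(states, er_rate_matrix(k, rate), "ER", root_prior)
        return model, -float(res.fun), {"converged": bool(res.success), "rate": rate}

    if model_class == "ARD":
        n_par = k * (k - 1)
        off = ~np.eye(k, dtype=bool)

        def build(lnx: np.ndarray) -> MkModel:
            Q = np.zeros((k, k))
            Q[off] = np.exp(lnx)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            return MkModel(states, Q, "ARD", root_prior)

        def neg(lnx: np.ndarray) -> float:
            val = mk_loglik(tree, tips, build(lnx))
            return 1e12 if not np.isfinite(val) else -val

        best = None
        for start_rate in np.geomspace(0.1 / depth, 10.0 / depth, n_starts):
            x0 = np.full(n_par, np.log(start_rate))
            res = minimize(neg, x0, method="L-BFGS-B",
                           bounds=[(lo, hi)] * n_par)
            if best is None or res.fun < best.fun:
                best = res
        model = build(best.x)
        return model, -float(best.fun), {"converged": bool(best.success)}

    raise ValueError(f"unknown model class {model_class!r} (use 'ER' or 'ARD')")


# ------------------------------------------------------------ marginal ASR
def ancestral_marginals(tree: DatedTree, tips: Mapping, model: MkModel) -> np.ndarray:
    """Exact marginal posterior state probabilities at every node, shape (N, k).

    Computed with a down pass (pruning) and an up pass that propagates the
    likelihood of everything outside each subtree; rows sum to one.
    """
    prop = CTMCPropagator(model.Q)
    L, D, _ = _prune(tree, tips, model, prop)
    P_all = prop.P_batch(tree.blen)
    out = np.zeros_like(L)
    out[0] = model.root_pi()
    marg = np.zeros_like(L)
    for v in tree.preorder:
        post = out[v] * L[v]
        marg[v] = post / post.sum()
        for c in tree.children[v]:
            sib = out[v].copy()
            for d in tree.children[v]:
                if d != c:
                    sib = sib * D[d]
            top = sib / max(sib.max(), 1e-300)
            out[c] = top @ P_all[c]
    return marg


# ------------------------------------------------------------------ SIMMAP
@dataclass
class StochasticMap:
    """One sampled character history on the whole tree.

    ``node_states[v]`` is the sampled state index at node v; ``segments[v]``
    lists ``(state_index, duration)`` pairs along the branch above v, ordered
    from the parent toward v; the first segment's state equals the parent's
    node state and durations sum to the branch length.  ``transitions`` counts
    i→j state changes over all branches.
    """

    node_states: np.ndarray
    segments: dict
    transitions: np.ndarray
    states: tuple = ()

    def root_state(self) -> int:
        return int(self.node_states[0])

    def n_changes(self) -> int:
        return int(self.transitions.sum())


def sample_maps(
    tree: DatedTree,
    tips: Mapping,
    model: MkModel,
    n_maps: int,
    rng: np.random.Generator,
):
    """Draw SIMMAP stochastic character maps conditional on the tip data.

    Conditional likelihoods are computed once; each map samples the root
    state from its posterior, then each node state conditional on its parent,
    then an endpoint-conditioned path along every branch by uniformization.
    Returns ``(maps, node_freq)`` where ``node_freq[v, s]`` is the fraction of
    maps assigning state s to node v — the ancestral-state summary.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    prop = CTMCPropagator(model.Q)
    L, D, _ = _prune(tree, tips, model, prop)
    P_all = prop.P_batch(tree.blen)
    pi = model.root_pi()
    k = model.k
    root_post = pi * L[0]
    root_post = root_post / root_post.sum()
    maps: list[StochasticMap] = []
    freq = np.zeros((tree.n_nodes, k))
    for _ in range(n_maps):
        node_states = np.zeros(tree.n_nodes, dtype=int)
        node_states[0] = rng.choice(k, p=root_post)
        segments: dict[int, list] = {}
        trans = np.zeros((k, k), dtype=int)
        for v in tree.preorder:
            if v == 0:
                continue
            ps = node_states[tree.parent[v]]
            w = P_all[v][ps, :] * L[v]
            s = w.sum()
            if s <= 0:
                raise ValueError(f"zero-probability endpoint at node {v}")
            sv = int(rng.choice(k, p=w / s))
            node_states[v] = sv
            segs = prop.sample_path(int(ps), sv, float(tree.blen[v]), rng)
            segments[v] = segs
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                trans[s1, s2] += 1
        maps.append(StochasticMap(node_states, segments, trans, model.states))
        freq[np.arange(tree.n_nodes), node_states] += 1.0
    return maps, freq / n_maps


def summarize_root(maps: Sequence[StochasticMap]) -> dict:
    """Root-state frequency table across maps, with the modal state flagged."""
    if not maps:
        raise ValueError("need at least one map")
    states = maps[0].states
    counts = np.zeros(len(states))
    for m in maps:
        counts[m.root_state()] += 1
    freq = counts / counts.sum()
    table = {states[i]: float(freq[i]) for i in range(len(states))}
    modal = states[int(np.argmax(counts))]
    return {"frequencies": table, "modal_state": modal}
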