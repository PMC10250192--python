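"""Synthetic data with known ground truth for every pipeline stage.

Generates dated birth-death trees, discrete traits evolved forward under an
Mk model, butterfly-by-host matrices with planted module structure and a
specialist/generalist mixture, hierarchical plant-family trees whose clades
mirror the planted modules, and geographic ranges evolved forward under DEC
dynamics.  Defaults emulate the study conditions the pipeline targets: a
~100-Ma butterfly radiation, 13 host modules, roughly two-thirds specialist
species, and dispersal much faster than range loss.

Every generator takes an explicit seeded random stream; identical seed and
configuration give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ctmc import stationary_distribution
from .dec import DECModel, cladogenesis_events, dec_rate_matrix
from .network import HostMatrix
from .trees import DatedTree, _from_lists

__all__ = [
    "SimulationConfig",
    "simulate_bd_tree",
    "simulate_mk_traits",
    "simulate_host_matrix",
    "simulate_plant_tree",
    "simulate_dec_history",
]

_MAX_BD_ATTEMPTS = 10_000


@dataclass
class SimulationConfig:
    """Ground-truth parameters for all synthetic inputs.

    Tree: ``n_tips`` extant species from a birth-death process with speciation
    ``birth_rate`` and extinction ``death_rate`` (events/Ma; defaults give a
    crown age near 100 Ma at 200 tips).  Host network: ``n_modules`` planted
    modules of ``n_hosts_per_module`` host families; a species is a generalist
    with probability ``p_generalist``; generalists' extra host families are
    drawn from the species' home module with probability
    ``within_module_edge_prob`` (default ``1 - noise_edge_prob``) and
    uniformly from all families otherwise.  Traits: ``mk_states`` equal-rates states at
    ``mk_rate`` /Ma (low saturation over a ~100-Ma tree).  Ranges: areas with
    ``true_d``/``true_e`` DEC rates and an adjacency matrix (default: all
    areas adjacent).
    """

    seed: int = 0
    n_tips: int = 200
    birth_rate: float = 0.06
    death_rate: float = 0.01
    n_modules: int = 13
    n_hosts_per_module: int = 3
    p_generalist: float = 0.323
    within_module_edge_prob: float | None = None  # default 1 - noise_edge_prob
    noise_edge_prob: float = 0.05
    generalist_k: int | None = None
    generalist_extra_mean: float = 1.2
    record_count_mean: float = 3.0
    areas: tuple = ("NEA", "NEO", "PAL", "AFR", "ORI", "AUS", "OCE")
    true_d: float = 0.05
    true_e: float = 0.01
    adjacency: np.ndarray | None = None
    mk_states: int = 2
    mk_rate: float = 0.005

    def __post_init__(self):
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.within_module_edge_prob is None:
            self.within_module_edge_prob = 1.0 - self.noise_edge_prob
        for p in (self.p_generalist, self.within_module_edge_prob, self.noise_edge_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_modules < 1 or self.n_modules * self.n_hosts_per_module < 2:
            raise ValueError("need at least 2 host families in total")
        if self.true_d < 0 or self.true_e < 0:
            raise ValueError("DEC rates must be non-negative")


# ------------------------------------------------------------------- trees
def simulate_bd_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    cfg: SimulationConfig | None = None,
) -> DatedTree:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant species.

    Forward (Gillespie) simulation from two crown lineages; the clock stops
    at the moment the event after reaching ``n_tips`` extant lineages would
    occur, so under pure birth the expected crown age is the Yule sum
    ``sum_{k=2..n} 1/(lambda k)``.  Replicates where the clade dies are
    rejected and re-simulated (bounded attempts).
    """
    if cfg is not None:
        n_tips, birth_rate, death_rate = cfg.n_tips, cfg.birth_rate, cfg.death_rate
    if rng is None:
        raise ValueError("an explicit rng is required")
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if death_rate >= birth_rate:
        raise ValueError("survival conditioning requires birth_rate > death_rate")
    lam, mu = float(birth_rate), float(death_rate)
    for _ in range(_MAX_BD_ATTEMPTS):
        result = _bd_attempt(n_tips, lam, mu, rng)
        if result is not None:
            return result
    raise RuntimeError("birth-death simulation failed to survive after bounded retries")


def _bd_attempt(n_tips, lam, mu, rng):
    parent = [-1, 0, 0]
    birth_time = [0.0, 0.0, 0.0]
    death_time: list = [None, None, None]
    children = [[1, 2], [], []]
    extant = [1, 2]
    t = 0.0
    while True:
        k = len(extant)
        if k == 0:
            return None
        dt = rng.exponential(1.0 / (k * (lam + mu)))
        t += dt
        if k == n_tips:
            break  # stop just before the next event; extant tips reach age 0
        v = extant[rng.integers(k)]
        if rng.random() < lam / (lam + mu):
            for _ in range(2):
                parent.append(v)
                birth_time.append(t)
                death_time.append(None)
                children.append([])
                children[v].append(len(parent) - 1)
            extant.remove(v)
            extant.extend(children[v])
            death_time[v] = t
        else:
            extant.remove(v)
            death_time[v] = t
    # assemble: survivors extend to the stop time t
    keep = set(extant)
    labels = {v: f"t{i + 1}" for i, v in enumerate(sorted(extant))}

    def build(v):
        end = death_time[v] if death_time[v] is not None else t
        if not children[v]:
            if v not in keep:
                return None
            return (labels[v], end - birth_time[v], [])
        kids = [build(c) for c in children[v]]
        kids = [kk for kk in kids if kk is not None]
        if not kids:
            return None
        if len(kids) == 1:
            lab, bl, gk = kids[0]
            return (lab, bl + end - birth_time[v], gk)
        return (None, end - birth_time[v], kids)

    top = build(0)
    if top is None or not top[2]:
        return None
    parent_l: list[int] = []
    blen_l: list[float] = []
    labels_l: list = []
    children_l: list = []

    def emit(node, par):
        lab, bl, kids = node
        i = len(parent_l)
        parent_l.append(par)
        blen_l.append(bl if par >= 0 else 0.0)
        labels_l.append(lab)
        children_l.append([])
        if par >= 0:
            children_l[par].append(i)
        for kk in kids:
            emit(kk, i)

    emit(top, -1)
    tree = _from_lists(parent_l, blen_l, labels_l, children_l)
    if tree.n_tips != n_tips:
        return None
    return tree


# ------------------------------------------------------------------- traits
def simulate_mk_traits(
    tree: DatedTree,
    q: np.ndarray,
    root_state=None,
    rng: np.random.Generator = None,
    states: Sequence | None = None,
):
    """Evolve a discrete trait forward along the tree under generator ``q``.

    ``root_state`` is a state label/index or None (draw from the stationary
    distribution).  Returns ``(tip_states, node_states)`` where node_states
    retains the true internal states for recovery tests.
    """
    q = np.asarray(q, dtype=float)
    k = q.shape[0]
    if q.shape != (k, k) or np.any(q - np.diag(np.diag(q)) < -1e-12) or (
        np.max(np.abs(q.sum(axis=1))) > 1e-8 * max(1.0, np.abs(q).max())
    ):
        raise ValueError("invalid rate matrix")
    if states is None:
        states = [f"s{i}" for i in range(k)]
    states = list(states)
    if root_state is None:
        root = int(rng.choice(k, p=stationary_distribution(q)))
    elif root_state in states:
        root = states.index(root_state)
    else:
        root = int(root_state)
    node_states = np.zeros(tree.n_nodes, dtype=int)
    node_states[0] = root
    for v in tree.preorder:
        if v == 0:
            continue
        s = int(node_states[tree.parent[v]])
        t_left = float(tree.blen[v])
        while True:
            rate = -q[s, s]
            if rate <= 0:
                break
            dt = rng.exponential(1.0 / rate)
            if dt >= t_left:
                break
            t_left -= dt
            probs = np.clip(q[s], 0, None)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
        node_states[v] = s
    tips = {tree.labels[v]: states[node_states[v]] for v in tree.tip_indices}
    return tips, node_states


# -------------------------------------------------------------- host matrix
def _zero_truncated_poisson(mean: float, rng: np.random.Generator) -> int:
    while True:
        x = rng.poisson(mean)
        if x > 0:
            return int(x)


def simulate_host_matrix(tree: DatedTree, cfg: SimulationConfig, rng: np.random.Generator):
    """Butterfly-by-host-family matrix with planted modules and known truth.

    Every species gets a home module; specialists use one family from it;
    generalists add extra families drawn from the home module with
    probability ``within_module_edge_prob`` and uniformly otherwise.  Weights
    are Poisson(record_count_mean)+1 record counts.  Returns
    ``(matrix, true_modules, true_class)`` keyed by species label.
    """
    hosts = [
        f"H{m + 1}_{h + 1}"
        for m in range(cfg.n_modules)
        for h in range(cfg.n_hosts_per_module)
    ]
    host_module = np.repeat(np.arange(cfg.n_modules), cfg.n_hosts_per_module)
    species = tree.tip_labels
    n_sp, n_h = len(species), len(hosts)
    W = np.zeros((n_sp, n_h))
    true_modules: dict = {}
    true_class: dict = {}
    # balanced planted blocks (sizes differ by at most one, seeded order), the
    # standard design for planted-partition recovery benchmarks: every module
    # carries enough weight that the planted structure is identifiable
    home_assign = rng.permutation(np.arange(n_sp) % cfg.n_modules)
    for i, sp in enumerate(species):
        home = int(home_assign[i])
        true_modules[sp] = home
        home_cols = np.flatnonzero(host_module == home)
        fams = {int(rng.choice(home_cols))}
        generalist = rng.random() < cfg.p_generalist
        if generalist:
            if cfg.generalist_k is not None:
                k = cfg.generalist_k
            else:
                # 1 + zero-truncated Poisson repertoire, capped at module size
                k = 1 + _zero_truncated_poisson(cfg.generalist_extra_mean, rng)
                k = min(k, max(cfg.n_hosts_per_module, 2))
            k = max(2, min(k, n_h))
            # one within/noise decision per repertoire slot, drawn without
            # replacement so the realized noise rate matches noise_edge_prob
            while len(fams) < k:
                if rng.random() < cfg.within_module_edge_prob:
                    cand = [j for j in home_cols if j not in fams]
                    if not cand:
                        cand = [j for j in range(n_h) if j not in fams]
                else:
                    cand = [j for j in range(n_h) if j not in fams]
                fams.add(int(rng.choice(cand)))
        true_class[sp] = "generalist" if len(fams) >= 2 else "specialist"
        for j in fams:
            W[i, j] = rng.poisson(cfg.record_count_mean) + 1
    used = np.flatnonzero(W.sum(axis=0) > 0)
    matrix = HostMatrix(species, [hosts[j] for j in used], W[:, used])
    return matrix, true_modules, true_class


# -------------------------------------------------------------- plant tree
def simulate_plant_tree(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    crown_age: float = 120.0,
    module_crown_age: float = 15.0,
) -> DatedTree:
    """Dated plant-family tree whose clades mirror the planted host modules.

    A backbone tree over modules (crown age ``crown_age`` Ma) carries one
    subtree per module (crown age ``module_crown_age`` Ma) holding that
    module's host families, so within-module hosts are mutually closely
    related — the property the relatedness null test has power against.
    """
    if not 0 < module_crown_age < crown_age:
        raise ValueError("need 0 < module_crown_age < crown_age")
    if cfg.n_modules == 1:
        sub = simulate_bd_tree(cfg.n_hosts_per_module, 1.0, 0.0, rng) \
            if cfg.n_hosts_per_module >= 2 else None
        if sub is None:
            raise ValueError("single module needs >= 2 host families")
        _scale_to_depth(sub, crown_age)
        sub.labels = [
            f"H1_{sub.labels[v][1:]}" if sub.is_tip[v] else sub.labels[v]
            for v in range(sub.n_nodes)
        ]
        sub._refresh()
        return sub
    backbone = simulate_bd_tree(cfg.n_modules, 1.0, 0.0, rng)
    _scale_to_depth(backbone, crown_age)
    # compress backbone node ages into [module_crown_age, crown_age] so every
    # pendant branch has room for a module subtree of the requested age
    lo = module_crown_age * 1.2
    for v in range(backbone.n_nodes):
        if not backbone.is_tip[v]:
            backbone.ages[v] = lo + backbone.ages[v] * (crown_age - lo) / crown_age

    def subtree_newick(mod_idx: int) -> str:
        n_h = cfg.n_hosts_per_module
        if n_h == 1:
            return f"H{mod_idx}_1"
        sub = simulate_bd_tree(n_h, 1.0, 0.0, rng)
        _scale_to_depth(sub, module_crown_age)
        s = sub.to_newick()[:-1]  # strip ';'
        for h in range(n_h, 0, -1):
            s = s.replace(f"t{h}:", f"H{mod_idx}_{h}:")
        return s

    tips = backbone.tip_labels

    def rec(v: int) -> str:
        if backbone.is_tip[v]:
            mod = tips.index(backbone.labels[v]) + 1
            pend = backbone.ages[backbone.parent[v]] - (
                module_crown_age if cfg.n_hosts_per_module > 1 else 0.0
            )
            return f"{subtree_newick(mod)}:{pend:.10f}"
        inner = ",".join(rec(c) for c in backbone.children[v])
        if v == 0:
            return f"({inner});"
        bl = backbone.ages[backbone.parent[v]] - backbone.ages[v]
        return f"({inner}):{bl:.10f}"

    from .trees import read_newick

    return read_newick(rec(0), strict_ultrametric=True)


def _scale_to_depth(tree: DatedTree, depth: float) -> None:
    f = depth / tree.root_age
    tree.blen = tree.blen * f
    tree._refresh()


# ------------------------------------------------------------- DEC ranges
def simulate_dec_history(
    tree: DatedTree,
    model: DECModel,
    rng: np.random.Generator,
    root_range=None,
):
    """Evolve geographic ranges forward under DEC dynamics with full truth.

    Anagenetic events run by Gillespie simulation along every branch
    (expansion at rate d into adjacent unoccupied areas, loss of each
    occupied area at rate e); at every node a cladogenetic event is drawn
    uniformly from the model's event set for the parent range.  A lineage
    hitting the null range is globally extinct in place: the null range is
    absorbing and its descendants (including tips) carry ``None``.

    Returns ``(tip_ranges, truth)`` where truth holds per-node range indices
    (-1 for null) and the per-branch event list ``(node, age, kind, area)``.
    """
    space = model.space
    n = space.n_states
    Q = dec_rate_matrix(space, model.d, model.e)
    if root_range is None:
        root = int(rng.integers(n))
    else:
        root = space.encode(root_range) if not isinstance(root_range, (int, np.integer)) else int(root_range)
    node_state = np.full(tree.n_nodes, -1, dtype=int)
    node_state[0] = root
    branch_top = np.full(tree.n_nodes, -1, dtype=int)
    events: list = []
    for v in tree.preorder:
        if v != 0:
            # evolve along the branch above v; parent already processed
            s = int(branch_top[v])
            if s < 0:  # extinct ancestry
                node_state[v] = -1
                continue
            age = tree.ages[tree.parent[v]]
            t_left = float(tree.blen[v])
            while True:
                rate = -Q[s, s]
                if rate <= 0:
                    break
                dt = rng.exponential(1.0 / rate)
                if dt >= t_left:
                    break
                t_left -= dt
                age -= dt
                probs = np.clip(Q[s], 0, None)
                probs[s] = 0.0
                new = int(rng.choice(n + 1, p=probs / probs.sum()))
                old_set = space.ranges[s]
                new_set = space.ranges[new] if new < n else frozenset()
                if len(new_set) > len(old_set):
                    (j,) = tuple(new_set - old_set)
                    events.append((v, age, "expansion", space.areas[j]))
                else:
                    lost = tuple(old_set - new_set)
                    events.append((v, age, "contraction", space.areas[lost[0]]))
                s = new
                if s == n:  # null range: extinct in place, absorbing
                    s = -1
                    break
            node_state[v] = s
        sv = int(node_state[v])
        if tree.children[v] and sv >= 0:
            evs = cladogenesis_events(space.ranges[sv], space, model.mode)
            l, r, _ = evs[rng.integers(len(evs))]
            x, y = tree.children[v]
            branch_top[x] = space.index[l]
            branch_top[y] = space.index[r]
    tip_ranges = {
        tree.labels[v]: (
            None if node_state[v] < 0
            else frozenset(space.areas[a] for a in space.ranges[node_state[v]])
        )
        for v in tree.tip_indices
    }
    truth = {"node_ranges": node_state, "events": events, "root_range": root}
    return tip_ranges, truth
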