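"""Dispersal-Extinction-Cladogenesis (DEC) range evolution on dated trees.

A species' geographic range is a non-empty set of bioregions.  Along a
branch the range expands into an adjacent area j at rate d * (number of
occupied areas adjacent to j) and loses an occupied area at rate e; losing
the last area leads to the absorbing null (globally extinct) range.  At a
speciation node the parent range splits according to the cladogenetic event
set of the chosen model: DEC allows subset sympatry (one daughter inherits a
single area, the other the full range) and vicariance with one single-area
daughter; DIVALIKE allows any vicariant split (both daughters may hold
several areas) and no subset sympatry.  Events within a range's set are
weighted equally.

The module provides the pruning likelihood over ranges, ML estimation of
(d, e), exact marginal ancestral ranges, biogeographic stochastic mapping
(sampled range histories with dispersal events attributed to source areas),
and the 5-Ma time-sliced dispersal-rate summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .ctmc import CTMCPropagator
from .trees import DatedTree

__all__ = [
    "Bioregions",
    "RangeStateSpace",
    "DECModel",
    "DispersalSummary",
    "build_state_space",
    "dec_rate_matrix",
    "cladogenesis_events",
    "dec_loglik",
    "fit_dec",
    "ancestral_ranges",
    "biogeo_stochastic_map",
    "timesliced_rates",
    "lineage_area_counts",
]

_RATE_BOUNDS = (1e-8, 1e2)  # events/Ma


@dataclass(frozen=True)
class Bioregions:
    """Ordered bioregion labels, optionally flagged tropical/temperate."""

    areas: tuple
    tropical: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "areas", tuple(self.areas))
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("area labels must be unique")
        if not 2 <= len(self.areas) <= 14:
            raise ValueError("between 2 and 14 areas supported")

    @property
    def n(self) -> int:
        return len(self.areas)


def _is_connected(members: frozenset, adjacency: np.ndarray) -> bool:
    if len(members) <= 1:
        return True
    members = set(members)
    seen = {next(iter(members))}
    frontier = list(seen)
    while frontier:
        v = frontier.pop()
        for u in members - seen:
            if adjacency[v, u] > 0 or adjacency[u, v] > 0:
                seen.add(u)
                frontier.append(u)
    return seen == members


@dataclass
class RangeStateSpace:
    """Enumerated allowed ranges (area subsets) in deterministic order."""

    regions: Bioregions
    ranges: tuple
    max_size: int
    adjacency: np.ndarray
    require_connected: bool = False

    def __post_init__(self):
        self.index = {r: i for i, r in enumerate(self.ranges)}

    @property
    def n_states(self) -> int:
        return len(self.ranges)

    @property
    def areas(self) -> tuple:
        return self.regions.areas

    def range_label(self, i: int, sep: str = "+") -> str:
        return sep.join(self.areas[a] for a in sorted(self.ranges[i]))

    def encode(self, area_codes) -> int:
        """Index of the range given area labels (iterable or 'A;B' string)."""
        if isinstance(area_codes, str):
            area_codes = [c for c in area_codes.replace("+", ";").split(";") if c]
        try:
            fs = frozenset(self.areas.index(c) for c in area_codes)
        except ValueError as exc:
            raise KeyError(f"unknown area in {area_codes!r}") from exc
        if fs not in self.index:
            raise KeyError(
                f"range {sorted(area_codes)} not allowed under the state space "
                "(adjacency/max-size constraints)"
            )
        return self.index[fs]


def build_state_space(
    regions: Bioregions | Sequence[str],
    max_size: int | None = None,
    adjacency: np.ndarray | None = None,
    require_connected: bool = False,
) -> RangeStateSpace:
    """Enumerate allowed ranges ordered by size then lexicographic area tuple."""
    if not isinstance(regions, Bioregions):
        regions = Bioregions(tuple(regions))
    n = regions.n
    if max_size is None:
        max_size = n
    if max_size > n or max_size < 1:
        raise ValueError("max_size must be in 1..n_areas")
    if adjacency is None:
        adjacency = np.ones((n, n)) - np.eye(n)
    adjacency = np.asarray(adjacency, dtype=float)
    ranges = []
    for size in range(1, max_size + 1):
        for combo in combinations(range(n), size):
            fs = frozenset(combo)
            if require_connected and not _is_connected(fs, adjacency):
                continue
            ranges.append(fs)
    if not ranges:
        raise ValueError("state space is empty")
    return RangeStateSpace(regions, tuple(ranges), max_size, adjacency, require_connected)


def dec_rate_matrix(
    space: RangeStateSpace, d: float, e: float, adjacency: np.ndarray | None = None
) -> np.ndarray:
    """Anagenetic generator over ranges plus the absorbing null range.

    State order follows ``space.ranges`` with the null range last.  Expansion
    R -> R+{j} proceeds at rate d * sum_{i in R} adj[i, j]; each occupied
    area is lost at rate e, the last loss entering null.  Transitions whose
    target is excluded from the state space are disallowed.
    """
    if d < 0 or e < 0:
        raise ValueError("rates must be non-negative")
    if adjacency is None:
        adjacency = space.adjacency
    n = space.n_states
    Q = np.zeros((n + 1, n + 1))
    for i, r in enumerate(space.ranges):
        for j in range(space.regions.n):
            if j in r:
                continue
            target = r | {j}
            ti = space.index.get(frozenset(target))
            if ti is None:
                continue
            rate = d * sum(adjacency[a, j] for a in r)
            Q[i, ti] += rate
        if len(r) == 1:
            Q[i, n] += e
        else:
            for a in r:
                target = frozenset(r - {a})
                ti = space.index.get(target)
                if ti is not None:
                    Q[i, ti] += e
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def cladogenesis_events(
    range_: frozenset | Iterable, space: RangeStateSpace, mode: str = "DEC"
) -> list:
    """Allowed (left, right, weight) daughter-range splits for a parent range.

    Single-area ranges copy themselves.  DEC: subset sympatry (one daughter a
    single occupied area, the other the full parent range) and vicariance
    with one single-area side.  DIVALIKE: every ordered split of the parent
    into two disjoint non-empty parts, no subset sympatry.  Daughters outside
    the state space are excluded; remaining events get equal weights that
    sum to one.
    """
    fs = frozenset(range_)
    if fs not in space.index:
        raise KeyError("parent range not in state space")
    if len(fs) == 1:
        return [(fs, fs, 1.0)]
    events: dict = {}
    if mode == "DEC":
        for a in fs:
            one = frozenset({a})
            rest = fs - one
            events[(one, fs)] = None
            events[(fs, one)] = None
            events[(one, rest)] = None
            events[(rest, one)] = None
    elif mode == "DIVALIKE":
        members = sorted(fs)
        for size in range(1, len(members)):
            for combo in combinations(members, size):
                left = frozenset(combo)
                events[(left, fs - left)] = None
    else:
        raise ValueError("mode must be 'DEC' or 'DIVALIKE'")
    kept = [
        (l, r)
        for (l, r) in events
        if l in space.index and r in space.index
    ]
    if not kept:
        raise ValueError(f"no allowed cladogenetic event for range {sorted(fs)}")
    w = 1.0 / len(kept)
    return [(l, r, w) for (l, r) in kept]


@dataclass
class DECModel:
    """DEC/DIVALIKE model: (d, e) rates, state space, optional time slices.

    ``slice_boundaries`` are ages (Ma before present, ascending) separating
    time slices; ``slice_adjacency`` holds one adjacency matrix per slice,
    youngest first, with ``len(slice_adjacency) == len(slice_boundaries)+1``.
    """

    d: float
    e: float
    space: RangeStateSpace
    mode: str = "DEC"
    slice_boundaries: tuple = ()
    slice_adjacency: tuple = ()

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be non-negative")
        self.slice_boundaries = tuple(self.slice_boundaries)
        if self.slice_boundaries:
            if list(self.slice_boundaries) != sorted(self.slice_boundaries):
                raise ValueError("slice boundaries must be ascending ages")
            if len(self.slice_adjacency) != len(self.slice_boundaries) + 1:
                raise ValueError("need one adjacency matrix per time slice")
        elif not self.slice_adjacency:
            self.slice_adjacency = (self.space.adjacency,)

    @property
    def n_slices(self) -> int:
        return len(self.slice_adjacency)

    def slice_of(self, age: float) -> int:
        """Index of the time slice containing an age (slices closed at the
        younger bound)."""
        return int(np.searchsorted(self.slice_boundaries, age, side="right"))


# ---------------------------------------------------------------- the engine
class _DECEngine:
    """Precomputed structure for repeated DEC likelihood evaluations."""

    def __init__(self, tree: DatedTree, tip_ranges: Mapping, model_or_space, mode="DEC",
                 slice_boundaries=(), slice_adjacency=()):
        if isinstance(model_or_space, DECModel):
            m = model_or_space
            space, mode = m.space, m.mode
            slice_boundaries, slice_adjacency = m.slice_boundaries, m.slice_adjacency
        else:
            space = model_or_space
            if not slice_adjacency:
                slice_adjacency = (space.adjacency,)
        self.tree = tree
        self.space = space
        self.mode = mode
        self.boundaries = tuple(slice_boundaries)
        self.adjacencies = tuple(np.asarray(a, float) for a in slice_adjacency)
        n = space.n_states
        self.n = n
        self.m = n + 1  # state vector length including the null range (last)
        # tip partials; a tip observed extinct-in-place (range None) is the
        # null state, "?" or an absent key is missing data (all-ones)
        self.tipL = np.zeros((tree.n_nodes, self.m))
        for v in tree.tip_indices:
            lab = tree.labels[v]
            r = tip_ranges.get(lab, "?")
            if r is None:
                self.tipL[v, n] = 1.0
            elif isinstance(r, str) and r in ("?", ""):
                self.tipL[v, :] = 1.0
            elif isinstance(r, (int, np.integer)):
                self.tipL[v, int(r)] = 1.0
            else:
                self.tipL[v, space.encode(r)] = 1.0
        # flattened cladogenesis tables; the null range copies itself so that
        # extinct-in-place subtrees stay consistently null
        owner, li, ri, w = [], [], [], []
        self.events_by_range = []
        for i, r in enumerate(space.ranges):
            evs = cladogenesis_events(r, space, mode)
            self.events_by_range.append(
                [(space.index[l], space.index[rr], ww) for l, rr, ww in evs]
            )
            for l, rr, ww in evs:
                owner.append(i)
                li.append(space.index[l])
                ri.append(space.index[rr])
                w.append(ww)
        self.events_by_range.append([(n, n, 1.0)])
        owner.append(n)
        li.append(n)
        ri.append(n)
        w.append(1.0)
        self.ev_owner = np.array(owner)
        self.ev_l = np.array(li)
        self.ev_r = np.array(ri)
        self.ev_w = np.array(w)
        # branch segmentation across slice boundaries (parent->child order)
        self.branch_segments: list = [None] * tree.n_nodes
        for v in range(1, tree.n_nodes):
            a_child = tree.ages[v]
            a_parent = tree.ages[tree.parent[v]]
            cuts = [b for b in self.boundaries if a_child < b < a_parent]
            pts = [a_parent] + sorted(cuts, reverse=True) + [a_child]
            segs = []
            for hi, lo in zip(pts, pts[1:]):
                mid = 0.5 * (hi + lo)
                segs.append((self._slice_of(mid), hi - lo))
            self.branch_segments[v] = segs

    def _slice_of(self, age: float) -> int:
        return int(np.searchsorted(self.boundaries, age, side="right"))

    def propagators(self, d: float, e: float) -> list:
        return [
            CTMCPropagator(dec_rate_matrix(self.space, d, e, adj))
            for adj in self.adjacencies
        ]

    def branch_P(self, props: list) -> np.ndarray:
        """Per-branch transition matrices over ranges plus null, (N, m, m)."""
        tree = self.tree
        if len(props) == 1:
            return props[0].P_batch(tree.blen)
        out = np.zeros((tree.n_nodes, self.m, self.m))
        out[0] = np.eye(self.m)
        for v in range(1, tree.n_nodes):
            P = np.eye(self.m)
            for s, dur in self.branch_segments[v]:
                P = P @ props[s].P(dur)
            out[v] = P
        return out

    def down_pass(self, props: list):
        tree = self.tree
        P = self.branch_P(props)
        L = self.tipL.copy()
        D = np.zeros_like(L)
        log_scale = 0.0
        for v in tree.postorder:
            if tree.children[v]:
                x, y = tree.children[v]
                contrib = self.ev_w * D[x][self.ev_l] * D[y][self.ev_r]
                Lv = np.zeros(self.m)
                np.add.at(Lv, self.ev_owner, contrib)
                mx = Lv.max()
                if mx <= 0:
                    return None
                log_scale += np.log(mx)
                L[v] = Lv / mx
            if v != 0:
                D[v] = P[v] @ L[v]
        return L, D, log_scale, P

    def loglik(self, d: float, e: float) -> float:
        res = self.down_pass(self.propagators(d, e))
        if res is None:
            return -np.inf
        L, _, log_scale, _ = res
        lik = L[0][: self.n].mean()  # flat root prior over non-null ranges
        if lik <= 0:
            return -np.inf
        return float(np.log(lik) + log_scale)


def dec_loglik(tree: DatedTree, tip_ranges: Mapping, model: DECModel) -> float:
    """Pruning log-likelihood of tip ranges under a DEC/DIVALIKE model."""
    return _DECEngine(tree, tip_ranges, model).loglik(model.d, model.e)


def fit_dec(
    tree: DatedTree,
    tip_ranges: Mapping,
    space: RangeStateSpace,
    mode: str = "DEC",
    slice_boundaries=(),
    slice_adjacency=(),
    n_starts: int = 3,
):
    """ML estimation of (d, e) on the log scale, bounded, multistart.

    Returns ``(model, loglik, info)``.
    """
    engine = _DECEngine(tree, tip_ranges, space, mode, slice_boundaries, slice_adjacency)
    lo, hi = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])
    depth = max(tree.root_age, 1e-12)

    def neg(x):
        val = engine.loglik(float(np.exp(x[0])), float(np.exp(x[1])))
        return 1e12 if not np.isfinite(val) else -val

    best = None
    for base in np.geomspace(0.1 / depth, 10.0 / depth, n_starts):
        x0 = np.log([base, base / 2.0])
        res = minimize(neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
        if best is None or res.fun < best.fun:
            best = res
    d_hat, e_hat = np.exp(best.x)
    model = DECModel(float(d_hat), float(e_hat), space, mode,
                     slice_boundaries, slice_adjacency)
    return model, -float(best.fun), {"converged": bool(best.success)}


def ancestral_ranges(tree: DatedTree, tip_ranges: Mapping, model: DECModel):
    """Exact marginal posterior range probabilities per node.

    Returns ``(marginals, modal)``: marginals is (n_nodes, n_states) with rows
    summing to one; modal maps node id to the most probable range label.
    """
    engine = _DECEngine(tree, tip_ranges, model)
    props = engine.propagators(model.d, model.e)
    res = engine.down_pass(props)
    if res is None:
        raise ValueError("data have zero likelihood under the model")
    L, D, _, P = res
    n, m = engine.n, engine.m
    out = np.zeros_like(L)
    out[0, :n] = 1.0 / n
    marg = np.zeros_like(L)
    for v in tree.preorder:
        post = out[v] * L[v]
        marg[v] = post / post.sum()
        if tree.children[v]:
            x, y = tree.children[v]
            contrib = out[v][engine.ev_owner] * engine.ev_w
            top_x = np.zeros(m)
            np.add.at(top_x, engine.ev_l, contrib * D[y][engine.ev_r])
            top_y = np.zeros(m)
            np.add.at(top_y, engine.ev_r, contrib * D[x][engine.ev_l])
            for c, top in ((x, top_x), (y, top_y)):
                top = top / max(top.max(), 1e-300)
                out[c] = top @ P[c]
    modal = {}
    for v in range(tree.n_nodes):
        i = int(np.argmax(marg[v]))
        modal[int(v)] = engine.space.range_label(i) if i < n else "extinct"
    return marg, modal


# -------------------------------------------------- biogeographic mapping
@dataclass
class DispersalSummary:
    """Dispersal events aggregated over biogeographic stochastic maps.

    ``counts[s, i, j]`` is the (fractionally attributed) number of dispersal
    events from source area i into destination j in simulation s.  Event-level
    arrays keep the time (Ma before present) of every logged event so rates
    can be re-binned.  ``relative_mean_rates`` averages counts over
    simulations; the /100 display scaling used in figure annotations is an
    output option and never applied to stored values.
    """

    areas: tuple
    counts: np.ndarray
    event_sim: np.ndarray
    event_time: np.ndarray
    event_src: np.ndarray
    event_dst: np.ndarray
    event_weight: np.ndarray
    contraction_counts: np.ndarray | None = None

    @property
    def n_sims(self) -> int:
        return self.counts.shape[0]

    def relative_mean_rates(self, div100: bool = False) -> np.ndarray:
        m = self.counts.mean(axis=0)
        return m / 100.0 if div100 else m


def _sample_branch_path(props, segs, a, b, rng):
    """Endpoint-conditioned path over a branch possibly crossing time slices.

    ``segs`` is an ordered list of (slice index, duration) from the parent
    toward the child.  Returns (state, duration) segments in the same order.
    """
    if len(segs) == 1:
        s, dur = segs[0]
        return props[s].sample_path(a, b, dur, rng)
    # sample states at slice boundaries by forward filtering
    mats = [props[s].P(dur) for s, dur in segs]
    m = len(mats)
    suffix = [np.eye(mats[0].shape[0])] * m  # suffix[i] = mats[i+1] @ ... @ mats[m-1]
    for i in range(m - 2, -1, -1):
        suffix[i] = mats[i + 1] @ suffix[i + 1]
    path = []
    cur = a
    for i, (s, dur) in enumerate(segs):
        if i == len(segs) - 1:
            nxt = b
        else:
            w = mats[i][cur, :] * suffix[i][:, b]
            nxt = int(rng.choice(len(w), p=w / w.sum()))
        path.extend(props[s].sample_path(cur, nxt, dur, rng))
        cur = nxt
    return path


def biogeo_stochastic_map(
    tree: DatedTree,
    tip_ranges: Mapping,
    model: DECModel,
    n_sims: int,
    rng: np.random.Generator,
    keep_maps: bool = False,
):
    """Sample complete range histories and summarize dispersal events.

    Node ranges and cladogenetic events are drawn from their joint posterior;
    each branch's anagenetic path is then drawn conditioned on its endpoints
    by uniformization.  Every range expansion R -> R+{j} is logged at its
    time and attributed as dispersal into j from each source area i in R with
    weight adj[i, j] / sum_{i'} adj[i', j].  Returns ``(maps, summary)``;
    ``maps`` is empty unless ``keep_maps`` (the per-branch histories of every
    simulation are bulky).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    engine = _DECEngine(tree, tip_ranges, model)
    props = engine.propagators(model.d, model.e)
    res = engine.down_pass(props)
    if res is None:
        raise ValueError("data have zero likelihood under the model")
    L, D, _, P = res
    space = engine.space
    nA = space.regions.n
    n, m = engine.n, engine.m
    root_post = L[0][:n] / L[0][:n].sum()
    counts = np.zeros((n_sims, nA, nA))
    contraction = np.zeros((n_sims, nA))
    ev_sim, ev_time, ev_src, ev_dst, ev_w = [], [], [], [], []
    maps = []
    node_state_freq = np.zeros((tree.n_nodes, m))
    for s_idx in range(n_sims):
        node_state = np.zeros(tree.n_nodes, dtype=int)
        node_state[0] = rng.choice(n, p=root_post)
        branch_top = np.zeros(tree.n_nodes, dtype=int)  # state at top of branch
        segments: dict[int, list] = {}
        for v in tree.preorder:
            if v != 0:
                # node state first (conditional on the branch-top state set by
                # the parent's cladogenetic event), then v's own event below
                top = int(branch_top[v])
                w = P[v][top, :] * L[v]
                sv = int(rng.choice(m, p=w / w.sum()))
                node_state[v] = sv
                try:
                    path = _sample_branch_path(
                        props, engine.branch_segments[v], top, sv, rng)
                except Exception as exc:
                    raise RuntimeError(
                        f"endpoint-conditioned path failed on branch above node {v}"
                    ) from exc
                segments[v] = path
                # log events along the branch (ages decrease toward the child)
                age = tree.ages[tree.parent[v]]
                prev = None
                for st, dur in path:
                    if prev is not None:
                        r_prev = space.ranges[prev] if prev < n else frozenset()
                        r_new = space.ranges[st] if st < n else frozenset()
                        if len(r_new) > len(r_prev):
                            (j,) = tuple(r_new - r_prev)
                            adj = engine.adjacencies[engine._slice_of(age)]
                            srcs = sorted(r_prev)
                            wts = np.array([adj[i, j] for i in srcs], dtype=float)
                            if wts.sum() <= 0:
                                wts = np.ones(len(srcs))
                            wts = wts / wts.sum()
                            for i, wt in zip(srcs, wts):
                                counts[s_idx, i, j] += wt
                                ev_sim.append(s_idx)
                                ev_time.append(age)
                                ev_src.append(i)
                                ev_dst.append(j)
                                ev_w.append(wt)
                        elif len(r_new) < len(r_prev):
                            (i,) = tuple(r_prev - r_new)
                            contraction[s_idx, i] += 1
                    prev = st
                    age -= dur
            if tree.children[v]:
                x, y = tree.children[v]
                evs = engine.events_by_range[node_state[v]]
                weights = np.array([w * D[x][l] * D[y][r] for l, r, w in evs])
                tot = weights.sum()
                if tot <= 0:
                    raise ValueError(f"no viable cladogenetic event at node {v}")
                l, r, _ = evs[rng.choice(len(evs), p=weights / tot)]
                branch_top[x], branch_top[y] = l, r
        node_state_freq[np.arange(tree.n_nodes), node_state] += 1.0
        if keep_maps:
            maps.append({"node_states": node_state.copy(), "segments": segments})
    summary = DispersalSummary(
        areas=space.areas,
        counts=counts,
        event_sim=np.array(ev_sim, dtype=int),
        event_time=np.array(ev_time, dtype=float),
        event_src=np.array(ev_src, dtype=int),
        event_dst=np.array(ev_dst, dtype=int),
        event_weight=np.array(ev_w, dtype=float),
        contraction_counts=contraction,
    )
    summary.node_state_freq = node_state_freq / n_sims
    return maps, summary


def timesliced_rates(
    summary: DispersalSummary,
    bin_width: float = 5.0,
    periods: Mapping | None = None,
):
    """Bin dispersal events into half-open [t, t+width) Ma-before-present bins.

    Returns a dict with ``bin_edges`` (older edge per bin), ``bins`` (array of
    per-bin mean source-by-destination rate matrices) and, if ``periods``
    maps names to (younger_age, older_age) intervals, ``periods`` holding the
    mean of the member bins (bins whose midpoint falls in the interval).
    """
    if len(summary.event_time) == 0:
        n_bins = 1
        binned = np.zeros((1, len(summary.areas), len(summary.areas)))
        edges = np.array([0.0])
    else:
        idx = np.floor(summary.event_time / bin_width).astype(int)
        n_bins = int(idx.max()) + 1
        nA = len(summary.areas)
        binned = np.zeros((n_bins, nA, nA))
        np.add.at(
            binned,
            (idx, summary.event_src, summary.event_dst),
            summary.event_weight / summary.n_sims,
        )
        edges = np.arange(n_bins) * bin_width
    out = {"bin_edges": edges, "bin_width": bin_width, "bins": binned}
    if periods:
        per = {}
        mids = edges + bin_width / 2.0
        for name, (young, old) in periods.items():
            member = (mids >= young) & (mids < old)
            per[name] = binned[member].mean(axis=0) if member.any() else np.zeros_like(binned[0])
        out["periods"] = per
    return out


def lineage_area_counts(
    tree: DatedTree, marginals: np.ndarray, model: DECModel, times: Sequence[float]
) -> np.ndarray:
    """Expected number of lineages occupying each area at given ages.

    A branch crossing age t contributes its child node's marginal range
    probabilities; entry [ti, a] sums P(area a occupied) over crossing
    branches.  Used for presence-through-time map summaries.
    """
    nA = model.space.regions.n
    occ = np.zeros((model.space.n_states + 1, nA))  # null row stays zero
    for i, r in enumerate(model.space.ranges):
        for a in r:
            occ[i, a] = 1.0
    out = np.zeros((len(times), nA))
    for ti, t in enumerate(times):
        for v in range(1, tree.n_nodes):
            if tree.ages[v] <= t < tree.ages[tree.parent[v]]:
                out[ti] += marginals[v] @ occ
    return out
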