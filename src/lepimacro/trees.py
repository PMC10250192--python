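"""Dated phylogenies: Newick I/O, validation, pruning and patristic distances.

The central container is :class:`DatedTree`, a rooted, strictly bifurcating,
ultrametric phylogeny with branch lengths in millions of years (Ma).  Node
ages are measured in Ma before present: every tip of an ultrametric tree has
age 0 and the root carries the crown age.  All downstream likelihood and
mapping machinery consumes this container.

Newick parsing is delegated to dendropy; the parsed tree is converted to a
flat array representation (parent pointers, branch lengths, postorder) that
the numerical code iterates over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "DatedTree",
    "TreeError",
    "NewickParseError",
    "DuplicateLabelError",
    "MissingBranchLengthError",
    "PolytomyError",
    "UltrametricityError",
    "UltrametricityWarning",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "make_rng",
]

#: relative tolerance on root-to-tip path sums for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Base class for tree validation errors; ``code`` identifies the failure."""

    code = "tree_error"


class NewickParseError(TreeError):
    code = "newick_parse"


class DuplicateLabelError(TreeError):
    code = "duplicate_labels"


class MissingBranchLengthError(TreeError):
    code = "missing_branch_length"


class PolytomyError(TreeError):
    code = "polytomy"


class UltrametricityError(TreeError):
    code = "not_ultrametric"


class UltrametricityWarning(UserWarning):
    pass


def make_rng(seed: int) -> np.random.Generator:
    """Seeded random stream used by every stochastic operation in the package.

    The same seed yields bit-identical downstream sampled output.  Stochastic
    functions never create their own global state; they all take an explicit
    ``rng`` argument.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    return np.random.default_rng(int(seed))


@dataclass
class DatedTree:
    """Rooted bifurcating ultrametric phylogeny in flat-array form.

    Nodes are integer ids ``0..n_nodes-1`` with the root at index 0 and the
    remaining nodes in preorder.  ``parent[i]`` is -1 for the root;
    ``blen[i]`` is the length (Ma) of the branch above node ``i`` (0 for the
    root).  Tips carry unique string labels; internal labels are preserved
    but unused.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list
    children: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        n = len(self.parent)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i in range(1, n):
                self.children[self.parent[i]].append(i)
        self._refresh()

    def _refresh(self) -> None:
        n = self.n_nodes
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self.tip_indices = np.flatnonzero(self.is_tip)
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.preorder = np.array(order, dtype=int)
        self.postorder = np.array(order[::-1], dtype=int)
        self.depths = np.zeros(n)
        for i in self.preorder[1:]:
            self.depths[i] = self.depths[self.parent[i]] + self.blen[i]
        self.ages = self.depths.max() - self.depths
        self._tip_index = {
            self.labels[i]: i for i in self.tip_indices if self.labels[i] is not None
        }

    # ------------------------------------------------------------------ info
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    def tip_index(self, label: str) -> int:
        return self._tip_index[label]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        tip_depths = self.depths[self.tip_indices]
        scale = max(tip_depths.max(), 1e-300)
        return bool((tip_depths.max() - tip_depths.min()) <= rtol * scale)

    # ------------------------------------------------------------ validation
    def validate(
        self,
        require_ultrametric: bool = True,
        require_bifurcating: bool = True,
        rtol: float = ULTRAMETRIC_RTOL,
    ) -> "DatedTree":
        labels = [l for l in self.tip_labels if l is not None]
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateLabelError(f"duplicate tip labels: {dups}")
        if np.any(self.blen[1:] < 0):
            raise TreeError("negative branch lengths")
        if require_bifurcating:
            bad = [
                i
                for i, c in enumerate(self.children)
                if len(c) not in (0, 2)
            ]
            if bad:
                raise PolytomyError(
                    f"non-bifurcating nodes (use resolve_polytomies): {bad[:5]}"
                )
        if require_ultrametric and not self.is_ultrametric(rtol):
            raise UltrametricityError(
                "root-to-tip path lengths differ beyond tolerance"
            )
        return self

    def resolve_polytomies(self, rng: np.random.Generator) -> "DatedTree":
        """Arbitrarily resolve polytomies with zero-length branches (seeded order)."""
        newick = self.to_newick()
        nodes = _parse_to_lists(newick)
        parent, blen, labels, children = nodes
        parent = list(parent)
        blen = list(blen)
        for v in range(len(parent)):
            while len(children[v]) > 2:
                order = list(children[v])
                rng.shuffle(order)
                a, b = order[0], order[1]
                new = len(parent)
                parent.append(v)
                blen.append(0.0)
                labels.append(None)
                children.append([a, b])
                parent[a] = parent[b] = new
                children[v] = [c for c in children[v] if c not in (a, b)] + [new]
        return _from_lists(parent, blen, labels, children)

    # -------------------------------------------------------------- export
    def to_newick(self, precision: int = 12) -> str:
        fmt = f"%.{precision}g"

        def rec(v: int) -> str:
            if not self.children[v]:
                lab = _quote_label(self.labels[v])
            else:
                lab = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if self.labels[v]:
                    lab += _quote_label(self.labels[v])
            if v == 0:
                return lab
            return lab + ":" + (fmt % self.blen[v])

        return rec(0) + ";"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ distances
    def patristic_matrix(self, labels: Sequence[str] | None = None) -> tuple[np.ndarray, list]:
        """Pairwise patristic (branch-length) distances between tips.

        Returns the distance matrix and the tip-label order used.  On an
        ultrametric tree the distance between two tips is twice the age of
        their most recent common ancestor.
        """
        if labels is None:
            labels = self.tip_labels
        idx = [self.tip_index(l) for l in labels]
        sel = {v: j for j, v in enumerate(idx)}
        n = len(idx)
        D = np.zeros((n, n))
        # postorder sweep carrying (tip, distance-to-current-node) lists
        carry: dict[int, list[tuple[int, float]]] = {}
        for v in self.postorder:
            if not self.children[v]:
                carry[v] = [(sel[v], 0.0)] if v in sel else []
                continue
            lists = []
            for c in self.children[v]:
                lst = [(t, d + self.blen[c]) for t, d in carry.pop(c)]
                lists.append(lst)
            for ai in range(len(lists)):
                for bi in range(ai + 1, len(lists)):
                    for t1, d1 in lists[ai]:
                        for t2, d2 in lists[bi]:
                            D[t1, t2] = D[t2, t1] = d1 + d2
            carry[v] = [x for lst in lists for x in lst]
        return D, list(labels)

    def pd_subtree(self, labels: Sequence[str], include_root: bool = False) -> float:
        """Total branch length of the minimal subtree spanning ``labels``.

        With ``include_root`` the path down to the root is always included
        (Faith's PD convention); otherwise only branches between the tips'
        most recent common ancestor and the tips count.
        """
        marked = np.zeros(self.n_nodes, dtype=int)
        for l in labels:
            marked[self.tip_index(l)] = 1
        for v in self.postorder:
            for c in self.children[v]:
                marked[v] += marked[c]
        total = marked[0]
        s = 0.0
        for v in range(1, self.n_nodes):
            if marked[v] == 0:
                continue
            if include_root or marked[v] < total:
                s += self.blen[v]
        return s


def _quote_label(label: str) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in "()[]{}/\\,;:=*'\"`<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _parse_to_lists(source: str):
    try:
        dtree = dendropy.Tree.get(
            data=source,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        if "duplicate" in type(exc).__name__.lower() or "multiple occurrences" in str(exc).lower():
            raise DuplicateLabelError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    parent: list[int] = []
    blen: list[float] = []
    labels: list = []
    children: list[list[int]] = []
    ids: dict = {}
    for node in dtree.preorder_node_iter():
        i = len(parent)
        ids[node] = i
        if node.parent_node is None:
            parent.append(-1)
            blen.append(0.0)
        else:
            parent.append(ids[node.parent_node])
            if node.edge.length is None:
                raise MissingBranchLengthError(
                    "branch without a length in Newick input"
                )
            blen.append(float(node.edge.length))
        lab = None
        if node.taxon is not None:
            lab = node.taxon.label
        elif node.label:
            lab = node.label
        labels.append(lab)
        children.append([])
        if node.parent_node is not None:
            children[ids[node.parent_node]].append(i)
    return parent, blen, labels, children


def _from_lists(parent, blen, labels, children) -> DatedTree:
    return DatedTree(
        parent=np.asarray(parent), blen=np.asarray(blen), labels=list(labels),
        children=[list(c) for c in children],
    )


def read_newick(
    source,
    strict_ultrametric: bool = True,
    allow_polytomies: bool = False,
    rtol: float = ULTRAMETRIC_RTOL,
) -> DatedTree:
    """Parse a Newick file or string into a validated :class:`DatedTree`.

    Node ages are computed as the maximum root-to-tip distance minus node
    depth.  With ``strict_ultrametric`` a non-ultrametric tree raises
    :class:`UltrametricityError`; otherwise a warning is emitted and the tree
    is returned (time-sliced summaries will refuse it downstream).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "(" not in text:  # path, not literal newick
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()
    tree = _from_lists(*_parse_to_lists(text))
    try:
        tree.validate(require_ultrametric=True, require_bifurcating=not allow_polytomies, rtol=rtol)
    except UltrametricityError:
        if strict_ultrametric:
            raise
        warnings.warn(
            "input tree is not ultrametric; time-based summaries are unreliable",
            UltrametricityWarning,
        )
    return tree


def write_newick(tree: DatedTree, path=None) -> str:
    s = tree.to_newick()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s + "\n")
    return s


def prune_to_taxa(tree: DatedTree, keep: Iterable[str]) -> DatedTree:
    """Induced subtree on ``keep``; unifurcations collapsed, lengths summed.

    The subtree is re-rooted at the most recent common ancestor of the kept
    tips, so ultrametricity (and tip ages) are preserved while the root age
    shrinks to the crown age of the kept set.
    """
    keep = set(keep)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    def build(v: int):
        # returns (parent_list_fragment...) via nested tuples (label, blen, kids)
        if not tree.children[v]:
            if tree.labels[v] in keep:
                return (tree.labels[v], tree.blen[v], [])
            return None
        kept = [build(c) for c in tree.children[v]]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            lab, bl, kids = kept[0]
            return (lab, bl + tree.blen[v], kids)
        return (tree.labels[v], tree.blen[v], kept)

    top = build(0)
    parent: list[int] = []
    blen: list[float] = []
    labels: list = []
    children: list[list[int]] = []

    def emit(node, par: int) -> int:
        lab, bl, kids = node
        i = len(parent)
        parent.append(par)
        blen.append(bl if par >= 0 else 0.0)
        labels.append(lab)
        children.append([])
        if par >= 0:
            children[par].append(i)
        for k in kids:
            emit(k, i)
        return i

    emit(top, -1)
    return _from_lists(parent, blen, labels, children)
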