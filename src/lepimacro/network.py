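"""Weighted bipartite modularity and module detection for host-use networks.

The butterfly-by-host-family record matrix is reduced to "host modules" —
groups of butterflies and hosts that interact more with each other than with
the rest of the network — by maximizing Barber's weighted bipartite
modularity

    Q = (1/F) * sum_ij (A_ij - r_i c_j / F) * delta(g_i, g_j)

with A the weight matrix, r and c its row and column sums, F the total
weight and g the module labels.  The search is a label-propagation ascent in
the spirit of LPAwb+/DIRTLPAwb+: alternating row/column sweeps that move
each node to the label maximizing its modularity contribution, followed by
greedy module merging, repeated over seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HostMatrix",
    "ModulePartition",
    "modularity_q",
    "find_modules",
    "assign_module_colors",
]

_SWEEP_TOL = 1e-10
_MAX_SWEEPS = 10_000


@dataclass
class HostMatrix:
    """Weighted bipartite association matrix (rows: species, columns: hosts)."""

    row_labels: list
    col_labels: list
    weights: np.ndarray

    def __post_init__(self):
        self.row_labels = list(self.row_labels)
        self.col_labels = list(self.col_labels)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("weight matrix shape does not match labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.weights.sum() <= 0:
            raise ValueError("total weight must be positive")
        if np.any(self.weights.sum(axis=1) == 0):
            raise ValueError("all-zero row (species without hosts)")
        if np.any(self.weights.sum(axis=0) == 0):
            raise ValueError("all-zero column (host without records)")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def binary(self) -> "HostMatrix":
        """Presence/absence version of the matrix."""
        return HostMatrix(self.row_labels, self.col_labels,
                          (self.weights > 0).astype(float))

    @classmethod
    def from_long(cls, df: pd.DataFrame, species_col: str = "species",
                  host_col: str = "host_family", count_col: str = "count") -> "HostMatrix":
        """Build from a long-format table (species, host_family, count)."""
        if count_col not in df.columns:
            df = df.assign(**{count_col: 1.0})
        wide = df.pivot_table(index=species_col, columns=host_col,
                              values=count_col, aggfunc="sum", fill_value=0.0)
        return cls(list(wide.index), list(wide.columns), wide.to_numpy(float))

    def to_long(self) -> pd.DataFrame:
        r, c = np.nonzero(self.weights)
        return pd.DataFrame({
            "species": [self.row_labels[i] for i in r],
            "host_family": [self.col_labels[j] for j in c],
            "count": self.weights[r, c],
        })


@dataclass
class ModulePartition:
    """Module assignment for every row and column node, with its Q."""

    row_modules: np.ndarray
    col_modules: np.ndarray
    Q: float
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self):
        self.row_modules = np.asarray(self.row_modules, dtype=int)
        self.col_modules = np.asarray(self.col_modules, dtype=int)

    @property
    def n_modules(self) -> int:
        return len(set(self.row_modules) | set(self.col_modules))

    def as_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame({
            "node": self.row_labels or list(range(len(self.row_modules))),
            "type": "butterfly",
            "module": self.row_modules,
        })
        cols = pd.DataFrame({
            "node": self.col_labels or list(range(len(self.col_modules))),
            "type": "host",
            "module": self.col_modules,
        })
        return pd.concat([rows, cols], ignore_index=True)


def modularity_q(
    m: HostMatrix,
    row_modules: Sequence[int] | ModulePartition,
    col_modules: Sequence[int] | None = None,
) -> float:
    """Barber's weighted bipartite modularity of a partition."""
    if isinstance(row_modules, ModulePartition):
        col_modules = row_modules.col_modules
        row_modules = row_modules.row_modules
    g_r = np.asarray(row_modules, dtype=int)
    g_c = np.asarray(col_modules, dtype=int)
    if len(g_r) != len(m.row_labels) or len(g_c) != len(m.col_labels):
        raise ValueError("partition does not cover all nodes")
    A = m.weights
    F = m.total_weight
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    delta = g_r[:, None] == g_c[None, :]
    return float(((A - np.outer(r, c) / F) * delta).sum() / F)


def _ascend(A, r, c, F, row_lab, col_lab):
    """Label-propagation ascent to a local optimum of Q; mutates labels."""
    n_rows, n_cols = A.shape
    q = _q_from_labels(A, r, c, F, row_lab, col_lab)
    for _ in range(_MAX_SWEEPS):
        # columns adopt the best row label, rows the best column label
        for j in range(n_cols):
            col_lab[j] = _best_label(A[:, j], row_lab, r, c[j], F, col_lab[j])
        for i in range(n_rows):
            row_lab[i] = _best_label(A[i, :], col_lab, c, r[i], F, row_lab[i])
        q_new = _q_from_labels(A, r, c, F, row_lab, col_lab)
        if q_new - q < _SWEEP_TOL:
            break
        q = q_new
    return max(q, q_new)


def _best_label(a, other_lab, other_sums, own_sum, F, current):
    """Label maximizing this node's Q contribution; ties to the lowest id."""
    candidates = np.unique(other_lab[a > 0])
    best_lab, best_score = current, -np.inf
    mask_cur = other_lab == current
    cur_score = a[mask_cur].sum() - own_sum * other_sums[mask_cur].sum() / F
    best_lab, best_score = current, cur_score
    for lab in candidates:
        if lab == current:
            continue
        mask = other_lab == lab
        score = a[mask].sum() - own_sum * other_sums[mask].sum() / F
        if score > best_score + 1e-15 or (
            abs(score - best_score) <= 1e-15 and lab < best_lab
        ):
            best_lab, best_score = lab, score
    return best_lab


def _q_from_labels(A, r, c, F, row_lab, col_lab):
    delta = row_lab[:, None] == col_lab[None, :]
    return float(((A - np.outer(r, c) / F) * delta).sum() / F)


def _merge_modules(A, r, c, F, row_lab, col_lab):
    """Greedy pairwise module merging while it increases Q."""
    while True:
        labels = np.unique(np.concatenate([row_lab, col_lab]))
        if len(labels) <= 1:
            return
        R = {l: r[row_lab == l].sum() for l in labels}
        C = {l: c[col_lab == l].sum() for l in labels}
        W_rc = {}
        for l1 in labels:
            rows = row_lab == l1
            for l2 in labels:
                W_rc[(l1, l2)] = A[np.ix_(rows, col_lab == l2)].sum()
        best = None
        for a_i in range(len(labels)):
            for b_i in range(a_i + 1, len(labels)):
                l1, l2 = labels[a_i], labels[b_i]
                dq = (W_rc[(l1, l2)] + W_rc[(l2, l1)]
                      - (R[l1] * C[l2] + R[l2] * C[l1]) / F) / F
                if dq > 1e-12 and (best is None or dq > best[0]):
                    best = (dq, l1, l2)
        if best is None:
            return
        _, keep, drop = best
        row_lab[row_lab == drop] = keep
        col_lab[col_lab == drop] = keep


def find_modules(
    m: HostMatrix, rng: np.random.Generator, n_restarts: int = 20
) -> ModulePartition:
    """Maximize bipartite modularity by multi-restart label propagation.

    Restart 0 starts from singleton row labels (the deterministic LPAwb+
    start); further restarts use seeded random initial labels.  Each restart
    runs the sweep ascent to a local optimum, then greedy module merging.
    The best partition is returned with canonical module ids (0..k-1 ordered
    by total module weight, ties by smallest member label).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    A = m.weights
    F = m.total_weight
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    n_rows, n_cols = A.shape
    best = None
    for restart in range(n_restarts):
        if restart == 1 and n_restarts > 1:
            # unique labels on the column side (the LPAwb+ start when columns
            # are the smaller set); rows adopt their best column label
            col_lab = np.arange(n_cols)
            row_lab = np.array([
                _best_label(A[i, :], col_lab, c, r[i], F, int(col_lab[np.argmax(A[i, :])]))
                for i in range(n_rows)
            ])
        else:
            if restart == 0:
                row_lab = np.arange(n_rows)
            else:
                k = int(rng.integers(1, max(n_rows, 2)))
                row_lab = rng.integers(0, k + 1, size=n_rows)
            col_lab = np.full(n_cols, -1)
            for j in range(n_cols):
                col_lab[j] = _best_label(A[:, j], row_lab, r, c[j], F, int(row_lab[np.argmax(A[:, j])]))
        # alternate sweep ascent and greedy merging until neither improves
        q = _ascend(A, r, c, F, row_lab, col_lab)
        while True:
            _merge_modules(A, r, c, F, row_lab, col_lab)
            q_new = _ascend(A, r, c, F, row_lab, col_lab)
            if q_new - q < _SWEEP_TOL:
                q = max(q, q_new)
                break
            q = q_new
        if best is None or q > best[0] + 1e-15:
            best = (q, row_lab.copy(), col_lab.copy())
    q, row_lab, col_lab = best
    row_lab, col_lab = _canonical_labels(m, row_lab, col_lab)
    return ModulePartition(row_lab, col_lab, float(q), m.row_labels, m.col_labels)


def _canonical_labels(m: HostMatrix, row_lab, col_lab):
    labels = sorted(set(row_lab) | set(col_lab))
    weight = {}
    member = {}
    for l in labels:
        w = m.weights[row_lab == l, :].sum() + m.weights[:, col_lab == l].sum()
        weight[l] = w
        members = [m.row_labels[i] for i in np.flatnonzero(row_lab == l)]
        members += [m.col_labels[j] for j in np.flatnonzero(col_lab == l)]
        member[l] = min(members) if members else ""
    order = sorted(labels, key=lambda l: (-weight[l], member[l]))
    remap = {l: i for i, l in enumerate(order)}
    return (np.array([remap[l] for l in row_lab]),
            np.array([remap[l] for l in col_lab]))


def assign_module_colors(p: ModulePartition, m: HostMatrix) -> pd.DataFrame:
    """Stable module table ordered by total weight (ties lexicographic).

    Returns one row per non-empty module with columns ``module_id`` (m1,
    m2, ... in weight order), ``total_weight``, ``n_butterflies``,
    ``n_hosts``.  Empty modules are never emitted.
    """
    rows = []
    for l in sorted(set(p.row_modules) | set(p.col_modules)):
        w = (m.weights[p.row_modules == l, :].sum()
             + m.weights[:, p.col_modules == l].sum())
        members = [m.row_labels[i] for i in np.flatnonzero(p.row_modules == l)]
        members += [m.col_labels[j] for j in np.flatnonzero(p.col_modules == l)]
        rows.append({
            "module": l,
            "total_weight": w,
            "first_member": min(members),
            "n_butterflies": int((p.row_modules == l).sum()),
            "n_hosts": int((p.col_modules == l).sum()),
        })
    df = pd.DataFrame(rows).sort_values(
        ["total_weight", "first_member"], ascending=[False, True]
    ).reset_index(drop=True)
    df["module_id"] = [f"m{i + 1}" for i in range(len(df))]
    return df[["module_id", "module", "total_weight", "n_butterflies", "n_hosts"]]
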