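"""Diet breadth classification and host-relatedness null tests.

A butterfly species is a *specialist* if its larvae feed on exactly one host
plant family and a *generalist* if on two or more.  For generalists, the
phylogenetic spread of the host repertoire on a dated plant-family tree is
summarized by patristic-distance metrics (MPD, MNTD, PD, maximum, variance),
and "do generalists eat closely related plants?" is tested per species by
comparing the observed MPD with a null of equally many families resampled
uniformly without replacement from the host pool.  The one-tailed p-value
uses the standard +1 correction, p = (#{null <= observed} + 1) / (N + 1), so
p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import HostMatrix
from .trees import DatedTree

__all__ = [
    "DietProfile",
    "RelatednessTest",
    "classify_diets",
    "host_distance_metrics",
    "generalist_relatedness_test",
    "relatedness_tests",
    "summarize_generalists",
]


@dataclass(frozen=True)
class DietProfile:
    """A species' deduplicated set of host families and its diet class."""

    species: str
    families: frozenset

    @property
    def k(self) -> int:
        return len(self.families)

    @property
    def diet_class(self) -> str:
        return "specialist" if self.k == 1 else "generalist"


@dataclass
class RelatednessTest:
    """Outcome of the per-species host-relatedness resampling test."""

    species: str
    observed_mpd: float
    n_null: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def classify_diets(
    m: HostMatrix, nonplant_groups: Iterable[str] = ()
) -> tuple[list, dict]:
    """Per-species diet profiles plus summary proportions.

    Host groups listed in ``nonplant_groups`` (lichen, Hemiptera, ...) are
    excluded from plant-diet profiles; species left with zero plant families
    are flagged and excluded from the summary.
    """
    nonplant = set(nonplant_groups)
    plant_cols = [j for j, h in enumerate(m.col_labels) if h not in nonplant]
    profiles = []
    excluded = []
    for i, sp in enumerate(m.row_labels):
        fams = frozenset(
            m.col_labels[j] for j in plant_cols if m.weights[i, j] > 0
        )
        if not fams:
            excluded.append(sp)
            continue
        profiles.append(DietProfile(sp, fams))
    n = len(profiles)
    n_spec = sum(1 for p in profiles if p.diet_class == "specialist")
    summary = {
        "n_species": n,
        "n_specialists": n_spec,
        "n_generalists": n - n_spec,
        "prop_specialists": n_spec / n if n else float("nan"),
        "prop_generalists": (n - n_spec) / n if n else float("nan"),
        "excluded_nonplant_only": excluded,
    }
    return profiles, summary


def _matched_families(profile: DietProfile, plant_tree: DatedTree):
    tips = set(plant_tree.tip_labels)
    matched = sorted(profile.families & tips)
    dropped = sorted(profile.families - tips)
    if not matched:
        raise ValueError(
            f"{profile.species}: no host family matches a plant-tree tip"
        )
    return matched, dropped


def host_distance_metrics(
    profile: DietProfile,
    plant_tree: DatedTree,
    include_root: bool = False,
    dist: np.ndarray | None = None,
    dist_labels: Sequence[str] | None = None,
) -> dict:
    """Host-repertoire richness and phylogenetic-distance metrics (Ma).

    Returns richness k, mean pairwise distance (MPD), mean nearest-taxon
    distance (MNTD), phylogenetic diversity (PD: spanning-subtree branch
    length, optionally including the path to the root), the maximum pairwise
    distance and the variance of pairwise distances.  For a single matched
    family the pairwise metrics are undefined and reported as NaN.  Families
    absent from the tree are reported under ``dropped_families``.
    """
    matched, dropped = _matched_families(profile, plant_tree)
    k = len(matched)
    out = {
        "species": profile.species,
        "k": k,
        "diet_class": profile.diet_class,
        "dropped_families": dropped,
        "mpd": np.nan,
        "mntd": np.nan,
        "pd": np.nan,
        "max_pairwise": np.nan,
        "var_pairwise": np.nan,
    }
    out["pd"] = plant_tree.pd_subtree(matched, include_root=include_root)
    if k < 2:
        return out
    if dist is None:
        D, dist_labels = plant_tree.patristic_matrix(matched)
        idx = np.arange(k)
    else:
        pos = {l: i for i, l in enumerate(dist_labels)}
        idx = np.array([pos[f] for f in matched])
        D = dist
    sub = D[np.ix_(idx, idx)]
    pair = sub[np.triu_indices(k, 1)]
    out["mpd"] = float(pair.mean())
    out["mntd"] = float(np.mean([np.min(np.delete(sub[i], i)) for i in range(k)]))
    out["max_pairwise"] = float(pair.max())
    out["var_pairwise"] = float(pair.var())
    return out


def _mpd_from_indices(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    return float(sub[np.triu_indices(len(idx), 1)].mean())


def generalist_relatedness_test(
    profile: DietProfile,
    plant_tree: DatedTree,
    pool: Iterable[str],
    n_null: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    exhaustive: bool = False,
    _pool_dist: np.ndarray | None = None,
    _pool_index: Mapping | None = None,
) -> RelatednessTest:
    """Lower-tail MPD resampling test of host relatedness for one generalist.

    The null draws k families uniformly without replacement from ``pool``
    (N = ``n_null`` draws, or every k-subset when ``exhaustive``); the
    alternative is that the observed families are more closely related
    (smaller MPD) than random.  p = (#{null MPD <= observed} + 1) / (N + 1).
    """
    pool = sorted(set(pool))
    matched, _ = _matched_families(profile, plant_tree)
    k = len(matched)
    if k < 2:
        raise ValueError("relatedness test requires a generalist (k >= 2)")
    missing = set(matched) - set(pool)
    if missing:
        raise ValueError(f"profile families not in pool: {sorted(missing)}")
    if k > len(pool):
        raise ValueError("k exceeds pool size")
    if _pool_dist is None:
        _pool_dist, labels = plant_tree.patristic_matrix(pool)
        _pool_index = {l: i for i, l in enumerate(labels)}
    obs_idx = np.array([_pool_index[f] for f in matched])
    observed = _mpd_from_indices(_pool_dist, obs_idx)
    npool = len(pool)
    if exhaustive:
        null = np.array([
            _mpd_from_indices(_pool_dist, np.array(c))
            for c in combinations(range(npool), k)
        ])
    else:
        if rng is None:
            raise ValueError("rng is required for Monte-Carlo null draws")
        if n_null < 99:
            raise ValueError("n_null must be >= 99")
        # vectorized draws without replacement via per-row argpartition
        keys = rng.random((n_null, npool))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
        iu = np.triu_indices(k, 1)
        null = _pool_dist[picks[:, iu[0]], picks[:, iu[1]]].mean(axis=1)
    n = len(null)
    p = (np.count_nonzero(null <= observed + 1e-12) + 1) / (n + 1)
    return RelatednessTest(profile.species, observed, n, float(p), alpha)


def relatedness_tests(
    profiles: Sequence[DietProfile],
    plant_tree: DatedTree,
    pool: Iterable[str] | None = None,
    n_null: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> list:
    """Run the relatedness test for every generalist profile (shared pool).

    By default the null pool is the set of families observed anywhere in the
    profiles (restricting the null to plausible hosts); pass ``pool``
    explicitly to override.  The pool distance matrix is computed once.
    """
    if pool is None:
        pool = sorted(
            set().union(*(p.families for p in profiles)) & set(plant_tree.tip_labels)
        )
    else:
        pool = sorted(set(pool))
    D, labels = plant_tree.patristic_matrix(pool)
    index = {l: i for i, l in enumerate(labels)}
    out = []
    for p in profiles:
        if len(p.families & set(pool)) < 2:
            continue
        out.append(
            generalist_relatedness_test(
                p, plant_tree, pool, n_null=n_null, rng=rng, alpha=alpha,
                _pool_dist=D, _pool_index=index,
            )
        )
    return out


def summarize_generalists(tests: Sequence[RelatednessTest], alpha: float = 0.05):
    """Fraction of generalists whose hosts are significantly closely related."""
    if not tests:
        raise ValueError("need at least one test")
    flags = [t.p_value <= alpha for t in tests]
    table = pd.DataFrame({
        "species": [t.species for t in tests],
        "observed_mpd": [t.observed_mpd for t in tests],
        "n_null": [t.n_null for t in tests],
        "p_value": [t.p_value for t in tests],
        "significant": flags,
    })
    return float(np.mean(flags)), table
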