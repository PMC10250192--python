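"""Clade-based sampling-fraction arithmetic for diversification models.

State-dependent diversification methods need, for every character state, the
fraction of the state's true global species richness that is present in the
tree.  True richness is not observed; it is estimated by clade-based
proportion arithmetic: a family's share of global richness times the share
of its sampled species in each state, summed over families — e.g. with
19,500 butterfly species globally, a family holding 21.91% of them, and
78.61% of its sampled species specialists, the estimated number of
specialist species in that family is 19,500 x 0.2191 x 0.7861 = 3,359.

For host-module states, genus-level richness is allocated: a genus' total
richness is split equally among the distinct modules its sampled species
belong to (24 species over 3 modules puts 8 in each), and module totals sum
those allocations.  Rounding is half-up and applied only at the final
reported step so intermediate arithmetic never compounds rounding error.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "estimate_state_richness",
    "allocate_genus_to_modules",
    "module_richness_from_genera",
    "family_state_estimates",
    "build_fraction_file",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (3358.5 -> 3359)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def estimate_state_richness(
    total_richness: float, family_proportion: float, state_proportion: float
) -> int:
    """Estimated global species count for one family-state combination.

    ``total_richness * family_proportion * state_proportion`` rounded
    half-up to an integer.
    """
    for p in (family_proportion, state_proportion):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    return round_half_up(total_richness * family_proportion * state_proportion)


def allocate_genus_to_modules(genus_total: float, sampled_module_assignments: Iterable) -> dict:
    """Split a genus' total richness equally over its observed modules.

    ``sampled_module_assignments`` may repeat modules (one entry per sampled
    species); duplicates collapse — the share is per *distinct* module.
    Fractional allocations are returned unrounded and conserve the total.
    """
    modules = sorted(set(sampled_module_assignments), key=str)
    if not modules:
        raise ValueError("no module assignments for genus")
    if genus_total < len(modules):
        raise ValueError("genus total below its number of distinct modules")
    share = genus_total / len(modules)
    return {m: share for m in modules}


def module_richness_from_genera(
    genus_totals: Mapping, genus_modules: Mapping
) -> dict:
    """Estimated richness per module by summing equal-split genus allocations.

    ``genus_totals`` maps genus -> total richness; ``genus_modules`` maps
    genus -> iterable of module assignments of its sampled species.  Module
    totals are rounded half-up only here, at the final step.
    """
    acc: dict = {}
    for genus, total in genus_totals.items():
        if genus not in genus_modules:
            raise KeyError(f"no module assignments for genus {genus!r}")
        for mod, share in allocate_genus_to_modules(total, genus_modules[genus]).items():
            acc[mod] = acc.get(mod, 0.0) + share
    return {m: round_half_up(v) for m, v in sorted(acc.items(), key=lambda kv: str(kv[0]))}


def family_state_estimates(
    total_richness: float, family_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-family, per-state estimated global richness.

    ``family_table`` needs a ``family`` column, a ``family_proportion``
    column, and one ``prop_<state>`` column per state holding the proportion
    of the family's sampled species in that state.  Unrounded estimates are
    returned (one row per family x state) so downstream sums do not compound
    rounding.
    """
    state_cols = [c for c in family_table.columns if c.startswith("prop_")]
    if not state_cols:
        raise ValueError("family_table needs prop_<state> columns")
    rows = []
    for _, rec in family_table.iterrows():
        for col in state_cols:
            rows.append({
                "family": rec["family"],
                "state": col[len("prop_"):],
                "estimated": total_richness * rec["family_proportion"] * rec[col],
            })
    return pd.DataFrame(rows)


def build_fraction_file(
    estimated_totals: Mapping, sampled_counts: Mapping
) -> pd.DataFrame:
    """Per-state sampling-fraction table for diversification software.

    ``estimated_totals`` maps state -> estimated global richness (float or
    int); ``sampled_counts`` maps state -> species sampled in the tree.
    Fractions are ``sampled / round_half_up(estimated)``; a sampled count
    exceeding the estimate is flagged with a warning and the fraction is
    clipped to 1.  Output is sorted by state, so the result is deterministic
    and invariant to input row order.
    """
    states = sorted(set(estimated_totals), key=str)
    missing = set(sampled_counts) - set(states)
    if missing:
        raise KeyError(f"sampled counts for unknown states: {sorted(missing, key=str)}")
    rows = []
    for s in states:
        est = round_half_up(estimated_totals[s])
        samp = int(sampled_counts.get(s, 0))
        if samp > est:
            warnings.warn(
                f"state {s!r}: sampled count {samp} exceeds estimated richness "
                f"{est}; clipping fraction to 1"
            )
            frac = 1.0
        else:
            frac = samp / est if est > 0 else np.nan
        rows.append({
            "state": s,
            "estimated_total": est,
            "sampled": samp,
            "fraction": frac,
        })
    return pd.DataFrame(rows)
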