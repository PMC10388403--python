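"""Urbanization strata, species occupancy groups, and trait summaries.

Patches are stratified by the impervious-surface percentage within 500 m:
low (< 20%), moderate (20-50% inclusive), high (> 50%).  Species are then
partitioned by their presence across strata:

    urban   — present at high urbanization, absent at low
    rural   — present at low, absent at high
    general — present at both high and low
    middle  — present only at moderate urbanization

Presence at moderate levels never moves a species out of urban/rural/general;
it only defines the middle group.  The four groups always partition the
species list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import normalize_taxon_label

__all__ = [
    "LEVELS",
    "GROUPS",
    "TRAITS",
    "HABITS",
    "classify_urbanization",
    "assign_species_groups",
    "summarize_group_traits",
    "reconcile_species",
    "NameMismatchError",
]

LEVELS = ("low", "moderate", "high")
GROUPS = ("urban", "rural", "general", "middle")
HABITS = ("tree", "shrub")

#: the nine functional traits, in canonical report order
TRAITS = (
    "leaf_N",            # leaf nitrogen content, g/kg
    "leaf_C",            # leaf carbon content, g/kg
    "leaf_CN",           # leaf C/N ratio, dimensionless
    "leaf_thickness",    # cm
    "leaf_area",         # cm^2
    "SLA",               # specific leaf area, mm^2/g
    "germination_rate",  # %, potential germination capacity
    "seed_mass",         # g per 1000 grains
    "max_height",        # m, height at maturity
)


class NameMismatchError(ValueError):
    """Species names fail to reconcile across tree and tables."""


def classify_urbanization(impervious_pct: float) -> str:
    """Map an impervious-surface percentage to an urbanization level.

    Boundaries follow the printed ranges literally: low = [0, 20),
    moderate = [20, 50], high = (50, 100].
    """
    p = float(impervious_pct)
    if not (0.0 <= p <= 100.0) or not np.isfinite(p):
        raise ValueError(f"impervious percentage out of [0, 100]: {impervious_pct!r}")
    if p < 20.0:
        return "low"
    if p <= 50.0:
        return "moderate"
    return "high"


def _patch_levels(patches: pd.DataFrame) -> pd.Series:
    if "level" in patches.columns:
        lv = patches.set_index("patch_id")["level"]
        bad = set(lv) - set(LEVELS)
        if bad:
            raise ValueError(f"unknown urbanization levels: {sorted(bad)}")
        return lv
    return patches.set_index("patch_id")["impervious_pct"].map(classify_urbanization)


def assign_species_groups(
    occupancy: pd.DataFrame, patches: pd.DataFrame
) -> pd.DataFrame:
    """Partition species into urban/rural/general/middle occupancy groups.

    Parameters
    ----------
    occupancy:
        Long table with columns ``species``, ``patch_id`` and either
        ``present`` (boolean) or ``count`` (presence = count > 0).
    patches:
        Table with ``patch_id`` and ``impervious_pct`` (or a precomputed
        ``level``) covering every patch id in ``occupancy``.

    Returns a DataFrame with columns ``species`` and ``group``; every species
    appearing in ``occupancy`` with at least one presence is assigned to
    exactly one group.
    """
    occ = occupancy.copy()
    if "present" in occ.columns:
        occ["present"] = occ["present"].astype(bool)
    elif "count" in occ.columns:
        occ["present"] = occ["count"].astype(float) > 0
    else:
        raise ValueError("occupancy table needs a 'present' or 'count' column")

    levels = _patch_levels(patches)
    unknown_patches = set(occ["patch_id"]) - set(levels.index)
    if unknown_patches:
        raise ValueError(f"occupancy references unknown patches: {sorted(unknown_patches)}")
    if set(levels) != set(LEVELS):
        missing = set(LEVELS) - set(levels)
        raise ValueError(f"urbanization levels not all represented: missing {sorted(missing)}")

    occ["level"] = occ["patch_id"].map(levels)
    present = occ[occ["present"]]
    all_species = sorted(set(occ["species"]))
    absent = sorted(set(all_species) - set(present["species"]))
    if absent:
        raise ValueError(f"species with no occupancy anywhere: {absent}")

    by_level = {
        lv: set(present.loc[present["level"] == lv, "species"]) for lv in LEVELS
    }
    high, low, mid = by_level["high"], by_level["low"], by_level["moderate"]

    def group_of(sp: str) -> str:
        at_h, at_l = sp in high, sp in low
        if at_h and at_l:
            return "general"
        if at_h:
            return "urban"
        if at_l:
            return "rural"
        assert sp in mid
        return "middle"

    return pd.DataFrame(
        {"species": all_species, "group": [group_of(s) for s in all_species]}
    )


def summarize_group_traits(
    traits: pd.DataFrame,
    groups: pd.DataFrame,
    habit: str | None = None,
) -> pd.DataFrame:
    """Per-(group, trait) mean, standard error and 95% t-interval.

    Missing trait values are dropped cell-wise (pairwise deletion); each
    cell reports the species count it actually used.  Cells with n = 0 are
    flagged empty; with n = 1 the mean is the single value and SE/CI are
    undefined (NaN, note ``single_species``).
    """
    df = traits.merge(groups, on="species", how="inner")
    if habit is not None:
        if habit not in HABITS:
            raise ValueError(f"unknown habit {habit!r}")
        df = df[df["habit"] == habit]

    rows = []
    for group in GROUPS:
        sub = df[df["group"] == group]
        for trait in TRAITS:
            vals = sub[trait].dropna().to_numpy(dtype=float) if trait in sub else np.array([])
            n = vals.size
            if n == 0:
                rows.append((group, trait, 0, np.nan, np.nan, np.nan, np.nan, "empty"))
                continue
            mean = float(vals.mean())
            if n == 1:
                rows.append((group, trait, 1, mean, np.nan, np.nan, np.nan, "single_species"))
                continue
            se = float(vals.std(ddof=1) / np.sqrt(n))
            tcrit = float(stats.t.ppf(0.975, n - 1))
            rows.append((group, trait, n, mean, se, mean - tcrit * se, mean + tcrit * se, ""))
    return pd.DataFrame(
        rows, columns=["group", "trait", "n", "mean", "se", "ci_low", "ci_high", "note"]
    )


def reconcile_species(
    tree_tips: list[str],
    *tables: pd.DataFrame,
    on_mismatch: str = "error",
) -> list[str]:
    """Cross-check species names between the tree and the data tables.

    Names are normalized (whitespace trimmed, internal spaces to
    underscores) before exact, case-sensitive comparison.  Returns the
    sorted list of species common to the tree and every table.  Species
    appearing somewhere but not everywhere are either a hard error (default,
    with the full offending list) or dropped with the list attached to a
    warning, per ``on_mismatch``.
    """
    if on_mismatch not in ("error", "drop"):
        raise ValueError(f"on_mismatch must be 'error' or 'drop', got {on_mismatch!r}")
    sets = [set(normalize_taxon_label(t) for t in tree_tips)]
    for tab in tables:
        sets.append(set(normalize_taxon_label(s) for s in tab["species"]))
    common = set.intersection(*sets)
    union = set.union(*sets)
    unmatched = sorted(union - common)
    if unmatched:
        msg = (
            f"{len(unmatched)} species do not reconcile across tree and tables: "
            f"{unmatched}"
        )
        if on_mismatch == "error":
            raise NameMismatchError(msg)
        import warnings

        warnings.warn(msg + " (dropped)", stacklevel=2)
    if len(common) < 2:
        raise NameMismatchError("fewer than 2 species reconcile across inputs")
    return sorted(common)
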