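"""Urbanization levels, occupancy groups, trait summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import urbanphylo as up
from urbanphylo.grouping import NameMismatchError, reconcile_species

PATCHES = pd.DataFrame(
    {
        "patch_id": [f"P{i}" for i in range(1, 10)],
        "impervious_pct": [10, 12, 15, 25, 35, 45, 60, 72, 88],
    }
)  # three patches per level


def occ_from_levels(spec: dict[str, set[str]]) -> pd.DataFrame:
    """Build an occupancy table putting each species in the first patch of
    each requested level (low -> P1, moderate -> P4, high -> P7)."""
    first = {"low": "P1", "moderate": "P4", "high": "P7"}
    rows = [
        (sp, first[lv], 1) for sp, lvs in spec.items() for lv in lvs
    ]
    return pd.DataFrame(rows, columns=["species", "patch_id", "count"])


class TestClassifyUrbanization:
    @pytest.mark.parametrize(
        "pct,level",
        [
            (10, "low"), (35, "moderate"), (72, "high"),   # printed ranges
            (0, "low"), (19.999, "low"),
            (20, "moderate"), (50, "moderate"),            # closed boundaries
            (50.001, "high"), (100, "high"),
        ],
    )
    def test_thresholds(self, pct, level):
        assert up.classify_urbanization(pct) == level

    @pytest.mark.parametrize("pct", [-1, 100.5, np.nan])
    def test_out_of_range(self, pct):
        with pytest.raises(ValueError):
            up.classify_urbanization(pct)

    def test_monotone_in_impervious_pct(self):
        order = {"low": 0, "moderate": 1, "high": 2}
        grid = np.linspace(0, 100, 401)
        levels = [order[up.classify_urbanization(p)] for p in grid]
        assert levels == sorted(levels)


class TestAssignSpeciesGroups:
    def test_worked_occupancy_cases(self):
        occ = occ_from_levels(
            {
                "h_only": {"high"},
                "hm": {"high", "moderate"},
                "m_only": {"moderate"},
                "ml": {"moderate", "low"},
                "hl": {"high", "low"},
                "hml": {"high", "moderate", "low"},
            }
        )
        got = up.assign_species_groups(occ, PATCHES).set_index("species")["group"]
        assert got["h_only"] == "urban"
        assert got["hm"] == "urban"
        assert got["m_only"] == "middle"
        assert got["ml"] == "rural"
        assert got["hl"] == "general"
        assert got["hml"] == "general"

    def test_counts_zero_means_absent(self):
        occ = pd.DataFrame(
            [("sp1", "P7", 3), ("sp1", "P1", 0), ("sp2", "P1", 2)],
            columns=["species", "patch_id", "count"],
        )
        got = up.assign_species_groups(occ, PATCHES).set_index("species")["group"]
        assert got["sp1"] == "urban"  # the zero-count low record is no presence
        assert got["sp2"] == "rural"

    def test_species_without_any_presence_is_error(self):
        occ = pd.DataFrame(
            [("sp1", "P1", 1), ("ghost", "P4", 0)],
            columns=["species", "patch_id", "count"],
        )
        with pytest.raises(ValueError, match="ghost"):
            up.assign_species_groups(occ, PATCHES)

    def test_missing_level_is_error(self):
        patches = PATCHES[PATCHES["impervious_pct"] < 50]
        occ = occ_from_levels({"sp1": {"low"}})
        with pytest.raises(ValueError, match="levels"):
            up.assign_species_groups(occ, patches)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.sampled_from(list(PATCHES["patch_id"])), min_size=1),
                    min_size=1, max_size=25))
    def test_groups_always_partition(self, patch_sets):
        rows = [
            (f"sp{i}", p, 1) for i, ps in enumerate(patch_sets) for p in ps
        ]
        occ = pd.DataFrame(rows, columns=["species", "patch_id", "count"])
        groups = up.assign_species_groups(occ, PATCHES)
        assert sorted(groups["species"]) == sorted({f"sp{i}" for i in range(len(patch_sets))})
        assert groups["species"].is_unique  # exactly one group per species
        assert set(groups["group"]) <= set(up.GROUPS)

    def test_only_level_pattern_matters_not_patch_identity(self, rng):
        spec = {f"sp{i}": set() for i in range(30)}
        levels = ["low", "moderate", "high"]
        for sp in spec:
            spec[sp] = set(rng.choice(levels, size=rng.integers(1, 4), replace=False))
        occ1 = occ_from_levels(spec)
        # move every presence to a different patch of the same level
        swap = {"P1": "P3", "P4": "P6", "P7": "P9"}
        occ2 = occ1.assign(patch_id=occ1["patch_id"].map(swap))
        g1 = up.assign_species_groups(occ1, PATCHES).set_index("species")["group"]
        g2 = up.assign_species_groups(occ2, PATCHES).set_index("species")["group"]
        pd.testing.assert_series_equal(g1, g2)


class TestSummaries:
    @staticmethod
    def _traits(values, habit="tree", trait="leaf_N"):
        df = pd.DataFrame({
            "species": [f"sp{i}" for i in range(len(values))],
            "habit": habit,
        })
        for t in up.TRAITS:
            df[t] = np.nan
        df[trait] = values
        return df

    def test_hand_mean_and_se(self):
        traits = self._traits([1.0, 2.0, 3.0])
        groups = pd.DataFrame({"species": traits["species"], "group": "urban"})
        out = up.summarize_group_traits(traits, groups, habit="tree")
        row = out[(out["group"] == "urban") & (out["trait"] == "leaf_N")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(1 / np.sqrt(3))
        assert row["n"] == 3

    def test_single_species_cell_flagged(self):
        traits = self._traits([4.2])
        groups = pd.DataFrame({"species": traits["species"], "group": "rural"})
        out = up.summarize_group_traits(traits, groups)
        row = out[(out["group"] == "rural") & (out["trait"] == "leaf_N")].iloc[0]
        assert row["mean"] == pytest.approx(4.2)
        assert np.isnan(row["se"]) and row["note"] == "single_species"

    def test_empty_cell_flagged_not_raised(self):
        traits = self._traits([1.0, 2.0])
        groups = pd.DataFrame({"species": traits["species"], "group": "urban"})
        out = up.summarize_group_traits(traits, groups)
        row = out[(out["group"] == "middle") & (out["trait"] == "leaf_N")].iloc[0]
        assert row["n"] == 0 and row["note"] == "empty"

    def test_ci_matches_t_interval_oracle(self, rng):
        vals = rng.normal(10, 3, size=30)
        traits = self._traits(vals)
        groups = pd.DataFrame({"species": traits["species"], "group": "general"})
        out = up.summarize_group_traits(traits, groups)
        row = out[(out["group"] == "general") & (out["trait"] == "leaf_N")].iloc[0]
        lo, hi = stats.t.interval(
            0.95, 29, loc=vals.mean(), scale=vals.std(ddof=1) / np.sqrt(30)
        )
        assert row["ci_low"] == pytest.approx(lo)
        assert row["ci_high"] == pytest.approx(hi)


class TestReconcile:
    def test_error_lists_all_offenders(self):
        t1 = pd.DataFrame({"species": ["a", "b", "c"]})
        t2 = pd.DataFrame({"species": ["a", "b", "d"]})
        with pytest.raises(NameMismatchError, match="'c'.*'d'|'d'.*'c'"):
            reconcile_species(["a", "b", "c"], t1, t2)

    def test_drop_mode_warns_and_intersects(self):
        t1 = pd.DataFrame({"species": ["a", "b", "c"]})
        t2 = pd.DataFrame({"species": ["a", "b"]})
        with pytest.warns(UserWarning, match="dropped"):
            got = reconcile_species(["a", "b", "c"], t1, t2, on_mismatch="drop")
        assert got == ["a", "b"]

    def test_normalization_bridges_space_vs_underscore(self):
        t1 = pd.DataFrame({"species": ["Quercus acutissima", " b "]})
        got = reconcile_species(["Quercus_acutissima", "b"], t1)
        assert got == ["Quercus_acutissima", "b"]
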