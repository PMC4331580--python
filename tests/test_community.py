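"""Relative abundance, the exact permutation screen and iron-reducer
filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fesip import community as cm
from fesip.errors import UndefinedRatioError


def small_table(counts, genera, meta=None):
    idx = [f"s{i}" for i in range(len(counts))]
    cdf = pd.DataFrame(counts, index=idx, columns=genera)
    if meta is None:
        meta = pd.DataFrame(
            {"soil": "NF", "amendment": "FER", "isotope": "C13", "fraction": 5},
            index=idx,
        )
    return cm.TaxonTable(cdf, meta)


class TestRelativeAbundance:
    def test_two_genus_percentages(self):
        t = small_table([[30, 70]], ["A", "B"])
        rel = cm.relative_abundance(t)
        assert list(rel.iloc[0]) == [30.0, 70.0]

    def test_single_genus_is_100(self):
        t = small_table([[17]], ["A"])
        assert cm.relative_abundance(t).iloc[0, 0] == 100.0

    def test_rows_sum_to_100(self, taxon_table):
        rel = cm.relative_abundance(taxon_table)
        assert np.allclose(rel.sum(axis=1), 100.0, atol=1e-9)

    def test_zero_count_sample_dropped_with_warning(self):
        t = small_table([[3, 1], [0, 0]], ["A", "B"])
        with pytest.warns(UserWarning, match="zero-count"):
            rel = cm.relative_abundance(t)
        assert list(rel.index) == ["s0"]

    def test_multinomial_table_recovers_proportions(self):
        rng = np.random.default_rng(5)
        p = np.array([0.2, 0.5, 0.3])
        depth = 4000
        counts = rng.multinomial(depth, p, size=6)
        t = small_table(counts, ["A", "B", "C"])
        rel = cm.relative_abundance(t).mean() / 100.0
        se = np.sqrt(p * (1 - p) / (depth * 6))
        assert np.all(np.abs(rel.values - p) < 4 * se)


def bitmask_pvalue(labeled, unlabeled):
    """Brute-force oracle: enumerate group assignments via bitmasks."""
    pooled = list(labeled) + list(unlabeled)
    n, k = len(pooled), len(labeled)
    obs = np.mean(labeled) - np.mean(unlabeled)
    hits = total = 0
    for mask in range(2 ** n):
        if bin(mask).count("1") != k:
            continue
        grp = [pooled[i] for i in range(n) if mask >> i & 1]
        rest = [pooled[i] for i in range(n) if not mask >> i & 1]
        total += 1
        if np.mean(grp) - np.mean(rest) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestPermutationScreen:
    @pytest.mark.parametrize("labeled, unlabeled", [
        ((30.0, 32.0, 31.0), (2.0, 3.0, 2.0)),
        ((5.0, 1.0, 3.0), (2.0, 4.0, 3.5)),
        ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
        ((2.0, 9.0, 4.0, 4.0), (3.0, 3.0, 8.0)),
    ])
    def test_exact_pvalue_matches_enumeration(self, labeled, unlabeled):
        ours = cm.permutation_pvalue_one_sided(
            np.array(labeled), np.array(unlabeled)
        )
        assert ours == pytest.approx(bitmask_pvalue(labeled, unlabeled))

    def test_clear_separation_is_minimal_p(self):
        res = cm.assimilator_screen([30.0, 32.0, 31.0], [2.0, 3.0, 2.0])
        assert res.p_value == pytest.approx(1 / 20)
        assert res.assimilator

    def test_identical_groups_p_one(self):
        res = cm.assimilator_screen([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0
        assert not res.assimilator

    def test_alpha_zero_never_flags(self):
        res = cm.assimilator_screen([30.0, 32.0, 31.0], [2.0, 3.0, 2.0],
                                    alpha=0.0)
        assert not res.assimilator

    def test_alpha_one_flags_any_higher_mean(self):
        up = cm.assimilator_screen([3.0, 4.0, 5.0], [3.0, 4.0, 4.0], alpha=1.0)
        down = cm.assimilator_screen([3.0, 4.0, 4.0], [3.0, 4.0, 5.0], alpha=1.0)
        assert up.assimilator
        assert not down.assimilator

    def test_type_one_error_controlled_under_null(self):
        """Null genera (same distribution in both groups) are flagged at a
        rate no more than alpha + 2·SE."""
        rng = np.random.default_rng(123)
        alpha, n_sim = 0.05, 1000
        flags = 0
        for _ in range(n_sim):
            vals = rng.normal(5.0, 1.0, 6)
            res = cm.assimilator_screen(vals[:3], vals[3:], alpha=alpha)
            flags += res.assimilator
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert flags / n_sim <= alpha + 2 * se


class TestChangeMetrics:
    @pytest.mark.parametrize("treat, ctrl, expected", [
        (31.0, 2.4, 28.6), (5.0, 5.0, 0.0), (0.0, 5.0, -5.0),
    ])
    def test_net_change(self, treat, ctrl, expected):
        assert cm.net_change(treat, ctrl) == pytest.approx(expected)

    def test_fold_change_examples(self):
        assert cm.fold_change(31.0, 2.4) == pytest.approx(12.9, abs=0.05)
        assert cm.fold_change(5.0, 5.0) == 1.0

    def test_zero_control_requires_pseudocount(self):
        with pytest.raises(UndefinedRatioError):
            cm.fold_change(5.0, 0.0)
        assert cm.fold_change(5.0, 0.0, pseudo_count=0.5) == 10.0

    @given(treat=st.floats(0, 100), ctrl=st.floats(0.01, 100))
    @settings(max_examples=50, derandomize=True)
    def test_net_and_fold_are_consistent(self, treat, ctrl):
        net = cm.net_change(treat, ctrl)
        fold = cm.fold_change(treat, ctrl)
        assert net == pytest.approx(ctrl * (fold - 1.0), abs=1e-9)


class TestIronReducerFilter:
    def test_simple_intersection(self):
        t = small_table([[5, 7]], ["Geobacter", "Methanosarcina"])
        ref = cm.IronReducerReference(genera={"Geobacter": "review"})
        sub = cm.filter_iron_reducers(t, ref)
        assert sub.genera == ["Geobacter"]
        assert sub.counts.iloc[0, 0] == 5  # counts untouched

    def test_default_reference_keeps_the_eleven_field_genera(self):
        field_genera = [
            "Geobacter", "Geothrix", "Desulfobulbus", "Clostridium",
            "Anaeromyxobacter", "Desulfovibrio", "Desulfosporosinus",
            "Dechloromonas", "Pseudomonas", "Desulfitobacterium",
            "Acidiphilium",
        ]
        extras = ["Methanosarcina", "Bacillus", "Solibacillus", "other"]
        t = small_table(
            [list(range(1, len(field_genera + extras) + 1))],
            field_genera + extras,
        )
        sub = cm.filter_iron_reducers(t)
        assert sorted(sub.genera) == sorted(field_genera)

    def test_empty_intersection_warns(self):
        t = small_table([[4, 6]], ["Methanosarcina", "other"])
        with pytest.warns(UserWarning, match="no reference"):
            sub = cm.filter_iron_reducers(t)
        assert sub.genera == []


class TestScreenTable:
    def test_screen_flags_enriched_genera(self, taxon_table):
        scr = cm.screen_table(taxon_table, "FER", "NF")
        assert scr.loc["Geobacter", "assimilator"]
        assert scr.loc["Geobacter", "p_value"] <= 0.05

    def test_top_n_restricts_screen(self, taxon_table):
        scr = cm.screen_table(taxon_table, "FER", "NF", top_n=3)
        assert len(scr) == 3

    def test_fdr_toggle_adds_adjusted_column(self, taxon_table):
        scr = cm.screen_table(taxon_table, "FER", "NF", fdr=True)
        assert "p_adjusted" in scr.columns
        assert (scr["p_adjusted"] >= scr["p_value"] - 1e-12).all()

    def test_treatment_effects_recover_generator_enrichment(self, taxon_table):
        eff = cm.treatment_effects(taxon_table, "NF")
        # Geobacter configured at 13x under FER; multinomial sampling error
        assert eff.loc["Geobacter", "fold_change_fer"] == pytest.approx(
            13.0, rel=0.15
        )
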