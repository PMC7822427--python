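"""ANOVA, Tukey HSD, compact letter displays and the trait screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootstress.datasets import PlantDataset
from rootstress.synthetic import FixtureCollection, SyntheticConfig, TraitSpec, generate_dataset
from rootstress.univariate import (DegenerateVarianceError, compact_letter_display,
                                   one_way_anova, percent_change, trait_screen,
                                   tukey_hsd)


class TestOneWayAnova:
    def test_hand_computed_f(self):
        r = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert r.F == pytest.approx(3.0)
        assert (r.df_between, r.df_within) == (2, 6)

    def test_zero_between_variance(self):
        r = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.F == pytest.approx(0.0)

    def test_separated_groups_tiny_p(self, rng):
        g1 = 0.0 + 1e-6 * rng.normal(size=4)
        g2 = 10.0 + 1e-6 * rng.normal(size=4)
        assert one_way_anova([g1, g2]).p < 0.001

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateVarianceError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])


class TestTukey:
    def test_well_separated_all_significant(self, rng):
        groups = [c + 0.01 * rng.normal(size=5) for c in (0.0, 10.0, 20.0)]
        t = tukey_hsd(groups)
        assert t["significant"].all()

    def test_identical_means_none_significant(self, rng):
        noise = rng.normal(size=5)
        t = tukey_hsd([noise, noise + 1e-9, noise - 1e-9])
        assert not t["significant"].any()

    def test_conservative_vs_t_test(self, rng):
        """Tukey adjusted p >= unadjusted pairwise t-test p on the same data."""
        groups = [rng.normal(loc=m, size=6) for m in (0.0, 0.5, 1.0, 1.5)]
        t = tukey_hsd(groups, labels=["a", "b", "c", "d"])
        idx = {lbl: g for lbl, g in zip("abcd", groups)}
        for row in t.itertuples():
            p_t = stats.ttest_ind(idx[row.group_a], idx[row.group_b]).pvalue
            assert row.p >= p_t - 1e-12

    def test_table_calibrated_rlr_contrasts(self):
        """At the published primary-root RLR means/SDs, drought and
        combined stress each separate from the control."""
        rng = np.random.default_rng(42)
        means, ses = [63, 123, 83, 117], [4, 12, 2, 15]
        groups = [rng.normal(m, se * 2, size=4) for m, se in zip(means, ses)]
        t = tukey_hsd(groups, labels=["Control", "Drought", "Heat", "Combined"])
        t = t.set_index(t["group_a"] + "|" + t["group_b"])
        assert t.loc["Control|Drought", "significant"]
        assert t.loc["Control|Combined", "significant"]


def _pairwise(sig_pairs, all_labels):
    rows = []
    from itertools import combinations
    for a, b in combinations(all_labels, 2):
        sig = (a, b) in sig_pairs or (b, a) in sig_pairs
        rows.append({"group_a": a, "group_b": b, "diff": 0.0,
                     "p": 0.01 if sig else 0.5, "significant": sig})
    return pd.DataFrame(rows)


class TestCompactLetterDisplay:
    def test_forced_pattern(self):
        cld = compact_letter_display(_pairwise({("A", "B"), ("A", "C")}, "ABC"))
        assert cld == {"A": "a", "B": "b", "C": "b"}

    def test_no_significance_single_letter(self):
        cld = compact_letter_display(_pairwise(set(), "ABC"))
        assert set(cld.values()) == {"a"}

    def test_chain_pattern(self):
        cld = compact_letter_display(_pairwise({("A", "C")}, "ABC"))
        assert cld == {"A": "a", "B": "a,b", "C": "b"}

    def test_all_pairs_distinct(self):
        pairs = {("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
                 ("C", "D")}
        cld = compact_letter_display(_pairwise(pairs, "ABCD"))
        assert len(set(cld.values())) == 4

    def test_largest_mean_gets_a(self):
        cld = compact_letter_display(
            _pairwise({("A", "B")}, "AB"), means={"A": 1.0, "B": 5.0})
        assert cld == {"B": "a", "A": "b"}

    @pytest.mark.parametrize("sig_pairs", [
        set(), {("A", "B")}, {("A", "C")}, {("A", "B"), ("A", "C")},
        {("A", "B"), ("A", "C"), ("B", "C")}, {("A", "B"), ("C", "D")},
        {("A", "D"), ("B", "D")},
    ])
    def test_roundtrip_significance_relation(self, sig_pairs):
        """Sharing a letter <=> not significantly different."""
        labels = "ABCD"
        pw = _pairwise(sig_pairs, labels)
        cld = compact_letter_display(pw)
        for row in pw.itertuples():
            share = bool(set(cld[row.group_a].split(","))
                         & set(cld[row.group_b].split(",")))
            assert share == (not row.significant)


class TestTraitScreen:
    def test_zero_noise_distinct_means_all_significant(self):
        specs = FixtureCollection([
            TraitSpec("primary", "length", t, mean=m, se=0.0)
            for t, m in zip(("Control", "Drought", "Heat", "Combined"),
                            (50, 60, 70, 80))
        ])
        # exact-zero noise is degenerate for ANOVA; add a whisper
        ds = generate_dataset(SyntheticConfig(seed=6, specs=specs))
        traits = ds.traits.copy()
        traits["value"] += np.random.default_rng(0).normal(0, 1e-6, len(traits))
        screen = trait_screen(PlantDataset(traits=traits))
        assert screen["anova_significant"].all()
        assert screen["differs_from_control"].all()

    def test_screen_shape_and_flags(self, trait_dataset):
        screen = trait_screen(trait_dataset)
        assert len(screen) == 42
        assert {"F", "p", "differs_from_control"} <= set(screen.columns)
        assert screen["Control_letters"].str.len().ge(1).all()

    def test_table_calibrated_rlr_letters(self):
        """Across replicate seeds the primary-lateral RLR letters mostly
        reproduce the published ordering: combined alone at the top,
        control alone at the bottom."""
        hits = 0
        n_seeds = 20
        specs = FixtureCollection([
            TraitSpec("primary_lateral", "RLR", t, mean=m, se=se)
            for t, m, se in zip(("Control", "Drought", "Heat", "Combined"),
                                (736, 1195, 1125, 1650), (41, 63, 75, 90))
        ])
        for seed in range(n_seeds):
            ds = generate_dataset(SyntheticConfig(seed=seed, specs=specs))
            row = trait_screen(ds).iloc[0]
            letters = {t: set(row[f"{t}_letters"].split(","))
                       for t in ("Control", "Drought", "Heat", "Combined")}
            combined_top = letters["Combined"] == {"a"} and all(
                "a" not in letters[t] for t in ("Control", "Drought", "Heat"))
            control_apart = not (letters["Control"]
                                 & (letters["Drought"] | letters["Heat"]
                                    | letters["Combined"]))
            hits += combined_top and control_apart
        assert hits >= n_seeds // 2


def test_percent_change_from_fixtures(fixtures):
    pc = percent_change(fixtures.to_frame(), "Combined")
    pl = pc[pc["root_type"] == "primary_lateral"].set_index("trait")
    assert round(pl.loc["RLR", "percent_change"]) == 124
    assert round(pl.loc["fineness", "percent_change"]) == 43
    assert round(pl.loc["average_length", "percent_change"]) == 57
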