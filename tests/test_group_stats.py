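"""Wilcoxon, bootstrap CI, and ANOVA machinery against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortistri import (
    CohortConfig,
    UndefinedResultError,
    ValidationError,
    behavior_category_anova,
    bootstrap_median_diff,
    exploration_summary,
    gen_cohort,
    mixed_anova,
    normality_screen,
    oneway_anova,
    wilcoxon_signed_rank,
)


class TestWilcoxon:
    def test_six_same_sign_differences_reproduce_reference_values(self):
        rep = wilcoxon_signed_rank([3.1, 5.2, 6.3, 7.4, 9.1, 12.5])
        assert round(rep.Z, 3) == 2.201
        assert round(rep.r, 2) == 0.64
        assert rep.W == 21.0 and rep.n_pairs == 6

    def test_sign_balanced_differences_give_zero_z(self):
        rep = wilcoxon_signed_rank([2.0, -2.0, 5.0, -5.0])
        assert rep.Z == pytest.approx(0.0)

    def test_antisymmetric_under_sign_flip(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.normal(0.5, 1.0, 10)
            assert wilcoxon_signed_rank(-d).Z == pytest.approx(
                -wilcoxon_signed_rank(d).Z
            )

    def test_zero_differences_dropped_before_ranking(self):
        rep = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -0.5])
        assert rep.n_pairs == 3

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(UndefinedResultError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 12)
            mine = wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(
                d, correction=False, method="approx", alternative="two-sided"
            )
            assert abs(mine.Z) == pytest.approx(abs(ref.zstatistic))
            assert mine.p == pytest.approx(ref.pvalue)

    def test_normal_p_close_to_exact_enumeration_at_n8(self):
        # the approximation without continuity correction estimates the
        # mid-p of the discrete exact distribution
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, 8)
            rep = wilcoxon_signed_rank(d)
            ranks = stats.rankdata(np.abs(d))
            obs = abs(np.sum(ranks[d > 0]) - 18.0)  # |W - n(n+1)/4|
            devs = [
                abs(sum(r for r, s in zip(ranks, signs) if s) - 18.0)
                for signs in itertools.product([0, 1], repeat=8)
            ]
            n_gt = sum(dev > obs + 1e-9 for dev in devs)
            n_eq = sum(abs(dev - obs) <= 1e-9 for dev in devs)
            p_mid = (n_gt + 0.5 * n_eq) / 2**8
            assert abs(rep.p - p_mid) < 0.05

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            rep = wilcoxon_signed_rank(rng.normal(0, 1, 15))
            assert 0.0 <= rep.p <= 1.0
            assert abs(rep.r) <= 1.0


class TestBootstrapMedianDiff:
    def test_identical_constant_groups_give_degenerate_zero_ci(self):
        ci = bootstrap_median_diff([2.0] * 6, [2.0] * 6, seed=0)
        assert ci.estimate == 0.0
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_reproducible_with_same_seed(self):
        rng = np.random.default_rng(4)
        s, p = rng.normal(6, 2, 6), rng.normal(0.5, 2, 6)
        a = bootstrap_median_diff(s, p, seed=11)
        b = bootstrap_median_diff(s, p, seed=11)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_single_animal_group_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_median_diff([1.0], [1.0, 2.0])

    def test_percentile_and_bca_bracket_the_estimate(self):
        rng = np.random.default_rng(5)
        s, p = rng.normal(6, 2, 8), rng.normal(0.5, 2, 8)
        for method in ("bca", "percentile"):
            ci = bootstrap_median_diff(s, p, seed=1, method=method)
            assert ci.lower <= ci.estimate <= ci.upper

    def test_ci_width_shrinks_with_group_size(self):
        rng = np.random.default_rng(6)
        widths = []
        for n in (6, 24, 96):
            w = []
            for rep in range(10):
                s, p = rng.normal(6, 2, n), rng.normal(0.5, 2, n)
                ci = bootstrap_median_diff(s, p, seed=rep)
                w.append(ci.upper - ci.lower)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_saline_only_novelty_preference_detected_on_cohorts(self):
        hits = 0
        for seed in range(20):
            sessions, _ = gen_cohort(CohortConfig(seed=seed))
            diffs = {"saline": [], "pcp": []}
            for s in sessions:
                tot = {
                    e.object_role: e.total_seconds
                    for e in exploration_summary(s.contacts, s.animal_id)
                    if e.trial == "retention"
                }
                diffs[s.group].append(tot["novel"] - tot["familiar"])
            ci = bootstrap_median_diff(diffs["saline"], diffs["pcp"], seed=seed)
            hits += ci.lower > 0
        assert hits >= 15


class TestOnewayAnova:
    def test_equal_means_give_zero_f(self):
        rep = oneway_anova([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["a"] * 3 + ["b"] * 3)
        assert rep.effects[0].F == 0.0

    def test_f_equals_squared_pooled_t_for_two_groups(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1.2, 12)
            rep = oneway_anova(
                np.concatenate([a, b]), ["a"] * 15 + ["b"] * 12
            )
            t, _ = stats.ttest_ind(a, b)
            assert rep.effects[0].F == pytest.approx(t**2)

    def test_39_units_in_two_groups_give_df_1_37(self):
        rng = np.random.default_rng(8)
        rep = oneway_anova(rng.normal(size=39), ["a"] * 20 + ["b"] * 19)
        e = rep.effects[0]
        assert (e.df1, e.df2) == (1, 37)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        a, b, c = rng.normal(0, 1, 10), rng.normal(1, 1, 12), rng.normal(2, 1, 9)
        rep = oneway_anova(
            np.concatenate([a, b, c]), ["a"] * 10 + ["b"] * 12 + ["c"] * 9
        )
        f, p = stats.f_oneway(a, b, c)
        assert rep.effects[0].F == pytest.approx(f)
        assert rep.effects[0].p == pytest.approx(p)


def _mixed_table(rng, n_a=6, n_b=6, interaction=0.0):
    rows = []
    for i in range(n_a + n_b):
        g = "a" if i < n_a else "b"
        base = rng.normal()
        for w in ("mPFC", "NAc"):
            val = base + rng.normal()
            if g == "a" and w == "NAc":
                val += interaction
            rows.append(
                {"animal": f"r{i}", "group": g, "structure": w, "value": val}
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    @pytest.mark.parametrize("n_b", [6, 7])
    def test_matches_pingouin_reference(self, n_b):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10 + n_b)
        df = _mixed_table(rng, 6, n_b, interaction=0.8)
        rep = mixed_anova(df, posthoc=False)
        ref = pg.mixed_anova(
            df, dv="value", within="structure", subject="animal", between="group"
        ).set_index("Source")
        for term, ref_name in [
            ("group", "group"),
            ("structure", "structure"),
            ("group*structure", "Interaction"),
        ]:
            e = rep.effect(term)
            assert e.F == pytest.approx(float(ref.loc[ref_name, "F"]), rel=1e-9)
            assert (e.df1, e.df2) == (
                int(ref.loc[ref_name, "DF1"]),
                int(ref.loc[ref_name, "DF2"]),
            )

    def test_constant_table_gives_zero_f(self):
        df = _mixed_table(np.random.default_rng(0))
        df["value"] = 3.0
        rep = mixed_anova(df, posthoc=False)
        assert all(e.F == 0.0 for e in rep.effects)

    def test_missing_cell_error_names_the_animal(self):
        df = _mixed_table(np.random.default_rng(1))
        df = df[~((df["animal"] == "r3") & (df["structure"] == "NAc"))]
        with pytest.raises(ValidationError, match="r3"):
            mixed_anova(df)

    def test_interaction_power_at_large_effect(self):
        rng = np.random.default_rng(12)
        detected = 0
        for _ in range(50):
            rep = mixed_anova(_mixed_table(rng, interaction=4.0), posthoc=False)
            detected += rep.effect("group*structure").p < 0.05
        assert detected >= 45

    def test_lsd_posthoc_flags_the_affected_structure(self):
        rng = np.random.default_rng(13)
        rep = mixed_anova(_mixed_table(rng, interaction=3.0))
        by_desc = {c.description: c for c in rep.posthoc}
        assert by_desc["a vs b at structure=NAc"].p < 0.01
        assert all(0.0 <= c.p <= 1.0 for c in rep.posthoc)

    def test_report_serializes_losslessly(self):
        rng = np.random.default_rng(14)
        rep = mixed_anova(_mixed_table(rng))
        d = rep.to_dict()
        assert {e["term"] for e in d["effects"]} == {
            "group", "structure", "group*structure"
        }
        assert all(0.0 <= e["p"] <= 1.0 for e in d["effects"])


def _behavior_table(rng, n=12, object_effect=0.0, single_group=False):
    rows = []
    for i in range(n):
        g = "g" if single_group else ("a" if i < n // 2 else "b")
        base = rng.normal()
        for beh in ("sniff", "touch", "approach"):
            for obj in ("familiar", "novel"):
                val = base + rng.normal()
                if obj == "novel":
                    val += object_effect
                rows.append(
                    {
                        "animal": f"r{i}", "group": g, "behavior": beh,
                        "object": obj, "seconds": val,
                    }
                )
    return pd.DataFrame(rows)


class TestBehaviorCategoryAnova:
    def test_matches_statsmodels_anovarm_for_within_effects(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(15)
        df = _behavior_table(rng, n=8, object_effect=0.5, single_group=True)
        rep = behavior_category_anova(df)
        ref = AnovaRM(df, "seconds", "animal", within=["behavior", "object"]).fit()
        tab = ref.anova_table
        for term, ref_name in [
            ("behavior", "behavior"),
            ("object", "object"),
            ("behavior*object", "behavior:object"),
        ]:
            e = rep.effect(term)
            assert e.F == pytest.approx(float(tab.loc[ref_name, "F Value"]), rel=1e-9)
            assert (e.df1, e.df2) == (
                int(tab.loc[ref_name, "Num DF"]),
                int(tab.loc[ref_name, "Den DF"]),
            )

    def test_constant_table_gives_all_zero_f(self):
        df = _behavior_table(np.random.default_rng(16))
        df["seconds"] = 1.0
        rep = behavior_category_anova(df)
        assert all(e.F == 0.0 for e in rep.effects)

    def test_object_main_effect_detected_at_large_effect(self):
        rng = np.random.default_rng(17)
        detected = 0
        for _ in range(20):
            rep = behavior_category_anova(_behavior_table(rng, object_effect=2.0))
            detected += rep.effect("object").p < 0.05
        assert detected >= 18

    def test_null_table_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(18)
        rej = 0
        n_sims = 400
        for _ in range(n_sims):
            rep = behavior_category_anova(_behavior_table(rng))
            rej += rep.effect("group*object").p < 0.05
        assert 0.02 <= rej / n_sims <= 0.09

    def test_incomplete_table_rejected(self):
        df = _behavior_table(np.random.default_rng(19))
        df = df.iloc[:-1]
        with pytest.raises(ValidationError, match="r11"):
            behavior_category_anova(df)


class TestNormalityScreen:
    def test_gaussian_sample_passes(self):
        rng = np.random.default_rng(20)
        out = normality_screen(rng.normal(size=200))
        assert out["normal"] and 0 < out["W"] <= 1

    def test_heavy_skew_fails(self):
        rng = np.random.default_rng(21)
        out = normality_screen(rng.lognormal(0, 1.5, 200))
        assert not out["normal"]
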