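"""Statistics: summaries, ANOVA vs a hand-computed oracle, correlation,
assumption checks, multiplicity corrections."""

import numpy as np
import pandas as pd
import pytest

import frlquant as fq
from frlquant.quantify import build_table
from frlquant.stats import (
    assumption_checks,
    bonferroni,
    holm_sidak,
    pearson_count_area,
    summarize,
    two_way_anova,
)


def _table(rows):
    df = pd.DataFrame(rows)
    if "included" not in df:
        df["included"] = True
    return df


def balanced_anova_oracle(y, a, b):
    """Closed-form two-way ANOVA sums of squares for a balanced design.

    Classical textbook decomposition: SS_A = n_b * r * sum_a (mean_a -
    grand)^2, etc.  Valid only when every cell has the same count, where
    Type II and Type I/III all coincide.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    lev_a, lev_b = np.unique(a), np.unique(b)
    r = len(y) / (len(lev_a) * len(lev_b))
    ss_a = r * len(lev_b) * sum((y[a == la].mean() - grand) ** 2 for la in lev_a)
    ss_b = r * len(lev_a) * sum((y[b == lb].mean() - grand) ** 2 for lb in lev_b)
    ss_cells = r * sum(
        (y[(a == la) & (b == lb)].mean() - grand) ** 2
        for la in lev_a
        for lb in lev_b
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cells
    df_a, df_b = len(lev_a) - 1, len(lev_b) - 1
    df_ab = df_a * df_b
    df_err = len(y) - len(lev_a) * len(lev_b)
    ms_err = ss_err / df_err
    return {
        "A": (ss_a, ss_a / df_a / ms_err),
        "B": (ss_b, ss_b / df_b / ms_err),
        "AB": (ss_ab, ss_ab / df_ab / ms_err),
        "err": (ss_err, np.nan),
    }


class TestSummarize:
    def test_single_synapse(self):
        t = _table(
            [
                dict(scene_id=0, genotype="WT", age_months=12, compartment="spine",
                     animal_id=0, n_ampar=7, area_um2=0.02, density_per_um2=350.0)
            ]
        )
        s = summarize(t)
        assert len(s) == 1
        row = s.iloc[0]
        assert row.count_median == 7
        assert (row.count_min, row.count_max) == (7, 7)
        assert np.isnan(row.density_sem)

    def test_permutation_invariance(self, wt12_scenes):
        t = build_table(wt12_scenes)
        s1 = summarize(t)
        s2 = summarize(t.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(s1, s2)

    def test_wt12_spine_median_near_published(self, wt12_scenes):
        """At the study's n the WT 12-month spine count median lands within
        +/-2 of the published median of 19."""
        s = summarize(build_table(wt12_scenes))
        assert abs(s.iloc[0].count_median - 19) <= 2


class TestPearson:
    def test_perfect_positive(self):
        t = _table(
            [
                dict(n_ampar=c, area_um2=2.0 * c, genotype="WT", age_months=12,
                     compartment="spine", animal_id=0, scene_id=i, density_per_um2=1.0)
                for i, c in enumerate([1, 2, 3])
            ]
        )
        r, p = pearson_count_area(t)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        t = _table(
            [
                dict(n_ampar=c, area_um2=-1.0 * c + 10, genotype="WT", age_months=12,
                     compartment="spine", animal_id=0, scene_id=i, density_per_um2=1.0)
                for i, c in enumerate([1, 2, 3, 4])
            ]
        )
        r, _ = pearson_count_area(t)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        t = _table(
            [
                dict(n_ampar=5, area_um2=0.02 * (i + 1), genotype="WT", age_months=12,
                     compartment="spine", animal_id=0, scene_id=i, density_per_um2=1.0)
                for i in range(5)
            ]
        )
        with pytest.raises(ValueError):
            pearson_count_area(t)

    def test_generated_wt12_in_expected_band(self, wt12_scenes):
        r, p = pearson_count_area(build_table(wt12_scenes))
        assert 0.55 <= r <= 0.85
        assert p < 1e-4


class TestTwoWayAnova:
    def _toy(self, rng, effect=0.0, n=8):
        rows = []
        for geno in ["WT", "APP_PS1"]:
            for comp in ["spine", "interneuron_shaft"]:
                mu = 100 + (effect if geno == "WT" else 0) + (10 if comp == "spine" else 0)
                for i in range(n):
                    rows.append(
                        dict(genotype=geno, compartment=comp, age_months=12,
                             density_per_um2=mu + rng.normal(0, 5),
                             n_ampar=1, area_um2=1, animal_id=0, scene_id=i)
                    )
        return _table(rows)

    def test_balanced_matches_hand_computed_ss(self, rng):
        """On a balanced design the fitted decomposition reproduces the
        classical closed-form sums of squares to 1e-10 relative."""
        t = self._toy(rng, effect=20.0)
        rep = two_way_anova(t)
        oracle = balanced_anova_oracle(
            t.density_per_um2, t.genotype, t.compartment
        )
        assert rep.table.loc["C(genotype)", "sum_sq"] == pytest.approx(
            oracle["A"][0], rel=1e-10
        )
        assert rep.table.loc["C(compartment)", "sum_sq"] == pytest.approx(
            oracle["B"][0], rel=1e-10
        )
        assert rep.table.loc["C(genotype):C(compartment)", "sum_sq"] == pytest.approx(
            oracle["AB"][0], rel=1e-10
        )
        assert rep.table.loc["C(genotype)", "F"] == pytest.approx(
            oracle["A"][1], rel=1e-10
        )

    def test_df_add_up(self, rng):
        t = self._toy(rng)
        rep = two_way_anova(t)
        assert rep.table["df"].sum() == len(t) - 1

    def test_identical_genotypes_give_null_p(self, rng):
        t = self._toy(rng, effect=0.0)
        # make the two genotype groups literally identical
        wt = t[t.genotype == "WT"].copy()
        app = wt.copy()
        app["genotype"] = "APP_PS1"
        rep = two_way_anova(pd.concat([wt, app], ignore_index=True))
        assert rep.p_genotype > 0.999

    def test_empty_cell_raises_naming_cell(self, rng):
        t = self._toy(rng)
        t = t[~((t.genotype == "WT") & (t.compartment == "spine"))]
        with pytest.raises(ValueError, match="spine"):
            two_way_anova(t)

    def test_posthoc_bonferroni_not_smaller_than_raw(self, rng):
        rep = two_way_anova(self._toy(rng, effect=10.0))
        assert (rep.posthoc.p_bonferroni >= rep.posthoc.p_raw - 1e-15).all()

    def test_power_at_study_scale(self):
        """At the published 12-month group means, spreads and sample sizes
        the genotype effect is overwhelming (p < 1e-4 across seeds)."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            frames = []
            for key, n in [
                (("WT", 12, "spine"), 111),
                (("APP_PS1", 12, "spine"), 109),
                (("WT", 12, "interneuron_shaft"), 135),
                (("APP_PS1", 12, "interneuron_shaft"), 173),
            ]:
                scenes = fq.generate_dataset(fq.make_preset(*key), n, rng)
                frames.append(build_table(scenes))
            rep = two_way_anova(pd.concat(frames, ignore_index=True), age_months=12)
            assert rep.p_genotype < 1e-4


class TestAssumptionChecks:
    def test_levene_alpha_behavior(self):
        """Equal-variance normal samples: Levene rejects in <= 10% of 100
        seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rep = assumption_checks(
                {"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50)}
            )
            hits += rep.levene_p > 0.05
        assert hits >= 90

    def test_shapiro_power_on_exponential(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rep = assumption_checks(
                {"e": rng.exponential(1.0, 200), "n": rng.normal(0, 1, 200)}
            )
            p = rep.shapiro.set_index("group").loc["e", "p"]
            hits += p < 0.05
        assert hits >= 90

    def test_small_group_skipped_with_note(self):
        rep = assumption_checks({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})
        assert any("n < 3" in n for n in rep.notes)

    def test_constant_group_noted(self):
        rep = assumption_checks({"a": [2.0] * 10, "b": [1.0, 2.0, 3.0, 4.0]})
        assert any("constant" in n for n in rep.notes)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            assumption_checks({"a": [1.0, 2.0, 3.0]})


class TestHolmSidak:
    def test_hand_computed_pair(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)  # 0.0199
        assert adj[1] == pytest.approx(0.04)

    def test_single_p_unchanged(self):
        assert holm_sidak([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(holm_sidak([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_raw_order(self, rng):
        p = rng.random(10)
        adj = holm_sidak(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            holm_sidak([0.1, 1.2])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(7)
        adj = holm_sidak(p)
        _, adj_sm, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(adj, adj_sm)


def test_bonferroni_floor():
    p = np.array([0.01, 0.2, 0.9])
    adj = bonferroni(p)
    assert np.all(adj >= p)
    assert np.allclose(adj, [0.03, 0.6, 1.0])
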