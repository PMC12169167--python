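import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from helpers import anova2_oracle, anova3_oracle
from tendonmech.stats import (
    bonferroni_posthoc,
    mann_whitney_u,
    mixed_anova_2way,
    mixed_anova_2way_arrays,
    mixed_anova_3way,
    mixed_anova_3way_arrays,
    pearson_r,
    student_t_independent,
    wilcoxon_signed_rank,
)
from tendonmech.synthgen import CohortSpec, generate_cohort

# enumerated toy table: 2 groups x 3 subjects x 2 times
TOY_Y = np.array([
    [10.0, 14.0],
    [12.0, 15.0],
    [11.0, 16.0],
    [20.0, 21.0],
    [19.0, 22.0],
    [21.0, 20.0],
])
TOY_CODES = np.array([0, 0, 0, 1, 1, 1])


def _ss(res: pd.DataFrame, effect: str) -> float:
    return float(res.loc[res.effect == effect, "SS"].iloc[0])


class TestMixedAnova2Way:
    def test_toy_table_matches_model_comparison_oracle(self):
        res = mixed_anova_2way_arrays(TOY_Y, TOY_CODES)
        oracle = anova2_oracle(TOY_Y, TOY_CODES)
        for effect in ("group", "subjects_within_group", "time", "time:group",
                       "time:subjects_within_group"):
            assert _ss(res, effect) == pytest.approx(oracle[effect], abs=1e-8), effect

    def test_toy_table_matches_pingouin(self):
        import pingouin as pg

        long = pd.DataFrame({
            "participant": np.repeat(np.arange(6), 2),
            "group": np.repeat(TOY_CODES, 2),
            "time": np.tile(["pre", "post"], 6),
            "outcome": TOY_Y.ravel(),
        })
        ref = pg.mixed_anova(long, dv="outcome", within="time", subject="participant",
                             between="group").set_index("Source")
        res = mixed_anova_2way_arrays(TOY_Y, TOY_CODES).set_index("effect")
        assert res.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert res.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert res.loc["time:group", "F"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-8)
        assert res.loc["time", "p"] == pytest.approx(ref.loc["time", "p_unc"], rel=1e-8)

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_oc, n_noc = rng.integers(3, 9, size=2)
            y = rng.normal(size=(n_oc + n_noc, 2))
            codes = np.repeat([0, 1], [n_oc, n_noc])
            res = mixed_anova_2way_arrays(y, codes)
            total = float(np.sum((y - y.mean()) ** 2))
            assert res.SS.sum() == pytest.approx(total, abs=1e-8)

    def test_all_equal_values_flagged(self):
        table = generate_cohort(CohortSpec(n_per_group=(3, 3), sd_between=0, sd_within=0))
        res = mixed_anova_2way(table)
        assert res.attrs["zero_variance"]
        assert np.isnan(res.loc[res.effect == "time", "F"].iloc[0])

    def test_pure_training_effect_has_zero_interaction_ss(self):
        table = generate_cohort(CohortSpec(n_per_group=(4, 4), sd_between=0, sd_within=0,
                                           training_effect=20.0))
        res = mixed_anova_2way(table)
        assert _ss(res, "time:group") == pytest.approx(0.0, abs=1e-16)
        assert _ss(res, "time") > 0

    def test_near_deterministic_interaction_detected(self):
        table = generate_cohort(CohortSpec(n_per_group=(8, 8), sd_between=1e-3, sd_within=1e-3,
                                           training_effect=5.0, interaction_effect=10.0, seed=2))
        res = mixed_anova_2way(table)
        assert res.loc[res.effect == "time:group", "p"].iloc[0] < 1e-10
        # interaction contrast equals the programmed effect
        wide = table.pivot_table(index=["participant", "group"], columns="time", values="outcome")
        diff = (wide["post"] - wide["pre"]).groupby(level="group").mean()
        assert diff["OC"] - diff["NOC"] == pytest.approx(10.0, abs=0.01)

    def test_incomplete_participants_dropped_and_counted(self):
        table = generate_cohort(CohortSpec(n_per_group=(4, 4), seed=3))
        table = table[~((table.participant == "P001") & (table.time == "post"))]
        res = mixed_anova_2way(table)
        assert res.attrs["n_dropped"] == 1
        assert sum(res.attrs["n_per_group"]) == 7

    def test_too_small_groups_rejected(self):
        table = generate_cohort(CohortSpec(n_per_group=(2, 2), seed=1))
        table = table[table.participant != "P001"]
        with pytest.raises(ValueError):
            mixed_anova_2way(table)


class TestMixedAnova3Way:
    def _toy3(self):
        rng = np.random.default_rng(5)
        y = rng.normal(50, 5, size=(6, 2, 3)).round(1)
        return y, np.array([0, 0, 0, 1, 1, 1])

    def test_toy_table_matches_model_comparison_oracle(self):
        y, codes = self._toy3()
        res = mixed_anova_3way_arrays(y, codes)
        oracle = anova3_oracle(y, codes)
        for effect in ("group", "subjects_within_group", "time", "time:group",
                       "time:subjects_within_group", "location", "location:group",
                       "location:subjects_within_group", "time:location",
                       "time:location:group", "time:location:subjects_within_group"):
            assert _ss(res, effect) == pytest.approx(oracle[effect], abs=1e-8), effect

    def test_unbalanced_groups_match_oracle(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(9, 2, 3))
        codes = np.repeat([0, 1], [4, 5])
        res = mixed_anova_3way_arrays(y, codes)
        oracle = anova3_oracle(y, codes)
        for effect in oracle:
            if effect != "total":
                assert _ss(res, effect) == pytest.approx(oracle[effect], abs=1e-8), effect

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n_oc, n_noc = rng.integers(3, 7, size=2)
            y = rng.normal(size=(n_oc + n_noc, 2, 3))
            codes = np.repeat([0, 1], [n_oc, n_noc])
            res = mixed_anova_3way_arrays(y, codes)
            total = float(np.sum((y - y.mean()) ** 2))
            assert res.SS.sum() == pytest.approx(total, abs=1e-8)

    def test_zero_location_offsets_give_zero_location_ss(self):
        table = generate_cohort(CohortSpec(n_per_group=(3, 3), n_locations=3,
                                           sd_between=0, sd_within=0, training_effect=5.0,
                                           location_offsets=(0.0, 0.0, 0.0)))
        res = mixed_anova_3way(table)
        assert _ss(res, "location") == pytest.approx(0.0, abs=1e-16)

    def test_site_specific_training_detected(self):
        # training applied only at the proximal site
        table = generate_cohort(CohortSpec(n_per_group=(8, 8), n_locations=3,
                                           sd_between=2.0, sd_within=1.0, seed=9))
        bump = (table.time == "post") & (table.location == "proximal")
        table.loc[bump, "outcome"] += 10.0
        res = mixed_anova_3way(table)
        assert res.loc[res.effect == "time:location", "p"].iloc[0] < 0.05


class TestPosthocAndSimpleTests:
    def test_single_comparison_unadjusted(self):
        table = generate_cohort(CohortSpec(n_per_group=(5, 5), n_locations=3,
                                           training_effect=3.0, seed=4))
        one = bonferroni_posthoc(table[table.location == "mid"], by="location")
        assert len(one) == 1
        assert one.p_bonferroni.iloc[0] == pytest.approx(one.p_raw.iloc[0])

    def test_bonferroni_multiplies_and_caps(self):
        table = generate_cohort(CohortSpec(n_per_group=(5, 5), n_locations=3,
                                           training_effect=1.0, seed=4))
        res = bonferroni_posthoc(table, by="location")
        assert len(res) == 3
        for _, row in res.iterrows():
            assert row.p_bonferroni == pytest.approx(min(row.p_raw * 3, 1.0))

    def test_t_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = student_t_independent(a, a + np.array([1e-12, -1e-12, 0]))
        assert t == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_t_large_effect(self):
        rng = np.random.default_rng(2)
        t, p = student_t_independent(rng.normal(0, 1, 100), rng.normal(1, 1, 100))
        assert p < 1e-3

    def test_t_antisymmetric_in_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, p1 = student_t_independent(a, b)
        t2, p2 = student_t_independent(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_mwu_separated_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_mwu_exact_matches_enumeration(self):
        from itertools import combinations

        a, b = np.array([1.3, 2.1, 4.0]), np.array([0.5, 3.2, 5.1])
        u_obs, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        n = len(a)
        us = []
        for idx in combinations(range(6), n):
            x = pooled[list(idx)]
            y = pooled[[i for i in range(6) if i not in idx]]
            us.append(sum(xi > yi for xi in x for yi in y))
        us = np.array(us)
        mu = us.mean()
        p_enum = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        assert p == pytest.approx(p_enum)

    def test_mwu_rank_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0.3, 1, 9)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(np.exp(a), np.exp(b))  # monotone transform
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_wilcoxon_all_zero_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(a, a)

    def test_wilcoxon_detects_shift(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        _, p = wilcoxon_signed_rank(a + 2.0, a)
        assert p < 1e-3

    def test_pearson_perfect_line(self):
        x = np.linspace(0, 1, 10)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_pearson_independent_is_small(self):
        rng = np.random.default_rng(6)
        r, p = pearson_r(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hst.floats(min_value=0.1, max_value=10), hst.floats(min_value=-5, max_value=5))
    def test_pearson_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0, _ = pearson_r(x, y)
        r1, _ = pearson_r(scale * x + shift, y)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))
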