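"""Statistics tests: summaries, chi-square, GLM contrasts, regressions, AIC."""

import numpy as np
import pandas as pd
import pytest

from mimiscape import predation_stats as ps, synthetic_data as sd
from mimiscape.cpm import DistanceSet

from conftest import make_predation_table


def table_with_group_counts(role_counts_by_group, n_per_group=100):
    """Table with exact attacked counts per (site_group, role)."""
    frames = []
    for g, role_counts in role_counts_by_group.items():
        frames.append(make_predation_table(role_counts, n_per_group, site_group=g))
    out = pd.concat(frames, ignore_index=True)
    out["site"] = out["site_group"]
    return out


class TestSummarizeAttacks:
    def test_mean_sd_se_hand_computed(self):
        table = table_with_group_counts(
            {"g1": {"het": 10}, "g2": {"het": 20}, "g3": {"het": 30}}, 50)
        out = ps.summarize_attacks(table).per_role
        row = out[out["role"] == "het"].iloc[0]
        assert row["mean_attacks"] == pytest.approx(20.0)
        assert row["sd_attacks"] == pytest.approx(10.0)
        assert row["se_attacks"] == pytest.approx(10 / np.sqrt(3), abs=1e-9)

    def test_single_group_se_undefined(self):
        table = make_predation_table({"het": 5, "hom1": 2})
        out = ps.summarize_attacks(table).per_role
        assert out["se_attacks"].isna().all()

    def test_unrecovered_excluded(self):
        table = make_predation_table({"het": 10}, 100)
        table.loc[:4, "recovered"] = False  # five attacked dummies lost
        table.loc[:4, "attacked"] = None
        out = ps.summarize_attacks(table)
        row = out.per_group.iloc[0]
        assert row["n_recovered"] == 95
        assert row["n_attacked"] == 5

    def test_totals_conserved(self):
        design = sd.ExperimentDesign(
            sites={f"s{i}": f"g{i % 3}" for i in range(6)},
            groups_per_site=180, seed=9)
        table = sd.simulate_predation(design)
        out = ps.summarize_attacks(table)
        assert out.total_attacks == int(table["attacked"].sum())
        assert (out.per_role.groupby("role")["n_attacked"].sum().sum()
                == out.total_attacks)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ps.summarize_attacks(pd.DataFrame())


class TestChisqHomogeneity:
    def test_df_is_sites_minus_one(self):
        chi2, df, p = ps.chisq_site_homogeneity([5, 6, 7, 8, 9], [100] * 5)
        assert df == 4

    def test_equal_proportions_give_zero(self):
        chi2, df, p = ps.chisq_site_homogeneity([5, 5, 5], [100, 100, 100])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_site_toy_value(self):
        # oracle: sum (O-E)^2/E over the four cells = 1.8018
        chi2, df, p = ps.chisq_site_homogeneity([5, 10], [100, 100])
        assert df == 1
        assert chi2 == pytest.approx(1.8018, abs=5e-4)

    def test_accepts_counts_frame(self):
        table = table_with_group_counts(
            {"g1": {"palatable": 5}, "g2": {"palatable": 10}})
        counts = ps.palatable_site_counts(table)
        chi2, df, p = ps.chisq_site_homogeneity(counts)
        assert chi2 == pytest.approx(1.8018, abs=5e-4)

    def test_zero_recovered_site_rejected(self):
        with pytest.raises(ValueError, match="zero recovered"):
            ps.chisq_site_homogeneity([1, 2], [100, 0])

    def test_type_one_error_near_nominal(self):
        # 2000 null simulations at k=5 sites, p=0.05, n=200/site
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            attacked = rng.binomial(200, 0.05, size=5)
            if attacked.sum() == 0:
                continue
            _, _, p = ps.chisq_site_homogeneity(attacked, [200] * 5)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


class TestAttackGLM:
    def test_identical_proportions_zero_contrast(self):
        table = make_predation_table({"het": 10, "hom1": 10})
        res = ps.fit_attack_glm(table, reference_role="het")
        c = res.contrasts.iloc[0]
        assert c["estimate"] == pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_closed_form(self):
        # oracle: ln((20/80)/(10/90)) and sqrt(1/10+1/90+1/20+1/80)
        table = make_predation_table({"hom1": 10, "exotic": 20})
        res = ps.fit_attack_glm(table)
        c = res.contrasts.iloc[0]
        assert abs(c["estimate"]) == pytest.approx(np.log(2.25), abs=1e-9)
        assert abs(c["estimate"]) == pytest.approx(0.8109, abs=5e-4)
        assert c["se"] == pytest.approx(0.4167, abs=5e-4)
        assert abs(c["z"]) == pytest.approx(1.946, abs=2e-3)

    def test_contrasts_match_closed_form_on_simulated_data(self):
        design = sd.ExperimentDesign(
            sites={f"s{i}": "g0" for i in range(4)}, groups_per_site=250,
            seed=17)
        table = sd.simulate_predation(design)
        res = ps.fit_attack_glm(table)
        counts = res.rates.set_index("role")
        for _, c in res.contrasts.iterrows():
            if c["flagged"]:
                continue
            a, b = counts.loc[c["role_a"]], counts.loc[c["role_b"]]
            expected = (np.log(a["n_attacked"] /
                               (a["n_recovered"] - a["n_attacked"]))
                        - np.log(b["n_attacked"] /
                                 (b["n_recovered"] - b["n_attacked"])))
            assert c["estimate"] == pytest.approx(expected, abs=1e-9)

    def test_aic_equals_deviance_plus_two_k(self):
        table = make_predation_table({"het": 12, "hom1": 4, "exotic": 18})
        res = ps.fit_attack_glm(table, reference_role="exotic")
        assert res.aic == pytest.approx(res.deviance + 2 * res.n_params,
                                        abs=1e-9)

    def test_separated_role_flagged_and_suppressed(self):
        table = make_predation_table({"het": 10, "hom1": 0, "exotic": 20})
        res = ps.fit_attack_glm(table)
        assert res.separated_roles == ("hom1",)
        flagged = res.contrasts[(res.contrasts["role_a"] == "hom1")
                                | (res.contrasts["role_b"] == "hom1")]
        assert flagged["flagged"].all()
        assert flagged["estimate"].isna().all()

    def test_detects_exotic_effect_with_power(self):
        # at the default 2:1 rates and n = 2000/role the exotic-vs-local
        # contrast should be positive and significant in >= 90% of seeds
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            counts = {
                "hom1": int(rng.binomial(2000, 0.04)),
                "exotic": int(rng.binomial(2000, 0.08)),
            }
            table = make_predation_table(counts, 2000)
            res = ps.fit_attack_glm(table, reference_role="hom1")
            c = res.contrasts.iloc[0]
            est = c["estimate"] if c["role_a"] == "exotic" else -c["estimate"]
            hits += (est > 0) and (c["p"] < 0.05)
        assert hits / n_seeds >= 0.90

    def test_anova_detects_phenotype_factor(self):
        table = make_predation_table({"het": 80, "hom1": 40, "exotic": 80}, 1000)
        chi2, df, p = ps.fit_attack_glm(table).anova
        assert df == 2
        assert p < 0.001


class TestPerSetGLM:
    def test_equal_rates_give_null_contrast(self):
        table = table_with_group_counts({"g1": {"het": 8, "hom1": 8}})
        res = ps.per_set_glm(table, {"setA": ["g1"]})
        c = res["setA"].contrasts.iloc[0]
        assert c["estimate"] == pytest.approx(0.0, abs=1e-9)

    def test_generating_odds_ratio_recovered_at_large_n(self):
        # closed-form odds ratio of the generating rates:
        # (0.08/0.92)/(0.04/0.96) = 2.0870
        n = 200000
        table = make_predation_table(
            {"het": int(0.08 * n), "hom1": int(0.04 * n)}, n)
        res = ps.per_set_glm(table, {"s": ["g1"]})["s"]
        c = res.contrasts.iloc[0]
        expected = np.log((0.08 / 0.92) / (0.04 / 0.96))
        est = c["estimate"] if c["role_a"] == "het" else -c["estimate"]
        assert est == pytest.approx(expected, abs=1e-3)

    def test_identical_sets_identical_results(self):
        table = table_with_group_counts(
            {"g1": {"het": 7, "hom1": 3}, "g2": {"het": 7, "hom1": 3}})
        res = ps.per_set_glm(table, {"A": ["g1"], "B": ["g2"]})
        pd.testing.assert_frame_equal(res["A"].contrasts, res["B"].contrasts)

    def test_missing_set_rejected(self):
        table = make_predation_table({"het": 5})
        with pytest.raises(ValueError, match="no rows"):
            ps.per_set_glm(table, {"A": ["nope"]})


class TestAttackRatio:
    def test_plain_ratio(self):
        assert ps.attack_ratio(10, 5) == (2.0, False)

    def test_zero_homozygote_correction(self):
        ratio, flagged = ps.attack_ratio(4, 0)
        assert flagged
        assert ratio == pytest.approx(9.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ps.attack_ratio(-1, 2)


def _records(xs, ys):
    out = []
    for i, (x, y) in enumerate(zip(xs, ys)):
        ds = DistanceSet(het_homD=x, het_homR=2 * x, hom_hom=3 * x,
                         encoding="binary")
        out.append(ps.RatioRecord(set_id=f"s{i}", locality=f"s{i}", ratio=y,
                                  distances={("binary", ""): ds}))
    return out


class TestRatioRegression:
    def test_collinear_points_perfect_fit(self):
        res = ps.regress_ratio_on_distance(
            _records([1, 2, 3, 4], [2, 4, 6, 8]), "binary")
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_hand_computed_ols(self):
        # oracle: hand OLS for x=(1,2,3), y=(1,2,2)
        res = ps.regress_ratio_on_distance(_records([1, 2, 3], [1, 2, 2]),
                                           "binary")
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(2 / 3)
        assert res.r_squared == pytest.approx(0.75)
        assert res.f_statistic == pytest.approx(3.0)

    def test_r_squared_invariant_to_distance_rescaling(self):
        y = [1.1, 1.9, 3.2, 3.8, 5.1]
        r1 = ps.regress_ratio_on_distance(_records([1, 2, 3, 4, 5], y), "binary")
        r2 = ps.regress_ratio_on_distance(
            _records([10.5, 20.5, 30.5, 40.5, 50.5], y), "binary")
        assert r1.r_squared == pytest.approx(r2.r_squared, rel=1e-9)

    def test_slope_coverage_under_noise(self):
        # OLS coverage: true slope within 3 se in >= 95% of 500 seeds at n=8
        beta, hits, n_seeds = 0.5, 0, 500
        x = np.linspace(1, 8, 8)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = 1 + beta * x + rng.normal(0, 0.5, x.size)
            res = ps.regress_ratio_on_distance(
                _records(x, np.maximum(y, 0)), "binary")
            hits += abs(res.slope - beta) <= 3 * res.slope_se
        assert hits / n_seeds >= 0.95

    def test_zero_variance_distances_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ps.regress_ratio_on_distance(_records([2, 2, 2], [1, 2, 3]),
                                         "binary")

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="three"):
            ps.regress_ratio_on_distance(_records([1, 2], [1, 2]), "binary")


def _het_strata(rng, n_strata=10, n_each=500, a=-3.0, b=0.0, c=0.0):
    D = np.linspace(0.2, 2.0, n_strata)
    R = 0.3 + 1.5 * ((D * 7.3) % 1.0)  # decorrelated from D, fixed pattern
    logits = a + b * D + c * D * R
    p = 1 / (1 + np.exp(-logits))
    return pd.DataFrame({
        "n_recovered": n_each,
        "n_attacked": rng.binomial(n_each, p),
        "het_homD": D,
        "het_homR": R,
    })


class TestCompareDistanceModels:
    def test_aic_identity_holds_for_every_model(self):
        rng = np.random.default_rng(0)
        cmp_ = ps.compare_distance_models(_het_strata(rng, b=0.5))
        for _, row in cmp_.table.iterrows():
            assert row["aic"] == pytest.approx(
                -2 * row["loglike"] + 2 * row["n_params"], abs=1e-9)

    def test_null_data_keeps_intercept_model_competitive(self):
        # AIC under the null: intercept within 2 of the best in >= 80% of seeds
        hits, n_seeds = 0, 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cmp_ = ps.compare_distance_models(_het_strata(rng))
            t = cmp_.table.set_index("model")
            hits += t.loc["intercept", "delta_aic"] <= 2.0
        assert hits / n_seeds >= 0.80

    def test_interaction_model_recovered_when_present(self):
        # generated with b, c > 0 at n = 5000: full model wins >= 90% of seeds
        hits, n_seeds = 0, 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            data = _het_strata(rng, b=1.2, c=1.2)
            cmp_ = ps.compare_distance_models(data)
            hits += cmp_.best_model == "D+R+DxR"
        assert hits / n_seeds >= 0.90

    def test_collinear_distances_warn(self):
        rng = np.random.default_rng(1)
        data = _het_strata(rng, b=0.5)
        data["het_homR"] = 2.0 * data["het_homD"]
        with pytest.warns(UserWarning, match="collinear"):
            ps.compare_distance_models(data)

    def test_accepts_per_dummy_rows(self):
        table = make_predation_table({"het": 12}, 200)
        table["het_homD"] = 1.0
        table["het_homR"] = 2.0
        table2 = make_predation_table({"het": 30}, 200)
        table2["het_homD"] = 2.0
        table2["het_homR"] = 1.0
        table3 = make_predation_table({"het": 21}, 200)
        table3["het_homD"] = 1.5
        table3["het_homR"] = 2.5
        cmp_ = ps.compare_distance_models(
            pd.concat([table, table2, table3], ignore_index=True))
        assert set(cmp_.table["model"]) == {
            "intercept", "D", "R", "D+R", "D+R+DxR"}
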