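"""Statistical kernels: effect sizes, BH-FDR, GAM behaviour, test batteries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from msburden.stats import (
    bh_fdr,
    cohens_d,
    cohens_f2,
    demographic_battery,
    fit_burden_gam,
    promis_comparisons,
)

from oracles import bh_adjust_bruteforce


def synthetic_table(n=300, seed=0, effect=0.03, age_effect=0.0):
    """Analysis table with a known linear severity effect on uf_burden."""
    rng = np.random.default_rng(seed)
    sev = rng.integers(0, 3, n)
    stratum = np.array(["none", "mild", "severe"])[sev]
    age = rng.uniform(20, 75, n)
    sex = rng.choice(["F", "M"], n, p=[0.8, 0.2])
    tbv = rng.normal(1.15e6, 1e5, n)
    uf = 0.02 + effect * sev + age_effect * np.sin(age / 8.0) + rng.normal(0, 0.02, n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "stratum": stratum,
            "anxiety_severity_code": sev,
            "depression": np.where(sev > 0, "depression", "no_depression"),
            "uf_burden": uf,
            "fornix_burden": rng.normal(0.04, 0.02, n),
            "total_lesion_volume": rng.normal(6000, 1500, n),
            "age": age,
            "sex": sex,
            "race": rng.choice(["White", "Black or African American"], n),
            "total_brain_volume": tbv,
            "phq2_mean": np.zeros(n),
            "promis_physical": rng.normal(50, 8, n),
            "promis_emotional": rng.normal(50 - 4 * sev, 8, n),
        }
    )


class TestCohensF2:
    @pytest.mark.parametrize(
        "full, red, expected", [(0.5, 0.5, 0.0), (0.5, 0.25, 0.5), (0.0, 0.0, 0.0)]
    )
    def test_formula(self, full, red, expected):
        assert cohens_f2(full, red) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0, 0.5)
        with pytest.raises(ValueError):
            cohens_f2(0.3, 0.5)

    def test_equals_t2_over_df_on_ols(self):
        rng = np.random.default_rng(1)
        n = 80
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 0.4 * x + 0.2 * z + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, z])
        full = sm.OLS(y, X).fit()
        red = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
        f2 = cohens_f2(full.rsquared, red.rsquared)
        assert f2 == pytest.approx(full.tvalues[1] ** 2 / full.df_resid, rel=1e-10)

    def test_bootstrap_b1_degenerate_ci(self):
        table = synthetic_table(n=120, seed=3)
        res = fit_burden_gam(
            table, "uf_burden", "severity_ordinal", f2_bootstrap=1, seed=0
        )
        assert res.f2_ci[0] == pytest.approx(res.f2_ci[1])


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_degenerate_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([0.0, 0.0], [1.0, 1.0])

    def test_hand_example(self):
        assert cohens_d([2.0, 4.0], [1.0, 3.0]) == pytest.approx(1 / np.sqrt(2))


class TestBhFdr:
    def test_single_p(self):
        adj, rej = bh_fdr([0.04])
        assert adj[0] == pytest.approx(0.04) and rej[0]

    def test_hand_step_up(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_all_ones_rejects_nothing(self):
        adj, rej = bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any() and np.allclose(adj, 1.0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            m = int(rng.integers(1, 13))
            p = np.round(rng.random(m), 4)
            adj, _rej = bh_fdr(p)
            assert np.allclose(adj, bh_adjust_bruteforce(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.random(10)
        adj, rej = bh_fdr(p, q=0.05)
        rej_sm, adj_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, adj_sm)
        assert np.array_equal(rej, rej_sm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestBurdenGam:
    def test_linear_spline_reproduces_ols(self):
        table = synthetic_table(n=200, seed=2)
        res = fit_burden_gam(table, "uf_burden", "severity_ordinal", age_spline="linear")
        sub = table[table["stratum"].isin(["none", "mild", "severe"])]
        y = sub["uf_burden"].to_numpy()
        tbv = sub["total_brain_volume"].to_numpy()
        X = np.column_stack(
            [
                np.ones(len(sub)),
                sub["anxiety_severity_code"].to_numpy(float),
                (sub["sex"] == "M").astype(float),
                (tbv - tbv.mean()) / tbv.std(),
                sub["age"].to_numpy(),
            ]
        )
        ols = sm.OLS(y, X).fit()
        assert res.estimate == pytest.approx(ols.params[1], rel=1e-6)

    def test_planted_effect_recovered_with_sign(self):
        table = synthetic_table(n=300, seed=4, effect=0.03)
        res = fit_burden_gam(table, "uf_burden", "severity_ordinal")
        assert res.T > 0 and res.p < 0.05
        assert res.estimate == pytest.approx(0.03, abs=0.01)

    def test_spline_captures_nonlinear_age(self):
        table = synthetic_table(n=400, seed=5, effect=0.0, age_effect=0.08)
        res = fit_burden_gam(table, "uf_burden", "severity_ordinal")
        # age smooth absorbs the structure: full model R2 dominated by spline
        assert res.r2_full > 0.5
        assert res.p > 0.001  # no spurious strong severity signal

    def test_diagnosis_contrast_uses_extreme_groups(self):
        table = synthetic_table(n=300, seed=6)
        res = fit_burden_gam(table, "uf_burden", "diagnosis_binary")
        n_expected = (table["stratum"].isin(["none", "severe"])).sum()
        assert res.n == n_expected

    def test_small_group_precondition(self):
        table = synthetic_table(n=40, seed=7)
        table.loc[table["stratum"] == "severe", "stratum"] = "mild"
        table.loc[table.index[:3], "stratum"] = "severe"
        table.loc[table.index[:3], "anxiety_severity_code"] = 2
        with pytest.raises(ValueError, match="< 10"):
            fit_burden_gam(table, "uf_burden", "diagnosis_binary")

    def test_mgcv_cross_check(self, tmp_path):
        """Independent oracle: R mgcv on the same data and formula."""
        import subprocess

        table = synthetic_table(n=300, seed=8, effect=0.03)
        sub = table[table["stratum"].isin(["none", "mild", "severe"])].copy()
        tbv = sub["total_brain_volume"]
        sub["tbv_std"] = (tbv - tbv.mean()) / tbv.std()
        sub["male"] = (sub["sex"] == "M").astype(int)
        csv = tmp_path / "tab.csv"
        sub.to_csv(csv, index=False)
        script = tmp_path / "gam.R"
        script.write_text(
            f"""
            library(mgcv)
            d <- read.csv("{csv}")
            m <- gam(uf_burden ~ anxiety_severity_code + male + tbv_std + s(age, k=4),
                     data=d, method="REML")
            s <- summary(m)
            cat(s$p.coeff["anxiety_severity_code"],
                s$p.t["anxiety_severity_code"], sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        if out.returncode != 0:
            pytest.skip(f"Rscript unavailable or failed: {out.stderr[:200]}")
        est_r, t_r = map(float, out.stdout.split())
        res = fit_burden_gam(sub, "uf_burden", "severity_ordinal")
        assert res.estimate == pytest.approx(est_r, rel=0.02)
        assert res.T == pytest.approx(t_r, rel=0.10)


class TestBatteries:
    def test_two_group_anova_equals_t_squared(self):
        table = synthetic_table(n=200, seed=10)
        rep = demographic_battery(table)
        row = rep[(rep.variable == "age") & (rep.contrast == "diagnosis")].iloc[0]
        sub = table[table["stratum"].isin(["none", "severe"])]
        a = sub.loc[sub["stratum"] == "none", "age"]
        b = sub.loc[sub["stratum"] == "severe", "age"]
        t, p = sps.ttest_ind(a, b)
        assert row["statistic"] == pytest.approx(t**2, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_chi2_matches_hand_yates_formula(self):
        # classic 2x2 example: chi2 with Yates continuity correction
        tab = np.array([[10, 20], [30, 25]])
        n = tab.sum()
        a, b, c, d = tab.ravel()
        hand = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, _p, _dof, _exp = sps.chi2_contingency(tab)
        assert stat == pytest.approx(hand, rel=1e-12)

    def test_report_covers_variables_and_contrasts(self):
        rep = demographic_battery(synthetic_table(n=250, seed=11))
        combos = set(zip(rep.variable, rep.contrast))
        for var in ("age", "sex", "race", "phq2_mean"):
            assert (var, "severity") in combos
            assert (var, "diagnosis") in combos


class TestPromisComparisons:
    def test_equal_summaries_give_zero_paired_t(self):
        table = synthetic_table(n=150, seed=12)
        table["promis_emotional"] = table["promis_physical"]
        rep = promis_comparisons(table)
        paired = rep["contrasts"][rep["contrasts"]["test"] == "paired_t"]
        assert np.allclose(paired["statistic"], 0.0)

    def test_paired_t_matches_closed_form(self):
        emo = np.array([48.0, 52.0, 45.0, 50.0, 47.0])
        phy = np.array([50.0, 55.0, 50.0, 51.0, 49.0])
        diff = emo - phy
        t_expected = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        table = synthetic_table(n=5, seed=13)
        table["stratum"] = "none"
        table["promis_emotional"] = emo
        table["promis_physical"] = phy
        rep = promis_comparisons(table)
        row = rep["contrasts"][rep["contrasts"]["contrast"] == "none:emotional_vs_physical"]
        assert row["statistic"].iloc[0] == pytest.approx(t_expected, rel=1e-10)

    def test_shapiro_nominal_rejection_rate_on_normal_data(self):
        rng = np.random.default_rng(14)
        rejections = sum(
            sps.shapiro(rng.normal(size=40))[1] < 0.05 for _ in range(200)
        )
        assert 1 <= rejections <= 25  # ~5% nominal, wide binomial bounds

    def test_fdr_family_present(self):
        rep = promis_comparisons(synthetic_table(n=200, seed=15))
        assert {"p_fdr", "significant"} <= set(rep["contrasts"].columns)
        assert len(rep["contrasts"]) == 5
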