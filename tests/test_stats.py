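"""Group statistics: GG epsilon, repeated-measures ANOVA, fine bins, WLS."""

import numpy as np
import pandas as pd
import pytest

from ridemix.stats import (
    fine_bin_effects,
    gg_epsilon,
    rm_anova,
    wls_regression,
)


def gg_epsilon_oracle(scores):
    """Box's epsilon from the raw k x k covariance matrix (textbook form).

    eps = k^2 (mean diagonal - grand mean)^2 /
          ((k-1) (sum s_ij^2 - 2k sum row_mean^2 + k^2 grand_mean^2))
    """
    s = np.cov(scores, rowvar=False, ddof=1)
    k = s.shape[0]
    grand = s.mean()
    diag = np.trace(s) / k
    row = s.mean(axis=1)
    num = k**2 * (diag - grand) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(row**2) + k**2 * grand**2)
    return num / den


class TestGGEpsilon:
    def test_two_levels_exactly_one(self):
        rng = np.random.default_rng(0)
        assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0

    def test_spherical_data_near_one(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(4000, 4))  # iid => compound symmetric
        assert gg_epsilon(scores) > 0.97

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(12, 1))
        scores = base * rng.uniform(0.5, 2.0, size=5) + rng.normal(size=(12, 5))
        assert gg_epsilon(scores) == pytest.approx(gg_epsilon_oracle(scores), abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            k = rng.integers(2, 6)
            scores = rng.normal(size=(8, k)) * rng.uniform(0.2, 3.0, size=k)
            eps = gg_epsilon(scores)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        data = pd.DataFrame(scores, columns=["a", "b", "c"]).reset_index(names="subj")
        long = data.melt(id_vars="subj", var_name="cond", value_name="y")
        eps_pg = pingouin.epsilon(long, subject="subj", within="cond", dv="y", correction="gg")
        assert gg_epsilon(scores) == pytest.approx(float(eps_pg), abs=1e-8)


def make_effect_table(rng, n=12, shift_uv=0.0, noise=0.5):
    cats, hemis, sites = ["Baseline", "High"], ["Left", "Right"], ["Inferior", "Middle", "Superior"]
    rows = []
    for p in range(n):
        for c in cats:
            for h in hemis:
                for s in sites:
                    val = rng.normal(0.0, noise) + (shift_uv if c == "High" else 0.0)
                    rows.append(
                        {"participant": p, "category": c, "hemisphere": h, "site": s, "mean_uv": val}
                    )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_null_data_not_inflated(self):
        # no true effects anywhere: rejection rate across effects and seeds
        # must stay near the nominal level
        pvals = []
        for seed in range(8):
            table = make_effect_table(np.random.default_rng(seed), shift_uv=0.0)
            res = rm_anova(table)
            assert ((res["eta_p2"] >= 0) & (res["eta_p2"] <= 1)).all()
            pvals.extend(res["p_gg"])
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.15

    def test_constant_cells_give_zero_f(self):
        table = make_effect_table(np.random.default_rng(1), noise=0.0)
        # per-participant offsets only: no within-subject differences at all
        table["mean_uv"] = table["participant"].astype(float)
        res = rm_anova(table)
        assert np.allclose(res["F"], 0.0, atol=1e-20)
        assert np.allclose(res["p_gg"], 1.0)

    def test_category_shift_detected(self):
        table = make_effect_table(np.random.default_rng(2), n=20, shift_uv=2.0, noise=0.5)
        res = rm_anova(table).set_index("effect")
        assert res.loc["category", "p_gg"] < 0.01
        assert res.loc["category", "eps"] == 1.0  # two levels

    def test_missing_cell_raises(self):
        table = make_effect_table(np.random.default_rng(3)).iloc[:-1]
        with pytest.raises(ValueError, match="missing design cell"):
            rm_anova(table)

    def test_corrected_df_scale_with_epsilon(self):
        table = make_effect_table(np.random.default_rng(4), n=9)
        res = rm_anova(table)
        np.testing.assert_allclose(res["df1_gg"], res["eps"] * res["df1"])
        np.testing.assert_allclose(res["df2_gg"], res["eps"] * res["df2"])

    def test_one_way_matches_textbook_decomposition(self):
        # classic one-factor within-subject ANOVA computed longhand
        rng = np.random.default_rng(5)
        y = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1)) + [0.0, 0.4, 1.0]
        n, k = y.shape
        grand = y.mean()
        ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((y - grand) ** 2) - ss_cond - ss_subj
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        long = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(n), k),
                "category": np.tile(["a", "b", "c"], n),
                "mean_uv": y.ravel(),
            }
        )
        res = rm_anova(long, within=("category",))
        assert res.loc[0, "F"] == pytest.approx(f_oracle, abs=1e-6)
        assert res.loc[0, "eta_p2"] == pytest.approx(ss_cond / (ss_cond + ss_err), abs=1e-9)

    def test_matches_pingouin_two_way(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        rows = []
        for p in range(14):
            subj = rng.normal()
            for a in ("x", "y"):
                for b in ("u", "v", "w"):
                    rows.append(
                        {
                            "participant": p,
                            "category": a,
                            "site": b,
                            "mean_uv": subj + rng.normal() + (1.0 if a == "x" and b == "u" else 0),
                        }
                    )
        table = pd.DataFrame(rows)
        res = rm_anova(table, within=("category", "site")).set_index("effect")
        pg = pingouin.rm_anova(
            data=table, dv="mean_uv", within=["category", "site"], subject="participant",
            detailed=True, correction=False,
        ).set_index("Source")
        for ours, theirs in [
            ("category", "category"),
            ("site", "site"),
            ("category x site", "category * site"),
        ]:
            assert res.loc[ours, "F"] == pytest.approx(pg.loc[theirs, "F"], abs=1e-6)

    def test_permuted_labels_destroy_effect(self):
        rng = np.random.default_rng(7)
        table = make_effect_table(rng, n=12, shift_uv=1.0, noise=0.5)
        pvals = []
        for _ in range(100):
            shuffled = table.copy()
            for p in range(12):
                m = shuffled["participant"] == p
                vals = shuffled.loc[m, "mean_uv"].to_numpy()
                shuffled.loc[m, "mean_uv"] = rng.permutation(vals)
            res = rm_anova(shuffled).set_index("effect")
            pvals.append(res.loc["category", "p_unc"])
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestFineBins:
    def make_trials(self, amps_by_bin=None, n_per_bin=20, n_participants=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_participants):
            for b in range(9):
                for _ in range(n_per_bin):
                    err = rng.uniform(b * 10 + 0.5, (b + 1) * 10)
                    amp = (amps_by_bin[b] if amps_by_bin else 0.0) + rng.normal(0, noise)
                    for hemi in ("Left", "Right"):
                        rows.append(
                            {
                                "participant": p,
                                "hemisphere": hemi,
                                "error_deg": err,
                                "mean_uv": amp,
                            }
                        )
            for _ in range(n_per_bin):
                for hemi in ("Left", "Right"):
                    rows.append(
                        {
                            "participant": p,
                            "hemisphere": hemi,
                            "error_deg": rng.uniform(91, 180),
                            "mean_uv": rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_single_bin_populated(self):
        trials = pd.DataFrame(
            {
                "participant": 0,
                "hemisphere": "Left",
                "error_deg": [4.0] * 5 + [120.0] * 5,
                "mean_uv": 1.0,
            }
        )
        table = fine_bin_effects(trials)
        assert set(table.per_participant["bin"]) == {1}
        assert len(table.omissions) == 8  # bins 2..9 missing

    def test_baseline_equal_amplitudes_give_zero(self):
        trials = self.make_trials(amps_by_bin=[0.0] * 9)
        table = fine_bin_effects(trials)
        np.testing.assert_allclose(table.summary["mean_uv"], 0.0, atol=1e-12)

    def test_linear_amplitude_map_is_monotone(self):
        amps = [2.0 - 0.2 * b for b in range(9)]
        table = fine_bin_effects(self.make_trials(amps_by_bin=amps, noise=0.01, seed=1))
        for _, grp in table.summary.groupby("hemisphere"):
            means = grp.sort_values("bin")["mean_uv"].to_numpy()
            assert (np.diff(means) < 0).all()

    def test_bin_centres(self):
        table = fine_bin_effects(self.make_trials(amps_by_bin=[0.0] * 9))
        centers = sorted(table.summary["center_deg"].unique())
        assert centers == [5.5 + 10 * b for b in range(9)]

    def test_missing_baseline_raises(self):
        trials = pd.DataFrame(
            {"participant": 0, "hemisphere": "Left", "error_deg": [5.0] * 5, "mean_uv": 1.0}
        )
        with pytest.raises(ValueError, match="Baseline"):
            fine_bin_effects(trials)


class TestWls:
    def make_summary(self, slope=-0.05, noise=0.0, var=None, seed=0):
        rng = np.random.default_rng(seed)
        centers = 5.5 + 10 * np.arange(9)
        var = np.ones(9) if var is None else np.asarray(var)
        y = 2.0 + slope * centers + rng.normal(0, noise, size=9) * np.sqrt(var)
        return pd.DataFrame({"center_deg": centers, "mean_uv": y, "var_uv": var})

    def test_equal_weights_match_ols(self):
        import statsmodels.api as sm

        summ = self.make_summary(noise=0.3, seed=1)
        res = wls_regression(summ)
        ols = sm.OLS(summ["mean_uv"], sm.add_constant(summ["center_deg"])).fit()
        assert res.slope == pytest.approx(ols.params.iloc[1], abs=1e-10)
        assert res.intercept == pytest.approx(ols.params.iloc[0], abs=1e-10)

    def test_exact_line(self):
        res = wls_regression(self.make_summary(slope=-0.05))
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.r == pytest.approx(-1.0, abs=1e-9)
        assert res.p < 1e-10
        assert res.slope == pytest.approx(-0.05, abs=1e-12)

    def test_r_squared_consistency(self):
        summ = self.make_summary(noise=0.5, var=np.linspace(0.5, 4.0, 9), seed=2)
        res = wls_regression(summ)
        assert res.r2 == pytest.approx(res.r**2, abs=1e-12)
        assert 0.0 <= res.r2 <= 1.0

    def test_degenerate_variance_raises(self):
        summ = self.make_summary()
        summ.loc[0, "var_uv"] = 0.0
        with pytest.raises(ValueError, match="variance"):
            wls_regression(summ)

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError, match="3 bins"):
            wls_regression(self.make_summary().iloc[:2])

    def test_heteroscedastic_slope_recovery(self):
        slopes, rs = [], []
        for seed in range(100):
            summ = self.make_summary(slope=-0.05, noise=0.3,
                                     var=np.linspace(0.2, 3.0, 9), seed=seed)
            res = wls_regression(summ)
            slopes.append(res.slope)
            rs.append(res.r)
        assert np.mean(slopes) == pytest.approx(-0.05, abs=0.015)
        assert np.mean(np.array(rs) < 0) >= 0.95
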