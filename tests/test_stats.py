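"""Mixed-model fitting, BH adjustment, and the gravity-effect family."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f_oneway

from gravgait.errors import DegenerateFitError, InvalidParameterError
from gravgait.stats import (
    TABLE2_INVENTORY,
    LmmSpec,
    bh_adjust,
    fit_lmm,
    run_table2,
)

GRAVITIES = [1.0, 0.76, 0.55, 0.31]
SPEEDS = [0.4, 0.8, 1.2, 1.6]


def simulate_features(rng, effect=0.0, n_part=12, sigma_b=1.0, sigma_e=1.0,
                      response="y"):
    """Balanced participant x gravity x speed table with a linear-in-support
    gravity effect of ``effect`` residual SDs (full range)."""
    rows = []
    for p in range(n_part):
        b = rng.normal(0.0, sigma_b)
        for g in GRAVITIES:
            for s in SPEEDS:
                rows.append({
                    "participant_id": f"P{p:02d}", "gravity_level": g,
                    "target_speed": s,
                    response: b + effect * sigma_e * (1.0 - g) / 0.69
                    + rng.normal(0.0, sigma_e)})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_reduces_to_oneway_anova_without_random_variance(self):
        rng = np.random.default_rng(4)
        rows = [{"participant_id": f"P{p}", "gravity_level": g,
                 "target_speed": 1.2, "y": rng.normal()}
                for p in range(8) for g in GRAVITIES for _ in range(2)]
        df = pd.DataFrame(rows)
        res = fit_lmm(df, LmmSpec(response="y", theta_fixed=0.0,
                                  ddf_method="residual"))
        groups = [df.loc[df.gravity_level == g, "y"] for g in GRAVITIES]
        _, p_anova = f_oneway(*groups)
        assert res.pvalue == pytest.approx(p_anova, abs=1e-6)

    def test_variance_components_match_statsmodels(self):
        import statsmodels.formula.api as smf
        df = simulate_features(np.random.default_rng(7), effect=1.0)
        mod = smf.mixedlm("y ~ C(gravity_level) + C(target_speed)", df,
                          groups=df["participant_id"]).fit(reml=True)
        res = fit_lmm(df, LmmSpec(response="y"))
        assert res.sigma2_resid == pytest.approx(mod.scale, rel=1e-3)
        assert res.sigma2_participant == pytest.approx(
            float(mod.cov_re.iloc[0, 0]), rel=1e-3)

    def test_type_one_error_near_nominal(self):
        rejections = 0
        n_sim = 400
        for i in range(n_sim):
            df = simulate_features(np.random.default_rng(10_000 + i))
            rejections += fit_lmm(df, LmmSpec(response="y")).pvalue < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.025)

    def test_power_at_two_sd_effect(self):
        hits = 0
        for i in range(60):
            df = simulate_features(np.random.default_rng(20_000 + i),
                                   effect=2.0)
            hits += fit_lmm(df, LmmSpec(response="y")).pvalue < 0.05
        assert hits / 60 >= 0.9

    def test_variance_ratio_recovery_median(self):
        # random-intercept variance at 4x residual: median recovered ratio
        # within 50% over replicate cohorts
        ratios = []
        for i in range(60):
            df = simulate_features(np.random.default_rng(30_000 + i),
                                   sigma_b=2.0, sigma_e=1.0)
            r = fit_lmm(df, LmmSpec(response="y"))
            ratios.append(r.sigma2_participant / r.sigma2_resid)
        med = float(np.median(ratios))
        assert 2.0 <= med <= 6.0

    def test_missing_gravity_level_warns_and_fits(self):
        df = simulate_features(np.random.default_rng(1))
        df.loc[df.gravity_level == 0.31, "y"] = np.nan
        with pytest.warns(UserWarning, match="0.31"):
            res = fit_lmm(df, LmmSpec(response="y"))
        assert res.df_num == 2        # three remaining levels

    def test_zero_residual_variance_rejected(self):
        df = simulate_features(np.random.default_rng(2))
        df["y"] = 1.0
        with pytest.raises(DegenerateFitError):
            fit_lmm(df, LmmSpec(response="y"))

    def test_interaction_terms_available(self):
        df = simulate_features(np.random.default_rng(3), effect=1.0)
        res = fit_lmm(df, LmmSpec(response="y", interaction=True))
        assert any("gravity" in k and ":" in k for k in res.coefficients)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04, 0.05]),
                                   [0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_adjust([0.1, 1.3])

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @staticmethod
    def _brute_force(p):
        p = np.asarray(p, float)
        m = p.size
        out = np.empty(m)
        for i in range(m):
            rank = np.sum(p <= p[i])      # step-up rank of p[i]
            # min over all p_j >= p[i] of p_j * m / rank_j
            cands = []
            for j in range(m):
                if p[j] >= p[i]:
                    cands.append(p[j] * m / np.sum(p <= p[j]))
            out[i] = min(1.0, min(cands))
        return out

    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1,
                    max_size=50))
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_step_up(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), self._brute_force(ps),
                                   atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        for size in (1, 2, 5, 26, 50):
            p = rng.uniform(size=size)
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                atol=1e-12)


class TestRunTable2:
    @staticmethod
    def _feature_table(rng, effects: dict[str, float]):
        base = simulate_features(rng, response=TABLE2_INVENTORY[0][2],
                                 effect=effects.get(TABLE2_INVENTORY[0][2],
                                                    0.0))
        df = base[["participant_id", "gravity_level", "target_speed"]].copy()
        for _, _, col in TABLE2_INVENTORY:
            df[col] = simulate_features(
                rng, response="y", effect=effects.get(col, 0.0))["y"]
        return df

    def test_inventory_order_matches_report(self):
        rng = np.random.default_rng(0)
        df = self._feature_table(rng, {})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_table2(df)
        assert rep.family_size == 26
        assert list(rep.table["column"]) == [c for _, _, c in TABLE2_INVENTORY]
        assert list(rep.table["variable"])[:2] == ["Maximum vertical",
                                                   "Maximum braking"]

    def test_adjusted_p_dominates_raw(self):
        df = self._feature_table(np.random.default_rng(1),
                                 {"peak_vertical_grf": 3.0})
        rep = run_table2(df)
        assert np.all(rep.table["p_adjusted"] >= rep.table["p_raw"] - 1e-15)

    def test_missing_variable_reported_and_family_shrinks(self):
        df = self._feature_table(np.random.default_rng(2), {})
        df = df.drop(columns=["stride_length_norm"])
        with pytest.warns(UserWarning, match="stride_length_norm"):
            rep = run_table2(df)
        assert rep.family_size == 25
        assert rep.missing == ["stride_length_norm"]

    def test_null_family_false_discoveries_bounded(self):
        # with no effects anywhere, expected significant count <= alpha * m
        total = 0
        n_rep = 10
        for i in range(n_rep):
            df = self._feature_table(np.random.default_rng(40_000 + i), {})
            total += int(run_table2(df).table["significant"].sum())
        assert total / n_rep <= 0.05 * 26 + 1.0
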