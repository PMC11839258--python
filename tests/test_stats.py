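"""Mixed RM-ANOVA, post hoc tests, correlations, normality, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pmgait
from pmgait.errors import DegenerateInputError, ValidationError
from pmgait.stats import greenhouse_geisser_epsilon, split_plot_anova


def _long_table(Y, groups, metric="lye", pm=3):
    rows = []
    for i in range(Y.shape[0]):
        for c in range(Y.shape[1]):
            rows.append(dict(subject=f"S{i:02d}", age_group=groups[i],
                             condition=str(c), pm=pm, metric=metric,
                             value=Y[i, c]))
    return pd.DataFrame(rows)


def _simulated(rng, n=26, L=8, cond_effect=1.5, noise=0.7):
    groups = ["young"] * (n // 2) + ["older"] * (n - n // 2)
    eff = np.linspace(0, cond_effect, L)
    Y = rng.normal(0, 1, (n, 1)) + eff + rng.normal(0, noise, (n, L))
    return Y, np.array(groups)


class TestSplitPlotAnova:
    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y, groups = _simulated(rng)
        tab = _long_table(Y, groups)
        mine = pmgait.mixed_rm_anova(tab, "lye", 3).set_index("effect")
        ref = pg.mixed_anova(data=tab, dv="value", within="condition",
                             subject="subject", between="age_group")
        ref = ref.set_index("Source")
        for eff, src in [("age", "age_group"), ("speed", "condition"),
                         ("interaction", "Interaction")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"],
                                                       rel=1e-8)
            assert mine.loc[eff, "p_uncorrected"] == pytest.approx(
                ref.loc[src, "p_unc"], abs=1e-8)
            assert mine.loc[eff, "partial_eta_sq"] == pytest.approx(
                ref.loc[src, "np2"], rel=1e-8)
        # epsilon conventions differ slightly (pooled within-group vs raw)
        assert mine.loc["speed", "epsilon_gg"] == pytest.approx(
            ref.loc["condition", "eps"], abs=0.05)

    def test_hand_worked_two_by_three_table(self):
        # 2 groups x 2 subjects x 3 levels; SS computed longhand below
        Y = np.array([
            [1.0, 2.0, 3.0],
            [2.0, 3.0, 4.0],
            [5.0, 5.0, 5.0],
            [4.0, 6.0, 8.0],
        ])
        groups = np.array(["a", "a", "b", "b"])
        res = {r.effect: r for r in split_plot_anova(Y, groups)}
        grand = Y.mean()
        ss_a = 3 * 2 * ((Y[:2].mean() - grand) ** 2 + (Y[2:].mean() - grand) ** 2)
        ss_subj = 3 * ((Y.mean(axis=1) - grand) ** 2).sum()
        ss_s_in_a = ss_subj - ss_a
        ss_b = 4 * ((Y.mean(axis=0) - grand) ** 2).sum()
        ss_ab = 0.0
        for g in ("a", "b"):
            sel = groups == g
            cell = Y[sel].mean(axis=0)
            ss_ab += sel.sum() * ((cell - Y[sel].mean() - Y.mean(axis=0)
                                   + grand) ** 2).sum()
        ss_tot = ((Y - grand) ** 2).sum()
        ss_err = ss_tot - ss_subj - ss_b - ss_ab
        f_a = (ss_a / 1) / (ss_s_in_a / 2)
        f_b = (ss_b / 2) / (ss_err / 4)
        f_ab = (ss_ab / 2) / (ss_err / 4)
        assert res["age"].F == pytest.approx(f_a, rel=1e-10)
        assert res["speed"].F == pytest.approx(f_b, rel=1e-10)
        assert res["interaction"].F == pytest.approx(f_ab, rel=1e-10)

    def test_two_level_within_equals_squared_paired_t(self, rng):
        # exact identity for the one-group repeated-measures design
        Y = rng.normal(0, 1, (20, 2))
        res = split_plot_anova(Y, np.array(["all"] * 20))
        t, p = sps.ttest_rel(Y[:, 0], Y[:, 1])
        assert res[0].F == pytest.approx(t**2, rel=1e-8)
        assert res[0].p_uncorrected == pytest.approx(p, abs=1e-10)

    def test_sum_of_squares_partition(self, rng):
        Y, groups = _simulated(rng)
        res = split_plot_anova(Y, groups)
        # reconstruct SS from F and dfs is circular; check via variances:
        # partial eta^2 in [0,1], dfs positive, eps within bounds
        L = Y.shape[1]
        for r in res:
            assert 0.0 <= r.partial_eta_sq <= 1.0
            assert r.df1 > 0 and r.df2 > 0
            assert 1.0 / (L - 1) - 1e-12 <= r.epsilon_gg <= 1.0 + 1e-12
            assert 0.0 <= r.p <= 1.0

    def test_epsilon_near_one_for_compound_symmetry(self, rng):
        Y = rng.normal(0, 1, (200, 1)) + rng.normal(0, 1, (200, 8))
        groups = np.array(["a"] * 100 + ["b"] * 100)
        res = split_plot_anova(Y, groups)
        assert res[1].epsilon_gg == pytest.approx(1.0, abs=0.05)

    def test_gg_epsilon_lower_bound_for_rank_one_covariance(self):
        # maximally non-spherical: all contrast variance on one direction
        u = np.arange(1.0, 5.0)
        cov = np.outer(u, u)
        eps = greenhouse_geisser_epsilon(cov)
        assert eps == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_all_equal_data_degenerate(self):
        with pytest.raises(DegenerateInputError):
            split_plot_anova(np.ones((8, 4)), np.array(["a"] * 4 + ["b"] * 4))

    def test_listwise_deletion(self, rng):
        Y, groups = _simulated(rng, n=10)
        tab = _long_table(Y, groups)
        tab.loc[(tab.subject == "S00") & (tab.condition == "3"),
                "value"] = np.nan
        res = pmgait.mixed_rm_anova(tab, "lye", 3)
        assert (res["n_subjects"] == 9).all()
        assert (res["n_dropped"] == 1).all()


class TestShapiroScreen:
    def test_matches_r_reference_value(self):
        # W and p from R's shapiro.test on this fixed vector
        x = [2.1, 3.4, 1.9, 5.6, 4.4, 2.7, 3.3, 6.1, 2.2, 3.9]
        tab = pd.DataFrame(dict(subject=range(10), age_group="young",
                                condition="100", pm=1, metric="rvar",
                                value=x))
        out = pmgait.shapiro_wilk_screen(tab)
        assert out["W"].iloc[0] == pytest.approx(0.9211327393, abs=1e-6)
        assert out["p"].iloc[0] == pytest.approx(0.3664993862, abs=1e-6)

    def test_degenerate_and_small_cells_flagged(self):
        tab = pd.DataFrame(dict(
            subject=list(range(5)) + [0, 1],
            age_group=["young"] * 5 + ["older"] * 2,
            condition="40", pm=1, metric="rvar",
            value=[1.0] * 5 + [0.3, 0.4],
        ))
        out = pmgait.shapiro_wilk_screen(tab).set_index("age_group")
        assert "degenerate" in out.loc["young", "flag"]
        assert "skipped" in out.loc["older", "flag"]


class TestBonferroniPosthoc:
    def test_28_comparisons_for_8_levels(self, rng):
        Y, groups = _simulated(rng)
        out = pmgait.bonferroni_posthoc(_long_table(Y, groups), "lye", 3)
        assert len(out) == 28
        assert (out["alpha_adj"] == 0.006).all()

    def test_paired_t_matches_hand_formula(self, rng):
        Y, groups = _simulated(rng, n=5, L=2)
        out = pmgait.bonferroni_posthoc(_long_table(Y, groups), "lye", 3)
        diff = Y[:, 0] - Y[:, 1]
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert out["t"].iloc[0] == pytest.approx(t_hand, rel=1e-8)

    def test_identical_pairs_flagged_nonsignificant(self):
        Y = np.tile(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0],
                              [4.0, 4.0]]), 1)
        out = pmgait.bonferroni_posthoc(
            _long_table(Y, np.array(["a", "a", "b", "b"])), "lye", 3)
        assert not out["significant"].any()
        assert (out["flag"] == "degenerate: identical paired samples").all()


class TestCorrelations:
    def test_exact_linear_relation(self):
        df = pd.DataFrame(dict(subject=range(6), condition="100", pm=3,
                               lye=2 * np.arange(6.0) + 1,
                               speed_m_s=np.arange(6.0)))
        out = pmgait.speed_stability_correlations(df)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_six_pairs(self):
        x = np.array([0.9, 1.1, 1.3, 1.0, 1.4, 1.2])
        y = np.array([2.3, 1.9, 1.4, 2.0, 1.2, 1.8])
        df = pd.DataFrame(dict(subject=range(6), condition="85", pm=3,
                               lye=y, speed_m_s=x))
        out = pmgait.speed_stability_correlations(df)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert out["r"].iloc[0] == pytest.approx(r_hand, abs=1e-10)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame(dict(subject=range(5), condition="40", pm=1,
                               lye=np.ones(5), speed_m_s=np.arange(5.0)))
        out = pmgait.speed_stability_correlations(df)
        assert np.isnan(out["r"].iloc[0])
        assert out["flag"].iloc[0] == "undefined: zero variance"

    def test_requires_speed_information(self):
        df = pd.DataFrame(dict(subject=range(5), condition="40", pm=1,
                               lye=np.arange(5.0)))
        with pytest.raises(ValidationError):
            pmgait.speed_stability_correlations(df)


class TestRequiredSampleSize:
    def test_study_design_returns_24(self):
        n = pmgait.required_sample_size(effect_f=0.25, alpha=0.05, power=0.95,
                                        n_groups=2, n_measures=8, corr=0.5,
                                        epsilon=1.0)
        assert n == 24

    def test_bracketing_at_returned_n(self):
        n = pmgait.required_sample_size()
        assert pmgait.within_factor_power(n) >= 0.95
        assert pmgait.within_factor_power(n - 2) < 0.95

    def test_monotone_in_effect_size(self):
        small = pmgait.required_sample_size(effect_f=0.25)
        large = pmgait.required_sample_size(effect_f=0.5)
        assert large <= small

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            pmgait.required_sample_size(effect_f=0.0)
        with pytest.raises(ValidationError):
            pmgait.required_sample_size(power=1.5)
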