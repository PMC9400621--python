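"""Similarity statistics: Fisher-Z, paired t, JZS BF, power, ANOVA, dz CIs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pinchbind.errors import (DegenerateDataError, InvalidParameterError,
                              NoSolutionError)
from pinchbind.stats import (PowerSpec, bonferroni_alpha, cohens_dz,
                             dz_confint, fisher_z, jzs_bf10, mixed_anova_2x2,
                             paired_t, power_paired_t, prime_probe_summary,
                             solve_power)

from _oracles import jzs_bf10_g_integral, pearson_by_hand


class TestFisherZ:
    def test_closed_form_value(self):
        assert fisher_z(0.9) == pytest.approx(0.5 * math.log(1.9 / 0.1),
                                              abs=1e-12)
        assert fisher_z(0.9) == pytest.approx(1.4722, abs=1e-4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(r=st.floats(-0.999999, 0.999999))
    def test_tanh_round_trip(self, r):
        assert math.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)


class TestPrimeProbeSummary:
    def make_cell(self, x, y, pid="p01", cond="congruent", dv="auc_Nms"):
        return pd.DataFrame({
            "participant_id": pid, "condition": cond,
            f"prime_{dv}": x, f"probe_{dv}": y})

    def test_identity_cell(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.warns(UserWarning, match="z_r infinite"):
            out = prime_probe_summary(self.make_cell(x, x), "auc_Nms")
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["mean_abs_diff"] == 0.0
        assert np.isinf(row["z_r"])

    def test_eight_trial_hand_pearson(self):
        x = [3.1, 4.5, 2.2, 5.0, 3.8, 4.1, 2.9, 3.5]
        y = [2.8, 4.9, 2.5, 4.6, 4.0, 3.7, 3.1, 3.9]
        out = prime_probe_summary(self.make_cell(x, y), "auc_Nms")
        assert out.iloc[0]["r"] == pytest.approx(pearson_by_hand(x, y),
                                                 abs=1e-12)
        assert out.iloc[0]["mean_abs_diff"] == pytest.approx(
            np.mean(np.abs(np.array(y) - np.array(x))))

    def test_zero_variance_cell_warns_and_is_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = prime_probe_summary(
                self.make_cell([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]), "auc_Nms")
        assert np.isnan(out.iloc[0]["r"])

    def test_tiny_cell_warns(self):
        with pytest.warns(UserWarning, match="< 3"):
            out = prime_probe_summary(self.make_cell([1.0, 2.0], [1.0, 2.0]),
                                      "auc_Nms")
        assert np.isnan(out.iloc[0]["r"])


class TestPairedT:
    def test_zero_mean_difference(self):
        x = np.array([10.0, 10.0, 10.0, 10.0])
        y = x - np.array([+1.0, -1.0, +2.0, -2.0])
        res = paired_t(x, y, compute_bf=False)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.dz == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("t, n, expected", [(2.08, 19, 0.48),
                                                (2.51, 53, 0.35),
                                                (-1.68, 19, 0.39)])
    def test_dz_matches_reported_effect_sizes(self, t, n, expected):
        # one unit in the 2nd decimal: t and dz were rounded independently
        assert cohens_dz(t, n) == pytest.approx(expected, abs=6e-3)

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        res = paired_t(x, y, compute_bf=False)
        ref = sps.ttest_1samp(x - y, 0.0)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 24

    def test_zero_difference_variance_is_an_error(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            paired_t(x, x + 1.0)

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 2.5])
        y = np.array([1.5, 1.0, 3.0, 5.0, 2.0])
        res = paired_t(x, y, compute_bf=False)
        assert res.n == 4


class TestJZSBayesFactor:
    # printed-report anchors: (t, n, expected BF10, relative tolerance)
    ANCHORS = [(-1.68, 19, 0.776, 0.02), (2.08, 19, 1.359, 0.02),
               (2.67, 19, 3.617, 0.02), (-2.43, 34, 2.329, 0.02),
               (2.51, 53, 2.553, 0.02), (-4.97, 19, 283.815, 0.05)]

    @pytest.mark.parametrize("t, n, expected, rtol", ANCHORS)
    def test_reproduces_reported_values(self, t, n, expected, rtol):
        assert jzs_bf10(t, n) == pytest.approx(expected, rel=rtol)

    @pytest.mark.parametrize("t, n", [(0.0, 10), (1.3, 19), (-2.2, 34),
                                      (3.7, 8), (5.5, 53)])
    def test_matches_g_integral_representation(self, t, n):
        """Effect-size-space quadrature equals the Zellner-Siow g-mixture."""
        assert jzs_bf10(t, n) == pytest.approx(jzs_bf10_g_integral(t, n),
                                               rel=1e-6)

    @pytest.mark.parametrize("n", [2, 5, 19, 100])
    def test_null_t_favours_null(self, n):
        assert jzs_bf10(0.0, n) < 1.0

    def test_strictly_increasing_in_abs_t(self):
        ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
        bfs = [jzs_bf10(t, 19) for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        # and symmetric in the sign of t
        assert jzs_bf10(-2.0, 19) == pytest.approx(jzs_bf10(2.0, 19),
                                                   rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            jzs_bf10(math.inf, 19)
        with pytest.raises(InvalidParameterError):
            jzs_bf10(1.0, 1)
        with pytest.raises(InvalidParameterError):
            jzs_bf10(1.0, 19, cauchy_scale=0.0)


class TestPower:
    def test_detectable_effect_at_n19(self):
        spec = solve_power(PowerSpec(n=19, power=0.80, alpha=0.05))
        assert round(spec.d, 2) == 0.68

    def test_required_n_for_medium_effect(self):
        spec = solve_power(PowerSpec(d=0.5, power=0.80, alpha=0.05))
        assert spec.n == 34

    def test_power_of_pooled_sample(self):
        spec = solve_power(PowerSpec(n=53, d=0.30, alpha=0.05))
        assert round(100 * spec.power) == 57

    def test_self_consistency(self):
        spec = solve_power(PowerSpec(d=0.5, power=0.80))
        assert power_paired_t(spec.n, 0.5) >= 0.80
        assert power_paired_t(spec.n - 1, 0.5) < 0.80
        d = solve_power(PowerSpec(n=19, power=0.80)).d
        assert power_paired_t(19, d) == pytest.approx(0.80, abs=1e-6)

    def test_matches_statsmodels_solver(self):
        import statsmodels.stats.power as smp
        ours = solve_power(PowerSpec(n=19, power=0.80)).d
        ref = smp.TTestPower().solve_power(effect_size=None, nobs=19,
                                           alpha=0.05, power=0.80,
                                           alternative="two-sided")
        assert ours == pytest.approx(ref, rel=1e-5)

    def test_exactly_one_unknown_required(self):
        with pytest.raises(InvalidParameterError):
            solve_power(PowerSpec(n=19))
        with pytest.raises(InvalidParameterError):
            solve_power(PowerSpec(n=19, d=0.5, power=0.8))

    def test_unreachable_power(self):
        with pytest.raises(NoSolutionError):
            solve_power(PowerSpec(n=2, power=0.999999999, alpha=1e-12))


class TestBonferroni:
    @pytest.mark.parametrize("alpha, m, expected", [(0.05, 2, 0.025),
                                                    (0.05, 1, 0.05),
                                                    (0.01, 4, 0.0025)])
    def test_division(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(InvalidParameterError):
            bonferroni_alpha(0.05, 0)


def anova_frame(groups):
    rows = []
    for g, subjects in groups.items():
        for s, (prime, probe) in enumerate(subjects):
            rows += [{"participant_id": f"{g}s{s}", "group": g,
                      "part": "prime", "value": prime},
                     {"participant_id": f"{g}s{s}", "group": g,
                      "part": "probe", "value": probe}]
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_groups_have_zero_between_f(self):
        pairs = [(1.0, 2.0), (2.0, 3.5), (0.5, 1.5), (3.0, 4.0)]
        data = anova_frame({"a": pairs, "b": pairs})
        res = {r.effect: r for r in mixed_anova_2x2(data)}
        assert res["between"].F == pytest.approx(0.0, abs=1e-12)
        assert res["interaction"].F == pytest.approx(0.0, abs=1e-12)

    def test_six_subject_hand_decomposition(self):
        """All F ratios match an explicit sums-of-squares decomposition."""
        data = anova_frame({"a": [(1.0, 3.0), (2.0, 5.0), (0.5, 2.5)],
                            "b": [(2.0, 2.5), (3.0, 4.5), (1.5, 3.0)]})
        res = {r.effect: r for r in mixed_anova_2x2(data)}

        wide = data.pivot_table(index=["participant_id", "group"],
                                columns="part", values="value")
        y = wide.to_numpy()                       # (6, 2): prime, probe
        groups = wide.index.get_level_values("group").to_numpy()
        grand = y.mean()
        # balanced design: classical textbook decomposition
        subj_means = y.mean(axis=1)
        g_means = np.array([y[groups == g].mean() for g in ("a", "b")])
        p_means = y.mean(axis=0)
        cell = np.array([[y[groups == g][:, j].mean() for j in (0, 1)]
                         for g in ("a", "b")])
        n_per = 3
        ss_A = 2 * n_per * ((g_means - grand) ** 2).sum()
        ss_B = 2 * 3 * ((p_means - grand) ** 2).sum()
        ss_AB = n_per * sum(
            (cell[i, j] - g_means[i] - p_means[j] + grand) ** 2
            for i in (0, 1) for j in (0, 1))
        ss_subj = 2 * sum(
            (subj_means[k] - g_means[0 if groups[k] == "a" else 1]) ** 2
            for k in range(6))
        ss_werr = (((y - subj_means[:, None])
                    - (cell[[0 if g == "a" else 1 for g in groups]]
                       - g_means[[0 if g == "a" else 1 for g in groups], None])
                    ) ** 2).sum()
        df_err = 4
        assert res["between"].F == pytest.approx(ss_A / (ss_subj / df_err))
        assert res["within"].F == pytest.approx(ss_B / (ss_werr / df_err))
        assert res["interaction"].F == pytest.approx(
            ss_AB / (ss_werr / df_err))
        # generalized eta squared: effect SS over effect + all error SS
        assert res["within"].ges == pytest.approx(
            ss_B / (ss_B + ss_subj + ss_werr))

    def test_single_group_within_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(5)
        prime = rng.normal(3.0, 1.0, size=12)
        probe = prime + rng.normal(0.5, 0.8, size=12)
        data = anova_frame({"a": list(zip(prime, probe))})
        res = mixed_anova_2x2(data)
        assert len(res) == 1 and res[0].effect == "within"
        tt = paired_t(prime, probe, compute_bf=False)
        assert res[0].F == pytest.approx(tt.t ** 2, abs=1e-9)
        assert res[0].p == pytest.approx(tt.p, abs=1e-9)

    def test_matches_pingouin_on_balanced_data(self):
        import pingouin as pg
        rng = np.random.default_rng(11)
        groups = {"a": [(p, p + d) for p, d in
                        zip(rng.normal(3, 1, 8), rng.normal(0.5, 0.6, 8))],
                  "b": [(p, p + d) for p, d in
                        zip(rng.normal(3.4, 1, 8), rng.normal(0.1, 0.6, 8))]}
        data = anova_frame(groups)
        ours = {r.effect: r for r in mixed_anova_2x2(data)}
        ref = pg.mixed_anova(data=data, dv="value", within="part",
                             between="group", subject="participant_id")
        ref = ref.set_index("Source")
        assert ours["between"].F == pytest.approx(ref.loc["group", "F"],
                                                  rel=1e-9)
        assert ours["within"].F == pytest.approx(ref.loc["part", "F"],
                                                 rel=1e-9)
        assert ours["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert ours["between"].p == pytest.approx(ref.loc["group", "p_unc"],
                                                  rel=1e-9)

    def test_missing_cells_rejected(self):
        data = anova_frame({"a": [(1.0, 2.0), (2.0, 3.0)],
                            "b": [(1.5, 2.5), (2.5, 3.5)]})
        from pinchbind.errors import DataError
        with pytest.raises(DataError):
            mixed_anova_2x2(data.drop(index=0))


class TestDzConfint:
    def test_null_t_is_symmetric(self):
        lo, hi = dz_confint(0.0, 19)
        assert lo == pytest.approx(-hi, abs=1e-9)
        assert lo < 0 < hi

    def test_interval_orders_and_contains_point(self):
        lo, hi = dz_confint(2.08, 19)
        assert lo < 2.08 / math.sqrt(19) < hi

    def test_sign_flips_with_t(self):
        lo_p, hi_p = dz_confint(2.5, 19)
        lo_n, hi_n = dz_confint(-2.5, 19)
        assert lo_n == pytest.approx(-hi_p, abs=1e-9)
        assert hi_n == pytest.approx(-lo_p, abs=1e-9)
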