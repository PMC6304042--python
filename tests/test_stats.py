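import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssvep_ratio.ratio_stats import (baseline_ratios, frequency_ratio,
                                     median_split, mixed_anova,
                                     oneway_anova_contrasts,
                                     regress_ratio_on_trait, ratio_index,
                                     ttest_ind)
from ssvep_ratio.crf import SupraBaselineSet

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestFrequencyRatio:
    @pytest.mark.parametrize("a1,a2,expected", [
        (4.0, 4.0, 0.0), (4.0, 0.0, 1.0), (0.0, 4.0, -1.0), (3.0, 1.0, 0.5),
    ])
    def test_values(self, a1, a2, expected):
        assert frequency_ratio(a1, a2) == pytest.approx(expected)

    @given(positive, positive)
    def test_antisymmetry(self, a, b):
        assert frequency_ratio(a, b) == pytest.approx(-frequency_ratio(b, a))

    @given(positive, positive, st.floats(1e-3, 1e3))
    def test_scale_invariance(self, a, b, k):
        assert frequency_ratio(k * a, k * b) == pytest.approx(
            frequency_ratio(a, b), abs=1e-9)

    @given(positive, positive)
    def test_bounded(self, a, b):
        assert -1.0 <= frequency_ratio(a, b) <= 1.0

    def test_both_zero_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(frequency_ratio(0.0, 0.0))

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            frequency_ratio(-1.0, 1.0)


def response_table(per_subject, group="g"):
    """per_subject: {subject: {contrast: (a1, a2)}} -> long frame."""
    rows = []
    for subject, by_c in per_subject.items():
        for contrast, (a1, a2) in by_c.items():
            rows.append((subject, group, float(contrast), 1, a1))
            rows.append((subject, group, float(contrast), 2, a2))
    return pd.DataFrame(rows, columns=["subject_id", "group", "contrast",
                                       "harmonic", "amplitude"])


class TestRatioIndex:
    def test_constant_ratio_across_conditions(self):
        table = response_table({"s0": {c: (4.0, 2.0) for c in (10, 20, 30)}})
        out = ratio_index(table, [10.0, 20.0, 30.0])
        assert out["value"].iloc[0] == pytest.approx(1.0 / 3.0)
        assert out["n_conditions_averaged"].iloc[0] == 3

    def test_single_condition_equals_its_ratio(self):
        table = response_table({"s0": {10.0: (3.0, 1.0)}})
        out = ratio_index(table, [10.0])
        assert out["value"].iloc[0] == pytest.approx(0.5)

    def test_invariant_to_subject_responsiveness(self, rng):
        per = {f"s{i}": {c: (rng.uniform(1, 5), rng.uniform(1, 5))
                         for c in (10.0, 20.0)} for i in range(4)}
        scaled = {s: {c: (7.3 * a1, 7.3 * a2) for c, (a1, a2) in d.items()}
                  for s, d in per.items()}
        out1 = ratio_index(response_table(per), [10.0, 20.0])
        out2 = ratio_index(response_table(scaled), [10.0, 20.0])
        np.testing.assert_allclose(out1["value"], out2["value"], atol=1e-12)

    def test_missing_condition_warns_and_uses_available(self):
        table = response_table({"s0": {10.0: (3.0, 1.0)},
                                "s1": {10.0: (3.0, 1.0), 20.0: (1.0, 3.0)}})
        with pytest.warns(UserWarning, match="missing"):
            out = ratio_index(table, [10.0, 20.0])
        s0 = out.set_index("subject_id").loc["s0"]
        assert s0["value"] == pytest.approx(0.5)
        assert s0["n_conditions_averaged"] == 1

    def test_accepts_suprabaseline_set(self):
        table = response_table({"s0": {10.0: (4.0, 2.0)}})
        out = ratio_index(table, SupraBaselineSet(1, (10.0,), 0.05))
        assert out["value"].iloc[0] == pytest.approx(1.0 / 3.0)


class TestBaselineRatios:
    def test_two_group_shift(self):
        df = pd.DataFrame({"group": ["a"] * 2 + ["b"] * 2,
                           "value": [0.1, 0.3, 0.3, 0.5]})
        out = baseline_ratios(df)
        means = out.groupby("group")["value"].mean()
        assert means["a"] == pytest.approx(-0.1)
        assert means["b"] == pytest.approx(0.1)

    def test_group_differences_preserved(self, rng):
        df = pd.DataFrame({"group": rng.choice(["a", "b", "c"], 30),
                           "value": rng.normal(0, 1, 30)})
        out = baseline_ratios(df)
        before = df.groupby("group")["value"].mean()
        after = out.groupby("group")["value"].mean()
        np.testing.assert_allclose(before["a"] - before["b"],
                                   after["a"] - after["b"], atol=1e-12)


def mixed_frame(y, groups):
    """y: (n_subjects, 2) amplitudes; groups: labels per subject."""
    rows = []
    for i, (row, g) in enumerate(zip(y, groups)):
        for h, val in zip((1, 2), row):
            rows.append((f"s{i}", g, h, val))
    return pd.DataFrame(rows, columns=["subject_id", "group", "harmonic",
                                       "amplitude"])


def splitplot_oracle(y, groups):
    """Brute-force split-plot sums of squares for a balanced 2x2 design."""
    labels = sorted(set(groups))
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    k = y.shape[1]
    n = len(y)
    g = len(labels)
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    ss_group = sum(k * (groups == lab).sum()
                   * (subj_mean[groups == lab].mean() - grand) ** 2
                   for lab in labels)
    ss_err_b = sum(k * ((subj_mean[groups == lab]
                         - subj_mean[groups == lab].mean()) ** 2).sum()
                   for lab in labels)
    ss_within = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_cells = sum((groups == lab).sum()
                   * ((y[groups == lab].mean(axis=0) - grand) ** 2).sum()
                   for lab in labels) - ss_group - ss_within
    resid = 0.0
    for lab in labels:
        sub = y[groups == lab]
        cell = sub.mean(axis=0)
        centered = sub - sub.mean(axis=1, keepdims=True)
        cell_centered = cell - cell.mean()
        resid += ((centered - cell_centered) ** 2).sum()
    f_group = (ss_group / (g - 1)) / (ss_err_b / (n - g))
    f_within = (ss_within / (k - 1)) / (resid / ((n - g) * (k - 1)))
    f_inter = (ss_cells / ((g - 1) * (k - 1))) / (resid / ((n - g) * (k - 1)))
    return f_group, f_within, f_inter


class TestMixedAnova:
    def test_matches_sums_of_squares_oracle_balanced(self):
        y = np.array([[3.1, 2.0], [2.9, 2.2], [3.5, 2.1], [3.0, 2.4],
                      [3.2, 1.1], [3.4, 1.0], [2.8, 1.3], [3.1, 0.9]])
        groups = ["a"] * 4 + ["b"] * 4
        res = mixed_anova(mixed_frame(y, groups))
        fg, fw, fi = splitplot_oracle(y, groups)
        assert res["group"].statistic == pytest.approx(fg, abs=1e-9)
        assert res["harmonic"].statistic == pytest.approx(fw, abs=1e-9)
        assert res["interaction"].statistic == pytest.approx(fi, abs=1e-9)
        assert res["interaction"].dof == (1.0, 6.0)

    @pytest.mark.parametrize("n_a,n_b", [(10, 10), (13, 17)])
    def test_matches_pingouin(self, n_a, n_b, rng):
        y = rng.normal(0, 1, size=(n_a + n_b, 2))
        y[n_a:, 1] += 0.8
        groups = ["a"] * n_a + ["b"] * n_b
        res = mixed_anova(mixed_frame(y, groups))
        aov = pg.mixed_anova(data=mixed_frame(y, groups), dv="amplitude",
                             within="harmonic", subject="subject_id",
                             between="group").set_index("Source")
        assert res["group"].statistic == pytest.approx(aov.loc["group", "F"],
                                                       abs=1e-9)
        assert res["harmonic"].statistic == pytest.approx(
            aov.loc["harmonic", "F"], abs=1e-9)
        assert res["interaction"].statistic == pytest.approx(
            aov.loc["Interaction", "F"], abs=1e-9)
        assert res["interaction"].p_value == pytest.approx(
            aov.loc["Interaction", "p_unc"], abs=1e-9)

    def test_incomplete_subject_excluded_with_warning(self, rng):
        y = rng.normal(0, 1, size=(6, 2))
        df = mixed_frame(y, ["a"] * 3 + ["b"] * 3)
        df = df.drop(df[(df.subject_id == "s0") & (df.harmonic == 2)].index)
        with pytest.warns(UserWarning, match="excluding"):
            res = mixed_anova(df)
        # five complete subjects remain: interaction dof (1, N - 2) = (1, 3)
        assert res["interaction"].dof == (1.0, 3.0)

    def test_interaction_direction(self):
        y = np.array([[3.0, 3.0], [3.1, 3.1], [3.0, 1.0], [3.1, 1.1]])
        res = mixed_anova(mixed_frame(y, ["a", "a", "b", "b"]))
        assert res["interaction"].effect_direction == -1


class TestOnewayAnovaContrasts:
    def test_identical_groups_null(self):
        data = {"ctrl": [1.0, 2.0, 3.0], "m1": [1.0, 2.0, 3.0],
                "m2": [1.0, 2.0, 3.0]}
        res = oneway_anova_contrasts(data, "ctrl")
        assert res["omnibus"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res["contrast_m1"].p_value == pytest.approx(1.0)

    def test_matches_pooled_variance_oracle(self):
        data = {"ctrl": [5.0, 6.0, 7.0, 6.0], "m1": [7.0, 8.0, 9.0, 8.0],
                "m2": [4.0, 5.0, 4.5, 4.5]}
        res = oneway_anova_contrasts(data, "ctrl")
        # brute-force decomposition
        all_vals = np.concatenate(list(data.values()))
        grand = all_vals.mean()
        ss_b = sum(len(v) * (np.mean(v) - grand) ** 2 for v in data.values())
        ss_w = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                   for v in data.values())
        f = (ss_b / 2) / (ss_w / 9)
        assert res["omnibus"].statistic == pytest.approx(f, abs=1e-9)
        assert res["omnibus"].dof == (2.0, 9.0)
        mse = ss_w / 9
        t_m1 = (8.0 - 6.0) / np.sqrt(mse * (1 / 4 + 1 / 4))
        assert res["contrast_m1"].statistic == pytest.approx(t_m1, abs=1e-9)
        assert res["contrast_m1"].dof == (9.0,)

    def test_control_label_required(self):
        with pytest.raises(ValueError, match="control"):
            oneway_anova_contrasts({"a": [1, 2], "b": [3, 4]}, "zzz")


class TestTtestInd:
    def test_identical_groups(self):
        res = ttest_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self):
        res = ttest_ind([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # pooled variance 1, se = sqrt(2/3)
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0),
                                              abs=1e-9)
        assert res.dof == (4.0,)

    @given(st.floats(-10, 10))
    def test_shift_invariance(self, c):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0, 3.0]
        t0 = ttest_ind(a, b).statistic
        t1 = ttest_ind([x + c for x in a], [x + c for x in b]).statistic
        assert t1 == pytest.approx(t0, abs=1e-9)

    def test_zero_variance_equal_means(self):
        res = ttest_ind([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestRegression:
    def test_perfect_line(self):
        res = regress_ratio_on_trait([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.extra["R"] == pytest.approx(1.0)
        assert res.effect_direction == 1

    def test_matches_least_squares_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.2, 0.5, 0.3, 0.9, 0.8])
        res = regress_ratio_on_trait(x, y)
        # explicit normal equations
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        r2 = 1 - np.sum((y - (y.mean() + slope * (x - x.mean()))) ** 2) \
            / np.sum((y - y.mean()) ** 2)
        f = r2 * 3 / (1 - r2)
        assert res.extra["R"] == pytest.approx(np.sqrt(r2), abs=1e-9)
        assert res.statistic == pytest.approx(f, abs=1e-9)
        assert res.dof == (1.0, 3.0)

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError, match="variance"):
            regress_ratio_on_trait([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestMedianSplit:
    def test_split_labels(self):
        labels, med = median_split([5, 10, 14, 20, 30])
        assert med == 14.0
        assert list(labels) == ["low", "low", "low", "high", "high"]
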