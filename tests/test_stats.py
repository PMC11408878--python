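"""Diagnostic statistics: comparisons, ROC/Youden, likelihood ratios,
regression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import lungwater as lw
from lungwater.errors import InputError, ParameterError
from lungwater.stats import (
    binormal_auc,
    compare_groups,
    correlate,
    diagnostic_performance,
    diagnostic_performance_at_cutoff,
    roc_youden,
    stepwise_multivariable,
    univariable_scan,
)


class TestCompareGroups:
    def test_identical_samples_no_effect(self):
        x = np.r_[np.arange(20.0), np.arange(20.0)]
        g = np.r_[["a"] * 20, ["b"] * 20]
        assert compare_groups(x, g).p_value > 0.9

    def test_normality_gate_selects_t_then_mw(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.2, 1, 40)
        assert compare_groups(np.r_[a, b], np.r_[["a"] * 40, ["b"] * 40]).test_used == "t"
        a2 = rng.lognormal(0, 1.2, 60)
        b2 = rng.lognormal(0.3, 1.2, 60)
        res = compare_groups(np.r_[a2, b2], np.r_[["a"] * 60, ["b"] * 60])
        assert res.test_used == "mann_whitney"
        assert "median" in next(iter(res.summaries.values()))

    def test_detection_rate_matches_power_oracle(self):
        """Two-group LWD comparison at the study's group sizes: empirical
        detection rate agrees with the closed-form noncentral-t power."""
        sd_pool = math.sqrt((14 * 4.3**2 + 154 * 5.0**2) / 168)
        ncp = (30.4 - 27.2) / (sd_pool * math.sqrt(1 / 15 + 1 / 155))
        crit = sps.t.ppf(0.975, 168)
        power = 1 - sps.nct.cdf(crit, 168, ncp) + sps.nct.cdf(-crit, 168, ncp)
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 60
        for _ in range(n_seeds):
            vals = np.r_[rng.normal(27.2, 4.3, 15), rng.normal(30.4, 5.0, 155)]
            g = np.r_[["c"] * 15, ["r"] * 155]
            hits += compare_groups(vals, g).p_value < 0.05
        assert hits / n_seeds == pytest.approx(power, abs=0.15)

    def test_chi2_sex_table(self):
        """2x2 sex-by-group table (8/15 vs 110/155 male): p ~ 0.16, not
        significant."""
        values = np.r_[["M"] * 8, ["F"] * 7, ["M"] * 110, ["F"] * 45]
        g = np.r_[["c"] * 15, ["r"] * 155]
        res = compare_groups(values, g, variable_kind="categorical")
        assert res.test_used == "chi2"
        assert res.p_value > 0.05
        assert res.p_value == pytest.approx(0.16, abs=0.01)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups(np.r_[1.0, 2.0, 3.0], np.r_[["a"], ["b"], ["b"]])


class TestRocYouden:
    def test_perfect_separation(self):
        vals = np.r_[np.arange(10.0), np.arange(20.0, 30.0)]
        labels = np.r_[np.zeros(10), np.ones(10)].astype(bool)
        res = roc_youden(vals, labels)
        assert res.auc == pytest.approx(1.0)
        assert 9.0 < res.youden_cutoff <= 20.0
        assert res.youden_index == pytest.approx(1.0)

    def test_null_auc(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert roc_youden(vals, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_cutoff_matches_brute_force(self):
        """Exhaustive maximization of J over all thresholds, 50 datasets."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(10, 40))
            vals = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_youden(vals, labels)
            pos, neg = vals[labels], vals[~labels]
            cuts = np.unique(np.r_[vals, vals.max() + 1.0])
            j = np.array([(pos >= c).mean() + (neg < c).mean() - 1 for c in cuts])
            assert res.youden_index == pytest.approx(j.max(), abs=1e-12)
            ties = cuts[np.isclose(j, j.max())]
            assert res.youden_cutoff == pytest.approx(ties.max())  # higher specificity

    def test_binormal_closed_form(self):
        """Empirical AUC at the study's LWD parameters vs the binormal
        closed form Phi(3.2/sqrt(4.3^2+5.0^2)) ~ 0.686."""
        expected = binormal_auc(27.2, 4.3, 30.4, 5.0)
        assert expected == pytest.approx(0.686, abs=0.001)
        rng = np.random.default_rng(4)
        n = 100_000
        vals = np.r_[rng.normal(27.2, 4.3, n), rng.normal(30.4, 5.0, n)]
        labels = np.r_[np.zeros(n), np.ones(n)].astype(bool)
        assert roc_youden(vals, labels).auc == pytest.approx(expected, abs=0.01)

    def test_auc_matches_independent_implementation(self):
        """Cross-check the rank-based AUC against scikit-learn's."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        vals = np.r_[rng.normal(0, 1, 80), rng.normal(0.7, 1.3, 120)]
        labels = np.r_[np.zeros(80), np.ones(120)].astype(bool)
        assert roc_youden(vals, labels).auc == pytest.approx(
            roc_auc_score(labels, vals), abs=1e-12
        )

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
        labels = np.r_[np.zeros(50), np.ones(50)].astype(bool)
        res = roc_youden(vals, labels)
        lo, hi = res.auc_ci_95
        assert lo < res.auc < hi
        assert 0.0 <= lo and hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_youden(np.arange(5.0), np.ones(5, dtype=bool))


class TestDiagnosticPerformance:
    def test_study_operating_point(self):
        """Sens 72 %, spec 73 % at prevalence 155/170 reproduces LR+ 2.7,
        inverse LR- 2.6, PPV 96 %, NPV 20 % at the reported rounding."""
        d = diagnostic_performance(0.72, 0.73, 155 / 170)
        assert round(d.lr_pos, 1) == 2.7
        assert round(d.inv_lr_neg, 1) == 2.6
        assert round(d.ppv * 100) == 96
        assert round(d.npv * 100) == 20

    def test_uninformative_and_perfect(self):
        d = diagnostic_performance(0.5, 0.5, 0.3)
        assert d.lr_pos == pytest.approx(1.0) and d.inv_lr_neg == pytest.approx(1.0)
        p = diagnostic_performance(1.0, 1.0, 0.5)
        assert p.ppv == pytest.approx(1.0) and p.npv == pytest.approx(1.0)
        assert math.isinf(p.lr_pos) and math.isinf(p.inv_lr_neg)

    @given(
        sens=st.floats(0.05, 0.95),
        spec=st.floats(0.05, 0.95),
        prev=st.floats(0.05, 0.95),
    )
    def test_odds_identity(self, sens, spec, prev):
        """ppv/(1-ppv) = LR+ * prev/(1-prev) on all valid inputs."""
        d = diagnostic_performance(sens, spec, prev)
        lhs = d.ppv / (1 - d.ppv)
        rhs = d.lr_pos * prev / (1 - prev)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            diagnostic_performance(1.2, 0.5, 0.5)
        with pytest.raises(ParameterError):
            diagnostic_performance(0.5, 0.5, 0.0)

    def test_empirical_cutoff_path(self):
        vals = np.r_[np.full(10, 20.0), np.full(10, 40.0)]
        labels = np.r_[np.zeros(10), np.ones(10)].astype(bool)
        d = diagnostic_performance_at_cutoff(vals, labels, 30.0)
        assert d.sensitivity == 1.0 and d.specificity == 1.0


class TestRegression:
    def test_identity_covariate(self):
        y = np.arange(50.0)
        df = pd.DataFrame({"x": y, "y": y})
        uni = univariable_scan(df, "y")
        assert uni.loc["x", "r_squared"] == pytest.approx(1.0)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=5000), "y": rng.normal(size=5000)})
        assert univariable_scan(df, "y").loc["x", "r_squared"] < 0.01

    def test_constant_covariate_flagged(self):
        df = pd.DataFrame({"x": np.ones(20), "y": np.arange(20.0)})
        uni = univariable_scan(df, "y")
        assert np.isnan(uni.loc["x", "r_squared"])
        assert uni.loc["x", "note"] == "constant"

    def test_cohort_bmi_r2_self_consistent(self):
        """Generator self-consistency at the study size: univariable R2 of
        true LWD on BMI within +-0.08 of the 0.323 target at n = 170."""
        subs = lw.sample_cohort(lw.CohortParams.default(seed=10), 15, 155)
        df = pd.DataFrame({"bmi": [s.bmi for s in subs], "lwd": [s.true_lwd for s in subs]})
        uni = univariable_scan(df, "lwd")
        assert uni.loc["bmi", "r_squared"] == pytest.approx(0.323, abs=0.08)

    def test_duplicate_covariate_excluded_for_collinearity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        y = x + rng.normal(scale=0.5, size=300)
        df = pd.DataFrame({"x1": x, "x2": x.copy(), "y": y})
        res = stepwise_multivariable(df, "y")
        assert len(res.retained) == 1
        assert len(res.excluded_collinear) == 1
        assert set(res.excluded_collinear[0]) == {"x1", "x2"}

    def test_all_noise_gives_empty_model(self):
        # distinct Fourier modes: covariates exactly orthogonal to the outcome
        t = np.arange(100)
        df = pd.DataFrame(
            {f"x{j}": np.cos(2 * np.pi * (j + 1) * t / 100) for j in range(4)}
            | {"y": np.cos(2 * np.pi * 10 * t / 100)}
        )
        res = stepwise_multivariable(df, "y")
        assert res.retained.empty
        assert res.global_r2 == 0.0
        assert any("empty model" in n for n in res.notes)

    def test_true_predictor_recovered(self):
        rng = np.random.default_rng(8)
        n = 1000
        x = rng.normal(size=n)
        df = pd.DataFrame(
            {"signal": x}
            | {f"n{j}": rng.normal(size=n) for j in range(5)}
            | {"y": 2.0 * x + rng.normal(size=n)}
        )
        res = stepwise_multivariable(df, "y")
        assert "signal" in res.retained.index

    def test_column_order_invariance(self):
        rng = np.random.default_rng(9)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + 0.5 * x2 + rng.normal(size=n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "z": rng.normal(size=n), "y": y})
        a = stepwise_multivariable(df, "y")
        b = stepwise_multivariable(df[["z", "x2", "x1", "y"]], "y")
        assert set(a.retained.index) == set(b.retained.index)
        assert a.global_r2 == pytest.approx(b.global_r2, rel=1e-9)


class TestCorrelate:
    def test_pearson_and_spearman(self):
        x = np.arange(50.0)
        y = x**3  # monotone, nonlinear
        r_p, _ = correlate(x, y)
        r_s, _ = correlate(x, y, method="spearman")
        assert r_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_unknown_method(self):
        with pytest.raises(ParameterError):
            correlate([1, 2], [1, 2], method="kendall")
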