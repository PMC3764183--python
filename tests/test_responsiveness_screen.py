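"""Pearson correlation, robust IRLS fitting, and outlier calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telostress.responsiveness_screen import (
    call_outliers,
    pearson,
    response_ratio,
    robust_fit,
)
from telostress.synthetic_data import gen_screen


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(10.0)
        rep = pearson(x, 2 * x + 1)
        assert rep.r == pytest.approx(1.0)
        assert rep.p < 1e-10

    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        # brute-force product-moment formula
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson(x, y).r == pytest.approx(r_direct, abs=1e-12)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        a=st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-10, max_value=10),
        c=st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-3),
        d=st.floats(min_value=-10, max_value=10),
    )
    @settings(max_examples=30, derandomize=True)
    def test_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        r0 = pearson(x, y).r
        r1 = pearson(a * x + b, c * y + d).r
        assert r1 == pytest.approx(np.sign(a * c) * r0, abs=1e-8)


class TestRobustFit:
    def test_noiseless_line_exact(self):
        x = np.linspace(150, 450, 40)
        fit = robust_fit(x, -0.8 * x + 40.0)
        assert fit.slope == pytest.approx(-0.8, abs=1e-6)
        assert fit.intercept == pytest.approx(40.0, abs=1e-4)
        assert fit.converged

    def test_contamination_recovery(self):
        hits = 0
        for seed in range(30):
            screen, truth = gen_screen(
                n_mutants=100, slope=-0.8, sigma=10.0,
                outlier_fraction=0.1, outlier_shift=80.0, seed=seed,
            )
            fit = robust_fit(screen.table["initial"], screen.table["delta"])
            hits += abs(fit.slope - truth.true_slope) / 0.8 <= 0.05
        assert hits >= 28

    def test_beats_ols_under_contamination(self):
        robust_err, ols_err = [], []
        for seed in range(30):
            screen, truth = gen_screen(
                n_mutants=100, slope=-0.8, sigma=10.0,
                outlier_fraction=0.1, outlier_shift=80.0, seed=seed,
            )
            x = screen.table["initial"].to_numpy()
            y = screen.table["delta"].to_numpy()
            fit = robust_fit(x, y)
            ols = np.polyfit(x, y, 1)
            robust_err.append(abs(fit.slope - truth.true_slope))
            ols_err.append(abs(ols[0] - truth.true_slope))
        assert np.median(robust_err) < np.median(ols_err)

    def test_matches_statsmodels_rlm(self):
        # independent IRLS implementation as cross-check
        import statsmodels.api as sm

        screen, _ = gen_screen(n_mutants=100, outlier_fraction=0.1,
                               outlier_shift=80.0, seed=3)
        x = screen.table["initial"].to_numpy()
        y = screen.table["delta"].to_numpy()
        fit = robust_fit(x, y)
        rlm = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight()).fit()
        assert fit.slope == pytest.approx(rlm.params[1], rel=0.02)
        assert fit.intercept == pytest.approx(rlm.params[0], abs=5.0)

    def test_breakdown_bounded_at_10pct_gross_contamination(self):
        clean_err, contam_err = [], []
        for seed in range(30):
            clean, truth = gen_screen(n_mutants=100, slope=-0.8, sigma=10.0,
                                      outlier_fraction=0.0, seed=seed)
            contam, _ = gen_screen(n_mutants=100, slope=-0.8, sigma=10.0,
                                   outlier_fraction=0.1, outlier_shift=200.0,
                                   seed=seed)
            clean_err.append(abs(
                robust_fit(clean.table["initial"], clean.table["delta"]).slope + 0.8))
            contam_err.append(abs(
                robust_fit(contam.table["initial"], contam.table["delta"]).slope + 0.8))
        assert np.median(contam_err) <= 2.0 * np.median(clean_err) + 1e-3

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="points"):
            robust_fit(np.arange(5.0), np.arange(5.0) * 2 + np.array([0, .1, -.1, .2, 0]))

    def test_weights_in_unit_interval_and_residual_identity(self):
        screen, _ = gen_screen(n_mutants=80, outlier_fraction=0.05, seed=5)
        x = screen.table["initial"].to_numpy()
        y = screen.table["delta"].to_numpy()
        fit = robust_fit(x, y)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))
        np.testing.assert_allclose(
            fit.residuals, y - (fit.slope * x + fit.intercept), atol=1e-9
        )


class TestCallOutliers:
    def test_calibration_on_clean_normal_residuals(self):
        fracs = []
        for seed in range(10):
            screen, _ = gen_screen(n_mutants=1000, outlier_fraction=0.0,
                                   sigma=10.0, seed=seed)
            fit = robust_fit(screen.table["initial"], screen.table["delta"])
            calls = call_outliers(fit, alpha=0.05, stress_direction="shortening")
            fracs.append(calls.table["flagged"].mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_tiny_alpha_flags_nothing(self):
        screen, _ = gen_screen(n_mutants=200, outlier_fraction=0.0, seed=1)
        fit = robust_fit(screen.table["initial"], screen.table["delta"])
        calls = call_outliers(fit, alpha=1e-9, stress_direction="elongating")
        assert not calls.table["flagged"].any()

    def test_planted_outliers_recovered(self):
        recalls, precisions = [], []
        for seed in range(30):
            screen, truth = gen_screen(
                n_mutants=100, sigma=10.0, outlier_fraction=0.05,
                outlier_shift=80.0, seed=seed,
            )
            fit = robust_fit(screen.table["initial"], screen.table["delta"])
            calls = call_outliers(fit, alpha=0.05, stress_direction="elongating",
                                  mutants=screen.table["mutant"])
            flagged = set(calls.table.loc[calls.table["flagged"], "mutant"])
            recalls.append(len(flagged & truth.screen_outliers) / len(truth.screen_outliers))
            precisions.append(
                len(flagged & truth.screen_outliers) / max(len(flagged), 1))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.7

    def test_direction_assignment(self):
        rng = np.random.default_rng(0)
        x = np.linspace(150, 450, 50)
        y = -0.5 * x + rng.normal(0, 5, 50)
        y[0] -= 100  # extra shortening
        y[1] += 100  # less shortening than predicted
        fit = robust_fit(x, y)
        calls = call_outliers(fit, alpha=0.05, stress_direction="shortening")
        t = calls.table
        assert t.loc[0, "flagged"] and t.loc[0, "direction"] == "over_responsive"
        assert t.loc[1, "flagged"] and t.loc[1, "direction"] == "under_responsive"
        # same residuals under an elongating stress flip roles
        calls_e = call_outliers(fit, alpha=0.05, stress_direction="elongating")
        assert calls_e.table.loc[0, "direction"] == "under_responsive"

    def test_rank_method_flags_fixed_count(self):
        screen, _ = gen_screen(n_mutants=100, outlier_fraction=0.0, seed=2)
        fit = robust_fit(screen.table["initial"], screen.table["delta"])
        calls = call_outliers(fit, alpha=0.05, stress_direction="elongating",
                              method="rank")
        assert int(calls.table["flagged"].sum()) == 4  # 2 per side

    def test_degenerate_scale_rejected(self):
        from telostress.responsiveness_screen import RegressionFit

        fit = RegressionFit(slope=2.0, intercept=1.0, scale=0.0,
                            weights=np.ones(20), residuals=np.zeros(20),
                            converged=True, n_iter=1)
        with pytest.raises(ValueError, match="scale"):
            call_outliers(fit, alpha=0.05, stress_direction="elongating")
        with pytest.raises(ValueError, match="scale"):
            call_outliers(fit, alpha=0.05, stress_direction="elongating",
                          scale_estimator="robust")


class TestResponseRatio:
    def test_basic_and_zero_delta(self):
        ratio, finite = response_ratio([200.0, 300.0], [100.0, 0.0])
        assert ratio[0] == pytest.approx(2.0)
        assert np.isinf(ratio[1]) and not finite[1]

    def test_ordering_invariant_under_common_rescaling(self, rng):
        initial = rng.uniform(100, 500, 20)
        delta = rng.normal(50, 30, 20)
        delta[delta == 0] = 1.0
        r1, _ = response_ratio(initial, delta)
        r2, _ = response_ratio(3.7 * initial, 3.7 * delta)
        assert np.array_equal(np.argsort(r1), np.argsort(r2))
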