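import numpy as np
import pandas as pd
import pytest

from relcap import (
    DesignError,
    SpecLimits,
    StabilityTable,
    ancova_type3,
    confidence_band,
    critical_alpha,
    fit_batch,
    fit_pooled,
    poolability,
    prediction_band,
    shelf_life,
    stability_analysis,
)
from relcap.stability import AncovaTable, BatchFit
from statsmodels.stats.anova import anova_lm

from .conftest import SEED

ICH_TIMES = [0.0, 3.0, 6.0, 9.0, 12.0]


def make_stability(slopes, intercepts=None, rsd=0.0, times=ICH_TIMES, seed=0, reps=1):
    """Straight-line degradation data with optional noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, b1 in enumerate(slopes):
        b0 = 1.46 if intercepts is None else intercepts[i]
        for t in np.repeat(times, reps):
            noise = rng.normal(0, rsd) if rsd else 0.0
            rows.append((f"b{i + 1}", float(t), float(b0 + b1 * t + noise)))
    return StabilityTable.from_records(rows)


class TestBatchFit:
    def test_exact_line_recovered(self):
        data = make_stability([-0.01])
        fit = fit_batch(data, "b1")
        assert fit.b1 == pytest.approx(-0.01, abs=1e-14)
        assert fit.b0 == pytest.approx(1.46, abs=1e-12)
        assert fit.rsd == pytest.approx(0.0, abs=1e-12)

    def test_slope_se_identity(self):
        rng = np.random.default_rng(SEED)
        for _ in range(20):
            data = make_stability([-0.01], rsd=0.01, seed=rng.integers(2**31))
            fit = fit_batch(data, "b1")
            assert fit.slope_se**2 == pytest.approx(fit.rsd**2 / fit.sxx, rel=1e-12)

    def test_missing_batch_and_degenerate_times(self):
        data = make_stability([-0.01])
        with pytest.raises(Exception):
            fit_batch(data, "zz")
        with pytest.raises(DesignError):
            BatchFit("x", 1.0, -0.01, 0.0, 5, 3.0, 0.0)


class TestPooledFit:
    def test_identical_batches_have_zero_deviations(self):
        data = make_stability([-0.01, -0.01, -0.01], rsd=0.01, seed=1)
        # duplicate one batch's values into all three so lines coincide
        df = data.df.copy()
        base = df[df.batch_id == "b1"][["time_months", "value"]]
        rows = []
        for b in ("b1", "b2", "b3"):
            for _, r in base.iterrows():
                rows.append((b, r.time_months, r.value))
        data = StabilityTable.from_records(rows)
        pooled = fit_pooled(data)
        for v in pooled.alpha_dev.values():
            assert v == pytest.approx(0.0, abs=1e-10)
        for v in pooled.beta_dev.values():
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_sum_zero_constraints(self):
        data = make_stability([-0.008, -0.010, -0.012], rsd=0.012, seed=2)
        pooled = fit_pooled(data)
        assert sum(pooled.alpha_dev.values()) == pytest.approx(0.0, abs=1e-10)
        assert sum(pooled.beta_dev.values()) == pytest.approx(0.0, abs=1e-10)

    def test_interaction_model_reproduces_per_batch_lines(self):
        data = make_stability([-0.008, -0.010, -0.012], rsd=0.012, seed=3)
        pooled = fit_pooled(data)
        for b in data.batches:
            sub = data.batch_frame(b)
            single = fit_batch(data, b)
            a = pooled.alpha0 + pooled.alpha_dev[b]
            s = pooled.beta0 + pooled.beta_dev[b]
            fitted_full = a + s * sub["time_months"].to_numpy()
            fitted_sep = single.predict(sub["time_months"].to_numpy())
            assert np.allclose(fitted_full, fitted_sep, atol=1e-10)


class TestAncova:
    def test_type3_equals_type1_on_balanced_design(self):
        """On a balanced design the time and interaction columns are
        orthogonal to everything fitted before them, so the marginal and
        sequential sums of squares coincide for those terms.  (The batch
        main effect is exempt: with an uncentred covariate its marginal SS
        tests intercept differences at t=0, not at the design centre.)"""
        data = make_stability([-0.008, -0.010, -0.012], rsd=0.012, seed=4)
        pooled = fit_pooled(data)
        t1 = anova_lm(pooled.model, typ=1)
        t3 = anova_lm(pooled.model, typ=3)
        for src in ("time_months", "C(batch, Sum):time_months"):
            assert t1.loc[src, "sum_sq"] == pytest.approx(
                t3.loc[src, "sum_sq"], abs=1e-10
            )

    def test_huge_slope_difference_detected(self):
        data = make_stability([-0.005, -0.005, -0.2], rsd=0.005, seed=5)
        table = ancova_type3(data)
        assert table.interaction_p < 1e-6

    def test_residual_ms_matches_pooled_rsd(self):
        data = make_stability([-0.008, -0.010, -0.012], rsd=0.012, seed=6)
        table = ancova_type3(data)
        pooled = fit_pooled(data)
        assert table.residual_ms == pytest.approx(pooled.rsd**2, rel=1e-10)


def _fake_table(p_int, p_batch):
    rows = {
        "Intercept": dict(sum_sq=5.0, df=1, mean_sq=5.0, F=1e4, p=0.0),
        "Times": dict(sum_sq=7e-3, df=1, mean_sq=7e-3, F=45.0, p=0.0),
        "Batch": dict(sum_sq=1e-4, df=2, mean_sq=5e-5, F=0.5, p=p_batch),
        "Times × Batch": dict(sum_sq=2e-4, df=2, mean_sq=1e-4, F=0.8, p=p_int),
        "Residuals": dict(
            sum_sq=2e-3, df=12, mean_sq=1.6e-4, F=float("nan"), p=float("nan")
        ),
    }
    return AncovaTable(pd.DataFrame.from_dict(rows, orient="index"))


class TestPoolability:
    def test_published_p_values_pool_all(self):
        assert poolability(_fake_table(0.460, 0.643), 0.25) == "pool_all"

    def test_interaction_failure_separates(self):
        assert poolability(_fake_table(0.01, 0.9), 0.25) == "separate"

    def test_common_slope_only_case(self):
        assert poolability(_fake_table(0.30, 0.10), 0.25) == "common_slope_only"


class TestCriticalAlpha:
    def test_power_round_trip(self):
        from scipy import stats as st

        data = make_stability([-0.008, -0.010, -0.012], rsd=0.012, seed=7)
        res = critical_alpha(data, delta=-8.606e-3, beta_power=0.10)
        assert res.attainable
        crit = st.f.isf(res.alpha, res.df_num, res.df_den)
        power = st.ncf.sf(crit, res.df_num, res.df_den, res.noncentrality)
        assert power == pytest.approx(0.90, abs=1e-6)

    def test_alpha_decreases_with_delta_magnitude(self):
        data = make_stability([-0.008, -0.010, -0.012], rsd=0.012, seed=8)
        alphas = [
            critical_alpha(data, delta=-d, beta_power=0.10).alpha
            for d in (0.004, 0.008, 0.016, 0.032)
        ]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_huge_delta_alpha_vanishes(self):
        data = make_stability([-0.008, -0.010, -0.012], rsd=0.012, seed=9)
        assert critical_alpha(data, delta=-1.0).alpha < 1e-6


class TestBands:
    def test_zero_rsd_bands_equal_fitted_line(self):
        fit = BatchFit("b1", 1.46, -0.01, 0.0, 5, 6.0, 90.0)
        for t in (0.0, 4.0, 12.0):
            assert confidence_band(fit, t) == pytest.approx(fit.predict(t))
            assert prediction_band(fit, t) == pytest.approx(fit.predict(t))

    def test_band_minimum_width_at_mean_time(self):
        from scipy import stats as st

        fit = BatchFit("b1", 1.46, -0.01, 0.012, 5, 6.0, 90.0)
        expected = fit.predict(6.0) - st.t.ppf(0.95, 3) * 0.012 / np.sqrt(5)
        assert confidence_band(fit, 6.0, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_closed_form_oracle_and_ordering(self):
        from scipy import stats as st

        rng = np.random.default_rng(SEED)
        for _ in range(20):
            fit = BatchFit(
                "b1",
                rng.uniform(1.4, 1.5),
                -rng.uniform(0.001, 0.02),
                rng.uniform(0.001, 0.03),
                int(rng.integers(4, 12)),
                rng.uniform(3, 8),
                rng.uniform(20, 200),
            )
            t = rng.uniform(0, 24)
            tq = st.t.ppf(0.95, fit.n - 2)
            conf = fit.b0 + fit.b1 * t - tq * fit.rsd * np.sqrt(
                1 / fit.n + (t - fit.x_bar) ** 2 / fit.sxx
            )
            pred = fit.b0 + fit.b1 * t - tq * fit.rsd * np.sqrt(
                1 + 1 / fit.n + (t - fit.x_bar) ** 2 / fit.sxx
            )
            assert confidence_band(fit, t, 0.05) == pytest.approx(conf, abs=1e-12)
            assert prediction_band(fit, t, 0.05) == pytest.approx(pred, abs=1e-12)
            assert pred < conf

    def test_too_few_points_rejected(self):
        fit = BatchFit("b1", 1.46, -0.01, 0.0, 2, 1.5, 4.5)
        with pytest.raises(DesignError):
            confidence_band(fit, 1.0)


class TestShelfLife:
    def test_exact_line_closed_form(self, spec):
        fit = BatchFit("b1", 1.46, -0.01, 0.0, 5, 6.0, 90.0)
        res = shelf_life(fit, spec, method="ich")
        assert res.t_months == pytest.approx((1.46 - spec.lsl) / 0.01, rel=1e-12)

    def test_prediction_shelf_life_not_longer(self, spec):
        rng = np.random.default_rng(SEED)
        for _ in range(10):
            fit = BatchFit(
                "b1",
                1.46,
                -rng.uniform(0.004, 0.02),
                rng.uniform(0.002, 0.02),
                10,
                6.0,
                rng.uniform(40, 160),
            )
            t_ich = shelf_life(fit, spec, method="ich").t_months
            t_pred = shelf_life(fit, spec, method="prediction").t_months
            assert t_pred <= t_ich

    def test_monotone_in_rsd_and_slope(self, spec):
        base = dict(batch_id="b1", b0=1.46, n=10, x_bar=6.0, sxx=90.0)
        lives = [
            shelf_life(BatchFit(b1=-0.008, rsd=r, **base), spec).t_months
            for r in np.linspace(0.001, 0.03, 8)
        ]
        assert all(a >= b for a, b in zip(lives, lives[1:]))
        lives = [
            shelf_life(BatchFit(b1=-s, rsd=0.01, **base), spec).t_months
            for s in np.linspace(0.004, 0.03, 8)
        ]
        assert all(a >= b for a, b in zip(lives, lives[1:]))

    def test_no_crossing_censored_at_horizon(self, spec):
        fit = BatchFit("b1", 1.46, -1e-5, 0.001, 10, 6.0, 90.0)
        res = shelf_life(fit, spec, horizon=24.0)
        assert res.censored and res.t_months == 24.0

    def test_below_at_time_zero_flagged(self, spec):
        fit = BatchFit("b1", spec.lsl - 0.01, -0.01, 0.005, 10, 6.0, 90.0)
        res = shelf_life(fit, spec)
        assert res.below_at_t0 and res.t_months == 0.0


class TestStabilityAnalysis:
    def test_poolable_data_uses_pooled_line(self, spec):
        data = make_stability([-0.0087, -0.0087, -0.0087], rsd=0.012, seed=11)
        rep = stability_analysis(data, spec)
        assert rep.decision in ("pool_all", "common_slope_only")
        assert rep.t_ich.basis == "pooled"
        assert rep.t_pred.t_months <= rep.t_ich.t_months

    def test_non_poolable_falls_back_to_worst_batch(self, spec):
        data = make_stability([-0.004, -0.004, -0.05], rsd=0.003, seed=12)
        rep = stability_analysis(data, spec)
        assert rep.decision == "separate"
        assert rep.t_ich.basis == "worst-batch"
        worst = min(
            shelf_life(f, spec).t_months for f in rep.batch_fits
        )
        assert rep.t_ich.t_months == pytest.approx(worst)
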