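import numpy as np
import pytest

from relcap import (
    AssayTable,
    DesignError,
    SpecLimits,
    ValidationError,
    VarianceComponents,
    bootstrap_cpk_ci,
    cp_index,
    defect_bounds,
    descriptive_stats,
    dpmo_empirical,
    dpmo_sigma_level,
    fit_variance_components,
    k_factor,
    model_cpk,
    natural_cpk,
)
from relcap.capability import _group_summaries, _moment_from_summaries

from .conftest import SEED, make_assay


class TestIndices:
    def test_centered_process_cpk_is_one(self, spec):
        sd = (spec.usl - spec.lsl) / 6
        assert natural_cpk(spec.center, sd, spec) == pytest.approx(1.0)

    def test_mean_at_usl_gives_zero(self, spec):
        assert natural_cpk(spec.usl, 0.01, spec) == 0.0

    def test_cp_two_at_twelfth_width(self, spec):
        assert cp_index((spec.usl - spec.lsl) / 12, spec) == pytest.approx(2.0)

    def test_centered_k_zero_so_cpk_equals_cp(self, spec):
        sd = 0.005
        assert k_factor(spec.center, spec) == 0.0
        assert natural_cpk(spec.center, sd, spec) == pytest.approx(cp_index(sd, spec))

    def test_cp_times_one_minus_k_identity(self, spec):
        rng = np.random.default_rng(SEED)
        for _ in range(50):
            mean = rng.uniform(spec.lsl, spec.usl)
            sd = rng.uniform(1e-4, 0.05)
            lhs = cp_index(sd, spec) * (1 - k_factor(mean, spec))
            assert lhs == pytest.approx(natural_cpk(mean, sd, spec), abs=1e-12)

    def test_nonpositive_sd_rejected(self, spec):
        with pytest.raises(ValidationError):
            natural_cpk(1.46, 0.0, spec)
        with pytest.raises(ValidationError):
            cp_index(-1.0, spec)

    def test_affine_rescaling_invariance(self, spec):
        c = 1000.0  # e.g. µg/mL -> ng/mL
        scaled = SpecLimits(spec.label_conc * c, spec.lower_frac, spec.upper_frac)
        assert natural_cpk(1.46 * c, 0.008 * c, scaled) == pytest.approx(
            natural_cpk(1.46, 0.008, spec), rel=1e-12
        )


class TestDefectBounds:
    def test_lower_is_twice_upper_and_decreasing(self):
        prev = None
        for cpk in np.linspace(0.2, 3.0, 30):
            lo, up = defect_bounds(cpk)
            assert lo == pytest.approx(2 * up, rel=1e-14)
            if prev is not None:
                assert lo < prev
            prev = lo

    def test_perfect_process_limit(self):
        assert defect_bounds(float("inf")) == (0.0, 0.0)


class TestDpmo:
    def test_six_sigma_is_3_4(self):
        assert dpmo_sigma_level(6.0) == pytest.approx(3.4, abs=0.05)

    def test_shift_convention_anchor(self):
        assert dpmo_sigma_level(1.5) == pytest.approx(500_000.0)

    def test_monotone_decreasing(self):
        grid = [dpmo_sigma_level(s) for s in np.linspace(0.5, 6.5, 25)]
        assert all(a > b for a, b in zip(grid, grid[1:]))

    def test_empirical_counts(self):
        assert dpmo_empirical(0, 100, 3) == 0.0
        assert dpmo_empirical(1, 1000, 1) == 1000.0
        # 34 defects in 10^7 opportunities is the six-sigma rate (3.4 DPMO)
        assert dpmo_empirical(34, 10**7, 1) == pytest.approx(
            dpmo_sigma_level(6.0), rel=0.02
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            dpmo_empirical(1, 0, 1)


class TestVarianceComponents:
    def test_reml_matches_balanced_anova_oracle(self):
        """On balanced data with an interior optimum, REML equals the
        closed-form ANOVA moment estimator."""
        table = make_assay(k=8, n=6, mu=10.0, sa=0.5, se=1.0, seed=SEED)
        n_i, means, ssw = _group_summaries(table)
        mu_m, sa_m, se_m = _moment_from_summaries(n_i, means, float(ssw.sum()))
        assert sa_m > 0  # interior: the comparison is only valid off-boundary
        vc = fit_variance_components(table, method="reml", ci=False)
        assert vc.mu == pytest.approx(mu_m, abs=1e-6)
        assert vc.sigma_batch == pytest.approx(sa_m, abs=1e-6)
        assert vc.sigma_within == pytest.approx(se_m, abs=1e-6)

    def test_degenerate_constant_data(self):
        table = AssayTable.from_records(
            [("b1", 1.46)] * 3 + [("b2", 1.46)] * 3
        )
        vc = fit_variance_components(table, ci=False)
        assert vc.degenerate
        assert vc.sigma_batch == 0.0 and vc.sigma_within == 0.0

    def test_single_batch_rejected(self):
        table = AssayTable.from_records([("b1", 1.4), ("b1", 1.5)])
        with pytest.raises(DesignError):
            fit_variance_components(table)

    def test_sigma_total_pythagorean(self):
        vc = VarianceComponents(mu=1.0, sigma_batch=0.3, sigma_within=0.4)
        assert vc.sigma_total == pytest.approx(0.5, abs=1e-12)

    def test_parameter_recovery_large_design(self, spec):
        table = make_assay(k=50, n=20, mu=1.46, sa=0.0016, se=0.0087, seed=SEED)
        vc = fit_variance_components(table, ci=False)
        assert vc.mu == pytest.approx(1.46, rel=0.15)
        assert vc.sigma_batch == pytest.approx(0.0016, rel=0.15)
        assert vc.sigma_within == pytest.approx(0.0087, rel=0.15)


class TestModelCpk:
    def test_published_capability_summary(self, reported_vc, spec):
        cap = model_cpk(reported_vc, spec)
        assert round(cap.cpk, 2) == 2.42
        assert cap.lcl == pytest.approx(1.436, abs=1.5e-3)
        assert cap.ucl == pytest.approx(1.489, abs=1.5e-3)
        assert cap.cpk <= cap.cp
        assert cap.defect_lower == pytest.approx(2 * cap.defect_upper, rel=1e-14)

    def test_no_batch_effect_reduces_to_natural(self, spec):
        vc = VarianceComponents(mu=1.46, sigma_batch=0.0, sigma_within=0.009)
        cap = model_cpk(vc, spec)
        assert cap.cpk == pytest.approx(natural_cpk(1.46, 0.009, spec), rel=1e-14)

    def test_monotone_decreasing_in_each_component(self, spec):
        base = dict(mu=1.4625, sigma_batch=0.0016, sigma_within=0.0087)
        for field in ("sigma_batch", "sigma_within"):
            prev = None
            for s in np.linspace(0.001, 0.02, 10):
                vc = VarianceComponents(**{**base, field: s})
                cpk = model_cpk(vc, spec).cpk
                if prev is not None:
                    assert cpk < prev
                prev = cpk

    def test_zero_total_variance_rejected(self, spec):
        vc = VarianceComponents(
            mu=1.46, sigma_batch=0.0, sigma_within=0.0, degenerate=True
        )
        with pytest.raises(ValidationError):
            model_cpk(vc, spec)


class TestBootstrapCpk:
    def test_fixed_seed_reproducible(self, spec):
        table = make_assay(k=3, n=20, mu=1.4625, sa=0.0016, se=0.0087, seed=SEED)
        a = bootstrap_cpk_ci(table, spec, reps=500, seed=7)
        b = bootstrap_cpk_ci(table, spec, reps=500, seed=7)
        assert a == b

    def test_interval_brackets_point_estimate(self, spec):
        table = make_assay(k=4, n=15, mu=1.4625, sa=0.0016, se=0.0087, seed=SEED)
        vc = fit_variance_components(table, ci=False)
        cpk = model_cpk(vc, spec).cpk
        lo, hi = bootstrap_cpk_ci(table, spec, reps=1000, seed=SEED)
        assert lo < cpk < hi


def test_descriptive_stats_layout(spec):
    table = make_assay(k=3, n=10, mu=1.46, sa=0.002, se=0.008, seed=SEED)
    stats = descriptive_stats(table, spec)
    assert list(stats.columns) == ["batch_id", "n", "min", "max", "mean", "sd", "cpk"]
    assert (stats["n"] == 10).all()
    assert (stats["min"] <= stats["mean"]).all()
    assert (stats["mean"] <= stats["max"]).all()
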