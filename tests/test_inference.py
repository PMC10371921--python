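"""Rubin pooling, nested bootstraps and percentile intervals."""

import numpy as np
import pytest
from dataclasses import replace

from panelmediate.imputation import ImputationConfig, multiply_impute
from panelmediate.inference import (
    BootstrapDistribution,
    bootstrap_then_imputation,
    imputation_then_bootstrap,
    percentile_ci,
    pool_indirect_effects,
    rubin_pool,
)
from panelmediate.path_models import compute_indirect_effects, fit_equations
from panelmediate.synthetic_data import default_config, generate_panel, impose_missingness

from .test_path_models import path_coefficients_from_values

SMALL_IMP = dict(burn_in=60, post_burn_iterations=60, n_imputations=6)


def make_dist(draws, point=None, **kw):
    arr = np.asarray(draws, dtype=float)
    effects = {k: arr for k in ("a1b1", "a2b2", "a3b3", "total_indirect")}
    points = {k: (point if point is not None else arr.mean()) for k in effects}
    defaults = dict(order="itb", m=1, b_per_unit=len(arr), seed=0)
    defaults.update(kw)
    return BootstrapDistribution(draws=effects, point_estimates=points, **defaults)


class TestRubinPool:
    def test_hand_computed_two_fit_example(self):
        # estimates 1 and 3 with SE 1: Qbar=2, Wbar=1, B=2, T=1+(1.5)(2)=4
        fits = [
            path_coefficients_from_values(a=(est, 0, 0), b=(0, 0, 0), se=1.0, df=100)
            for est in (1.0, 3.0)
        ]
        pooled = rubin_pool(fits)
        row = pooled.coefficient("m1", "x_t1")
        assert row["estimate"] == pytest.approx(2.0)
        assert row["between"] == pytest.approx(2.0)
        assert row["total_var"] == pytest.approx(4.0)
        assert row["se"] == pytest.approx(2.0)
        assert 0 < row["df"] <= 100
        assert row["t"] == pytest.approx(1.0)

    def test_degenerate_pooling_recovers_single_fit(self):
        fit = path_coefficients_from_values(a=(0.4, 0.1, 0.0), b=(0.2, 0.3, 0.1), se=0.05)
        pooled = rubin_pool([fit, fit, fit])
        row = pooled.coefficient("m1", "x_t1")
        assert row["between"] == pytest.approx(0.0, abs=1e-16)
        assert row["total_var"] == pytest.approx(row["within"])
        assert row["estimate"] == pytest.approx(0.4)
        assert row["se"] == pytest.approx(0.05)

    def test_fractional_df_below_complete_data_df(self):
        cfg = default_config(n=300, seed=41, missing_mechanism="MCAR")
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        result = multiply_impute(panel, ImputationConfig(**SMALL_IMP, seed=42), force=True)
        fits = [fit_equations(t.to_frame()) for t in result.completed_tables]
        pooled = rubin_pool(fits)
        df_com = fits[0].equations["m2"].df_resid
        row = pooled.coefficient("m2", "x_t1")
        assert 0 < row["df"] < df_com
        assert row["df"] != round(row["df"])  # genuinely fractional
        assert row["between"] > 0  # missingness induces between-imputation variance

    def test_pooled_point_estimate_is_mean_of_fits(self):
        fits = [
            path_coefficients_from_values(a=(a, 0, 0), b=(0.5, 0, 0), se=0.1)
            for a in (0.1, 0.2, 0.6)
        ]
        pooled = rubin_pool(fits)
        assert pooled.coefficient("m1", "x_t1")["estimate"] == pytest.approx(0.3)
        effects = pool_indirect_effects(fits)
        assert effects["a1b1"] == pytest.approx(np.mean([0.05, 0.1, 0.3]))

    def test_requires_consistent_specifications(self):
        f1 = path_coefficients_from_values(a=(0, 0, 0), b=(0, 0, 0))
        f2 = path_coefficients_from_values(a=(0, 0, 0), b=(0, 0, 0))
        f2.equations["m1"].params.index = ["const", "other"]
        with pytest.raises(ValueError, match="inconsistent"):
            rubin_pool([f1, f2])
        with pytest.raises(ValueError, match="at least two"):
            rubin_pool([f1])

    def test_pooled_decomposition_identity(self):
        cfg = default_config(n=250, seed=43, missing_mechanism="MCAR")
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        result = multiply_impute(panel, ImputationConfig(**SMALL_IMP, seed=44), force=True)
        fits = [fit_equations(t.to_frame()) for t in result.completed_tables]
        effects = pool_indirect_effects(fits)
        assert effects["total"] == pytest.approx(
            effects["direct"] + effects["total_indirect"], abs=1e-10
        )


class TestPercentileCI:
    def test_sorted_order_oracle(self):
        dist = make_dist(np.arange(1.0, 1001.0))
        cis = percentile_ci(dist, level=0.95)
        # inverse-CDF convention: ceil(0.025*1000)=25th and ceil(0.975*1000)=975th
        assert cis["a2b2"].lower == 25.0
        assert cis["a2b2"].upper == 975.0

    def test_constant_draws_degenerate_interval(self):
        cis = percentile_ci(make_dist(np.full(500, 0.4)))
        assert cis["a2b2"].lower == cis["a2b2"].upper == pytest.approx(0.4)
        assert cis["a2b2"].significant

    def test_symmetric_null_draws_not_significant(self, rng):
        draws = rng.standard_normal(2000)
        cis = percentile_ci(make_dist(draws))
        assert not cis["a2b2"].significant

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            percentile_ci(make_dist(np.arange(50.0)))
        with pytest.raises(ValueError, match="level"):
            percentile_ci(make_dist(np.arange(500.0)), level=1.2)


class TestImputationThenBootstrap:
    def test_draw_count_is_m_times_b(self):
        cfg = default_config(n=80, seed=51, missing_mechanism="MCAR",
                             missing_rates={"y_t2": 0.25, "m2_t2": 0.25})
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        config = ImputationConfig(burn_in=50, post_burn_iterations=30, n_imputations=3, seed=52)
        dist = imputation_then_bootstrap(panel, config, B=40, seed=53, force=True)
        assert dist.n_draws == 3 * 40
        for effect in ("a1b1", "a2b2", "a3b3", "total_indirect"):
            assert dist.draws[effect].shape == (120,)

    def test_zero_outcome_noise_degenerate_direct_effect_distribution(self):
        """With a perfectly fitting outcome equation every resample reproduces
        the same direct effect, so its bootstrap distribution is a point mass
        and the percentile interval degenerates.  (Fully noiseless mediator
        equations would make the outcome design exactly collinear, so the
        outcome equation is the only place this degeneracy is observable.)"""
        cfg = default_config(
            n=120,
            seed=54,
            resid_sds={"m1_t2": 0.3, "m2_t2": 0.3, "m3_t2": 0.3, "y_t2": 0.0},
            truncate=False,
            missing_rates={},
        )
        panel = generate_panel(cfg)
        config = ImputationConfig(burn_in=30, post_burn_iterations=10, n_imputations=2, seed=55)
        dist = imputation_then_bootstrap(panel, config, B=60, seed=56)
        point = dist.point_estimates["direct"]
        assert point == pytest.approx(cfg.true_cprime, abs=1e-10)
        assert np.allclose(dist.draws["direct"], point, atol=1e-8)
        ci = percentile_ci(dist, effects=("direct",))["direct"]
        assert ci.upper - ci.lower < 1e-8

    def test_seed_determinism(self):
        cfg = default_config(n=80, seed=51, missing_mechanism="MCAR",
                             missing_rates={"y_t2": 0.25})
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        config = ImputationConfig(burn_in=40, post_burn_iterations=20, n_imputations=2, seed=52)
        d1 = imputation_then_bootstrap(panel, config, B=60, seed=53, force=True)
        d2 = imputation_then_bootstrap(panel, config, B=60, seed=53, force=True)
        assert np.array_equal(d1.draws["a2b2"], d2.draws["a2b2"])


class TestBootstrapThenImputation:
    def test_reduces_to_case_bootstrap_when_complete(self):
        cfg = default_config(n=70, seed=61, missing_rates={})
        panel = generate_panel(cfg)
        config = ImputationConfig(burn_in=30, post_burn_iterations=10, n_imputations=2, seed=62)
        dist = bootstrap_then_imputation(panel, config, B=25, seed=63)
        assert dist.n_draws == 25
        frame = panel.to_frame()
        n = panel.n
        for b_idx in (0, 7, 19):  # replay: same child stream as the implementation
            rng = np.random.default_rng([63, 404, b_idx])
            idx = rng.integers(0, n, size=n)
            boot = frame.iloc[idx].reset_index(drop=True)
            boot["subject_id"] = np.arange(1, n + 1)
            effects = compute_indirect_effects(fit_equations(boot))
            assert dist.draws["a2b2"][b_idx] == pytest.approx(
                effects.specific[1], abs=1e-12
            )

    def test_concordance_with_itb_on_strong_effect(self):
        cfg = default_config(
            n=300,
            seed=64,
            true_a=(0.0, 0.3, 0.0),
            true_b=(0.0, 0.4, 0.0),
            missing_mechanism="MCAR",
            missing_rates={"m2_t2": 0.2, "y_t2": 0.2},
        )
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        itb_config = ImputationConfig(burn_in=60, post_burn_iterations=60, n_imputations=4, seed=65)
        itb = imputation_then_bootstrap(panel, itb_config, B=50, seed=66, force=True)
        bti_config = ImputationConfig(burn_in=40, post_burn_iterations=10, n_imputations=2, seed=65)
        bti = bootstrap_then_imputation(panel, bti_config, B=100, m_per_boot=1, seed=66)
        ci_itb = percentile_ci(itb)["a2b2"]
        ci_bti = percentile_ci(bti)["a2b2"]
        assert ci_itb.significant and ci_bti.significant
        # intervals overlap substantially
        overlap = min(ci_itb.upper, ci_bti.upper) - max(ci_itb.lower, ci_bti.lower)
        width = max(ci_itb.upper - ci_itb.lower, ci_bti.upper - ci_bti.lower)
        assert overlap > 0.5 * width


class TestCIWidthMonotonicity:
    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (200, 800, 3200):
            cfg = default_config(n=n, seed=71, missing_rates={})
            panel = generate_panel(cfg)
            config = ImputationConfig(burn_in=30, post_burn_iterations=10, n_imputations=2, seed=72)
            dist = imputation_then_bootstrap(panel, config, B=150, seed=73)
            ci = percentile_ci(dist)["a2b2"]
            widths.append(ci.upper - ci.lower)
        assert widths[0] > widths[1] > widths[2]
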