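"""Data-augmentation imputer: oracles, PSRF, draw mechanics, invariants."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from panelmediate.data_model import PanelTable
from panelmediate.imputation import (
    ConvergenceDiagnostics,
    ConvergenceError,
    ImputationConfig,
    JointNormalImputer,
    compute_psrf,
    draw_imputations,
    fcs_impute,
    multiply_impute,
    run_data_augmentation,
)
from panelmediate.synthetic_data import default_config, generate_panel, impose_missingness

from .conftest import make_small_panel


def bivariate_panel(n, rho, missing_frac, seed, sd2=0.25):
    """Two panel columns (x_t1, y_t2) from a bivariate normal, MCAR on y_t2."""
    r = np.random.default_rng(seed)
    mu = np.array([5.0, 2.5])
    sd = np.array([1.0, sd2])
    cov = np.array([[1.0, rho * sd2], [rho * sd2, sd2**2]])
    xy = r.multivariate_normal(mu, cov, size=n)
    xy = np.clip(xy, [1, 1], [9, 4])
    y = xy[:, 1].copy()
    drop = r.random(n) < missing_frac
    y[drop] = np.nan
    table = make_small_panel({"x_t1": xy[:, 0], "y_t2": y})
    return table, xy, drop, mu, sd, rho


SMALL = dict(burn_in=60, post_burn_iterations=60, n_imputations=10)


class TestDataAugmentation:
    def test_fully_observed_tables_equal_input(self):
        cfg = default_config(n=120, seed=1, missing_rates={})
        panel = generate_panel(cfg)
        result = multiply_impute(panel, ImputationConfig(**SMALL, seed=2))
        assert result.m == 10
        for table in result.completed_tables:
            assert table.equals(panel)

    def test_observed_cells_never_altered(self):
        cfg = default_config(n=150, seed=3, missing_mechanism="MCAR")
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        result = multiply_impute(panel, ImputationConfig(**SMALL, seed=4), force=True)
        observed = panel.mask.to_numpy()
        original = panel.data.to_numpy()
        for table in result.completed_tables:
            completed = table.data.to_numpy()
            assert np.array_equal(completed[observed], original[observed])
            assert not np.isnan(completed).any()

    def test_imputed_values_vary_across_imputations(self):
        cfg = default_config(n=150, seed=3, missing_mechanism="MCAR")
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        result = multiply_impute(panel, ImputationConfig(**SMALL, seed=4), force=True)
        missing = ~panel.mask["y_t2"].to_numpy()
        first = result.completed_tables[0].data["y_t2"].to_numpy()[missing]
        second = result.completed_tables[1].data["y_t2"].to_numpy()[missing]
        assert not np.allclose(first, second)

    def test_conditional_mean_oracle_bivariate(self):
        table, xy, drop, mu, sd, rho = bivariate_panel(400, 0.8, 0.3, seed=11)
        config = ImputationConfig(
            burn_in=100,
            post_burn_iterations=300,
            n_imputations=60,
            included_variables=("x_t1", "y_t2"),
            seed=12,
        )
        result = multiply_impute(table, config, force=True)
        stacked = np.stack(
            [t.data["y_t2"].to_numpy()[drop] for t in result.completed_tables]
        )
        imputed_mean = stacked.mean(axis=0)
        cond_mean = mu[1] + rho * sd[1] / sd[0] * (xy[drop, 0] - mu[0])
        # across-imputation means track the conditional mean given x
        assert np.corrcoef(imputed_mean, cond_mean)[0, 1] > 0.9
        assert np.mean(np.abs(imputed_mean - cond_mean)) < 0.12

    def test_chain_mean_matches_em_oracle(self):
        table, xy, drop, mu, sd, rho = bivariate_panel(300, 0.6, 0.3, seed=21)
        # independent oracle: EM for the bivariate normal MLE under MAR
        data = table.data[["x_t1", "y_t2"]].to_numpy()
        em_mu, em_cov = _em_mvn(data, n_iter=300)

        config = ImputationConfig(
            burn_in=1500,
            post_burn_iterations=10,
            n_imputations=10,
            included_variables=("x_t1", "y_t2"),
            seed=22,
        )
        states = run_data_augmentation(table, config)
        # long-run average of mu over the retained window of chain 0
        chain_mu = states.history[0, :, :2].mean(axis=0)
        assert np.allclose(chain_mu, em_mu, atol=0.05)

    def test_variable_with_no_observed_values_rejected(self):
        table = make_small_panel(
            {"x_t1": [2.0] * 30, "y_t2": [np.nan] * 30}
        )
        config = ImputationConfig(
            **SMALL, included_variables=("x_t1", "y_t2"), seed=1
        )
        with pytest.raises(ValueError, match="no observed values"):
            run_data_augmentation(table, config)


def _em_mvn(data, n_iter=200):
    """EM for the MVN MLE with missing data (test-local oracle)."""
    n, p = data.shape
    miss = np.isnan(data)
    mu = np.nanmean(data, axis=0)
    cov = np.diag(np.nanvar(data, axis=0, ddof=1))
    for _ in range(n_iter):
        filled = np.where(miss, 0.0, data)
        correction = np.zeros((p, p))
        for i in range(n):
            m = miss[i]
            if not m.any():
                continue
            o = ~m
            coef = np.linalg.solve(cov[np.ix_(o, o)], cov[np.ix_(o, m)])
            filled[i, m] = mu[m] + (data[i, o] - mu[o]) @ coef
            cond = cov[np.ix_(m, m)] - cov[np.ix_(m, o)] @ coef
            idx = np.where(m)[0]
            correction[np.ix_(idx, idx)] += cond
        mu = filled.mean(axis=0)
        centered = filled - mu
        cov = (centered.T @ centered + correction) / n
    return mu, cov


class TestPSRF:
    def test_identical_chains_psrf_one(self):
        draws = np.random.default_rng(0).standard_normal((10_000, 3))
        history = np.stack([draws, draws])
        diag = compute_psrf(history)
        assert np.allclose(diag.psrf.to_numpy(), 1.0, atol=1e-3)
        assert diag.converged

    def test_non_overlapping_chains_flagged(self):
        r = np.random.default_rng(1)
        history = np.stack(
            [r.normal(0, 0.01, (200, 2)), r.normal(10, 0.01, (200, 2))]
        )
        diag = compute_psrf(history)
        assert diag.max_psrf > 10
        assert not diag.converged

    def test_iid_chains_within_gate(self):
        r = np.random.default_rng(2)
        history = r.standard_normal((2, 10_000, 4))
        diag = compute_psrf(history)
        assert diag.psrf.min() > 0.999
        assert diag.max_psrf < 1.05

    def test_zero_within_variance_rejected(self):
        history = np.zeros((2, 50, 2))
        with pytest.raises(ValueError, match="within-chain variance"):
            compute_psrf(history)

    def test_too_short_history_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            compute_psrf(np.random.default_rng(0).standard_normal((2, 5, 2)))


class TestDrawImputations:
    def _states(self):
        cfg = default_config(n=100, seed=5, missing_mechanism="MCAR")
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        config = ImputationConfig(burn_in=60, post_burn_iterations=40, n_imputations=8, seed=6)
        return run_data_augmentation(panel, config), config

    def test_exact_m_tables_at_configured_spacing(self):
        states, config = self._states()
        result = draw_imputations(states, config, force=True)
        assert result.m == config.n_imputations

    def test_m_exceeding_spacing_rejected(self):
        with pytest.raises(ValueError, match="post_burn_iterations"):
            ImputationConfig(burn_in=40, post_burn_iterations=5, n_imputations=8)

    def test_gate_blocks_nonconverged_chains(self):
        states, config = self._states()
        fake = ConvergenceDiagnostics(
            psrf=pd.Series([8.0], index=["mu[x_t1]"]),
            converged=False,
            chain_length=100,
            threshold=1.05,
        )
        with pytest.raises(ConvergenceError, match="PSRF"):
            draw_imputations(states, config, fake)
        # explicit override proceeds
        result = draw_imputations(states, config, fake, force=True)
        assert result.m == config.n_imputations

    def test_seed_determinism(self):
        cfg = default_config(n=100, seed=5, missing_mechanism="MCAR")
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        config = ImputationConfig(burn_in=40, post_burn_iterations=20, n_imputations=4, seed=6)
        r1 = multiply_impute(panel, config, force=True)
        r2 = multiply_impute(panel, config, force=True)
        for t1, t2 in zip(r1.completed_tables, r2.completed_tables):
            assert t1.data.equals(t2.data)


class TestRecoveryAndPooling:
    def test_pooled_mean_recovers_generating_mean_under_mcar(self):
        """Rubin-pooled mean of an incomplete variable is unbiased under MCAR."""
        biases = []
        for rep in range(8):
            cfg = default_config(
                n=300,
                seed=500 + rep,
                missing_mechanism="MCAR",
                missing_rates={"y_t2": 0.3},
            )
            full = generate_panel(replace(cfg, missing_rates={}))
            truth = full.data["y_t2"].mean()
            panel = impose_missingness(full, cfg)
            result = multiply_impute(
                panel,
                ImputationConfig(
                    burn_in=60, post_burn_iterations=60, n_imputations=10,
                    seed=600 + rep,
                ),
                force=True,
            )
            pooled = np.mean(
                [t.data["y_t2"].mean() for t in result.completed_tables]
            )
            biases.append(pooled - truth)
        biases = np.asarray(biases)
        mcse = biases.std(ddof=1) / np.sqrt(len(biases))
        assert abs(biases.mean()) < 3 * mcse + 1e-3


class TestAlternativeEngines:
    def test_fcs_completes_and_preserves_observed(self):
        cfg = default_config(n=150, seed=9, missing_mechanism="MCAR")
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        result = fcs_impute(panel, ImputationConfig(**SMALL, seed=10))
        assert result.m == 10
        observed = panel.mask.to_numpy()
        for table in result.completed_tables:
            assert not np.isnan(table.data.to_numpy()).any()
            assert np.array_equal(
                table.data.to_numpy()[observed], panel.data.to_numpy()[observed]
            )

    def test_sklearn_imputer_facade(self):
        from sklearn.base import clone

        cfg = default_config(n=120, seed=13, missing_mechanism="MCAR",
                             missing_rates={"y_t2": 0.2, "m2_t2": 0.2})
        panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)
        imp = JointNormalImputer(
            n_imputations=5, burn_in=60, post_burn_iterations=30,
            force=True, random_state=3,
        )
        assert clone(imp).get_params()["n_imputations"] == 5
        imp.fit(panel)
        assert len(imp.imputations_) == 5
        completed = imp.transform(panel)
        assert not completed.drop(columns="subject_id").isna().any().any()
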