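"""Firth-penalized regression: closed forms, oracles, separation, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from xburden import ConfigError, bonferroni, firth_lrt, fit_firth, penalized_loglik
from xburden import test_all_genes as run_gene_tests
from xburden.qualify import CarrierMatrix


def table_design(a, b, c, d):
    """Intercept+carrier design for a 2x2 table (case carriers a, case
    non-carriers b, control carriers c, control non-carriers d)."""
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    carrier = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return np.column_stack([np.ones_like(y), carrier]), y


def half_corrected_logor(a, b, c, d):
    return np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))


def pll_oracle(beta, X, y):
    """Dense-determinant penalized log-likelihood, independent arithmetic."""
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(pi) + (1 - y) * np.log(1 - pi)))
    W = np.diag(pi * (1 - pi))
    return ll + 0.5 * np.log(np.linalg.det(X.T @ W @ X))


class TestFitFirth:
    @pytest.mark.parametrize(
        "table",
        [
            (21, 1181, 0, 331),  # the separated carrier table
            (10, 90, 5, 95),
            (1, 49, 0, 50),
            (3, 7, 3, 7),  # balanced: log OR = 0
        ],
    )
    def test_equals_half_corrected_2x2(self, table):
        X, y = table_design(*table)
        fit = fit_firth(X, y)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(half_corrected_logor(*table), abs=1e-6)

    def test_balanced_table_beta_zero(self):
        X, y = table_design(5, 20, 5, 20)
        assert abs(fit_firth(X, y).beta[1]) < 1e-8

    def test_hat_diagonals_sum_to_ncols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        y = (rng.uniform(size=60) < 0.5).astype(float)
        fit = fit_firth(X, y)
        assert fit.hat_diagonals.sum() == pytest.approx(X.shape[1], abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ConfigError, match="x2"):
            fit_firth(X, y, columns=["intercept", "x1", "x2"])

    def test_grid_search_oracle(self):
        """Exhaustive lattice maximization of l* agrees within 2e-3/coordinate."""
        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(8), rng.normal(size=8), rng.normal(size=8)])
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        fit = fit_firth(X, y)

        def grid_argmax(center, half_width, spacing):
            axes = [np.arange(c - half_width, c + half_width + spacing / 2, spacing)
                    for c in center]
            B = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            eta = B @ X.T  # (M, n)
            pi = expit(eta)
            ll = eta @ y - np.logaddexp(0.0, eta).sum(axis=1)
            w = pi * (1 - pi)  # (M, n)
            # 3x3 information determinant, closed form, vectorized over the lattice
            M = np.einsum("mn,ni,nj->mij", w, X, X)
            det = (
                M[:, 0, 0] * (M[:, 1, 1] * M[:, 2, 2] - M[:, 1, 2] * M[:, 2, 1])
                - M[:, 0, 1] * (M[:, 1, 0] * M[:, 2, 2] - M[:, 1, 2] * M[:, 2, 0])
                + M[:, 0, 2] * (M[:, 1, 0] * M[:, 2, 1] - M[:, 1, 1] * M[:, 2, 0])
            )
            val = ll + 0.5 * np.log(det)
            return B[np.argmax(val)]

        best = grid_argmax(np.zeros(3), 3.0, 0.1)
        best = grid_argmax(best, 0.15, 0.01)
        best = grid_argmax(best, 0.015, 0.001)
        assert np.abs(fit.beta - best).max() <= 2e-3

    def test_optimizer_oracle_on_random_datasets(self):
        """Independent quasi-Newton maximization of l* agrees within 1e-4."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(25, 60))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            beta_true = rng.normal(scale=0.8, size=3)
            y = (rng.uniform(size=n) < expit(X @ beta_true)).astype(float)
            fit = fit_firth(X, y)
            res = minimize(lambda b: -pll_oracle(b, X, y), np.zeros(3), method="BFGS",
                           options={"gtol": 1e-10})
            assert np.abs(fit.beta - res.x).max() < 1e-4


class TestPenalizedLoglik:
    def test_closed_form_at_zero_intercept_only(self):
        n = 20
        X = np.ones((n, 1))
        y = np.r_[np.ones(8), np.zeros(12)]
        got = penalized_loglik(np.zeros(1), X, y)
        assert got == pytest.approx(n * np.log(0.5) + 0.5 * np.log(n / 4), abs=1e-12)

    def test_matches_dense_determinant_oracle(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = (rng.uniform(size=20) < 0.5).astype(float)
        beta = rng.normal(size=3)
        assert penalized_loglik(beta, X, y) == pytest.approx(pll_oracle(beta, X, y), abs=1e-10)

    def test_extreme_linear_predictor_no_overflow(self):
        X = np.column_stack([np.ones(10), np.r_[np.full(5, 50.0), np.full(5, -50.0)]])
        y = np.r_[np.ones(5), np.zeros(5)]
        val = penalized_loglik(np.array([0.0, 20.0]), X, y)
        assert np.isfinite(val) or val == -np.inf

    def test_maximal_at_fit(self):
        X, y = table_design(6, 14, 3, 17)
        fit = fit_firth(X, y)
        best = penalized_loglik(fit.beta, X, y)
        rng = np.random.default_rng(2)
        for _ in range(20):
            assert penalized_loglik(fit.beta + rng.normal(scale=0.05, size=2), X, y) <= best + 1e-10


class TestLrt:
    def test_constant_carrier_column_null_result(self):
        X, y = table_design(0, 100, 0, 50)
        stat, p, _, _ = firth_lrt(X, y)
        assert stat <= 1e-8
        assert p == pytest.approx(1.0)

    def test_separation_gives_finite_valid_result(self):
        # zero carriers among controls: complete separation in the carrier stratum
        X, y = table_design(21, 1181, 0, 331)
        stat, p, full, null = firth_lrt(X, y)
        assert np.isfinite(full.beta).all() and np.isfinite(stat)
        assert 0.0 < p < 1.0
        assert full.converged and null.converged
        # ascent from the initialization
        assert full.penalized_loglik >= penalized_loglik(np.zeros(2), X, y)

    def test_lrt_self_consistency_via_penalized_loglik(self):
        """Statistic recomputed from independent l* evaluations at the fitted
        estimates (full: closed-form table estimates) agrees within 1e-6."""
        a, b, c, d = 12, 88, 3, 97
        X, y = table_design(a, b, c, d)
        stat, p, full, null = firth_lrt(X, y)
        # closed-form 0.5-table estimates for intercept+carrier
        beta_full = np.array(
            [np.log((b + 0.5) / (d + 0.5)), half_corrected_logor(a, b, c, d)]
        )
        ll_full = pll_oracle(beta_full, X, y)
        # constrained null: carrier pinned at 0, full-design penalty; profile
        # over the intercept by dense scalar search
        grid = np.linspace(-3, 3, 60001)
        vals = [pll_oracle(np.array([g, 0.0]), X, y) for g in grid[::600]]
        g0 = grid[::600][int(np.argmax(vals))]
        fine = np.arange(g0 - 0.15, g0 + 0.15, 1e-5)
        ll_null = max(pll_oracle(np.array([g, 0.0]), X, y) for g in fine)
        stat_oracle = 2 * (ll_full - ll_null)
        assert stat == pytest.approx(stat_oracle, abs=1e-6)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        n = 80
        age = rng.normal(50, 15, n)
        carrier = (rng.uniform(size=n) < 0.2).astype(float)
        y = (rng.uniform(size=n) < expit(-1 + 1.2 * carrier + 0.02 * age)).astype(float)
        X1 = np.column_stack([np.ones(n), carrier, age])
        X2 = np.column_stack([np.ones(n), carrier, (age - 50.0) / 10.0])
        s1 = firth_lrt(X1, y)[0]
        s2 = firth_lrt(X2, y)[0]
        assert s1 == pytest.approx(s2, abs=1e-8)


class TestTestAllGenes:
    def make_inputs(self, carriers_by_gene, n_case=60, n_control=40, seed=0):
        rng = np.random.default_rng(seed)
        n = n_case + n_control
        ids = [f"S{i}" for i in range(n)]
        samples = pd.DataFrame(
            {
                "sample_id": ids,
                "phenotype": ["case"] * n_case + ["control"] * n_control,
                "age": rng.normal(45, 12, n).clip(1),
                "stratum": ["S1"] * n,
            }
        )
        ind = pd.DataFrame(carriers_by_gene, index=ids).T.astype(int)
        carrier = ind.to_numpy() > 0
        is_case = (samples["phenotype"] == "case").to_numpy()
        counts = pd.DataFrame(
            {
                "gene": ind.index,
                "case_carriers": carrier[:, is_case].sum(axis=1),
                "control_carriers": carrier[:, ~is_case].sum(axis=1),
            }
        )
        cm = CarrierMatrix(indicators=ind, counts=counts)
        cov = pd.DataFrame({"age": samples.set_index("sample_id")["age"]})
        return cm, cov, samples

    def test_single_gene_matrix(self):
        rng = np.random.default_rng(4)
        cm, cov, samples = self.make_inputs({"G1": rng.binomial(1, 0.2, 100)})
        res = run_gene_tests(cm, cov, samples, min_case_carriers=1)
        assert len(res) == 1
        assert {"gene", "p_value", "eligible", "beta_carrier"} <= set(res.columns)

    def test_all_zero_carrier_gene(self):
        cm, cov, samples = self.make_inputs({"G1": np.zeros(100, dtype=int)})
        res = run_gene_tests(cm, cov, samples)
        assert res.loc[0, "lrt_stat"] == 0.0
        assert res.loc[0, "p_value"] == 1.0

    def test_missing_covariates_error(self):
        rng = np.random.default_rng(4)
        cm, cov, samples = self.make_inputs({"G1": rng.binomial(1, 0.2, 100)})
        with pytest.raises(ConfigError, match="missing"):
            run_gene_tests(cm, cov.iloc[:50], samples)


class TestBonferroni:
    def make_results(self, n_eligible, n_total, p=0.001):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n_total)],
                "p_value": [p] * n_total,
                "eligible": [True] * n_eligible + [False] * (n_total - n_eligible),
            }
        )

    def test_printed_threshold_for_226_genes(self):
        thr, out = bonferroni(self.make_results(226, 731), alpha=0.05)
        assert float(f"{thr:.1e}") == pytest.approx(2.2e-4)
        assert out.loc[0, "p_corrected"] == pytest.approx(0.001 * 226)

    def test_single_eligible_gene(self):
        thr, out = bonferroni(self.make_results(1, 3), alpha=0.05)
        assert thr == 0.05
        assert out.loc[0, "p_corrected"] == out.loc[0, "p_value"]

    def test_clipping_at_one(self):
        thr, out = bonferroni(self.make_results(10, 10, p=0.5))
        assert (out["p_corrected"] == 1.0).all()

    def test_ineligible_keep_raw_p_untested(self):
        _, out = bonferroni(self.make_results(2, 4))
        assert out["p_corrected"].isna().sum() == 2

    def test_no_eligible_genes_errors(self):
        with pytest.raises(ConfigError):
            bonferroni(self.make_results(0, 5))
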