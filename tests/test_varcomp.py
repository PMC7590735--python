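import math
from dataclasses import replace

import numpy as np
import pytest

from trionurture.experiments import DEPRESSION_TRIO
from trionurture.relatedness import build_relatedness
from trionurture.synthetic_data import simulate_trios
from trionurture.varcomp import (
    fit_rdr,
    greml_single,
    he_regression,
    implied_single_component,
    reml_fit,
)


@pytest.fixture(scope="module")
def replicate_fits():
    """Small-scale replicates fitted by both REML and the method-of-moments
    oracle; reused by the agreement, coverage and ascent checks."""
    truth = replace(DEPRESSION_TRIO, n_trios=300, n_snps=300, mediated_fraction=0.0)
    rows = []
    for seed in range(50):
        cohort = simulate_trios(replace(truth, seed=seed))
        rel = build_relatedness(cohort)
        fit = fit_rdr(cohort.child_phenotype, None, rel)
        he = he_regression(
            cohort.child_phenotype, None, rel.matrices, names=("v_delta", "v_eta", "c")
        )
        rows.append((fit, he))
    return truth, rows


class TestRemlBasics:
    def test_residual_only_model_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n = 120
        cov = rng.standard_normal((n, 2))
        y = 0.5 + cov @ [0.3, -0.2] + rng.standard_normal(n)
        res = reml_fit(y, cov, [np.eye(n)], names=("v_e",), include_residual=False)
        x = np.column_stack([np.ones(n), cov])
        beta, rss, *_ = np.linalg.lstsq(x, y, rcond=None)
        expected = rss[0] / (n - x.shape[1])  # REML-unbiased denominator
        assert res.components["v_e"] == pytest.approx(expected, rel=1e-5)

    def test_duplicate_matrices_not_identifiable(self, small_relatedness):
        K = small_relatedness.K_oo
        y = np.random.default_rng(1).standard_normal(K.shape[0])
        with pytest.raises(ValueError, match="identifiable"):
            reml_fit(y, None, [K, K.copy()])

    def test_rank_deficient_covariates_rejected(self):
        n = 50
        c1 = np.arange(n, dtype=float)
        cov = np.column_stack([c1, 2 * c1])
        with pytest.raises(ValueError, match="rank-deficient"):
            reml_fit(np.zeros(n), cov, [np.eye(n)], include_residual=False)

    def test_loglik_ascends_across_iterations(self, replicate_fits):
        _, rows = replicate_fits
        for fit, _ in rows[:10]:
            trace = np.array(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-9)

    def test_noise_covariate_barely_moves_estimates(self, small_relatedness, small_cohort):
        y = small_cohort.child_phenotype
        base = fit_rdr(y, None, small_relatedness)
        noise = np.random.default_rng(2).standard_normal(len(y))
        with_noise = fit_rdr(y, noise, small_relatedness)
        for k in base.components:
            # an irrelevant covariate costs one degree of freedom: O(1/n)
            assert abs(base.components[k] - with_noise.components[k]) < 10 / len(y)


class TestHeRegression:
    def test_hand_solved_normal_equations(self):
        """4-individual worked instance: coefficients equal the directly
        solved least-squares normal equations over pair products."""
        K = np.array(
            [
                [1.0, 0.2, -0.1, 0.05],
                [0.2, 1.1, 0.15, -0.2],
                [-0.1, 0.15, 0.9, 0.1],
                [0.05, -0.2, 0.1, 1.0],
            ]
        )
        y = np.array([0.3, -1.2, 0.8, 1.5])
        est = he_regression(y, None, [K], names=("v_g",))
        r = y - y.mean()
        iu = np.triu_indices(4)
        design = np.column_stack([K[iu], np.eye(4)[iu]])
        z = np.outer(r, r)[iu]
        beta = np.linalg.solve(design.T @ design, design.T @ z)
        assert est["v_g"] == pytest.approx(beta[0], rel=1e-10)
        assert est["v_e"] == pytest.approx(beta[1], rel=1e-10)

    def test_pure_direct_signal_loads_on_child_matrix(self, small_relatedness):
        """Phenotypes built as pure child genetic signal put all the
        variance on K_oo in expectation (limit case of zero residual)."""
        rng = np.random.default_rng(3)
        n = small_relatedness.K_oo.shape[0]
        L = np.linalg.cholesky(small_relatedness.K_oo + 1e-6 * np.eye(n))
        vg, ve = [], []
        for _ in range(12):
            y = L @ rng.standard_normal(n)
            est = he_regression(y, None, [small_relatedness.K_oo], names=("v_g",))
            vg.append(est["v_g"])
            ve.append(est["v_e"])
        mc = np.std(vg, ddof=1) / math.sqrt(len(vg))
        assert np.mean(vg) == pytest.approx(1.0, abs=3 * mc)
        mc_e = np.std(ve, ddof=1) / math.sqrt(len(ve))
        assert abs(np.mean(ve)) < 3 * mc_e

    def test_permuted_phenotype_has_no_genetic_component(self, small_relatedness, small_cohort):
        """Shuffling the phenotype destroys every genetic signal."""
        rng = np.random.default_rng(4)
        ests = {"v_delta": [], "v_eta": [], "c": []}
        for _ in range(12):
            y = rng.permutation(small_cohort.child_phenotype)
            est = he_regression(
                y, None, small_relatedness.matrices, names=("v_delta", "v_eta", "c")
            )
            for k in ests:
                ests[k].append(est[k])
        for k, vals in ests.items():
            mc = np.std(vals, ddof=1) / math.sqrt(len(vals))
            assert abs(np.mean(vals)) < 3 * mc + 0.02

    def test_collinear_matrices_rejected(self, small_relatedness):
        K = small_relatedness.K_oo
        y = np.random.default_rng(5).standard_normal(K.shape[0])
        with pytest.raises(ValueError, match="collinear"):
            he_regression(y, None, [K, 2 * K])


class TestOracleAgreementAndCoverage:
    def test_reml_matches_moments_oracle_in_expectation(self, replicate_fits):
        """REML and Haseman-Elston agree in expectation over replicates."""
        _, rows = replicate_fits
        for name in ("v_delta", "v_eta", "c"):
            diffs = np.array([fit.components[name] - he[name] for fit, he in rows])
            mc_se = diffs.std(ddof=1) / math.sqrt(len(diffs))
            assert abs(diffs.mean()) < 2 * mc_se + 1e-3

    def test_mean_recovery_against_truth(self, replicate_fits):
        truth, rows = replicate_fits
        target = {"v_delta": truth.v_delta, "v_eta": truth.v_eta, "c": truth.c}
        for name, t in target.items():
            vals = np.array([fit.components[name] for fit, _ in rows])
            mc_se = vals.std(ddof=1) / math.sqrt(len(vals))
            assert abs(vals.mean() - t) < 2 * mc_se

    def test_wald_interval_coverage_sane(self, replicate_fits):
        """95% intervals from the average-information SEs cover simulated
        truth for 90-100% of replicates."""
        truth, rows = replicate_fits
        target = {"v_delta": truth.v_delta, "v_eta": truth.v_eta, "c": truth.c}
        for name, t in target.items():
            hits = [
                abs(fit.components[name] - t) <= 1.96 * fit.se[name]
                for fit, _ in rows
            ]
            assert 0.90 <= np.mean(hits) <= 1.0


class TestGremlAndImplied:
    def test_null_phenotype_estimates_zero(self, small_relatedness):
        y = np.random.default_rng(6).standard_normal(small_relatedness.K_oo.shape[0])
        res = greml_single(y, None, small_relatedness.K_oo)
        assert abs(res.components["v_g"]) <= 2 * res.se["v_g"] + 0.05

    def test_implied_single_component_arithmetic(self):
        assert implied_single_component(19, 14, -16) == pytest.approx(10.0)
        assert implied_single_component(0.42, 0.0, 0.0) == pytest.approx(0.42)
        assert implied_single_component(0.19, 0.14, -0.16) == pytest.approx(0.10)

    def test_implied_accepts_fitted_result(self, small_relatedness, small_cohort):
        fit = fit_rdr(small_cohort.child_phenotype, None, small_relatedness)
        s = fit.shares
        assert implied_single_component(fit) == pytest.approx(
            s["v_delta"] + s["v_eta"] / 2 + s["c"]
        )

    def test_shares_sum_to_one(self, small_relatedness, small_cohort):
        fit = fit_rdr(small_cohort.child_phenotype, None, small_relatedness)
        assert sum(fit.shares.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in fit.se.values())
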