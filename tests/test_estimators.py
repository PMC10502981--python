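"""TSLS estimators, Sargan test and cis-PC MR against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.sandbox.regression.gmm import IV2SLS

from collidermr._regression import FitError, logistic_irls
from collidermr.containers import ParameterError
from collidermr.estimators import (
    CisSummary,
    cis_pc_mr,
    observational_association,
    sargan_test,
    tsls_mvmr,
    tsls_uvmr,
)
from collidermr.simulate import SimulationConfig, simulate_two_exposure_cohort


class TestObservational:
    def test_identity_regression(self, rng):
        x = rng.standard_normal(200)
        est = observational_association(x, x)
        assert est.beta[0] == pytest.approx(1.0, abs=1e-10)
        assert est.se[0] < 1e-8

    def test_null_binary_ci_coverage(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.standard_normal(600)
            y = rng.binomial(1, 0.3, 600)
            est = observational_association(x, y, outcome_type="binary")
            hits += est.ci_low[0] <= 0 <= est.ci_high[0]
        # binomial band around nominal 95%
        assert abs(hits / reps - 0.95) < 4 * np.sqrt(0.95 * 0.05 / reps)

    def test_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal(500)
        c = rng.standard_normal(500)
        eta = 0.5 * x - 0.3 * c
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        est = observational_association(x, y, covariates=c[:, None], outcome_type="binary")
        ref = sm.Logit(y, sm.add_constant(np.column_stack([c, x]))).fit(disp=0)
        assert est.beta[0] == pytest.approx(ref.params[2], abs=1e-6)
        assert est.se[0] == pytest.approx(ref.bse[2], rel=1e-4)


class TestTslsUvmr:
    def test_wald_ratio_identity(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        x = 0.3 * g + rng.standard_normal(500)
        y = 0.5 * x + rng.standard_normal(500)
        est = tsls_uvmr(g, x, y, diagnostics=False)
        gc, xc, yc = g - g.mean(), x - x.mean(), y - y.mean()
        wald = (gc @ yc) / (gc @ xc)
        assert est.beta[0] == pytest.approx(wald, abs=1e-10)

    def test_self_regression_is_one(self, rng):
        g = rng.binomial(2, 0.3, size=(300, 5)).astype(float)
        x = g @ np.full(5, 0.2) + rng.standard_normal(300)
        est = tsls_uvmr(g, x, x, diagnostics=False)
        assert est.beta[0] == pytest.approx(1.0, abs=1e-10)

    def test_parameter_recovery_over_replicates(self):
        reps = 200
        est = np.empty(reps)
        for r in range(reps):
            rng = np.random.default_rng(5000 + r)
            n = 5000
            g = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
            u = rng.standard_normal(n)
            # strong instruments (per-SNP F in the hundreds) so the
            # finite-sample TSLS bias is negligible next to the MC error
            x = g @ np.full(10, 0.3) + 0.3 * u + rng.standard_normal(n)
            y = 0.3 * x + 0.3 * u + rng.standard_normal(n)
            est[r] = tsls_uvmr(g, x, y, diagnostics=False).beta[0]
        assert abs(est.mean() - 0.3) < 4 * est.std(ddof=1) / np.sqrt(reps)

    def test_matches_statsmodels_iv2sls(self, rng):
        n = 800
        g = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
        c = rng.standard_normal((n, 2))
        u = rng.standard_normal(n)
        x = g @ np.full(6, 0.25) + c @ [0.2, -0.1] + u + rng.standard_normal(n)
        y = 0.4 * x + c @ [0.1, 0.3] + u + rng.standard_normal(n)
        est = tsls_uvmr(g, x, y, covariates=c, diagnostics=False)
        exog = np.column_stack([np.ones(n), c, x])
        instr = np.column_stack([np.ones(n), c, g])
        ref = IV2SLS(y, exog, instrument=instr).fit()
        assert est.beta[0] == pytest.approx(ref.params[-1], abs=1e-8)
        assert est.se[0] == pytest.approx(ref.bse[-1], rel=1e-6)

    def test_affine_instrument_recoding_invariance(self, rng):
        g = rng.binomial(2, 0.3, size=(400, 4)).astype(float)
        x = g @ np.full(4, 0.3) + rng.standard_normal(400)
        y = 0.2 * x + rng.standard_normal(400)
        a = tsls_uvmr(g, x, y, diagnostics=False).beta[0]
        b = tsls_uvmr(2.0 - g, x, y, diagnostics=False).beta[0]
        assert a == pytest.approx(b, abs=1e-10)

    def test_binary_outcome_directionally_consistent(self, rng):
        n = 20_000
        g = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        x = g @ np.full(10, 0.2) + rng.standard_normal(n)
        from collidermr.simulate import binary_from_latent

        y = binary_from_latent(0.5 * (x - x.mean()) / x.std(), 0.05, seed=1)
        est = tsls_uvmr(g, x, y, outcome_type="binary", diagnostics=False)
        assert est.beta[0] > 0
        assert est.beta[0] - 1.96 * est.se[0] > 0

    def test_degenerate_instrument_rejected(self, rng):
        g = np.ones((100, 1))
        x = rng.standard_normal(100)
        with pytest.raises(FitError):
            tsls_uvmr(g, x, x, diagnostics=False)


class TestTslsMvmr:
    def test_disjoint_instruments_match_uvmr(self, strong_two_exposure):
        geno, cohort, truth = strong_two_exposure
        mv = tsls_mvmr(geno, cohort[["x1", "x2"]], cohort["y"], diagnostics=False)
        for k, (col, ids) in enumerate(
            (("x1", truth.snp_ids_x1), ("x2", truth.snp_ids_x2))
        ):
            uv = tsls_uvmr(
                geno.values(ids), cohort[col].to_numpy(), cohort["y"], diagnostics=False
            )
            joint_se = np.hypot(mv.se[k], uv.se[0])
            assert abs(mv.beta[k] - uv.beta[0]) < 2 * joint_se

    def test_recovers_generating_effects(self, strong_two_exposure):
        geno, cohort, _ = strong_two_exposure
        mv = tsls_mvmr(geno, cohort[["x1", "x2"]], cohort["y"])
        assert np.all(np.abs(mv.beta - [1.0, 0.5]) < 4 * mv.se)
        assert mv.diagnostics["conditional_f"]["x1"] > 10

    def test_duplicated_exposure_degenerate(self, strong_two_exposure):
        geno, cohort, _ = strong_two_exposure
        X = pd.DataFrame({"a": cohort["x1"], "b": cohort["x1"]})
        with pytest.raises((FitError, np.linalg.LinAlgError)):
            tsls_mvmr(geno, X, cohort["y"], diagnostics=False)

    def test_fewer_instruments_than_exposures_rejected(self, rng):
        g = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        with pytest.raises(ParameterError):
            tsls_mvmr(g, X, rng.standard_normal(100))


class TestSargan:
    def test_just_identified_rejected(self, rng):
        g = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        x = 0.3 * g[:, 0] + rng.standard_normal(200)
        with pytest.raises(ParameterError):
            sargan_test(g, x, 0.2 * x + rng.standard_normal(200))

    def test_null_rejection_rate(self):
        reps, hits = 200, 0
        for r in range(reps):
            rng = np.random.default_rng(9000 + r)
            n = 1000
            g = rng.binomial(2, 0.3, size=(n, 15)).astype(float)
            u = rng.standard_normal(n)
            x = g @ np.full(15, 0.15) + u + rng.standard_normal(n)
            y = 0.3 * x + u + rng.standard_normal(n)
            hits += sargan_test(g, x, y)["p"] < 0.05
        assert abs(hits / reps - 0.05) < 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_detects_directional_pleiotropy(self):
        reps, hits = 100, 0
        for r in range(reps):
            rng = np.random.default_rng(11_000 + r)
            n = 10_000
            g = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
            x = g @ np.full(20, 0.15) + rng.standard_normal(n)
            alpha = np.zeros(20)
            alpha[:4] = 0.2  # 20% of SNPs with large direct effects
            y = 0.3 * x + g @ alpha + rng.standard_normal(n)
            hits += sargan_test(g, x, y)["p"] < 0.05
        assert hits / reps > 0.9


class TestCisPcMr:
    def _orthogonal_summary(self, rng, m=8):
        bx = rng.normal(0.1, 0.03, m)
        sy = np.full(m, 0.02)
        by = 0.4 * bx + rng.normal(0, 0.002, m)
        return CisSummary(
            beta_exposure=bx,
            se_exposure=np.full(m, 0.01),
            beta_outcome=by,
            se_outcome=sy,
            ld=np.eye(m),
        )

    def test_identity_ld_reduces_to_ivw(self, rng):
        summ = self._orthogonal_summary(rng)
        est = cis_pc_mr(summ, k=summ.beta_exposure.shape[0], ridge=0.0)
        w = summ.beta_exposure**2 / summ.se_outcome**2
        ivw = float(
            np.sum(summ.beta_exposure * summ.beta_outcome / summ.se_outcome**2) / np.sum(w)
        )
        assert est.beta[0] == pytest.approx(ivw, abs=1e-8)
        assert est.se[0] == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-8)

    def test_duplicated_snp_invariance(self, rng):
        summ = self._orthogonal_summary(rng, m=6)
        # duplicate the first SNP with r = 1
        m = 7
        ld = np.eye(m)
        ld[0, 1] = ld[1, 0] = 1.0
        dup = CisSummary(
            beta_exposure=np.r_[summ.beta_exposure[0], summ.beta_exposure],
            se_exposure=np.r_[summ.se_exposure[0], summ.se_exposure],
            beta_outcome=np.r_[summ.beta_outcome[0], summ.beta_outcome],
            se_outcome=np.r_[summ.se_outcome[0], summ.se_outcome],
            ld=ld,
        )
        base = cis_pc_mr(summ, var_threshold=0.999)
        dupe = cis_pc_mr(dup, var_threshold=0.999)
        assert dupe.beta[0] == pytest.approx(base.beta[0], rel=0.05)

    def test_invalid_k(self, rng):
        summ = self._orthogonal_summary(rng)
        with pytest.raises(ParameterError):
            cis_pc_mr(summ, k=0)
        with pytest.raises(ParameterError):
            cis_pc_mr(summ, k=99)

    def test_recovers_effect_under_correlation(self, rng):
        # construct correlated summary data with a known causal slope
        m = 12
        A = rng.standard_normal((m, m))
        R = A @ A.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        bx = rng.normal(0.15, 0.04, m)
        by = 0.5 * bx
        summ = CisSummary(
            beta_exposure=bx,
            se_exposure=np.full(m, 0.01),
            beta_outcome=by,
            se_outcome=np.full(m, 0.02),
            ld=R,
        )
        est = cis_pc_mr(summ)
        assert est.beta[0] == pytest.approx(0.5, abs=0.02)


class TestLogisticKernel:
    def test_weighted_logistic_matches_glm(self, rng):
        import statsmodels.api as sm

        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.binomial(1, 0.4, n).astype(float)
        w = rng.dirichlet(np.ones(n)) * n
        beta, cov = logistic_irls(X, y, w)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        assert np.allclose(beta, ref.params, atol=1e-8)
        assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-6)

    def test_separation_raises(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        y = (np.arange(20) >= 10).astype(float)
        with pytest.raises(FitError):
            logistic_irls(X, y)
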