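"""2SLS, Sargan, Wald-ratio estimators and weak-instrument diagnostics."""

import numpy as np
import pandas as pd
import pytest

from dyadmr import (
    ScenarioParams,
    SpousalMR,
    SummaryMR,
    WaldRatioSet,
    egger_estimate,
    ivw_estimate,
    lad_estimate,
    mv_regression,
    mv_vs_mr_ztest,
    per_snp_wald_ratios,
    sargan_test,
    simulate_couples,
    weak_instrument_diagnostics,
)
from dyadmr.results import EffectEstimate


def _ratio_set(beta_gx, beta_gy, se_gy, se_gx=None):
    beta_gx = np.asarray(beta_gx, dtype=float)
    beta_gy = np.asarray(beta_gy, dtype=float)
    se_gy = np.asarray(se_gy, dtype=float)
    se_gx = np.full_like(beta_gx, 0.05) if se_gx is None else np.asarray(se_gx)
    t = pd.DataFrame(
        dict(
            variant_id=[f"v{i}" for i in range(len(beta_gx))],
            beta_gx=beta_gx,
            se_gx=se_gx,
            beta_gy=beta_gy,
            se_gy=se_gy,
            ratio=beta_gy / beta_gx,
            ratio_se=se_gy / np.abs(beta_gx),
        )
    )
    return WaldRatioSet(t)


class TestTwoStageLeastSquares:
    def test_identity_instrument_recovers_ols(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        fit = SpousalMR(y, x, x).fit()
        ols = mv_regression(y, x)
        assert fit.beta == pytest.approx(ols.beta, abs=1e-10)

    def test_matches_covariance_ratio_oracle(self, rng):
        # single instrument: beta = cov(z_res, y_res) / cov(z_res, x_res)
        n = 12
        z = rng.integers(0, 3, n).astype(float)
        c = rng.standard_normal(n)
        x = 0.5 * z + 0.3 * c + rng.standard_normal(n)
        y = 0.25 * x + 0.2 * c + rng.standard_normal(n)
        W = np.column_stack([np.ones(n), c])

        def resid(v):
            return v - W @ np.linalg.lstsq(W, v, rcond=None)[0]

        expect = np.cov(resid(z), resid(y))[0, 1] / np.cov(resid(z), resid(x))[0, 1]
        fit = SpousalMR(y, x, z, covariates=c).fit()
        assert fit.beta == pytest.approx(expect, rel=1e-8)

    def test_iv_se_uses_structural_residuals(self, rng):
        n = 2000
        z = rng.integers(0, 3, n).astype(float)
        x = 0.5 * z + rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n)
        fit = SpousalMR(y, x, z).fit()
        # independent oracle: classic IV variance with structural residuals
        Z = np.column_stack([z, np.ones(n)])
        X = np.column_stack([x, np.ones(n)])
        P = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        beta = np.linalg.solve(X.T @ P @ X, X.T @ P @ y)
        u = y - X @ beta
        cov = (u @ u / (n - 2)) * np.linalg.inv(X.T @ P @ X)
        assert fit.beta == pytest.approx(beta[0], rel=1e-10)
        assert fit.se == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-10)

    def test_agrees_with_statsmodels_iv2sls(self, rng):
        """Independent cross-check against the reference IV implementation."""
        from statsmodels.sandbox.regression.gmm import IV2SLS

        n = 800
        z = rng.integers(0, 3, n).astype(float)
        c = rng.standard_normal(n)
        x = 0.4 * z + 0.3 * c + rng.standard_normal(n)
        y = 0.25 * x + 0.2 * c + rng.standard_normal(n)
        fit = SpousalMR(y, x, z, covariates=c).fit()
        X = np.column_stack([x, c, np.ones(n)])
        Z = np.column_stack([z, c, np.ones(n)])
        ref = IV2SLS(y, X, instrument=Z).fit()
        assert fit.beta == pytest.approx(ref.params[0], rel=1e-8)
        assert fit.se == pytest.approx(ref.bse[0], rel=1e-6)

    def test_unidentified_instrument_errors(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        z = np.zeros(n)
        z[0] = 1e-13
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            SpousalMR(y, x, z).fit()

    def test_interaction_ci_coverage(self):
        # 2SLS 95% CI covers the structural effect at the nominal rate
        covered = 0
        reps = 500
        beta_true = 0.2
        for s in range(reps):
            params = ScenarioParams(
                scenario="interaction", n_couples=2000, alpha_g=0.3,
                beta_i=beta_true, n_snps=10, seed=1000 + s,
            )
            c = simulate_couples(params)
            one = c.orientations(pooled=False)
            fit = SpousalMR(
                one["spouse_phenotype"], one["index_phenotype"], one["index_grs_std"]
            ).fit()
            lo, hi = fit.conf_int()
            covered += lo <= beta_true <= hi
        rate = covered / reps
        assert abs(rate - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps)

    def test_grs_level_wald_ratio_agrees_with_2sls(self, interaction_cohort):
        one = interaction_cohort.orientations(pooled=False)
        y = one["spouse_phenotype"].to_numpy()
        x = one["index_phenotype"].to_numpy()
        g = one["index_grs_std"].to_numpy()
        fit = SpousalMR(y, x, g).fit()
        ratios = per_snp_wald_ratios(g[:, None], x, y)
        assert ivw_estimate(ratios).beta == pytest.approx(fit.beta, rel=1e-8)


class TestZTest:
    @pytest.mark.parametrize(
        "mv, mr, expected_p",
        [
            ((-0.113, 0.005), (-0.152, 0.055), 0.480),
            ((-0.008, 0.004), (-0.154, 0.061), 0.017),
        ],
    )
    def test_reported_rows_reproduce(self, mv, mr, expected_p):
        a = EffectEstimate(mv[0], mv[1], 0, "MV")
        b = EffectEstimate(mr[0], mr[1], 0, "2SLS")
        assert mv_vs_mr_ztest(a, b).p == pytest.approx(expected_p, abs=5e-4)

    def test_identical_estimates_give_p_one(self):
        a = EffectEstimate(0.1, 0.02, 0, "MV")
        b = EffectEstimate(0.1, 0.05, 0, "2SLS")
        res = mv_vs_mr_ztest(a, b)
        assert res.z == 0.0 and res.p == 1.0


class TestSargan:
    def test_single_instrument_not_applicable(self, rng):
        res = sargan_test(rng.standard_normal(50), rng.standard_normal(50))
        assert res.df == 0 and not res.applicable

    def test_matches_n_r2_oracle(self, rng):
        n = 100
        Z = rng.integers(0, 3, size=(n, 2)).astype(float)
        u = rng.standard_normal(n)
        res = sargan_test(u, Z)
        A = np.column_stack([np.ones(n), Z])
        fitted = A @ np.linalg.lstsq(A, u, rcond=None)[0]
        r2 = 1 - ((u - fitted) ** 2).sum() / ((u - u.mean()) ** 2).sum()
        assert res.stat == pytest.approx(n * r2, rel=1e-10)
        assert res.df == 1

    def test_duplicated_instrument_collinearity(self, rng):
        n = 60
        z = rng.integers(0, 3, n).astype(float)
        Z = np.column_stack([z, z])
        with pytest.raises(np.linalg.LinAlgError):
            sargan_test(rng.standard_normal(n), Z)


class TestWaldRatios:
    def test_ratio_arithmetic(self):
        rs = _ratio_set([0.5], [0.1], [0.05])
        row = rs.table.iloc[0]
        assert row.ratio == pytest.approx(0.2)
        assert row.ratio_se == pytest.approx(0.1)

    def test_zero_outcome_association_gives_zero_ratio(self):
        rs = _ratio_set([0.5], [0.0], [0.05])
        assert rs.table.ratio.iloc[0] == 0.0

    def test_matches_per_variant_regression_oracle(self, rng):
        n, m = 400, 3
        D = rng.integers(0, 3, size=(n, m)).astype(float)
        c = rng.standard_normal(n)
        x = D @ [0.2, 0.1, 0.3] + 0.4 * c + rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        rs = per_snp_wald_ratios(D, x, y, c)
        W = np.column_stack([np.ones(n), c])
        for j in range(m):
            X = np.column_stack([D[:, j], W])
            bx = np.linalg.lstsq(X, x, rcond=None)[0][0]
            by = np.linalg.lstsq(X, y, rcond=None)[0][0]
            row = rs.table.iloc[j]
            assert row.beta_gx == pytest.approx(bx, rel=1e-9)
            assert row.ratio == pytest.approx(by / bx, rel=1e-9)


class TestIvw:
    def test_single_ratio_passthrough(self):
        est = ivw_estimate(_ratio_set([1.0], [0.3], [0.1]))
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.1)

    def test_equal_weights_average(self):
        est = ivw_estimate(_ratio_set([1.0, 1.0], [1.0, 0.0], [1.0, 1.0]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(1 / np.sqrt(2))

    def test_matches_weighted_mean_oracle(self, rng):
        gx = rng.uniform(0.2, 1.0, 5)
        gy = rng.normal(0.3 * gx, 0.05)
        se = rng.uniform(0.02, 0.1, 5)
        rs = _ratio_set(gx, gy, se)
        w = (se / np.abs(gx)) ** -2
        expect = np.sum(w * gy / gx) / np.sum(w)
        assert ivw_estimate(rs).beta == pytest.approx(expect, rel=1e-10)


class TestEgger:
    def test_points_through_origin(self):
        gx = np.array([0.2, 0.4, 0.6, 0.8])
        rs = _ratio_set(gx, 0.3 * gx, [0.05] * 4)
        slope, intercept = egger_estimate(rs)
        assert abs(intercept.beta) < 1e-10
        assert slope.beta == pytest.approx(0.3, abs=1e-10)

    def test_matches_closed_form_weighted_regression(self, rng):
        gx = np.array([0.2, 0.5, 0.7, 1.0])
        gy = np.array([0.10, 0.12, 0.30, 0.28])
        se = np.array([0.05, 0.04, 0.06, 0.05])
        slope, intercept = egger_estimate(_ratio_set(gx, gy, se))
        w = se**-2.0
        X = np.column_stack([gx, np.ones(4)])
        coef = np.linalg.solve(X.T @ (X * w[:, None]), (X * w[:, None]).T @ gy)
        assert slope.beta == pytest.approx(coef[0], rel=1e-10)
        assert intercept.beta == pytest.approx(coef[1], rel=1e-10)

    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            egger_estimate(_ratio_set([0.2, 0.4], [0.1, 0.2], [0.05, 0.05]))

    def test_negative_gx_oriented(self):
        gx = np.array([-0.5, 0.5, 0.7])
        rs = _ratio_set(gx, 0.4 * gx, [0.05] * 3)
        slope, intercept = egger_estimate(rs)
        assert slope.beta == pytest.approx(0.4, abs=1e-10)


class TestLad:
    def test_symmetric_odd_set_gives_median(self):
        est = lad_estimate(
            _ratio_set([1.0, 1.0, 1.0], [0.1, 0.3, 0.5], [0.1] * 3), n_boot=0
        )
        assert est.beta == pytest.approx(0.3)

    def test_matches_grid_search_oracle(self, rng):
        gx = rng.uniform(0.3, 1.0, 9)
        gy = rng.normal(0.25 * gx, 0.08)
        se = rng.uniform(0.03, 0.1, 9)
        rs = _ratio_set(gx, gy, se)
        est = lad_estimate(rs, n_boot=0)
        w = 1.0 / se
        grid = np.linspace(-1, 1, 2_000_001)
        obj = np.abs(gy[None, :] - grid[:, None] * gx[None, :]) @ w
        best = grid[np.argmin(obj)]
        assert est.beta == pytest.approx(best, abs=1e-6)

    def test_constant_ratios_zero_bootstrap_se(self):
        rs = _ratio_set([0.5, 0.8, 1.0], [0.1, 0.16, 0.2], [0.05] * 3)
        est = lad_estimate(rs, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.0, abs=1e-12)


class TestWeakInstrumentDiagnostics:
    def test_identical_gx_zero_heterogeneity(self):
        rs = _ratio_set([0.4, 0.4, 0.4], [0.1, 0.1, 0.1], [0.05] * 3)
        _, i2 = weak_instrument_diagnostics(rs)
        assert i2 == 0.0

    def test_single_variant_mean_f(self):
        rs = _ratio_set([0.4], [0.1], [0.05], se_gx=[0.1])
        mean_f, i2 = weak_instrument_diagnostics(rs)
        assert mean_f == pytest.approx((0.4 / 0.1) ** 2)
        assert i2 == 0.0

    def test_matches_q_oracle(self, rng):
        gx = rng.uniform(0.1, 0.9, 6)
        se_gx = rng.uniform(0.02, 0.08, 6)
        rs = _ratio_set(gx, 0.3 * gx, [0.05] * 6, se_gx=se_gx)
        mean_f, i2 = weak_instrument_diagnostics(rs)
        w = se_gx**-2.0
        mu = np.sum(w * gx) / np.sum(w)
        q = np.sum(w * (gx - mu) ** 2)
        expect = max(0.0, (q - 5) / q) * 100
        assert i2 == pytest.approx(expect, rel=1e-10)


def test_estimators_agree_without_pleiotropy(interaction_cohort):
    """IVW, Egger and LAD concur (within joint SEs) on pleiotropy-free data."""
    one = interaction_cohort.orientations(pooled=False)
    geno = interaction_cohort.genotypes
    ids = pd.Index(geno.individual_id)
    D = geno.dosage[ids.get_indexer(one["index_id"])]
    ratios = per_snp_wald_ratios(
        D, one["index_phenotype"], one["spouse_phenotype"]
    )
    bundle = SummaryMR(ratios).fit_all(seed=0, n_boot=200)
    for a in (bundle.ivw, bundle.egger_slope, bundle.lad):
        for b in (bundle.ivw, bundle.egger_slope, bundle.lad):
            joint = np.sqrt(a.se**2 + b.se**2)
            assert abs(a.beta - b.beta) <= 2 * joint + 1e-12
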