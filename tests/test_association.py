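import numpy as np
import pandas as pd
import pytest

from autozyg.association import (build_design, eigendecompose, fit_ols,
                                 fit_polygenic, subset_under_age,
                                 zscore_heights)
from autozyg.relatedness import KinshipMatrix
from oracles import m2ll_exact, m2ll_grid_min


def pheno_frame(heights, cohort="c1", ages=None, sexes=None):
    n = len(heights)
    return pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "height_cm": heights,
        "age_years": ages if ages is not None else np.full(n, 40.0),
        "sex": sexes if sexes is not None else ["male"] * n,
        "cohort": cohort,
    })


class TestZscores:
    def test_symmetric_triple(self):
        z = zscore_heights(pheno_frame([160.0, 170.0, 180.0]), "c1")
        assert list(z.values) == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero height variance"):
            zscore_heights(pheno_frame([170.0, 170.0, 170.0]), "c1")

    def test_normalisation_identity(self, demo_cohort):
        z = zscore_heights(demo_cohort.phenotypes, "demo")
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestSubsetUnderAge:
    def test_strict_inequality(self):
        ph = pheno_frame([160, 170, 180], ages=[31.0, 40.0, 55.0])
        out = subset_under_age(ph, 40.0)
        assert list(out["age_years"]) == [31.0]

    def test_all_young_is_identity(self):
        ph = pheno_frame([160, 170], ages=[20.0, 30.0])
        assert len(subset_under_age(ph, 40.0)) == 2

    def test_empty_errors(self):
        ph = pheno_frame([160], ages=[50.0])
        with pytest.raises(ValueError):
            subset_under_age(ph, 40.0)


def design_frame(rng, n=200, p_extra=2):
    x = pd.DataFrame({"intercept": np.ones(n),
                      "f": rng.uniform(0, 10, n)})
    for j in range(p_extra):
        x[f"c{j}"] = rng.normal(size=n)
    return x


class TestOls:
    def test_exact_fit_recovers_coefficient(self, rng):
        x = design_frame(rng)
        y = 0.3 - 0.065 * x["f"] + 0.5 * x["c0"]
        fit = fit_ols(y.values, x, term="f")
        assert fit.beta == pytest.approx(-0.065, abs=1e-10)
        assert fit.se < 1e-8

    def test_constant_column_raises_named_rank_error(self, rng):
        x = design_frame(rng)
        x["f"] = 4.2
        with pytest.raises(ValueError, match="f"):
            fit_ols(rng.normal(size=len(x)), x, term="f")

    def test_matches_normal_equations_oracle(self, rng):
        x = design_frame(rng, n=200)
        y = rng.normal(size=200) - 0.05 * x["f"].values
        fit = fit_ols(y, x, term="f")
        xm = x.to_numpy()
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        resid = y - xm @ beta
        sigma2 = resid @ resid / (200 - xm.shape[1])
        cov = sigma2 * np.linalg.inv(xm.T @ xm)
        assert fit.beta == pytest.approx(beta[1], abs=1e-10)
        assert fit.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)
        t = beta[1] / np.sqrt(cov[1, 1])
        assert fit.var_explained == pytest.approx(
            t * t / (t * t + (200 - xm.shape[1])), abs=1e-10)


class TestPolygenic:
    def test_identity_kinship_collapses_to_ols(self, rng):
        n = 120
        x = design_frame(rng, n=n)
        y = rng.normal(size=n) - 0.1 * x["f"].values
        kin = KinshipMatrix([f"s{i}" for i in range(n)],
                            0.5 * np.eye(n), m_snps_used=1)
        ols = fit_ols(y, x, term="f")
        mm, vc = fit_polygenic(y, x, kin, term="f")
        assert mm.beta == pytest.approx(ols.beta, abs=1e-8)
        assert mm.se == pytest.approx(ols.se, abs=1e-8)

    def test_matches_grid_oracle(self, rng):
        """-2logL at the optimiser's solution beats/matches a dense 51x51
        variance-component grid on a related 60-sample instance."""
        n = 60
        # block-diagonal relatedness: 30 sib pairs
        a = np.eye(n)
        for i in range(0, n, 2):
            a[i, i + 1] = a[i + 1, i] = 0.5
        rng_l = np.random.default_rng(12)
        x = design_frame(rng_l, n=n)
        g = np.linalg.cholesky(a) @ rng_l.normal(size=n)
        y = (-0.05 * x["f"].values + np.sqrt(0.5) * g
             + np.sqrt(0.5) * rng_l.normal(size=n))
        eig = eigendecompose(a)
        fit, vc = fit_polygenic(y, x, term="f", eig=eig)
        total = vc.sigma2_g + vc.sigma2_e
        grid_min = m2ll_grid_min(y, x.to_numpy(), a,
                                 g_max=3 * total, e_max=3 * total)
        assert fit.minus2logl <= grid_min + 1e-6
        assert fit.minus2logl == pytest.approx(grid_min, abs=0.05)
        # and the optimum really is a likelihood: exact recomputation agrees
        assert fit.minus2logl == pytest.approx(
            m2ll_exact(y, x.to_numpy(), a, vc.sigma2_g, vc.sigma2_e), abs=1e-6)

    def test_se_calibration_coverage(self, rng):
        """beta_hat +/- 2 SE covers the truth in >= 93% of replicates under
        a strongly heritable polygenic model."""
        n = 150
        a = np.eye(n)
        for i in range(0, n, 3):  # sib trios
            a[i:i + 3, i:i + 3] = 0.5
        np.fill_diagonal(a, 1.0)
        eig = eigendecompose(a)
        rng_l = np.random.default_rng(77)
        x = design_frame(rng_l, n=n, p_extra=1)
        chol = np.linalg.cholesky(a + 1e-9 * np.eye(n))
        beta_true = -0.065
        hits = 0
        reps = 200
        for _ in range(reps):
            g = chol @ rng_l.normal(size=n) * np.sqrt(0.8)
            y = beta_true * x["f"].values + g + np.sqrt(0.2) * rng_l.normal(size=n)
            fit, _ = fit_polygenic(y, x, term="f", eig=eig)
            hits += abs(fit.beta - beta_true) <= 2 * fit.se
        assert hits / reps >= 0.93

    def test_mixed_se_not_below_ols_se_on_related_data(self, rng):
        n = 100
        a = np.eye(n)
        for i in range(0, n, 2):
            a[i, i + 1] = a[i + 1, i] = 0.5
        eig = eigendecompose(a)
        rng_l = np.random.default_rng(5)
        chol = np.linalg.cholesky(a + 1e-9 * np.eye(n))
        ratios = []
        for _ in range(40):
            x = design_frame(rng_l, n=n, p_extra=1)
            # homozygosity clusters in families too
            fam = np.repeat(rng_l.uniform(0, 10, n // 2), 2)
            x["f"] = fam + rng_l.normal(scale=0.5, size=n)
            g = chol @ rng_l.normal(size=n) * np.sqrt(0.7)
            y = -0.05 * x["f"].values + g + np.sqrt(0.3) * rng_l.normal(size=n)
            mm, _ = fit_polygenic(y, x, term="f", eig=eig)
            ols = fit_ols(y, x, term="f")
            ratios.append(mm.se / ols.se)
        assert np.mean(ratios) >= 1.0


class TestBuildDesign:
    def test_covariate_columns_and_units(self, demo_cohort, demo_analysis):
        z, x = build_design(demo_cohort.phenotypes, demo_analysis.measures,
                            "f_rohld", extra_covariates=("ea",))
        assert list(x.columns) == ["intercept", "f_rohld", "age", "sex_male", "ea"]
        assert set(x["sex_male"].unique()) <= {0.0, 1.0}
        assert len(z) == len(x)

    def test_uncorrelated_ses_covariate_leaves_beta_alone(self, demo_cohort,
                                                          demo_analysis):
        """With no built-in confounding, adjusting for educational attainment
        moves the homozygosity coefficient by less than 2 SE."""
        ph, ms = demo_cohort.phenotypes, demo_analysis.measures
        z, x0 = build_design(ph, ms, "f_rohld")
        z1, x1 = build_design(ph, ms, "f_rohld", extra_covariates=("ea",))
        f0 = fit_ols(z.values, x0, term="f_rohld")
        f1 = fit_ols(z1.values, x1, term="f_rohld")
        assert abs(f0.beta - f1.beta) < 2 * f0.se
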