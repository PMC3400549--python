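"""Per-cohort association between height and genome-wide homozygosity.

Heights are z-scored within cohort.  Cohorts of unrelated individuals are
fitted by ordinary least squares; cohorts containing related individuals use
a linear mixed polygenic model

    y = X beta + g + e,   cov(g) = sigma_g^2 * 2K,   cov(e) = sigma_e^2 * I,

with K the genomic kinship matrix.  The mixed model is fitted by maximum
likelihood via a one-time eigendecomposition of 2K and one-dimensional
profile-likelihood optimisation of the variance ratio lambda =
sigma_g^2/sigma_e^2.  Fixed-effect covariates are age (linear), sex (single
indicator) and optionally an ordinal socio-economic measure; the homozygosity
measure enters in percent units, so beta is in z-score units per 1%
homozygosity.

Standard errors of the fixed effects use the degrees-of-freedom-corrected
residual variance, so that in the absence of relatedness information
(2K proportional to I) the mixed fit reproduces the OLS estimate and SE
exactly; the reported -2 log-likelihood is the uncorrected ML value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .relatedness import KinshipMatrix, relationship_matrix

logger = logging.getLogger("autozyg")

LAMBDA_BOUNDS = (1e-6, 1e6)
BOUNDARY_BOUNDS = (1e-5, 1e5)


@dataclass
class CohortFit:
    cohort: str
    measure: str
    covariates: str
    n: int
    beta: float
    se: float
    p: float
    var_explained: float
    minus2logl: float = float("nan")
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def zscore_heights(pheno: pd.DataFrame, cohort: str) -> pd.Series:
    """Within-cohort z-scores of height (SD with n-1 denominator)."""
    sub = pheno.loc[pheno["cohort"] == cohort]
    if len(sub) < 2:
        raise ValueError(f"cohort {cohort!r} has fewer than 2 samples")
    sd = sub["height_cm"].std(ddof=1)
    if sd == 0:
        raise ValueError(f"cohort {cohort!r} has zero height variance")
    z = (sub["height_cm"] - sub["height_cm"].mean()) / sd
    z.index = sub["sample"].values
    return z


def subset_under_age(pheno: pd.DataFrame, max_age: float = 40.0) -> pd.DataFrame:
    """Strictly-younger-than-`max_age` subset of a phenotype table."""
    out = pheno.loc[pheno["age_years"] < max_age].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no samples aged under {max_age}")
    return out


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")


def fit_ols(z: np.ndarray, design: pd.DataFrame, term: str,
            cohort: str = "", measure: str = "") -> CohortFit:
    """Least-squares fit; reports the coefficient of `term`.

    `design` must contain an intercept column; var_explained is the partial
    R-squared of `term` (t^2 / (t^2 + df_resid)).
    """
    y = np.asarray(z, dtype=float)
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    n, p_dim = x.shape
    if n < p_dim + 2:
        raise ValueError("too few samples for the design")
    _check_full_rank(x, names)
    j = names.index(term)

    beta_hat, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta_hat
    df_resid = n - p_dim
    sigma2 = resid @ resid / df_resid
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov[j, j]))
    tval = beta_hat[j] / se if se > 0 else np.inf
    pval = 2 * stats.t.sf(abs(tval), df_resid)
    var_exp = tval**2 / (tval**2 + df_resid)
    return CohortFit(cohort=cohort, measure=measure,
                     covariates=",".join(c for c in names if c != "intercept"),
                     n=n, beta=float(beta_hat[j]), se=max(se, np.finfo(float).tiny),
                     p=float(pval), var_explained=float(var_exp))


def eigendecompose(kinship: KinshipMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the bent relationship matrix 2K."""
    a = relationship_matrix(kinship) if isinstance(kinship, KinshipMatrix) else kinship
    d, u = np.linalg.eigh(a)
    if d[0] < -1e-8:
        raise ValueError("relationship matrix not PSD after bending")
    return np.clip(d, 0.0, None), u


def _profile_m2ll(log_lam: float, d: np.ndarray, yt: np.ndarray,
                  xt: np.ndarray) -> tuple[float, np.ndarray, float, np.ndarray]:
    """ML -2logL profiled over beta and sigma_e^2 at fixed lambda."""
    lam = np.exp(log_lam)
    w = lam * d + 1.0
    xw = xt / w[:, None]
    xtwx = xt.T @ xw
    beta = np.linalg.solve(xtwx, xw.T @ yt)
    resid = yt - xt @ beta
    rss = float(resid @ (resid / w))
    n = len(yt)
    sigma2_e = rss / n
    m2ll = n * np.log(2 * np.pi * sigma2_e) + float(np.log(w).sum()) + n
    return m2ll, beta, sigma2_e, xtwx


def fit_polygenic(
    z: np.ndarray,
    design: pd.DataFrame,
    kinship: KinshipMatrix | None = None,
    term: str = "",
    cohort: str = "",
    measure: str = "",
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    reml: bool = False,
) -> tuple[CohortFit, VarianceComponents]:
    """Maximum-likelihood polygenic mixed model fit.

    Either `kinship` or a precomputed eigendecomposition `eig` of the bent
    relationship matrix must be given.  An optimum at the edge of the
    variance-ratio search range sets ``boundary=True`` on the returned fit
    (reported, with a warning, rather than raised -- the analysis treats
    such cohorts as convergence failures).
    """
    y = np.asarray(z, dtype=float)
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    n, p_dim = x.shape
    if n < p_dim + 2:
        raise ValueError("too few samples for the design")
    _check_full_rank(x, names)
    j = names.index(term)

    if eig is None:
        if kinship is None:
            raise ValueError("need kinship matrix or precomputed eigendecomposition")
        eig = eigendecompose(kinship)
    d, u = eig
    yt = u.T @ y
    xt = u.T @ x

    def objective(log_lam: float) -> float:
        m2ll, _, sigma2_e, xtwx = _profile_m2ll(log_lam, d, yt, xt)
        if reml:
            w = np.exp(log_lam) * d + 1.0
            sig2 = sigma2_e * n / (n - p_dim)
            m2ll = ((n - p_dim) * np.log(2 * np.pi * sig2) + float(np.log(w).sum())
                    + float(np.linalg.slogdet(xtwx)[1]) + (n - p_dim))
        return m2ll

    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    # the profile in log-lambda can be multimodal: bracket the global
    # minimum on a coarse grid, then refine with a bounded 1-D search
    grid = np.linspace(lo, hi, 61)
    values = [objective(g) for g in grid]
    best = int(np.argmin(values))
    b_lo = grid[max(best - 1, 0)]
    b_hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(objective, bounds=(b_lo, b_hi),
                                   method="bounded",
                                   options={"xatol": 1e-8, "maxiter": 200})
    log_lam = float(res.x)
    if objective(grid[best]) < objective(log_lam):
        log_lam = float(grid[best])
    lam = float(np.exp(log_lam))
    boundary = not (BOUNDARY_BOUNDS[0] <= lam <= BOUNDARY_BOUNDS[1])
    if boundary:
        logger.warning("cohort %s: variance-ratio optimum at boundary "
                       "(lambda=%.3g); fit reported but flagged", cohort, lam)

    m2ll, beta, sigma2_e_ml, xtwx = _profile_m2ll(log_lam, d, yt, xt)
    sigma2_df = sigma2_e_ml * n / (n - p_dim)
    cov = sigma2_df * np.linalg.inv(xtwx)
    se = float(np.sqrt(cov[j, j]))
    zval = beta[j] / se
    pval = 2 * stats.norm.sf(abs(zval))
    var_exp = zval**2 / (zval**2 + (n - p_dim))

    fit = CohortFit(cohort=cohort, measure=measure,
                    covariates=",".join(c for c in names if c != "intercept"),
                    n=n, beta=float(beta[j]), se=max(se, np.finfo(float).tiny),
                    p=float(pval), var_explained=float(var_exp),
                    minus2logl=float(m2ll), boundary=boundary)
    vc = VarianceComponents(sigma2_g=lam * sigma2_e_ml, sigma2_e=sigma2_e_ml)
    return fit, vc


def build_design(
    pheno: pd.DataFrame,
    measures: pd.DataFrame,
    measure: str,
    extra_covariates: tuple[str, ...] = (),
    adjust_for: tuple[str, ...] = (),
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge phenotypes and homozygosity measures into (z, design).

    The design has intercept, the homozygosity `measure` (percent), age,
    sex (male = 1) and any `extra_covariates`/`adjust_for` columns (ordinal
    covariates entered linearly).  Rows with a missing required value are
    dropped.  Assumes a single cohort in `pheno`.
    """
    cohorts = pheno["cohort"].unique()
    if len(cohorts) != 1:
        raise ValueError("build_design expects a single-cohort phenotype table")
    merged = pheno.merge(measures, on="sample", how="inner")
    cols = [measure, "age_years", *extra_covariates, *adjust_for]
    merged = merged.dropna(subset=[c for c in cols if c in merged.columns])
    for c in cols:
        if c not in merged.columns:
            raise ValueError(f"covariate {c!r} not available")
        if c in extra_covariates and merged[c].nunique() < 2:
            raise ValueError(f"ordinal covariate {c!r} has <2 observed levels")
    z = zscore_heights(merged, str(cohorts[0]))
    design = pd.DataFrame({
        "intercept": 1.0,
        measure: merged[measure].to_numpy(dtype=float),
        "age": merged["age_years"].to_numpy(dtype=float),
        "sex_male": (merged["sex"] == "male").to_numpy(dtype=float),
    }, index=merged["sample"].values)
    for c in (*adjust_for, *extra_covariates):
        design[c] = merged[c].to_numpy(dtype=float)
    return z, design
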