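"""Fixed-effect inverse-variance meta-analysis with heterogeneity diagnostics.

Per-cohort effect estimates are pooled with weights w_i = 1/SE_i^2; the pooled
p-value uses a two-sided normal reference and heterogeneity is quantified by
Cochran's Q on k-1 degrees of freedom.  Only the fixed-effect model is
offered: no random-effects estimator, meta-regression or publication-bias
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import CohortFit


@dataclass
class MetaResult:
    beta_pooled: float
    se_pooled: float
    p: float
    q_stat: float
    df: int
    p_het: float
    k_studies: int


def inverse_variance_pool(fits: list[CohortFit]) -> MetaResult:
    """Pool cohort fits by fixed-effect inverse-variance weighting."""
    if not fits:
        raise ValueError("no cohort fits to pool")
    betas = np.array([f.beta for f in fits], dtype=float)
    ses = np.array([f.se for f in fits], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("non-positive standard error")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    q = float((w * (betas - beta) ** 2).sum())
    k = len(fits)
    p_het = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
    return MetaResult(beta_pooled=beta, se_pooled=se, p=p, q_stat=q,
                      df=k - 1, p_het=p_het, k_studies=k)


def leave_out_pool(fits: list[CohortFit], excluded: set[str]) -> MetaResult:
    """Pool the fits whose cohort labels are not in `excluded`."""
    kept = [f for f in fits if f.cohort not in excluded]
    if not kept:
        raise ValueError("all cohorts excluded")
    return inverse_variance_pool(kept)


def cohort_diagnostics(fits: list[CohortFit],
                       cohort_mean_f: dict[str, float]) -> tuple[float, float]:
    """Pearson correlations of cohort mean homozygosity with beta and with SE.

    Used to probe heterogeneity: no correlation with effect size argues
    against the signal being entirely recent parental relatedness, while a
    negative correlation with the SE reflects the power gained from a larger
    homozygosity variance.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 cohorts for diagnostics")
    mean_f = np.array([cohort_mean_f[f.cohort] for f in fits], dtype=float)
    betas = np.array([f.beta for f in fits])
    ses = np.array([f.se for f in fits])
    for v, name in ((mean_f, "mean homozygosity"), (betas, "beta"), (ses, "se")):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}")
    r_beta = float(np.corrcoef(mean_f, betas)[0, 1])
    r_se = float(np.corrcoef(mean_f, ses)[0, 1])
    return r_beta, r_se


def forest_table(fits: list[CohortFit], meta: MetaResult) -> pd.DataFrame:
    """Forest-plot backing table: per-cohort beta, 95% CI and weight share."""
    w = np.array([1.0 / f.se**2 for f in fits])
    rows = [{
        "cohort": f.cohort,
        "n": f.n,
        "beta": f.beta,
        "ci_lo": f.beta - 1.96 * f.se,
        "ci_hi": f.beta + 1.96 * f.se,
        "weight": wi / w.sum(),
    } for f, wi in zip(fits, w)]
    rows.append({
        "cohort": "POOLED",
        "n": sum(f.n for f in fits),
        "beta": meta.beta_pooled,
        "ci_lo": meta.beta_pooled - 1.96 * meta.se_pooled,
        "ci_hi": meta.beta_pooled + 1.96 * meta.se_pooled,
        "weight": 1.0,
    })
    return pd.DataFrame(rows)
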