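"""End-to-end parameter-recovery experiment shared by the acceptance suite.

Six synthetic cohorts (500 samples each, 5000 SNPs) are generated under the
reduced-form inbreeding-depression model, pushed through the full measurement
chain (QC -> LD pruning -> pruned-panel ROH -> F_ROHLD -> genomic kinship ->
polygenic mixed model) and pooled by inverse-variance meta-analysis.  The
true effect is the generator's homozygosity load expressed on the realised
z-score scale: b_ID divided by the sample-size-weighted height SD.

A companion null experiment re-draws heritable phenotypes with zero
homozygosity load on the same cohorts and measures the two-sided rejection
rate of the pooled test at alpha = 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from autozyg.association import (build_design, eigendecompose, fit_polygenic)
from autozyg.genotype_io import MISSING, qc_filter, restrict_to_panel
from autozyg.homozygosity import f_roh, typed_genome_length
from autozyg.ld_prune import prune
from autozyg.meta import inverse_variance_pool
from autozyg.relatedness import genomic_kinship
from autozyg.roh import FROHLD_PRUNED, call_roh
from autozyg.simulate import SimConfig, simulate_consortium


def recovery_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, n_cohorts=6, n_samples=500, n_snps=5000,
                     phenotype_mode="reduced_form")


def prepare_cohorts(seed: int) -> list[dict]:
    """Simulate and measure the six recovery cohorts."""
    cohorts = simulate_consortium(recovery_config(seed))
    prepared = []
    for c in cohorts:
        g, _ = qc_filter(c.genotypes)
        gp = restrict_to_panel(g, set(prune(g)))
        segments = call_roh(gp, FROHLD_PRUNED)
        frohld = f_roh(segments, typed_genome_length(gp.snps), 1000.0,
                       g.samples)
        measures = pd.DataFrame({"sample": g.samples,
                                 "f_rohld": frohld.values})
        eig = eigendecompose(genomic_kinship(g))
        prepared.append({"data": c, "genotypes": g, "measures": measures,
                         "eig": eig})
    return prepared


def pooled_fit(prepared: list[dict]):
    """Mixed-model F_ROHLD fit per cohort, pooled; boundary fits excluded."""
    fits = []
    for p in prepared:
        z, design = build_design(p["data"].phenotypes, p["measures"], "f_rohld")
        try:
            fit, _ = fit_polygenic(z.values, design, term="f_rohld",
                                   cohort=p["data"].name, measure="f_rohld",
                                   eig=p["eig"])
        except ValueError:
            # a cohort with no ROH has a constant measure and cannot be fit
            continue
        fits.append(fit)
    kept = [f for f in fits if not f.boundary]
    return inverse_variance_pool(kept), fits


def true_beta(prepared: list[dict], fits=None) -> float:
    """The pooled estimand implied by the generator load.

    Heights are z-scored within cohort, so cohort i's true coefficient is
    b_ID / sd_i, which varies across cohorts (the homozygosity load itself
    inflates the SD of consanguineous cohorts).  The fixed-effect pooled
    estimator therefore targets the inverse-variance-weighted mean of
    b_ID / sd_i over the pooled cohorts; with `fits` omitted the
    sample-size-weighted mean is returned instead.
    """
    b = prepared[0]["data"].config.b_id_cm_per_pct
    sd = {p["data"].name: p["data"].phenotypes["height_cm"].std(ddof=1)
          for p in prepared}
    if fits:
        w = np.array([1.0 / f.se**2 for f in fits])
        per = np.array([b / sd[f.cohort] for f in fits])
        return float((w * per).sum() / w.sum())
    n = np.array([len(p["data"].phenotypes) for p in prepared])
    sds = np.array([sd[p["data"].name] for p in prepared])
    return b / float((n * sds).sum() / n.sum())


def recovery_experiment(seed: int, n_consortia: int = 3):
    """Pooled recovery over several independent consortium replicates.

    Pooling 3 x 6 cohorts narrows the Monte-Carlo SE of the combined
    estimate, making the 2-SE comparison with the estimand a sharper test
    of unbiasedness than a single consortium draw.  Returns the combined
    meta-result, the combined estimand and the first replicate's prepared
    cohorts (reused by the null-calibration experiment).
    """
    fits_all, truths_all, first_prepared = [], [], None
    for i in range(n_consortia):
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                       % (2**31))
        prepared = prepare_cohorts(sub_seed)
        if first_prepared is None:
            first_prepared = prepared
        _, fits = pooled_fit(prepared)
        sd = {p["data"].name: p["data"].phenotypes["height_cm"].std(ddof=1)
              for p in prepared}
        b = prepared[0]["data"].config.b_id_cm_per_pct
        for f in fits:
            if not f.boundary:
                fits_all.append(f)
                truths_all.append(b / sd[f.cohort])
    meta = inverse_variance_pool(fits_all)
    w = np.array([1.0 / f.se**2 for f in fits_all])
    truth = float((w * np.array(truths_all)).sum() / w.sum())
    return meta, truth, first_prepared


def null_rejection_rate(prepared: list[dict], seed: int,
                        n_reps: int = 400, alpha: float = 0.05,
                        additive_sd: float = 4.0,
                        residual_sd: float = 8.5) -> float:
    """Two-sided rejection rate of the pooled test under b_ID = 0.

    Each replicate redraws a heritable phenotype (polygenic additive part
    from the cohort's own genotypes plus residual noise) with no
    homozygosity load, re-fits every cohort with its precomputed kinship
    eigendecomposition and pools.  Covariates (age, sex) stay fixed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    per_cohort = []
    for p in prepared:
        if p["measures"]["f_rohld"].std() == 0:
            continue  # no ROH, nothing to test in this cohort
        g = p["genotypes"]
        ph = p["data"].phenotypes
        loci = rng.choice(g.n_snps, size=200, replace=False)
        x = np.where(g.calls[:, loci] == MISSING, 0, g.calls[:, loci]).astype(float)
        x -= x.mean(axis=0)
        base = pd.DataFrame({
            "intercept": 1.0,
            "f_rohld": p["measures"]["f_rohld"].values,
            "age": ph["age_years"].values,
            "sex_male": (ph["sex"] == "male").astype(float).values,
        })
        fixed = (0.1 * base["sex_male"].values - 0.005 * base["age"].values)
        per_cohort.append((x, base, fixed, p["eig"]))

    rejections = 0
    logger = logging.getLogger("autozyg")
    previous_level = logger.level
    logger.setLevel(logging.ERROR)  # boundary hits are expected and counted
    try:
        for _ in range(n_reps):
            fits = []
            for x, base, fixed, eig in per_cohort:
                eff = rng.normal(size=x.shape[1])
                additive = x @ eff
                sd = additive.std()
                additive *= additive_sd / sd if sd > 0 else 0.0
                y = fixed + additive + rng.normal(0, residual_sd, size=len(base))
                z = (y - y.mean()) / y.std(ddof=1)
                fit, _ = fit_polygenic(z, base, term="f_rohld", eig=eig)
                fits.append(fit)
            kept = [f for f in fits if not f.boundary] or fits
            rejections += inverse_variance_pool(kept).p < alpha
    finally:
        logger.setLevel(previous_level)
    return rejections / n_reps
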