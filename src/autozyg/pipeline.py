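"""End-to-end orchestration: QC -> ROH (both presets) -> pruning ->
homozygosity statistics -> kinship -> per-cohort fits -> meta-analyses ->
first-cousin-scale conversion -> report bundle.

Every stage is a pure function of its inputs and configuration; a fixed
config yields byte-identical outputs.  Cohorts whose mixed-model variance
ratio lands on the search boundary are treated as convergence failures:
they are flagged, logged and excluded from the affected meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (CohortFit, build_design, eigendecompose, fit_ols,
                          fit_polygenic, subset_under_age)
from .cousins import conversion_report, delta_f_cousin_offspring, weighted_sd
from .genotype_io import (GenotypeMatrix, IntervalSet, Pedigree, qc_filter,
                          read_genotypes, read_intervals, read_pedigree,
                          read_phenotypes, restrict_to_panel)
from .homozygosity import compute_measures
from .ld_prune import PruneParams, prune
from .meta import MetaResult, forest_table, inverse_variance_pool
from .relatedness import genomic_kinship
from .roh import PRESETS, RohParams, call_roh

logger = logging.getLogger("autozyg")

#: supported covariate-set menu: name -> (measure, extra covs, adjust-for, max age)
COVARIATE_SETS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...], float | None]] = {
    "froh_base": ("f_roh", (), (), None),
    "frohld_base": ("f_rohld", (), (), None),
    "fhom_base": ("f_hom", (), (), None),
    "frohld_ea": ("f_rohld", ("ea",), (), None),
    "frohld_os": ("f_rohld", ("os",), (), None),
    "fhom_adj_froh": ("f_hom", (), ("f_roh",), None),
    "frohld_under40": ("f_rohld", (), (), 40.0),
}


@dataclass
class CohortInputs:
    name: str
    genotype_prefix: str
    genotype_format: str = "tsv_matrix"
    phenotype_path: str = ""
    pedigree_path: str | None = None


@dataclass
class RunConfig:
    cohorts: list[CohortInputs]
    outdir: str
    seed: int = 0
    covariate_sets: tuple[str, ...] = tuple(COVARIATE_SETS)
    meta_exclude: tuple[str, ...] = ()
    panel_path: str | None = None
    centromere_path: str | None = None
    prune_params: PruneParams = field(default_factory=PruneParams)
    roh_dense: RohParams = field(default_factory=lambda: PRESETS["froh_dense"])
    roh_pruned: RohParams = field(default_factory=lambda: PRESETS["frohld_pruned"])
    related_kinship_threshold: float = 0.05
    reml: bool = False

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort required")
        unknown = set(self.covariate_sets) - set(COVARIATE_SETS)
        if unknown:
            raise ValueError(f"unsupported covariate sets: {sorted(unknown)}")


@dataclass
class CohortResult:
    name: str
    measures: pd.DataFrame
    fits: dict[str, CohortFit]
    mixed_model: bool
    qc_report: object
    pedigree: Pedigree | None = None
    phenotypes: pd.DataFrame | None = None


def analyze_cohort(
    name: str,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariate_sets: tuple[str, ...] = tuple(COVARIATE_SETS),
    centromeres: IntervalSet | None = None,
    prune_params: PruneParams = PruneParams(),
    roh_dense: RohParams = PRESETS["froh_dense"],
    roh_pruned: RohParams = PRESETS["frohld_pruned"],
    related_kinship_threshold: float = 0.05,
    reml: bool = False,
    pedigree: Pedigree | None = None,
) -> CohortResult:
    """Run the whole per-cohort analysis in memory."""
    g_qc, report = qc_filter(genotypes)
    retained = prune(g_qc, prune_params)
    g_pruned = restrict_to_panel(g_qc, set(retained))
    seg_dense = call_roh(g_qc, roh_dense)
    seg_pruned = call_roh(g_pruned, roh_pruned)
    measures = compute_measures(g_qc, seg_dense, g_pruned, seg_pruned,
                                centromeres,
                                min_len_dense_kb=roh_dense.min_length_kb,
                                min_len_pruned_kb=roh_pruned.min_length_kb)

    kin = genomic_kinship(g_qc)
    off = kin.values[~np.eye(len(kin.samples), dtype=bool)]
    mixed = bool(off.max() > related_kinship_threshold)
    eig = eigendecompose(kin) if mixed else None

    fits: dict[str, CohortFit] = {}
    for cs in covariate_sets:
        measure, extra, adjust, max_age = COVARIATE_SETS[cs]
        pheno = phenotypes
        if max_age is not None:
            try:
                pheno = subset_under_age(pheno, max_age)
            except ValueError:
                logger.warning("cohort %s: no samples under %s; skipping %s",
                               name, max_age, cs)
                continue
        try:
            z, design = build_design(pheno, measures, measure,
                                     extra_covariates=extra, adjust_for=adjust)
            if mixed:
                sub_eig = eig
                if len(z) != len(kin.samples):
                    sub = [kin.samples.index(s) for s in design.index]
                    from .relatedness import KinshipMatrix
                    kin_sub = KinshipMatrix(list(design.index),
                                            kin.values[np.ix_(sub, sub)],
                                            kin.m_snps_used)
                    sub_eig = eigendecompose(kin_sub)
                fit, _ = fit_polygenic(z.values, design, term=measure,
                                       cohort=name, measure=measure,
                                       eig=sub_eig, reml=reml)
            else:
                fit = fit_ols(z.values, design, term=measure,
                              cohort=name, measure=measure)
            fits[cs] = fit
        except ValueError as exc:
            logger.warning("cohort %s: covariate set %s failed: %s", name, cs, exc)
    return CohortResult(name=name, measures=measures, fits=fits,
                        mixed_model=mixed, qc_report=report,
                        pedigree=pedigree, phenotypes=phenotypes)


def pool_covariate_set(results: list[CohortResult], covariate_set: str,
                       exclude: tuple[str, ...] = ()) -> tuple[MetaResult, list[CohortFit]]:
    """Inverse-variance pool one covariate set across cohorts.

    Boundary (non-converged) fits and explicitly excluded cohorts are left
    out, with a log line each.
    """
    fits = []
    for r in results:
        f = r.fits.get(covariate_set)
        if f is None:
            continue
        if r.name in exclude:
            logger.info("meta %s: cohort %s excluded by config", covariate_set, r.name)
            continue
        if f.boundary:
            logger.warning("meta %s: cohort %s excluded (variance ratio at "
                           "boundary, treated as convergence failure)",
                           covariate_set, r.name)
            continue
        fits.append(f)
    return inverse_variance_pool(fits), fits


def fits_frame(results: list[CohortResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for cs, f in r.fits.items():
            rows.append({"cohort": f.cohort, "covariate_set": cs,
                         "measure": f.measure, "covariates": f.covariates,
                         "n": f.n, "beta": f.beta, "se": f.se, "p": f.p,
                         "var_explained": f.var_explained,
                         "minus2logl": f.minus2logl, "boundary": f.boundary,
                         "mixed_model": r.mixed_model})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full multi-cohort analysis from files; write the bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    centromeres = (read_intervals(cfg.centromere_path)
                   if cfg.centromere_path else None)
    panel = None
    if cfg.panel_path:
        panel = set(Path(cfg.panel_path).read_text().split())

    results: list[CohortResult] = []
    for ci in cfg.cohorts:
        g = read_genotypes(ci.genotype_prefix, ci.genotype_format)
        if panel:
            g = restrict_to_panel(g, panel)
        pheno = read_phenotypes(ci.phenotype_path)
        ped = read_pedigree(ci.pedigree_path) if ci.pedigree_path else None
        res = analyze_cohort(
            ci.name, g, pheno, cfg.covariate_sets, centromeres,
            cfg.prune_params, cfg.roh_dense, cfg.roh_pruned,
            cfg.related_kinship_threshold, cfg.reml, pedigree=ped)
        res.measures.assign(cohort=ci.name).to_csv(
            outdir / f"{ci.name}.measures.tsv", sep="\t", index=False)
        res.qc_report.write_tsv(outdir / f"{ci.name}.qc.tsv")
        results.append(res)

    all_fits = fits_frame(results)
    all_fits.to_csv(outdir / "cohort_fits.tsv", sep="\t", index=False)

    metas = {}
    for cs in cfg.covariate_sets:
        try:
            meta, used = pool_covariate_set(results, cs, cfg.meta_exclude)
        except ValueError:
            continue
        metas[cs] = meta
        forest_table(used, meta).to_csv(outdir / f"forest_{cs}.tsv",
                                        sep="\t", index=False)
    pd.DataFrame([{"covariate_set": cs, **vars(m)} for cs, m in metas.items()]
                 ).to_csv(outdir / "meta.tsv", sep="\t", index=False)

    # conversion to the first-cousin-offspring scale
    sd_table = pd.DataFrame([
        {"cohort": r.name, "n": len(r.phenotypes),
         "sd_cm": r.phenotypes["height_cm"].std(ddof=1)} for r in results])
    sd_w = weighted_sd(sd_table)
    conv_frames = []
    for cs, measure in (("frohld_base", "f_rohld"), ("fhom_base", "f_hom"),
                        ("froh_base", "f_roh")):
        if cs not in metas:
            continue
        delta_fs = {}
        for r in results:
            if r.pedigree is None:
                continue
            try:
                delta_fs[r.name] = delta_f_cousin_offspring(
                    r.measures, r.pedigree, measure)
            except ValueError:
                continue
        conv_frames.append(conversion_report(
            metas[cs].beta_pooled, metas[cs].se_pooled, delta_fs, sd_w, measure))
    conversion = (pd.concat(conv_frames, ignore_index=True)
                  if conv_frames else pd.DataFrame())
    conversion.to_csv(outdir / "conversion.tsv", sep="\t", index=False)

    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"autozyg {__version__}\nseed = {cfg.seed}\n")
        fh.write(f"weighted_sd_cm = {sd_w!r}\n")
        for key in ("covariate_sets", "meta_exclude", "related_kinship_threshold",
                    "reml"):
            fh.write(f"{key} = {getattr(cfg, key)!r}\n")
        fh.write(f"prune = {cfg.prune_params}\nroh_dense = {cfg.roh_dense}\n"
                 f"roh_pruned = {cfg.roh_pruned}\n")
    return {"results": results, "metas": metas, "conversion": conversion,
            "weighted_sd_cm": sd_w, "fits": all_fits}
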