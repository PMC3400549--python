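"""Synthetic consanguineous-cohort generator.

Emulates the statistical structure a genome-wide homozygosity analysis
assumes: multi-cohort SNP panels with LD-structured founder haplotypes,
pedigrees containing first- and second-cousin matings, gene-drop transmission
with Poisson recombination on a uniform genetic map, and a height phenotype
with additive effects, rare recessive (directionally dominant) effects, sex
and age effects and cohort-varying mean homozygosity.

Founder haplotypes are mosaics copied from a small ancestral pool: a copied
segment switches to a fresh (uniformly chosen) pool member between adjacent
SNPs with probability 1 - exp(-rho * d_bp), where rho scales with the
recombination rate and a mixing-generations constant.  The pool size controls
LD: two loci a distance d apart are copied from the same pool member with
probability 1/P + (1 - 1/P) * exp(-rho * d), so small pools give long-range
r2 and large pools approach linkage equilibrium.  This keeps the generator
dependency-free and analytically tractable (a coalescent backend could be
slotted in later).

Ground truth: every founder haplotype carries a unique label which is
transmitted through the pedigree, so autozygous (identical-by-descent) tracts
and per-sample autozygosity fractions are known exactly on the SNP grid.

The phenotype is mechanistic by default -- height gains d_k (negative) per
rare recessive locus that is homozygous for the rare allele -- with a
reduced-form alternative that adds b_ID centimetres per percentage point of
true autozygosity.  Defaults target the analysis conditions: overall height
SD near 9.4 cm, sex difference 13 cm, and a directional-dominance load of
about -0.61 cm per 1% autozygosity (-0.065 z-score units at SD 9.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, GenotypeMatrix, Pedigree, write_genotypes,
                          write_pedigree, write_phenotypes)

__all__ = [
    "SimConfig", "FounderPool", "simulate_founders", "simulate_cohort",
    "simulate_consortium", "normalize_alt_alleles", "CohortData",
]


@dataclass(frozen=True)
class SimConfig:
    """Consortium-level simulation settings (desk-scale defaults).

    Cohort-to-cohort spread in homozygosity comes from the mating-mix and
    founder-pool schedules: cohort i of k interpolates linearly between the
    panmictic end (no cousin matings, large pool) and the isolate end
    (``max_first_cousin``/``max_second_cousin`` matings, ``pool_min``
    founder haplotypes).
    """

    seed: int
    n_cohorts: int = 21
    n_samples: int = 500              # per cohort
    n_snps: int = 5000
    n_chromosomes: int = 4
    chromosome_length_bp: int = 12_000_000
    recomb_rate_cm_per_mb: float = 1.0
    pool_mixing_generations: float = 300.0
    pool_min: int = 40
    pool_max: int = 400
    maf_floor: float = 0.01
    max_first_cousin: float = 0.30    # mating-mix fractions at the isolate end
    max_second_cousin: float = 0.20
    fraction_sib_pairs: float = 0.2   # families contributing two full sibs
    missing_rate: float = 0.002
    genotype_error_rate: float = 0.001
    # phenotype model
    phenotype_mode: str = "mechanistic"   # or "reduced_form"
    n_recessive_loci: int = 500
    recessive_effect_cm: float = -2.5     # per rare-homozygote, directional
    recessive_freq_range: tuple[float, float] = (0.02, 0.08)
    n_additive_loci: int = 200
    additive_sd_cm: float = 2.5           # SD of the total additive value
    b_id_cm_per_pct: float = -0.61        # reduced-form load per 1% autozygosity
    base_height_cm: float = 162.0
    sex_effect_cm: float = 13.0
    age_effect_cm_per_year: float = -0.05
    age_range_years: tuple[float, float] = (20.0, 75.0)
    residual_sd_cm: float = 5.5
    ses_levels: int = 4
    ses_autozygosity_corr: float = 0.0    # confounding dial for EA
    ses_effect_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        mix = self.max_first_cousin + self.max_second_cousin
        if mix > 1.0:
            raise ValueError("mating-mix fractions exceed 1")
        for name in ("n_cohorts", "n_samples", "n_snps", "n_chromosomes",
                     "chromosome_length_bp", "pool_min", "pool_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")


def chrom22_preset(seed: int, **overrides) -> SimConfig:
    """Higher-fidelity 22-chromosome configuration."""
    base = dict(n_chromosomes=22, chromosome_length_bp=130_000_000,
                n_snps=300_000, n_samples=1700)
    base.update(overrides)
    return SimConfig(seed=seed, **base)


# ---------------------------------------------------------------------------
# founders


@dataclass
class FounderPool:
    """Ancestral haplotype pool plus the mosaic-copying switch process."""

    snps: pd.DataFrame            # id, chrom, pos_bp (alleles assigned later)
    pool: np.ndarray              # (P, m) 0/1 haplotypes
    switch_prob: np.ndarray       # (m,) prob of re-picking before each SNP

    @property
    def pool_size(self) -> int:
        return self.pool.shape[0]

    def same_member_prob(self, d_bp: float, rho: float) -> float:
        """P(two loci d_bp apart are copied from the same pool member)."""
        p = self.pool_size
        return 1.0 / p + (1.0 - 1.0 / p) * np.exp(-rho * d_bp)

    def draw_haplotype(self, rng: np.random.Generator) -> np.ndarray:
        m = self.pool.shape[1]
        switch = rng.random(m) < self.switch_prob
        switch[0] = True
        idx = np.zeros(m, dtype=np.int64)
        idx[switch] = rng.integers(0, self.pool_size, size=int(switch.sum()))
        # forward-fill the pool-member choice between switch points
        fill = np.maximum.accumulate(np.where(switch, np.arange(m), 0))
        return self.pool[idx[fill], np.arange(m)]


def _snp_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    for c, count in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(
            np.arange(1, cfg.chromosome_length_bp, dtype=np.int64),
            size=count, replace=False))
        rows.append(pd.DataFrame({
            "id": [f"snp{c}_{i}" for i in range(count)],
            "chrom": c, "pos_bp": pos,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_founders(cfg: SimConfig, pool_size: int,
                      rng: np.random.Generator,
                      snps: pd.DataFrame | None = None) -> FounderPool:
    """Build the ancestral pool and switch process for one cohort."""
    if pool_size < 2:
        raise ValueError("founder pool needs at least 2 haplotypes")
    if snps is None:
        snps = _snp_map(cfg, rng)
    m = len(snps)
    # MAF roughly uniform (array-like spectrum), random allele orientation
    maf = rng.uniform(cfg.maf_floor, 0.5, size=m)
    freqs = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)
    pool = (rng.random((pool_size, m)) < freqs).astype(np.int8)
    # guarantee the pool is polymorphic at every SNP
    mono = np.flatnonzero(pool.sum(axis=0) % pool_size == 0)
    for j in mono:
        i = rng.integers(0, pool_size)
        pool[i, j] = 1 - pool[i, j]

    rho = cfg.recomb_rate_cm_per_mb * 1e-8 * cfg.pool_mixing_generations
    pos = snps["pos_bp"].to_numpy(dtype=np.int64)
    chrom = snps["chrom"].to_numpy()
    gaps = np.diff(pos, prepend=pos[0]).astype(float)
    new_chrom = np.diff(chrom, prepend=chrom[0]) != 0
    switch = 1.0 - np.exp(-rho * gaps)
    switch[new_chrom] = 1.0
    switch[0] = 1.0
    return FounderPool(snps=snps.reset_index(drop=True), pool=pool,
                       switch_prob=switch)


# ---------------------------------------------------------------------------
# pedigrees and gene drop


def _cousin_pedigree(fam: str, degree: int, sib: bool) -> list[tuple]:
    """Rows (individual, sire, dam, sex) for a first/second-cousin mating.

    degree 1: the proband's parents are first cousins (F = 1/16);
    degree 2: second cousins (F = 1/64).
    """
    rows = [(f"{fam}_g1", "0", "0", "male"), (f"{fam}_g2", "0", "0", "female"),
            (f"{fam}_s1", f"{fam}_g1", f"{fam}_g2", "male"),
            (f"{fam}_s2", f"{fam}_g1", f"{fam}_g2", "female"),
            (f"{fam}_w1", "0", "0", "female"), (f"{fam}_w2", "0", "0", "male")]
    left, right = (f"{fam}_s1", f"{fam}_w1"), (f"{fam}_w2", f"{fam}_s2")
    for g in range(degree):
        last = g == degree - 1
        rows += [(f"{fam}_l{g}", left[0], left[1], "male"),
                 (f"{fam}_r{g}", right[0], right[1], "female")]
        if not last:
            rows += [(f"{fam}_lw{g}", "0", "0", "female"),
                     (f"{fam}_rw{g}", "0", "0", "male")]
            left = (f"{fam}_l{g}", f"{fam}_lw{g}")
            right = (f"{fam}_rw{g}", f"{fam}_r{g}")
    probands = [(f"{fam}_p0", f"{fam}_l{degree-1}", f"{fam}_r{degree-1}", "male")]
    if sib:
        probands.append((f"{fam}_p1", f"{fam}_l{degree-1}",
                         f"{fam}_r{degree-1}", "female"))
    return rows + probands


def _outbred_pedigree(fam: str, sib: bool) -> list[tuple]:
    rows = [(f"{fam}_f", "0", "0", "male"), (f"{fam}_m", "0", "0", "female"),
            (f"{fam}_p0", f"{fam}_f", f"{fam}_m", "male")]
    if sib:
        rows.append((f"{fam}_p1", f"{fam}_f", f"{fam}_m", "female"))
    return rows


def _meiose(hap_a: np.ndarray, hap_b: np.ndarray, pos_by_chrom: list[np.ndarray],
            offsets: list[int], morgans_per_bp: float,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete: recombine two label arrays with Poisson crossovers."""
    out = np.empty_like(hap_a)
    for pos, off in zip(pos_by_chrom, offsets):
        length = int(pos[-1]) if len(pos) else 0
        n_xo = rng.poisson(length * morgans_per_bp)
        cuts = np.sort(rng.integers(1, length + 1, size=n_xo)) if n_xo else np.array([])
        phase = int(rng.integers(0, 2))
        cross = np.searchsorted(cuts, pos, side="left")
        use_a = (cross + phase) % 2 == 0
        sl = slice(off, off + len(pos))
        out[sl] = np.where(use_a, hap_a[sl], hap_b[sl])
    return out


@dataclass
class CohortData:
    name: str
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    pedigree: Pedigree
    truth: pd.DataFrame          # sample, true_autozygosity_pct
    tracts: pd.DataFrame         # sample, chrom, start_bp, end_bp, length_kb
    config: "SimConfig" = None


def normalize_alt_alleles(calls: np.ndarray, snps: pd.DataFrame
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosages so the counted allele is the rarer one (ties: label 'A').

    Matches the read-time convention of the IO layer, so written files
    round-trip bit-for-bit.
    """
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    alt_count = np.where(obs, calls, 0).sum(axis=0)
    freq = np.where(n_obs > 0, alt_count / (2 * n_obs), 0.0)
    flip = freq > 0.5
    out = calls.copy()
    out[:, flip] = np.where(obs[:, flip], 2 - calls[:, flip], MISSING)
    a1 = np.where(flip, "B", "A")
    a2 = np.where(flip, "A", "B")
    return out, snps.assign(a1=a1, a2=a2)


def simulate_cohort(cfg: SimConfig, name: str, pool_size: int,
                    frac_first_cousin: float, frac_second_cousin: float,
                    rng: np.random.Generator,
                    snps: pd.DataFrame | None = None) -> CohortData:
    """Gene-drop one cohort and attach phenotypes.

    The mating mix assigns each family a type (first-cousin, second-cousin or
    unrelated mating); a `fraction_sib_pairs` share of families contribute two
    full sibs, the rest one offspring.
    """
    founders = simulate_founders(cfg, pool_size, rng, snps=snps)
    snps = founders.snps
    pos_all = snps["pos_bp"].to_numpy(dtype=np.int64)
    chrom_all = snps["chrom"].to_numpy()
    chroms = list(pd.unique(chrom_all))
    pos_by_chrom, offsets = [], []
    off = 0
    for c in chroms:
        idx = np.flatnonzero(chrom_all == c)
        pos_by_chrom.append(pos_all[idx])
        offsets.append(off)
        off += len(idx)
    morgans_per_bp = cfg.recomb_rate_cm_per_mb * 1e-8
    m = len(snps)

    ped_rows: list[tuple] = []
    sample_names: list[str] = []
    geno_rows: list[np.ndarray] = []
    auto_pct: list[float] = []
    tract_rows: list[tuple] = []

    n_needed = cfg.n_samples
    fam_i = 0
    while len(sample_names) < n_needed:
        u = rng.random()
        sib = rng.random() < cfg.fraction_sib_pairs and len(sample_names) + 2 <= n_needed
        fam = f"{name}_fam{fam_i}"
        fam_i += 1
        if u < frac_first_cousin:
            rows = _cousin_pedigree(fam, 1, sib)
        elif u < frac_first_cousin + frac_second_cousin:
            rows = _cousin_pedigree(fam, 2, sib)
        else:
            rows = _outbred_pedigree(fam, sib)
        # probands get a random sex (templates only fix parental sexes)
        rows = [(iid, s, d,
                 ("male" if rng.random() < 0.5 else "female")
                 if iid.split("_")[-1].startswith("p") else sex)
                for iid, s, d, sex in rows]
        ped_rows += rows

        # founder haplotypes: labels unique within the family
        parents = {r[0]: (r[1], r[2]) for r in rows}
        hap_label: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        hap_allele: list[np.ndarray] = []
        order = [r[0] for r in rows]  # parents listed before offspring
        for iid in order:
            sire, dam = parents[iid]
            if sire == "0":
                labels = []
                for _ in range(2):
                    hap_allele.append(founders.draw_haplotype(rng))
                    labels.append(np.full(m, len(hap_allele) - 1, dtype=np.int32))
                hap_label[iid] = (labels[0], labels[1])
            else:
                hap_label[iid] = (
                    _meiose(*hap_label[sire], pos_by_chrom, offsets,
                            morgans_per_bp, rng),
                    _meiose(*hap_label[dam], pos_by_chrom, offsets,
                            morgans_per_bp, rng),
                )
        alleles = np.stack(hap_allele)  # (n_haps, m)
        probands = [r[0] for r in rows if r[0].split("_")[-1].startswith("p")]
        for iid in probands:
            pat, mat = hap_label[iid]
            dosage = (alleles[pat, np.arange(m)]
                      + alleles[mat, np.arange(m)]).astype(np.int8)
            ibd = pat == mat
            auto_pct.append(100.0 * ibd.mean())
            # record autozygous tracts on the SNP grid
            for c, p_chrom, o in zip(chroms, pos_by_chrom, offsets):
                run = np.flatnonzero(np.diff(np.concatenate(
                    [[0], ibd[o:o + len(p_chrom)].astype(np.int8), [0]])))
                for a, b in zip(run[::2], run[1::2] - 1):
                    tract_rows.append((iid, int(c), int(p_chrom[a]),
                                       int(p_chrom[b]),
                                       (p_chrom[b] - p_chrom[a] + 1) / 1000.0))
            sample_names.append(iid)
            geno_rows.append(dosage)

    clean, snps_out = normalize_alt_alleles(np.stack(geno_rows), snps)
    sex_by_iid = {r[0]: r[3] for r in ped_rows}
    sex = np.array([sex_by_iid[iid] for iid in sample_names])
    clean_g = GenotypeMatrix(sample_names, snps_out, clean)
    # genotyping noise is applied to the emitted calls only; the phenotype
    # below is driven by the true genotypes
    err = rng.random(clean.shape) < cfg.genotype_error_rate
    shift = rng.integers(1, 3, size=clean.shape)
    calls = np.where(err, (clean + shift) % 3, clean).astype(np.int8)
    calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    genotypes = GenotypeMatrix(sample_names, snps_out, calls)
    pedigree = Pedigree(pd.DataFrame(ped_rows,
                                     columns=["individual", "sire", "dam", "sex"]))
    truth = pd.DataFrame({"sample": sample_names,
                          "true_autozygosity_pct": auto_pct})
    tracts = pd.DataFrame(
        tract_rows, columns=["sample", "chrom", "start_bp", "end_bp", "length_kb"])
    phenotypes = _simulate_phenotype(cfg, clean_g, truth, sex, name, rng)
    return CohortData(name=name, genotypes=genotypes, phenotypes=phenotypes,
                      pedigree=pedigree, truth=truth, tracts=tracts, config=cfg)


def _simulate_phenotype(cfg: SimConfig, g: GenotypeMatrix, truth: pd.DataFrame,
                        sex: np.ndarray, cohort: str,
                        rng: np.random.Generator) -> pd.DataFrame:
    n, m = g.calls.shape
    freq = g.alt_allele_frequency()
    age = rng.uniform(*cfg.age_range_years, size=n)
    male = (np.asarray(sex) == "male").astype(float)
    height = (cfg.base_height_cm + cfg.sex_effect_cm * male
              + cfg.age_effect_cm_per_year * (age - 50.0))

    if cfg.phenotype_mode == "reduced_form":
        height = height + cfg.b_id_cm_per_pct * truth["true_autozygosity_pct"].values
    elif cfg.phenotype_mode == "mechanistic":
        lo, hi = cfg.recessive_freq_range
        eligible = np.flatnonzero((freq >= lo) & (freq <= hi))
        k = min(cfg.n_recessive_loci, len(eligible))
        if k == 0:
            raise ValueError("no SNPs in the recessive allele-frequency range")
        loci = rng.choice(eligible, size=k, replace=False)
        rare_hom = (g.calls[:, loci] == 2).astype(float)
        height = height + cfg.recessive_effect_cm * rare_hom.sum(axis=1)
    else:
        raise ValueError(f"unknown phenotype_mode {cfg.phenotype_mode!r}")

    if cfg.n_additive_loci > 0 and cfg.additive_sd_cm > 0:
        add_loci = rng.choice(m, size=min(cfg.n_additive_loci, m), replace=False)
        eff = rng.normal(size=len(add_loci))
        x = np.where(g.calls[:, add_loci] == MISSING, 0, g.calls[:, add_loci])
        raw = (x - 2 * freq[add_loci]) @ eff
        sd = raw.std()
        if sd > 0:
            height = height + raw * (cfg.additive_sd_cm / sd)

    out = pd.DataFrame({
        "sample": g.samples,
        "height_cm": height + rng.normal(0, cfg.residual_sd_cm, size=n),
        "age_years": age,
        "sex": sex,
        "cohort": cohort,
    })
    # ordinal SES measures, optionally correlated with autozygosity
    zc = truth["true_autozygosity_pct"].values
    zc = (zc - zc.mean()) / (zc.std() if zc.std() > 0 else 1.0)
    rho = cfg.ses_autozygosity_corr
    latent = -rho * zc + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(size=n)
    qs = np.quantile(latent, np.linspace(0, 1, cfg.ses_levels + 1)[1:-1])
    ea = np.searchsorted(qs, latent).astype(int)
    out["ea"] = ea
    out["os"] = np.searchsorted(qs, rng.permutation(latent)).astype(int)
    if cfg.ses_effect_cm:
        out["height_cm"] = out["height_cm"] + cfg.ses_effect_cm * (ea - ea.mean())
    return out


def consortium_schedule(cfg: SimConfig) -> pd.DataFrame:
    """Per-cohort mating mix and pool size: panmictic -> isolate gradient."""
    k = cfg.n_cohorts
    t = np.linspace(0.0, 1.0, k) if k > 1 else np.array([1.0])
    return pd.DataFrame({
        "cohort": [f"cohort{i:02d}" for i in range(k)],
        "frac_first_cousin": t * cfg.max_first_cousin,
        "frac_second_cousin": t * cfg.max_second_cousin,
        "pool_size": np.round(cfg.pool_max - t * (cfg.pool_max - cfg.pool_min)
                              ).astype(int),
    })


def simulate_consortium(cfg: SimConfig, outdir: str | Path | None = None,
                        fmt: str = "tsv_matrix") -> list[CohortData]:
    """Simulate every cohort in the schedule; optionally write standard files.

    Each cohort draws from an independent child seed of ``cfg.seed``; with a
    fixed config the output is fully reproducible.
    """
    schedule = consortium_schedule(cfg)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_cohorts)
    cohorts = []
    for row, ss in zip(schedule.itertuples(), seeds):
        rng = np.random.default_rng(ss)
        cohorts.append(simulate_cohort(
            cfg, row.cohort, int(row.pool_size),
            float(row.frac_first_cousin), float(row.frac_second_cousin), rng))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        schedule.to_csv(outdir / "schedule.tsv", sep="\t", index=False)
        with open(outdir / "sim_config.txt", "w") as fh:
            for key, val in vars(cfg).items():
                fh.write(f"{key} = {val}\n")
        for c in cohorts:
            write_genotypes(c.genotypes, outdir / c.name, fmt)
            write_phenotypes(c.phenotypes, outdir / f"{c.name}.pheno.tsv")
            write_pedigree(c.pedigree, outdir / f"{c.name}.ped.tsv")
            c.truth.to_csv(outdir / f"{c.name}.truth.tsv", sep="\t", index=False)
            c.tracts.to_csv(outdir / f"{c.name}.tracts.tsv", sep="\t", index=False)
    return cohorts
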