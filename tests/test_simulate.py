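import numpy as np
import pytest

from autozyg.simulate import (SimConfig, consortium_schedule, simulate_cohort,
                              simulate_consortium, simulate_founders)


def small_cfg(**kw):
    base = dict(seed=21, n_cohorts=2, n_samples=60, n_snps=600,
                n_chromosomes=2)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            SimConfig(seed=None)

    def test_infeasible_maf_floor(self):
        with pytest.raises(ValueError, match="maf_floor"):
            small_cfg(maf_floor=0.6)

    def test_mating_mix_bounded(self):
        with pytest.raises(ValueError, match="mix"):
            small_cfg(max_first_cousin=0.7, max_second_cousin=0.5)


class TestFounderLd:
    def adjacent_r2(self, cfg, pool_size, n_haps, seed):
        rng = np.random.default_rng(seed)
        pool = simulate_founders(cfg, pool_size, rng)
        haps = np.stack([pool.draw_haplotype(rng) for _ in range(n_haps)])
        r2 = []
        chrom = pool.snps["chrom"].values
        for j in range(haps.shape[1] - 1):
            if chrom[j] != chrom[j + 1]:
                continue
            a, b = haps[:, j].astype(float), haps[:, j + 1].astype(float)
            if a.std() == 0 or b.std() == 0:
                continue
            r2.append(np.corrcoef(a, b)[0, 1] ** 2)
        return float(np.mean(r2))

    def test_tiny_pool_forces_high_adjacent_r2(self):
        cfg = small_cfg(n_snps=200, n_chromosomes=1,
                        chromosome_length_bp=2_000_000)
        assert self.adjacent_r2(cfg, 2, 400, seed=1) > 0.8

    def test_large_pool_approaches_equilibrium(self):
        cfg = small_cfg(n_snps=200, n_chromosomes=1)
        assert self.adjacent_r2(cfg, 500, 400, seed=2) < 0.05

    def test_r2_decay_matches_copying_process_form(self):
        """Mean r2 at distance d tracks c(d)^2 x pool r2, where c(d) is the
        same-pool-member probability of the copying process."""
        cfg = small_cfg(n_snps=300, n_chromosomes=1,
                        chromosome_length_bp=60_000_000,
                        pool_mixing_generations=50.0)
        rng = np.random.default_rng(7)
        pool = simulate_founders(cfg, 10, rng)
        haps = np.stack([pool.draw_haplotype(rng) for _ in range(4000)])
        pos = pool.snps["pos_bp"].values
        rho = cfg.recomb_rate_cm_per_mb * 1e-8 * cfg.pool_mixing_generations
        pred, obs = [], []
        pairs = [(i, i + k) for k in (1, 3, 10, 30) for i in range(0, 260, 13)]
        for i, j in pairs:
            pr = np.corrcoef(pool.pool[:, i].astype(float),
                             pool.pool[:, j].astype(float))[0, 1] ** 2
            c = pool.same_member_prob(pos[j] - pos[i], rho)
            pred.append(c * c * pr)
            obs.append(np.corrcoef(haps[:, i].astype(float),
                                   haps[:, j].astype(float))[0, 1] ** 2)
        pred, obs = np.array(pred), np.array(obs)
        assert np.corrcoef(pred, obs)[0, 1] > 0.9
        assert np.mean(obs - pred) == pytest.approx(0.0, abs=0.02)


class TestGeneDrop:
    def test_all_unrelated_mix_has_no_autozygosity(self):
        rng = np.random.default_rng(5)
        c = simulate_cohort(small_cfg(), "u", 100, 0.0, 0.0, rng)
        assert c.tracts.empty
        assert (c.truth["true_autozygosity_pct"] == 0).all()

    def test_cousin_offspring_autozygosity_near_theory(self):
        rng = np.random.default_rng(6)
        cfg = small_cfg(n_samples=200, n_snps=2000, n_chromosomes=4,
                        fraction_sib_pairs=0.0)
        c = simulate_cohort(cfg, "fc", 300, 1.0, 0.0, rng)
        vals = c.truth["true_autozygosity_pct"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert vals.mean() == pytest.approx(6.25, abs=3 * se)

    def test_tract_length_scale_matches_exponential_oracle(self):
        """Cousin-offspring tract lengths have the scale predicted by the
        renewal approximation (mean ~ 1/6 Morgan, censored at the chromosome
        ends); re-entry makes the approximation coarse, so only scale
        agreement is asserted."""
        cfg = small_cfg(n_samples=150, n_snps=3000, n_chromosomes=1,
                        chromosome_length_bp=100_000_000)
        rng = np.random.default_rng(3)
        c = simulate_cohort(cfg, "t", 300, 1.0, 0.0, rng)
        observed = c.tracts["length_kb"].mean() / 1000.0

        r = np.random.default_rng(1)
        mean_mb, length_mb = 100.0 / 6.0, 100.0
        lens = []
        for _ in range(5000):
            pts, x = [0.0], r.exponential(mean_mb)
            while x < length_mb:
                pts.append(x)
                x += r.exponential(mean_mb)
            pts.append(length_mb)
            segs = np.diff(pts)
            lens.extend(segs[r.random(len(segs)) < 1 / 16])
        oracle = float(np.mean(lens))
        assert 0.5 * oracle < observed < 1.5 * oracle


class TestPhenotype:
    def test_null_model_recovers_zero_slope(self):
        cfg = small_cfg(n_samples=300, n_snps=2000,
                        recessive_effect_cm=0.0, n_recessive_loci=1)
        rng = np.random.default_rng(8)
        c = simulate_cohort(cfg, "null", 200, 0.3, 0.1, rng)
        import statsmodels.api as sm
        df = c.phenotypes.merge(c.truth, on="sample")
        x = sm.add_constant(df[["true_autozygosity_pct"]].assign(
            male=(df.sex == "male").astype(float), age=df.age_years))
        fit = sm.OLS(df.height_cm / df.height_cm.std(), x).fit()
        assert abs(fit.params["true_autozygosity_pct"]) < 2 * fit.bse[
            "true_autozygosity_pct"]

    def test_panmictic_cohort_sd_near_target(self):
        """Height SD lands within 5% of the 9.4 cm design target in a
        low-consanguinity cohort (isolates legitimately exceed it)."""
        cfg = small_cfg(n_samples=400, n_snps=4000)
        rng = np.random.default_rng(9)
        c = simulate_cohort(cfg, "pan", 400, 0.0, 0.0, rng)
        assert c.phenotypes["height_cm"].std() == pytest.approx(9.4, rel=0.05)

    def test_confounded_ses_biases_unadjusted_fit_only(self):
        """Built-in EA-autozygosity confounding shifts the crude estimate;
        adjusting for EA restores the truth (reduced-form mode)."""
        cfg = small_cfg(n_samples=500, n_snps=1500,
                        phenotype_mode="reduced_form",
                        ses_autozygosity_corr=0.6, ses_effect_cm=4.0,
                        fraction_sib_pairs=0.0)
        rng = np.random.default_rng(10)
        c = simulate_cohort(cfg, "conf", 200, 0.4, 0.0, rng)
        import statsmodels.api as sm
        df = c.phenotypes.merge(c.truth, on="sample")
        sd = df.height_cm.std()
        truth = cfg.b_id_cm_per_pct / sd
        base = df[["true_autozygosity_pct"]].assign(
            male=(df.sex == "male").astype(float), age=df.age_years)
        crude = sm.OLS(df.height_cm / sd, sm.add_constant(base)).fit()
        adj = sm.OLS(df.height_cm / sd,
                     sm.add_constant(base.assign(ea=df.ea))).fit()
        name = "true_autozygosity_pct"
        assert abs(adj.params[name] - truth) < 2.5 * adj.bse[name]
        assert abs(crude.params[name] - truth) > abs(adj.params[name] - truth)


class TestConsortium:
    def test_schedule_spans_isolate_gradient(self):
        sched = consortium_schedule(small_cfg(n_cohorts=5))
        assert sched["frac_first_cousin"].is_monotonic_increasing
        assert sched["pool_size"].is_monotonic_decreasing

    def test_mean_homozygosity_follows_schedule(self):
        from scipy import stats
        cfg = small_cfg(n_cohorts=3, n_samples=300, n_snps=1200)
        cohorts = simulate_consortium(cfg)
        means = [c.truth["true_autozygosity_pct"].mean() for c in cohorts]
        rho = stats.spearmanr(np.arange(3), means).statistic
        assert rho == 1.0

    def test_isolate_has_higher_frohld_than_panmictic(self):
        from autozyg.pipeline import analyze_cohort
        cfg = small_cfg(n_cohorts=4, n_samples=150, n_snps=2500)
        cohorts = simulate_consortium(cfg)
        vals = {}
        for c in (cohorts[0], cohorts[-1]):
            res = analyze_cohort(c.name, c.genotypes, c.phenotypes, ())
            vals[c.name] = res.measures["f_rohld"].mean()
        assert vals[cohorts[-1].name] > 10 * max(vals[cohorts[0].name], 1e-6) \
            or vals[cohorts[0].name] < 0.05

    def test_identical_seed_byte_identical_outputs(self, tmp_path):
        cfg = small_cfg(n_samples=40, n_snps=400)
        simulate_consortium(cfg, tmp_path / "a")
        simulate_consortium(cfg, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files_a == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files_a:
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name
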