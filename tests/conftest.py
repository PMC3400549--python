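import numpy as np
import pandas as pd
import pytest

from autozyg.genotype_io import GenotypeMatrix
from autozyg.simulate import SimConfig, normalize_alt_alleles, simulate_cohort


def make_matrix(calls, positions=None, chrom=1, samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw call array (no allele bookkeeping)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 10_000
    snps = pd.DataFrame({
        "id": [f"s{j}" for j in range(m)],
        "chrom": chrom,
        "pos_bp": np.asarray(positions, dtype=np.int64),
        "a1": "A",
        "a2": "B",
    })
    if samples is None:
        samples = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(samples, snps, calls)


def random_matrix(rng, n=20, m=50, maf_range=(0.1, 0.5),
                  missing_rate=0.0) -> GenotypeMatrix:
    """Random HWE genotypes with alt = rarer allele (round-trip safe)."""
    p = rng.uniform(*maf_range, size=m)
    calls = (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p)
    if missing_rate:
        calls[rng.random((n, m)) < missing_rate] = -1
    g = make_matrix(calls)
    calls2, snps2 = normalize_alt_alleles(g.calls, g.snps.drop(columns=["a1", "a2"]))
    return GenotypeMatrix(g.samples, snps2, calls2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def demo_config():
    """Desk-scale cohort settings shared across the suite."""
    return SimConfig(seed=11, n_samples=300)


@pytest.fixture(scope="session")
def demo_cohort(demo_config):
    """One consanguineous cohort with ground truth (isolate-like mix)."""
    rng = np.random.default_rng(np.random.SeedSequence(demo_config.seed))
    return simulate_cohort(demo_config, "demo", pool_size=120,
                           frac_first_cousin=0.3, frac_second_cousin=0.1,
                           rng=rng)


@pytest.fixture(scope="session")
def demo_analysis(demo_cohort):
    """Full per-cohort analysis of the demo cohort (QC -> fits)."""
    from autozyg.pipeline import analyze_cohort
    return analyze_cohort("demo", demo_cohort.genotypes, demo_cohort.phenotypes,
                          ("froh_base", "frohld_base", "fhom_base",
                           "fhom_adj_froh"),
                          pedigree=demo_cohort.pedigree)
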