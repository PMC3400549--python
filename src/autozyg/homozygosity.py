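"""Per-individual genome-wide homozygosity measures.

Three complementary statistics of the inbreeding-coefficient family:

* ``f_roh`` -- percentage of the typed autosomal genome in ROH at least
  1.5 Mb long, called on the full QC'd panel.
* ``f_rohld`` -- the same quantity with ROH of at least 1.0 Mb called on an
  LD-pruned panel, so that detected runs reflect recent parental relatedness
  rather than ancient haplotype sharing.
* ``f_hom`` -- percentage of an individual's non-missing genotypes that are
  homozygous, a single-point measure also sensitive to ancient population
  history.

The typed autosomal genome is the summed first-to-last-SNP span of each
autosome, minus any overlap with supplied centromere intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, IntervalSet

logger = logging.getLogger("autozyg")


def typed_genome_length(snps: pd.DataFrame,
                        centromeres: IntervalSet | None = None) -> float:
    """Typed autosomal genome length in kb.

    Sum over chromosomes of (last SNP position - first SNP position), minus
    the overlap of that span with centromere intervals.  A represented
    chromosome with no centromere record gets a warning and no subtraction.
    """
    total_bp = 0
    known_chroms = {c for c, _, _ in centromeres.intervals} if centromeres else set()
    for chrom, grp in snps.groupby("chrom"):
        first, last = int(grp["pos_bp"].min()), int(grp["pos_bp"].max())
        span = last - first
        if centromeres is not None:
            if int(chrom) in known_chroms:
                span -= centromeres.overlap_bp(int(chrom), first, last)
            else:
                logger.warning("no centromere record for chromosome %s; "
                               "span not adjusted", chrom)
        total_bp += span
    return total_bp / 1000.0


def f_roh(segments: pd.DataFrame, typed_kb: float, min_len_kb: float,
          samples: list[str] | None = None) -> pd.Series:
    """Percent of the typed genome in ROH of at least ``min_len_kb``.

    `segments` is a call_roh table (possibly for many samples).  `samples`
    fixes the output index (samples without segments get 0.0).
    """
    if typed_kb <= 0:
        raise ValueError("typed genome length must be positive")
    kept = segments.loc[segments["length_kb"] >= min_len_kb]
    sums = kept.groupby("sample")["length_kb"].sum()
    if samples is not None:
        sums = sums.reindex(samples, fill_value=0.0)
    return 100.0 * sums / typed_kb


def f_hom(g: GenotypeMatrix, sample: str | None = None) -> pd.Series | float:
    """Observed homozygosity: percent of non-missing calls that are homozygous."""
    obs = g.calls != MISSING
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("sample with all calls missing")
    hom = (g.calls == 0) | (g.calls == 2)
    values = pd.Series(100.0 * hom.sum(axis=1) / n_obs, index=g.samples)
    if sample is not None:
        return float(values[sample])
    return values


def compute_measures(
    dense: GenotypeMatrix,
    dense_segments: pd.DataFrame,
    pruned: GenotypeMatrix,
    pruned_segments: pd.DataFrame,
    centromeres: IntervalSet | None = None,
    min_len_dense_kb: float = 1500.0,
    min_len_pruned_kb: float = 1000.0,
) -> pd.DataFrame:
    """Assemble the per-sample measures table.

    F_hom is computed on the QC'd dense panel (its definition covers all
    genotyped SNPs, not the pruned subset); each ROH measure uses its own
    panel's typed-genome length.
    """
    typed_dense = typed_genome_length(dense.snps, centromeres)
    typed_pruned = typed_genome_length(pruned.snps, centromeres)
    out = pd.DataFrame({
        "sample": dense.samples,
        "f_roh": f_roh(dense_segments, typed_dense, min_len_dense_kb,
                       dense.samples).values,
        "f_rohld": f_roh(pruned_segments, typed_pruned, min_len_pruned_kb,
                         dense.samples).values,
        "f_hom": f_hom(dense).values,
        "typed_genome_kb": typed_dense,
    })
    return out
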