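"""Allele-frequency-weighted genomic kinship.

Pairwise relatedness is estimated from identity-by-state sharing weighted by
allele frequency, so that sharing a rare allele counts for more than sharing
a common one.  With half-dosages x in {0, 0.5, 1} and alternate-allele
frequency p estimated from non-missing calls:

* off-diagonal  K_ij = mean over SNPs non-missing in both individuals of
  (x_i - p)(x_j - p) / (p(1 - p));
* diagonal      K_ii = 0.5 * (1 + f_i), where f_i is the individual's excess
  homozygosity: observed homozygous fraction minus the allele-frequency
  expectation p^2 + (1-p)^2 averaged over the individual's non-missing SNPs.

Downstream the polygenic model uses 2K as the genetic covariance structure;
``bend`` nudges 2K to positive semi-definiteness when needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("autozyg")


@dataclass
class KinshipMatrix:
    samples: list[str]
    values: np.ndarray
    m_snps_used: int

    def __post_init__(self) -> None:
        k = np.asarray(self.values, dtype=float)
        if k.shape != (len(self.samples),) * 2:
            raise ValueError("kinship matrix shape does not match sample count")
        if not np.allclose(k, k.T):
            raise ValueError("kinship matrix not symmetric")
        if not np.isfinite(k).all():
            raise ValueError("non-finite kinship entries")
        self.values = k

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.samples,
                     columns=self.samples).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), m_snps_used=0)


def genomic_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Estimate the genomic kinship matrix from a QC'd genotype matrix."""
    p = g.alt_allele_frequency()
    if np.any((p <= 0) | (p >= 1) | ~np.isfinite(p)):
        raise ValueError("monomorphic SNP present; run QC first")

    valid = (g.calls != MISSING)
    x = np.where(valid, g.calls, 0) / 2.0  # half-dosage, 0 where missing
    w = np.sqrt(p * (1 - p))
    z = np.where(valid, (x - p) / w, 0.0)

    num = z @ z.T
    counts = valid.astype(float) @ valid.astype(float).T
    if np.any(counts == 0):
        raise ValueError("a sample pair shares no non-missing SNPs")
    k = num / counts

    # diagonal: 0.5 * (1 + excess homozygosity)
    hom = (g.calls == 0) | (g.calls == 2)
    obs_hom = hom.sum(axis=1) / valid.sum(axis=1)
    e0 = (valid * (p * p + (1 - p) * (1 - p))).sum(axis=1) / valid.sum(axis=1)
    np.fill_diagonal(k, 0.5 * (1 + obs_hom - e0))
    k = (k + k.T) / 2.0
    return KinshipMatrix(list(g.samples), k, m_snps_used=g.n_snps)


def bend(matrix: np.ndarray, eps_extra: float = 1e-6) -> tuple[np.ndarray, float]:
    """Make a symmetric matrix PSD by adding |lambda_min| + eps to the diagonal.

    Returns the (possibly unchanged) matrix and the shift applied.
    """
    lam_min = float(np.linalg.eigvalsh(matrix)[0])
    if lam_min >= 0:
        return matrix, 0.0
    shift = abs(lam_min) + eps_extra
    logger.info("bending covariance: min eigenvalue %.3g, diagonal shift %.3g",
                lam_min, shift)
    return matrix + shift * np.eye(matrix.shape[0]), shift


def relationship_matrix(k: KinshipMatrix) -> np.ndarray:
    """2K (numerator-relationship scale) bent to positive semi-definiteness."""
    a, _ = bend(2.0 * k.values)
    return a
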