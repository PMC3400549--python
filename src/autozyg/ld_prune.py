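"""Pairwise-r² LD pruning in sliding SNP windows.

Produces the quasi-independent SNP panel underlying the pruned-panel ROH
statistic: within each 50-SNP window (advancing by a 5-SNP step) any pair of
retained SNPs with squared dosage correlation above ``r2_max`` loses one
member, and a SNP removed in any window stays removed.  r² is the squared
Pearson correlation of dosage codes over pairwise-complete samples
(composite/genotypic LD; phase is unavailable from array genotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("autozyg")


@dataclass(frozen=True)
class PruneParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.1

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not 1 <= self.step_snps <= self.window_snps:
            raise ValueError("step_snps must be in [1, window_snps]")
        if not 0 < self.r2_max < 1:
            raise ValueError("r2_max must be in (0, 1)")


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing calls (-1) are dropped pairwise.  A SNP monomorphic among the
    complete pairs yields r² = 0 with a warning: such a pair carries no LD
    information to prune on.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete samples")
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        logger.warning("monomorphic SNP among complete pairs; r2 defined as 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² matrix for a samples x snps dosage block."""
    valid = (x != MISSING).astype(float)
    x0 = np.where(x == MISSING, 0.0, x.astype(float))
    n = valid.T @ valid
    sx = x0.T @ valid
    sxx = (x0 * x0).T @ valid
    sxy = x0.T @ x0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n          # var of row-SNP over both-valid rows
        vary = sxx.T - sx.T * sx.T / n    # var of col-SNP
        r2 = cov * cov / (varx * vary)
    r2 = np.where(np.isfinite(r2), r2, 0.0)  # monomorphic pairs prune nothing
    return np.clip(r2, 0.0, 1.0)


def prune(g: GenotypeMatrix, params: PruneParams = PruneParams()) -> list[str]:
    """Return the IDs of SNPs retained after windowed r² pruning.

    Within each window the currently-worst pair (largest r², ties broken by
    SNP index order) is eliminated first; the removed member is the one with
    the smaller MAF, or on an MAF tie the SNP at the larger position.  The
    procedure is deterministic for a fixed input.
    """
    p = g.alt_allele_frequency()
    maf = np.minimum(p, 1 - p)
    pos = g.snps["pos_bp"].values
    removed = np.zeros(g.n_snps, dtype=bool)

    for chrom in g.snps["chrom"].unique():
        idx = np.flatnonzero((g.snps["chrom"] == chrom).values)
        c = len(idx)
        starts = range(0, max(c - 1, 1), params.step_snps)
        for s in starts:
            w_idx = idx[s:s + params.window_snps]
            live = w_idx[~removed[w_idx]]
            if len(live) < 2:
                continue
            r2 = _r2_matrix(g.calls[:, live])
            np.fill_diagonal(r2, 0.0)
            while True:
                flat = int(np.argmax(r2))
                i, j = divmod(flat, len(live))
                if r2[i, j] <= params.r2_max:
                    break
                a, b = live[i], live[j]
                if maf[a] < maf[b]:
                    loser = i
                elif maf[b] < maf[a]:
                    loser = j
                else:
                    loser = i if pos[a] > pos[b] else j
                removed[live[loser]] = True
                r2[loser, :] = 0.0
                r2[:, loser] = 0.0
    return [str(sid) for sid in g.snps.loc[~removed, "id"]]


def write_prune_lists(g: GenotypeMatrix, retained: list[str],
                      in_path, out_path) -> None:
    """Write retained (prune.in analogue) and removed ID lists, one per line."""
    retained_set = set(retained)
    with open(in_path, "w") as fh:
        fh.writelines(f"{sid}\n" for sid in retained)
    with open(out_path, "w") as fh:
        fh.writelines(f"{sid}\n" for sid in g.snps["id"] if sid not in retained_set)
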