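"""Runs-of-homozygosity detection by the sliding-window hit-rate routine.

The caller mirrors the classic array-genotype ROH workflow: windows of a
target SNP count (capped in kb) slide across each chromosome; a window
tolerating at most one heterozygous and five missing calls is
"homozygous-passing"; each SNP's hit rate is the fraction of windows covering
it that pass; maximal runs of high-hit-rate SNPs become candidate segments,
which are trimmed to homozygous ends, split at large inter-SNP gaps and then
filtered on SNP count, length and SNP density.

Two parameter presets are provided: ``froh_dense`` for the full QC'd panel
(>=25 SNPs, >=1500 kb, <=100 kb gap, <=20 kb/SNP) and ``frohld_pruned`` for
the LD-pruned panel (>=12 SNPs, >=1000 kb, <=250 kb gap, <=100 kb/SNP).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class RohParams:
    window_kb: float = 5000.0
    window_min_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_rate_threshold: float = 0.05
    min_snps_in_roh: int = 25
    min_length_kb: float = 1500.0
    max_gap_kb: float = 100.0
    max_density_kb_per_snp: float = 20.0

    def __post_init__(self) -> None:
        for name in ("window_kb", "window_min_snps", "hit_rate_threshold",
                     "min_snps_in_roh", "min_length_kb", "max_gap_kb",
                     "max_density_kb_per_snp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: dense-panel preset: segments of >=25 SNPs spanning >=1.5 Mb
FROH_DENSE = RohParams()
#: pruned-panel preset: >=12 SNPs spanning >=1.0 Mb, relaxed gap/density
FROHLD_PRUNED = RohParams(min_snps_in_roh=12, min_length_kb=1000.0,
                          max_gap_kb=250.0, max_density_kb_per_snp=100.0)
PRESETS = {"froh_dense": FROH_DENSE, "frohld_pruned": FROHLD_PRUNED}


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


SEGMENT_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]


def _window_extents(pos: np.ndarray, params: RohParams) -> np.ndarray:
    """Inclusive end index of the window starting at each SNP.

    A window targets ``window_min_snps`` consecutive SNPs but is truncated at
    the chromosome end and at the ``window_kb`` span cap; truncated windows
    are still formed.
    """
    cap_bp = params.window_kb * 1000.0
    by_span = np.searchsorted(pos, pos + cap_bp, side="right") - 1
    by_count = np.arange(len(pos)) + params.window_min_snps - 1
    return np.minimum(np.minimum(by_span, by_count), len(pos) - 1)


def _chrom_segments(calls: np.ndarray, pos: np.ndarray, ends: np.ndarray,
                    params: RohParams) -> list[tuple[int, int]]:
    """Candidate (start_idx, end_idx) inclusive segments for one sample/chrom."""
    het = calls == 1
    mis = calls == MISSING
    hcum = np.concatenate([[0], np.cumsum(het)])
    mcum = np.concatenate([[0], np.cumsum(mis)])
    n_het = hcum[ends + 1] - hcum[np.arange(len(pos))]
    n_mis = mcum[ends + 1] - mcum[np.arange(len(pos))]
    passing = ((n_het <= params.max_het_per_window)
               & (n_mis <= params.max_missing_per_window))
    pcum = np.concatenate([[0], np.cumsum(passing)])

    k = np.arange(len(pos))
    lo = np.searchsorted(ends, k, side="left")  # first window covering SNP k
    total = k - lo + 1
    n_pass = pcum[k + 1] - pcum[lo]
    hit = n_pass / total
    in_run = hit >= params.hit_rate_threshold

    homo = (calls == 0) | (calls == 2)
    gap_bp = params.max_gap_kb * 1000.0
    out: list[tuple[int, int]] = []
    # maximal runs of in_run
    edges = np.flatnonzero(np.diff(np.concatenate([[0], in_run.view(np.int8), [0]])))
    for a, b in zip(edges[::2], edges[1::2] - 1):
        # trim candidate ends to outermost homozygous non-missing SNP
        hom_idx = np.flatnonzero(homo[a:b + 1])
        if hom_idx.size == 0:
            continue
        a2, b2 = a + hom_idx[0], a + hom_idx[-1]
        # split at adjacent-SNP gaps larger than the allowance
        breaks = np.flatnonzero(np.diff(pos[a2:b2 + 1]) > gap_bp)
        starts = [a2] + [a2 + br + 1 for br in breaks]
        stops = [a2 + br for br in breaks] + [b2]
        out.extend(zip(starts, stops))
    return out


def call_roh(g: GenotypeMatrix, params: RohParams) -> pd.DataFrame:
    """Detect ROH for every sample; returns a .hom-style table.

    Columns: sample, chrom, start_bp, end_bp, n_snps, length_kb; sorted by
    (sample order, chrom, start_bp).  Chromosomes with fewer SNPs than
    ``min_snps_in_roh`` simply yield no segments.
    """
    rows: list[tuple] = []
    chroms = g.snps["chrom"].values
    positions = g.snps["pos_bp"].values
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx].astype(np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"SNPs not sorted by position on chromosome {chrom}")
        if len(idx) < params.min_snps_in_roh:
            continue
        ends = _window_extents(pos, params)
        sub = g.calls[:, idx]
        for si, sample in enumerate(g.samples):
            for a, b in _chrom_segments(sub[si], pos, ends, params):
                n_snps = b - a + 1
                length_kb = (pos[b] - pos[a] + 1) / 1000.0
                if (n_snps >= params.min_snps_in_roh
                        and length_kb >= params.min_length_kb
                        and length_kb / n_snps <= params.max_density_kb_per_snp):
                    rows.append((sample, int(chrom), int(pos[a]), int(pos[b]),
                                 n_snps, length_kb))
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    order = {s: i for i, s in enumerate(g.samples)}
    return df.sort_values(
        ["sample", "chrom", "start_bp"],
        key=lambda col: col.map(order) if col.name == "sample" else col,
        kind="stable",
    ).reset_index(drop=True)


def params_for_preset(name: str, **overrides) -> RohParams:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)
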