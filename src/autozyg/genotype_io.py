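"""Genotype, phenotype, pedigree and interval file IO plus quality control.

Dosage convention
-----------------
Genotype calls are stored as the number of copies of the *alternate* allele,
which is defined at read time as the rarer of the two observed alleles
(lexicographically smaller label on a tie).  Calls take values in
``{0, 1, 2, MISSING}`` with :data:`MISSING` == -1.  Only autosomes (labelled
1-22) are kept; SNP-map coordinates are 1-based inclusive, interval tables are
half-open ``[start_bp, end_bp)``.

Supported layouts: PLINK PED/MAP text, PLINK BED/BIM/FAM binary (SNP-major,
v1.00 magic) and a plain TSV matrix (samples x SNPs) with a companion SNP
table.  No installed library reads these array-genotype formats, so the codecs
live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hwe import hwe_exact_test

logger = logging.getLogger("autozyg")

MISSING: int = -1
AUTOSOMES = set(range(1, 23))

_SNP_COLUMNS = ["id", "chrom", "pos_bp", "a1", "a2"]


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alternate-allele dosage matrix.

    Attributes
    ----------
    samples : list of sample IDs (unique).
    snps : DataFrame with columns id, chrom, pos_bp, a1, a2; sorted by
        (chrom, pos_bp), strictly increasing positions within chromosome.
        ``a1`` is the counted (alternate, rarer) allele.
    calls : int8 array of shape (n_samples, n_snps), values {0,1,2,-1}.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def alt_allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from non-missing calls."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, np.where(obs, self.calls, 0).sum(axis=0) / (2 * n), np.nan)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples,
            self.snps.iloc[index].reset_index(drop=True),
            self.calls[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.samples[i] for i in np.atleast_1d(index)],
            self.snps,
            self.calls[np.atleast_1d(index), :],
        )


@dataclass
class QcReport:
    n_samples_in: int
    n_snps_in: int
    n_samples_removed_missing: int = 0
    n_snps_removed_missing: int = 0
    n_snps_removed_hwe: int = 0
    n_snps_removed_maf: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class IntervalSet:
    """Half-open [start_bp, end_bp) genomic intervals, normalised per chromosome."""

    intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: list[tuple[int, int, int]] = []
        for chrom, start, end in sorted(self.intervals):
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged.pop()
                merged.append((chrom, prev[1], max(prev[2], end)))
            else:
                merged.append((chrom, start, end))
        self.intervals = merged

    def overlap_bp(self, chrom: int, start: int, end: int) -> int:
        """Total overlap of [start, end) with intervals on `chrom`."""
        total = 0
        for c, s, e in self.intervals:
            if c == chrom:
                total += max(0, min(end, e) - max(start, s))
        return total


@dataclass
class Pedigree:
    """Parent links; founders have sire/dam set to "0".

    ``table`` columns: individual, sire, dam, sex, generation.  Generation
    indices are assigned topologically (founders are generation 0) and the
    graph is checked acyclic at construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"individual", "sire", "dam"}
        if not required.issubset(t.columns):
            raise ValueError(f"pedigree missing columns {required - set(t.columns)}")
        if t["individual"].duplicated().any():
            raise ValueError("duplicate individual IDs in pedigree")
        self.table = t = t.astype({"individual": str, "sire": str, "dam": str})
        known = set(t["individual"])
        for col in ("sire", "dam"):
            unknown = set(t[col]) - known - {"0"}
            if unknown:
                raise ValueError(f"{col} IDs not in pedigree: {sorted(unknown)[:5]}")
        # topological generation assignment; failure to converge == cycle
        gen = {iid: -1 for iid in t["individual"]}
        gen["0"] = -1
        parents = {r.individual: (r.sire, r.dam) for r in t.itertuples()}
        remaining = set(parents)
        level = 0
        while remaining:
            placed = {
                i for i in remaining
                if all(p == "0" or (p in gen and gen[p] >= 0 and p not in remaining)
                       for p in parents[i])
            }
            if not placed:
                raise ValueError("cyclic pedigree")
            for i in placed:
                gen[i] = max(
                    (gen[p] for p in parents[i] if p != "0"), default=-1
                ) + 1
            remaining -= placed
            level += 1
        self.table = t.assign(generation=[gen[i] for i in t["individual"]])

    def parents_of(self, individual: str) -> tuple[str, str]:
        row = self.table.loc[self.table["individual"] == individual]
        if row.empty:
            raise KeyError(f"individual {individual!r} not in pedigree")
        return str(row["sire"].iloc[0]), str(row["dam"].iloc[0])

    @property
    def founders(self) -> list[str]:
        t = self.table
        return list(t.loc[(t["sire"] == "0") & (t["dam"] == "0"), "individual"])


def _finalise_snp_order(snps: pd.DataFrame, calls: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop non-autosomal SNPs, sort by (chrom, pos), dedupe ids/positions."""
    chrom_num = pd.to_numeric(snps["chrom"], errors="coerce")
    auto = chrom_num.isin(list(AUTOSOMES))
    n_dropped = int((~auto).sum())
    if n_dropped:
        logger.info("dropping %d non-autosomal SNPs", n_dropped)
    snps = snps.loc[auto.values].assign(chrom=chrom_num[auto.values].astype(int))
    calls = calls[:, auto.values]
    order = np.lexsort((snps["pos_bp"].values, snps["chrom"].values))
    snps = snps.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    keep = ~(snps.duplicated("id") | snps.duplicated(["chrom", "pos_bp"]))
    if not keep.all():
        logger.info("dropping %d duplicate SNPs", int((~keep).sum()))
        snps = snps.loc[keep].reset_index(drop=True)
        calls = calls[:, keep.values]
    if (snps["pos_bp"] <= 0).any():
        raise ValueError("non-positive SNP position")
    return snps, calls


def _recode_to_rarer_alt(allele_pairs: np.ndarray, snp_meta: pd.DataFrame
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Turn an (n, m, 2) allele-label array into rarer-allele dosages."""
    n, m, _ = allele_pairs.shape
    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1_out, a2_out = [], []
    for j in range(m):
        col = allele_pairs[:, j, :]
        ok = (col != "0").all(axis=1)
        labels, counts = np.unique(col[ok], return_counts=True)
        if len(labels) > 2:
            raise ParseError(f"SNP {snp_meta['id'].iloc[j]!r} has >2 alleles")
        if len(labels) == 0:
            a1, a2 = "0", "0"
        elif len(labels) == 1:
            a1, a2 = labels[0], labels[0]
        else:
            # alternate = rarer allele, lexicographic tie-break
            if counts[0] < counts[1] or (counts[0] == counts[1] and labels[0] < labels[1]):
                a1, a2 = labels[0], labels[1]
            else:
                a1, a2 = labels[1], labels[0]
        calls[ok, j] = (col[ok] == a1).sum(axis=1)
        a1_out.append(a1)
        a2_out.append(a2)
    meta = snp_meta.assign(a1=a1_out, a2=a2_out)
    return calls, meta


# ---------------------------------------------------------------------------
# PED/MAP


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    rows = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 4:
            raise ParseError(f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
        rows.append((parts[1], parts[0], int(parts[3])))
    snps = pd.DataFrame(rows, columns=["id", "chrom", "pos_bp"])
    m = len(snps)

    samples: list[str] = []
    pairs = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}")
        iid = parts[1]
        if iid in samples:
            raise ValueError(f"duplicate sample ID {iid!r}")
        samples.append(iid)
        pairs.append(np.array(parts[6:], dtype="U8").reshape(m, 2))
    allele_pairs = np.stack(pairs) if pairs else np.empty((0, m, 2), dtype="U8")
    calls, snps = _recode_to_rarer_alt(allele_pairs, snps)
    snps, calls = _finalise_snp_order(snps, calls)
    return GenotypeMatrix(samples, snps, calls)


def _write_ped_map(g: GenotypeMatrix, prefix: Path) -> None:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in g.snps.itertuples():
            fh.write(f"{r.chrom}\t{r.id}\t0\t{r.pos_bp}\n")
    a1 = g.snps["a1"].values
    a2 = g.snps["a2"].values
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(g.samples):
            alleles = []
            for j, c in enumerate(g.calls[i]):
                if c == MISSING:
                    alleles += ["0", "0"]
                elif c == 0:
                    alleles += [a2[j], a2[j]]
                elif c == 1:
                    alleles += [a1[j], a2[j]]
                else:
                    alleles += [a1[j], a1[j]]
            fh.write(" ".join([f"F{i}", iid, "0", "0", "0", "-9"] + alleles) + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM (SNP-major v1.00)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of A1 (alternate): 00=hom A1, 01=missing, 10=het, 11=hom A2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    samples = list(fam["iid"])
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ID in FAM")
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major v1.00)")
    n, m = len(samples), len(bim)
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * m:
        raise ParseError(f"{prefix.with_suffix('.bed')}: unexpected length")
    codes = np.unpackbits(
        body.reshape(m, bytes_per_snp)[:, :, None], axis=2, bitorder="little"
    ).reshape(m, bytes_per_snp * 8 // 2, 2)
    two_bit = codes[:, :n, 0] + 2 * codes[:, :n, 1]
    calls = _BED_DECODE[two_bit].T  # samples x snps
    snps = bim[["id", "chrom", "pos_bp", "a1", "a2"]].copy()
    snps, calls = _finalise_snp_order(snps, calls)
    return GenotypeMatrix(samples, snps, calls)


def _write_bed(g: GenotypeMatrix, prefix: Path) -> None:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for r in g.snps.itertuples():
            fh.write(f"{r.chrom}\t{r.id}\t0\t{r.pos_bp}\t{r.a1}\t{r.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, iid in enumerate(g.samples):
            fh.write(f"F{i} {iid} 0 0 0 -9\n")
    n = g.n_samples
    bytes_per_snp = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        lut[np.int8(dosage).view(np.uint8)] = code
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(g.n_snps):
            col = g.calls[:, j]
            codes = lut[col.view(np.uint8)]
            padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
            padded[:n] = codes
            bits = padded.reshape(bytes_per_snp, 4)
            packed = (bits[:, 0] | (bits[:, 1] << 2) | (bits[:, 2] << 4)
                      | (bits[:, 3] << 6)).astype(np.uint8)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# TSV matrix (prefix.geno.tsv + prefix.snps.tsv)


def _read_tsv_matrix(prefix: Path) -> GenotypeMatrix:
    snps = pd.read_csv(Path(str(prefix) + ".snps.tsv"), sep="\t",
                       dtype={"id": str, "a1": str, "a2": str})
    missing_cols = set(_SNP_COLUMNS) - set(snps.columns)
    if missing_cols:
        raise ParseError(f"{prefix}.snps.tsv: missing columns {sorted(missing_cols)}")
    geno = pd.read_csv(Path(str(prefix) + ".geno.tsv"), sep="\t", index_col=0)
    if list(geno.columns) != list(snps["id"]):
        raise ParseError(f"{prefix}.geno.tsv columns do not match SNP table order")
    samples = [str(s) for s in geno.index]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ID in genotype TSV")
    calls = geno.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    snps, calls = _finalise_snp_order(snps, calls)
    return GenotypeMatrix(samples, snps, calls)


def _write_tsv_matrix(g: GenotypeMatrix, prefix: Path) -> None:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g.snps.to_csv(Path(str(prefix) + ".snps.tsv"), sep="\t", index=False)
    vals = g.calls.astype(object)
    df = pd.DataFrame(vals, index=g.samples, columns=list(g.snps["id"]))
    df = df.mask(df == MISSING, other=pd.NA)
    df.to_csv(Path(str(prefix) + ".geno.tsv"), sep="\t", index_label="sample")


_FORMATS = {
    "ped_map": (_read_ped_map, _write_ped_map),
    "bed_bim_fam": (_read_bed, _write_bed),
    "tsv_matrix": (_read_tsv_matrix, _write_tsv_matrix),
}


def read_genotypes(prefix: str | Path, fmt: str) -> GenotypeMatrix:
    """Read a genotype matrix from `prefix` in the named dialect.

    `prefix` is the path without extension (e.g. ``cohort1`` for
    ``cohort1.ped``/``cohort1.map``).
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_FORMATS)}")
    return _FORMATS[fmt][0](Path(prefix))


def write_genotypes(g: GenotypeMatrix, prefix: str | Path, fmt: str) -> None:
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_FORMATS)}")
    _FORMATS[fmt][1](g, Path(prefix))


# ---------------------------------------------------------------------------
# Panel restriction and QC


def restrict_to_panel(g: GenotypeMatrix, panel_ids: set[str]) -> GenotypeMatrix:
    """Keep exactly the SNPs whose IDs are in `panel_ids` (order preserved)."""
    if not panel_ids:
        raise ValueError("empty SNP panel")
    keep = g.snps["id"].isin(panel_ids).values
    if not keep.any():
        raise ValueError("no overlap between genotype SNPs and panel")
    return g.take_snps(np.flatnonzero(keep))


def qc_filter(
    g: GenotypeMatrix,
    max_sample_missing: float = 0.05,
    max_snp_missing: float = 0.10,
    hwe_alpha: float = 1e-4,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply sample-missingness, SNP-missingness, HWE and MAF filters in order.

    Samples with strictly more than `max_sample_missing` missing calls are
    removed first; SNP statistics (missingness, HWE, allele frequency) are then
    computed on the retained samples.  HWE uses the exact conditional
    two-sided test (no mid-p).
    """
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_samples_in=g.n_samples, n_snps_in=g.n_snps)

    keep_samples = g.sample_missing_fraction() <= max_sample_missing
    report.n_samples_removed_missing = int((~keep_samples).sum())
    if not keep_samples.any():
        raise ValueError("QC removed all samples")
    g = g.take_samples(np.flatnonzero(keep_samples))

    keep = g.snp_missing_fraction() <= max_snp_missing
    report.n_snps_removed_missing = int((~keep).sum())
    g = g.take_snps(np.flatnonzero(keep))

    n0 = (g.calls == 0).sum(axis=0)
    n1 = (g.calls == 1).sum(axis=0)
    n2 = (g.calls == 2).sum(axis=0)
    pvals = np.array([hwe_exact_test(int(h), int(a), int(b))
                      for h, a, b in zip(n1, n2, n0)])
    keep = pvals >= hwe_alpha
    report.n_snps_removed_hwe = int((~keep).sum())
    g = g.take_snps(np.flatnonzero(keep))

    p = g.alt_allele_frequency()
    maf = np.minimum(p, 1 - p)
    keep = ~np.isnan(maf) & (maf >= min_maf)
    report.n_snps_removed_maf = int((~keep).sum())
    if not keep.any():
        raise ValueError("QC removed all SNPs")
    g = g.take_snps(np.flatnonzero(keep))

    report.n_samples_out = g.n_samples
    report.n_snps_out = g.n_snps
    return g, report


# ---------------------------------------------------------------------------
# Phenotype / pedigree / interval tables


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV with mandatory header.

    Required columns: sample, height_cm, age_years, sex, cohort.  Optional
    ordinal covariates: ea (educational attainment), os (occupational status).
    """
    t = pd.read_csv(path, sep="\t", dtype={"sample": str, "cohort": str})
    required = {"sample", "height_cm", "age_years", "sex", "cohort"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    if t["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    bad_sex = ~t["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(f"{path}: sex must be male/female")
    if (t["height_cm"] < 3).any():
        logger.warning("%s: heights < 3 found; values look like metres, expected cm", path)
    if (t["height_cm"] <= 0).any() or (t["age_years"] <= 0).any():
        raise ValueError(f"{path}: non-positive height or age")
    return t


def write_phenotypes(t: pd.DataFrame, path: str | Path) -> None:
    t.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    t = pd.read_csv(path, sep="\t", dtype=str)
    return Pedigree(t)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_intervals(path: str | Path) -> IntervalSet:
    t = pd.read_csv(path, sep="\t")
    required = {"chrom", "start_bp", "end_bp"}
    if not required.issubset(t.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(t.columns))}")
    return IntervalSet([(int(r.chrom), int(r.start_bp), int(r.end_bp))
                        for r in t.itertuples()])


def write_intervals(iv: IntervalSet, path: str | Path) -> None:
    pd.DataFrame(iv.intervals, columns=["chrom", "start_bp", "end_bp"]).to_csv(
        path, sep="\t", index=False)
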