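"""Conversion of z-score effects to the first-cousin-offspring height scale.

A pooled regression coefficient (z-score units per 1% homozygosity) is turned
into centimetres lost by the offspring of first cousins relative to the
offspring of unrelated parents: multiply |beta| by the homozygosity
difference between the two groups (percentage points, estimated empirically
from pedigree + measures when possible, falling back to the theoretical
100 x 0.0625 otherwise) and by the sample-size-weighted height SD.

Pedigree inbreeding coefficients use Wright's path counting, implemented via
the recursive kinship algorithm: F(individual) = kinship(sire, dam).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .genotype_io import Pedigree

logger = logging.getLogger("autozyg")

#: theoretical inbreeding coefficient of first-cousin offspring, in percent
THEORETICAL_COUSIN_DELTA_F_PCT = 6.25


@dataclass
class ConversionInputs:
    beta_pooled: float   # z-score units per 1% homozygosity
    delta_f: float       # percentage points of the homozygosity measure
    weighted_sd_cm: float

    def __post_init__(self) -> None:
        if self.weighted_sd_cm <= 0:
            raise ValueError("weighted SD must be positive")
        if self.delta_f < 0:
            raise ValueError("delta_f must be non-negative")


def _kinship_fn(ped: Pedigree):
    parents = {r.individual: (r.sire, r.dam) for r in ped.table.itertuples()}
    gen = dict(zip(ped.table["individual"], ped.table["generation"]))
    gen["0"] = -1

    @lru_cache(maxsize=None)
    def phi(a: str, b: str) -> float:
        if a == "0" or b == "0":
            return 0.0
        if a == b:
            sa, da = parents[a]
            return 0.5 * (1.0 + phi(sa, da))
        # recurse on the individual from the later generation
        if gen[a] < gen[b]:
            a, b = b, a
        sa, da = parents[a]
        return 0.5 * (phi(sa, b) + phi(da, b))

    return phi


def expected_f_ped(ped: Pedigree, individual: str) -> float:
    """Wright's pedigree inbreeding coefficient of `individual` in [0, 1]."""
    sire, dam = ped.parents_of(individual)  # raises on unknown individual
    return _kinship_fn(ped)(sire, dam)


def delta_f_cousin_offspring(measures: pd.DataFrame, ped: Pedigree,
                             measure: str) -> float:
    """Mean measure difference: first-cousin offspring minus outbred offspring.

    Group membership comes from pedigree expectation: individuals with
    F_ped within 1e-9 of 0.0625 versus F_ped == 0.  Units are percentage
    points of the homozygosity measure.
    """
    f_ped = {iid: expected_f_ped(ped, iid) for iid in ped.table["individual"]}
    m = measures.set_index("sample")[measure]
    cousin = [iid for iid, f in f_ped.items()
              if abs(f - 0.0625) < 1e-9 and iid in m.index]
    outbred = [iid for iid, f in f_ped.items() if f == 0.0 and iid in m.index]
    if not cousin or not outbred:
        raise ValueError("need measured first-cousin offspring and outbred "
                         "offspring in the pedigree")
    return float(m[cousin].mean() - m[outbred].mean())


def weighted_sd(cohorts: pd.DataFrame) -> float:
    """Sample-size-weighted mean of per-cohort height SDs (cm).

    `cohorts` needs columns ``n`` and ``sd_cm``.
    """
    if cohorts.empty:
        raise ValueError("empty cohort table")
    n = cohorts["n"].to_numpy(dtype=float)
    sd = cohorts["sd_cm"].to_numpy(dtype=float)
    if (n < 1).any() or (sd <= 0).any():
        raise ValueError("need n >= 1 and sd > 0 for every cohort")
    return float((n * sd).sum() / n.sum())


def effect_in_cm(ci: ConversionInputs) -> float:
    """|beta| x delta_F x weighted SD, in cm (direction reported separately)."""
    return abs(ci.beta_pooled) * ci.delta_f * ci.weighted_sd_cm


def conversion_report(
    beta_pooled: float,
    se_pooled: float,
    delta_f_estimates: dict[str, float],
    weighted_sd_cm: float,
    measure: str,
) -> pd.DataFrame:
    """Per-ΔF-source cm estimates plus the min-max range.

    When several populations supply a ΔF estimate, each cm figure is reported
    along with the overall range, mirroring "between x and y cm" reporting.
    An empty `delta_f_estimates` falls back to the theoretical 6.25
    percentage points with a logged caveat.
    """
    if not delta_f_estimates:
        logger.warning("no empirical delta-F available; falling back to the "
                       "theoretical first-cousin expectation of 6.25%%")
        delta_f_estimates = {"theoretical": THEORETICAL_COUSIN_DELTA_F_PCT}
    rows = []
    for source, df_pct in delta_f_estimates.items():
        cm = effect_in_cm(ConversionInputs(beta_pooled, df_pct, weighted_sd_cm))
        rows.append({
            "measure": measure,
            "beta_pooled": beta_pooled,
            "se_pooled": se_pooled,
            "delta_f_source": source,
            "delta_f_pct": df_pct,
            "direction": "decrease" if beta_pooled < 0 else "increase",
            "cm_estimate": cm,
        })
    out = pd.DataFrame(rows)
    out["cm_min"] = out["cm_estimate"].min()
    out["cm_max"] = out["cm_estimate"].max()
    return out
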