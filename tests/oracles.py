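"""Independent reference implementations used to cross-check the package.

Everything here is written as literal, loop-based evaluation of the
documented rules (or textbook formulas), deliberately sharing no code with
the library implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# ROH: exhaustive window enumeration


def roh_oracle(calls: np.ndarray, pos: np.ndarray, params) -> list[tuple[int, int, int]]:
    """All ROH segments for one sample on one chromosome.

    Literal evaluation of the window rules: enumerate every window, score
    hit rates, extract candidate runs, trim to homozygous ends, split at
    gaps, filter on count/length/density.  Returns (start_bp, end_bp,
    n_snps) tuples.
    """
    n = len(pos)
    cap = params.window_kb * 1000.0
    windows = []
    for i in range(n):
        j = i
        while (j + 1 < n and j + 1 - i < params.window_min_snps
               and pos[j + 1] - pos[i] <= cap):
            j += 1
        windows.append((i, j))

    passing = []
    for i, j in windows:
        het = sum(1 for k in range(i, j + 1) if calls[k] == 1)
        mis = sum(1 for k in range(i, j + 1) if calls[k] == MISSING)
        passing.append(het <= params.max_het_per_window
                       and mis <= params.max_missing_per_window)

    in_run = []
    for k in range(n):
        covering = [w for w, (i, j) in enumerate(windows) if i <= k <= j]
        hits = sum(1 for w in covering if passing[w])
        in_run.append(hits / len(covering) >= params.hit_rate_threshold)

    segments = []
    k = 0
    while k < n:
        if not in_run[k]:
            k += 1
            continue
        end = k
        while end + 1 < n and in_run[end + 1]:
            end += 1
        hom = [i for i in range(k, end + 1) if calls[i] in (0, 2)]
        if hom:
            a, b = hom[0], hom[-1]
            pieces, start = [], a
            for i in range(a, b):
                if pos[i + 1] - pos[i] > params.max_gap_kb * 1000.0:
                    pieces.append((start, i))
                    start = i + 1
            pieces.append((start, b))
            for s, e in pieces:
                n_snps = e - s + 1
                length_kb = (pos[e] - pos[s] + 1) / 1000.0
                if (n_snps >= params.min_snps_in_roh
                        and length_kb >= params.min_length_kb
                        and length_kb / n_snps <= params.max_density_kb_per_snp):
                    segments.append((int(pos[s]), int(pos[e]), n_snps))
        k = end + 1
    return segments


# ---------------------------------------------------------------------------
# LD pruning: naive re-execution of the documented procedure


def prune_oracle(calls: np.ndarray, pos: np.ndarray, maf: np.ndarray,
                 window: int, step: int, r2_max: float) -> list[int]:
    """Retained SNP indices for a single chromosome, by brute force."""

    def r2(a, b):
        ok = [(x, y) for x, y in zip(calls[:, a], calls[:, b])
              if x != MISSING and y != MISSING]
        xs = [x for x, _ in ok]
        ys = [y for _, y in ok]
        mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        if sxx == 0 or syy == 0:
            return 0.0
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        return sxy * sxy / (sxx * syy)

    m = calls.shape[1]
    removed = set()
    for s in range(0, max(m - 1, 1), step):
        live = [i for i in range(s, min(s + window, m)) if i not in removed]
        while True:
            best, best_pair = -1.0, None
            for ai in range(len(live)):
                for bi in range(ai + 1, len(live)):
                    v = r2(live[ai], live[bi])
                    if v > best:
                        best, best_pair = v, (live[ai], live[bi])
            if best_pair is None or best <= r2_max:
                break
            a, b = best_pair
            if maf[a] < maf[b]:
                loser = a
            elif maf[b] < maf[a]:
                loser = b
            else:
                loser = a if pos[a] > pos[b] else b
            removed.add(loser)
            live.remove(loser)
    return [i for i in range(m) if i not in removed]


# ---------------------------------------------------------------------------
# HWE: exact enumeration with rational arithmetic


def hwe_oracle(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """Two-sided exact HWE p-value via exact integer weights."""
    n = n_het + n_hom_a + n_hom_b
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het
    if n == 0 or n_rare == 0:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        ra = (n_rare - h) // 2
        co = n - h - ra
        # multinomial weight x 2^h, exact integers
        weights[h] = (math.factorial(n) * 2**h
                      // (math.factorial(ra) * math.factorial(h) * math.factorial(co)))
    total = sum(weights.values())
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / total


# ---------------------------------------------------------------------------
# Mixed model: dense likelihood grid


def m2ll_exact(y: np.ndarray, x: np.ndarray, a: np.ndarray,
               sigma2_g: float, sigma2_e: float) -> float:
    """Exact -2 log-likelihood with GLS beta at the given variance components."""
    n = len(y)
    v = sigma2_g * a + sigma2_e * np.eye(n)
    vinv = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
    r = y - x @ beta
    sign, logdet = np.linalg.slogdet(v)
    return float(n * np.log(2 * np.pi) + logdet + r @ vinv @ r)


def m2ll_grid_min(y: np.ndarray, x: np.ndarray, a: np.ndarray,
                  g_max: float, e_max: float, n_grid: int = 51) -> float:
    """Minimum -2 logL over an n_grid x n_grid variance-component grid."""
    best = np.inf
    for sg in np.linspace(0.0, g_max, n_grid):
        for se in np.linspace(e_max / n_grid, e_max, n_grid):
            best = min(best, m2ll_exact(y, x, a, sg, se))
    return best


# ---------------------------------------------------------------------------
# Pedigree: single-locus gene-drop Monte Carlo


def genedrop_f(ped_table, individual: str, n_drops: int,
               rng: np.random.Generator) -> float:
    """P(the two alleles of `individual` are IBD), by allelic gene drop.

    Founders receive unique allele labels; each transmission picks one of
    the parent's two alleles at random.  Vectorised over drops.
    """
    rows = list(ped_table.itertuples())
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    counter = 0
    for r in sorted(rows, key=lambda r: r.generation):
        if r.sire == "0":
            a = np.full(n_drops, counter)
            b = np.full(n_drops, counter + 1)
            counter += 2
        else:
            sa, sb = alleles[r.sire]
            da, db = alleles[r.dam]
            pick = rng.integers(0, 2, size=n_drops)
            a = np.where(pick == 0, sa, sb)
            pick = rng.integers(0, 2, size=n_drops)
            b = np.where(pick == 0, da, db)
        alleles[r.individual] = (a, b)
    a, b = alleles[individual]
    return float((a == b).mean())
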