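"""Exact conditional test of Hardy-Weinberg equilibrium.

Given observed genotype counts at a biallelic locus, the test conditions on
the allele counts and enumerates the probability of every possible
heterozygote count under random mating.  The two-sided p-value is the sum of
probabilities of all configurations no more probable than the observed one
(no mid-p correction).  Deterministic and exact at low counts, where the
chi-square approximation fails.
"""

from __future__ import annotations

import numpy as np


def hwe_exact_test(n_het: int, n_hom_alt: int, n_hom_ref: int) -> float:
    """Two-sided exact HWE p-value from genotype counts.

    Parameters are counts of heterozygotes and the two homozygote classes
    (label order is irrelevant).  Returns 1.0 for a monomorphic locus.
    """
    if min(n_het, n_hom_alt, n_hom_ref) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom_alt + n_hom_ref
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_alt, n_hom_ref) + n_het  # rarer-allele count
    if n_rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalised log-probabilities: P(het) ∝ n_rare!n_common!n!2^het /
    #   (hom_r! het! hom_c! (2n)!) -- compute via log-gamma, normalise below
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    from scipy.special import gammaln

    logp = (hets * np.log(2.0) - gammaln(hom_r + 1) - gammaln(hets + 1)
            - gammaln(hom_c + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValueError("observed heterozygote count impossible given allele counts")
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= obs[0] * (1 + 1e-12)].sum()))
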