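"""Shared simulation helpers for the statistical tests."""

import numpy as np


def zinb_groups(rng, n_per_group=500, rate=0.12, alpha=0.5, zero_frac_a=0.3,
                zero_frac_b=0.3, rate_mult_b=1.0, mean_offset=12):
    """Two groups of zero-inflated NB donor counts with read-depth offsets.

    Mirrors pooled donor read counts at a low allele frequency: NB2 counts
    with mean rate*depth and dispersion alpha, plus a structural-zero
    component (loci that produced no donor read at all).
    """
    n = n_per_group
    offsets = rng.poisson(mean_offset, 2 * n) + 1
    labels = np.r_[np.zeros(n), np.ones(n)]
    mu = rate * offsets * np.where(labels == 1, rate_mult_b, 1.0)
    counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
    zero_frac = np.where(labels == 1, zero_frac_b, zero_frac_a)
    counts = np.where(rng.random(2 * n) < zero_frac, 0, counts)
    return counts, offsets, labels
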