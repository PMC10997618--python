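"""Closed-form decision rules shared by several pipeline stages.

Each function is a direct transcription of a thresholding rule used in the
pipeline, kept free of any graph or I/O machinery so the rules can be
evaluated (and tested) in isolation.
"""

from __future__ import annotations

import numpy as np


def piecewise_rate_threshold(total, r_l: float, r_h: float, n_l: float, n_h: float):
    """Support-count threshold that relaxes from rate ``r_l`` to ``r_h``.

    For a family with total support ``total`` the threshold is ``r_l * total``
    up to ``n_l``, ``r_h * total`` beyond ``n_h``, and the linear interpolation
    between ``r_l * n_l`` and ``r_h * n_h`` in between. Used both for marking
    important in-edges in the correction graph (defaults 0.5/0.2/10/200) and
    for calling heterozygous sites from a pileup (defaults 0.4/0.2/10/100).
    Accepts scalars or numpy arrays.
    """
    total = np.asarray(total, dtype=float)
    low = r_l * total
    mid = (r_h * n_h - r_l * n_l) / (n_h - n_l) * (total - n_l) + r_l * n_l
    high = r_h * total
    out = np.where(total <= n_l, low, np.where(total <= n_h, mid, high))
    return out if out.ndim else float(out)


def overhang_limit(read_len, abs_limit: float, frac_limit: float):
    """Longest tolerated residual overhang on a read of length ``read_len``:
    ``min(abs_limit, frac_limit * read_len)`` (100/1% PacBio, 300/3% ONT)."""
    return np.minimum(abs_limit, frac_limit * np.asarray(read_len, dtype=float))


def identity_threshold(identities) -> float:
    """Outlier cutoff for string-graph edge identities.

    ``((m1 - 6*1.253*MAD1) + 2*(m2 - 6*1.4826*MAD2)) / 3`` where m1/MAD1 are
    the mean and mean absolute deviation and m2/MAD2 the median and median
    absolute deviation of the identity multiset. The 1.253 and 1.4826 factors
    scale each deviation estimate to a normal-equivalent sigma, so the cutoff
    sits six sigma below a blend of the two location estimates.
    """
    x = np.asarray(identities, dtype=float)
    m1 = float(np.mean(x))
    m2 = float(np.median(x))
    mad1 = float(np.mean(np.abs(x - m1)))
    mad2 = float(np.median(np.abs(x - m2)))
    return ((m1 - 6 * 1.253 * mad1) + 2 * (m2 - 6 * 1.4826 * mad2)) / 3


def bog_gap_ok(s0: float, s_i: float, C: float, R1: float, R2: float) -> bool:
    """Best-overlap-graph candidate rule: is ``s_i`` close enough to the top
    score ``s0``? The allowed gap is ``max(C, s_i*R1)`` for non-negative
    scores and ``max(C, -s_i*R2)`` for negative ones."""
    gap = s0 - s_i
    if s_i >= 0:
        return gap < max(C, s_i * R1)
    return gap < max(C, -s_i * R2)


def trio_classify(k_p: int, k_m: int, K_p: int, K_m: int) -> str:
    """Trio-binning read classification from haplotype-specific k-mer hits.

    Paternal iff ``k_p/K_p > (k_m + max(10, 0.1*k_m))/K_m``; maternal by the
    symmetric rule; otherwise untagged.
    """
    if k_p / K_p > (k_m + max(10.0, k_m * 0.1)) / K_m:
        return "paternal"
    if k_m / K_m > (k_p + max(10.0, k_p * 0.1)) / K_p:
        return "maternal"
    return "untagged"
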