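"""Exact Wilcoxon signed-rank test by full sign-assignment enumeration.

With the small fixed trial counts of this assay (8 paired block AUCs per
neuron), the exact null distribution of W+ is cheap to enumerate: zeros are
dropped, |differences| are ranked with midranks for ties, and all
2^n_effective sign assignments of the observed ranks are enumerated, so ties
and discreteness are handled without any large-sample approximation.  The
two-sided p-value doubles the smaller tail and caps at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

#: largest n_effective for which full enumeration is attempted (2^24 patterns)
MAX_EXACT_N = 24


@dataclass
class WilcoxonResult:
    """Outcome of one exact paired test.

    ``w_plus`` is the sum of the ranks of positive differences;
    ``direction`` compares ``w_plus`` with its null mean n(n+1)/4.
    """

    w_plus: float
    n_effective: int
    p_two_sided: float
    direction: str  # "increase" | "decrease" | "none"


def wilcoxon_signed_rank_exact(post: np.ndarray, pre: np.ndarray) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``post - pre`` equal to zero are dropped (classical zero
    handling); with no nonzero differences the test is uninformative and
    returns p = 1, direction "none".
    """
    post = np.asarray(post, dtype=float)
    pre = np.asarray(pre, dtype=float)
    if post.shape != pre.shape or post.ndim != 1 or post.size < 1:
        raise ValueError("post and pre must be equal-length 1-D arrays of length >= 1")
    if not (np.isfinite(post).all() and np.isfinite(pre).all()):
        raise ValueError("inputs must be finite")

    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(w_plus=0.0, n_effective=0, p_two_sided=1.0, direction="none")
    if n > MAX_EXACT_N:
        raise ValueError(f"exact enumeration limited to n_effective <= {MAX_EXACT_N}, got {n}")

    ranks = rankdata(np.abs(d))  # midranks for ties; multiples of 0.5, exact in float64
    w_plus = float(ranks[d > 0].sum())

    n_patterns = 1 << n
    count_le = 0
    count_ge = 0
    # enumerate sign assignments in chunks to bound memory at large n
    chunk = 1 << min(n, 16)
    bit_idx = np.arange(n)
    for start in range(0, n_patterns, chunk):
        idx = np.arange(start, min(start + chunk, n_patterns), dtype=np.int64)
        signs = (idx[:, None] >> bit_idx) & 1
        w = signs @ ranks
        count_le += int(np.count_nonzero(w <= w_plus))
        count_ge += int(np.count_nonzero(w >= w_plus))

    p = min(1.0, 2.0 * min(count_le, count_ge) / n_patterns)
    mean_w = n * (n + 1) / 4.0
    if w_plus > mean_w:
        direction = "increase"
    elif w_plus < mean_w:
        direction = "decrease"
    else:
        direction = "none"
    return WilcoxonResult(w_plus=w_plus, n_effective=n, p_two_sided=p, direction=direction)
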