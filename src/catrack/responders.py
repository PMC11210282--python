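"""Block AUCs and per-neuron responder classification.

For every neuron and trial, the baseline-re-referenced peristimulus Z trace
is integrated over three fixed blocks (pre [-5, 0), post [0, 5) and [5, 10) s
by default).  Each post block's 8 trial AUCs are compared with the pre
block's by the exact Wilcoxon signed-rank test, and the neuron is labelled:

* ``increased`` — a significant AUC increase in at least one post block
  (configurable to require both);
* ``decreased`` — a significant decrease in both post blocks;
* ``unresponsive`` — otherwise.

If one block shows a significant increase and the other a significant
decrease, increase takes precedence and the conflict is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import BlockDefinition
from .session import PeristimTensor
from .wilcoxon import WilcoxonResult, wilcoxon_signed_rank_exact

logger = logging.getLogger("catrack")

LABELS = ("increased", "unresponsive", "decreased")


def block_auc(tensor: PeristimTensor, blocks: BlockDefinition | None = None) -> np.ndarray:
    """Left-Riemann AUC per neuron x trial x block, in Z * seconds.

    Block [a, b) covers the samples with a <= t < b, so a constant-1 signal
    over a 5-s block at 10 Hz integrates to exactly 5.0 (50 samples x 0.1 s).
    Block edges are mapped to sample indices by rounding a * fs, which is
    exact for edges on whole tenths of a second.
    """
    blocks = blocks or BlockDefinition()
    fs = tensor.sampling_rate_hz
    dt = 1.0 / fs
    t0 = tensor.time_axis_s[0]
    n_win = tensor.values.shape[2]
    zero_idx = int(round(-t0 * fs))  # index of the stimulus sample

    out = np.empty((*tensor.values.shape[:2], len(blocks.all_blocks)))
    for b, (lo, hi) in enumerate(blocks.all_blocks):
        i0 = zero_idx + int(round(lo * fs))
        i1 = zero_idx + int(round(hi * fs))
        if i0 < 0 or i1 > n_win:
            raise ValueError(f"block [{lo}, {hi})s outside the peristimulus window")
        out[:, :, b] = tensor.values[:, :, i0:i1].sum(axis=2) * dt
    return out


@dataclass
class ResponderCall:
    """Per-neuron, per-day classification with its supporting statistics."""

    neuron_id: str
    day: int
    p_post1: float
    p_post2: float
    dir_post1: str
    dir_post2: str
    label: str
    alpha: float
    conflict: bool = False


def classify_neuron(
    post_results: Sequence[WilcoxonResult],
    alpha: float = 0.05,
    mode: str = "any",
) -> Tuple[str, bool]:
    """Label from the post-block test results.

    ``mode='any'`` calls a neuron increased when at least one post block shows
    a significant increase; ``mode='both'`` requires both.  A decreased label
    always requires both blocks significantly down.  Returns (label,
    conflict) where conflict flags one block significantly up and another
    significantly down.
    """
    if mode not in ("any", "both"):
        raise ValueError("mode must be 'any' or 'both'")
    sig_up = [r.p_two_sided < alpha and r.direction == "increase" for r in post_results]
    sig_down = [r.p_two_sided < alpha and r.direction == "decrease" for r in post_results]
    conflict = any(sig_up) and any(sig_down)
    n_up_needed = 1 if mode == "any" else len(post_results)
    if sum(sig_up) >= n_up_needed:
        return "increased", conflict
    if all(sig_down):
        return "decreased", conflict
    return "unresponsive", conflict


def classify_day(
    tensor: PeristimTensor,
    blocks: BlockDefinition | None = None,
    alpha: float = 0.05,
    mode: str = "any",
) -> List[ResponderCall]:
    """Run block AUCs + exact Wilcoxon tests for every neuron of one day."""
    blocks = blocks or BlockDefinition()
    if not tensor.re_referenced:
        raise ValueError("peristimulus tensor must be baseline-re-referenced")
    auc = block_auc(tensor, blocks)
    n_post = len(blocks.post)
    calls = []
    for i, nid in enumerate(tensor.neuron_ids):
        pre = auc[i, :, 0]
        results = [wilcoxon_signed_rank_exact(auc[i, :, 1 + b], pre) for b in range(n_post)]
        label, conflict = classify_neuron(results, alpha=alpha, mode=mode)
        if conflict:
            logger.warning(
                "neuron %s day %d: conflicting significant directions across post blocks",
                nid, tensor.day,
            )
        calls.append(
            ResponderCall(
                neuron_id=nid,
                day=tensor.day,
                p_post1=results[0].p_two_sided,
                p_post2=results[1].p_two_sided if n_post > 1 else float("nan"),
                dir_post1=results[0].direction,
                dir_post2=results[1].direction if n_post > 1 else "none",
                label=label,
                alpha=alpha,
                conflict=conflict,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[ResponderCall]) -> pd.DataFrame:
    cols = ["neuron_id", "day", "p_post1", "p_post2", "dir_post1", "dir_post2",
            "label", "alpha", "conflict"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in calls], columns=cols)
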