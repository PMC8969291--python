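"""Target-decoy q-value estimation and FDR-thresholded selection.

The false discovery rate among PSMs above a score cutoff is estimated by the
decoy count over the target count in that prefix (optionally with the +1
correction on the decoy count); a PSM's q-value is the minimum estimated FDR
over all cutoffs that admit it.  Ties are resolved decoys-first, the
conservative choice.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["qvalues_from_scores", "psms_at_fdr"]


def qvalues_from_scores(
    scores: Sequence[float],
    is_decoy: Sequence[bool],
    plus_one: bool = False,
) -> np.ndarray:
    """Per-PSM q-values from scores and decoy labels, in input order.

    Sorts descending by score (decoys first on ties), computes the running
    decoy/target ratio, and takes the cumulative minimum from the worst prefix
    upward, so q is monotone non-increasing in score.
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != decoy.shape:
        raise ValueError("scores and is_decoy must have equal length")
    n = scores.size
    if n == 0:
        return np.zeros(0)
    if decoy.all():
        raise ValueError("all PSMs are decoys; FDR is undefined without targets")
    # ascending lexsort on (-score, target-ness) = descending score, decoys first
    order = np.lexsort((~decoy, -scores))
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    numer = d_cum + 1 if plus_one else d_cum
    fdr = numer / np.maximum(t_cum, 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


def psms_at_fdr(
    qvalues: Sequence[float],
    is_decoy: Sequence[bool],
    threshold: float = 0.01,
) -> np.ndarray:
    """Indices of *target* PSMs accepted at ``q <= threshold`` (decoys never
    reported)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    q = np.asarray(qvalues, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    return np.flatnonzero((q <= threshold) & ~decoy)
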