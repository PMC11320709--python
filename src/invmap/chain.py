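"""Co-linear anchor chaining by dynamic programming.

Each anchor alone scores 1; extending a chain by one anchor adds a flat
reward of 1 (no gap cost). A precursor must share both strand bits and lie
within distance ``d`` of the anchor on read and reference, with strictly
increasing reference position. On the read the direction depends on
orientation: same-orientation chains advance along the main diagonal
(read position increasing), opposite-orientation chains along the
anti-diagonal (read position decreasing as reference increases), so that
reverse-strand reads chain without any coordinate transform. The main
chain is the backpointer path with the largest score increase; since every
step adds exactly 1 and every path origin scores 1, that is the path
ending at the globally maximal score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import chain_dp
from .anchors import AnchorSet

#: bound on the read/reference gap between chained anchors, as a fraction
#: of read length; 1.15 allows for a 15% error rate on noisy long reads.
D_FACTOR = 1.15


def compute_d(read_len: int, d_factor: float = D_FACTOR) -> int:
    """Maximum anchor-to-anchor distance: ceil(d_factor * read_len)."""
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    return math.ceil(d_factor * read_len)


@dataclass
class ChainScores:
    """Per-anchor DP score and backpointer (-1 where no precursor)."""

    score: np.ndarray
    pred: np.ndarray


@dataclass
class Chain:
    """An extracted chain: indices into the AnchorSet it was built from.

    ``strand`` is '+' when the chained anchors have dr == dg (read maps to
    the reference forward strand), '-' otherwise. Spans are half-open and
    include the k-mer extent of the terminal anchors.
    """

    indices: np.ndarray
    score_gain: int
    strand: str
    read_span: tuple[int, int]
    ref_span: tuple[int, int]
    seq_id: int

    def __len__(self) -> int:
        return self.indices.size


def _chain_u(anchors: AnchorSet) -> np.ndarray:
    # read-axis DP coordinate: pr for same-orientation anchors, -pr for
    # opposite-orientation ones (anti-diagonal progression).
    return np.where(anchors.same_orientation(), anchors.pr, -anchors.pr)


def chain_scores(anchors: AnchorSet, d: int) -> ChainScores:
    """Run the chaining DP over anchors sorted by (seq_id, pg, pr)."""
    if not anchors.is_sorted():
        raise ValueError("anchors must be sorted by (seq_id, pg, pr)")
    n = len(anchors)
    if n == 0:
        z = np.empty(0, dtype=np.int64)
        return ChainScores(z, z.copy())
    group = anchors.dr * 2 + anchors.dg
    u = _chain_u(anchors)
    score, pred = chain_dp(anchors.seq_id, group, u, anchors.pg,
                           np.int64(d))
    return ChainScores(score, pred)


def _trace(pred: np.ndarray, end: int) -> np.ndarray:
    path = [end]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return np.asarray(path[::-1], dtype=np.int64)


def _make_chain(anchors: AnchorSet, idx: np.ndarray, k: int,
                score_gain: int) -> Chain:
    prs = anchors.pr[idx]
    pgs = anchors.pg[idx]
    strand = "+" if anchors.dr[idx[0]] == anchors.dg[idx[0]] else "-"
    return Chain(
        indices=idx,
        score_gain=score_gain,
        strand=strand,
        read_span=(int(prs.min()), int(prs.max()) + k),
        ref_span=(int(pgs.min()), int(pgs.max()) + k),
        seq_id=int(anchors.seq_id[idx[0]]),
    )


def best_chain(anchors: AnchorSet, scores: ChainScores,
               k: int = 15) -> Chain | None:
    """Extract the chain with the maximal score increase.

    Returns None for an empty anchor set (the read is unmapped). Ties on
    the score break to the smallest reference span start, then the
    smallest read span start.
    """
    if len(anchors) == 0:
        return None
    s = scores.score
    smax = int(s.max())
    ends = np.nonzero(s == smax)[0]
    best: Chain | None = None
    for end in ends:
        idx = _trace(scores.pred, int(end))
        cand = _make_chain(anchors, idx, k, smax - 1)
        if best is None or (cand.ref_span[0], cand.read_span[0]) < (
                best.ref_span[0], best.read_span[0]):
            best = cand
        # equal keys cannot occur: chains are distinguished by their spans
    return best
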