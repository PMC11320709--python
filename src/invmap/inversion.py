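"""Inversion discovery: region extension, anchor transform, re-chaining.

After the main chain is fixed, anchors left inside (an extension of) the
aligned region are linearized by mirroring the read coordinate of every
opposite-orientation anchor: mpr = len(read) - pr, mpg = pg. Anchors from
an exactly inverted block are anti-diagonal in (pr, pg) but co-linear in
(mpr, mpg), so the ordinary chaining DP finds them. A residual chain whose
anchors all carry the '-' orientation, with at least ``min_anchors``
anchors and both read and reference spans strictly longer than
``min_span`` bases, is reported as an inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._kernels import chain_dp
from .anchors import AnchorSet
from .chain import Chain

#: aligned-region extension factor and the minimum unchained read flank
#: (in bp) that triggers the extension.
EXTEND_FACTOR = 1.2
MIN_FLANK = 50

#: inversion acceptance thresholds: anchors per chain and span in bp
#: (exclusive, i.e. spans must exceed MIN_INV_SPAN).
MIN_INV_ANCHORS = 3
MIN_INV_SPAN = 50

#: safety cap on chain-and-remove iterations per read
MAX_INV_ROUNDS = 5


@dataclass
class AlignedRegion:
    """Reference interval covered by the main chain, plus its extension."""

    seq_id: int
    p_start: int
    p_end: int
    ext_start: int
    ext_end: int

    def __post_init__(self) -> None:
        assert self.ext_start <= self.p_start <= self.p_end <= self.ext_end


def locate_region(main: Chain, read_len: int, refseq_len: int,
                  extend_factor: float = EXTEND_FACTOR,
                  min_flank: int = MIN_FLANK) -> AlignedRegion:
    """Locate and extend the reference region covered by the main chain.

    If the read prefix before the first chained base is longer than
    ``min_flank`` bp, the region start moves left by
    ceil(extend_factor * prefix_len) (clamped to the sequence) so anchors
    of a boundary inversion fall inside the region; the read suffix extends
    the region end symmetrically. For reverse-orientation main chains the
    read prefix lies beyond the region *end*, so the roles swap.
    """
    if len(main) == 0:
        raise ValueError("main chain is empty")
    p_start, p_end = main.ref_span
    pre = main.read_span[0]
    suf = read_len - main.read_span[1]
    left, right = (pre, suf) if main.strand == "+" else (suf, pre)
    ext_start = p_start
    ext_end = p_end
    if left > min_flank:
        ext_start = max(0, p_start - math.ceil(extend_factor * left))
    if right > min_flank:
        ext_end = min(refseq_len, p_end + math.ceil(extend_factor * right))
    return AlignedRegion(main.seq_id, p_start, p_end, ext_start, ext_end)


class TransformedAnchor(NamedTuple):
    mpr: int
    mpg: int
    r: str


class TransformedAnchors:
    """Transformed residual anchors with their original coordinates kept.

    Sorted by (mpg, mpr); ``neg`` marks '-' orientation (dr != dg).
    """

    __slots__ = ("mpr", "mpg", "neg", "pr", "pg", "seq_id")

    def __init__(self, mpr, mpg, neg, pr, pg, seq_id):
        order = np.lexsort((mpr, mpg))
        self.mpr = np.asarray(mpr, dtype=np.int64)[order]
        self.mpg = np.asarray(mpg, dtype=np.int64)[order]
        self.neg = np.asarray(neg, dtype=bool)[order]
        self.pr = np.asarray(pr, dtype=np.int64)[order]
        self.pg = np.asarray(pg, dtype=np.int64)[order]
        self.seq_id = np.asarray(seq_id, dtype=np.int64)[order]

    def __len__(self) -> int:
        return self.mpr.size

    def __getitem__(self, i: int) -> TransformedAnchor:
        return TransformedAnchor(int(self.mpr[i]), int(self.mpg[i]),
                                 "-" if self.neg[i] else "+")

    def take(self, idx) -> "TransformedAnchors":
        idx = np.asarray(idx)
        return TransformedAnchors(self.mpr[idx], self.mpg[idx],
                                  self.neg[idx], self.pr[idx], self.pg[idx],
                                  self.seq_id[idx])


def transform_anchors(residual: AnchorSet, read_len: int,
                      main_strand: str = "+") -> TransformedAnchors:
    """Mirror the read coordinate of anchors opposing the main chain.

    With a forward main chain, same-orientation anchors keep mpr = pr with
    r = '+' and opposite-orientation anchors get mpr = read_len - pr with
    r = '-'; the reference coordinate is unchanged. When the main chain is
    itself reverse-oriented the whole picture is mirrored, so the roles
    swap: anchors matching the main chain's orientation keep r = '+' and
    get the mirrored coordinate, while anchors opposing it (candidate
    inversions) are labelled '-'. Either way a '-' chain runs against the
    main chain and ends up jointly monotone in (mpr, mpg). The transform
    is an involution on '-' anchors: applying it twice restores pr.
    """
    same = residual.same_orientation()
    rel_same = same if main_strand == "+" else ~same
    # absolute-opposite anchors are mirrored in both cases; only the
    # '-' label is relative to the main chain's orientation
    mpr = np.where(same, residual.pr, read_len - residual.pr)
    return TransformedAnchors(mpr, residual.pg, ~rel_same, residual.pr,
                              residual.pg, residual.seq_id)


@dataclass
class InversionCall:
    """One detected inversion: the quadruple plus its supporting chain."""

    seq_id: int
    ps_ref: int
    pe_ref: int
    ps_read: int
    pe_read: int
    n_anchors: int
    score_gain: int
    # supporting anchors in original coordinates, ordered by pg
    pr: np.ndarray = field(repr=False, default=None)
    pg: np.ndarray = field(repr=False, default=None)
    strand: str = "-"


def find_inversion_chains(residual_t: TransformedAnchors, d: int, k: int,
                          min_anchors: int = MIN_INV_ANCHORS,
                          min_span: int = MIN_INV_SPAN,
                          max_rounds: int = MAX_INV_ROUNDS) -> list[InversionCall]:
    """Chain-and-remove over transformed residual anchors.

    Repeatedly runs the chaining DP on the remaining transformed anchors
    (orientation uniformity enforced through the DP's group key) and takes
    the best chain. A chain of all-'-' anchors with >= min_anchors anchors
    and both spans > min_span becomes an InversionCall; any extracted
    chain's anchors are removed before the next round. Uniform-'+' chains
    (duplication-like signals) are discarded unclassified. Stops when the
    best chain is too small to ever qualify or after ``max_rounds``.
    """
    calls: list[InversionCall] = []
    cur = residual_t
    for _ in range(max_rounds):
        n = len(cur)
        if n == 0:
            break
        group = cur.neg.astype(np.int64)
        score, pred = chain_dp(cur.seq_id, group, cur.mpr, cur.mpg,
                               np.int64(d))
        smax = int(score.max())
        if smax < min_anchors:
            break  # no remaining chain can qualify
        end = int(np.nonzero(score == smax)[0][0])
        path = [end]
        while pred[path[-1]] >= 0:
            path.append(int(pred[path[-1]]))
        idx = np.asarray(path[::-1], dtype=np.int64)
        sub = cur.take(idx)
        if bool(sub.neg.all()):
            ps_ref = int(sub.mpg[0])
            pe_ref = int(sub.mpg[-1]) + k
            ps_read = int(sub.pr.min())
            pe_read = int(sub.pr.max()) + k
            ref_ok = (pe_ref - ps_ref) > min_span
            read_ok = (pe_read - ps_read) > min_span
            disjoint = all(pe_ref <= c.ps_ref or ps_ref >= c.pe_ref
                           for c in calls)
            if len(idx) >= min_anchors and ref_ok and read_ok and disjoint:
                order = np.argsort(sub.pg)
                calls.append(InversionCall(
                    seq_id=int(sub.seq_id[0]),
                    ps_ref=ps_ref, pe_ref=pe_ref,
                    ps_read=ps_read, pe_read=pe_read,
                    n_anchors=int(len(idx)), score_gain=smax - 1,
                    pr=sub.pr[order], pg=sub.pg[order]))
        keep = np.setdiff1d(np.arange(n), idx, assume_unique=True)
        cur = cur.take(keep)
    return calls
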