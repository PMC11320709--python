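"""Anchor extraction: read minimizers looked up in the reference index.

An anchor is one exact k-mer match between read and reference, the 4-tuple
(pr, pg, dr, dg): start on the read (forward read orientation), start on the
reference forward strand, and a strand bit for each side. Only the predicate
``dr == dg`` ("same orientation") is consumed downstream; a match of the
read k-mer's reverse complement to the reference forward strand is encoded
dr=0, dg=1.
"""

from __future__ import annotations

from typing import Iterator, NamedTuple

import numpy as np

from .index import MinimizerIndex, minimizers


class Anchor(NamedTuple):
    pr: int
    pg: int
    dr: int
    dg: int
    seq_id: int = 0


class AnchorSet:
    """Column-array container for anchors, sorted by (seq_id, pg, pr, dr).

    Iterating yields :class:`Anchor` tuples; the columns (``pr``, ``pg``,
    ``dr``, ``dg``, ``seq_id``) are int64 arrays shared with the chaining
    kernels.
    """

    __slots__ = ("pr", "pg", "dr", "dg", "seq_id")

    def __init__(self, pr, pg, dr, dg, seq_id, *, presorted: bool = False):
        self.pr = np.asarray(pr, dtype=np.int64)
        self.pg = np.asarray(pg, dtype=np.int64)
        self.dr = np.asarray(dr, dtype=np.int64)
        self.dg = np.asarray(dg, dtype=np.int64)
        self.seq_id = np.asarray(seq_id, dtype=np.int64)
        if not presorted and len(self) > 1:
            order = np.lexsort((self.dr, self.pr, self.pg, self.seq_id))
            for name in self.__slots__:
                setattr(self, name, getattr(self, name)[order])

    @classmethod
    def from_anchors(cls, anchors: list[Anchor]) -> "AnchorSet":
        if not anchors:
            return cls.empty()
        a = np.asarray(anchors, dtype=np.int64)
        return cls(a[:, 0], a[:, 1], a[:, 2], a[:, 3], a[:, 4])

    @classmethod
    def empty(cls) -> "AnchorSet":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z, z, z, z, presorted=True)

    def __len__(self) -> int:
        return self.pr.size

    def __getitem__(self, i: int) -> Anchor:
        return Anchor(int(self.pr[i]), int(self.pg[i]), int(self.dr[i]),
                      int(self.dg[i]), int(self.seq_id[i]))

    def __iter__(self) -> Iterator[Anchor]:
        for i in range(len(self)):
            yield self[i]

    def take(self, idx) -> "AnchorSet":
        idx = np.asarray(idx)
        return AnchorSet(self.pr[idx], self.pg[idx], self.dr[idx],
                         self.dg[idx], self.seq_id[idx], presorted=False)

    def same_orientation(self) -> np.ndarray:
        return self.dr == self.dg

    def is_sorted(self) -> bool:
        if len(self) < 2:
            return True
        ds, dg, dp = (np.diff(self.seq_id), np.diff(self.pg), np.diff(self.pr))
        ok = (ds > 0) | ((ds == 0) & ((dg > 0) | ((dg == 0) & (dp >= 0))))
        return bool(np.all(ok))


def collect_anchors(read: str, index: MinimizerIndex) -> AnchorSet:
    """Match the read's minimizers against the index and return all anchors.

    The read is sampled with the same (k, w, hash) scheme as the reference,
    so wherever both sides selected the same minimizer an exact-match anchor
    is produced. Anchors come back sorted by (seq_id, pg, pr). A read
    shorter than k yields an empty set.
    """
    if len(read) < index.k:
        return AnchorSet.empty()
    pos, keys, strand = minimizers(read, index.k, index.w)
    prs, pgs, drs, dgs, sids = [], [], [], [], []
    for p, key, zr in zip(pos.tolist(), keys.tolist(), strand.tolist()):
        hits = index.lookup(key)
        if hits is None:
            continue
        n = hits.shape[0]
        prs.append(np.full(n, p, dtype=np.int64))
        pgs.append(hits[:, 1])
        sids.append(hits[:, 0])
        same = hits[:, 2] == zr
        # same canonical strand on both sides -> forward/forward match
        drs.append(np.where(same, 1, 0).astype(np.int64))
        dgs.append(np.ones(n, dtype=np.int64))
    if not prs:
        return AnchorSet.empty()
    return AnchorSet(np.concatenate(prs), np.concatenate(pgs),
                     np.concatenate(drs), np.concatenate(dgs),
                     np.concatenate(sids))
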