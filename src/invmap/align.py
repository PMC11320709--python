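"""Base-level alignment: partition by chains, gap filling, record stitching.

The chains decide the skeleton: every anchor contributes an exact-match
segment, consecutive anchors enclose a read/reference gap pair that is
filled by affine-gap global alignment, and the read's unchained prefix and
suffix are paired with reference windows inside the extended region and
aligned with the distal reference end free. A read with inversions is
separated into parts - the main-chain flanks and each inverted block - and
every part becomes one SAM-style record; internal soft clips do not exist
in SAM, so a middle inversion necessarily splits the main chain's record.

All read coordinates below are *record-frame* coordinates: the orientation
in which the record stores the sequence (the read itself, or its reverse
complement when the part aligns to the reverse strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import OP_DEL, OP_EQ, OP_INS, OP_X, gotoh
from .anchors import AnchorSet
from .chain import Chain
from .inversion import AlignedRegion, InversionCall
from .io import encode

Cigar = list[tuple[str, int]]

_OPCHR = {OP_EQ: "=", OP_X: "X", OP_INS: "I", OP_DEL: "D"}
_QRY_OPS = frozenset("=XIMS")
_REF_OPS = frozenset("=XMD")


@dataclass
class ScoringParams:
    """Alignment scoring and banding policy.

    Gap of length L costs ``gap_open + L * gap_extend``. Segments longer
    than ``band_threshold`` use a diagonal band of half-width
    ``max(min_band, band_frac * seglen) + |length difference|``; shorter
    segments get a full DP. ``boundary_slack`` pairs a boundary read flank
    of length L with ceil(boundary_slack * L) reference bases, matching the
    15% error allowance of the chaining distance bound.
    """

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    band_threshold: int = 1000
    band_frac: float = 0.15
    min_band: int = 64
    boundary_slack: float = 1.15
    min_boundary_identity: float = 0.30
    seg_cap: int = 20000


@dataclass
class PairedSegment:
    """One read/reference subsequence pair awaiting base-level alignment."""

    read_iv: tuple[int, int]
    ref_iv: tuple[int, int]
    kind: str  # anchor-match | inner-gap | boundary-prefix | boundary-suffix
    orientation: str = "+"


@dataclass
class SegmentAlignment:
    """CIGAR-level alignment of one paired segment."""

    cigar: Cigar
    score: int
    read_iv: tuple[int, int]
    ref_iv: tuple[int, int]

    def __post_init__(self) -> None:
        q = sum(n for op, n in self.cigar if op in _QRY_OPS)
        r = sum(n for op, n in self.cigar if op in _REF_OPS)
        assert q == self.read_iv[1] - self.read_iv[0], "query length mismatch"
        assert r == self.ref_iv[1] - self.ref_iv[0], "reference length mismatch"


@dataclass
class Part:
    """One prospective SAM record: a main-chain flank or an inverted block.

    ``record_rev`` says whether the record stores the reverse complement of
    the read; segment read intervals are in that orientation's coordinates.
    """

    kind: str  # 'main' | 'inversion'
    seq_id: int
    record_rev: bool
    segments: list[PairedSegment] = field(default_factory=list)
    call: InversionCall | None = None


def _merge_cigar(cig: Cigar) -> Cigar:
    out: Cigar = []
    for op, n in cig:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def align_gap(read_seg: str, ref_seg: str, params: ScoringParams | None = None,
              *, free_ref_start: bool = False,
              free_ref_end: bool = False) -> SegmentAlignment:
    """Optimal affine-gap global alignment of one segment pair.

    Empty read against ref becomes all-D, empty ref against read all-I,
    empty-vs-empty an empty alignment of score 0. With a free reference
    end the unaligned reference bases are trimmed from ``ref_iv`` rather
    than emitted as deletions.
    """
    params = params or ScoringParams()
    n, m = len(read_seg), len(ref_seg)
    if max(n, m) > params.seg_cap:
        raise ValueError(f"segment longer than cap ({params.seg_cap})")
    if n == 0 and m == 0:
        return SegmentAlignment([], 0, (0, 0), (0, 0))
    if n == 0:
        if free_ref_start or free_ref_end:
            return SegmentAlignment([], 0, (0, 0), (0, 0))
        return SegmentAlignment([("D", m)], params.gap_open + m * params.gap_extend,
                                (0, 0), (0, m))
    if m == 0:
        return SegmentAlignment([("I", n)], params.gap_open + n * params.gap_extend,
                                (0, n), (0, 0))
    if max(n, m) > params.band_threshold:
        band = max(params.min_band, int(params.band_frac * max(n, m)))
    else:
        band = max(n, m)
    score, ops, n_ops, j0, j1 = gotoh(
        encode(read_seg), encode(ref_seg),
        np.int64(params.match), np.int64(params.mismatch),
        np.int64(params.gap_open), np.int64(params.gap_extend),
        np.int64(band), free_ref_start, free_ref_end)
    cig = _merge_cigar([(_OPCHR[int(o)], 1) for o in ops[:n_ops]])
    return SegmentAlignment(cig, int(score), (0, n), (j0, j1))


def _identity(cigar: Cigar) -> float:
    cols = sum(n for op, n in cigar if op in "=XID")
    eq = sum(n for op, n in cigar if op == "=")
    return eq / cols if cols else 0.0


def partition(main: Chain, anchors: AnchorSet, invs: list[InversionCall],
              region: AlignedRegion, read_len: int, k: int,
              params: ScoringParams | None = None) -> list[Part]:
    """Partition the read and local reference into alignable parts.

    ``invs`` must be mutually disjoint and compatible with the main chain
    (each inversion's read interval falls strictly between two consecutive
    main-chain anchors, or beyond the chain's ends); the mapper filters
    calls before handing them over. Returns the ordered parts whose
    segments tile the aligned portions of the read; read bases that no
    part covers end up soft-clipped.
    """
    params = params or ScoringParams()
    rev = main.strand == "-"
    L = read_len

    def frame(pr: int) -> int:
        return L - pr - k if rev else pr

    mq = np.sort(np.array([frame(int(p)) for p in anchors.pr[main.indices]]))
    mg = np.sort(anchors.pg[main.indices])
    # frame read intervals of the inversions, sorted along the frame read
    items = []
    for call in invs:
        fs, fe = ((L - call.pe_read, L - call.ps_read) if rev
                  else (call.ps_read, call.pe_read))
        items.append((fs, fe, call))
    items.sort()
    for (_, e1, _), (s2, _, _) in zip(items, items[1:]):
        if s2 < e1:
            raise ValueError("overlapping inversion calls")

    # split main anchors into groups separated by the inversion intervals
    groups: list[np.ndarray] = []
    cuts = [fs for fs, _, _ in items]
    start = 0
    for fs in cuts:
        endi = int(np.searchsorted(mq, fs))
        groups.append(np.arange(start, endi))
        start = endi
    groups.append(np.arange(start, mq.size))

    parts: list[Part] = []
    for gi, grp in enumerate(groups):
        left_call = items[gi - 1][2] if gi > 0 else None
        right_call = items[gi][2] if gi < len(items) else None
        if grp.size:
            part = Part("main", main.seq_id, rev)
            q = mq[grp]
            g = mg[grp]
            # leading gap
            if left_call is None:
                pre = int(q[0])
                if pre > 0:
                    w = min(int(np.ceil(params.boundary_slack * pre)),
                            int(g[0]) - region.ext_start)
                    part.segments.append(PairedSegment(
                        (0, pre), (int(g[0]) - max(w, 0), int(g[0])),
                        "boundary-prefix"))
            else:
                lr = (items[gi - 1][1], int(q[0]))
                lg = (left_call.pe_ref, int(g[0]))
                if lr[1] > lr[0] or lg[1] > lg[0]:
                    part.segments.append(PairedSegment(lr, lg, "inner-gap"))
            _anchor_walk(part, q, g, k)
            # trailing gap
            if right_call is None:
                er, eg = int(q[-1]) + k, int(g[-1]) + k
                suf = L - er
                if suf > 0:
                    w = min(int(np.ceil(params.boundary_slack * suf)),
                            region.ext_end - eg)
                    part.segments.append(PairedSegment(
                        (er, L), (eg, eg + max(w, 0)), "boundary-suffix"))
            else:
                tr = (int(q[-1]) + k, items[gi][0])
                tg = (int(g[-1]) + k, right_call.ps_ref)
                if tr[1] > tr[0] or tg[1] > tg[0]:
                    part.segments.append(PairedSegment(tr, tg, "inner-gap"))
            parts.append(part)
        if gi < len(items):
            call = items[gi][2]
            ipart = Part("inversion", call.seq_id, not rev, call=call)
            # anchor coordinates in the inversion record's own frame
            iq = np.sort(np.array([pr if rev else L - pr - k
                                   for pr in call.pr.tolist()]))
            ig = np.sort(call.pg)
            _anchor_walk(ipart, iq, ig, k, orientation="-")
            parts.append(ipart)
    return parts


def _anchor_walk(part: Part, q: np.ndarray, g: np.ndarray, k: int,
                 orientation: str = "+") -> None:
    """Emit anchor-match and inner-gap segments for co-linear anchors."""
    cur_r, cur_g = int(q[0]), int(g[0])
    for ar, ag in zip(q.tolist(), g.tolist()):
        clip = max(cur_r - ar, cur_g - ag, 0)
        sr, sg = ar + clip, ag + clip
        if sr >= ar + k:
            continue  # anchor swallowed by the previous one
        if sr > cur_r or sg > cur_g:
            part.segments.append(PairedSegment(
                (cur_r, sr), (cur_g, sg), "inner-gap", orientation))
        part.segments.append(PairedSegment(
            (sr, ar + k), (sg, ag + k), "anchor-match", orientation))
        cur_r, cur_g = ar + k, ag + k


@dataclass
class SamRecord:
    """A minimal SAM record; conversion to pysam happens at write time."""

    qname: str
    flag: int
    seq_id: int
    pos: int  # 0-based leftmost reference position
    mapq: int
    cigar: Cigar
    seq: str
    tags: dict = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 4)

    @property
    def ref_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS)

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"


@dataclass
class ReadMapping:
    """All records and inversion calls produced for one read."""

    qname: str
    records: list[SamRecord]
    calls: list[InversionCall]

    @property
    def is_unmapped(self) -> bool:
        return not self.records or self.records[0].is_unmapped


def _align_part(part: Part, record_read: str, refseq: str,
                params: ScoringParams) -> tuple[Cigar, int, int, int, int] | None:
    """Align a part's segments; returns (cigar, ref_start, read_start,
    read_end, score) in record-frame coordinates, or None if nothing
    aligned."""
    cig: Cigar = []
    ref_start = None
    read_start = None
    read_end = None
    total = 0
    for seg in part.segments:
        rs, re_ = seg.read_iv
        gs, ge = seg.ref_iv
        if seg.kind == "anchor-match":
            sa = SegmentAlignment([("=", re_ - rs)], (re_ - rs) * params.match,
                                  (0, re_ - rs), (0, ge - gs))
            gs_eff, ge_eff = gs, ge
        else:
            free_s = seg.kind == "boundary-prefix"
            free_e = seg.kind == "boundary-suffix"
            if ge - gs <= 0 and (free_s or free_e) and re_ - rs > 0:
                # no reference window at all: the flank is soft-clipped
                continue
            sa = align_gap(record_read[rs:re_], refseq[gs:ge], params,
                           free_ref_start=free_s, free_ref_end=free_e)
            if (free_s or free_e) and re_ - rs > 0:
                if _identity(sa.cigar) < params.min_boundary_identity:
                    continue  # garbage boundary: soft clip instead
            gs_eff = gs + sa.ref_iv[0]
            ge_eff = gs + sa.ref_iv[1]
        if re_ - rs == 0 and not sa.cigar:
            continue
        if read_start is None:
            read_start = rs
            ref_start = gs_eff
        read_end = re_
        total += sa.score
        cig.extend(sa.cigar)
    if read_start is None:
        return None
    cig = _merge_cigar(cig)
    # a record must not begin or end with a deletion: shift pos instead
    while cig and cig[0][0] == "D":
        ref_start += cig.pop(0)[1]
    while cig and cig[-1][0] == "D":
        cig.pop()
    if not cig:
        return None
    return cig, ref_start, read_start, read_end, total


def stitch(parts: list[Part], read: str, read_rc: str, refseqs: list[str],
           qname: str, mapq: int,
           params: ScoringParams | None = None) -> list[SamRecord]:
    """Align every part and assemble the per-part SAM records.

    The primary record is the main-chain part covering the most read
    bases; every other part becomes a supplementary record (flag 2048)
    with the strand bit reflecting its own orientation. SA tags
    cross-reference the records. Query-consuming CIGAR lengths (soft clips
    included) sum to the read length on every record.
    """
    params = params or ScoringParams()
    L = len(read)
    aligned = []
    for part in parts:
        record_read = read_rc if part.record_rev else read
        res = _align_part(part, record_read, refseqs[part.seq_id], params)
        if res is None:
            continue
        cig, ref_start, rs, re_, score = res
        full: Cigar = []
        if rs > 0:
            full.append(("S", rs))
        full.extend(cig)
        if L - re_ > 0:
            full.append(("S", L - re_))
        nm = sum(n for op, n in cig if op in "XID")
        rec = SamRecord(qname=qname, flag=16 if part.record_rev else 0,
                        seq_id=part.seq_id, pos=ref_start, mapq=mapq,
                        cigar=full, seq=record_read,
                        tags={"NM": nm, "AS": score})
        q = sum(n for op, n in full if op in _QRY_OPS)
        assert q == L, f"CIGAR consumes {q} of {L} read bases"
        aligned.append((part, rec))
    if not aligned:
        return []
    main_order = sorted(
        range(len(aligned)),
        key=lambda i: (aligned[i][0].kind != "main",
                       -(sum(n for op, n in aligned[i][1].cigar
                             if op in "=XIM"))))
    primary = main_order[0]
    for i, (part, rec) in enumerate(aligned):
        if i != primary:
            rec.flag |= 2048
    return [rec for _, rec in aligned]
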