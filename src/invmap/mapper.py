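"""Per-read mapping pipeline and SAM/BED output.

``map_read`` runs the full pipeline for one read: anchor collection,
main-chain DP, aligned-region extension, residual-anchor transform and
re-chaining for inversions, partition into parts, base-level gap
alignment, and record stitching. Reads are independent of each other, so
``map_reads`` is a plain deterministic loop in input order.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pysam

from . import __version__
from .align import ReadMapping, SamRecord, ScoringParams, partition, stitch
from .anchors import AnchorSet, collect_anchors
from .chain import Chain, best_chain, chain_scores, compute_d
from .index import MinimizerIndex
from .inversion import (MAX_INV_ROUNDS, MIN_INV_ANCHORS, MIN_INV_SPAN,
                        InversionCall, find_inversion_chains, locate_region,
                        transform_anchors)
from .io import revcomp


@dataclass
class RunConfig:
    """All mapper knobs; the defaults are the method's printed constants."""

    k: int = 15
    w: int = 5
    max_occ: int = 500
    d_factor: float = 1.15
    extend_factor: float = 1.2
    min_flank: int = 50
    min_inv_anchors: int = MIN_INV_ANCHORS
    min_inv_span: int = MIN_INV_SPAN
    max_inv_rounds: int = MAX_INV_ROUNDS
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def command_line(self) -> str:
        s = self.scoring
        return (f"invmap k={self.k} w={self.w} max_occ={self.max_occ} "
                f"d_factor={self.d_factor} extend_factor={self.extend_factor} "
                f"min_inv_anchors={self.min_inv_anchors} "
                f"min_inv_span={self.min_inv_span} "
                f"scores={s.match},{s.mismatch},{s.gap_open},{s.gap_extend}")


def _frame(pr: int, read_len: int, k: int, rev: bool) -> int:
    return read_len - pr - k if rev else pr


def _filter_calls(calls: list[InversionCall], main: Chain,
                  anchors: AnchorSet, read_len: int, k: int,
                  min_anchors: int, min_span: int) -> list[InversionCall]:
    """Keep only calls compatible with the main chain geometry.

    A call must sit inside a single main-chain gap on both the read (in
    main-chain frame coordinates) and the reference. Chance k-mer matches
    crossing an inversion breakpoint can make a raw call protrude a few
    bases into the flanking main-chain anchors, so supporting anchors are
    first trimmed to the enclosing gap and the quadruple is recomputed;
    the call survives if it still meets the anchor-count and span rules.
    Accepted calls must be mutually disjoint on both axes. Calls are
    considered in descending score order, ties to the leftmost reference
    start.
    """
    rev = main.strand == "-"
    mq = np.sort(np.array([_frame(int(p), read_len, k, rev)
                           for p in anchors.pr[main.indices]]))
    mg = np.sort(anchors.pg[main.indices])
    kept: list[InversionCall] = []
    occupied: list[tuple[int, int]] = []
    for call in sorted(calls, key=lambda c: (-c.score_gain, c.ps_ref)):
        if call.seq_id != main.seq_id:
            continue
        q = np.array([_frame(int(p), read_len, k, rev) for p in call.pr])
        # locate the enclosing main-chain gap by the call's median anchor
        i1 = int(np.searchsorted(mq, int(np.median(q))))
        i2 = int(np.searchsorted(mg, int(np.median(call.pg))))
        if i1 != i2:
            continue  # read gap and reference gap disagree
        lo_q = int(mq[i1 - 1]) + k if i1 > 0 else 0
        lo_g = int(mg[i1 - 1]) + k if i1 > 0 else 0
        hi_q = int(mq[i1]) if i1 < mq.size else read_len
        hi_g = int(mg[i1]) if i1 < mg.size else np.iinfo(np.int64).max
        fit = ((q >= lo_q) & (q + k <= hi_q)
               & (call.pg >= lo_g) & (call.pg + k <= hi_g))
        if int(fit.sum()) < min_anchors:
            continue
        pr, pg = call.pr[fit], call.pg[fit]
        ps_ref, pe_ref = int(pg.min()), int(pg.max()) + k
        ps_read, pe_read = int(pr.min()), int(pr.max()) + k
        if pe_ref - ps_ref <= min_span or pe_read - ps_read <= min_span:
            continue
        fs, fe = ((read_len - pe_read, read_len - ps_read) if rev
                  else (ps_read, pe_read))
        ok = all(fe <= s or fs >= e for s, e in occupied)
        ok = ok and all(pe_ref <= c.ps_ref or ps_ref >= c.pe_ref
                        for c in kept)
        if not ok:
            continue
        occupied.append((fs, fe))
        kept.append(replace(call, ps_ref=ps_ref, pe_ref=pe_ref,
                            ps_read=ps_read, pe_read=pe_read,
                            n_anchors=int(fit.sum()), pr=pr, pg=pg))
    return kept


def _mapq(main: Chain, scores, n_anchors: int) -> int:
    if len(main) <= 1:
        return 0
    off = np.ones(n_anchors, dtype=bool)
    off[main.indices] = False
    second = int(scores.score[off].max()) - 1 if off.any() else 0
    second = max(second, 0)
    q = 60.0 * (1.0 - second / main.score_gain)
    return int(np.clip(round(q), 0, 60))


def map_read(name: str, read: str, index: MinimizerIndex,
             config: RunConfig | None = None,
             refseqs: list[str] | None = None) -> ReadMapping:
    """Map one read; returns its records and inversion calls.

    ``refseqs`` (the reference sequences, in index order) must be supplied
    for base-level alignment; the index alone carries only k-mer hits.
    """
    config = config or RunConfig()
    if refseqs is None:
        raise ValueError("refseqs required for base-level alignment")
    k = index.k
    unmapped = SamRecord(qname=name, flag=4, seq_id=-1, pos=-1, mapq=0,
                         cigar=[], seq=read)
    anchors = collect_anchors(read, index)
    if len(anchors) == 0:
        return ReadMapping(name, [unmapped], [])
    d = compute_d(len(read), config.d_factor)
    scores = chain_scores(anchors, d)
    main = best_chain(anchors, scores, k)
    region = locate_region(main, len(read), index.lengths[main.seq_id],
                           config.extend_factor, config.min_flank)
    on_main = np.zeros(len(anchors), dtype=bool)
    on_main[main.indices] = True
    in_region = ((anchors.seq_id == region.seq_id)
                 & (anchors.pg >= region.ext_start)
                 & (anchors.pg < region.ext_end))
    residual = anchors.take(np.nonzero(~on_main & in_region)[0])
    calls: list[InversionCall] = []
    if len(residual):
        transformed = transform_anchors(residual, len(read), main.strand)
        raw = find_inversion_chains(transformed, d, k,
                                    config.min_inv_anchors,
                                    config.min_inv_span,
                                    config.max_inv_rounds)
        calls = _filter_calls(raw, main, anchors, len(read), k,
                              config.min_inv_anchors, config.min_inv_span)
    parts = partition(main, anchors, calls, region, len(read), k,
                      config.scoring)
    mapq = _mapq(main, scores, len(anchors))
    records = stitch(parts, read, revcomp(read), refseqs, name, mapq,
                     config.scoring)
    if not records:
        return ReadMapping(name, [unmapped], [])
    _add_sa_tags(records, index.names)
    return ReadMapping(name, records, calls)


def _add_sa_tags(records: list[SamRecord], names: list[str]) -> None:
    if len(records) < 2:
        return
    def sa_entry(r: SamRecord) -> str:
        strand = "-" if r.flag & 16 else "+"
        return (f"{names[r.seq_id]},{r.pos + 1},{strand},"
                f"{r.cigar_string()},{r.mapq},{r.tags.get('NM', 0)}")
    for i, r in enumerate(records):
        others = ";".join(sa_entry(o) for j, o in enumerate(records) if j != i)
        r.tags["SA"] = others + ";"


def sam_header(index: MinimizerIndex, config: RunConfig) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln}
               for n, ln in zip(index.names, index.lengths)],
        "PG": [{"ID": "invmap", "PN": "invmap", "VN": __version__,
                "CL": config.command_line()}],
    })


def to_pysam(rec: SamRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = rec.qname
    a.flag = rec.flag
    a.query_sequence = rec.seq
    if rec.is_unmapped:
        a.reference_id = -1
        a.reference_start = -1
        a.mapping_quality = 0
    else:
        a.reference_id = rec.seq_id
        a.reference_start = rec.pos
        a.mapping_quality = rec.mapq
        a.cigarstring = rec.cigar_string()
        a.set_tags(sorted(rec.tags.items()))
    return a


def map_reads(reads: Iterable[tuple[str, str]], index: MinimizerIndex,
              refseqs: list[str], config: RunConfig | None = None,
              sam_out: TextIO | str | Path | None = None,
              bed_out: TextIO | str | Path | None = None) -> list[ReadMapping]:
    """Map reads in order, optionally streaming SAM and inversion BED.

    The BED is a BED6-like TSV: ref name, PS_ref, PE_ref, read name,
    n_anchors, strand '-', plus two extra columns PS_read, PE_read so the
    evaluation's double-overlap test is self-contained.
    """
    config = config or RunConfig()
    header = sam_header(index, config)
    mappings: list[ReadMapping] = []

    def run(sam_fh: TextIO | None, bed_fh: TextIO | None) -> None:
        if sam_fh is not None:
            sam_fh.write(str(header))
        for name, seq in reads:
            rm = map_read(name, seq, index, config, refseqs)
            mappings.append(rm)
            if sam_fh is not None:
                for rec in rm.records:
                    sam_fh.write(to_pysam(rec, header).to_string() + "\n")
            if bed_fh is not None:
                for c in rm.calls:
                    bed_fh.write(f"{index.names[c.seq_id]}\t{c.ps_ref}\t"
                                 f"{c.pe_ref}\t{name}\t{c.n_anchors}\t-\t"
                                 f"{c.ps_read}\t{c.pe_read}\n")

    sam_fh, close_sam = _open_out(sam_out)
    bed_fh, close_bed = _open_out(bed_out)
    try:
        run(sam_fh, bed_fh)
    finally:
        if close_sam:
            sam_fh.close()
        if close_bed:
            bed_fh.close()
    return mappings


def _open_out(out):
    if out is None:
        return None, False
    if isinstance(out, (str, Path)):
        if str(out) == "-":
            return sys.stdout, False
        return open(out, "w"), True
    return out, False
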