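"""Evaluation metrics: location accuracy and inversion recovery.

Location accuracy: a read counts as correctly located when its primary
record maps to the true strand and the union of its aligned reference
intervals (primary + supplementary records on the true sequence; clipped
and unaligned portions excluded) overlaps at least 90% of the length of
the true interval. Unmapped reads stay in the denominator.

Inversion recovery: a predicted quadruple (PS_ref, PE_ref, PS_read,
PE_read) is correct when it shares at least one base with a ground-truth
quadruple of the same read on *both* the reference axis and the read
axis. Sensitivity is correctly recovered truths over all truths;
precision is correct predictions over all predictions (reported as 0
with a degenerate flag when nothing was predicted). A truth recovered by
several calls counts once for sensitivity; every matching call counts
for precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pysam

from .simulate import TruthRecord

#: minimum fraction of the true interval a read's aligned reference
#: span must overlap to count as correctly located
LOCATION_OVERLAP = 0.9


@dataclass
class PredictedInversion:
    """One predicted quadruple attributed to a read."""

    read_name: str
    seq_id: int
    ps_ref: int
    pe_ref: int
    ps_read: int
    pe_read: int


@dataclass
class EvalReport:
    n_reads: int = 0
    n_located_correctly: int = 0
    location_accuracy: float = 0.0
    n_true_inversions: int = 0
    n_predicted: int = 0
    n_truth_recovered: int = 0
    n_correct_predictions: int = 0
    sensitivity: float = 0.0
    precision: float = 0.0
    precision_degenerate: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


@dataclass
class _ReadAln:
    primary_strand: str | None = None
    primary_seq_id: int | None = None
    intervals: list[tuple[int, int, int]] = field(default_factory=list)


def _collect_sam(sam_path: str | Path) -> dict[str, _ReadAln]:
    out: dict[str, _ReadAln] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            aln = out.setdefault(rec.query_name, _ReadAln())
            if rec.is_unmapped or rec.is_secondary:
                continue
            if not rec.is_supplementary:
                aln.primary_strand = "-" if rec.is_reverse else "+"
                aln.primary_seq_id = rec.reference_id
            aln.intervals.append((rec.reference_id, rec.reference_start,
                                  rec.reference_end))
    return out


def _union_overlap(intervals: list[tuple[int, int]],
                   lo: int, hi: int) -> int:
    """Total bases of [lo, hi) covered by the union of intervals."""
    clipped = sorted((max(s, lo), min(e, hi)) for s, e in intervals)
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if e <= s:
            continue
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def location_accuracy(sam_path: str | Path,
                      truth: list[TruthRecord]) -> tuple[float, int, int]:
    """Fraction of reads correctly located; returns (acc, correct, total).

    Every read in the SAM must appear in the truth; truth reads absent
    from the SAM count as unmapped (incorrect).
    """
    by_name = {t.name: t for t in truth}
    alns = _collect_sam(sam_path)
    for name in alns:
        if name not in by_name:
            raise ValueError(f"read {name!r} not present in truth")
    correct = 0
    for t in truth:
        aln = alns.get(t.name)
        if aln is None or aln.primary_strand is None:
            continue  # unmapped
        if aln.primary_strand != t.strand or aln.primary_seq_id != t.seq_id:
            continue
        ivs = [(s, e) for sid, s, e in aln.intervals if sid == t.seq_id]
        need = LOCATION_OVERLAP * (t.end - t.start)
        if _union_overlap(ivs, t.start, t.end) >= need:
            correct += 1
    total = len(truth)
    return (correct / total if total else 0.0), correct, total


def inversion_recovery(calls: list[PredictedInversion],
                       truth: list[TruthRecord],
                       full_span_only: bool = False) -> EvalReport:
    """Score predicted inversion quadruples against per-read ground truth.

    ``full_span_only`` restricts the *truth* set to quadruples whose read
    fully spans the implanted inversion (both breakpoints inside the
    read); predictions are always scored in full.
    """
    truths = []
    by_read: dict[str, list] = {}
    for t in truth:
        for qi, q in enumerate(t.quads):
            if not full_span_only or q.spans_fully:
                truths.append((t.name, qi, q))
            by_read.setdefault(t.name, []).append((qi, q))

    counted = {(name, qi) for name, qi, _ in truths}

    def overlaps(a0, a1, b0, b1):
        return max(a0, b0) < min(a1, b1)

    recovered: set[tuple[str, int]] = set()
    n_correct_calls = 0
    for c in calls:
        hit = False
        for qi, q in by_read.get(c.read_name, []):
            if (overlaps(c.ps_ref, c.pe_ref, q.ps_ref, q.pe_ref)
                    and overlaps(c.ps_read, c.pe_read, q.ps_read, q.pe_read)):
                if (c.read_name, qi) in counted:
                    recovered.add((c.read_name, qi))
                hit = True
        if hit:
            n_correct_calls += 1
    rep = EvalReport()
    rep.n_true_inversions = len(truths)
    rep.n_predicted = len(calls)
    rep.n_truth_recovered = len(recovered)
    rep.n_correct_predictions = n_correct_calls
    rep.sensitivity = (len(recovered) / len(truths)) if truths else 0.0
    if calls:
        rep.precision = n_correct_calls / len(calls)
    else:
        rep.precision = 0.0
        rep.precision_degenerate = True
    return rep


def read_calls_bed(path: str | Path, names: list[str]) -> list[PredictedInversion]:
    """Parse the mapper's BED6+2 inversion table."""
    name_to_id = {n: i for i, n in enumerate(names)}
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(PredictedInversion(
                read_name=f[3], seq_id=name_to_id[f[0]],
                ps_ref=int(f[1]), pe_ref=int(f[2]),
                ps_read=int(f[6]), pe_read=int(f[7])))
    return out


def evaluate(sam_path: str | Path, truth: list[TruthRecord],
             calls: list[PredictedInversion],
             full_span_only: bool = False) -> EvalReport:
    """Combined report: location accuracy + inversion recovery."""
    rep = inversion_recovery(calls, truth, full_span_only)
    acc, correct, total = location_accuracy(sam_path, truth)
    rep.n_reads = total
    rep.n_located_correctly = correct
    rep.location_accuracy = acc
    return rep
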