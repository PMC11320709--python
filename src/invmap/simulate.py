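"""Synthetic genomes, implanted structural variants, and noisy long reads.

A desk-scale stand-in for a read simulator plus an SV implanter: a uniform
random genome receives non-overlapping inversions (reverse-complemented in
place) and optionally deletions/insertions, then reads are sampled
uniformly from the altered genome with per-base substitution/indel errors.
Every read carries ground truth: the interval of the *original* genome it
came from, its strand, and - for reads crossing an inversion breakpoint -
the true quadruple (PS_ref, PE_ref, PS_read, PE_read) of the inverted
content on reference and read. A read sampled entirely inside an inverted
block is locally co-linear, so it gets a flipped truth strand and no
quadruple.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Reference, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SVRecord:
    """One implanted SV with coordinates on both genomes (half-open)."""

    kind: str  # 'INV' | 'DEL' | 'INS'
    orig_start: int
    orig_end: int
    alt_start: int
    alt_end: int
    sv_id: int


@dataclass
class InvTruth:
    """Ground-truth inversion quadruple for one read."""

    ps_ref: int
    pe_ref: int
    ps_read: int
    pe_read: int
    spans_fully: bool
    sv_id: int


@dataclass
class TruthRecord:
    """Per-read ground truth used by the evaluation metrics."""

    name: str
    seq_id: int
    start: int  # original-genome interval the read derives from
    end: int
    strand: str
    quads: list[InvTruth] = field(default_factory=list)


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    Defaults emulate noisy single-pass long reads: 15% total error split
    10% insertions / 40% deletions / 50% substitutions, read lengths
    log-normal with an 8 kb median truncated to [1 kb, 30 kb], and
    inversion lengths uniform in [100, 2000] bp.
    """

    genome_len: int = 100_000
    n_inv: int = 5
    inv_len: tuple[int, int] = (100, 2000)
    n_del: int = 0
    del_len: tuple[int, int] = (100, 1000)
    n_ins: int = 0
    ins_len: tuple[int, int] = (100, 1000)
    coverage: float = 20.0
    error_rate: float = 0.15
    mix_sub: float = 0.5
    mix_ins: float = 0.1
    mix_del: float = 0.4
    read_len: int | None = None  # fixed length; None -> log-normal
    read_len_median: int = 8000
    read_len_sigma: float = 0.45
    read_len_min: int = 1000
    read_len_max: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        mix = self.mix_sub + self.mix_ins + self.mix_del
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("error mix fractions must sum to 1")


def make_genome(length: int, seed: int, name: str = "chr1") -> Reference:
    """Uniform-random ACGT genome, deterministic per seed."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    return Reference([(name, seq)])


def implant_svs(ref: Reference, config: SimConfig,
                seed: int | None = None) -> tuple[Reference, list[SVRecord]]:
    """Place non-overlapping SVs on each genome and apply them.

    Inversions reverse-complement their interval in place, deletions drop
    it, insertions add random sequence. Raises if the requested SVs cannot
    be placed disjointly (with a small separation margin). The returned
    truth carries both original- and altered-genome coordinates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out_seqs = []
    truth: list[SVRecord] = []
    sv_id = 0
    margin = 500
    for name, seq in ref.sequences:
        glen = len(seq)
        wanted = ([("INV", config.inv_len)] * config.n_inv
                  + [("DEL", config.del_len)] * config.n_del
                  + [("INS", config.ins_len)] * config.n_ins)
        placed: list[tuple[int, int, str, int]] = []
        for kind, (lo, hi) in wanted:
            ln = int(rng.integers(lo, hi + 1))
            if ln < 50:
                raise ValueError("SVs must be >= 50 bp")
            ok = False
            for _ in range(1000):
                s = int(rng.integers(margin, max(glen - ln - margin, margin + 1)))
                if all(s + ln + margin <= ps or s >= pe + margin
                       for ps, pe, _, _ in placed):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"cannot place {len(wanted)} disjoint SVs on {name} "
                    f"({glen} bp)")
            placed.append((s, s + ln, kind, ln))
        placed.sort()
        parts = []
        cur = 0
        alt_pos = 0
        for s, e, kind, ln in placed:
            parts.append(seq[cur:s])
            alt_pos += s - cur
            if kind == "INV":
                parts.append(revcomp(seq[s:e]))
                truth.append(SVRecord("INV", s, e, alt_pos, alt_pos + ln, sv_id))
                alt_pos += ln
            elif kind == "DEL":
                truth.append(SVRecord("DEL", s, e, alt_pos, alt_pos, sv_id))
            else:  # INS: insertion of novel sequence after position s
                ins = "".join(_BASES[rng.integers(0, 4, size=ln)])
                parts.append(ins)
                truth.append(SVRecord("INS", s, s, alt_pos, alt_pos + ln, sv_id))
                alt_pos += ln
            cur = e if kind != "INS" else s
            sv_id += 1
        parts.append(seq[cur:])
        out_seqs.append((name, "".join(parts)))
    return Reference(out_seqs), truth


def _alt_to_orig(pos: int, svs: list[SVRecord]) -> int:
    """Project an altered-genome position onto the original genome.

    Positions inside an inversion map to their mirror; positions inside
    an inserted block map to the insertion point.
    """
    shift = 0
    for sv in svs:
        if sv.alt_end <= pos:
            shift += (sv.orig_end - sv.orig_start) - (sv.alt_end - sv.alt_start)
        elif sv.alt_start <= pos:
            if sv.kind == "INS":
                return sv.orig_start
            return sv.orig_start + (sv.alt_end - 1 - pos)  # INV mirror
        else:
            break
    return pos + shift


def _apply_errors(template: str, rng: np.random.Generator,
                  config: SimConfig) -> tuple[str, np.ndarray]:
    """Per-base error channel; returns (read, outpos).

    outpos[i] is the read coordinate where template base i landed (or
    would have landed, for deleted bases); outpos has length
    len(template)+1 with the final entry = len(read).
    """
    n = len(template)
    e = config.error_rate
    if e == 0.0 or n == 0:
        return template, np.arange(n + 1)
    from .io import encode
    codes = encode(template).astype(np.int64)
    u = rng.random(n)
    sub = u < e * config.mix_sub
    dele = (u >= e * config.mix_sub) & (u < e * (config.mix_sub + config.mix_del))
    ins = (u >= e * (config.mix_sub + config.mix_del)) & (u < e)
    kept = ~dele
    sub &= kept
    ins &= kept  # an insertion rides after a surviving base
    # substituted bases shift by 1..3 in base space so they always differ
    shifts = rng.integers(1, 4, size=int(sub.sum()))
    ins_bases = rng.integers(0, 4, size=int(ins.sum()))
    counts = kept.astype(np.int64) + ins
    outpos = np.concatenate([[0], np.cumsum(counts)])
    out_codes = np.empty(int(outpos[-1]), dtype=np.int64)
    newc = codes.copy()
    newc[sub] = (codes[sub] + shifts) % 4
    out_codes[outpos[:-1][kept]] = newc[kept]
    out_codes[outpos[:-1][ins] + 1] = ins_bases
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    read = alphabet[out_codes].tobytes().decode("ascii")
    return read, outpos


def simulate_reads(alt_ref: Reference, svs: list[SVRecord],
                   config: SimConfig) -> tuple[list[tuple[str, str]],
                                               list[TruthRecord]]:
    """Sample noisy reads from the altered genome with per-read truth.

    Reads are drawn uniformly in position and strand until the total read
    bases reach coverage x genome length. Inversion quadruples are emitted
    for reads whose interval crosses at least one inversion breakpoint;
    coordinates are projected through the error channel so PS_read/PE_read
    are positions on the final noisy read.
    """
    rng = np.random.default_rng(config.seed)
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    for seq_id, (name, alt_seq) in enumerate(alt_ref.sequences):
        glen = len(alt_seq)
        target = config.coverage * glen
        total = 0
        i = 0
        invs = [sv for sv in svs if sv.kind == "INV"]
        while total < target:
            if config.read_len is not None:
                ln = config.read_len
            else:
                ln = int(round(config.read_len_median
                               * np.exp(rng.normal(0.0, config.read_len_sigma))))
                ln = int(np.clip(ln, config.read_len_min, config.read_len_max))
            ln = min(ln, glen)
            a = int(rng.integers(0, glen - ln + 1))
            b = a + ln
            minus = bool(rng.random() < 0.5)
            template = alt_seq[a:b]
            if minus:
                template = revcomp(template)
            read, outpos = _apply_errors(template, rng, config)
            rname = f"{name}_read{i}"
            reads.append((rname, read))
            # original-genome interval of the sampled window
            o1 = _alt_to_orig(a, svs)
            o2 = _alt_to_orig(b - 1, svs)
            start, end = min(o1, o2), max(o1, o2) + 1
            strand = "-" if minus else "+"
            inside = any(sv.alt_start <= a and b <= sv.alt_end for sv in invs)
            if inside:
                strand = "+" if minus else "-"
            rec = TruthRecord(rname, seq_id, start, end, strand)
            if not inside:
                for sv in invs:
                    s, e = max(a, sv.alt_start), min(b, sv.alt_end)
                    if e - s <= 0:
                        continue
                    # inverted content of the read, on the original genome
                    off = sv.orig_start - sv.alt_start  # 0 for INV-only genomes
                    ps_ref = off + sv.alt_start + (sv.alt_end - e)
                    pe_ref = off + sv.alt_start + (sv.alt_end - s)
                    t0, t1 = (s - a, e - a) if not minus else (b - e, b - s)
                    rec.quads.append(InvTruth(
                        ps_ref, pe_ref,
                        int(outpos[t0]), int(outpos[t1]),
                        spans_fully=(sv.alt_start >= a and sv.alt_end <= b),
                        sv_id=sv.sv_id))
            truth.append(rec)
            total += len(read)
            i += 1
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: list[TruthRecord], names: list[str],
                path: str | Path) -> None:
    """TSV schema: name, ref, start, end, strand, quads.

    ``quads`` is '.' or a comma-separated list of
    ps_ref:pe_ref:ps_read:pe_read:full:sv_id entries.
    """
    with open(path, "w") as fh:
        fh.write("#name\tref\tstart\tend\tstrand\tquads\n")
        for t in truth:
            q = ",".join(
                f"{x.ps_ref}:{x.pe_ref}:{x.ps_read}:{x.pe_read}:"
                f"{int(x.spans_fully)}:{x.sv_id}" for x in t.quads) or "."
            fh.write(f"{t.name}\t{names[t.seq_id]}\t{t.start}\t{t.end}\t"
                     f"{t.strand}\t{q}\n")


def read_truth(path: str | Path, names: list[str]) -> list[TruthRecord]:
    name_to_id = {n: i for i, n in enumerate(names)}
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            name, ref, start, end, strand, quads = line.rstrip("\n").split("\t")
            rec = TruthRecord(name, name_to_id[ref], int(start), int(end),
                              strand)
            if quads != ".":
                for ent in quads.split(","):
                    a, b, c, d, f, s = ent.split(":")
                    rec.quads.append(InvTruth(int(a), int(b), int(c), int(d),
                                              bool(int(f)), int(s)))
            out.append(rec)
    return out


def simulate(config: SimConfig) -> tuple[Reference, Reference,
                                         list[SVRecord],
                                         list[tuple[str, str]],
                                         list[TruthRecord]]:
    """One-call pipeline: genome -> SV implant -> reads with truth."""
    ref = make_genome(config.genome_len, config.seed)
    alt, svs = implant_svs(ref, config, config.seed + 1)
    reads, truth = simulate_reads(alt, svs, config)
    return ref, alt, svs, reads, truth
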