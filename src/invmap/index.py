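"""Minimizer hash index over a reference genome.

The index is a plain hash table keyed by canonical k-mer: for every window
of ``w`` consecutive k-mer start positions the k-mer with the smallest
64-bit mixed hash is stored (leftmost position on ties), so each window is
guaranteed to contribute at least one indexed position. ``w=1`` degenerates
to indexing every k-mer. Keys occurring more than ``max_occ`` times across
the whole reference are dropped (repeat masking).

Canonicalization: a k-mer and its reverse complement share one key (the
numerically smaller 2-bit packing); a strand bit records whether the
forward-strand k-mer at that position equals the canonical form. K-mers
containing N are never indexed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Reference, encode

# Sentinel hash for k-mers containing N: never selected as a minimizer.
_INVALID = np.uint64(0xFFFFFFFFFFFFFFFF)


def _mix64(x: np.ndarray) -> np.ndarray:
    """Invertible 64-bit finalizer (splitmix/murmur style) on uint64 arrays."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xFF51AFD7ED558CCD)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xC4CEB9FE1A85EC53)
    x ^= x >> np.uint64(33)
    return x


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward and reverse-complement values of every k-mer.

    Returns (fwd, rev) uint64 arrays of length ``len(codes)-k+1``; positions
    whose k-mer contains an invalid base hold ``_INVALID`` in both.
    """
    n = codes.size - k + 1
    if n <= 0:
        z = np.empty(0, dtype=np.uint64)
        return z, z
    valid_base = codes < 4
    # windows with any invalid base
    ok = np.convolve(valid_base.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    c = np.where(valid_base, codes, 0).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(c, k)
    shifts_f = np.array([2 * (k - 1 - j) for j in range(k)], dtype=np.uint64)
    fwd = (win << shifts_f).sum(axis=1, dtype=np.uint64)
    # reverse complement: complement code is 3-c, read right-to-left
    shifts_r = np.array([2 * j for j in range(k)], dtype=np.uint64)
    rev = ((np.uint64(3) - win) << shifts_r).sum(axis=1, dtype=np.uint64)
    fwd = np.where(ok, fwd, _INVALID)
    rev = np.where(ok, rev, _INVALID)
    return fwd, rev


def minimizers(seq: str, k: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimizer sweep over one sequence.

    Returns (positions, keys, strand) where ``keys`` are canonical k-mer
    packings, and ``strand`` is 1 where the forward k-mer is the canonical
    form, 0 where the reverse complement is. Ties within a window break to
    the smallest hash then the leftmost position; k-mers containing N are
    skipped, and a window of all-N k-mers yields nothing.
    """
    codes = encode(seq)
    fwd, rev = kmer_values(codes, k)
    n = fwd.size
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=np.uint64), e
    canon = np.minimum(fwd, rev)
    strand = (fwd <= rev).astype(np.int8)
    h = np.where(canon == _INVALID, _INVALID, _mix64(canon))
    if w <= 1 or n <= 1:
        pos = np.nonzero(h != _INVALID)[0]
        return pos.astype(np.int64), canon[pos], strand[pos].astype(np.int64)
    ww = min(w, n)
    hw = np.lib.stride_tricks.sliding_window_view(h, ww)
    arg = hw.argmin(axis=1)  # leftmost min per window
    pos = np.unique(np.arange(hw.shape[0]) + arg)
    pos = pos[h[pos] != _INVALID]
    return pos.astype(np.int64), canon[pos], strand[pos].astype(np.int64)


@dataclass
class MinimizerIndex:
    """Hash table from canonical k-mer key to its reference hit list.

    ``table[key]`` is an int64 array of shape (n_hits, 3) with columns
    (seq_id, pg, strand); rows sorted by (seq_id, pg). ``strand`` is 1 when
    the reference forward-strand k-mer at pg equals the canonical k-mer.
    """

    k: int
    w: int
    max_occ: int
    names: list[str]
    lengths: list[int]
    table: dict[int, np.ndarray] = field(default_factory=dict)

    FORMAT_VERSION = 1

    def lookup(self, key: int) -> np.ndarray | None:
        return self.table.get(int(key))

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive (tool-private, versioned)."""
        keys = np.fromiter(self.table.keys(), dtype=np.uint64, count=len(self.table))
        counts = np.fromiter((v.shape[0] for v in self.table.values()), dtype=np.int64,
                             count=len(self.table))
        hits = (np.concatenate(list(self.table.values()))
                if self.table else np.empty((0, 3), dtype=np.int64))
        np.savez_compressed(
            path,
            version=np.int64(self.FORMAT_VERSION),
            k=np.int64(self.k), w=np.int64(self.w), max_occ=np.int64(self.max_occ),
            names=np.array(self.names, dtype=object),
            lengths=np.array(self.lengths, dtype=np.int64),
            keys=keys, counts=counts, hits=hits,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MinimizerIndex":
        with np.load(path, allow_pickle=True) as z:
            if int(z["version"]) != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported index format version {int(z['version'])}")
            idx = cls(k=int(z["k"]), w=int(z["w"]), max_occ=int(z["max_occ"]),
                      names=[str(n) for n in z["names"]],
                      lengths=[int(x) for x in z["lengths"]])
            offs = np.concatenate([[0], np.cumsum(z["counts"])])
            hits = z["hits"]
            for i, key in enumerate(z["keys"]):
                idx.table[int(key)] = hits[offs[i]:offs[i + 1]]
        return idx


def build_index(ref: Reference, k: int = 15, w: int = 5,
                max_occ: int = 500) -> MinimizerIndex:
    """Build the minimizer index for a reference.

    Parameters
    ----------
    ref : Reference
        One or more named sequences.
    k : int
        k-mer length, 1..28 (2-bit packing must fit 64 bits with headroom).
    w : int
        Minimizer window: one k-mer kept per window of ``w`` consecutive
        starts. ``w=1`` indexes every k-mer.
    max_occ : int
        Keys with more than this many hits genome-wide are dropped.
    """
    if not 1 <= k <= 28:
        raise ValueError("k must be in 1..28")
    if w < 1:
        raise ValueError("w must be >= 1")
    if max_occ < 1:
        raise ValueError("max_occ must be >= 1")
    if len(ref) == 0:
        raise ValueError("empty reference")

    buckets: dict[int, list[tuple[int, int, int]]] = {}
    for seq_id, (name, seq) in enumerate(ref.sequences):
        if len(seq) < k:
            warnings.warn(f"sequence {name!r} shorter than k={k}; skipped")
            continue
        pos, keys, strand = minimizers(seq, k, w)
        for p, key, s in zip(pos.tolist(), keys.tolist(), strand.tolist()):
            buckets.setdefault(key, []).append((seq_id, p, s))

    idx = MinimizerIndex(k=k, w=w, max_occ=max_occ,
                         names=ref.names, lengths=ref.lengths)
    for key, hits in buckets.items():
        if len(hits) > max_occ:
            continue
        arr = np.asarray(sorted(hits), dtype=np.int64).reshape(-1, 3)
        idx.table[key] = arr
    return idx
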