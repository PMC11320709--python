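"""Sequence I/O and basic DNA utilities.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; this module adds the
:class:`Reference` container used throughout the mapper and fast 2-bit
encoding helpers shared by the index and the aligner.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Base -> 2-bit code; N (and any other letter) -> 4, treated as invalid.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit-encode a DNA string; non-ACGT bases become code 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Reference:
    """A loaded reference genome: an ordered list of named uppercase sequences.

    Coordinates into a sequence are 0-based half-open everywhere inside the
    package; conversion to SAM's 1-based POS happens only at output time.
    """

    sequences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sequences]
        if len(names) != len(set(names)):
            raise ValueError("reference sequence names must be unique")
        for name, seq in self.sequences:
            if not seq:
                raise ValueError(f"reference sequence {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, i: int) -> tuple[str, str]:
        return self.sequences[i]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    @property
    def lengths(self) -> list[int]:
        return [len(s) for _, s in self.sequences]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Reference":
        seqs = [(rec.id, str(rec.seq).upper()) for rec in _parse(path, "fasta")]
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(seqs)


def _parse(path: str | Path, fmt: str):
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, fmt)
    else:
        yield from SeqIO.parse(path, fmt)


def read_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Iterate (name, sequence) over a FASTA or FASTQ file (gzip allowed).

    The format is sniffed from the first non-blank character; quality
    strings are ignored.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in _parse(path, fmt):
        yield rec.id, str(rec.seq).upper()
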