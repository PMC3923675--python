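"""Genome container and dinucleotide-block sequence arithmetic.

Sequences are held as uint8 code arrays (A=0, C=1, G=2, T=3, N=4) for fast
window extraction.  The block layout used throughout the package tiles the
+/-78 bp environment of a CpG into 78 non-overlapping dinucleotide blocks:
39 on the left covering offsets (-78,-77)...(-2,-1) relative to the C, and
39 on the right covering (+2,+3)...(+78,+79), i.e. the 78 bases after the G.
The central CpG itself is never part of the environment.
"""

from __future__ import annotations

import os
from typing import Dict, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

BASES = "ACGT"
N_CODE = 4
_CODE_OF = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_OF[ord(_b)] = _i
    _CODE_OF[ord(_b.lower())] = _i

#: the 16 dinucleotides in code order (AA, AC, ..., TT)
DINUCS = [a + b for a in BASES for b in BASES]
TT_CODE = DINUCS.index("TT")
CG_CODE = DINUCS.index("CG")

N_BLOCKS = 78
FLANK = 78  # bp of environment on each side of the CpG
WINDOW = 2 * FLANK + 2  # full extraction window including the CpG

#: left-base offset of every block relative to the C of the central CpG
BLOCK_LEFT_OFFSETS = np.concatenate(
    [np.arange(-FLANK, 0, 2), np.arange(2, FLANK + 2, 2)]
)
#: midpoint offset of every block (used for periodic ground-truth components)
BLOCK_CENTERS = BLOCK_LEFT_OFFSETS + 0.5


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.empty(len(codes), dtype="S1")
    lut = np.frombuffer(b"ACGTN", dtype="S1")
    out[:] = lut[codes]
    return out.tobytes().decode("ascii")


def dinuc_code(d: str) -> int:
    return DINUCS.index(d.upper())


def block_of_offset(offset: int) -> int | None:
    """Block index containing a signed offset from the C, or None.

    Offsets 0 and 1 are the CpG itself; offsets outside [-78, 79] are
    outside the modeled environment.
    """
    if -FLANK <= offset <= -1:
        return (offset + FLANK) // 2
    if 2 <= offset <= FLANK + 1:
        return N_BLOCKS // 2 + (offset - 2) // 2
    return None


class Genome:
    """A set of named chromosomes stored as code arrays."""

    def __init__(self, chroms: Mapping[str, np.ndarray]):
        self.chroms: Dict[str, np.ndarray] = {
            name: np.asarray(arr, dtype=np.uint8) for name, arr in chroms.items()
        }

    @classmethod
    def from_strings(cls, seqs: Mapping[str, str]) -> "Genome":
        return cls({name: encode(s) for name, s in seqs.items()})

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        genome = cls({name: encode(str(fa[name][:])) for name in fa.keys()})
        fa.close()
        return genome

    def to_fasta(self, path: str | os.PathLike, width: int = 80) -> None:
        records = [
            SeqRecord(Seq(decode(arr)), id=name, description="")
            for name, arr in self.chroms.items()
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")

    def __iter__(self) -> Iterator[str]:
        return iter(self.chroms)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.chroms[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def lengths(self) -> Dict[str, int]:
        return {name: len(arr) for name, arr in self.chroms.items()}

    def sequence(self, chrom: str, start: int, end: int) -> str:
        return decode(self.chroms[chrom][start:end])


def find_cpgs(codes: np.ndarray) -> np.ndarray:
    """0-based positions of the C of every CpG in a code array."""
    return np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))


def window_codes(codes: np.ndarray, positions: np.ndarray, flank: int = FLANK):
    """Extract the full (2*flank+2)-long windows around CpG positions.

    Returns ``(windows, valid)`` where ``valid`` marks positions whose
    window lies entirely on the chromosome and contains no N.  Windows of
    invalid positions are filled but must not be used.
    """
    positions = np.asarray(positions, dtype=np.int64)
    n = len(codes)
    if n < 2 * flank + 2:
        win = np.full((len(positions), 2 * flank + 2), N_CODE, dtype=np.uint8)
        return win, np.zeros(len(positions), dtype=bool)
    inside = (positions >= flank) & (positions + flank + 2 <= n)
    safe = np.where(inside, positions, flank)
    offs = np.arange(-flank, flank + 2)
    win = codes[safe[:, None] + offs[None, :]]
    valid = inside & ~(win == N_CODE).any(axis=1)
    return win, valid


def block_codes(windows: np.ndarray) -> np.ndarray:
    """Dinucleotide code (0..15) of each of the 78 blocks, per window row."""
    w = windows
    left = 4 * w[:, 0:FLANK:2].astype(np.int16) + w[:, 1:FLANK:2]
    right = 4 * w[:, FLANK + 2 :: 2].astype(np.int16) + w[:, FLANK + 3 :: 2]
    return np.concatenate([left, right], axis=1).astype(np.int8)
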