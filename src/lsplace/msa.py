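"""Aligned-sequence container and aligned-FASTA I/O.

Sequences are stored as a dense ``(n_rows, L)`` matrix of uppercase ASCII
codes.  A character is either a *residue* of the declared alphabet, the gap
character ``-``, or a recognized ambiguity code.  For all distance
computations ambiguity codes are treated like gaps ("missing"), so the only
mask that matters downstream is :meth:`Alignment.valid_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

GAP = ord("-")

_DNA_RESIDUES = b"ACGT"
_AA_RESIDUES = b"ACDEFGHIKLMNPQRSTVWY"
# accepted on input, treated as missing data in comparisons
_DNA_AMBIG = b"RYSWKMBDHVN?."
_AA_AMBIG = b"BZXJUO*?."


def _table(chars: bytes) -> np.ndarray:
    t = np.zeros(256, dtype=bool)
    t[np.frombuffer(chars, dtype=np.uint8)] = True
    return t


# alphabet -> (residue table, legal-character table)
_TABLES = {
    "dna": (_table(_DNA_RESIDUES), _table(_DNA_RESIDUES + _DNA_AMBIG + b"-")),
    "aa": (_table(_AA_RESIDUES), _table(_AA_RESIDUES + _AA_AMBIG + b"-")),
}


def encode(seq: str) -> np.ndarray:
    """Encode an aligned sequence string as uppercase ASCII codes."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def decode(row: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return row.astype(np.uint8).tobytes().decode("ascii")


def residue_table(alphabet: str) -> np.ndarray:
    """Boolean lookup (length 256): True for unambiguous residues."""
    return _TABLES[alphabet.lower()][0]


@dataclass
class Alignment:
    """Fixed-width character matrix over a declared alphabet.

    Parameters
    ----------
    ids
        Unique, non-empty sequence identifiers (one per row).
    matrix
        ``(n_rows, L)`` uint8 matrix of ASCII codes.  Lowercase input is
        uppercased; for DNA, ``U`` is mapped to ``T``.
    alphabet
        ``"dna"`` or ``"aa"``.
    """

    ids: list
    matrix: np.ndarray
    alphabet: str = "dna"
    _index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        self.alphabet = str(self.alphabet).lower()
        if self.alphabet not in _TABLES:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        m = np.ascontiguousarray(self.matrix, dtype=np.uint8).copy()
        if m.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        ids = [str(s) for s in self.ids]
        if len(ids) != m.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if any(not s for s in ids):
            raise ValueError("empty sequence id")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in alignment")
        # normalize case
        lower = (m >= ord("a")) & (m <= ord("z"))
        m[lower] -= 32
        if self.alphabet == "dna":
            m[m == ord("U")] = ord("T")
        legal = _TABLES[self.alphabet][1]
        if m.size and not legal[m].all():
            bad = sorted({chr(c) for c in np.unique(m[~legal[m]])})
            raise ValueError(f"illegal character(s) for {self.alphabet}: {bad}")
        self.matrix = m
        self.ids = ids
        self._index = {s: k for k, s in enumerate(ids)}

    # -- basic views ------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        """Return the (L,) code row for ``seq_id``."""
        return self.matrix[self._index[seq_id]]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def valid_mask(self) -> np.ndarray:
        """(n_rows, L) boolean: True where the character is an unambiguous
        residue (gaps and ambiguity codes are False)."""
        return _TABLES[self.alphabet][0][self.matrix]

    # -- subsetting -------------------------------------------------------
    def subset(self, ids: Sequence[str]) -> "Alignment":
        rows = [self._index[s] for s in ids]
        return Alignment(list(ids), self.matrix[rows], self.alphabet)

    def drop(self, ids: Iterable[str]) -> "Alignment":
        drop = set(ids)
        keep = [s for s in self.ids if s not in drop]
        return self.subset(keep)


def read_alignment(path, alphabet: str = "dna") -> Alignment:
    """Read an aligned FASTA file.

    All records must have equal length; ragged records are an error, never
    silently padded.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in alignment file {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {path}: record lengths {sorted(lengths)}")
    ids = [r.id for r in records]
    mat = np.vstack([encode(str(r.seq)) for r in records])
    return Alignment(ids, mat, alphabet)


def write_alignment(aln: Alignment, path) -> None:
    """Write an :class:`Alignment` as FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for k, seq_id in enumerate(aln.ids):
            fh.write(f">{seq_id}\n{decode(aln.matrix[k])}\n")
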