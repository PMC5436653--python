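"""Multiple sequence alignments, core positions, and residue-number mapping.

A super-family alignment is a rectangle of amino-acid symbols and gaps.
Columns that are mostly gap-free correspond to the structurally conserved
core of the family; each core column gets a family-wide position number
(1..K, in column order) that plays the role of a structure-based residue
numbering: equivalent residues in every member share one number regardless
of their per-protein numbering.  Per-sequence integer offsets emulate
species-specific numbering (the first residue of a row is ``offset + 1``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    EmptyCoreError,
    EmptyInputError,
    EmptySubsetError,
    ResidueRangeError,
    UnknownSequenceError,
)

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
#: Integer code used for gaps and 'X' in the encoded matrix.
GAP_CODE = 20

_ALLOWED = set(AMINO_ACIDS) | {GAP, "X"}


@dataclass
class Msa:
    """An aligned set of protein sequences.

    Parameters
    ----------
    ids : list of str
        Unique sequence identifiers, in alignment order.
    rows : list of str
        Aligned rows (upper case, ``-`` for gaps), all the same length.
    offsets : dict, optional
        Per-sequence residue-numbering offset; the first residue of a row
        is numbered ``offset + 1`` (default 0).
    """

    ids: list[str]
    rows: list[str]
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            raise EmptyInputError("alignment contains no sequences")
        if len(self.ids) != len(set(self.ids)):
            raise AlignmentShapeError("sequence ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - _ALLOWED
            if bad:
                col = next(i for i, c in enumerate(row) if c in bad) + 1
                raise AlphabetError(
                    f"illegal symbol {sorted(bad)[0]!r} in sequence {sid!r} "
                    f"at column {col}"
                )
        self._index = {sid: k for k, sid in enumerate(self.ids)}
        self._encoded: np.ndarray | None = None

    # -- basic properties -------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def offset(self, seq_id: str) -> int:
        return self.offsets.get(seq_id, 0)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self._index[seq_id]]
        except KeyError:
            raise UnknownSequenceError(seq_id) from None

    def encoded(self) -> np.ndarray:
        """Integer matrix (n_sequences x length); gaps and 'X' are GAP_CODE."""
        if self._encoded is None:
            lut = np.full(128, -1, dtype=np.int8)
            for aa, i in AA_INDEX.items():
                lut[ord(aa)] = i
            lut[ord(GAP)] = GAP_CODE
            lut[ord("X")] = GAP_CODE
            buf = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            )
            self._encoded = lut[buf].reshape(self.n_sequences, self.length)
        return self._encoded

    def subset(self, seq_ids: Sequence[str]) -> "Msa":
        """Row subset (columns unchanged), preserving the given order."""
        if len(seq_ids) == 0:
            raise EmptySubsetError("subset selects no sequences")
        rows = [self.row(sid) for sid in seq_ids]
        offsets = {sid: self.offset(sid) for sid in seq_ids if self.offset(sid)}
        return Msa(list(seq_ids), rows, offsets)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass(frozen=True)
class CorePositions:
    """Ordered core columns; the k-th entry carries position number k.

    ``columns`` are 1-based alignment column indices, strictly increasing.
    """

    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.columns, self.columns[1:])):
            raise ValueError("core columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def numbers(self) -> range:
        """All core-position numbers, 1..K."""
        return range(1, len(self.columns) + 1)

    def column_of(self, number: int) -> int:
        """1-based alignment column for a core-position number."""
        if not 1 <= number <= len(self.columns):
            raise ResidueRangeError(
                f"core position {number} out of range 1..{len(self.columns)}"
            )
        return self.columns[number - 1]

    def number_of(self, column: int) -> int | None:
        """Core-position number of a 1-based column, or None if not core."""
        try:
            return self._lookup()[column]
        except KeyError:
            return None

    def _lookup(self) -> Mapping[int, int]:
        d = self.__dict__.get("_map")
        if d is None:
            d = {c: k + 1 for k, c in enumerate(self.columns)}
            object.__setattr__(self, "_map", d)
        return d


@dataclass
class ResidueDistribution:
    """Amino-acid counts at one core position (gaps excluded)."""

    position: int
    counts: dict[str, int]
    n_nongap: int

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n_nongap

    def frequencies(self) -> dict[str, float]:
        if self.n_nongap == 0:
            return {}
        return {aa: c / self.n_nongap for aa, c in self.counts.items()}


# -- operations ----------------------------------------------------------


def read_alignment(path, offsets: Mapping[str, int] | None = None) -> Msa:
    """Read an aligned FASTA file.

    Lower case is normalised to upper case and ``.`` gaps to ``-``.
    Raises :class:`EmptyInputError`, :class:`AlignmentShapeError` or
    :class:`AlphabetError` on malformed input.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    return Msa(ids, rows, dict(offsets) if offsets else {})


def read_alignment_string(text: str, offsets=None) -> Msa:
    """Like :func:`read_alignment` but from an in-memory FASTA string."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise EmptyInputError("no FASTA records in string")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    return Msa(ids, rows, dict(offsets) if offsets else {})


def derive_core_positions(msa: Msa, max_gap_frac: float = 0.3) -> CorePositions:
    """Core columns by per-column gap fraction.

    A column is core when its fraction of gaps (``-`` and ``X``) is at
    most ``max_gap_frac``.  This is a sequence-only stand-in for the
    structural criterion (loop/variable regions excluded from the core)
    used by structure-based numbering schemes.
    """
    if not 0.0 <= max_gap_frac <= 1.0:
        raise ValueError("max_gap_frac must be in [0, 1]")
    enc = msa.encoded()
    gap_frac = (enc == GAP_CODE).mean(axis=0)
    cols = tuple(int(c) + 1 for c in np.nonzero(gap_frac <= max_gap_frac)[0])
    if not cols:
        raise EmptyCoreError(
            f"no column has gap fraction <= {max_gap_frac}"
        )
    return CorePositions(cols)


def core_position_table(msa: Msa, core: CorePositions):
    """Per-core-position table: number, alignment column, gap fraction."""
    import pandas as pd

    enc = msa.encoded()
    gap_frac = (enc == GAP_CODE).mean(axis=0)
    return pd.DataFrame(
        {
            "position": list(core.numbers),
            "alignment_column": list(core.columns),
            "gap_fraction": [float(gap_frac[c - 1]) for c in core.columns],
        }
    )


def _column_of_residue(msa: Msa, seq_id: str, residue_number: int) -> int:
    """1-based alignment column holding the given residue of a sequence."""
    row = msa.row(seq_id)
    offset = msa.offset(seq_id)
    k = residue_number - offset
    n_res = sum(1 for c in row if c != GAP)
    if k < 1 or k > n_res:
        raise ResidueRangeError(
            f"residue {residue_number} out of range "
            f"{offset + 1}..{offset + n_res} for sequence {seq_id!r}"
        )
    seen = 0
    for col, c in enumerate(row, start=1):
        if c != GAP:
            seen += 1
            if seen == k:
                return col
    raise AssertionError("unreachable")


def map_residue_to_3d(
    msa: Msa, core: CorePositions, seq_id: str, residue_number: int
) -> int | None:
    """Core-position number of a residue, or None when its column is not core."""
    col = _column_of_residue(msa, seq_id, residue_number)
    return core.number_of(col)


def map_3d_to_residue(
    msa: Msa, core: CorePositions, seq_id: str, number: int
) -> tuple[int, str] | None:
    """Inverse of :func:`map_residue_to_3d`.

    Returns ``(residue_number, amino_acid)`` for the sequence's residue at
    core position ``number``, or None when the sequence is gapped there.
    """
    col = core.column_of(number)
    row = msa.row(seq_id)
    if row[col - 1] == GAP:
        return None
    n_before = sum(1 for c in row[:col] if c != GAP)
    return msa.offset(seq_id) + n_before, row[col - 1]


def column_distribution(
    msa: Msa,
    core: CorePositions,
    number: int,
    subset_ids: Iterable[str] | None = None,
) -> ResidueDistribution:
    """Amino-acid counts at one core position, optionally over a row subset."""
    col = core.column_of(number)
    if subset_ids is None:
        rows = msa.rows
    else:
        subset_ids = list(subset_ids)
        if not subset_ids:
            raise EmptySubsetError("empty subset for column distribution")
        rows = [msa.row(sid) for sid in subset_ids]
    counts: dict[str, int] = {}
    for row in rows:
        c = row[col - 1]
        if c in AA_INDEX:
            counts[c] = counts.get(c, 0) + 1
    return ResidueDistribution(number, counts, sum(counts.values()))
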