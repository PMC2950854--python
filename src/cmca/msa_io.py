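"""Reading, validating and writing aligned protein families and result tables.

The analysis operates on a gapped multiple alignment of a protein family:
``N`` equal-length rows over the 20 standard amino acids plus the gap
character.  The gap is treated as a 21st residue type throughout the package,
so the alphabet is fixed at ``M = 21`` symbols with the gap at index 0.

Input normalisation is deliberately conservative: lowercase letters are
uppercased, the ``.`` and space gap dialects become ``-``, and ambiguity or
non-standard codes (``X B Z U O J *``) are replaced by the gap symbol with a
logged warning — the statistical model has exactly 21 residue classes and no
natural place for a 22nd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, EmptyInputError, ValidationError

logger = logging.getLogger("cmca")

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Characters accepted as gaps on input and normalised to ``-``.
_GAP_DIALECTS = {".", " ", "-"}
#: Ambiguity / non-standard residue codes mapped to the gap symbol on input.
_AMBIGUOUS = set("XBZUOJ*")


@dataclass(frozen=True)
class Alphabet:
    """The 21-symbol residue alphabet: gap first, then the 20 amino acids.

    Attributes
    ----------
    symbols:
        Ordered symbols; ``symbols[0]`` is the gap, ``symbols[1:]`` the amino
        acids in alphabetical one-letter order.
    """

    symbols: tuple[str, ...] = tuple(GAP + AMINO_ACIDS)
    index: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.symbols) != 21 or self.symbols[0] != GAP:
            raise ValidationError(
                "alphabet must have 21 symbols with the gap at index 0"
            )
        object.__setattr__(
            self, "index", {s: k for k, s in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index


#: Module-level default alphabet; every operation accepts an explicit one.
PROTEIN = Alphabet()


@dataclass(frozen=True)
class Alignment:
    """A validated, equal-length protein family alignment.

    ``rows[i][l]`` is the symbol of sequence ``i`` at column ``l`` (0-based
    internally; all user-facing outputs use 1-based column numbers).
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows must have equal length")
        if len(self.rows) < 2:
            raise ValidationError("an alignment needs at least 2 sequences")
        if any(not i for i in self.ids):
            raise ValidationError("sequence identifiers must be non-empty")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence identifiers: {dupes}")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentShapeError("alignment has zero columns")
        for seq_id, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentShapeError(
                    f"sequence {seq_id!r} has length {len(row)}, "
                    f"expected {length}"
                )
        allowed = set(GAP + AMINO_ACIDS)
        for seq_id, row in zip(self.ids, self.rows):
            bad = set(row) - allowed
            if bad:
                raise ValidationError(
                    f"sequence {seq_id!r} contains invalid symbols {sorted(bad)}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, l: int) -> str:
        """Return alignment column ``l`` (0-based) as a string of length N."""
        return "".join(row[l] for row in self.rows)


class AlignmentRead(NamedTuple):
    """Result of :func:`read_alignment`: the alignment plus the number of
    non-standard residue codes that were replaced by gaps."""

    alignment: Alignment
    replaced: int


def _normalise(raw: str, seq_id: str) -> tuple[str, int]:
    """Uppercase, unify gap dialects, map ambiguity codes to gap."""
    replaced = 0
    out = []
    for ch in raw.upper():
        if ch in _GAP_DIALECTS:
            out.append(GAP)
        elif ch in _AMBIGUOUS:
            out.append(GAP)
            replaced += 1
        elif ch in AMINO_ACIDS:
            out.append(ch)
        else:
            raise ValidationError(
                f"sequence {seq_id!r} contains unrecognised character {ch!r}"
            )
    return "".join(out), replaced


def read_alignment(path: str | Path, dialect: str = "fasta") -> AlignmentRead:
    """Read an aligned FASTA file into a validated :class:`Alignment`.

    Parameters
    ----------
    path:
        Path to an aligned FASTA file (equal-length records).
    dialect:
        Input format; only ``"fasta"`` is supported.

    Returns
    -------
    AlignmentRead
        Named tuple ``(alignment, replaced)`` where ``replaced`` counts
        non-standard residue codes (X, B, Z, U, O, J, *) mapped to gaps.

    Raises
    ------
    EmptyInputError
        If the file holds no records.
    AlignmentShapeError
        If record lengths differ (the offending record is named).
    ValidationError
        On duplicate identifiers or unrecognised characters.
    """
    if dialect != "fasta":
        raise ValidationError(f"unsupported alignment dialect {dialect!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no sequence records found in {path}")
    ids, rows = [], []
    replaced = 0
    for rec in records:
        row, n_rep = _normalise(str(rec.seq), rec.id)
        ids.append(rec.id)
        rows.append(row)
        replaced += n_rep
    if replaced:
        logger.warning(
            "replaced %d non-standard residue code(s) with gaps in %s",
            replaced, path.name,
        )
    return AlignmentRead(Alignment(tuple(ids), tuple(rows)), replaced)


def write_alignment(alignment: Alignment, path: str | Path) -> Path:
    """Write an alignment back to aligned FASTA (inverse of read)."""
    path = Path(path)
    records = [
        SeqRecord(Seq(row), id=seq_id, description="")
        for seq_id, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def write_matrix(
    matrix: np.ndarray,
    row_labels: Sequence,
    col_labels: Sequence,
    path: str | Path,
) -> Path:
    """Write a labelled matrix as TSV: header row, label column.

    Floating matrices are serialised with 6 decimal places; integer matrices
    keep exact integers so that a round-trip through :func:`read_matrix`
    reproduces them.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValidationError("write_matrix expects a 2-D matrix")
    if matrix.shape != (len(row_labels), len(col_labels)):
        raise ValidationError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(row_labels)} row / {len(col_labels)} column labels"
        )
    frame = pd.DataFrame(matrix, index=list(row_labels), columns=list(col_labels))
    fmt = None if np.issubdtype(matrix.dtype, np.integer) else "%.6f"
    frame.to_csv(path, sep="\t", float_format=fmt)
    return Path(path)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix written by :func:`write_matrix` (labels preserved)."""
    return pd.read_csv(path, sep="\t", index_col=0)
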