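"""Position frequency statistics and gap-column reduction.

An alignment of N sequences over the 21-symbol alphabet (gap + 20 amino
acids) is first one-hot encoded into a binary occupancy tensor of shape
(N, M, L).  Summing over sequences gives the integer position frequency
matrix F (M x L): ``F[k, l]`` counts how often symbol ``k`` occurs in column
``l``, and every column sums to N.

Columns dominated by gaps carry little signal about the family and distort
the downstream correlations, so columns where the fraction of natural
(non-gap) residues

    q_l = (sum of the 20 amino-acid counts at l) / N

falls below a threshold (default 20%) are deleted.  The comparison is
strict: a column at exactly the threshold is kept.  A :class:`PositionMap`
records which original columns survive, so every reduced-index result can be
traced back to the input alignment and, optionally, to the residue numbering
of a named reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ReductionError, ValidationError
from .msa_io import GAP, PROTEIN, Alignment, Alphabet

__all__ = [
    "FrequencyMatrix",
    "PositionMap",
    "encode",
    "position_frequencies",
    "natural_fraction",
    "reduce_gaps",
    "map_reference_numbering",
]

DEFAULT_GAP_THRESHOLD = 0.20


@dataclass(frozen=True)
class FrequencyMatrix:
    """Integer residue counts per alignment column.

    Attributes
    ----------
    counts:
        (M, L) non-negative integers; row 0 is the gap, rows 1..20 the amino
        acids.  Each column sums to ``n_sequences``.
    n_sequences:
        Number of sequences N the counts were tallied over.
    reduced:
        True once gap-dominated columns have been removed.
    """

    counts: np.ndarray
    n_sequences: int
    reduced: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != PROTEIN.size:
            raise ValidationError(
                f"frequency matrix must be 21 x L, got shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("frequency counts must be integers")
        if (counts < 0).any():
            raise ValidationError("frequency counts must be non-negative")
        sums = counts.sum(axis=0)
        if not (sums == self.n_sequences).all():
            raise ValidationError(
                "every frequency column must sum to the sequence count"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PositionMap:
    """Trace from reduced column indices back to the original alignment.

    ``kept`` holds 0-based original column indices (strictly increasing);
    ``q`` holds the natural-residue fraction of *every* original column.
    When a reference sequence has been mapped, ``reference_numbering[r]`` is
    the 1-based residue ordinal of the reference at kept column ``r``, or
    ``None`` where the reference itself has a gap.
    """

    kept: tuple[int, ...]
    q: tuple[float, ...]
    threshold: float
    reference_id: str | None = None
    reference_numbering: tuple[int | None, ...] | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.kept, self.kept[1:])):
            raise ValidationError("kept column indices must strictly increase")
        if self.reference_numbering is not None:
            present = [x for x in self.reference_numbering if x is not None]
            if any(b <= a for a, b in zip(present, present[1:])):
                raise ValidationError(
                    "reference numbering must strictly increase where defined"
                )

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_json_dict(self) -> dict:
        """JSON-ready form; kept columns reported 1-based."""
        ref = None
        if self.reference_id is not None:
            ref = {
                "id": self.reference_id,
                "numbering": list(self.reference_numbering or ()),
            }
        return {
            "kept": [k + 1 for k in self.kept],
            "q": [float(v) for v in self.q],
            "threshold": self.threshold,
            "reference": ref,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "PositionMap":
        ref = data.get("reference") or {}
        numbering = ref.get("numbering")
        return cls(
            kept=tuple(k - 1 for k in data["kept"]),
            q=tuple(data["q"]),
            threshold=float(data.get("threshold", DEFAULT_GAP_THRESHOLD)),
            reference_id=ref.get("id"),
            reference_numbering=tuple(numbering) if numbering is not None else None,
        )


def encode(alignment: Alignment, alphabet: Alphabet = PROTEIN) -> np.ndarray:
    """One-hot encode an alignment into a binary tensor of shape (N, M, L).

    Entry ``(i, k, l)`` is 1 exactly when sequence ``i`` carries symbol ``k``
    at column ``l``; each (i, l) slice therefore sums to 1.
    """
    n, length = alignment.n_sequences, alignment.length
    codes = np.empty((n, length), dtype=np.intp)
    for i, row in enumerate(alignment.rows):
        codes[i] = [alphabet.index[ch] for ch in row]
    tensor = np.zeros((n, alphabet.size, length), dtype=np.uint8)
    seq_idx = np.repeat(np.arange(n), length)
    col_idx = np.tile(np.arange(length), n)
    tensor[seq_idx, codes.ravel(), col_idx] = 1
    return tensor


def position_frequencies(tensor: np.ndarray) -> FrequencyMatrix:
    """Tally the occupancy tensor into the integer frequency matrix F (M x L)."""
    tensor = np.asarray(tensor)
    if tensor.ndim != 3 or tensor.shape[1] != PROTEIN.size:
        raise ValidationError(
            f"occupancy tensor must be (N, 21, L), got {tensor.shape}"
        )
    counts = tensor.sum(axis=0, dtype=np.int64)
    return FrequencyMatrix(counts=counts, n_sequences=tensor.shape[0])


def natural_fraction(freq: FrequencyMatrix) -> np.ndarray:
    """Fraction q_l of natural (non-gap) residues at each column, in [0, 1]."""
    return freq.counts[1:].sum(axis=0) / freq.n_sequences


def reduce_gaps(
    freq: FrequencyMatrix,
    threshold: float = DEFAULT_GAP_THRESHOLD,
) -> tuple[FrequencyMatrix, PositionMap]:
    """Delete gap-dominated columns (q_l strictly below ``threshold``).

    Returns the reduced frequency matrix (gap row retained — residual gaps
    in surviving columns still participate in the statistics) and the
    :class:`PositionMap` tracing reduced to original columns.

    Raises
    ------
    ReductionError
        If no column survives.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("gap threshold must lie in [0, 1]")
    q = natural_fraction(freq)
    kept = np.flatnonzero(q >= threshold)
    if kept.size == 0:
        raise ReductionError(
            "gap reduction removed every column of the alignment"
        )
    reduced = FrequencyMatrix(
        counts=freq.counts[:, kept], n_sequences=freq.n_sequences, reduced=True
    )
    position_map = PositionMap(
        kept=tuple(int(k) for k in kept),
        q=tuple(float(v) for v in q),
        threshold=threshold,
    )
    return reduced, position_map


def map_reference_numbering(
    alignment: Alignment,
    position_map: PositionMap,
    reference_id: str,
) -> PositionMap:
    """Attach reference-sequence residue numbering to a position map.

    For each kept column the numbering is the 1-based count of non-gap
    residues of the reference sequence up to and including that column, or
    ``None`` where the reference has a gap (rendered as an explicit absent
    marker in reports).
    """
    try:
        ref_row = alignment.rows[alignment.ids.index(reference_id)]
    except ValueError:
        raise ValidationError(
            f"reference sequence {reference_id!r} not found in alignment"
        ) from None
    ordinal = 0
    per_column: list[int | None] = []
    for ch in ref_row:
        if ch == GAP:
            per_column.append(None)
        else:
            ordinal += 1
            per_column.append(ordinal)
    numbering = tuple(per_column[k] for k in position_map.kept)
    return replace(
        position_map,
        reference_id=reference_id,
        reference_numbering=numbering,
    )
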