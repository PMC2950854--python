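"""Conservation and mutation correlation matrices.

Two L x L Pearson correlation matrices are computed over the 21-dimensional
symbol profiles of alignment columns:

* **Conservation flavour** — profiles are the integer residue counts
  ``F[:, l]``.  Two columns correlate when the same symbols are frequent or
  rare together across the family.

* **Mutation flavour** — profiles are per-symbol *mutative factors*

      t(f; N, n) = (n - 1) / (|f - N/n| + 1)

  where ``f`` is the symbol's count at the column, ``N`` the number of
  sequences and ``n`` the number of distinct symbols (gap included) observed
  at the column.  ``N/n`` is the column's average symbol frequency.  The
  factor is largest (value ``n - 1``) when a symbol sits exactly at that
  average — the signature of an actively mutating position — and is
  identically zero at invariant columns (``n = 1``).  The ``+1`` in the
  denominator keeps the value finite at the average; the ``-1`` in the
  numerator zeroes invariant columns.

Correlations are computed over all 21 symbol indices by default; the gap row
can be excluded via ``include_gap_row=False``.  Columns whose profile has
zero variance cannot carry a correlation: they are reported in
``undefined_positions`` and their rows/columns are set to 0 off-diagonal
(diagonal 1 by convention) instead of propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .frequencies import FrequencyMatrix
from .msa_io import PROTEIN

__all__ = [
    "MutationMatrix",
    "CorrelationMatrix",
    "amino_acid_types",
    "mutative_factor",
    "mutation_matrix",
    "profile_correlation",
    "conservation_correlation",
    "mutation_correlation",
]

MAX_TYPES = PROTEIN.size  # 21: the 20 amino acids plus the gap


@dataclass(frozen=True)
class MutationMatrix:
    """Per-symbol, per-column mutative factors.

    ``values[k, l] = t(F[k, l]; N, n_l)`` for all 21 symbols, including
    symbols absent from the column (their count is 0).  Invariant columns
    (``n_l = 1``) are identically zero; no value exceeds ``n_l - 1``.
    """

    values: np.ndarray
    n_sequences: int
    n_types: np.ndarray  # per-column distinct-symbol count n_l

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric L x L Pearson correlation matrix of column profiles.

    ``flavor`` is ``"conservation"`` or ``"mutation"``.
    ``undefined_positions`` holds 0-based columns whose profile had zero
    variance; their correlations are 0 by convention (diagonal 1).
    """

    values: np.ndarray
    flavor: str
    undefined_positions: tuple[int, ...] = ()

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]


def amino_acid_types(freq: FrequencyMatrix) -> np.ndarray:
    """Number of distinct symbols n_l (gap included) observed per column."""
    return np.count_nonzero(freq.counts, axis=0)


def mutative_factor(f, n_sequences: int, n_types) -> np.ndarray | float:
    """Mutative factor t(f; N, n) = (n - 1) / (|f - N/n| + 1).

    Accepts scalars or arrays (broadcast together).  ``N/n`` is kept as an
    exact real; ``f`` is an (integer) count but any real in [0, N] is valid.

    Raises
    ------
    DomainError
        If ``f`` is outside [0, N], ``n`` outside [1, 21] or ``N < 1``.
    """
    f = np.asarray(f, dtype=float)
    n = np.asarray(n_types, dtype=float)
    if n_sequences < 1:
        raise DomainError(f"sample count must be >= 1, got {n_sequences}")
    if ((f < 0) | (f > n_sequences)).any():
        raise DomainError(f"frequency must lie in [0, {n_sequences}]")
    if ((n < 1) | (n > MAX_TYPES)).any():
        raise DomainError(f"type count must lie in [1, {MAX_TYPES}]")
    t = (n - 1.0) / (np.abs(f - n_sequences / n) + 1.0)
    return t if t.shape else float(t)


def mutation_matrix(freq: FrequencyMatrix) -> MutationMatrix:
    """Build the 21 x L mutative-factor matrix T from a frequency matrix."""
    n_types = amino_acid_types(freq)
    values = mutative_factor(
        freq.counts.astype(float),
        freq.n_sequences,
        n_types[np.newaxis, :],
    )
    return MutationMatrix(
        values=np.asarray(values),
        n_sequences=freq.n_sequences,
        n_types=n_types,
    )


def profile_correlation(
    profile: np.ndarray,
    flavor: str = "conservation",
    ddof: int = 0,
) -> CorrelationMatrix:
    """Pearson correlation between all pairs of column profiles.

    Parameters
    ----------
    profile:
        (M, L) matrix; column ``l`` is the symbol profile of position ``l``.
    flavor:
        Tag stored on the result ("conservation" or "mutation").
    ddof:
        Covariance divisor ``M - ddof``.  It cancels in the correlation, so
        the result is identical for 0 and 1; exposed for covariance exports.

    Notes
    -----
    Zero-variance profiles are flagged in ``undefined_positions`` with their
    correlations set to 0 (diagonal 1).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2:
        raise ValidationError("profile matrix must be 2-D (symbols x positions)")
    m, length = profile.shape
    if length < 2:
        raise ValidationError("need at least 2 positions to correlate")
    centred = profile - profile.mean(axis=0, keepdims=True)
    cov = centred.T @ centred / (m - ddof)
    var = np.diag(cov).copy()
    undefined = np.flatnonzero(var <= 0.0)
    scale = np.sqrt(np.where(var > 0.0, var, 1.0))
    corr = cov / np.outer(scale, scale)
    corr[undefined, :] = 0.0
    corr[:, undefined] = 0.0
    corr[undefined, undefined] = 1.0  # diagonal restored by convention
    return CorrelationMatrix(
        values=corr,
        flavor=flavor,
        undefined_positions=tuple(int(i) for i in undefined),
    )


def _select_rows(matrix: np.ndarray, include_gap_row: bool) -> np.ndarray:
    return matrix if include_gap_row else matrix[1:]


def conservation_correlation(
    freq: FrequencyMatrix,
    include_gap_row: bool = True,
    ddof: int = 0,
) -> CorrelationMatrix:
    """Position conservation correlation matrix from residue-count profiles."""
    profile = _select_rows(freq.counts.astype(float), include_gap_row)
    return profile_correlation(profile, flavor="conservation", ddof=ddof)


def mutation_correlation(
    freq: FrequencyMatrix,
    include_gap_row: bool = True,
    ddof: int = 0,
) -> CorrelationMatrix:
    """Position mutation correlation matrix from mutative-factor profiles.

    The per-column type count ``n_l`` always counts the gap; the
    ``include_gap_row`` switch only controls whether the gap's own factor
    enters the correlation sums.
    """
    t_matrix = mutation_matrix(freq)
    profile = _select_rows(t_matrix.values, include_gap_row)
    return profile_correlation(profile, flavor="mutation", ddof=ddof)
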