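"""Optional rendering of correlation matrices as heatmaps and contour maps.

The colour convention bands correlations at 0.70 / 0.80 / 0.90: entries
above 0.90 red, above 0.80 pink, above 0.70 orange, and everything between
the display floor and 0.70 pale yellow.  Entries below the floor and the
self-correlation diagonal are masked.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # file output only; no display needed

import matplotlib.pyplot as plt
from matplotlib.colors import BoundaryNorm, ListedColormap

from .correlation import CorrelationMatrix
from .coupling import DEFAULT_DISPLAY_FLOOR, filter_display

__all__ = ["plot_heatmap", "plot_contour"]

_BAND_COLORS = ["#fff7bc", "#fe9929", "#fa9fb5", "#d7191c"]


def _banded_cmap(floor: float):
    bounds = [floor, 0.70, 0.80, 0.90, 1.0]
    bounds = sorted(set(b for b in bounds if b >= floor)) or [floor, 1.0]
    cmap = ListedColormap(_BAND_COLORS[-(len(bounds) - 1):])
    return cmap, BoundaryNorm(bounds, cmap.N)


def plot_heatmap(
    matrix: CorrelationMatrix,
    path: str | Path,
    floor: float = DEFAULT_DISPLAY_FLOOR,
    title: str | None = None,
) -> Path:
    """Banded heatmap of a masked correlation matrix."""
    masked = filter_display(matrix, floor=floor)
    cmap, norm = _banded_cmap(floor)
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    image = ax.imshow(
        masked, cmap=cmap, norm=norm, origin="lower",
        extent=(0.5, matrix.n_positions + 0.5, 0.5, matrix.n_positions + 0.5),
    )
    ax.set_xlabel("position j")
    ax.set_ylabel("position i")
    ax.set_title(title or f"{matrix.flavor} correlation")
    fig.colorbar(image, ax=ax, label="r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_contour(
    matrix: CorrelationMatrix,
    path: str | Path,
    floor: float = DEFAULT_DISPLAY_FLOOR,
    title: str | None = None,
) -> Path:
    """Filled contour map of a masked correlation matrix."""
    masked = filter_display(matrix, floor=floor)
    cmap, norm = _banded_cmap(floor)
    positions = range(1, matrix.n_positions + 1)
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    contour = ax.contourf(
        positions, positions, masked,
        levels=norm.boundaries, cmap=cmap, norm=norm,
    )
    ax.set_xlabel("position j")
    ax.set_ylabel("position i")
    ax.set_title(title or f"{matrix.flavor} correlation")
    fig.colorbar(contour, ax=ax, label="r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
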