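"""End-to-end orchestration: alignment in, matrices and coupling report out.

The pipeline runs the full analysis in order: read and validate the
alignment, one-hot encode, tally position frequencies, delete gap-dominated
columns, optionally map a reference sequence's residue numbering, build the
conservation and mutation correlation matrices, extract coupled pairs,
cluster them into regions, and connect them into mutative groups.  Every
stage writes its result to the output directory so each can be inspected or
re-thresholded without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .correlation import (
    conservation_correlation,
    mutation_correlation,
    mutation_matrix,
)
from .coupling import (
    DEFAULT_DISPLAY_FLOOR,
    DEFAULT_MIN_GROUP_SIZE,
    DEFAULT_PAIR_THRESHOLD,
    DEFAULT_REGION_RADIUS,
    build_groups,
    cluster_regions,
    extract_pairs,
    report,
    write_report,
)
from .errors import ConfigError
from .frequencies import (
    DEFAULT_GAP_THRESHOLD,
    encode,
    map_reference_numbering,
    position_frequencies,
    reduce_gaps,
)
from .msa_io import PROTEIN, read_alignment, write_matrix

logger = logging.getLogger("cmca")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    input: str
    outdir: str
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    pair_threshold: float = DEFAULT_PAIR_THRESHOLD
    display_floor: float = DEFAULT_DISPLAY_FLOOR
    include_gap_row: bool = True
    region_radius: int = DEFAULT_REGION_RADIUS
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE
    reference: str | None = None
    plot: bool = False

    def __post_init__(self) -> None:
        for name in ("gap_threshold", "pair_threshold", "display_floor"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.region_radius < 0:
            raise ConfigError("region_radius must be >= 0")
        if self.min_group_size < 2:
            raise ConfigError("min_group_size must be >= 2")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write all outputs to ``config.outdir``.

    Writes ``frequency.tsv`` (reduced counts, columns labelled by original
    1-based index), ``position_map.json``, ``mutation_matrix.tsv``,
    ``r_con.tsv`` / ``r_mut.tsv`` (reduced 1-based labels), ``pairs.tsv``,
    ``report.json`` and, with ``plot=True``, heatmap/contour figures.
    """
    in_path = Path(config.input)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    alignment, replaced = read_alignment(in_path)
    logger.info(
        "alignment: %d sequences x %d columns (%d residue codes mapped to gap)",
        alignment.n_sequences, alignment.length, replaced,
    )

    freq0 = position_frequencies(encode(alignment))
    freq, position_map = reduce_gaps(freq0, threshold=config.gap_threshold)
    deleted = freq0.n_columns - freq.n_columns
    logger.info(
        "gap reduction: %d of %d columns deleted, %d kept",
        deleted, freq0.n_columns, freq.n_columns,
    )
    if config.reference is not None:
        position_map = map_reference_numbering(
            alignment, position_map, config.reference
        )

    kept_labels = [k + 1 for k in position_map.kept]
    reduced_labels = list(range(1, freq.n_columns + 1))
    symbols = list(PROTEIN.symbols)

    write_matrix(freq.counts, symbols, kept_labels, outdir / "frequency.tsv")
    (outdir / "position_map.json").write_text(
        json.dumps(position_map.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )

    t_matrix = mutation_matrix(freq)
    write_matrix(
        t_matrix.values, symbols, kept_labels, outdir / "mutation_matrix.tsv"
    )

    r_con = conservation_correlation(freq, include_gap_row=config.include_gap_row)
    r_mut = mutation_correlation(freq, include_gap_row=config.include_gap_row)
    write_matrix(r_con.values, reduced_labels, reduced_labels, outdir / "r_con.tsv")
    write_matrix(r_mut.values, reduced_labels, reduced_labels, outdir / "r_mut.tsv")

    pairs = extract_pairs(
        r_mut, threshold=config.pair_threshold, position_map=position_map
    )
    regions = cluster_regions(pairs, radius=config.region_radius)
    groups = build_groups(pairs, min_size=config.min_group_size)
    logger.info(
        "coupling: %d pairs in %d regions forming %d groups",
        len(pairs), len(regions), len(groups),
    )

    parameters = asdict(config)
    # paths live in provenance (by name/checksum); keeping them out of the
    # parameter block makes report.json identical across output locations
    parameters.pop("input")
    parameters.pop("outdir")
    provenance = {
        "package": "cmca",
        "version": __version__,
        "input": in_path.name,
        "input_sha256": _sha256(in_path),
        "n_sequences": alignment.n_sequences,
        "n_columns_original": freq0.n_columns,
        "n_columns_deleted": deleted,
        "n_columns_reduced": freq.n_columns,
    }
    coupling_report = report(
        pairs,
        regions,
        groups,
        position_map=position_map,
        undefined_positions=tuple(p + 1 for p in r_mut.undefined_positions),
        parameters=parameters,
        provenance=provenance,
    )
    write_report(
        coupling_report, outdir / "report.json", outdir / "pairs.tsv"
    )

    if config.plot:
        from .viz import plot_contour, plot_heatmap

        plot_heatmap(r_mut, outdir / "heatmap.png", floor=config.display_floor)
        plot_contour(r_mut, outdir / "contour.png", floor=config.display_floor)

    return outdir
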