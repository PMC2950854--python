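"""Coupled-pair extraction, region clustering and mutative-group networks.

From a position correlation matrix three views are produced:

* **Pairs** — lower-triangle entries strictly above a threshold (default
  0.80), the candidate co-evolving position pairs.
* **Regions** — clusters of pair cells that sit close together in the
  (i, j) plane of the matrix, labelled R1, R2, ...  Clustering is
  single-linkage under Chebyshev distance with a configurable radius; the
  labels order clusters by their smallest member cell (ascending j, then i).
* **Groups** — connected components of the undirected graph whose vertices
  are positions and whose edges are the extracted pairs.  A component of
  mutually coupled positions is interpreted as a co-mutating evolutionary
  unit of the family.

For display, matrix entries below a floor (default 0.5) and the
self-correlation diagonal are masked.

All positions are reported in two numbering systems: the reduced-alignment
index (1-based) and, when a reference sequence is mapped, the residue number
in that reference ("–" where the reference has a gap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .correlation import CorrelationMatrix
from .errors import ConsistencyError, ValidationError
from .frequencies import PositionMap

__all__ = [
    "CouplingPair",
    "Region",
    "MutativeGroup",
    "CouplingReport",
    "filter_display",
    "extract_pairs",
    "cluster_regions",
    "build_groups",
    "report",
    "write_report",
]

DEFAULT_PAIR_THRESHOLD = 0.80
DEFAULT_DISPLAY_FLOOR = 0.5
DEFAULT_REGION_RADIUS = 5
DEFAULT_MIN_GROUP_SIZE = 2

#: Marker rendered for positions where the reference sequence has a gap.
ABSENT = "–"


@dataclass(frozen=True)
class CouplingPair:
    """One coupled position pair (i > j, 1-based reduced numbering)."""

    i: int
    j: int
    r: float
    region: str | None = None
    reference_i: int | None = None
    reference_j: int | None = None

    def __post_init__(self) -> None:
        if self.i <= self.j:
            raise ValidationError("pair must satisfy i > j")


@dataclass(frozen=True)
class Region:
    """A labelled cluster of pair cells in the (i, j) plane."""

    label: str
    pairs: tuple[CouplingPair, ...]
    i_range: tuple[int, int]
    j_range: tuple[int, int]


@dataclass(frozen=True)
class MutativeGroup:
    """A connected component of mutually coupled positions."""

    positions: tuple[int, ...]
    reference_positions: tuple[int | None, ...]
    pairs: tuple[tuple[int, int], ...]

    @property
    def size(self) -> int:
        return len(self.positions)


def filter_display(
    matrix: CorrelationMatrix,
    floor: float = DEFAULT_DISPLAY_FLOOR,
) -> np.ma.MaskedArray:
    """Mask entries below ``floor`` and the diagonal for display.

    The comparison keeps entries >= floor (an entry exactly at the floor
    survives); diagonal self-correlations are always masked.
    """
    values = matrix.values
    mask = values < floor
    np.fill_diagonal(mask, True)
    return np.ma.MaskedArray(values, mask=mask)


def _reference_lookup(position_map: PositionMap | None):
    if position_map is None or position_map.reference_numbering is None:
        return lambda pos: None
    numbering = position_map.reference_numbering

    def lookup(pos: int) -> int | None:  # pos is 1-based reduced index
        return numbering[pos - 1]

    return lookup


def extract_pairs(
    matrix: CorrelationMatrix,
    threshold: float = DEFAULT_PAIR_THRESHOLD,
    position_map: PositionMap | None = None,
) -> list[CouplingPair]:
    """Extract lower-triangle entries with r strictly above ``threshold``.

    Pairs are returned sorted by (i, j); an empty list is valid.  Reference
    numbering is attached when ``position_map`` carries it.
    """
    if position_map is not None and position_map.n_kept != matrix.n_positions:
        raise ConsistencyError(
            "position map and correlation matrix describe different runs"
        )
    ref = _reference_lookup(position_map)
    values = matrix.values
    ii, jj = np.nonzero(np.tril(values, k=-1) > threshold)
    pairs = [
        CouplingPair(
            i=int(i) + 1,
            j=int(j) + 1,
            r=float(values[i, j]),
            reference_i=ref(int(i) + 1),
            reference_j=ref(int(j) + 1),
        )
        for i, j in zip(ii, jj)
    ]
    return sorted(pairs, key=lambda p: (p.i, p.j))


def cluster_regions(
    pairs: list[CouplingPair],
    radius: int = DEFAULT_REGION_RADIUS,
) -> list[Region]:
    """Single-linkage clustering of pair cells under Chebyshev distance.

    Two pair cells join the same region when max(|di|, |dj|) <= radius
    (transitively).  Regions are labelled R1..Rk by ascending smallest
    member cell, ordered by (j, i).
    """
    if radius < 0:
        raise ValidationError("region radius must be >= 0")
    if not pairs:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(range(len(pairs)))
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            di = abs(pairs[a].i - pairs[b].i)
            dj = abs(pairs[a].j - pairs[b].j)
            if max(di, dj) <= radius:
                graph.add_edge(a, b)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: min((pairs[k].j, pairs[k].i) for k in c))
    regions = []
    for rank, members in enumerate(components, start=1):
        label = f"R{rank}"
        labelled = tuple(
            replace(pairs[k], region=label)
            for k in sorted(members, key=lambda k: (pairs[k].i, pairs[k].j))
        )
        regions.append(
            Region(
                label=label,
                pairs=labelled,
                i_range=(min(p.i for p in labelled), max(p.i for p in labelled)),
                j_range=(min(p.j for p in labelled), max(p.j for p in labelled)),
            )
        )
    return regions


def build_groups(
    pairs: list[CouplingPair],
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> list[MutativeGroup]:
    """Connected components of the position graph induced by the pairs.

    Components with fewer than ``min_size`` positions are dropped; groups
    are returned sorted by their smallest member position.
    """
    if min_size < 2:
        raise ValidationError("minimum group size must be >= 2")
    graph = nx.Graph()
    ref: dict[int, int | None] = {}
    for pair in pairs:
        graph.add_edge(pair.i, pair.j)
        ref[pair.i] = pair.reference_i
        ref[pair.j] = pair.reference_j
    groups = []
    for component in nx.connected_components(graph):
        if len(component) < min_size:
            continue
        positions = tuple(sorted(component))
        supporting = tuple(
            sorted(
                (p.i, p.j)
                for p in pairs
                if p.i in component and p.j in component
            )
        )
        groups.append(
            MutativeGroup(
                positions=positions,
                reference_positions=tuple(ref[p] for p in positions),
                pairs=supporting,
            )
        )
    return sorted(groups, key=lambda g: g.positions)


@dataclass(frozen=True)
class CouplingReport:
    """Machine-readable summary of one coupling analysis run."""

    pairs: tuple[CouplingPair, ...]
    regions: tuple[Region, ...]
    groups: tuple[MutativeGroup, ...]
    undefined_positions: tuple[int, ...]  # 1-based reduced indices
    parameters: dict
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "pairs": [
                {
                    "region": p.region,
                    "i": p.i,
                    "j": p.j,
                    "r": round(p.r, 6),
                    "reference_i": p.reference_i,
                    "reference_j": p.reference_j,
                }
                for p in self.pairs
            ],
            "regions": [
                {
                    "label": reg.label,
                    "pairs": [[p.i, p.j] for p in reg.pairs],
                    "i_range": list(reg.i_range),
                    "j_range": list(reg.j_range),
                }
                for reg in self.regions
            ],
            "groups": [
                {
                    "positions": list(g.positions),
                    "reference_positions": list(g.reference_positions),
                    "pairs": [list(p) for p in g.pairs],
                }
                for g in self.groups
            ],
            "undefined_positions": list(self.undefined_positions),
            "parameters": self.parameters,
            "provenance": self.provenance,
        }

    def to_tsv(self) -> str:
        """Table of pairs: region, i, j, r (6 decimals), ref_i, ref_j."""

        def fmt_ref(value: int | None) -> str:
            return ABSENT if value is None else str(value)

        lines = ["region\ti\tj\tr\tref_i\tref_j"]
        for p in self.pairs:
            lines.append(
                "\t".join(
                    [
                        p.region or "",
                        str(p.i),
                        str(p.j),
                        f"{p.r:.6f}",
                        fmt_ref(p.reference_i),
                        fmt_ref(p.reference_j),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def report(
    pairs: list[CouplingPair],
    regions: list[Region],
    groups: list[MutativeGroup],
    position_map: PositionMap | None = None,
    undefined_positions: tuple[int, ...] = (),
    parameters: dict | None = None,
    provenance: dict | None = None,
) -> CouplingReport:
    """Assemble the coupling report, with pairs labelled by their region.

    Pairs are ordered by (region rank, i, j); region labels come from
    ``regions``.  An empty analysis yields a valid empty report.
    """
    label_of = {}
    rank_of = {}
    for rank, reg in enumerate(regions):
        for p in reg.pairs:
            label_of[(p.i, p.j)] = reg.label
            rank_of[(p.i, p.j)] = rank
    n_kept = position_map.n_kept if position_map is not None else None
    labelled = []
    for pair in pairs:
        key = (pair.i, pair.j)
        if n_kept is not None and (pair.i > n_kept or pair.j < 1):
            raise ConsistencyError(
                f"pair {key} lies outside the reduced alignment (L={n_kept})"
            )
        labelled.append(replace(pair, region=label_of.get(key)))
    labelled.sort(key=lambda p: (rank_of.get((p.i, p.j), len(regions)), p.i, p.j))
    return CouplingReport(
        pairs=tuple(labelled),
        regions=tuple(regions),
        groups=tuple(groups),
        undefined_positions=tuple(undefined_positions),
        parameters=parameters or {},
        provenance=provenance or {},
    )


def write_report(
    coupling_report: CouplingReport,
    json_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write the report as JSON and as a table-style TSV."""
    Path(json_path).write_text(
        json.dumps(coupling_report.to_json_dict(), indent=2, sort_keys=True)
        + "\n"
    )
    Path(tsv_path).write_text(coupling_report.to_tsv())
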