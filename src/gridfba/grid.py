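"""Rectangular grid geometry for the discretised cell.

A cell is idealised as an ``I x J`` rectangle of unit square regions.
Region ``(i, j)`` has a *layer* index — the depth of the concentric
rectangular peel it belongs to, ``min(i, j, I-1-i, J-1-j)`` — with layer 0
the outermost ring of regions touching the plasma membrane.  Adjacency is
4-connected (edge-sharing squares only); the extracellular medium is a
single homogeneous compartment outside the grid, not a region.

The perimeter-to-area ratio (boundary regions / total regions) is the 2-D
analogue of the surface-area-to-volume ratio and is the shape descriptor
used throughout the experiment battery.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Region", "Grid", "build_grid", "pa_ratio", "regions_in_layer", "PAPER_SHAPES"]

#: The five 36-region shapes used in the shape sweeps.
PAPER_SHAPES = [(1, 36), (2, 18), (3, 12), (4, 9), (6, 6)]


@dataclass(frozen=True, order=True)
class Region:
    row: int
    col: int
    layer: int
    is_boundary: bool

    @property
    def key(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class Grid:
    rows: int
    cols: int
    regions: tuple[Region, ...]          # row-major order
    neighbour_pairs: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "_by_key", {r.key: r for r in self.regions}
        )

    def region(self, i: int, j: int) -> Region:
        return self._by_key[(i, j)]

    @property
    def n_regions(self) -> int:
        return self.rows * self.cols

    @property
    def max_layer(self) -> int:
        return max(r.layer for r in self.regions)

    def boundary_regions(self) -> list[Region]:
        return [r for r in self.regions if r.is_boundary]

    def to_table(self):
        """Tidy per-region table (i, j, layer, is_boundary) for inspection."""
        import pandas as pd

        return pd.DataFrame(
            {
                "i": [r.row for r in self.regions],
                "j": [r.col for r in self.regions],
                "layer": [r.layer for r in self.regions],
                "is_boundary": [r.is_boundary for r in self.regions],
            }
        )


def build_grid(rows: int, cols: int) -> Grid:
    """Enumerate regions, layers and 4-connected neighbour pairs of an I x J grid."""
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    regions = []
    for i in range(rows):
        for j in range(cols):
            layer = min(i, j, rows - 1 - i, cols - 1 - j)
            regions.append(Region(i, j, layer, layer == 0))
    pairs = []
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                pairs.append(((i, j), (i, j + 1)))
            if i + 1 < rows:
                pairs.append(((i, j), (i + 1, j)))
    return Grid(rows, cols, tuple(regions), tuple(pairs))


def pa_ratio(grid: Grid) -> float:
    """Boundary regions over total regions — the 2-D surface-to-volume proxy."""
    return len(grid.boundary_regions()) / grid.n_regions


def regions_in_layer(grid: Grid, layer: int) -> list[Region]:
    if not 0 <= layer <= grid.max_layer:
        raise ValueError(
            f"layer {layer} out of range 0..{grid.max_layer} for {grid.rows}x{grid.cols} grid"
        )
    return [r for r in grid.regions if r.layer == layer]
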