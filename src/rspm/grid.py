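"""Bounded hexagonal patch lattice.

Patches tile the surface as pointy-top hexagons addressed by (row, col) in an
odd-r offset layout, with six neighbours each and centre-to-centre spacing
``l_p``.  The domain is bounded (non-periodic); missing neighbours are encoded
as -1 in the neighbour table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Pointy-top, odd-r offset neighbour displacements: (d_row, d_col) for even
# and odd rows.  Order: E, W, NE, NW, SE, SW.
_EVEN_ROW_OFFSETS = np.array(
    [(0, 1), (0, -1), (-1, 0), (-1, -1), (1, 0), (1, -1)], dtype=np.int64
)
_ODD_ROW_OFFSETS = np.array(
    [(0, 1), (0, -1), (-1, 1), (-1, 0), (1, 1), (1, 0)], dtype=np.int64
)

#: Regular-hexagon patch area for circumdiameter l_p: (3*sqrt(3)/8) * l_p^2.
HEX_AREA_FACTOR = 3.0 * np.sqrt(3.0) / 8.0

#: Shared edge length between adjacent patches, as a fraction of l_p.
HEX_EDGE_FACTOR = 0.5


@dataclass
class HexLattice:
    """Geometry and adjacency of an ``n_rows x n_cols`` hexagonal lattice."""

    n_rows: int
    n_cols: int
    l_p: float = 5e-4

    neighbors: np.ndarray = field(init=False, repr=False)
    positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("degenerate grid: need at least 4x4 patches")
        if self.l_p <= 0:
            raise ValueError("patch size l_p must be positive")
        self.neighbors = self._build_neighbors()
        self.positions = self._build_positions()

    # ------------------------------------------------------------------
    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def patch_area(self) -> float:
        """Patch area in m^2."""
        return HEX_AREA_FACTOR * self.l_p**2

    @property
    def edge_length(self) -> float:
        """Length of the shared edge between two adjacent patches, m."""
        return HEX_EDGE_FACTOR * self.l_p

    def index(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, idx):
        idx = np.asarray(idx)
        return idx // self.n_cols, idx % self.n_cols

    # ------------------------------------------------------------------
    def _build_neighbors(self) -> np.ndarray:
        rows, cols = np.divmod(np.arange(self.n_patches), self.n_cols)
        nbr = np.full((self.n_patches, 6), -1, dtype=np.int64)
        for k in range(6):
            even = _EVEN_ROW_OFFSETS[k]
            odd = _ODD_ROW_OFFSETS[k]
            dr = np.where(rows % 2 == 0, even[0], odd[0])
            dc = np.where(rows % 2 == 0, even[1], odd[1])
            rr, cc = rows + dr, cols + dc
            ok = (rr >= 0) & (rr < self.n_rows) & (cc >= 0) & (cc < self.n_cols)
            nbr[ok, k] = rr[ok] * self.n_cols + cc[ok]
        return nbr

    def _build_positions(self) -> np.ndarray:
        rows, cols = np.divmod(np.arange(self.n_patches), self.n_cols)
        x = (cols + 0.5 * (rows % 2)) * self.l_p
        y = rows * (np.sqrt(3.0) / 2.0) * self.l_p
        return np.column_stack([x, y])

    # ------------------------------------------------------------------
    def edges(self) -> np.ndarray:
        """Unique undirected adjacent pairs, shape (E, 2), i < j."""
        i = np.repeat(np.arange(self.n_patches), 6)
        j = self.neighbors.ravel()
        ok = (j >= 0) & (i < j)
        return np.column_stack([i[ok], j[ok]])

    def boundary_mask(self) -> np.ndarray:
        """Boolean mask of patches on the lattice boundary."""
        rows, cols = np.divmod(np.arange(self.n_patches), self.n_cols)
        return (
            (rows == 0)
            | (rows == self.n_rows - 1)
            | (cols == 0)
            | (cols == self.n_cols - 1)
        )

    def center_patches(self, n: int = 4) -> np.ndarray:
        """Indices of the ``n`` patches closest to the domain centroid."""
        centre = self.positions.mean(axis=0)
        d2 = ((self.positions - centre) ** 2).sum(axis=1)
        return np.argsort(d2)[:n]

    def unbiased_direction_probabilities(self, idx: int) -> np.ndarray:
        """Uniform probabilities over in-domain moves + stay (used in tests)."""
        opts = np.append(self.neighbors[idx][self.neighbors[idx] >= 0], idx)
        return np.full(opts.size, 1.0 / opts.size)
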