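"""Tensor-product piecewise-constant (degree-0) spline basis on a knot grid.

The domain rectangle is partitioned by k1 regularly spaced interior knots in
the north-south (y) direction and k2 in the east-west (x) direction into
m1 x m2 cells, m1 = k1 + 1 and m2 = k2 + 1.  The spatially varying
coefficient surface is constant within each cell: beta(l) = phi_ij for l in
cell (i, j).  Exactly one basis function is 1 at any location (partition of
unity), which is what makes the basis a piecewise-constant B-spline basis.

Conventions (fixed so coefficient indexing is unambiguous):

* i in 1..m1 indexes the north-south direction, increasing with y (south to
  north); j in 1..m2 indexes east-west, increasing with x.
* cells are half-open, [a, b) in both axes, except the final (north / east)
  edge which is closed so boundary sites are never lost;
* flat (0-based) cell index q = (j - 1) * m1 + (i - 1) — row-major with the
  north-south index i fastest.

Basis *trimming* removes cells containing no observations (the model never
has data to identify them); the kept-cell count Q and a flat->kept index
remap live on the basis object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SplineBasis:
    """Knot grid + cell indexing for the degree-0 tensor-product basis."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    k1: int  # interior knots, north-south (y)
    k2: int  # interior knots, east-west (x)
    kept_mask: np.ndarray = field(default=None)  # bool, length m1*m2

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("degenerate (zero-area) domain")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("knot counts must be >= 0")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.m1 * self.m2, dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (self.m1 * self.m2,):
                raise ValueError("kept_mask length must be m1*m2")

    @property
    def m1(self) -> int:
        return self.k1 + 1

    @property
    def m2(self) -> int:
        return self.k2 + 1

    @property
    def n_cells(self) -> int:
        return self.m1 * self.m2

    @property
    def Q(self) -> int:
        """Number of kept (untrimmed) cells."""
        return int(self.kept_mask.sum())

    @property
    def kept_index(self) -> np.ndarray:
        """Flat cell index -> index into the length-Q coefficient vector
        (-1 for trimmed cells)."""
        idx = np.full(self.n_cells, -1, dtype=int)
        idx[self.kept_mask] = np.arange(self.Q)
        return idx

    # ---- geometry ------------------------------------------------------
    def y_edges(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.m1 + 1)

    def x_edges(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.m2 + 1)

    def flat(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """(i, j) 1-based cell indices -> flat 0-based index."""
        return (np.asarray(j) - 1) * self.m1 + (np.asarray(i) - 1)

    def cell_of(self, q: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Flat 0-based index -> (i, j) 1-based."""
        q = np.asarray(q)
        return q % self.m1 + 1, q // self.m1 + 1

    def locate(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map locations to 1-based cell indices (i, j).

        Half-open [a, b) convention: a point exactly on an interior knot is
        assigned to the higher cell; the top/east domain edge is closed.
        Locations outside the domain raise, naming the offending coordinate.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if np.any(x < self.x_min) or np.any(x > self.x_max):
            bad = x[(x < self.x_min) | (x > self.x_max)][0]
            raise ValueError(f"x coordinate {bad} outside domain "
                             f"[{self.x_min}, {self.x_max}]")
        if np.any(y < self.y_min) or np.any(y > self.y_max):
            bad = y[(y < self.y_min) | (y > self.y_max)][0]
            raise ValueError(f"y coordinate {bad} outside domain "
                             f"[{self.y_min}, {self.y_max}]")
        # searchsorted on interior edges implements [a, b); clip closes the
        # final edge.
        i = np.searchsorted(self.y_edges()[1:-1], y, side="right") + 1
        j = np.searchsorted(self.x_edges()[1:-1], x, side="right") + 1
        i = np.minimum(i, self.m1)
        j = np.minimum(j, self.m2)
        return i, j

    def basis_row(self, x: float, y: float) -> np.ndarray:
        """All m1*m2 basis functions evaluated at one location (0/1)."""
        i, j = self.locate(x, y)
        row = np.zeros(self.n_cells)
        row[self.flat(i, j)[0]] = 1.0
        return row

    def site_cell_index(self, x, y) -> np.ndarray:
        """Kept-cell coefficient index for each location.

        Raises if any location falls in a trimmed cell (the surface is not
        defined outside the fitted support).
        """
        i, j = self.locate(x, y)
        q = self.flat(i, j)
        kidx = self.kept_index[q]
        if np.any(kidx < 0):
            bad = int(q[kidx < 0][0])
            raise ValueError(f"location falls in trimmed cell (flat index {bad})")
        return kidx


def build_knot_grid(
    x_min: float, x_max: float, y_min: float, y_max: float, k1: int, k2: int
) -> SplineBasis:
    """Build the m1 x m2 knot-grid basis over a rectangular domain."""
    return SplineBasis(x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max,
                       k1=k1, k2=k2)


def evaluate_beta(basis: SplineBasis, phi: np.ndarray, x, y) -> np.ndarray:
    """Evaluate the piecewise-constant coefficient surface.

    ``phi`` has length Q (one coefficient per kept cell, in kept order).
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (basis.Q,):
        raise ValueError(f"phi must have length Q={basis.Q}, got {phi.shape}")
    return phi[basis.site_cell_index(x, y)]


def trim_basis(basis: SplineBasis, x, y) -> SplineBasis:
    """Keep exactly the cells containing at least one site."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size == 0:
        raise ValueError("trim_basis requires at least one site")
    i, j = basis.locate(x, y)
    mask = np.zeros(basis.n_cells, dtype=bool)
    mask[basis.flat(i, j)] = True
    return SplineBasis(
        x_min=basis.x_min, x_max=basis.x_max,
        y_min=basis.y_min, y_max=basis.y_max,
        k1=basis.k1, k2=basis.k2, kept_mask=mask,
    )
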