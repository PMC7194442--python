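"""Intrinsic CAR (ICAR) graph structure and log density.

An ICAR prior on a vector x over a graph with binary adjacency W and degree
matrix D is the improper Gaussian with precision s*(D - W):

    log p(x | s)  =  const  -  (s / 2) * x' (D - W) x
                  =  const  -  (s / 4) * sum over edges (x_q - x_q')^2,

invariant to adding a constant within each connected component.  D - W is
the graph Laplacian: symmetric PSD, row sums zero, rank n - n_components.
Only the quadratic form enters MCMC; where a proper density is needed
(simulation, marginal checks) we work on the sum-to-zero subspace using the
pseudo-determinant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .splines import SplineBasis


@dataclass
class CARStructure:
    """Adjacency W (sparse binary, symmetric, zero diagonal), degrees and
    component structure of an ICAR graph."""

    W: sp.csr_matrix
    precision_scale: float = 1.0

    def __post_init__(self) -> None:
        self.W = sp.csr_matrix(self.W, dtype=float)
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if (self.W != self.W.T).nnz:
            raise ValueError("W must be symmetric")
        if self.W.diagonal().any():
            raise ValueError("W must have zero diagonal")
        if self.precision_scale <= 0:
            raise ValueError("precision_scale must be > 0")
        # immutable after construction: cache the derived structure
        self._degrees = np.asarray(self.W.sum(axis=1)).ravel()
        self._laplacian = (sp.diags(self._degrees) - self.W).tocsr()
        ncomp, labels = connected_components(self.W, directed=False)
        self._n_components = int(ncomp)
        self._component_labels = labels

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self._degrees

    @property
    def D(self) -> sp.csr_matrix:
        return sp.diags(self._degrees).tocsr()

    @property
    def laplacian(self) -> sp.csr_matrix:
        """D - W, the ICAR precision structure."""
        return self._laplacian

    @property
    def n_components(self) -> int:
        return self._n_components

    @property
    def component_labels(self) -> np.ndarray:
        return self._component_labels

    @property
    def rank(self) -> int:
        """Rank of D - W: n minus the number of connected components."""
        return self.n - self.n_components

    # ---- density -------------------------------------------------------
    def quadratic_form(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"x must have length {self.n}, got {x.shape}")
        return float(x @ (self.laplacian @ x))

    def log_density(self, x: np.ndarray, scale: float | None = None) -> float:
        """Unnormalized ICAR log density -(s/2) x'(D-W)x."""
        s = self.precision_scale if scale is None else scale
        return -0.5 * s * self.quadratic_form(x)

    # ---- simulation (proper, sum-to-zero subspace) ---------------------
    def sample_constrained(
        self, variance: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw from the ICAR restricted to the sum-to-zero subspace.

        Eigendecompose D - W; sample independently along eigenvectors with
        nonzero eigenvalue (variance `variance`/eigenvalue), leaving zero
        mass on the null space.  The draw sums to zero within each
        connected component.
        """
        if variance <= 0:
            raise ValueError("variance must be > 0")
        lam, vec = np.linalg.eigh(self.laplacian.toarray())
        pos = lam > 1e-10 * max(1.0, lam.max())
        z = rng.standard_normal(int(pos.sum()))
        return vec[:, pos] @ (z * np.sqrt(variance / lam[pos]))

    # ---- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        coo = self.W.tocoo()
        payload = {
            "n": self.n,
            "precision_scale": self.precision_scale,
            "edges": [[int(r), int(c)] for r, c in zip(coo.row, coo.col)
                      if r < c],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CARStructure":
        payload = json.loads(Path(path).read_text())
        n = payload["n"]
        rows, cols = [], []
        for r, c in payload["edges"]:
            rows += [r, c]
            cols += [c, r]
        W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return cls(W=W, precision_scale=payload["precision_scale"])


def build_spline_adjacency(basis: SplineBasis) -> CARStructure:
    """Rook adjacency among *kept* spline cells.

    Two kept cells are adjacent iff their (i, j) indices differ by one in
    exactly one direction.  Two kept cells separated by a trimmed cell are
    NOT adjacent (adjacency is computed on the kept subgraph).
    """
    kidx = basis.kept_index
    m1, m2 = basis.m1, basis.m2
    rows, cols = [], []
    for q in np.flatnonzero(basis.kept_mask):
        i, j = int(q % m1) + 1, int(q // m1) + 1
        for di, dj in ((1, 0), (0, 1)):  # upper neighbors; symmetrized below
            ii, jj = i + di, j + dj
            if ii > m1 or jj > m2:
                continue
            qq = (jj - 1) * m1 + (ii - 1)
            if basis.kept_mask[qq]:
                a, b = int(kidx[q]), int(kidx[qq])
                rows += [a, b]
                cols += [b, a]
    Q = basis.Q
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(Q, Q))
    return CARStructure(W=W)


def build_region_adjacency(
    region_ids: np.ndarray, row: np.ndarray, col: np.ndarray
) -> CARStructure:
    """Region adjacency from site-grid membership.

    Two regions are adjacent iff some pair of rook-neighboring sites (grid
    positions ``(row, col)``) belongs to the two regions.

    Parameters
    ----------
    region_ids : integer array, one id in 0..R-1 per site
    row, col : integer grid positions of each site
    """
    region_ids = np.asarray(region_ids, dtype=int)
    R = region_ids.max() + 1
    counts = np.bincount(region_ids, minlength=R)
    if (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"region {empty} has zero sites")
    # index sites on their grid to find rook neighbors
    nr, nc = int(row.max()) + 1, int(col.max()) + 1
    grid = np.full((nr, nc), -1, dtype=int)
    grid[row, col] = region_ids
    W = np.zeros((R, R))
    for (a, b) in ((grid[:-1, :], grid[1:, :]), (grid[:, :-1], grid[:, 1:])):
        ok = (a >= 0) & (b >= 0) & (a != b)
        for ra, rb in zip(a[ok].ravel(), b[ok].ravel()):
            W[ra, rb] = W[rb, ra] = 1.0
    return CARStructure(W=sp.csr_matrix(W))


def car_log_density(x: np.ndarray, car: CARStructure,
                    scale: float | None = None) -> float:
    """Unnormalized ICAR log density of ``x`` under ``car``."""
    return car.log_density(x, scale=scale)
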