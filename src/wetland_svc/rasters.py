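"""Regular-grid raster container with ESRI ASCII-grid (.asc) I/O.

All grids live in a projected km coordinate system.  A nodata sentinel of
-9999 is used throughout and propagates through grid arithmetic.  Grid
arithmetic is only defined between co-registered grids (same origin, cell
size and shape); anything else raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band float raster on a regular grid.

    Parameters
    ----------
    origin : (float, float)
        (x, y) of the lower-left corner in km.
    cell_size : float
        Cell edge length in km (> 0).
    values : ndarray, shape (n_rows, n_cols)
        Row 0 is the *top* row (map convention); finite values or NODATA.
    units : str
        Free-text unit label, e.g. ``"ha per 100 km^2"``.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    units: str = ""
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata

    def is_coregistered(self, other: "RasterGrid") -> bool:
        return (
            np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.values.shape == other.values.shape
        )

    def _require_coregistered(self, other: "RasterGrid") -> None:
        if not self.is_coregistered(other):
            raise ValueError(
                "grids are not co-registered (origin/cell_size/shape differ)"
            )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates, each shaped (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        # row 0 is the top row
        ys = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "RasterGrid":
        return RasterGrid(
            origin=self.origin,
            cell_size=self.cell_size,
            values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
            nodata=self.nodata,
        )

    # ---- arithmetic (nodata-propagating) -------------------------------
    def __sub__(self, other: "RasterGrid") -> "RasterGrid":
        self._require_coregistered(other)
        out = self.values - other.values
        out[~(self.mask & other.mask)] = self.nodata
        return self.copy_with(out)

    def __add__(self, other: "RasterGrid") -> "RasterGrid":
        self._require_coregistered(other)
        out = self.values + other.values
        out[~(self.mask & other.mask)] = self.nodata
        return self.copy_with(out)

    # ---- I/O -----------------------------------------------------------
    def write_asc(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        path = Path(path)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin[0]!r}\n"
            f"yllcorner {self.origin[1]!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            for row in self.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_asc(cls, path: str | Path, units: str = "") -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value"}:
                    header[key] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        values = np.asarray(rows, dtype=float)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(f"malformed ASCII grid {path}")
        return cls(
            origin=(header["xllcorner"], header["yllcorner"]),
            cell_size=header["cellsize"],
            values=values,
            units=units,
            nodata=header.get("nodata_value", NODATA),
        )


def empty_grid(
    origin: tuple[float, float],
    cell_size: float,
    n_rows: int,
    n_cols: int,
    fill: float = 0.0,
    units: str = "",
) -> RasterGrid:
    return RasterGrid(
        origin=origin,
        cell_size=cell_size,
        values=np.full((n_rows, n_cols), fill, dtype=float),
        units=units,
    )
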