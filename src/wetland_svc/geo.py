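"""Geospatial preprocessing: point filtering, kernel-density cover, simple
kriging, correlation screening, cover change, and site-table assembly.

Wetland features are represented as point tables (pandas DataFrames with
columns ``x_km, y_km, area_ha, wetland_class``).  Cover is estimated by an
area-weighted kernel density with a finite search radius, expressed as
hectares of wetland per 100 km^2 grid cell.  Sparse climate points are
interpolated to the grid by simple kriging (known prior mean) under a
fitted variogram model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .rasters import NODATA, RasterGrid

logger = logging.getLogger(__name__)

POINT_COLUMNS = ["x_km", "y_km", "area_ha", "wetland_class"]

#: Default exclusions: large open-water features bias cover estimates upward
#: and terrestrial-relevant wetland types cluster near them anyway.
DEFAULT_EXCLUDED_CLASSES = ("lake", "river")
DEFAULT_MIN_AREA_HA = 0.01
DEFAULT_SEARCH_RADIUS_KM = 100.0


def make_point_table(x, y, area_ha, wetland_class) -> pd.DataFrame:
    """Build a wetland point table, validating areas."""
    df = pd.DataFrame({
        "x_km": np.asarray(x, dtype=float),
        "y_km": np.asarray(y, dtype=float),
        "area_ha": np.asarray(area_ha, dtype=float),
        "wetland_class": list(wetland_class),
    })
    if (df["area_ha"] < 0).any():
        raise ValueError("negative wetland areas are not allowed")
    return df


def filter_wetland_points(
    points: pd.DataFrame,
    min_area_ha: float = DEFAULT_MIN_AREA_HA,
    excluded_classes: tuple[str, ...] = DEFAULT_EXCLUDED_CLASSES,
) -> pd.DataFrame:
    """Drop sub-threshold and excluded-class points, preserving order.

    Points with ``area_ha < min_area_ha`` are treated as digitization
    artifacts and removed; class labels in ``excluded_classes`` (by default
    open-water lake/river features) are removed outright.
    """
    if min_area_ha < 0:
        raise ValueError("min_area_ha must be >= 0")
    if points.empty:
        return points.copy()
    keep = (points["area_ha"] >= min_area_ha) & (
        ~points["wetland_class"].isin(excluded_classes)
    )
    return points.loc[keep].copy()


# ---------------------------------------------------------------------------
# Kernel density cover
# ---------------------------------------------------------------------------

def _quartic(d: np.ndarray, radius: float) -> np.ndarray:
    """Quartic (biweight) kernel, normalized to integrate to 1 over the
    disc of the given radius: K(d) = 3/(pi R^2) (1 - (d/R)^2)^2."""
    u = d / radius
    out = np.zeros_like(u)
    inside = u <= 1.0
    out[inside] = 3.0 / (np.pi * radius**2) * (1.0 - u[inside] ** 2) ** 2
    return out


def _gaussian(d: np.ndarray, radius: float) -> np.ndarray:
    """Truncated Gaussian with sigma = radius/3, renormalized on the disc."""
    sigma = radius / 3.0
    out = np.exp(-0.5 * (d / sigma) ** 2) / (2 * np.pi * sigma**2)
    out[d > radius] = 0.0
    mass = 1.0 - np.exp(-0.5 * (radius / sigma) ** 2)
    return out / mass


_KERNELS = {"quartic": _quartic, "gaussian": _gaussian}


def kde_cover(
    points: pd.DataFrame,
    grid: RasterGrid,
    search_radius_km: float = DEFAULT_SEARCH_RADIUS_KM,
    kernel: str = "quartic",
    weighted: bool = True,
) -> RasterGrid:
    """Area-weighted kernel density of wetland points on a raster grid.

    The density (weight per km^2) is evaluated at cell centers and scaled
    by 100 so that, with point weights in hectares, the value reads as
    "hectares of wetland per 100 km^2 cell".  Cells farther than the search
    radius from every point are exactly zero.  ``weighted=False`` ignores
    areas and counts points instead.
    """
    if search_radius_km <= 0:
        raise ValueError("search_radius_km must be > 0")
    kern = _KERNELS[kernel]
    out = np.zeros((grid.n_rows, grid.n_cols))
    if not points.empty:
        cx, cy = grid.cell_centers()
        centers = np.column_stack([cx.ravel(), cy.ravel()])
        pts = points[["x_km", "y_km"]].to_numpy()
        w = points["area_ha"].to_numpy() if weighted else np.ones(len(points))
        tree = cKDTree(pts)
        neighbor_lists = tree.query_ball_point(centers, search_radius_km)
        dens = np.zeros(len(centers))
        for c, nbrs in enumerate(neighbor_lists):
            if nbrs:
                d = np.hypot(*(pts[nbrs] - centers[c]).T)
                dens[c] = np.sum(w[nbrs] * kern(d, search_radius_km))
        out = (100.0 * dens).reshape(grid.n_rows, grid.n_cols)
    return grid.copy_with(out, units="ha per 100 km^2")


# ---------------------------------------------------------------------------
# Simple kriging
# ---------------------------------------------------------------------------

@dataclass
class VariogramModel:
    """Parametric variogram for kriging.

    ``family`` is one of exponential/spherical/gaussian.  The covariance at
    separation h is ``psill * corr(h)`` with a nugget added on the diagonal;
    ``range_km`` is the correlation length of the family, not an effective
    range.  ``mean`` is the known prior mean used by simple kriging.
    """

    family: str = "exponential"
    nugget: float = 0.0
    psill: float = 1.0
    range_km: float = 1.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "spherical", "gaussian"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("sill components must be non-negative")
        if self.range_km <= 0:
            raise ValueError("range must be > 0")

    def correlation(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        a = self.range_km
        if self.family == "exponential":
            return np.exp(-h / a)
        if self.family == "gaussian":
            return np.exp(-((h / a) ** 2))
        # spherical
        u = np.minimum(h / a, 1.0)
        return 1.0 - 1.5 * u + 0.5 * u**3

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Covariance excluding the nugget (which acts only at h == 0)."""
        return self.psill * self.correlation(h)

    def semivariance(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        gamma = self.nugget + self.psill * (1.0 - self.correlation(h))
        return np.where(h == 0, 0.0, gamma)


def _dedupe(obs_xy: np.ndarray, obs_z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average duplicated locations (keeps kriging systems nonsingular)."""
    _, inv, counts = np.unique(
        obs_xy.round(decimals=9), axis=0, return_inverse=True,
        return_counts=True,
    )
    if (counts > 1).any():
        logger.warning("simple_krige: %d duplicate locations averaged",
                       int((counts > 1).sum()))
        z = np.bincount(inv, weights=obs_z) / counts
        xy = np.zeros((len(counts), 2))
        np.add.at(xy, inv, obs_xy)
        xy /= counts[:, None]
        return xy, z
    return obs_xy, obs_z


def simple_krige(
    obs_xy: np.ndarray,
    obs_z: np.ndarray,
    variogram: VariogramModel,
    grid: RasterGrid,
) -> RasterGrid:
    """Simple kriging of observations onto a raster grid.

    The predictor is ``mean + c' Sigma^{-1} (z - mean)`` with Sigma the
    observation covariance (nugget on the diagonal) and c the covariance
    between each cell center and the observations.  With zero nugget the
    predictor interpolates the data exactly; far from all data it relaxes
    to the prior mean.
    """
    obs_xy = np.atleast_2d(np.asarray(obs_xy, dtype=float))
    obs_z = np.asarray(obs_z, dtype=float).ravel()
    if len(obs_z) == 0:
        raise ValueError("simple kriging needs at least one observation")
    obs_xy, obs_z = _dedupe(obs_xy, obs_z)
    d_obs = np.hypot(*(obs_xy[:, None, :] - obs_xy[None, :, :]).T)
    sigma = variogram.covariance(d_obs)
    sigma[np.diag_indices_from(sigma)] += variogram.nugget
    weights_rhs = np.linalg.solve(sigma, obs_z - variogram.mean)
    cx, cy = grid.cell_centers()
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    d_pred = np.hypot(
        centers[:, 0:1] - obs_xy[None, :, 0].reshape(1, -1),
        centers[:, 1:2] - obs_xy[None, :, 1].reshape(1, -1),
    )
    pred = variogram.mean + variogram.covariance(d_pred) @ weights_rhs
    return grid.copy_with(pred.reshape(grid.n_rows, grid.n_cols))


def krige_at(
    obs_xy: np.ndarray, obs_z: np.ndarray, variogram: VariogramModel,
    targets: np.ndarray,
) -> np.ndarray:
    """Simple-kriging prediction at arbitrary target locations."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    obs_xy = np.atleast_2d(np.asarray(obs_xy, dtype=float))
    obs_z = np.asarray(obs_z, dtype=float).ravel()
    obs_xy, obs_z = _dedupe(obs_xy, obs_z)
    d_obs = np.hypot(*(obs_xy[:, None, :] - obs_xy[None, :, :]).T)
    sigma = variogram.covariance(d_obs)
    sigma[np.diag_indices_from(sigma)] += variogram.nugget
    rhs = np.linalg.solve(sigma, obs_z - variogram.mean)
    d = np.hypot(targets[:, 0:1] - obs_xy[None, :, 0],
                 targets[:, 1:2] - obs_xy[None, :, 1])
    return variogram.mean + variogram.covariance(d) @ rhs


def empirical_semivariogram(
    obs_xy: np.ndarray, obs_z: np.ndarray, n_bins: int = 15,
    max_dist: float | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram (distance, gamma, pair count)."""
    obs_xy = np.atleast_2d(np.asarray(obs_xy, dtype=float))
    obs_z = np.asarray(obs_z, dtype=float).ravel()
    iu = np.triu_indices(len(obs_z), k=1)
    d = np.hypot(*(obs_xy[iu[0]] - obs_xy[iu[1]]).T)
    sv = 0.5 * (obs_z[iu[0]] - obs_z[iu[1]]) ** 2
    if max_dist is None:
        max_dist = d.max() / 2.0
    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    inside = d <= max_dist
    rows = []
    for b in range(n_bins):
        sel = inside & (which == b)
        if sel.sum() > 0:
            rows.append({
                "distance": d[sel].mean(),
                "gamma": sv[sel].mean(),
                "n_pairs": int(sel.sum()),
            })
    return pd.DataFrame(rows)


def fit_variogram(
    obs_xy: np.ndarray,
    obs_z: np.ndarray,
    family: str = "exponential",
    n_bins: int = 15,
    mean: float | None = None,
) -> VariogramModel:
    """Weighted least-squares variogram fit (Cressie weights N_h/gamma^2).

    A flat empirical variogram (no resolvable spatial structure) falls back
    to a nugget-only model with a warning.
    """
    obs_z = np.asarray(obs_z, dtype=float).ravel()
    if len(obs_z) < 10:
        raise ValueError("variogram fitting needs at least 10 points")
    emp = empirical_semivariogram(obs_xy, obs_z, n_bins=n_bins)
    h, g, npairs = (emp["distance"].to_numpy(), emp["gamma"].to_numpy(),
                    emp["n_pairs"].to_numpy())
    prior_mean = float(np.mean(obs_z)) if mean is None else mean
    var_z = float(np.var(obs_z))
    if var_z == 0 or g.max() <= 0:
        logger.warning("fit_variogram: constant field; nugget-only model")
        return VariogramModel(family=family, nugget=max(var_z, 1e-12),
                              psill=0.0, range_km=h.max() or 1.0,
                              mean=prior_mean)

    def resid(theta):
        nugget, psill, rng = theta
        model = VariogramModel(family=family, nugget=max(nugget, 0.0),
                               psill=max(psill, 1e-12),
                               range_km=max(rng, 1e-6))
        gm = model.semivariance(h)
        weights = np.sqrt(npairs) / np.maximum(gm, 1e-12)
        return weights * (gm - g)

    # range below the first lag is unresolvable and aliases into the
    # nugget, so bound it by the shortest binned distance
    x0 = np.array([0.1 * var_z, 0.9 * var_z, h.max() / 3.0])
    sol = least_squares(
        resid, x0,
        bounds=([0.0, 1e-12, h.min()], [2 * var_z + 1e-9, 5 * var_z + 1e-9,
                                        10 * h.max()]),
    )
    nugget, psill, rng = sol.x
    # a fitted range collapsing to the lower bound means no structure
    if psill < 1e-8 * max(var_z, 1e-12):
        logger.warning("fit_variogram: flat variogram; nugget-only model")
        return VariogramModel(family=family, nugget=var_z, psill=0.0,
                              range_km=h.max(), mean=prior_mean)
    return VariogramModel(family=family, nugget=float(nugget),
                          psill=float(psill), range_km=float(rng),
                          mean=prior_mean)


# ---------------------------------------------------------------------------
# Correlation screen, cover change, site assembly
# ---------------------------------------------------------------------------

def correlation_screen(
    table: pd.DataFrame, cutoff: float = 0.7
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Drop one member of every covariate pair with |Pearson r| >= cutoff.

    Columns are scanned in input order; of a correlated pair the *later*
    column is dropped, so the earliest-listed covariates survive.  A
    zero-variance column has undefined correlations and is dropped with a
    warning.  Returns (kept, dropped, full correlation matrix).
    """
    cols = list(table.columns)
    if len(cols) < 2 or len(table) < 3:
        raise ValueError("correlation screen needs >= 2 columns, >= 3 rows")
    corr = table.corr(method="pearson")
    kept: list[str] = []
    dropped: list[str] = []
    for name in cols:
        if table[name].std(ddof=0) == 0:
            logger.warning("correlation_screen: zero-variance column %r "
                           "dropped", name)
            dropped.append(name)
            continue
        if any(abs(corr.loc[name, k]) >= cutoff for k in kept):
            dropped.append(name)
        else:
            kept.append(name)
    return kept, dropped, corr


def wetland_change(
    cover_t1: RasterGrid, cover_t2: RasterGrid
) -> tuple[RasterGrid, RasterGrid]:
    """Decadal cover change: ``change = t1 - t2`` (positive = loss) and
    per-cell percent change ``100 * change / t1`` (nodata where t1 == 0)."""
    change = cover_t1 - cover_t2
    both = cover_t1.mask & cover_t2.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * change.values / cover_t1.values
    bad = ~both | (cover_t1.values == 0)
    pct[bad] = NODATA
    n_zero = int((both & (cover_t1.values == 0)).sum())
    if n_zero:
        logger.info("wetland_change: %d zero-baseline cells set to nodata",
                    n_zero)
    return change, cover_t1.copy_with(pct, units="percent of t1 cover")


SITE_CSV_COLUMNS = [
    "site_id", "x_km", "y_km", "y_count", "wetland_cover",
    "elev", "precip", "temp", "region_id",
]


def assemble_site_table(
    cover: RasterGrid,
    covariates: dict[str, RasterGrid],
    regions: RasterGrid,
    counts: RasterGrid,
) -> pd.DataFrame:
    """Join co-registered rasters into one site table (one row per cell).

    Cells with nodata in *any* layer are dropped and the drop count logged.
    Column order follows the site-CSV schema.
    """
    layers = {"wetland_cover": cover, **covariates,
              "region_id": regions, "y_count": counts}
    base = cover
    for name, ras in layers.items():
        base._require_coregistered(ras)
    valid = np.ones((base.n_rows, base.n_cols), dtype=bool)
    for ras in layers.values():
        valid &= ras.mask
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("assemble_site_table: %d cells dropped for nodata",
                    n_dropped)
    if valid.sum() == 0:
        raise ValueError("no cells survive nodata screening")
    cx, cy = base.cell_centers()
    df = pd.DataFrame({
        "site_id": np.arange(int(valid.sum())),
        "x_km": cx[valid],
        "y_km": cy[valid],
        "y_count": layers["y_count"].values[valid].astype(int),
        "wetland_cover": layers["wetland_cover"].values[valid],
        "elev": covariates["elev"].values[valid],
        "precip": covariates["precip"].values[valid],
        "temp": covariates["temp"].values[valid],
        "region_id": layers["region_id"].values[valid].astype(int),
    })
    return df[SITE_CSV_COLUMNS]
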