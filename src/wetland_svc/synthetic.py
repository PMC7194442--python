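"""Synthetic study generator with known ground truth.

Emulates the structure of the real inputs the analysis consumes — a regular
grid of 10x10 km sites with spatially autocorrelated covariates, a
contiguous partition into watershed-like regions, a known piecewise-constant
wetland-effect surface, CAR-distributed region effects, and conditionally
independent Poisson counts — so that parameter-recovery and coverage tests
have an exact truth to compare against.

Covariate fields are produced by smoothing white noise with a Gaussian
kernel of stated range (cheap, and induces the autocorrelation/collinearity
regimes the tests need) and are standardized to mean 0, sd 1.  Wetland
cover is a log-Gaussian transform of such a field, so it is positive and
right-skewed like real cover densities.  Region effects are drawn from the
intrinsic CAR restricted to its sum-to-zero subspace — the identifiable
component of the improper prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.vq import kmeans2

from .car import CARStructure, build_region_adjacency
from .geo import SITE_CSV_COLUMNS

ETA_MAX = 700.0  # exp() overflow guard, shared with the likelihood

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class SimulationConfig:
    """Ground-truth configuration for one synthetic study.

    ``true_surface`` is the wetland-effect surface beta(l): a scalar, a 2-D
    array of per-cell values on a coarse grid stretched over the domain
    (piecewise constant), or a callable f(x, y).  ``true_alpha`` is
    (intercept, elev, precip, temp).  Variance scales are the CAR variances
    used to draw region effects (``tau2_psi``) and, when the surface is
    drawn rather than stated, spline coefficients (``sigma2_phi``).
    """

    n_sites_x: int = 20
    n_sites_y: int = 20
    domain_extent: tuple[float, float, float, float] = (0.0, 200.0, 0.0, 200.0)
    n_regions: int = 4
    true_alpha: tuple[float, ...] = (1.0, -0.5, 0.3, 0.0)
    true_surface: object = 0.0
    covariate_range_km: float = 30.0
    sigma2_phi: float = 1.0
    tau2_psi: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites_x < 2 or self.n_sites_y < 2:
            raise ValueError("need at least a 2x2 site grid")
        x0, x1, y0, y1 = self.domain_extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("degenerate domain extent")
        n_sites = self.n_sites_x * self.n_sites_y
        if not (1 <= self.n_regions <= n_sites):
            raise ValueError("n_regions must be in [1, n_sites]")
        if self.sigma2_phi <= 0 or self.tau2_psi <= 0:
            raise ValueError("variance scales must be > 0")
        if len(self.true_alpha) != 4:
            raise ValueError("true_alpha is (intercept, elev, precip, temp)")


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated site table."""

    alpha: np.ndarray
    beta_surface: np.ndarray  # per-site beta(l_s)
    psi: np.ndarray           # per-region effects (sum-to-zero)
    eta: np.ndarray           # per-site linear predictor
    lam: np.ndarray           # per-site Poisson mean exp(eta)
    region_car: CARStructure | None = None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "beta_surface": self.beta_surface,
            "eta": self.eta,
            "lam": self.lam,
        }).to_csv(path, index=False)


def _smooth_field(shape: tuple[int, int], sigma_cells: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to mean 0, sd 1.

    The noise is generated on a grid padded by 4 smoothing lengths and
    cropped back, so the field is stationary: naive edge handling inflates
    boundary variance severalfold and produces spurious extremes.
    """
    pad = int(np.ceil(4 * sigma_cells)) + 1
    big = rng.standard_normal((shape[0] + 2 * pad, shape[1] + 2 * pad))
    f = ndimage.gaussian_filter(big, sigma_cells, mode="constant")
    f = f[pad: pad + shape[0], pad: pad + shape[1]]
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _contiguous_regions(
    coords: np.ndarray, shape: tuple[int, int], n_regions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """K-means partition of the site grid followed by connectivity repair.

    Produces watershed-like contiguous blocks of unequal size.  Minor
    disconnected fragments of a region are merged into the neighboring
    region they touch most.
    """
    ny, nx = shape
    if n_regions == 1:
        return np.zeros(ny * nx, dtype=int)
    _, labels = kmeans2(coords, n_regions, minit="++",
                        seed=int(rng.integers(2**31)))
    # guarantee non-empty regions
    for r in range(n_regions):
        if not (labels == r).any():
            labels[int(rng.integers(len(labels)))] = r
    grid = labels.reshape(shape)
    for _ in range(10 * n_regions):
        changed = False
        for r in range(n_regions):
            comp, ncomp = ndimage.label(grid == r, structure=_ROOK)
            if ncomp <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones(shape), comp,
                                       index=np.arange(1, ncomp + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, ncomp + 1):
                if c == keep:
                    continue
                mask = comp == c
                # most-touched neighboring region along the fragment border
                dil = ndimage.binary_dilation(mask, structure=_ROOK) & ~mask
                nbr = grid[dil]
                nbr = nbr[nbr != r]
                if len(nbr):
                    grid[mask] = np.bincount(nbr).argmax()
                    changed = True
        if not changed:
            break
    return grid.ravel()


def _surface_values(spec, x: np.ndarray, y: np.ndarray,
                    extent: tuple[float, float, float, float]) -> np.ndarray:
    """Evaluate a surface spec (scalar | coarse array | callable) at sites."""
    if callable(spec):
        return np.asarray(spec(x, y), dtype=float)
    if np.isscalar(spec):
        return np.full(x.shape, float(spec))
    arr = np.asarray(spec, dtype=float)  # (ny, nx) blocks over the domain
    x0, x1, y0, y1 = extent
    iy = np.clip(((y - y0) / (y1 - y0) * arr.shape[0]).astype(int),
                 0, arr.shape[0] - 1)
    ix = np.clip(((x - x0) / (x1 - x0) * arr.shape[1]).astype(int),
                 0, arr.shape[1] - 1)
    return arr[iy, ix]


def simulate_sites(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one site table and its ground truth.

    The generative model mirrors the fitted one: counts are conditionally
    independent Poisson with log-mean
    ``eta = z alpha + x beta(l) + psi_region``.
    """
    rng = np.random.default_rng(config.seed)
    nx, ny = config.n_sites_x, config.n_sites_y
    x0, x1, y0, y1 = config.domain_extent
    dx, dy = (x1 - x0) / nx, (y1 - y0) / ny
    xs = x0 + (np.arange(nx) + 0.5) * dx
    ys = y0 + (np.arange(ny) + 0.5) * dy
    gx, gy = np.meshgrid(xs, ys)  # row iy from south to north
    x_flat, y_flat = gx.ravel(), gy.ravel()

    sigma_cells = config.covariate_range_km / max(dx, dy)
    covs = {name: _smooth_field((ny, nx), sigma_cells, rng).ravel()
            for name in ("elev", "precip", "temp")}
    cover_field = _smooth_field((ny, nx), sigma_cells, rng).ravel()
    wetland_cover = np.exp(0.5 * cover_field)  # positive, right-skewed

    coords = np.column_stack([x_flat, y_flat])
    region_ids = _contiguous_regions(coords, (ny, nx), config.n_regions, rng)

    iy, ix = np.divmod(np.arange(nx * ny), nx)
    if config.n_regions > 1:
        region_car = build_region_adjacency(region_ids, iy, ix)
        psi = region_car.sample_constrained(config.tau2_psi, rng)
        # center within components (already sum-to-zero per component)
        labels = region_car.component_labels
        for comp in range(region_car.n_components):
            sel = labels == comp
            psi[sel] -= psi[sel].mean()
    else:
        region_car = None
        psi = np.zeros(1)

    alpha = np.asarray(config.true_alpha, dtype=float)
    beta = _surface_values(config.true_surface, x_flat, y_flat,
                           config.domain_extent)
    Z = np.column_stack([np.ones(nx * ny), covs["elev"], covs["precip"],
                         covs["temp"]])
    eta = Z @ alpha + wetland_cover * beta + psi[region_ids]
    if np.max(eta) > ETA_MAX:
        raise ValueError(
            f"config implies exp(eta) overflow (max eta {np.max(eta):.1f} "
            f"> {ETA_MAX:.0f}); reduce effect sizes"
        )
    lam = np.exp(eta)
    y = rng.poisson(lam)

    sites = pd.DataFrame({
        "site_id": np.arange(nx * ny),
        "x_km": x_flat,
        "y_km": y_flat,
        "y_count": y,
        "wetland_cover": wetland_cover,
        "elev": covs["elev"],
        "precip": covs["precip"],
        "temp": covs["temp"],
        "region_id": region_ids,
    })[SITE_CSV_COLUMNS]
    truth = SyntheticTruth(alpha=alpha, beta_surface=beta, psi=psi, eta=eta,
                           lam=lam, region_car=region_car)
    return sites, truth


def simulate_wetland_points(
    extent: tuple[float, float, float, float],
    n_points: int,
    area_distribution=("lognormal", -2.0, 1.5),
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform point pattern with per-point area (ha) and class label.

    ``area_distribution`` is a scalar (every point that area) or
    ``("lognormal", mu, sigma)`` of log-area in hectares; the default mode
    is ~0.14 ha with a heavy right tail, like inventory point features.
    """
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = extent
    if class_mix is None:
        class_mix = {"freshwater emergent": 0.45,
                     "freshwater forested/shrub": 0.45,
                     "lake": 0.05, "river": 0.05}
    names = list(class_mix)
    probs = np.array([class_mix[k] for k in names], dtype=float)
    probs /= probs.sum()
    x = rng.uniform(x0, x1, n_points)
    y = rng.uniform(y0, y1, n_points)
    if np.isscalar(area_distribution):
        if area_distribution < 0:
            raise ValueError("negative wetland area")
        area = np.full(n_points, float(area_distribution))
    else:
        kind, mu, sig = area_distribution
        if kind != "lognormal":
            raise ValueError(f"unknown area distribution {kind!r}")
        area = rng.lognormal(mu, sig, n_points)
    cls = rng.choice(names, size=n_points, p=probs)
    return pd.DataFrame({
        "x_km": x, "y_km": y, "area_ha": area, "wetland_class": cls,
    })


def simulate_cover_raster_pair(
    extent: tuple[float, float, float, float],
    cell_size: float,
    base_field=100.0,
    loss_mask=0.0,
    seed: int = 0,
):
    """Co-registered cover rasters (t1, t2 = t1 - loss), both non-negative.

    ``base_field``/``loss_mask`` are scalars, arrays of the grid shape, or
    "random" (smooth non-negative field) for the base.
    """
    from .rasters import RasterGrid

    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = extent
    n_cols = int(round((x1 - x0) / cell_size))
    n_rows = int(round((y1 - y0) / cell_size))
    if isinstance(base_field, str) and base_field == "random":
        base = 50.0 * (1.0 + np.abs(_smooth_field((n_rows, n_cols), 2.0, rng)))
    elif np.isscalar(base_field):
        base = np.full((n_rows, n_cols), float(base_field))
    else:
        base = np.asarray(base_field, dtype=float).copy()
    loss = (np.full((n_rows, n_cols), float(loss_mask))
            if np.isscalar(loss_mask) else np.asarray(loss_mask, dtype=float))
    if base.shape != (n_rows, n_cols) or loss.shape != (n_rows, n_cols):
        raise ValueError("base/loss shape does not match the grid")
    if (base < 0).any():
        raise ValueError("base cover must be non-negative")
    if (loss > base).any():
        raise ValueError("loss exceeds baseline cover somewhere")
    t1 = RasterGrid(origin=(x0, y0), cell_size=cell_size, values=base,
                    units="ha per 100 km^2")
    t2 = t1.copy_with(base - loss)
    return t1, t2


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_site_csv(sites: pd.DataFrame, path: str | Path) -> None:
    sites[SITE_CSV_COLUMNS].to_csv(path, index=False)


def read_site_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SITE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site CSV missing columns {sorted(missing)}")
    return df[SITE_CSV_COLUMNS]
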