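"""The hierarchical spatial Poisson model as a log-posterior.

Counts are conditionally independent Poisson with log-mean

    eta_s = z_s' alpha + x_s beta(l_s) + psi_region(s),

where z_s collects the intercept and fixed covariates, x_s is wetland
cover, beta(.) is a piecewise-constant spline surface with coefficients phi
under an ICAR penalty at precision scale sigma^-2, and psi are region
random effects under their own ICAR at precision scale tau^-2.  Priors:
alpha ~ N(0, v I) with v = 1000, and independent IG(1, 1) priors on both
precision scales.  The ICAR terms contribute the quadratic form plus a
rank-adjusted (rank/2) log(scale) term so the scales have a proper joint
update; 2*pi constants of the improper ICAR are dropped (consistently, for
both the full and the no-random-effect model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

from .car import build_region_adjacency, build_spline_adjacency
from .splines import SplineBasis, build_knot_grid, trim_basis

ETA_MAX = 700.0

FIXED_COVARIATES = ("elev", "precip", "temp")


@dataclass
class ParameterState:
    """One point in parameter space."""

    alpha: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    sigma2_inv: float = 1.0
    tau2_inv: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float)) \
            if np.size(self.phi) else np.zeros(0)
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float)) \
            if np.size(self.psi) else np.zeros(0)
        if self.sigma2_inv <= 0 or self.tau2_inv <= 0:
            raise ValueError("precision scales must be > 0")

    def copy(self) -> "ParameterState":
        return ParameterState(self.alpha.copy(), self.phi.copy(),
                              self.psi.copy(), self.sigma2_inv,
                              self.tau2_inv)


@dataclass
class PriorSettings:
    alpha_prior_var: float = 1000.0
    ig_shape_sigma: float = 1.0
    ig_scale_sigma: float = 1.0
    ig_shape_tau: float = 1.0
    ig_scale_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_prior_var <= 0:
            raise ValueError("alpha prior variance must be > 0")
        for v in (self.ig_shape_sigma, self.ig_scale_sigma,
                  self.ig_shape_tau, self.ig_scale_tau):
            if v <= 0:
                raise ValueError("IG parameters must be > 0")


class ModelSpec:
    """Binds a site table to the basis, CAR structures, and priors.

    Precomputes the design pieces the sampler needs: the fixed-effect
    matrix Z (intercept first, covariates z-scored by default with the
    transform stored), wetland cover x, and per-site kept-cell and region
    indices.  ``include_svc`` / ``include_random_effects`` switch the
    wetland-surface and region-effect terms off for reduced models.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        basis: SplineBasis | None,
        covariates: tuple[str, ...] = FIXED_COVARIATES,
        include_svc: bool = True,
        include_random_effects: bool = True,
        standardize: bool = True,
        priors: PriorSettings | None = None,
    ):
        self.sites = sites.reset_index(drop=True)
        self.covariates = tuple(covariates)
        self.include_svc = include_svc and basis is not None
        self.include_random_effects = include_random_effects
        self.priors = priors or PriorSettings()
        self.y = self.sites["y_count"].to_numpy(dtype=float)
        if (self.y < 0).any() or not np.allclose(self.y, np.round(self.y)):
            raise ValueError("counts must be non-negative integers")
        self._lgamma_sum = float(gammaln(self.y + 1).sum())

        cols = [np.ones(len(self.sites))]
        self.standardize = standardize
        self.covariate_transform: dict[str, tuple[float, float]] = {}
        for name in self.covariates:
            v = self.sites[name].to_numpy(dtype=float)
            if standardize:
                mu, sd = float(v.mean()), float(v.std())
                sd = sd if sd > 0 else 1.0
                self.covariate_transform[name] = (mu, sd)
                v = (v - mu) / sd
            cols.append(v)
        self.Z = np.column_stack(cols)
        self.alpha_names = ("intercept",) + self.covariates

        self.x = self.sites["wetland_cover"].to_numpy(dtype=float)
        if self.include_svc:
            self.basis = basis
            self.spline_car = build_spline_adjacency(basis)
            self.cell_index = basis.site_cell_index(
                self.sites["x_km"].to_numpy(), self.sites["y_km"].to_numpy())
            self.Q = basis.Q
        else:
            self.basis = None
            self.spline_car = None
            self.cell_index = None
            self.Q = 0

        if include_random_effects:
            raw = self.sites["region_id"].to_numpy()
            uniq = np.unique(raw)
            remap = {r: i for i, r in enumerate(uniq)}
            self.region_index = np.array([remap[r] for r in raw])
            self.R = len(uniq)
            row, col = self._grid_positions()
            self.region_car = build_region_adjacency(self.region_index,
                                                     row, col)
        else:
            self.region_index = None
            self.R = 0
            self.region_car = None

    def _grid_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer grid positions of sites (regular-grid site tables)."""
        x = self.sites["x_km"].to_numpy()
        y = self.sites["y_km"].to_numpy()
        xs, ys = np.unique(x), np.unique(y)
        col = np.searchsorted(xs, x)
        row = np.searchsorted(ys, y)
        return row, col

    @property
    def P(self) -> int:
        return self.Z.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def initial_state(self) -> ParameterState:
        """Moment-based initialization: intercept at log(mean count)."""
        alpha = np.zeros(self.P)
        alpha[0] = np.log(max(self.y.mean(), 1e-8))
        return ParameterState(
            alpha=alpha,
            phi=np.zeros(self.Q),
            psi=np.zeros(self.R),
            sigma2_inv=1.0,
            tau2_inv=1.0,
        )

    def validate_state(self, state: ParameterState) -> None:
        if state.alpha.shape != (self.P,):
            raise ValueError(f"alpha must have length {self.P}")
        if self.include_svc and state.phi.shape != (self.Q,):
            raise ValueError(f"phi must have length {self.Q}")
        if self.include_random_effects and state.psi.shape != (self.R,):
            raise ValueError(f"psi must have length {self.R}")


def build_model_spec(
    sites: pd.DataFrame,
    k1: int,
    k2: int,
    pad_km: float = 1e-6,
    **kwargs,
) -> ModelSpec:
    """Convenience: knot grid over the site bounding box, trimmed to the
    observed sites, then bound into a ModelSpec."""
    x = sites["x_km"].to_numpy()
    y = sites["y_km"].to_numpy()
    basis = build_knot_grid(x.min() - pad_km, x.max() + pad_km,
                            y.min() - pad_km, y.max() + pad_km, k1, k2)
    basis = trim_basis(basis, x, y)
    return ModelSpec(sites, basis, **kwargs)


# ---------------------------------------------------------------------------
# Log posterior pieces
# ---------------------------------------------------------------------------

def linear_predictor(state: ParameterState, spec: ModelSpec) -> np.ndarray:
    """eta_s = z_s' alpha + x_s beta(l_s) + psi_region(s)."""
    spec.validate_state(state)
    eta = spec.Z @ state.alpha
    if spec.include_svc:
        eta = eta + spec.x * state.phi[spec.cell_index]
    if spec.include_random_effects:
        eta = eta + state.psi[spec.region_index]
    return eta


def log_likelihood(state: ParameterState, spec: ModelSpec) -> float:
    """Poisson log likelihood sum_s [y_s eta_s - exp(eta_s) - log(y_s!)]."""
    eta = linear_predictor(state, spec)
    if np.max(eta) > ETA_MAX:
        raise ValueError(
            f"linear predictor exceeds {ETA_MAX:.0f}; exp(eta) would "
            "overflow — state rejected")
    return float(spec.y @ eta - np.exp(eta).sum() - spec._lgamma_sum)


def _ig_logpdf(x: float, shape: float, scale: float) -> float:
    """Inverse-gamma log density (normalized)."""
    return (shape * np.log(scale) - gammaln(shape)
            - (shape + 1) * np.log(x) - scale / x)


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Gaussian prior on alpha, ICAR terms for phi/psi with rank-adjusted
    log-scale terms, IG priors on both precision scales."""
    spec.validate_state(state)
    if state.sigma2_inv <= 0 or state.tau2_inv <= 0:
        return -np.inf
    pr = spec.priors
    v = pr.alpha_prior_var
    lp = (-0.5 * spec.P * np.log(2 * np.pi * v)
          - 0.5 * state.alpha @ state.alpha / v)
    if spec.include_svc:
        car = spec.spline_car
        lp += (0.5 * car.rank * np.log(state.sigma2_inv)
               - 0.5 * state.sigma2_inv * car.quadratic_form(state.phi))
    if spec.include_random_effects:
        car = spec.region_car
        lp += (0.5 * car.rank * np.log(state.tau2_inv)
               - 0.5 * state.tau2_inv * car.quadratic_form(state.psi))
    lp += _ig_logpdf(state.sigma2_inv, pr.ig_shape_sigma, pr.ig_scale_sigma)
    lp += _ig_logpdf(state.tau2_inv, pr.ig_shape_tau, pr.ig_scale_tau)
    return float(lp)


def log_posterior(state: ParameterState, spec: ModelSpec) -> float:
    """log likelihood + log prior (errors propagate)."""
    return log_likelihood(state, spec) + log_prior(state, spec)


def log_posterior_safe(state: ParameterState, spec: ModelSpec) -> float:
    """Sampler-facing wrapper: overflow / invalid states map to -inf."""
    try:
        return log_posterior(state, spec)
    except ValueError:
        return -np.inf


# ---------------------------------------------------------------------------
# Residual spatial-dependence check (Moran's I)
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    expected: float
    p_value: float
    n_permutations: int


def deviance_residuals(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Signed square-root Poisson deviance residuals."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / lam), 0.0)
    dev = 2.0 * (term - (y - lam))
    return np.sign(y - lam) * np.sqrt(np.maximum(dev, 0.0))


def _rook_weights(row: np.ndarray, col: np.ndarray) -> sp.csr_matrix:
    nr, nc = int(row.max()) + 1, int(col.max()) + 1
    idx = np.full((nr, nc), -1, dtype=int)
    idx[row, col] = np.arange(len(row))
    rows, cols = [], []
    for (a, b) in ((idx[:-1, :], idx[1:, :]), (idx[:, :-1], idx[:, 1:])):
        ok = (a >= 0) & (b >= 0)
        rows += list(a[ok].ravel()) + list(b[ok].ravel())
        cols += list(b[ok].ravel()) + list(a[ok].ravel())
    n = len(row)
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def morans_i(values: np.ndarray, W: sp.csr_matrix) -> float:
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for constant values")
    s0 = W.sum()
    return float(len(z) / s0 * (z @ (W @ z)) / denom)


def residual_spatial_check(
    y: np.ndarray,
    eta_hat: np.ndarray,
    row: np.ndarray,
    col: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I of deviance residuals on the site grid with a one-sided
    (positive-autocorrelation) permutation test.

    Used to show that the no-random-effect model leaves spatially dependent
    residuals.  Expected value under the null is -1/(n-1).
    """
    resid = deviance_residuals(y, np.exp(np.asarray(eta_hat, dtype=float)))
    if np.allclose(resid, resid[0]):
        raise ValueError("Moran's I undefined: residuals are constant")
    W = _rook_weights(np.asarray(row), np.asarray(col))
    i_obs = morans_i(resid, W)
    rng = np.random.default_rng(seed)
    # permuting z leaves z'z unchanged, so only z'Wz needs recomputing
    z = resid - resid.mean()
    perms = np.array([rng.permutation(z) for _ in range(n_permutations)])
    cross = np.einsum("ij,ij->i", perms, (W @ perms.T).T)
    i_perm = len(z) / W.sum() * cross / (z @ z)
    count = int((i_perm >= i_obs).sum())
    n = len(resid)
    return MoranResult(
        I=i_obs,
        expected=-1.0 / (n - 1),
        p_value=(1 + count) / (1 + n_permutations),
        n_permutations=n_permutations,
    )
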