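"""Reference experiments establishing sampler correctness and calibration.

Each function sets up one self-contained study — data generation, fit, and
an independent yardstick — and returns plain numbers.  The yardsticks are
deliberately computed outside the model/sampler code path: deterministic
quadrature of the exact posterior for the reduced models, closed-form AR(1)
theory for effective-sample-size checks, and the known simulation truth for
recovery and coverage.

Problem sizes here are the package's reference study conditions: large
enough for the asymptotics the checks rely on, small enough to run on a
laptop in minutes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import ess_1d, geweke_z, summarize
from .geo import filter_wetland_points, kde_cover
from .mcmc import SamplerConfig, run_sampler
from .model import ModelSpec, build_model_spec
from .outputs import build_fixed_effects_table, build_surface, export_products
from .rasters import empty_grid
from .splines import SplineBasis
from .synthetic import (SimulationConfig, _surface_values, simulate_sites,
                        simulate_wetland_points, write_site_csv)

# ---------------------------------------------------------------------------
# Quadrature oracles (independent of the model/sampler implementation)
# ---------------------------------------------------------------------------


def _poisson_posterior_moments_1d(
    y: np.ndarray, prior_var: float = 1000.0, n_grid: int = 4001
) -> tuple[float, float]:
    """Deterministic quadrature of the intercept-only Poisson posterior.

    log p(a | y) = const + a sum(y) - n e^a - a^2 / (2 v).
    """
    y = np.asarray(y, dtype=float)
    n, s = len(y), y.sum()
    mode = np.log(max(s / n, 1e-12))
    sd0 = 1.0 / np.sqrt(max(s, 1.0))
    a = np.linspace(mode - 10 * sd0, mode + 10 * sd0, n_grid)
    lp = a * s - n * np.exp(a) - 0.5 * a**2 / prior_var
    w = np.exp(lp - lp.max())
    w /= w.sum()
    mean = float(w @ a)
    var = float(w @ (a - mean) ** 2)
    return mean, np.sqrt(var)


def _poisson_glm_posterior_moments(
    A: np.ndarray, y: np.ndarray, prior_vars: np.ndarray,
    n_grid: int = 61, half_width_sd: float = 7.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid quadrature of a P-parameter Poisson GLM posterior.

    log p(theta | y) = const + y'A theta - sum exp(A theta)
                       - sum_k theta_k^2 / (2 v_k),
    with v_k = inf meaning a flat prior on that coordinate.  The grid is
    centered on the MAP with Laplace-scaled half-widths.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    pv = np.asarray(prior_vars, dtype=float)
    pen = np.where(np.isfinite(pv), 1.0 / pv, 0.0)

    def neg_lp(theta):
        eta = A @ theta
        return -(y @ eta - np.exp(eta).sum() - 0.5 * np.sum(pen * theta**2))

    def grad(theta):
        eta = A @ theta
        return -(A.T @ (y - np.exp(eta)) - pen * theta)

    res = minimize(neg_lp, np.zeros(A.shape[1]), jac=grad, method="BFGS")
    mode = res.x
    lam = np.exp(A @ mode)
    hess = A.T @ (A * lam[:, None]) + np.diag(pen)
    sds = np.sqrt(np.diag(np.linalg.inv(hess)))

    axes = [np.linspace(m - half_width_sd * s, m + half_width_sd * s, n_grid)
            for m, s in zip(mode, sds)]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta_grid = np.column_stack([m.ravel() for m in mesh])
    lp = np.empty(len(theta_grid))
    chunk = 20000
    for k in range(0, len(theta_grid), chunk):
        block = theta_grid[k: k + chunk]
        eta = block @ A.T
        lp[k: k + chunk] = (eta @ y - np.exp(eta).sum(axis=1)
                            - 0.5 * (block**2 * pen).sum(axis=1))
    w = np.exp(lp - lp.max())
    w /= w.sum()
    mean = w @ theta_grid
    var = w @ (theta_grid - mean) ** 2
    return mean, np.sqrt(var)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _bare_sites(y: np.ndarray) -> pd.DataFrame:
    n = len(y)
    side = int(np.ceil(np.sqrt(n)))
    iy, ix = np.divmod(np.arange(n), side)
    return pd.DataFrame({
        "site_id": np.arange(n), "x_km": ix * 10.0 + 5.0,
        "y_km": iy * 10.0 + 5.0, "y_count": y,
        "wetland_cover": np.zeros(n), "elev": np.zeros(n),
        "precip": np.zeros(n), "temp": np.zeros(n),
        "region_id": np.zeros(n, dtype=int),
    })


def intercept_only_experiment(
    seed: int, n_sites: int = 200, lam: float = 5.0,
    n_iterations: int = 4000, n_burnin: int = 2000,
) -> dict:
    """MCMC vs 1-D quadrature on the intercept-only Poisson model.

    Returns the z-distances (in Monte Carlo standard errors) between the
    sampler's posterior mean/SD of the intercept and the quadrature truth.
    """
    rng = np.random.default_rng(seed)
    y = rng.poisson(lam, n_sites)
    spec = ModelSpec(_bare_sites(y), basis=None, covariates=(),
                     include_svc=False, include_random_effects=False,
                     standardize=False)
    chain = run_sampler(spec, SamplerConfig(
        n_iterations=n_iterations, n_burnin=n_burnin, seed=seed + 1))
    draws = chain.column("alpha_intercept")
    ess = ess_1d(draws)
    mc_mean, mc_sd = draws.mean(), draws.std(ddof=1)
    q_mean, q_sd = _poisson_posterior_moments_1d(y)
    se_mean = mc_sd / np.sqrt(ess)
    se_sd = mc_sd / np.sqrt(2 * ess)
    return {
        "mcmc_mean": mc_mean, "mcmc_sd": mc_sd,
        "quad_mean": q_mean, "quad_sd": q_sd, "ess": ess,
        "z_mean": (mc_mean - q_mean) / se_mean,
        "z_sd": (mc_sd - q_sd) / se_sd,
        "n": n_sites,
    }


def glm_reduction_experiment(
    seed: int, n_sites: int = 150,
    n_iterations: int = 8000, n_burnin: int = 4000,
) -> dict:
    """Single-spline-cell, no-random-effect model vs 3-D quadrature.

    With one spline cell the wetland surface collapses to a single slope,
    so the model is an ordinary Poisson GLM (intercept, one covariate, one
    wetland slope) whose exact posterior is integrable on a grid.
    """
    rng = np.random.default_rng(seed)
    sites = _bare_sites(rng.poisson(1.0, n_sites))
    sites["elev"] = rng.standard_normal(n_sites)
    sites["wetland_cover"] = np.exp(0.5 * rng.standard_normal(n_sites))
    theta_true = np.array([0.5, -0.3, 0.4])
    A = np.column_stack([np.ones(n_sites), sites["elev"],
                         sites["wetland_cover"]])
    sites["y_count"] = rng.poisson(np.exp(A @ theta_true))

    spec = build_model_spec(sites, k1=0, k2=0, covariates=("elev",),
                            include_random_effects=False, standardize=False)
    chain = run_sampler(spec, SamplerConfig(
        n_iterations=n_iterations, n_burnin=n_burnin, seed=seed + 1))
    names = ["alpha_intercept", "alpha_elev", "phi_0"]
    prior_vars = np.array([1000.0, 1000.0, np.inf])  # flat on the lone cell
    q_mean, q_sd = _poisson_glm_posterior_moments(
        A, sites["y_count"].to_numpy(), prior_vars)
    out = {"n": n_sites}
    z_means, z_sds = [], []
    for k, name in enumerate(names):
        draws = chain.column(name)
        ess = ess_1d(draws)
        se_mean = draws.std(ddof=1) / np.sqrt(ess)
        se_sd = draws.std(ddof=1) / np.sqrt(2 * ess)
        z_means.append((draws.mean() - q_mean[k]) / se_mean)
        z_sds.append((draws.std(ddof=1) - q_sd[k]) / se_sd)
        out[f"mcmc_mean_{name}"] = draws.mean()
        out[f"quad_mean_{name}"] = q_mean[k]
    out["max_abs_z_mean"] = float(np.max(np.abs(z_means)))
    out["max_abs_z_sd"] = float(np.max(np.abs(z_sds)))
    return out


THREE_BAND_SURFACE = np.array([[-0.5, 0.0, 0.5]])
RECOVERY_ALPHA = (1.0, -0.5, 0.3, 0.0)


def basis_cell_centers(basis: SplineBasis) -> tuple[np.ndarray, np.ndarray]:
    """Center coordinates of the kept cells, in kept order."""
    q = np.flatnonzero(basis.kept_mask)
    i, j = basis.cell_of(q)
    ye, xe = basis.y_edges(), basis.x_edges()
    return (0.5 * (xe[j - 1] + xe[j]), 0.5 * (ye[i - 1] + ye[i]))


def surface_recovery_experiment(
    seeds=range(10), n_side: int = 50, k: int = 5,
    n_iterations: int = 5000, n_burnin: int = 2500,
) -> dict:
    """Recovery of a three-band wetland-effect surface at n = n_side^2.

    The true surface takes values (-0.5, 0, +0.5) on vertical thirds of
    the domain, aligned with the 6x6 knot grid.  Reports sign agreement of
    the posterior mean in strong-signal cells (|truth| = 0.5) and 95% CI
    coverage of the per-cell truth, pooled over seeds.
    """
    sign_hits = sign_total = 0
    cover_hits = cover_total = 0
    alpha_err = []
    for seed in seeds:
        cfg = SimulationConfig(
            n_sites_x=n_side, n_sites_y=n_side,
            domain_extent=(0.0, 10.0 * n_side, 0.0, 10.0 * n_side),
            n_regions=6, true_alpha=RECOVERY_ALPHA,
            true_surface=THREE_BAND_SURFACE, tau2_psi=0.1, seed=seed,
        )
        sites, truth = simulate_sites(cfg)
        spec = build_model_spec(sites, k1=k, k2=k)
        chain = run_sampler(spec, SamplerConfig(
            n_iterations=n_iterations, n_burnin=n_burnin, seed=seed + 1000))
        summ = summarize(chain)
        cx, cy = basis_cell_centers(spec.basis)
        cell_truth = _surface_values(THREE_BAND_SURFACE, cx, cy,
                                     cfg.domain_extent)
        phi = summ.loc[[f"phi_{q}" for q in range(spec.Q)]]
        strong = np.abs(cell_truth) > 0.25
        sign_hits += int((np.sign(phi["mean"].to_numpy()[strong])
                          == np.sign(cell_truth[strong])).sum())
        sign_total += int(strong.sum())
        inside = ((phi["lower"].to_numpy() <= cell_truth)
                  & (cell_truth <= phi["upper"].to_numpy()))
        cover_hits += int(inside.sum())
        cover_total += spec.Q
        a_mean = summ.loc[[f"alpha_{n}" for n in spec.alpha_names],
                          "mean"].to_numpy()
        alpha_err.append(a_mean - np.array(RECOVERY_ALPHA))
    return {
        "sign_agreement_pct": 100.0 * sign_hits / sign_total,
        "ci_coverage_pct": 100.0 * cover_hits / cover_total,
        "n_strong_cells": sign_total,
        "n_cells": cover_total,
        "mean_abs_alpha_error": float(np.mean(np.abs(alpha_err))),
        "n_sites": n_side**2,
        "n_seeds": len(list(seeds)),
    }


def alpha_calibration_experiment(
    n_replicates: int = 50, seed: int = 0, n_side: int = 20,
    n_iterations: int = 2000, n_burnin: int = 1000,
) -> dict:
    """Empirical 95%-CI coverage of the fixed effects over replicates.

    Each replicate simulates n_side^2 sites with a 2x2 wetland surface and
    region effects, fits the full model with a shortened chain, and checks
    whether each alpha interval covers its true value.
    """
    truth = np.array([1.0, -0.5, 0.3, 0.0])
    surface = np.array([[0.3, -0.3], [-0.2, 0.2]])
    hits = total = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_sites_x=n_side, n_sites_y=n_side,
            domain_extent=(0.0, 10.0 * n_side, 0.0, 10.0 * n_side),
            n_regions=4, true_alpha=tuple(truth), true_surface=surface,
            tau2_psi=0.1, seed=seed + 7919 * (r + 1),
        )
        sites, _ = simulate_sites(cfg)
        spec = build_model_spec(sites, k1=1, k2=1)
        chain = run_sampler(spec, SamplerConfig(
            n_iterations=n_iterations, n_burnin=n_burnin,
            seed=seed + 104729 * (r + 1)))
        summ = summarize(chain)
        rows = summ.loc[[f"alpha_{n}" for n in spec.alpha_names]]
        inside = ((rows["lower"].to_numpy() <= truth)
                  & (truth <= rows["upper"].to_numpy()))
        hits += int(inside.sum())
        total += len(truth)
    return {"coverage_pct": 100.0 * hits / total,
            "n_intervals": total, "n_replicates": n_replicates}


def ar1_ess_experiment(seed: int = 0, n: int = 20000, rho: float = 0.9
                       ) -> dict:
    """ESS/N of an AR(1) chain vs the closed form (1-rho)/(1+rho)."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return {"ess_ratio": ess_1d(x) / n,
            "theory": (1 - rho) / (1 + rho), "n": n}


def geweke_null_experiment(seed: int = 0, n_seeds: int = 100,
                           n: int = 5000) -> dict:
    """Fraction of i.i.d. chains passing |Geweke z| < 3."""
    passed = 0
    for k in range(n_seeds):
        x = np.random.default_rng(seed + k).standard_normal(n)
        if abs(geweke_z(x)) < 3:
            passed += 1
    return {"pass_pct": 100.0 * passed / n_seeds, "n_seeds": n_seeds}


def pipeline_run(
    out_dir: str | Path, seed: int, n_side: int = 15,
    n_iterations: int = 900, n_burnin: int = 450,
) -> Path:
    """simulate -> preprocess -> fit -> summarize with one seed.

    Writes the site CSV, a KDE cover raster from simulated wetland points,
    the chain, and the posterior products under ``out_dir``.  Used by the
    end-to-end determinism check: two runs with the same seed must produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    extent = (0.0, 10.0 * n_side, 0.0, 10.0 * n_side)
    cfg = SimulationConfig(
        n_sites_x=n_side, n_sites_y=n_side, domain_extent=extent,
        n_regions=3, true_alpha=(1.0, -0.5, 0.3, 0.0),
        true_surface=np.array([[-0.4, 0.4]]), tau2_psi=0.1, seed=seed,
    )
    sites, _ = simulate_sites(cfg)
    write_site_csv(sites, out / "sites.csv")

    points = simulate_wetland_points(extent, 400, seed=seed + 1)
    kept = filter_wetland_points(points)
    grid = empty_grid((0.0, 0.0), 10.0, n_side, n_side)
    kde_cover(kept, grid, search_radius_km=50.0).write_asc(
        out / "cover.asc")

    spec = build_model_spec(sites, k1=1, k2=1)
    chain = run_sampler(spec, SamplerConfig(
        n_iterations=n_iterations, n_burnin=n_burnin, seed=seed + 2))
    chain.save(out)
    summ = summarize(chain)
    surface = build_surface(spec.basis, summ)
    table = build_fixed_effects_table(summ, spec.alpha_names)
    export_products(surface, table, grid, out, seed=seed,
                    chain_length=chain.n_retained)
    return out
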