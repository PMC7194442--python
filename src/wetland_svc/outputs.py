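"""Posterior deliverables: coefficient surface, significance map, tables.

The fitted wetland-effect surface is reported per kept spline cell as a
(posterior mean, 95% CI) triple and classified as positively significant
(lower bound > 0), negatively significant (upper bound < 0) or not
significant.  Class codes on rasters are +1 / -1 / 0 with -9999 nodata in
trimmed cells — the surface is only reported on the fitted support, never
extrapolated into trimmed cells.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import NODATA, RasterGrid
from .splines import SplineBasis

CLASS_POSITIVE, CLASS_NONE, CLASS_NEGATIVE = 1, 0, -1


def classify(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Significance class from CI bounds (pure, idempotent)."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    out = np.full(lower.shape, CLASS_NONE, dtype=int)
    out[lower > 0] = CLASS_POSITIVE
    out[upper < 0] = CLASS_NEGATIVE
    return out


@dataclass
class CoefficientSurface:
    """Per-kept-cell posterior summary of the wetland-effect surface."""

    basis: SplineBasis
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.mean, self.lower, self.upper):
            if np.asarray(arr).shape != (self.basis.Q,):
                raise ValueError("surface summaries must cover all Q kept "
                                 "cells")

    @property
    def sig_class(self) -> np.ndarray:
        return classify(self.lower, self.upper)

    def rasterize(self, template: RasterGrid) -> dict[str, RasterGrid]:
        """Map cell summaries onto a site grid; trimmed cells get nodata."""
        cx, cy = template.cell_centers()
        i, j = self.basis.locate(cx.ravel(), cy.ravel())
        kidx = self.basis.kept_index[self.basis.flat(i, j)]
        out = {}
        for name, vals in (("mean", self.mean), ("lower", self.lower),
                           ("upper", self.upper),
                           ("class", self.sig_class.astype(float))):
            v = np.where(kidx >= 0, np.asarray(vals, dtype=float)[
                np.clip(kidx, 0, None)], NODATA)
            out[name] = template.copy_with(
                v.reshape(template.values.shape),
                units="wetland-effect " + name)
        return out


def build_surface(basis: SplineBasis, summary: pd.DataFrame
                  ) -> CoefficientSurface:
    """Build the surface from a posterior summary table.

    ``summary`` is the output of :func:`wetland_svc.diagnostics.summarize`
    and must contain rows ``phi_0 .. phi_{Q-1}``.
    """
    names = [f"phi_{q}" for q in range(basis.Q)]
    missing = [n for n in names if n not in summary.index]
    if missing:
        raise ValueError(f"summary missing cell rows {missing[:3]}...")
    sub = summary.loc[names]
    return CoefficientSurface(
        basis=basis,
        mean=sub["mean"].to_numpy(),
        lower=sub["lower"].to_numpy(),
        upper=sub["upper"].to_numpy(),
    )


@dataclass
class FixedEffectsTable:
    """Fixed-effect posterior summaries in report layout."""

    full: pd.DataFrame        # includes the intercept
    covariates: pd.DataFrame  # intercept excluded

    def to_csv(self, path: str | Path, include_intercept: bool = False
               ) -> None:
        (self.full if include_intercept else self.covariates).to_csv(path)


def build_fixed_effects_table(summary: pd.DataFrame,
                              alpha_names: tuple[str, ...]
                              ) -> FixedEffectsTable:
    """Extract fixed-effect rows into the report layout
    (Mean, Lower 95% CI, Upper 95% CI, Significant)."""
    rows = [f"alpha_{n}" for n in alpha_names]
    missing = [r for r in rows if r not in summary.index]
    if missing:
        raise ValueError(f"summary missing fixed-effect rows {missing}")
    tab = summary.loc[rows, ["mean", "lower", "upper", "significant"]].copy()
    tab.index = pd.Index(alpha_names, name="covariate")
    tab.columns = ["Mean", "Lower 95% CI", "Upper 95% CI", "Significant"]
    return FixedEffectsTable(full=tab,
                             covariates=tab.drop(index="intercept",
                                                 errors="ignore"))


def export_products(
    surface: CoefficientSurface,
    table: FixedEffectsTable,
    template: RasterGrid,
    out_dir: str | Path,
    seed: int | None = None,
    chain_length: int | None = None,
    config_path: str | Path | None = None,
) -> dict[str, Path]:
    """Write surface rasters (one .asc per band), tables and a provenance
    manifest; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, ras in surface.rasterize(template).items():
        p = out_dir / f"surface_{name}.asc"
        ras.write_asc(p)
        paths[f"surface_{name}"] = p
    p = out_dir / "fixed_effects.csv"
    table.to_csv(p)
    paths["fixed_effects"] = p
    p = out_dir / "fixed_effects_full.csv"
    table.to_csv(p, include_intercept=True)
    paths["fixed_effects_full"] = p

    config_hash = None
    if config_path is not None:
        config_hash = hashlib.sha256(
            Path(config_path).read_bytes()).hexdigest()
    manifest = {
        "seed": seed,
        "chain_length": chain_length,
        "config_hash": config_hash,
        "n_cells": int(surface.basis.Q),
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = p
    return paths
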