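"""Geoprocess the simulated inputs into model-ready layers.

Steps mirror the preprocessing a national analysis would apply: filter the
wetland point layer (area >= 0.01 ha, lake/river classes out), rasterize
cover by area-weighted kernel density (100 km search radius, 10 km cells),
krige the sparse temperature points under a fitted variogram, screen the
covariates for collinearity (|r| >= 0.7), and difference the two cover
rasters into absolute and percent decadal change.

Run after 01_simulate.py:  python analysis/02_preprocess.py
Writes under results/preprocess/.
"""

import json
from pathlib import Path

import pandas as pd

from wetland_svc.geo import (correlation_screen, filter_wetland_points,
                             fit_variogram, kde_cover, simple_krige,
                             wetland_change)
from wetland_svc.rasters import RasterGrid, empty_grid

data = Path("results/data")
out = Path("results/preprocess")
out.mkdir(parents=True, exist_ok=True)

points = pd.read_csv(data / "wetland_points.csv")
kept = filter_wetland_points(points)
print(f"wetland points: {len(points)} -> {len(kept)} after the "
      f"0.01 ha / lake-river filter "
      f"({len(points) - len(kept)} removed)")

grid = empty_grid((0.0, 0.0), 10.0, 50, 50)
cover = kde_cover(kept, grid, search_radius_km=100.0)
cover.write_asc(out / "wetland_cover.asc")
print(f"KDE cover: range {cover.values.min():.1f}-"
      f"{cover.values.max():.1f} {cover.units}")

obs = pd.read_csv(data / "temperature_points.csv")
xy = obs[["x_km", "y_km"]].to_numpy()
vg = fit_variogram(xy, obs["value"].to_numpy())
(out / "variogram.json").write_text(json.dumps({
    "family": vg.family, "nugget": vg.nugget, "psill": vg.psill,
    "range_km": vg.range_km, "mean": vg.mean}, indent=2))
temp = simple_krige(xy, obs["value"].to_numpy(), vg, grid)
temp.write_asc(out / "temperature.asc")
print(f"kriged temperature with {vg.family} variogram "
      f"(range {vg.range_km:.0f} km, nugget {vg.nugget:.2f}, "
      f"psill {vg.psill:.2f})")

sites = pd.read_csv(data / "sites.csv")
kept_cols, dropped_cols, corr = correlation_screen(
    sites[["elev", "precip", "temp"]], cutoff=0.7)
corr.to_csv(out / "covariate_correlations.csv")
print(f"correlation screen (cutoff 0.7): kept {kept_cols}, "
      f"dropped {dropped_cols or 'none'}")

t1 = RasterGrid.read_asc(data / "cover_2001.asc")
t2 = RasterGrid.read_asc(data / "cover_2011.asc")
change, pct = wetland_change(t1, t2)
change.write_asc(out / "change_abs.asc")
pct.write_asc(out / "change_pct.asc")
total = change.values[change.mask].sum()
print(f"decadal cover change: net loss {total:.0f} units; "
      f"max per-cell loss {change.values[change.mask].max():.0f} "
      f"({pct.values[pct.mask].max():.0f}% of baseline)")
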