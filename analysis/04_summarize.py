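"""Turn the posterior chain into the study deliverables.

Builds the wetland-effect coefficient surface (posterior mean and 95%
interval per spline cell), the three-class significance map, and the
fixed-effects table, compares them against the simulation truth, and
exports everything as rasters + CSV + manifest.

Run after 03_fit.py:  python analysis/04_summarize.py
Writes under results/products/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import wetland_svc as w
from wetland_svc.experiments import basis_cell_centers
from wetland_svc.mcmc import Chain
from wetland_svc.outputs import build_fixed_effects_table, build_surface
from wetland_svc.rasters import empty_grid
from wetland_svc.synthetic import _surface_values, read_site_csv

out = Path("results/products")
out.mkdir(parents=True, exist_ok=True)

sites = read_site_csv("results/data/sites.csv")
spec = w.build_model_spec(sites, k1=5, k2=5)
chain = Chain.load("results/fit")
summ = w.summarize(chain)
summ.to_csv(Path("results/fit") / "summary.csv")

surface = build_surface(spec.basis, summ)
table = build_fixed_effects_table(summ, spec.alpha_names)
template = empty_grid((0.0, 0.0), 10.0, 50, 50)
w.export_products(surface, table, template, out, seed=chain.seed,
                  chain_length=chain.n_retained)

print("fixed effects (posterior mean [95% CI]):")
for name, row in table.full.iterrows():
    star = "*" if row["Significant"] else " "
    print(f"  {name:<10} {row['Mean']:+.3f} "
          f"[{row['Lower 95% CI']:+.3f}, {row['Upper 95% CI']:+.3f}]{star}")

cls = surface.sig_class
print(f"surface: {int((cls == 1).sum())} cells significantly positive, "
      f"{int((cls == -1).sum())} negative, "
      f"{int((cls == 0).sum())} not significant (of {spec.Q})")

# compare with the simulation truth
cx, cy = basis_cell_centers(spec.basis)
truth_cells = _surface_values(np.array([[-0.5, 0.0, 0.5]]), cx, cy,
                              (0.0, 500.0, 0.0, 500.0))
strong = np.abs(truth_cells) > 0.25
agree = (np.sign(surface.mean[strong]) == np.sign(truth_cells[strong]))
inside = ((surface.lower <= truth_cells) & (truth_cells <= surface.upper))
print(f"vs truth: sign agreement {100 * agree.mean():.0f}% in "
      f"strong-signal cells; 95% CIs cover the true cell value in "
      f"{100 * inside.mean():.0f}% of cells")
pd.DataFrame({
    "cell_x_km": cx, "cell_y_km": cy, "truth": truth_cells,
    "mean": surface.mean, "lower": surface.lower, "upper": surface.upper,
    "sig_class": cls,
}).to_csv(out / "surface_vs_truth.csv", index=False)
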