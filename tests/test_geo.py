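"""Geoprocessing: filtering, KDE cover, kriging, screening, change."""

import numpy as np
import pandas as pd
import pytest

from wetland_svc import geo
from wetland_svc.geo import (VariogramModel, assemble_site_table,
                             correlation_screen, empirical_semivariogram,
                             filter_wetland_points, fit_variogram, kde_cover,
                             krige_at, make_point_table, simple_krige,
                             wetland_change)
from wetland_svc.rasters import NODATA, RasterGrid, empty_grid


class TestFilter:
    @pytest.mark.parametrize("area,cls,kept", [
        (0.005, "freshwater emergent", False),  # below 0.01 ha threshold
        (5.0, "lake", False),                   # open-water class excluded
        (5.0, "river", False),
        (0.01, "freshwater emergent", True),    # at threshold: kept
        (0.5, "freshwater forested/shrub", True),
    ])
    def test_rules(self, area, cls, kept):
        pts = make_point_table([0.0], [0.0], [area], [cls])
        out = filter_wetland_points(pts)
        assert (len(out) == 1) is kept

    def test_empty_in_empty_out(self):
        pts = make_point_table([], [], [], [])
        assert len(filter_wetland_points(pts)) == 0

    def test_order_preserved(self):
        pts = make_point_table([1, 2, 3, 4], [0, 0, 0, 0],
                               [1.0, 0.001, 1.0, 1.0],
                               ["a", "b", "lake", "c"])
        out = filter_wetland_points(pts)
        assert out["x_km"].tolist() == [1, 4]


class TestKDE:
    def grid(self, n=60, cell=10.0):
        return empty_grid((0.0, 0.0), cell, n, n)

    def test_no_points_all_zero(self):
        out = kde_cover(make_point_table([], [], [], []), self.grid())
        assert (out.values == 0).all()

    def test_mass_conservation_single_point(self):
        """Integrated density recovers the point weight within 1%."""
        pts = make_point_table([300.0], [300.0], [250.0], ["emergent"])
        grid = self.grid()
        out = kde_cover(pts, grid, search_radius_km=100.0)
        total = out.values.sum() * grid.cell_size**2 / 100.0
        assert abs(total - 250.0) / 250.0 < 0.01

    def test_mass_conservation_many_points(self):
        rng = np.random.default_rng(0)
        pts = make_point_table(rng.uniform(150, 450, 40),
                               rng.uniform(150, 450, 40),
                               rng.uniform(0.5, 30, 40),
                               ["emergent"] * 40)
        grid = self.grid()
        out = kde_cover(pts, grid, search_radius_km=100.0)
        total = out.values.sum() * grid.cell_size**2 / 100.0
        w = pts["area_ha"].sum()
        assert abs(total - w) / w < 0.01

    def test_rotational_symmetry(self):
        """A single point on the grid center gives a 90-degree symmetric
        raster (radial kernel)."""
        pts = make_point_table([300.0], [300.0], [10.0], ["emergent"])
        out = kde_cover(pts, self.grid(), search_radius_km=95.0).values
        assert np.allclose(out, np.rot90(out), atol=1e-9)

    def test_zero_beyond_radius(self):
        pts = make_point_table([50.0], [50.0], [10.0], ["emergent"])
        out = kde_cover(pts, self.grid(), search_radius_km=100.0)
        cx, cy = out.cell_centers()
        far = np.hypot(cx - 50.0, cy - 50.0) > 100.0
        assert (out.values[far] == 0).all()
        assert (out.values >= 0).all()

    def test_count_weighting_flag(self):
        pts = make_point_table([300.0, 310.0], [300.0, 300.0],
                               [5.0, 50.0], ["a", "b"])
        grid = self.grid()
        unweighted = kde_cover(pts, grid, weighted=False)
        total = unweighted.values.sum() * grid.cell_size**2 / 100.0
        assert abs(total - 2.0) < 0.02  # two points, unit weight each


class TestKriging:
    def toy(self):
        obs_xy = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0],
                           [7.0, 7.0], [3.0, 9.0]])
        obs_z = np.array([1.0, 2.0, 0.5, 1.5, 3.0])
        vg = VariogramModel(family="exponential", nugget=0.0, psill=2.0,
                            range_km=15.0, mean=1.0)
        return obs_xy, obs_z, vg

    def test_exact_at_observations_zero_nugget(self):
        obs_xy, obs_z, vg = self.toy()
        pred = krige_at(obs_xy, obs_z, vg, obs_xy)
        assert np.allclose(pred, obs_z, atol=1e-8)

    def test_prior_mean_far_from_data(self):
        obs_xy, obs_z, vg = self.toy()
        pred = krige_at(obs_xy, obs_z, vg, np.array([[5000.0, 5000.0]]))
        assert abs(pred[0] - vg.mean) < 1e-6

    def test_matches_dense_linear_algebra_oracle(self):
        """Direct dense solve of the simple-kriging system."""
        obs_xy, obs_z, vg = self.toy()
        targets = np.array([[2.0, 3.0], [8.0, 8.0], [5.0, 1.0]])
        pred = krige_at(obs_xy, obs_z, vg, targets)
        # oracle: full covariance assembly, one target at a time
        def cov(a, b):
            return vg.psill * np.exp(-np.hypot(*(a - b)) / vg.range_km)
        n = len(obs_z)
        Sigma = np.array([[cov(obs_xy[i], obs_xy[j]) for j in range(n)]
                          for i in range(n)])
        for t, p in zip(targets, pred):
            c = np.array([cov(t, obs_xy[i]) for i in range(n)])
            lam = np.linalg.solve(Sigma, c)
            assert p == pytest.approx(vg.mean + lam @ (obs_z - vg.mean),
                                      abs=1e-10)

    def test_linearity_in_observations(self):
        """Scaling observations-minus-mean by c scales predictions-minus-
        mean by c."""
        obs_xy, obs_z, vg = self.toy()
        vg0 = VariogramModel(nugget=0.1, psill=2.0, range_km=15.0, mean=0.0)
        targets = np.array([[2.0, 3.0], [9.0, 9.0]])
        p1 = krige_at(obs_xy, obs_z, vg0, targets)
        p2 = krige_at(obs_xy, 3.0 * obs_z, vg0, targets)
        assert np.allclose(3.0 * p1, p2, atol=1e-10)

    def test_duplicates_deduplicated(self):
        obs_xy = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        obs_z = np.array([1.0, 3.0, 2.0])
        vg = VariogramModel(nugget=0.0, psill=1.0, range_km=5.0, mean=0.0)
        pred = krige_at(obs_xy, obs_z, vg, np.array([[0.0, 0.0]]))
        assert pred[0] == pytest.approx(2.0)  # average of the duplicates

    def test_grid_prediction_shape(self):
        obs_xy, obs_z, vg = self.toy()
        grid = empty_grid((0.0, 0.0), 2.0, 8, 8)
        out = simple_krige(obs_xy, obs_z, vg, grid)
        assert out.values.shape == (8, 8)


class TestVariogramFit:
    def _gp_field(self, rng, n=400, range_km=50.0, psill=2.0, nugget=0.1):
        xy = rng.uniform(0, 300, (n, 2))
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).T)
        cov = psill * np.exp(-d / range_km) + nugget * np.eye(n)
        z = np.linalg.cholesky(cov + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        return xy, z

    def test_recovers_exponential_range(self):
        """Median fitted range over seeds within +-50% of truth."""
        ranges = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            xy, z = self._gp_field(rng)
            ranges.append(fit_variogram(xy, z).range_km)
        med = np.median(ranges)
        assert 25.0 < med < 75.0

    def test_white_noise_mostly_nugget(self):
        """Spatially unstructured data: the nugget absorbs the variance."""
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            xy = rng.uniform(0, 300, (800, 2))
            z = rng.standard_normal(800)
            vg = fit_variogram(xy, z)
            ratios.append(vg.psill / max(vg.nugget, 1e-12))
        assert np.median(ratios) < 0.2

    def test_constant_field_nugget_only(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 100, (50, 2))
        vg = fit_variogram(xy, np.full(50, 3.0))
        assert vg.psill == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_variogram(np.zeros((5, 2)), np.zeros(5))

    def test_empirical_semivariogram_hand_check(self):
        # three collinear points: pairs at distance 1, 1, 2
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        z = np.array([0.0, 1.0, 3.0])
        emp = empirical_semivariogram(xy, z, n_bins=2, max_dist=2.5)
        # bin 1: distances 1,1 -> gamma = (0.5*1 + 0.5*4)/2 = 1.25
        # bin 2: distance 2 -> gamma = 0.5*9 = 4.5
        assert emp["gamma"].tolist() == [1.25, 4.5]
        assert emp["n_pairs"].tolist() == [2, 1]


class TestCorrelationScreen:
    def test_duplicate_column_second_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(100)
        df = pd.DataFrame({"a": a, "b": a.copy()})
        kept, dropped, _ = correlation_screen(df)
        assert kept == ["a"] and dropped == ["b"]

    def test_independent_columns_all_kept(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((1000, 3)),
                          columns=["a", "b", "c"])
        kept, dropped, _ = correlation_screen(df)
        assert kept == ["a", "b", "c"] and not dropped

    def test_matrix_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        _, _, corr = correlation_screen(df)
        a, b = df["a"] - df["a"].mean(), df["b"] - df["b"].mean()
        r = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert corr.loc["a", "b"] == pytest.approx(r, abs=1e-12)

    def test_invariant_to_appending_screened_duplicate(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((200, 3)),
                          columns=["a", "b", "c"])
        kept1, _, _ = correlation_screen(df)
        df2 = df.assign(dup_a=df["a"] * 1.0)
        kept2, dropped2, _ = correlation_screen(df2)
        assert kept1 == kept2 and "dup_a" in dropped2

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.standard_normal(50),
                           "const": np.ones(50)})
        kept, dropped, _ = correlation_screen(df)
        assert kept == ["a"] and dropped == ["const"]

    def test_surviving_pairs_below_cutoff(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(300)
        df = pd.DataFrame({
            "a": base,
            "b": 0.95 * base + 0.3 * rng.standard_normal(300),
            "c": rng.standard_normal(300),
            "d": -0.9 * base + 0.3 * rng.standard_normal(300),
        })
        kept, _, corr = correlation_screen(df, cutoff=0.7)
        sub = corr.loc[kept, kept].to_numpy()
        off = sub[~np.eye(len(kept), dtype=bool)]
        assert (np.abs(off) < 0.7).all()


class TestWetlandChange:
    def make(self, vals):
        return RasterGrid((0.0, 0.0), 10.0, np.asarray(vals, dtype=float))

    def test_identical_rasters(self):
        t1 = self.make([[10.0, 20.0], [5.0, 0.0]])
        change, pct = wetland_change(t1, self.make(t1.values.copy()))
        assert (change.values == 0).all()
        assert (pct.values[pct.mask] == 0).all()

    def test_subtraction_order_and_percent(self):
        """t1=100, t2=80 -> loss of 20 ha, 20% of the baseline."""
        change, pct = wetland_change(self.make([[100.0]]), self.make([[80.0]]))
        assert change.values[0, 0] == 20.0
        assert pct.values[0, 0] == 20.0

    def test_zero_baseline_percent_nodata(self):
        change, pct = wetland_change(self.make([[0.0]]), self.make([[5.0]]))
        assert change.values[0, 0] == -5.0
        assert pct.values[0, 0] == NODATA

    def test_sum_identity_with_nodata(self):
        t1 = self.make([[10.0, NODATA], [5.0, 7.0]])
        t2 = self.make([[3.0, 1.0], [NODATA, 2.0]])
        change, _ = wetland_change(t1, t2)
        both = t1.mask & t2.mask
        assert change.values[both].sum() == (t1.values[both].sum()
                                             - t2.values[both].sum())

    def test_mismatched_grids_rejected(self):
        t1 = self.make([[1.0]])
        t2 = RasterGrid((5.0, 0.0), 10.0, [[1.0]])
        with pytest.raises(ValueError, match="co-registered"):
            wetland_change(t1, t2)


class TestAssemble:
    def layers(self, n=5):
        mk = lambda v: RasterGrid((0.0, 0.0), 10.0, np.full((n, n), float(v)))
        cover = mk(100.0)
        covs = {"elev": mk(1.0), "precip": mk(2.0), "temp": mk(3.0)}
        regions = mk(0.0)
        counts = mk(4.0)
        return cover, covs, regions, counts

    def test_full_grid_gives_all_rows(self):
        df = assemble_site_table(*self.layers())
        assert len(df) == 25
        assert list(df.columns) == geo.SITE_CSV_COLUMNS

    def test_nodata_cell_dropped(self):
        cover, covs, regions, counts = self.layers()
        covs["elev"].values[2, 2] = NODATA
        df = assemble_site_table(cover, covs, regions, counts)
        assert len(df) == 24

    def test_all_nodata_rejected(self):
        cover, covs, regions, counts = self.layers(2)
        cover.values[:] = NODATA
        with pytest.raises(ValueError, match="survive"):
            assemble_site_table(cover, covs, regions, counts)
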