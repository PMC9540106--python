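"""Grid I/O, geodesic cell areas, and polygon masking."""

import numpy as np
import pandas as pd
import pytest
import shapely.geometry as sgeom
from hypothesis import given
from hypothesis import strategies as st

from shelfhypso import (
    EARTH_RADIUS_KM,
    BathymetryGrid,
    GridSpec,
    RegionMask,
    ShelfCellTable,
    cell_areas,
    load_bathymetry,
    mask_cells,
    mask_cells_single,
)
from shelfhypso.synthetic import write_netcdf


def small_grid(values, lat_min=0.0, lon_min=0.0, res=1.0):
    values = np.asarray(values, dtype=float)
    spec = GridSpec(
        lat_min=lat_min,
        lat_max=lat_min + res * values.shape[0],
        lon_min=lon_min,
        lon_max=lon_min + res * values.shape[1],
        resolution=res,
    )
    return BathymetryGrid(spec=spec, values=values)


class TestGridSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 10, 0, 10, -1.0)
        with pytest.raises(ValueError):
            GridSpec(-95, 10, 0, 10, 1.0)
        with pytest.raises(ValueError):
            GridSpec(0, 10.5, 0, 10, 1.0)  # non-integer multiple

    def test_centers(self):
        spec = GridSpec(0, 2, 10, 12, 1.0)
        assert np.allclose(spec.lat_centers, [0.5, 1.5])
        assert np.allclose(spec.lon_centers, [10.5, 11.5])


class TestCellAreas:
    def test_equatorial_one_degree_closed_form(self):
        a = cell_areas(GridSpec(-0.5, 0.5, 0, 1, 1.0))[0]
        expected = EARTH_RADIUS_KM**2 * np.radians(1.0) * 2 * np.sin(np.radians(0.5))
        assert a == pytest.approx(expected, rel=1e-12)
        assert a == pytest.approx(12364.0, rel=1e-4)

    def test_equatorial_arcminute(self):
        res = 1.0 / 60.0
        a = cell_areas(GridSpec(-res / 2, res / 2, 0, res, res))[0]
        assert a == pytest.approx(3.43, abs=0.01)

    def test_global_sum_is_sphere_area(self):
        spec = GridSpec(-90, 90, -180, 180, 1.0)
        total = cell_areas(spec).sum() * spec.nlon
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_KM**2, rel=1e-6)

    @given(res=st.sampled_from([0.25, 0.5, 1.0, 2.0]))
    def test_monotone_decreasing_in_abs_latitude_and_symmetric(self, res):
        spec = GridSpec(-90, 90, 0, 10 * res, res)
        a = cell_areas(spec)
        lat = spec.lat_centers
        north = a[lat > 0]
        assert np.all(np.diff(north) < 0)  # strictly decreasing poleward
        assert np.allclose(a, a[::-1])  # symmetric about the equator


class TestLoadBathymetry:
    def test_netcdf_round_trip(self, tmp_path):
        vals = np.array([[-10.0, 20.0], [-30.0, -2000.0]])
        grid = small_grid(vals)
        path = tmp_path / "g.nc"
        write_netcdf(grid, path)
        loaded = load_bathymetry(path)
        assert np.allclose(loaded.values, vals)
        assert loaded.spec == grid.spec

    def test_netcdf_nodata_survives(self, tmp_path):
        import xarray as xr

        vals = np.array([[-10.0, -9999.0], [-30.0, -40.0]])
        da = xr.DataArray(
            vals,
            coords={"lat": [0.5, 1.5], "lon": [0.5, 1.5]},
            dims=("lat", "lon"),
            name="z",
        )
        da.encoding["_FillValue"] = -9999.0
        da.to_netcdf(tmp_path / "g.nc", engine="scipy", format="NETCDF3_CLASSIC")
        loaded = load_bathymetry(tmp_path / "g.nc")
        assert np.isnan(loaded.values[0, 1])
        assert np.isfinite(loaded.values).sum() == 3

    def test_bbox_selects_half_the_columns(self, tmp_path):
        vals = -np.arange(16, dtype=float).reshape(4, 4) - 1
        grid = small_grid(vals)
        write_netcdf(grid, tmp_path / "g.nc")
        loaded = load_bathymetry(tmp_path / "g.nc", bbox=(0, 4, 0, 2))
        assert loaded.values.shape == (4, 2)
        assert np.allclose(loaded.values, vals[:, :2])

    def test_geotiff_round_trip_and_projected_rejected(self, tmp_path):
        import tifffile

        vals = np.array([[-1.0, -2.0], [-3.0, -4.0]], dtype=np.float64)
        # north-up GeoTIFF: row 0 is the northern row
        def write(path, model_type):
            keys = np.array([1, 1, 0, 1, 1024, 0, 1, model_type], dtype=np.uint16)
            tifffile.imwrite(
                path,
                vals,
                extratags=[
                    (33550, "d", 3, (1.0, 1.0, 0.0)),
                    (33922, "d", 6, (0.0, 0.0, 0.0, 10.0, 2.0, 0.0)),
                    (34735, "H", len(keys), tuple(int(k) for k in keys)),
                ],
            )

        write(tmp_path / "geo.tif", 2)
        loaded = load_bathymetry(tmp_path / "geo.tif")
        assert loaded.spec.lat_min == 0.0 and loaded.spec.lon_min == 10.0
        assert np.allclose(loaded.values, vals[::-1, :])  # stored south-up

        write(tmp_path / "proj.tif", 1)
        with pytest.raises(ValueError, match="projected"):
            load_bathymetry(tmp_path / "proj.tif")

    def test_projected_netcdf_rejected(self, tmp_path):
        import xarray as xr

        da = xr.DataArray(
            np.zeros((2, 2)),
            coords={
                "y": ("y", [0.5, 1.5], {"units": "m"}),
                "x": ("x", [0.5, 1.5], {"units": "m"}),
            },
            dims=("y", "x"),
            name="z",
        )
        da.to_netcdf(tmp_path / "p.nc", engine="scipy", format="NETCDF3_CLASSIC")
        with pytest.raises(ValueError, match="projected"):
            load_bathymetry(tmp_path / "p.nc")


class TestMaskCells:
    def region(self, lon0=0.0, lat0=0.0, lon1=4.0, lat1=4.0, name="r"):
        return RegionMask(name=name, geometry=sgeom.box(lon0, lat0, lon1, lat1))

    def test_all_land_gives_empty_table(self):
        grid = small_grid(np.full((2, 2), 5.0))
        with pytest.warns(UserWarning, match="no shelf cells"):
            table = mask_cells_single(grid, self.region())
        assert len(table) == 0

    def test_depth_cutoff_keeps_shallower_cells(self):
        grid = small_grid(np.array([[-100.0, -1500.0, -2500.0]]))
        table = mask_cells_single(grid, self.region())
        assert sorted(table.depths) == [100.0, 1500.0]

    def test_cell_at_exact_cutoff_kept(self):
        grid = small_grid(np.array([[-2000.0]]))
        assert len(mask_cells_single(grid, self.region())) == 1

    def test_zero_elevation_excluded(self):
        grid = small_grid(np.array([[0.0, -1.0]]))
        table = mask_cells_single(grid, self.region())
        assert list(table.depths) == [1.0]

    def test_west_half_polygon_keeps_west_columns(self):
        grid = small_grid(-np.ones((1, 4)))
        west = self.region(lon0=0.0, lon1=2.0)
        table = mask_cells_single(grid, west)
        assert sorted(table.df["lon"]) == [0.5, 1.5]

    def test_center_on_boundary_counts_inside(self):
        grid = small_grid(-np.ones((1, 2)))
        # polygon edge passes exactly through the first cell center (0.5)
        edge = self.region(lon0=0.5, lon1=0.7)
        table = mask_cells_single(grid, edge)
        assert 0.5 in set(table.df["lon"])

    def test_shelf_intersection_applied(self):
        grid = small_grid(-np.ones((1, 4)))
        shelf = self.region(lon0=1.0, lon1=3.0, name="shelf")
        table = mask_cells_single(grid, self.region(), shelf=shelf)
        assert sorted(table.df["lon"]) == [1.5, 2.5]

    def test_masking_idempotent(self):
        rng = np.random.default_rng(0)
        grid = small_grid(-rng.uniform(1, 3000, (5, 5)))
        poly = self.region(lon0=0.7, lat0=0.2, lon1=4.1, lat1=4.9)
        t1 = mask_cells_single(grid, poly)
        # re-masking the surviving cells with the same polygon changes nothing
        import shapely

        shapely.prepare(poly.geometry)
        inside = shapely.intersects_xy(
            poly.geometry, t1.df["lon"].to_numpy(), t1.df["lat"].to_numpy()
        )
        assert inside.all()
        assert (t1.depths <= t1.depth_max).all()

    def test_masked_area_bounded_by_grid_extent(self):
        rng = np.random.default_rng(1)
        grid = small_grid(-rng.uniform(1, 3000, (4, 4)))
        total_extent = cell_areas(grid.spec).sum() * grid.spec.nlon
        table = mask_cells_single(grid, self.region())
        assert table.total_area() <= total_extent + 1e-9

    def test_antimeridian_polygon_wrapped(self):
        geom = sgeom.box(170.0, 0.0, 190.0, 4.0)  # crosses the dateline
        region = RegionMask(name="dateline", geometry=geom)
        minx, _, maxx, _ = region.geometry.bounds
        assert minx >= -180.0 and maxx <= 180.0
        grid = small_grid(-np.ones((1, 2)), lon_min=-180.0)  # centers −179.5, −178.5
        table = mask_cells_single(grid, region)
        assert len(table) == 2

    def test_duplicate_region_names_rejected(self):
        grid = small_grid(-np.ones((1, 1)))
        with pytest.raises(ValueError, match="unique"):
            mask_cells(grid, [self.region(name="a"), self.region(name="a")])


class TestShelfCellTableIO:
    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"lat": [0.5], "lon": [1.5], "depth_m": [42.0], "area_km2": [3.0]}
        )
        table = ShelfCellTable(df=df, region="demo", depth_max=2000.0, source="x.nc")
        path = tmp_path / "cells.csv"
        table.to_csv(path)
        back = ShelfCellTable.from_csv(path)
        pd.testing.assert_frame_equal(back.df, table.df)
        assert back.region == "demo" and back.depth_max == 2000.0

    def test_invariants_enforced(self):
        bad = pd.DataFrame(
            {"lat": [0.0], "lon": [0.0], "depth_m": [-5.0], "area_km2": [1.0]}
        )
        with pytest.raises(ValueError):
            ShelfCellTable(df=bad)
        dup = pd.DataFrame(
            {"lat": [0, 0], "lon": [0, 0], "depth_m": [1, 2], "area_km2": [1, 1]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            ShelfCellTable(df=dup)


def test_geojson_round_trip(tmp_path):
    region = RegionMask(name="poly", geometry=sgeom.box(0, 0, 2, 2))
    region.to_geojson(tmp_path / "r.geojson")
    back = RegionMask.from_geojson(tmp_path / "r.geojson")
    assert back.name == "poly"
    assert back.geometry.equals(region.geometry)
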