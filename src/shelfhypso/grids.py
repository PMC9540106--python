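"""Gridded bathymetry, geodesic cell areas, and polygon masking.

This module turns a georeferenced elevation grid plus region/shelf polygons
into the per-cell shelf table that every downstream analysis consumes:
one record per retained grid cell with its center coordinates, water depth
(positive down, in meters) and geodesic cell area in km².

Cell areas use the spherical-cap formula on the authalic sphere,

    A = R² · Δλ · (sin φ_top − sin φ_bot),   R = 6371.0 km,

which is exact on the sphere and constant along a latitude row.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

#: Authalic Earth radius, km (sphere with the same surface area as the ellipsoid).
EARTH_RADIUS_KM = 6371.0

#: Depth cutoff in meters separating shelf (incl. misclassification margin) from slope.
DEFAULT_DEPTH_MAX = 2000.0


class EmptyTableError(ValueError):
    """Raised when an operation requires at least one shelf cell."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid with cell-center registration.

    ``lat_min``/``lat_max`` etc. are the *outer edges* of the grid in degrees;
    cell centers sit half a resolution step inside them.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float  # degrees per cell

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must satisfy -90 <= lat_min < lat_max <= 90")
        if not (self.lon_min < self.lon_max):
            raise ValueError("lon_min must be < lon_max")
        for span, name in (
            (self.lat_max - self.lat_min, "latitude"),
            (self.lon_max - self.lon_min, "longitude"),
        ):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-6 * max(1.0, abs(n)):
                raise ValueError(f"{name} span is not an integer multiple of the resolution")

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, ascending (south to north)."""
        return self.lat_min + (np.arange(self.nlat) + 0.5) * self.resolution

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.nlon) + 0.5) * self.resolution


@dataclass
class BathymetryGrid:
    """Elevation values (m, negative below sea level) on a :class:`GridSpec`.

    ``values[i, j]`` corresponds to ``(lat_centers[i], lon_centers[j])``.
    Missing data is NaN internally; ``nodata`` records the sentinel used on disk.
    """

    spec: GridSpec
    values: np.ndarray
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nlat, self.spec.nlon):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.nlat}, {self.spec.nlon})"
            )


@dataclass
class RegionMask:
    """A named multipolygon region in lon/lat degrees.

    Invalid geometries are repaired on construction; polygons extending past
    the ±180° meridian are wrapped back into [−180, 180].
    """

    name: str
    geometry: sgeom.base.BaseGeometry

    def __post_init__(self) -> None:
        geom = self.geometry
        if not geom.is_valid:
            logger.info("repairing invalid polygon for region %r", self.name)
            geom = make_valid(geom)
        self.geometry = _wrap_antimeridian(geom)

    @classmethod
    def from_geojson(cls, path, name: str | None = None) -> "RegionMask":
        """Read the first (Multi)Polygon feature of a GeoJSON file."""
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") == "FeatureCollection":
            feats = doc["features"]
            if not feats:
                raise ValueError(f"no features in {path}")
            geoms = [sgeom.shape(f["geometry"]) for f in feats]
            geom = shapely.unary_union(geoms) if len(geoms) > 1 else geoms[0]
            props = feats[0].get("properties") or {}
        elif doc.get("type") == "Feature":
            geom = sgeom.shape(doc["geometry"])
            props = doc.get("properties") or {}
        else:
            geom = sgeom.shape(doc)
            props = {}
        if name is None:
            name = str(props.get("name", "region"))
        return cls(name=name, geometry=geom)

    def to_geojson(self, path) -> None:
        doc = {
            "type": "Feature",
            "properties": {"name": self.name},
            "geometry": sgeom.mapping(self.geometry),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _wrap_antimeridian(geom: sgeom.base.BaseGeometry) -> sgeom.base.BaseGeometry:
    """Split geometry at ±180° and wrap out-of-range lobes into [−180, 180]."""
    minx, _, maxx, _ = geom.bounds
    if minx >= -180.0 and maxx <= 180.0:
        return geom
    world = sgeom.box(-180.0, -90.0, 180.0, 90.0)
    parts = [geom.intersection(world)]
    for shift in (-360.0, 360.0):
        shifted = shapely.transform(geom, lambda c: c + np.array([shift, 0.0]))
        parts.append(shifted.intersection(world))
    return shapely.unary_union([p for p in parts if not p.is_empty])


@dataclass
class ShelfCellTable:
    """Per-cell shelf records after land/depth/polygon masking.

    Wraps a DataFrame with columns ``lat``, ``lon``, ``depth_m`` (positive
    down) and ``area_km2``. ``region`` and ``depth_max`` record provenance.
    """

    df: pd.DataFrame
    region: str = ""
    depth_max: float = DEFAULT_DEPTH_MAX
    source: str = ""

    REQUIRED = ("lat", "lon", "depth_m", "area_km2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = self.df
        if len(df):
            if (df["depth_m"] <= 0).any() or (df["depth_m"] > self.depth_max).any():
                raise ValueError(f"depths must lie in (0, {self.depth_max}]")
            if (df["area_km2"] <= 0).any():
                raise ValueError("cell areas must be positive")
            if df.duplicated(subset=["lat", "lon"]).any():
                raise ValueError("duplicate (lat, lon) cell records")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depths(self) -> np.ndarray:
        return self.df["depth_m"].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.df["area_km2"].to_numpy()

    def total_area(self) -> float:
        return float(self.df["area_km2"].sum())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# region: {self.region}\n")
            fh.write(f"# depth_max_m: {self.depth_max}\n")
            fh.write(f"# source: {self.source}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ShelfCellTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        return cls(
            df=df,
            region=meta.get("region", ""),
            depth_max=float(meta.get("depth_max_m", DEFAULT_DEPTH_MAX)),
            source=meta.get("source", ""),
        )


def cell_areas(spec: GridSpec) -> np.ndarray:
    """Geodesic area (km²) of one cell in each latitude row of ``spec``.

    Returns an array aligned with ``spec.lat_centers``. Areas are constant
    along a row, strictly decrease with |latitude| and are symmetric about
    the equator.
    """
    half = spec.resolution / 2.0
    lat = spec.lat_centers
    top = np.radians(np.clip(lat + half, -90.0, 90.0))
    bot = np.radians(np.clip(lat - half, -90.0, 90.0))
    dlon = np.radians(spec.resolution)
    return EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bot))


def _read_netcdf(path, bbox):
    import xarray as xr

    try:
        ds = xr.open_dataset(path)
    except Exception:
        ds = xr.open_dataset(path, engine="scipy")
    lat_name = next((c for c in ("lat", "latitude", "y") if c in ds.coords), None)
    lon_name = next((c for c in ("lon", "longitude", "x") if c in ds.coords), None)
    if lat_name is None or lon_name is None:
        raise ValueError(f"could not find lat/lon coordinates in {path}")
    for cname in (lat_name, lon_name):
        units = str(ds[cname].attrs.get("units", "")).lower()
        if units.startswith(("m", "km")) and "degree" not in units:
            raise ValueError(
                f"coordinate {cname!r} has projected units {units!r}; "
                "a geographic (lon/lat degrees) grid is required"
            )
    var = next(
        (v for v in ds.data_vars if ds[v].ndim == 2),
        None,
    )
    if var is None:
        raise ValueError(f"no 2-D elevation variable found in {path}")
    da = ds[var]
    da = da.sortby(lat_name).sortby(lon_name)
    if bbox is not None:
        lat_lo, lat_hi, lon_lo, lon_hi = bbox
        da = da.sel({lat_name: slice(lat_lo, lat_hi), lon_name: slice(lon_lo, lon_hi)})
    lat = da[lat_name].values.astype(float)
    lon = da[lon_name].values.astype(float)
    values = da.transpose(lat_name, lon_name).values.astype(float)
    nodata = da.attrs.get("_FillValue", da.encoding.get("_FillValue"))
    ds.close()
    return lat, lon, values, nodata


# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GT_MODEL_TYPE_KEY = 1024
_MODEL_TYPE_GEOGRAPHIC = 2


def _read_geotiff(path, bbox):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = {t.code: t.value for t in page.tags.values()}
        if _GEO_KEY_DIRECTORY in tags:
            keys = np.asarray(tags[_GEO_KEY_DIRECTORY]).reshape(-1, 4)
            for key_id, _, _, value in keys[1:]:
                if key_id == _GT_MODEL_TYPE_KEY and value != _MODEL_TYPE_GEOGRAPHIC:
                    raise ValueError(
                        f"{path} uses a projected CRS (GTModelType={value}); "
                        "a geographic (lon/lat) grid is required"
                    )
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path} lacks GeoTIFF georeferencing tags")
        sx, sy = tags[_MODEL_PIXEL_SCALE][:2]
        _, _, _, tx, ty = tags[_MODEL_TIEPOINT][:5]
        values = page.asarray().astype(float)
        nodata = None
        gdal_nodata = tags.get(42113)  # GDAL_NODATA ascii tag
        if gdal_nodata is not None:
            nodata = float(gdal_nodata)
    nrow, ncol = values.shape
    # tiepoint references the outer corner of the top-left pixel
    lon = tx + (np.arange(ncol) + 0.5) * sx
    lat = ty - (np.arange(nrow) + 0.5) * sy
    values = values[::-1, :]  # reorder south-to-north
    lat = lat[::-1]
    if bbox is not None:
        lat_lo, lat_hi, lon_lo, lon_hi = bbox
        li = (lat >= lat_lo) & (lat <= lat_hi)
        lj = (lon >= lon_lo) & (lon <= lon_hi)
        lat, lon, values = lat[li], lon[lj], values[np.ix_(li, lj)]
    return lat, lon, values, nodata


def load_bathymetry(path, bbox=None) -> BathymetryGrid:
    """Load a single-band geographic elevation grid (netCDF or GeoTIFF).

    Parameters
    ----------
    path : str or Path
        ``.nc``/``.cdf`` (CF conventions, read via xarray) or ``.tif``/``.tiff``
        (minimal GeoTIFF georeferencing; geographic model required).
    bbox : tuple, optional
        ``(lat_min, lat_max, lon_min, lon_max)`` selecting cells whose centers
        fall inside the box.

    Coordinates in the file are treated as cell centers; grid-registered
    sources are therefore shifted by half a cell, which is logged.
    """
    spath = str(path)
    if spath.endswith((".tif", ".tiff")):
        lat, lon, values, nodata = _read_geotiff(path, bbox)
    else:
        lat, lon, values, nodata = _read_netcdf(path, bbox)
    if len(lat) < 1 or len(lon) < 1:
        raise ValueError(f"bbox selects no cells from {path}")
    res_candidates = [np.diff(lat), np.diff(lon)]
    res = float(np.median(np.abs(np.concatenate([r for r in res_candidates if len(r)]))))
    if res <= 0 or not np.isfinite(res):
        raise ValueError(f"cannot infer grid resolution from {path}")
    if abs(abs(lat[0]) - 90.0) < 1e-9 or abs(abs(lat[-1]) - 90.0) < 1e-9:
        logger.info(
            "%s appears grid-registered (coordinates reach the poles); "
            "treating coordinates as cell centers shifts the frame by half a cell",
            path,
        )
    spec = GridSpec(
        lat_min=float(lat[0] - res / 2),
        lat_max=float(lat[-1] + res / 2),
        lon_min=float(lon[0] - res / 2),
        lon_max=float(lon[-1] + res / 2),
        resolution=res,
    )
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return BathymetryGrid(spec=spec, values=values, nodata=nodata)


def mask_cells(
    grid: BathymetryGrid,
    regions: RegionMask | list[RegionMask],
    shelf: RegionMask | None = None,
    depth_max: float = DEFAULT_DEPTH_MAX,
) -> dict[str, ShelfCellTable]:
    """Mask the grid to submerged shelf cells inside each region polygon.

    A cell is retained iff its elevation is strictly negative, its depth
    (−elevation) does not exceed ``depth_max``, and its *center* lies inside
    region ∩ shelf (boundary counts as inside). Cells dropped by the depth
    cutoff are counted after the polygon masking and logged.

    Returns a dict mapping region name to its :class:`ShelfCellTable`;
    an empty intersection yields an empty table with a warning.
    """
    if depth_max <= 0:
        raise ValueError("depth_max must be positive")
    if isinstance(regions, RegionMask):
        regions = [regions]
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique within a run")

    spec = grid.spec
    lon2d, lat2d = np.meshgrid(spec.lon_centers, spec.lat_centers)
    row_area = cell_areas(spec)
    area2d = np.broadcast_to(row_area[:, None], grid.values.shape)
    wet = np.isfinite(grid.values) & (grid.values < 0)

    out: dict[str, ShelfCellTable] = {}
    for region in regions:
        geom = region.geometry
        if shelf is not None:
            geom = geom.intersection(shelf.geometry)
        sel = wet.copy()
        if not geom.is_empty:
            shapely.prepare(geom)
            inside = shapely.intersects_xy(geom, lon2d[wet], lat2d[wet])
            sel[wet] = inside
        else:
            sel[:] = False
        depth = -grid.values[sel]
        n_inside = depth.size
        keep = depth <= depth_max
        n_dropped = int(n_inside - keep.sum())
        if n_inside:
            logger.info(
                "region %r: %d/%d submerged cells (%.4f%%) dropped by the %g m cutoff",
                region.name, n_dropped, n_inside, 100.0 * n_dropped / n_inside, depth_max,
            )
        df = pd.DataFrame(
            {
                "lat": lat2d[sel][keep],
                "lon": lon2d[sel][keep],
                "depth_m": depth[keep],
                "area_km2": area2d[sel][keep],
            }
        )
        if df.empty:
            warnings.warn(
                f"region {region.name!r}: no shelf cells after masking", stacklevel=2
            )
        out[region.name] = ShelfCellTable(
            df=df.reset_index(drop=True), region=region.name, depth_max=depth_max
        )
    return out


def mask_cells_single(
    grid: BathymetryGrid,
    region: RegionMask,
    shelf: RegionMask | None = None,
    depth_max: float = DEFAULT_DEPTH_MAX,
) -> ShelfCellTable:
    """Convenience wrapper for a single region."""
    return mask_cells(grid, [region], shelf=shelf, depth_max=depth_max)[region.name]
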