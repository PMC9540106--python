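"""End-to-end orchestration: regions → depth classification and SAR
projections; coastlines → latitude profiles, flags, trends and projections.

The two entry points mirror the analysis structure:

* :func:`run_depth_analysis` — per region: shelf cell table → 1 m
  hypsometric curve → five-way classification → 15 m depth bands → SAR
  depthward projections, plus the category-share summary.
* :func:`run_latitude_analysis` — per coastline-hemisphere: 2° bin series →
  poleward expansion/contraction flags and summary → OLS trend → SAR
  poleward projections.

Both accept a :class:`RunConfig` (file paths, loaded lazily) or can be fed
pre-built cell tables directly via the ``*_from_tables`` functions, which is
how synthetic fixtures exercise them. Every step is deterministic given the
configured seed, so reruns produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import (
    DEFAULT_DEPTH_MAX,
    RegionMask,
    ShelfCellTable,
    load_bathymetry,
    mask_cells,
)
from .hypsometry import (
    DepthBandSeries,
    HypsometricCurve,
    depth_band_areas,
    hypsometric_curve,
    mean_depth,
)
from .latitude import (
    LatitudeBinSeries,
    coastline_trend,
    latitude_bin_areas,
    poleward_transitions,
    transition_summary,
)
from .modality import CATEGORIES, ClassifierConfig, classify_depth_distribution
from .sar import DEFAULT_Z_LIST, project_depth_shift, project_latitude_shift, project_multi_z

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-based run configuration (a key-value YAML document on disk)."""

    bathymetry: str
    regions: dict[str, str] = field(default_factory=dict)  # name -> GeoJSON path
    shelf: str | None = None
    exclude: list[str] = field(default_factory=list)  # e.g. polar regions
    coastlines: dict[str, list[str]] = field(default_factory=dict)
    depth_max: float = DEFAULT_DEPTH_MAX
    band_width: float = 15.0
    z_list: tuple[float, ...] = DEFAULT_Z_LIST
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    out_dir: str = "shelfhypso_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.z_list:
            raise ValueError("z_list must not be empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        classifier_keys = {
            "skew_hi", "skew_lo", "dip_D_threshold", "alpha",
            "resample_n", "mc_replicates", "seed",
        }
        ckwargs = {k: doc.pop(k) for k in list(doc) if k in classifier_keys}
        coastlines = doc.pop("coastlines", {}) or {}
        norm = {}
        for name, val in coastlines.items():
            norm[name] = list(val["regions"] if isinstance(val, dict) else val)
        doc["coastlines"] = norm
        if "z_list" in doc:
            doc["z_list"] = tuple(float(z) for z in doc["z_list"])
        base = Path(path).parent
        doc["bathymetry"] = str(base / doc["bathymetry"])
        if doc.get("shelf"):
            doc["shelf"] = str(base / doc["shelf"])
        doc["regions"] = {k: str(base / v) for k, v in (doc.get("regions") or {}).items()}
        cfg = cls(classifier=ClassifierConfig(**ckwargs), **doc)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Collected tables from a depth and/or latitude run."""

    classifications: pd.DataFrame | None = None
    category_shares: pd.DataFrame | None = None
    curves: dict[str, HypsometricCurve] = field(default_factory=dict)
    bands: dict[str, DepthBandSeries] = field(default_factory=dict)
    mean_depths: dict[str, float] = field(default_factory=dict)
    depth_projections: dict[str, pd.DataFrame] = field(default_factory=dict)
    unclassifiable: list[str] = field(default_factory=list)
    latitude_series: dict[str, LatitudeBinSeries] = field(default_factory=dict)
    transitions: dict[str, pd.DataFrame] = field(default_factory=dict)
    latitude_summary: pd.DataFrame | None = None
    latitude_projections: dict[str, pd.DataFrame] = field(default_factory=dict)
    coastline_errors: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Serialize every table as CSV plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []

        def save(df: pd.DataFrame, name: str) -> None:
            path = out / name
            df.to_csv(path, index=False, float_format="%.10g")
            files.append(name)

        if self.classifications is not None:
            save(self.classifications, "classifications.csv")
        if self.category_shares is not None:
            save(self.category_shares, "category_shares.csv")
        for region, curve in self.curves.items():
            save(curve.df, f"curve_{_slug(region)}.csv")
        for region, bands in self.bands.items():
            save(bands.df, f"bands_{_slug(region)}.csv")
        for region, proj in self.depth_projections.items():
            save(proj, f"sar_depth_{_slug(region)}.csv")
        for key, series in self.latitude_series.items():
            save(series.df, f"latbins_{_slug(key)}.csv")
        for key, trans in self.transitions.items():
            save(trans, f"transitions_{_slug(key)}.csv")
        if self.latitude_summary is not None:
            save(self.latitude_summary, "latitude_summary.csv")
        for key, proj in self.latitude_projections.items():
            save(proj, f"sar_latitude_{_slug(key)}.csv")
        manifest = {
            "provenance": self.provenance,
            "unclassifiable": self.unclassifiable,
            "coastline_errors": self.coastline_errors,
            "files": sorted(files),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in str(name)).strip("_")


def _category_shares(
    classified: pd.DataFrame, n_total: int
) -> pd.DataFrame:
    """Share per category, raw and rounded to whole percent, with both the
    classified-region and all-region denominators."""
    counts = classified["category"].value_counts()
    n_cls = int(counts.sum())
    rows = []
    for cat in CATEGORIES:
        c = int(counts.get(cat, 0))
        rows.append(
            {
                "category": cat,
                "count": c,
                "pct_of_classified": 100.0 * c / n_cls if n_cls else np.nan,
                "pct_of_classified_rounded": round(100.0 * c / n_cls) if n_cls else np.nan,
                "pct_of_all_regions": 100.0 * c / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def depth_analysis_from_tables(
    tables: dict[str, ShelfCellTable],
    classifier: ClassifierConfig | None = None,
    z_list: tuple[float, ...] = DEFAULT_Z_LIST,
    band_width: float = 15.0,
) -> RunReport:
    """Depth pipeline over prebuilt per-region cell tables."""
    if not tables:
        raise ValueError("no regions to analyze")
    classifier = classifier or ClassifierConfig()
    report = RunReport()
    records = []
    for name, cells in tables.items():
        if len(cells) == 0:
            logger.warning("region %r has no shelf cells; unclassifiable", name)
            report.unclassifiable.append(name)
            continue
        curve = hypsometric_curve(cells, bin_width=1.0)
        bands = depth_band_areas(cells, band_width=band_width)
        result = classify_depth_distribution(cells, classifier)
        report.curves[name] = curve
        report.bands[name] = bands
        report.mean_depths[name] = mean_depth(cells)
        report.depth_projections[name] = project_multi_z(
            project_depth_shift, bands, z_list
        )
        records.append(result.as_record())
    if not records:
        raise ValueError("no region produced any shelf cells")
    report.classifications = pd.DataFrame(records)
    report.category_shares = _category_shares(
        report.classifications, n_total=len(tables)
    )
    return report


def latitude_analysis_from_tables(
    coastline_tables: dict[str, ShelfCellTable],
    z_list: tuple[float, ...] = DEFAULT_Z_LIST,
) -> RunReport:
    """Latitude pipeline over prebuilt per-coastline cell tables.

    Each coastline is split at the equator and each hemisphere analyzed
    equator → pole. A coastline failing a precondition (e.g. a single bin)
    is reported in ``coastline_errors``, not fatal.
    """
    if not coastline_tables:
        raise ValueError("no coastlines to analyze")
    report = RunReport()
    rows = []
    for coast, cells in coastline_tables.items():
        if len(cells) == 0:
            report.coastline_errors[coast] = "no shelf cells"
            continue
        lat = cells.df["lat"].to_numpy()
        hemis = [h for h, sel in (("N", lat >= 0), ("S", lat < 0)) if sel.any()]
        for hemi in hemis:
            key = f"{coast}-{hemi}"
            try:
                series = latitude_bin_areas(
                    cells, hemisphere=hemi, coastline=coast
                )
                trans = poleward_transitions(series)
                pct_con, pct_exp = transition_summary(trans)
                trend = coastline_trend(series)
            except (ValueError, KeyError) as exc:
                report.coastline_errors[key] = str(exc)
                continue
            report.latitude_series[key] = series
            report.transitions[key] = trans
            report.latitude_projections[key] = project_multi_z(
                project_latitude_shift, series, z_list
            )
            rows.append(
                {
                    "coastline": coast,
                    "hemisphere": hemi,
                    "pct_contractions": pct_con,
                    "pct_expansions": pct_exp,
                    "coefficient_km2_per_deg": trend.slope,
                    "p_value": trend.p_value,
                    "n_bins": trend.n_bins,
                }
            )
    report.latitude_summary = pd.DataFrame(rows)
    return report


def _load_tables(config: RunConfig) -> dict[str, ShelfCellTable]:
    grid = load_bathymetry(config.bathymetry)
    shelf = RegionMask.from_geojson(config.shelf, name="shelf") if config.shelf else None
    regions = [
        RegionMask.from_geojson(path, name=name)
        for name, path in config.regions.items()
        if name not in config.exclude
    ]
    if not regions:
        raise ValueError("no regions left after exclusions")
    return mask_cells(grid, regions, shelf=shelf, depth_max=config.depth_max)


def run_depth_analysis(config: RunConfig) -> RunReport:
    """Load inputs per config and run the full depth pipeline."""
    tables = _load_tables(config)
    classifier = config.classifier
    if classifier.seed != config.seed:
        from dataclasses import replace

        classifier = replace(classifier, seed=config.seed)
    report = depth_analysis_from_tables(
        tables,
        classifier=classifier,
        z_list=config.z_list,
        band_width=config.band_width,
    )
    report.provenance = _provenance(config)
    return report


def run_latitude_analysis(config: RunConfig) -> RunReport:
    """Load inputs per config and run the full latitude pipeline."""
    if not config.coastlines:
        raise ValueError("config defines no coastlines")
    tables = _load_tables(config)
    coastline_tables: dict[str, ShelfCellTable] = {}
    for coast, names in config.coastlines.items():
        missing = [n for n in names if n not in tables]
        if missing:
            raise KeyError(f"coastline {coast!r} references unknown regions {missing}")
        df = pd.concat([tables[n].df for n in names], ignore_index=True)
        df = df.drop_duplicates(subset=["lat", "lon"]).reset_index(drop=True)
        coastline_tables[coast] = ShelfCellTable(
            df=df, region=coast, depth_max=config.depth_max
        )
    report = latitude_analysis_from_tables(coastline_tables, z_list=config.z_list)
    report.provenance = _provenance(config)
    return report


def _provenance(config: RunConfig) -> dict:
    return {
        "shelfhypso_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
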