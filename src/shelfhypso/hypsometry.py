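"""Area-at-depth summaries of a shelf cell table.

Hypsometric curves accumulate geodesic cell area into depth bins
(default 1 m), the marine analogue of terrestrial area-elevation curves.
Coarser 15 m bands represent depth-assemblage habitat slices used for
range-shift projections.

Binning convention: bins are half-open ``[lower, lower + width)``; the final
bin is closed at ``depth_max`` so a cell exactly at the cutoff is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EmptyTableError, ShelfCellTable

DEFAULT_BAND_WIDTH = 15.0  # m; approximate expected depth shift over four decades


@dataclass
class HypsometricCurve:
    """Area (km²) per depth bin for one region."""

    df: pd.DataFrame  # columns: depth_lower_m, area_km2
    bin_width: float
    region: str = ""

    @property
    def depth_lower(self) -> np.ndarray:
        return self.df["depth_lower_m"].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.df["area_km2"].to_numpy()

    def total_area(self) -> float:
        return float(self.df["area_km2"].sum())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bin_width=None, region="") -> "HypsometricCurve":
        df = pd.read_csv(path)
        if bin_width is None:
            bin_width = float(df["depth_lower_m"].diff().iloc[1])
        return cls(df=df, bin_width=bin_width, region=region)


# A 15 m band series is structurally a curve with coarser bins.
DepthBandSeries = HypsometricCurve


def _binned_areas(cells: ShelfCellTable, bin_width: float) -> pd.DataFrame:
    if len(cells) == 0:
        raise EmptyTableError(
            f"region {cells.region!r} has no shelf cells; cannot bin depths"
        )
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nbins = int(np.ceil(cells.depth_max / bin_width - 1e-12))
    edges = np.arange(nbins + 1) * bin_width
    edges[-1] = max(edges[-1], cells.depth_max)  # close the last bin at depth_max
    areas, _ = np.histogram(cells.depths, bins=edges, weights=cells.areas)
    return pd.DataFrame({"depth_lower_m": edges[:-1], "area_km2": areas})


def hypsometric_curve(cells: ShelfCellTable, bin_width: float = 1.0) -> HypsometricCurve:
    """Accumulate cell areas into half-open depth bins of ``bin_width`` meters."""
    return HypsometricCurve(
        df=_binned_areas(cells, bin_width), bin_width=bin_width, region=cells.region
    )


def depth_band_areas(
    cells: ShelfCellTable, band_width: float = DEFAULT_BAND_WIDTH
) -> DepthBandSeries:
    """Hypsometric areas in coarse depth bands (default 15 m), tiling from 0 m."""
    return hypsometric_curve(cells, bin_width=band_width)


def mean_depth(cells: ShelfCellTable) -> float:
    """Area-weighted arithmetic mean depth (m) of the table."""
    if len(cells) == 0:
        raise EmptyTableError(
            f"region {cells.region!r} has no shelf cells; mean depth undefined"
        )
    return float(np.average(cells.depths, weights=cells.areas))


def band_transition_deltas(series: DepthBandSeries) -> pd.DataFrame:
    """Area change between each depth band and the next deeper band.

    Returns one record per adjacent pair ordered shallow → deep with columns
    ``depth_lower_m``, ``delta_km2`` (A_next − A_current) and ``ratio``
    (A_next / A_current, NaN and flagged ``undefined`` when A_current is 0).
    """
    a = series.areas
    if len(a) < 2:
        raise ValueError("need at least two depth bands to form transitions")
    cur, nxt = a[:-1], a[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cur > 0, nxt / np.where(cur > 0, cur, 1.0), np.nan)
    return pd.DataFrame(
        {
            "depth_lower_m": series.depth_lower[:-1],
            "delta_km2": nxt - cur,
            "ratio": ratio,
            "undefined": cur == 0,
        }
    )
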