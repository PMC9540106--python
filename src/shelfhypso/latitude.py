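"""Shelf area per 2° latitude bin, poleward expansion/contraction flags,
and the area-versus-latitude trend.

Bins are aligned to even-integer latitudes and half-open on the signed
latitude (a cell at exactly 2.0° falls in [2, 4); a cell at −2.0° in
[−2, 0)). The equator bin [0, 2) belongs to the Northern hemisphere.
Transitions run equator → pole; a poleward step that at least doubles the
area is an *expansion*, one that at least halves it a *contraction* —
thresholds motivated by the IUCN criterion that a 50% habitat loss marks a
species Vulnerable. The trend is an ordinary least-squares fit of bin area
on absolute mid-latitude, so a positive slope means area gain poleward in
either hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EmptyTableError, ShelfCellTable


@dataclass
class LatitudeBinSeries:
    """Shelf area per 2° bin for one coastline-hemisphere, equator → pole."""

    df: pd.DataFrame  # columns: lat_lower, lat_mid, area_km2
    coastline: str = ""
    hemisphere: str = "N"  # "N" | "S"

    @property
    def areas(self) -> np.ndarray:
        return self.df["area_km2"].to_numpy()

    @property
    def lat_mid(self) -> np.ndarray:
        return self.df["lat_mid"].to_numpy()

    def total_area(self) -> float:
        return float(self.df["area_km2"].sum())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class TrendFit:
    """OLS fit of bin area against absolute mid-latitude."""

    slope: float  # km² per 1° latitude
    intercept: float  # km²
    p_value: float
    n_bins: int
    stderr: float = float("nan")


def latitude_bin_areas(
    cells: ShelfCellTable,
    width: float = 2.0,
    hemisphere: str | None = None,
    coastline: str = "",
) -> LatitudeBinSeries:
    """Accumulate cell areas into half-open 2° latitude bins.

    ``hemisphere`` selects "N" (lat ≥ 0) or "S" (lat < 0) cells; it may be
    omitted when the table lies in a single hemisphere. Empty interior bins
    are emitted with zero area.
    """
    if len(cells) == 0:
        raise EmptyTableError(f"region {cells.region!r} has no shelf cells")
    if width <= 0:
        raise ValueError("bin width must be positive")
    lat = cells.df["lat"].to_numpy()
    north = lat >= 0
    if hemisphere is None:
        if north.all():
            hemisphere = "N"
        elif (~north).all():
            hemisphere = "S"
        else:
            raise ValueError(
                "table spans both hemispheres; pass hemisphere='N' or 'S'"
            )
    hemisphere = hemisphere.upper()
    if hemisphere not in ("N", "S"):
        raise ValueError("hemisphere must be 'N' or 'S'")
    sel = north if hemisphere == "N" else ~north
    if not sel.any():
        raise EmptyTableError(f"no cells in hemisphere {hemisphere!r}")
    lat = lat[sel]
    area = cells.areas[sel]
    lower = np.floor(lat / width) * width  # half-open on signed latitude
    if hemisphere == "N":
        abs_lower = lower
    else:
        abs_lower = -lower - width  # [−2, 0) has |equatorward edge| 0
    kmax = int(abs_lower.max() / width)
    abs_lowers = np.arange(kmax + 1) * width  # equator → pole, with gaps
    sums = pd.Series(area).groupby(abs_lower).sum()
    areas = np.array([sums.get(al, 0.0) for al in abs_lowers])
    if hemisphere == "N":
        lat_lower = abs_lowers
        lat_mid = abs_lowers + width / 2
    else:
        lat_lower = -abs_lowers - width
        lat_mid = lat_lower + width / 2
    df = pd.DataFrame({"lat_lower": lat_lower, "lat_mid": lat_mid, "area_km2": areas})
    return LatitudeBinSeries(df=df, coastline=coastline, hemisphere=hemisphere)


def poleward_transitions(series: LatitudeBinSeries) -> pd.DataFrame:
    """Percent area change and expansion/contraction flag for each poleward step.

    Returns columns ``from_lat_lower``, ``to_lat_lower``, ``pct_change`` and
    ``flag`` (expansion | contraction | none | undefined). A transition out of
    a zero-area bin is undefined.
    """
    a = series.areas
    if len(a) < 2:
        raise ValueError("need at least two latitude bins to form transitions")
    src, dst = a[:-1], a[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(src > 0, (dst - src) / np.where(src > 0, src, 1.0) * 100.0, np.nan)
        ratio = np.where(src > 0, dst / np.where(src > 0, src, 1.0), np.nan)
    flag = np.full(len(src), "none", dtype=object)
    flag[ratio >= 2.0] = "expansion"
    flag[ratio <= 0.5] = "contraction"
    flag[src == 0] = "undefined"
    ll = series.df["lat_lower"].to_numpy()
    return pd.DataFrame(
        {
            "from_lat_lower": ll[:-1],
            "to_lat_lower": ll[1:],
            "pct_change": pct,
            "flag": flag,
        }
    )


def transition_summary(transitions: pd.DataFrame) -> tuple[float, float]:
    """Shares (%) of defined poleward transitions that contract / expand."""
    defined = transitions[transitions["flag"] != "undefined"]
    if defined.empty:
        raise ValueError("all transitions are undefined; no summary possible")
    n = len(defined)
    pct_con = 100.0 * (defined["flag"] == "contraction").sum() / n
    pct_exp = 100.0 * (defined["flag"] == "expansion").sum() / n
    return float(pct_con), float(pct_exp)


def coastline_trend(series: LatitudeBinSeries) -> TrendFit:
    """OLS of bin area on absolute mid-latitude (km² per degree)."""
    x = np.abs(series.lat_mid)
    y = series.areas
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 bins with finite area for a trend fit")
    if np.ptp(y) == 0:
        return TrendFit(slope=0.0, intercept=float(y[0]), p_value=1.0,
                        n_bins=len(y), stderr=0.0)
    res = stats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n_bins=len(y),
        stderr=float(res.stderr),
    )
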