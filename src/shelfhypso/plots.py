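"""Minimal diagnostic plots for curves and latitude profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .hypsometry import HypsometricCurve
from .latitude import LatitudeBinSeries


def plot_hypsometric_curve(curve: HypsometricCurve, mean_depth_m=None, ax=None):
    """Area against depth; optional dashed line at the mean depth."""
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve.depth_lower, curve.areas, step="post", alpha=0.6)
    if mean_depth_m is not None:
        ax.axvline(mean_depth_m, color="red", linestyle="--", label="mean depth")
        ax.legend()
    ax.set_xlabel("depth (m)")
    ax.set_ylabel(f"area (km² per {curve.bin_width:g} m bin)")
    ax.set_title(curve.region or "hypsometric curve")
    return ax


def plot_latitude_profile(series: LatitudeBinSeries, transitions=None, ax=None):
    """Shelf area per 2° bin; expansions/contractions highlighted."""
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(series.lat_mid, series.areas / 1e3, width=1.8, color="lightgray")
    if transitions is not None:
        colors = {"expansion": "tab:orange", "contraction": "tab:purple"}
        for _, row in transitions.iterrows():
            c = colors.get(row["flag"])
            if c:
                ax.axvline(row["to_lat_lower"], color=c, alpha=0.8)
    ax.set_xlabel("latitude (°)")
    ax.set_ylabel("shelf area (1000 km² per 2° bin)")
    ax.set_title(f"{series.coastline} ({series.hemisphere})")
    return ax
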