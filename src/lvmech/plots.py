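"""Report figures: AHA bulls-eye maps, dendrogram-heatmap, KM and forest plots.

All functions return a matplotlib Figure and optionally save PNG+SVG next to
each other; layouts are deterministic (no randomized placement).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm, colors
from matplotlib.patches import Wedge
from scipy.cluster.hierarchy import dendrogram

from .cohort import SEGMENTS_BY_SLICE

__all__ = ["bullseye_render", "dendrogram_heatmap", "km_plot", "forest_plot",
           "save_figure"]

# ring radii (inner, outer) per slice level, apical innermost
_RINGS = {"apical": (0.28, 0.52), "mid": (0.52, 0.76), "basal": (0.76, 1.0)}


def save_figure(fig: plt.Figure, path: str | Path) -> None:
    """Save as both PNG and SVG (path given without extension)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(p.with_suffix(".png"), dpi=150, bbox_inches="tight")
    fig.savefig(p.with_suffix(".svg"), bbox_inches="tight")


def bullseye_render(values: dict[str, float], title: str = "",
                    cmap: str = "RdYlBu_r", vmin: float | None = None,
                    vmax: float | None = None, fmt: str = "{:.0f}",
                    out: str | Path | None = None) -> plt.Figure:
    """16-segment AHA bulls-eye plot (6 basal outer, 6 mid, 4 apical inner).

    ``values`` maps feature-style keys (e.g. ``peakRS_mid_anteroseptal`` or
    ``mid_anteroseptal``) to numbers; missing segments are hatched.  Segment
    boundaries start at the anterior position (12 o'clock) and proceed
    counterclockwise, matching the segment-map convention.
    """
    def lookup(slice_level: str, seg: str) -> float:
        for key in (f"peakRS_{slice_level}_{seg}", f"{slice_level}_{seg}"):
            if key in values:
                return values[key]
        return np.nan

    vals = {(sl, seg): lookup(sl, seg)
            for sl in _RINGS for seg in SEGMENTS_BY_SLICE[sl]}
    finite = [v for v in vals.values() if np.isfinite(v)]
    if vmin is None:
        vmin = min(finite) if finite else 0.0
    if vmax is None:
        vmax = max(finite) if finite else 1.0
    if vmax == vmin:
        vmax = vmin + 1.0
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    cmap_obj = plt.get_cmap(cmap)

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_aspect("equal")
    ax.axis("off")
    for sl, (r_in, r_out) in _RINGS.items():
        segs = SEGMENTS_BY_SLICE[sl]
        n = len(segs)
        width_deg = 360.0 / n
        for i, seg in enumerate(segs):
            # anterior boundary at 90 deg, counterclockwise
            th1 = 90.0 + i * width_deg
            th2 = th1 + width_deg
            v = vals[(sl, seg)]
            if np.isfinite(v):
                face = cmap_obj(norm(v))
                hatch = None
            else:
                face = "0.85"
                hatch = "///"
            ax.add_patch(Wedge((0, 0), r_out, th1, th2, width=r_out - r_in,
                               facecolor=face, edgecolor="k", hatch=hatch))
            mid_th = np.deg2rad((th1 + th2) / 2.0)
            r_mid = (r_in + r_out) / 2.0
            if np.isfinite(v):
                ax.text(r_mid * np.cos(mid_th), r_mid * np.sin(mid_th),
                        fmt.format(v), ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_title(title)
    sm = cm.ScalarMappable(norm=norm, cmap=cmap_obj)
    fig.colorbar(sm, ax=ax, fraction=0.046, pad=0.04)
    if out is not None:
        save_figure(fig, out)
    return fig


def dendrogram_heatmap(linkage_matrix: np.ndarray, z: pd.DataFrame,
                       labels: np.ndarray | None = None,
                       out: str | Path | None = None) -> plt.Figure:
    """Ward dendrogram over a heatmap of the standardized feature matrix."""
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(max(8, len(z) * 0.06), 9),
        gridspec_kw={"height_ratios": [1, 2.5], "hspace": 0.05})
    dres = dendrogram(linkage_matrix, ax=ax_d, no_labels=True,
                      color_threshold=None)
    ax_d.set_yticks([])
    order = dres["leaves"]
    mat = z.to_numpy()[order].T
    lim = np.nanmax(np.abs(mat)) or 1.0
    ax_h.imshow(mat, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim,
                interpolation="nearest")
    ax_h.set_yticks(range(len(z.columns)))
    ax_h.set_yticklabels(z.columns, fontsize=6)
    ax_h.set_xticks([])
    if labels is not None:
        for x, lab in enumerate(np.asarray(labels)[order]):
            ax_h.text(x, -1.0, str(lab), ha="center", va="bottom", fontsize=4)
    if out is not None:
        save_figure(fig, out)
    return fig


def km_plot(records: pd.DataFrame, label_col: str = "cluster",
            duration_col: str = "time_months", event_col: str = "event",
            out: str | Path | None = None) -> plt.Figure:
    """Kaplan-Meier curves per cluster."""
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(7, 5))
    for lab, sub in records.groupby(label_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=f"{label_col} {lab}")
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time since CMR (months)")
    ax.set_ylabel("PVR-free survival")
    ax.set_ylim(0, 1.02)
    if out is not None:
        save_figure(fig, out)
    return fig


def forest_plot(forest: pd.DataFrame, out: str | Path | None = None) -> plt.Figure:
    """Hazard-ratio forest plot from a ``forest_table`` frame (HR descending)."""
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(forest) + 1.5))
    y = np.arange(len(forest))[::-1]
    ax.errorbar(forest["hazard_ratio"], y,
                xerr=[forest["hazard_ratio"] - forest["ci_lower"],
                      forest["ci_upper"] - forest["hazard_ratio"]],
                fmt="s", color="k", capsize=3)
    ax.axvline(1.0, color="0.5", ls="--", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(forest["covariate"])
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (95% CI)")
    if out is not None:
        save_figure(fig, out)
    return fig
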