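"""Figure helpers: stacked occupancy curves, top-view floor-gaze and path
scatter, and per-configuration floor-looking bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .floormap import STACK_ORDER
from .geometry import RoomLayout

__all__ = ["plot_occupancy", "plot_floor_gaze", "plot_floor_fraction_bars"]

_CAT_COLORS = {
    "turquoise": "#40e0d0", "yellow": "#ebdc1e", "red": "#dc1e1e",
    "blue": "#1e3cdc", "purple": "#8c28a0", "cups_on_table": "#90ee90",
    "table": "#606060", "floor": "#c8c8c8", "elsewhere": "#f5deb3",
    "blink": "#1e5c1e", "none": "#ffffff",
}


def plot_occupancy(occupancy: pd.DataFrame, path: str | None = None):
    """Stacked-area plot of category fractions against distance to the
    target cup (walker approaches right to left)."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = (occupancy.bin_lo_cm + occupancy.bin_hi_cm) / 2.0
    ys = [occupancy[c].fillna(0).to_numpy() for c in STACK_ORDER]
    ax.stackplot(x, ys, labels=STACK_ORDER,
                 colors=[_CAT_COLORS[c] for c in STACK_ORDER])
    ax.set_xlim(x.max(), x.min())
    ax.set_ylim(0, 1)
    ax.set_xlabel("distance from target cup (cm)")
    ax.set_ylabel("fraction of time")
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_floor_gaze(points: pd.DataFrame, tracks: list[pd.DataFrame] | None = None,
                    layout: RoomLayout = RoomLayout(),
                    floor_cups_xy: dict[str, tuple[float, float]] | None = None,
                    path: str | None = None):
    """Top view of the room with floor-gaze points and optional walking
    paths (door at the bottom, table at the top)."""
    fig, ax = plt.subplots(figsize=(4.5, 6))
    hw = layout.room_width / 2
    ax.add_patch(plt.Rectangle((-hw, 0), layout.room_width, layout.door_to_table + 60,
                               fill=False, lw=1))
    ax.add_patch(plt.Rectangle((-layout.table_width / 2, layout.door_to_table),
                               layout.table_width, layout.table_depth,
                               color="#d0c8b8"))
    if floor_cups_xy:
        for cid, (cx, cy) in floor_cups_xy.items():
            ax.add_patch(plt.Circle((cx, cy), 4.5, color=_CAT_COLORS[cid]))
    if tracks:
        for tr in tracks:
            ok = np.isfinite(tr.x_s_cm) & np.isfinite(tr.y_s_cm)
            ax.plot(tr.x_s_cm[ok], tr.y_s_cm[ok], color="0.6", lw=0.6, alpha=0.6)
    if len(points):
        ax.scatter(points.x_cm, points.y_cm, s=4, c="#3060c0", alpha=0.5, lw=0)
    ax.set_xlim(-hw - 20, hw + 20)
    ax.set_ylim(-120, layout.door_to_table + layout.table_depth + 20)
    ax.set_aspect("equal")
    ax.set_xlabel("lateral position (cm)")
    ax.set_ylabel("depth from door (cm)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_floor_fraction_bars(cell_table: pd.DataFrame, path: str | None = None):
    """Per-configuration mean floor-looking fraction with 95% confidence
    intervals across participants."""
    from .design import FACTORS

    g = cell_table.groupby(list(FACTORS)).fraction
    mean = g.mean()
    sem = g.sem()
    n = cell_table.participant.nunique()
    from scipy import stats as sstats
    ci = sem * sstats.t.isf(0.025, n - 1)

    fig, ax = plt.subplots(figsize=(9, 4))
    xs = np.arange(len(mean))
    ax.bar(xs, mean.to_numpy(), yerr=ci.to_numpy(), capsize=2, color="#b0b0b0")
    labels = ["".join(s[0].upper() for s in idx) for idx in mean.index]
    ax.set_xticks(xs, labels, rotation=90, fontsize=7)
    ax.set_ylabel("fraction of time on floor")
    ax.set_xlabel("configuration (near/far/table-obstacle/destination sides)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
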