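"""Plotting helpers mirroring the standard figures of this assay.

All functions take a matplotlib Axes (or create one) and return it, so
they compose into multi-panel figures.
"""

from __future__ import annotations

import math

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["speed_histogram", "arc_fan", "class_bars", "track_overlay"]


def speed_histogram(speeds_nm_s, ax=None, bins=26, range_nm_s=(0, 260), **kwargs):
    """Distribution of per-step projected speeds with band edges marked."""
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(speeds_nm_s, bins=bins, range=range_nm_s, density=True, **kwargs)
    for edge in (40, 160):
        ax.axvline(edge, color="gray", ls=":", lw=0.8)
    ax.set_xlabel("projected speed (nm/s)")
    ax.set_ylabel("density")
    return ax


def arc_fan(arc_results, ax=None):
    """Fan plot of arc angles β on the projected-nucleus circle.

    Dashed arcs mark chords longer than the nominal radius.
    """
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"aspect": "equal"})
    for k, arc in enumerate(arc_results):
        beta = math.radians(arc.beta_deg)
        theta = np.linspace(math.pi / 2 - beta / 2, math.pi / 2 + beta / 2, 64)
        r = 1.0 + 0.04 * k
        ax.plot(r * np.cos(theta), r * np.sin(theta), ls="--" if arc.dashed else "-")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="gray", lw=0.8)
    ax.add_patch(circle)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.8, 1.8)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def class_bars(class_table, ax=None, which="events"):
    """Bar chart of binned event-count or dwell classes."""
    if ax is None:
        _, ax = plt.subplots()
    data = (
        class_table.event_count_classes if which == "events" else class_table.dwell_classes
    )
    ax.bar(list(data.keys()), list(data.values()))
    ax.set_ylabel("nuclei" if which == "events" else "coalescences")
    ax.tick_params(axis="x", rotation=45)
    return ax


def track_overlay(tracks_df, ax=None, geometry=None):
    """Displacement tracks, one color per identity, over the nucleus circle."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"aspect": "equal"})
    for _, g in tracks_df.groupby("track_id"):
        g = g.sort_values("frame")
        ax.plot(g["x_um"], g["y_um"], lw=0.8)
    if geometry is not None:
        circle = plt.Circle(geometry.center, geometry.radius_um, fill=False, color="gray", lw=0.8)
        ax.add_patch(circle)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    return ax
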