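"""Fusion/splitting event statistics and coalescence dwell times.

Aggregates transiently coalesce: a fusion reduces the number of visible
aggregates by one, the subsequent splitting restores it.  Events are
counted either directly from a merge/split log (preferred) or from the
aggregate-count time series (each decrement of k counts k fusions, each
increment k splits).  The dwell between a fusion and the next splitting
of that aggregate is the *coalescence time*, binned into the standard
classes t<1 min, 1 min≤t<3 min, t≥3 min; per-nucleus event totals are
binned into classes 0, 1–5, …, 21–25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plaquedyn.tracking import CountSeries

__all__ = [
    "EventLog",
    "ClassTable",
    "count_events",
    "coalescence_times",
    "bin_classes",
    "EVENT_COUNT_BINS",
    "DWELL_BIN_EDGES_S",
]

#: Per-nucleus event-count classes (inclusive ranges); totals above 25 go
#: to an overflow bin with a warning.
EVENT_COUNT_BINS: tuple[tuple[int, int], ...] = (
    (0, 0),
    (1, 5),
    (6, 10),
    (11, 15),
    (16, 20),
    (21, 25),
)

#: Coalescence-dwell class edges in seconds: [0, 60), [60, 180), [180, ∞).
DWELL_BIN_EDGES_S = (60.0, 180.0)

DWELL_CLASS_LABELS = ("t<1min", "1min<=t<3min", "t>=3min")


@dataclass
class EventLog:
    """Fusion/splitting events and coalescence dwells of one nucleus."""

    events: pd.DataFrame  # columns frame, t_s, kind, parent_id, child_id
    coalescences: pd.DataFrame  # columns t_fusion_s, duration_s, censored, dwell_class
    window_s: float = 900.0


@dataclass
class ClassTable:
    """Binned per-nucleus event counts and dwell classes."""

    event_count_classes: dict[str, int]
    dwell_classes: dict[str, int]

    def event_class_vector(self) -> list[int]:
        return list(self.event_count_classes.values())

    def dwell_class_vector(self) -> list[int]:
        return list(self.dwell_classes.values())


def count_events(
    data: pd.DataFrame | CountSeries,
    window_s: float = 900.0,
) -> tuple[int, int]:
    """Count (fusions, splits) within the analysis window.

    From an event log (DataFrame with columns t_s and kind) the counts
    are direct.  From a :class:`CountSeries` alone, each decrement of k
    in the aggregate number counts as k fusions and each increment of k
    as k splits.
    """
    if isinstance(data, pd.DataFrame):
        if len(data) == 0:
            return 0, 0
        sel = data[data["t_s"] <= window_s]
        n_fus = int((sel["kind"] == "fusion").sum())
        n_spl = int((sel["kind"] == "splitting").sum())
        return n_fus, n_spl
    if isinstance(data, CountSeries):
        if len(data.n) == 0:
            raise ValueError("empty count series")
        mask = data.t_s <= window_s
        n = data.n[mask]
        dn = np.diff(n)
        n_fus = int(-dn[dn < 0].sum())
        n_spl = int(dn[dn > 0].sum())
        return n_fus, n_spl
    raise TypeError("expected an event-log DataFrame or a CountSeries")


def dwell_class(duration_s: float) -> str:
    """Coalescence-time class of one dwell (half-open bins at 60 s, 180 s)."""
    lo, hi = DWELL_BIN_EDGES_S
    if duration_s < lo:
        return DWELL_CLASS_LABELS[0]
    if duration_s < hi:
        return DWELL_CLASS_LABELS[1]
    return DWELL_CLASS_LABELS[2]


def coalescence_times(
    events: pd.DataFrame,
    recording_end_s: float,
    include_censored: bool = False,
) -> pd.DataFrame:
    """Dwell durations between each fusion and the next splitting.

    For every fusion of identity ``p`` at time ``t0``, the dwell ends at
    the next splitting event whose parent is ``p`` after ``t0``.  Dwells
    truncated by the end of the recording are flagged ``censored`` and
    excluded unless ``include_censored``.

    Returns a table with columns t_fusion_s, duration_s, censored,
    dwell_class.
    """
    required = {"t_s", "kind", "parent_id"}
    if not required.issubset(events.columns):
        raise ValueError(
            "event log must have columns t_s, kind, parent_id; for logs "
            "without lineage use count-based interval approximation "
            "(count_events on the CountSeries)"
        )
    rows = []
    splits = events[events["kind"] == "splitting"]
    for _, fus in events[events["kind"] == "fusion"].iterrows():
        t0 = float(fus["t_s"])
        later = splits[(splits["parent_id"] == fus["parent_id"]) & (splits["t_s"] > t0)]
        if len(later):
            t1 = float(later["t_s"].min())
            dur = t1 - t0
            rows.append((t0, dur, False, dwell_class(dur)))
        else:
            dur = recording_end_s - t0
            rows.append((t0, dur, True, dwell_class(dur)))
    df = pd.DataFrame(rows, columns=["t_fusion_s", "duration_s", "censored", "dwell_class"])
    if not include_censored:
        df = df[~df["censored"]].reset_index(drop=True)
    return df


def bin_classes(
    per_nucleus_totals: list[int] | np.ndarray,
    dwell_durations_s: list[float] | np.ndarray = (),
) -> ClassTable:
    """Bin per-nucleus event totals and dwell durations into class tables."""
    totals = np.asarray(per_nucleus_totals, dtype=int)
    if (totals < 0).any():
        raise ValueError("event totals must be >= 0")
    counts: dict[str, int] = {}
    for lo, hi in EVENT_COUNT_BINS:
        label = "0" if lo == hi == 0 else f"{lo}-{hi}"
        counts[label] = int(((totals >= lo) & (totals <= hi)).sum())
    overflow = int((totals > EVENT_COUNT_BINS[-1][1]).sum())
    if overflow:
        warnings.warn(
            f"{overflow} nuclei exceed {EVENT_COUNT_BINS[-1][1]} events; "
            "reported in the '>25' overflow bin",
            stacklevel=2,
        )
        counts[">25"] = overflow
    dwells = np.asarray(dwell_durations_s, dtype=float)
    dwell_counts = {label: 0 for label in DWELL_CLASS_LABELS}
    for d in dwells:
        dwell_counts[dwell_class(float(d))] += 1
    return ClassTable(event_count_classes=counts, dwell_classes=dwell_counts)
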