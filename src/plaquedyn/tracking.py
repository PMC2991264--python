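"""Frame-to-frame linking of detections with merge/split lineage.

Automates the manual tracking conventions of the original analysis: an
optimal minimum-total-distance assignment within a distance gate; when
two tracks converge on one detection the event is a *fusion* and the
identity of the larger-area track continues; when one track splits into
two detections the larger fragment keeps the identity and the smaller
starts a new track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from plaquedyn.synthetic import ConfigurationError

__all__ = [
    "Track",
    "CountSeries",
    "link_detections",
    "count_series",
    "nucleus_summary",
    "tracks_to_dataframe",
]

#: Default linking gate, µm per frame.  At a 5 s frame interval this is
#: ≈300 nm/s, just above the fastest observed aggregate speeds (~260 nm/s).
DEFAULT_GATE_UM = 1.5


@dataclass
class Track:
    """One aggregate identity across frames.

    ``samples`` rows are (frame, t_s, x_um, y_um, area_um2); lineage is
    recorded via ``parent_id`` (the track this one split from, if any).
    """

    track_id: int
    samples: list[tuple[int, float, float, float, float]] = field(default_factory=list)
    parent_id: int | None = None

    @property
    def start_frame(self) -> int:
        return self.samples[0][0]

    @property
    def end_frame(self) -> int:
        return self.samples[-1][0]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class CountSeries:
    """Number of aggregates alive per frame."""

    t_s: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if len(self.t_s) != len(self.n):
            raise ValueError("t_s and n must have equal length")
        if (self.n < 0).any():
            raise ValueError("counts must be >= 0")


def _frames_dict(detections: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {int(f): g.reset_index(drop=True) for f, g in detections.groupby("frame")}


def link_detections(
    detections: pd.DataFrame,
    gate_um: float = DEFAULT_GATE_UM,
    frame_interval_s: float = 5.0,
) -> tuple[list[Track], pd.DataFrame]:
    """Link per-frame detections into tracks with merge/split lineage.

    Parameters
    ----------
    detections:
        Table with columns frame, x_um, y_um and optionally area_um2.
    gate_um:
        Maximum frame-to-frame displacement for a link.
    frame_interval_s:
        Frame interval used to stamp sample times.

    Returns
    -------
    (tracks, events):
        ``tracks`` is a list of :class:`Track`; ``events`` is a table
        with columns frame, t_s, kind ('fusion'|'splitting'), parent_id,
        child_id.  At a fusion, ``parent_id`` is the surviving identity
        and ``child_id`` the absorbed one; at a splitting, ``parent_id``
        continues on the larger fragment and ``child_id`` is the new
        track started by the smaller one.

    Assignment minimizes the total frame-to-frame displacement over all
    in-gate (track, detection) pairs (Hungarian algorithm); distance
    ties are broken by smaller area difference, making the result
    independent of detection order within a frame.
    """
    if gate_um <= 0:
        raise ConfigurationError("gate_um must be > 0")
    det = detections.copy()
    if "area_um2" not in det:
        det["area_um2"] = 1.0
    frames = _frames_dict(det)
    if not frames:
        return [], _empty_events()

    tracks: list[Track] = []
    events: list[tuple] = []
    active: dict[int, Track] = {}  # track_id -> Track, alive last frame
    next_id = 0

    first_frame = min(frames)
    last_frame = max(frames)
    for frame in range(first_frame, last_frame + 1):
        t_s = frame * frame_interval_s
        dets = frames.get(frame)
        if dets is None or len(dets) == 0:
            active = {}
            continue
        n_det = len(dets)
        det_xy = dets[["x_um", "y_um"]].to_numpy()
        det_area = dets["area_um2"].to_numpy()

        track_ids = sorted(active)
        assignment: dict[int, int] = {}  # det index -> track_id
        assigned_tracks: set[int] = set()
        if track_ids:
            trk_xy = np.array([[active[i].samples[-1][2], active[i].samples[-1][3]] for i in track_ids])
            trk_area = np.array([active[i].samples[-1][4] for i in track_ids])
            dist = np.linalg.norm(trk_xy[:, None, :] - det_xy[None, :, :], axis=-1)
            # optimal (minimum-total-distance) assignment within the gate;
            # a tiny area-difference term breaks distance ties deterministically
            big = 1e6
            cost = np.where(dist <= gate_um, dist, big)
            cost = cost + 1e-9 * np.abs(trk_area[:, None] - det_area[None, :])
            row_ind, col_ind = linear_sum_assignment(cost)
            for ti, di in zip(row_ind, col_ind):
                if dist[ti, di] <= gate_um:
                    assignment[int(di)] = track_ids[ti]
                    assigned_tracks.add(track_ids[ti])

            # merges: an unassigned track whose nearest in-gate detection is
            # already claimed by another track is absorbed by it
            for ti, tid in enumerate(track_ids):
                if tid in assigned_tracks:
                    continue
                in_gate = np.where(dist[ti] <= gate_um)[0]
                if len(in_gate) == 0:
                    continue  # track terminates
                di = int(in_gate[np.argmin(dist[ti, in_gate])])
                holder = assignment.get(di)
                if holder is None:
                    continue
                merging = active[tid]
                current = active[holder]
                # identity of the larger-area track continues
                if merging.samples[-1][4] > current.samples[-1][4] or (
                    merging.samples[-1][4] == current.samples[-1][4] and tid < holder
                ):
                    assignment[di] = tid
                    assigned_tracks.add(tid)
                    parent, child = tid, holder
                else:
                    parent, child = holder, tid
                    assigned_tracks.add(tid)
                events.append((frame, t_s, "fusion", parent, child))

        # splits: an unassigned detection near a track that already received
        # a detection this frame starts a child track of it.  Candidate
        # order is canonical (by position) so results do not depend on
        # detection order within the frame.
        def _canonical(indices):
            return sorted(indices, key=lambda di: (det_xy[di, 0], det_xy[di, 1], det_area[di]))

        new_dets = _canonical(di for di in range(n_det) if di not in assignment)
        split_parent: dict[int, int] = {}
        if track_ids and new_dets:
            for di in list(new_dets):
                d_to_tracks = np.linalg.norm(trk_xy - det_xy[di], axis=1)
                order = np.argsort(d_to_tracks, kind="stable")
                for ti in order:
                    if d_to_tracks[ti] > gate_um:
                        break
                    tid = track_ids[ti]
                    # the parent must continue this frame (it was assigned)
                    if tid in assigned_tracks and tid in assignment.values():
                        split_parent[di] = tid
                        break

        # materialize assignments
        for di in range(n_det):
            x, y = det_xy[di]
            a = det_area[di]
            if di in assignment:
                active[assignment[di]].samples.append((frame, t_s, float(x), float(y), float(a)))
        for di, parent_tid in split_parent.items():
            parent = active[parent_tid]
            # larger fragment keeps the identity: swap if the new detection
            # is larger than the one the parent just received
            parent_frame, parent_t, px, py, pa = parent.samples[-1]
            x, y = det_xy[di]
            a = float(det_area[di])
            child = Track(track_id=next_id, parent_id=parent_tid)
            next_id += 1
            if a > pa:
                # new detection is the larger fragment: it keeps the parent
                # identity, the old assignment becomes the child
                parent.samples[-1] = (frame, t_s, float(x), float(y), a)
                child.samples.append((parent_frame, parent_t, px, py, pa))
            else:
                child.samples.append((frame, t_s, float(x), float(y), a))
            tracks.append(child)
            active[child.track_id] = child
            events.append((frame, t_s, "splitting", parent_tid, child.track_id))

        for di in _canonical(range(n_det)):
            if di not in assignment and di not in split_parent:
                x, y = det_xy[di]
                tr = Track(track_id=next_id)
                next_id += 1
                tr.samples.append((frame, t_s, float(x), float(y), float(det_area[di])))
                tracks.append(tr)
                active[tr.track_id] = tr

        # tracks not continued this frame terminate (no gap closing)
        survivors = set(assignment.values()) | {t for t in active if active[t].samples[-1][0] == frame}
        active = {tid: tr for tid, tr in active.items() if tid in survivors}

    tracks_sorted = sorted(tracks, key=lambda t: t.track_id)
    return tracks_sorted, pd.DataFrame(
        events, columns=["frame", "t_s", "kind", "parent_id", "child_id"]
    )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["frame", "t_s", "kind", "parent_id", "child_id"])


def tracks_to_dataframe(tracks: list[Track], nucleus_id: int = 0) -> pd.DataFrame:
    """Flatten tracks into a long table (one row per sample)."""
    rows = [
        (nucleus_id, t.track_id, f, ts, x, y, a)
        for t in tracks
        for (f, ts, x, y, a) in t.samples
    ]
    return pd.DataFrame(
        rows, columns=["nucleus_id", "track_id", "frame", "t_s", "x_um", "y_um", "area_um2"]
    )


def count_series(
    data: list[Track] | pd.DataFrame,
    n_frames: int | None = None,
    frame_interval_s: float = 5.0,
) -> CountSeries:
    """Aggregates alive per frame, from tracks or a detections table."""
    if isinstance(data, pd.DataFrame):
        frames = data["frame"].to_numpy(dtype=int)
    else:
        frames = np.array([f for t in data for (f, *_rest) in t.samples], dtype=int)
    if n_frames is None:
        if len(frames) == 0:
            raise ValueError("empty input and no n_frames given")
        n_frames = int(frames.max()) + 1
    n = np.bincount(frames, minlength=n_frames)
    t_s = np.arange(n_frames) * frame_interval_s
    return CountSeries(t_s=t_s, n=n)


def nucleus_summary(series: CountSeries) -> tuple[float, float, float]:
    """Per-nucleus (mean, min, max) of the aggregate count over time."""
    if len(series.n) == 0:
        raise ValueError("empty count series")
    return float(series.n.mean()), float(series.n.min()), float(series.n.max())
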