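"""Linking, lineage, count series and per-nucleus summaries."""

import numpy as np
import pandas as pd
import pytest
from itertools import permutations

from plaquedyn.synthetic import ConfigurationError, SimulationConfig, project_and_noise, simulate_tracks
from plaquedyn.tracking import (
    CountSeries,
    count_series,
    link_detections,
    nucleus_summary,
    tracks_to_dataframe,
)


def _det(rows):
    df = pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])
    df["area_um2"] = 1.0
    return df


def test_stationary_detection_one_track():
    det = _det([(f, 1.0, 1.0) for f in range(10)])
    tracks, events = link_detections(det)
    assert len(tracks) == 1
    assert len(tracks[0]) == 10
    assert len(events) == 0


def test_gate_rule_breaks_track():
    det = _det([(0, 0.0, 0.0), (1, 5.0, 0.0)])
    tracks, _ = link_detections(det, gate_um=1.5)
    assert len(tracks) == 2
    assert all(len(t) == 1 for t in tracks)


def test_negative_gate_rejected():
    with pytest.raises(ConfigurationError):
        link_detections(_det([(0, 0, 0)]), gate_um=-1)


def test_merge_event_larger_identity_continues():
    # track A (area 2) and B (area 1) converge on one detection at frame 2
    rows = [
        (0, 0.0, 0.0, 2.0),
        (0, 1.0, 0.0, 1.0),
        (1, 0.2, 0.0, 2.0),
        (1, 0.8, 0.0, 1.0),
        (2, 0.4, 0.0, 3.0),
    ]
    det = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "area_um2"])
    tracks, events = link_detections(det, gate_um=1.0)
    assert len(events) == 1
    ev = events.iloc[0]
    assert ev["kind"] == "fusion"
    # identity 0 started at area 2 (larger) and continues
    surviving = [t for t in tracks if t.end_frame == 2]
    assert len(surviving) == 1
    assert surviving[0].track_id == ev["parent_id"]


def test_split_event_larger_fragment_keeps_identity():
    rows = [
        (0, 0.0, 0.0, 3.0),
        (1, 0.0, 0.0, 3.0),
        (2, -0.3, 0.0, 1.0),  # smaller fragment
        (2, 0.3, 0.0, 2.0),  # larger fragment keeps identity
    ]
    det = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "area_um2"])
    tracks, events = link_detections(det, gate_um=1.0)
    assert len(events) == 1
    ev = events.iloc[0]
    assert ev["kind"] == "splitting"
    parent = next(t for t in tracks if t.track_id == ev["parent_id"])
    child = next(t for t in tracks if t.track_id == ev["child_id"])
    assert parent.samples[-1][4] == 2.0  # larger area stayed on the parent id
    assert child.samples[-1][4] == 1.0
    assert child.parent_id == parent.track_id


def test_linking_is_permutation_invariant():
    rng = np.random.default_rng(0)
    rows = []
    for f in range(8):
        for k in range(4):
            rows.append((f, k * 2.0 + rng.normal(0, 0.05), rng.normal(0, 0.05)))
    det = _det(rows)
    shuffled = det.sample(frac=1.0, random_state=1).sort_values("frame").reset_index(drop=True)
    a = tracks_to_dataframe(link_detections(det)[0])
    b = tracks_to_dataframe(link_detections(shuffled)[0])
    key = ["track_id", "frame"]
    pd.testing.assert_frame_equal(
        a.sort_values(key).reset_index(drop=True), b.sort_values(key).reset_index(drop=True)
    )


def test_linker_matches_bruteforce_oracle():
    """≥99% agreement with exhaustive min-total-distance matching."""
    cfg = SimulationConfig(seed=4, mean_aggregate_count=4.0, fuse_prob=0.0,
                           localization_noise_nm=0.0, n_frames=100)
    obs = project_and_noise(simulate_tracks(cfg))
    det = obs[["frame", "x_um", "y_um"]].copy()
    det["area_um2"] = 1.0
    tracks, events = link_detections(det, 1.5, 5.0)
    assert len(events) == 0
    ldf = tracks_to_dataframe(tracks)
    frames = {f: g.reset_index(drop=True) for f, g in ldf.groupby("frame")}
    agree = total = 0
    for f in range(1, 100):
        a, b = frames[f - 1], frames[f]
        A = a[["x_um", "y_um"]].to_numpy()
        B = b[["x_um", "y_um"]].to_numpy()
        best, best_perm = None, None
        for perm in permutations(range(len(B)), min(len(A), len(B))):
            c = sum(np.linalg.norm(A[i] - B[perm[i]]) for i in range(min(len(A), len(B))))
            if best is None or c < best:
                best, best_perm = c, perm
        for i in range(min(len(A), len(B))):
            total += 1
            agree += a["track_id"][i] == b["track_id"][best_perm[i]]
    assert agree / total >= 0.99


def test_count_series_from_tracks_matches_groundtruth():
    cfg = SimulationConfig(seed=11, mean_aggregate_count=4.0, localization_noise_nm=0.0)
    truth = simulate_tracks(cfg)
    obs = project_and_noise(truth)
    det = obs[["frame", "x_um", "y_um"]].copy()
    det["area_um2"] = obs["constituents"].astype(float)
    tracks, _ = link_detections(det, 1.5, 5.0)
    cs = count_series(tracks_to_dataframe(tracks), n_frames=cfg.n_frames)
    assert np.array_equal(cs.n, truth.live_counts(0))


def test_count_series_merge_drop():
    rows = [(0, x, 0.0) for x in (0.0, 2.0, 4.0)] + [(1, x, 0.0) for x in (0.0, 3.0)]
    cs = count_series(_det(rows))
    assert cs.n.tolist() == [3, 2]


def test_nucleus_summary_mean_min_max():
    cs = CountSeries(t_s=np.arange(3) * 5.0, n=[3, 4, 5])
    assert nucleus_summary(cs) == (4.0, 3.0, 5.0)
    with pytest.raises(ValueError):
        nucleus_summary(CountSeries(t_s=np.array([]), n=np.array([])))
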