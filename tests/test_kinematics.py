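"""Speeds, arc statistic, 3D reconstruction, geometry estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from plaquedyn.kinematics import (
    NucleusGeometry,
    compute_arc,
    compute_speeds,
    estimate_geometry,
    rayleigh_scale_from_mean,
    reconstruct_3d,
)
from plaquedyn.synthetic import SimulationConfig, project_and_noise, simulate_planar_track, simulate_tracks


def track(points):
    df = pd.DataFrame(points, columns=["x_um", "y_um"])
    df["frame"] = range(len(points))
    df["t_s"] = df["frame"] * 5.0
    return df


GEOM = NucleusGeometry((0.0, 0.0), 2.0)


# ---------------------------------------------------------------------------
# speeds
# ---------------------------------------------------------------------------


def test_speed_worked_example():
    sd = compute_speeds(track([(1.0, 1.0), (1.3, 1.4)]))
    assert np.allclose(sd.speeds_nm_s, [100.0])


def test_stationary_track_background_fraction_one():
    sd = compute_speeds(track([(0.5, 0.5)] * 5))
    assert np.all(sd.speeds_nm_s == 0)
    assert sd.band_fractions == (1.0, 0.0, 0.0)
    assert not sd.tail_flag


def test_band_fraction_edges():
    # construct steps of exactly 10, 50, 170, 90 nm/s
    xs = np.cumsum([0, 10, 50, 170, 90]) * 5e-3  # µm
    sd = compute_speeds(track([(x, 0.0) for x in xs]))
    assert sd.band_fractions == (0.25, 0.5, 0.25)
    assert sd.tail_flag  # 25% of steps above 160 nm/s


def test_single_sample_track_errors():
    with pytest.raises(ValueError):
        compute_speeds(track([(0, 0)]))


def test_rayleigh_scale_recovery():
    tr = simulate_planar_track(1000, 80.0, seed=2)
    sd = compute_speeds(tr)
    assert abs(rayleigh_scale_from_mean(sd.speeds_nm_s) - 80.0) / 80.0 < 0.05


# ---------------------------------------------------------------------------
# arcs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "chord_points,beta",
    [
        ([(0, 0), (0, 0)], 0.0),
        ([(0, 0), (2, 0)], 60.0),
        ([(0, 0), (2, 2)], 90.0),
        ([(0, 0), (4, 0)], 180.0),
    ],
)
def test_arc_fixed_points(chord_points, beta):
    res = compute_arc(track(chord_points), GEOM)
    assert res.beta_deg == pytest.approx(beta, abs=1e-9)


def test_arc_pythagoras_and_dashed_flag():
    res = compute_arc(track([(0, 0), (0.3, 0.4)]), GEOM)
    assert res.c_um == pytest.approx(math.hypot(res.a_um, res.b_um), abs=1e-12)
    assert not res.dashed
    res2 = compute_arc(track([(0, 0), (2.5, 0)]), GEOM)
    assert res2.dashed and res2.effective_radius_um == 2.0
    res3 = compute_arc(track([(0, 0), (4.5, 0)]), GEOM)
    assert res3.beta_deg == 180.0 and res3.effective_radius_um == pytest.approx(2.25)


def test_arc_uses_extreme_pair():
    # middle excursion defines the chord, not the endpoints
    res = compute_arc(track([(0, 0), (3, 0), (0.5, 0)]), GEOM)
    assert res.c_um == pytest.approx(3.0)


def test_arc_matches_bisection_oracle():
    """β inverts c = 2r·sin(β/2) to 1e-9 over random chords."""
    rng = np.random.default_rng(0)
    for _ in range(500):
        r = rng.uniform(0.5, 5.0)
        c = rng.uniform(0.0, 2.0 * r)
        res = compute_arc(track([(0, 0), (c, 0)]), NucleusGeometry((0, 0), r))
        beta_oracle = bisect(lambda b: 2 * r * math.sin(b / 2) - c, 0.0, math.pi, xtol=1e-13)
        assert abs(math.radians(res.beta_deg) - beta_oracle) < 1e-9


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    r=st.floats(0.5, 5.0),
    c1=st.floats(0.0, 1.0),
    c2=st.floats(0.0, 1.0),
)
def test_arc_monotone_in_chord(r, c1, c2):
    lo, hi = sorted((c1 * 2 * r, c2 * 2 * r))
    g = NucleusGeometry((0, 0), r)
    b_lo = compute_arc(track([(0, 0), (lo, 0)]), g).beta_deg
    b_hi = compute_arc(track([(0, 0), (hi, 0)]), g).beta_deg
    assert b_lo <= b_hi + 1e-9


# ---------------------------------------------------------------------------
# 3D reconstruction
# ---------------------------------------------------------------------------


def test_reconstruct_fixed_points():
    r3 = reconstruct_3d(track([(0, 0), (2, 0)]), GEOM)
    assert np.allclose(r3.samples["z_um"], [2.0, 0.0])


def test_reconstruct_out_of_disk_reuses_previous_z():
    # (1.8, 1.2) has x²+y² = 4.68 > 4: previous z carried forward
    pts = [(1.32287565553, 1.0), (1.8, 1.2)]
    r3 = reconstruct_3d(track(pts), GEOM)
    z0 = math.sqrt(4 - pts[0][0] ** 2 - pts[0][1] ** 2)
    assert r3.samples["z_um"].tolist() == pytest.approx([z0, z0])


def test_reconstruct_first_sample_out_of_disk_zero():
    r3 = reconstruct_3d(track([(3, 0), (0, 0)]), GEOM)
    assert r3.samples["z_um"].tolist() == [0.0, 2.0]


def test_round_trip_simulated_hemisphere_tracks():
    """Project noiselessly, reconstruct: z equals |true z| exactly in-disk."""
    cfg = SimulationConfig(seed=6, n_frames=50, localization_noise_nm=0.0, n_nuclei=4)
    truth = simulate_tracks(cfg)
    obs = project_and_noise(truth)
    geom = NucleusGeometry((0.0, 0.0), cfg.nucleus_radius_um)
    for (nid, tid), g in obs.groupby(["nucleus_id", "track_id"]):
        g = g.sort_values("frame")
        true_z = truth.tracks[
            (truth.tracks["nucleus_id"] == nid) & (truth.tracks["track_id"] == tid)
        ].sort_values("frame")["z_um"].to_numpy()
        rec = reconstruct_3d(g, geom).samples["z_um"].to_numpy()
        assert np.allclose(rec, np.abs(true_z), atol=1e-9)


# ---------------------------------------------------------------------------
# geometry estimation
# ---------------------------------------------------------------------------


def test_geometry_exact_on_circle_points():
    th = np.array([0.3, 2.0, 4.0])
    pts = np.c_[1.5 + 2 * np.cos(th), -0.5 + 2 * np.sin(th)]
    geo = estimate_geometry(pts)
    assert geo.center == pytest.approx((1.5, -0.5), abs=1e-9)
    assert geo.radius_um == pytest.approx(2.0, abs=1e-9)


def test_geometry_collinear_errors():
    with pytest.raises(ValueError, match="non-collinear"):
        estimate_geometry(np.array([[0, 0], [1, 1], [2, 2]]))


def test_geometry_noisy_circle_radius_within_2pct():
    rng = np.random.default_rng(0)
    th = rng.uniform(0, 2 * np.pi, 100)
    pts = np.c_[2 * np.cos(th), 2 * np.sin(th)] + rng.normal(0, 0.02, (100, 2))
    geo = estimate_geometry(pts, method="least_squares")
    assert abs(geo.radius_um - 2.0) / 2.0 < 0.02


def test_geometry_radius_floor():
    pts = np.array([[0, 0], [0.1, 0], [0.05, 0.08]])
    geo = estimate_geometry(pts, min_radius_um=1.0)
    assert geo.radius_um == 1.0
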