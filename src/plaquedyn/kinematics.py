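"""Kinematics of projected aggregate motion.

Three statistics characterize how vigorously an attachment plaque moves:

* **projected speed** — Euclidean 2D displacement between successive
  samples divided by the frame interval, in nm/s, summarized into a
  background band [0, 40] nm/s (apparent motion in immobilized
  specimens), a bulk band (40, 160] nm/s, and a long tail (160, ∞);
* **arc angle β** — the chord ``c`` between a track's two most separated
  points is circumscribed on the projected-nucleus circle of radius
  ``r`` and converted to the subtended angle via the cosine law,
  ``β = arccos(1 − c²/2r²)``; unlike total path length, β measures how
  far a track *reaches* rather than how much it jitters;
* **3D reconstruction** — assuming motion on one hemisphere of a sphere
  of radius r, ``z = √(r² − x² − y²)``; where a (noisy) sample falls
  outside the disk the previous z is carried forward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from plaquedyn.synthetic import ConfigurationError

__all__ = [
    "NucleusGeometry",
    "SpeedDistribution",
    "ArcResult",
    "Trajectory3D",
    "SPEED_BANDS_NM_S",
    "compute_speeds",
    "compute_arc",
    "reconstruct_3d",
    "estimate_geometry",
    "rayleigh_scale_from_mean",
]

#: Speed-band edges in nm/s: background [0, 40], bulk (40, 160], tail (160, ∞).
SPEED_BANDS_NM_S = (40.0, 160.0)

#: A speed distribution is flagged long-tailed when at least this share of
#: steps exceeds the 160 nm/s band edge.
LONG_TAIL_MIN_FRACTION = 0.05


@dataclass(frozen=True)
class NucleusGeometry:
    """Projected nucleus circle: center (µm) and radius r (µm)."""

    center: tuple[float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ConfigurationError("nucleus radius must be > 0")


@dataclass
class SpeedDistribution:
    """Per-step projected speeds with band fractions and shape metrics."""

    speeds_nm_s: np.ndarray
    band_fractions: tuple[float, float, float]  # background, bulk, tail
    skewness: float
    tail_flag: bool

    @property
    def mean_nm_s(self) -> float:
        return float(np.mean(self.speeds_nm_s))


@dataclass(frozen=True)
class ArcResult:
    """Arc travel statistic of one track.

    a_um, b_um are the axis-aligned distances between the two most
    separated track points, c_um = √(a²+b²) the chord, beta_deg the
    angle subtended on the circle of ``effective_radius_um``.  ``dashed``
    flags chords longer than the nominal radius (extended-arc plotting
    convention).
    """

    a_um: float
    b_um: float
    c_um: float
    beta_deg: float
    effective_radius_um: float
    dashed: bool


@dataclass
class Trajectory3D:
    """Reconstructed on-sphere samples (t_s, x, y, z) in µm."""

    samples: pd.DataFrame  # columns t_s, x_um, y_um, z_um
    radius_um: float


def _track_xy(track) -> np.ndarray:
    if isinstance(track, pd.DataFrame):
        return track[["x_um", "y_um"]].to_numpy(dtype=float)
    # plaquedyn.tracking.Track
    return np.array([[s[2], s[3]] for s in track.samples], dtype=float)


def _track_t(track, frame_interval_s: float) -> np.ndarray:
    if isinstance(track, pd.DataFrame):
        if "t_s" in track:
            return track["t_s"].to_numpy(dtype=float)
        return track["frame"].to_numpy(dtype=float) * frame_interval_s
    return np.array([s[1] for s in track.samples], dtype=float)


def compute_speeds(track, frame_interval_s: float = 5.0) -> SpeedDistribution:
    """Per-step projected speeds of one track, in nm/s.

    Speed between successive samples is the 2D Euclidean distance covered
    divided by the time required to cover it.  Band fractions use the
    closed-right convention [0, 40], (40, 160], (160, ∞) nm/s; the track
    is flagged long-tailed when ≥5% of steps exceed 160 nm/s.
    """
    if frame_interval_s <= 0:
        raise ConfigurationError("frame_interval_s must be > 0")
    xy = _track_xy(track)
    if len(xy) < 2:
        raise ValueError("track must have at least 2 samples to compute speeds")
    t = _track_t(track, frame_interval_s)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("sample times must be strictly increasing")
    disp_um = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speeds = disp_um * 1e3 / dt  # nm/s

    b1, b2 = SPEED_BANDS_NM_S
    n = len(speeds)
    background = float(np.sum(speeds <= b1) / n)
    bulk = float(np.sum((speeds > b1) & (speeds <= b2)) / n)
    tail = float(np.sum(speeds > b2) / n)
    skew = float(stats.skew(speeds)) if n >= 3 and np.std(speeds) > 0 else 0.0
    return SpeedDistribution(
        speeds_nm_s=speeds,
        band_fractions=(background, bulk, tail),
        skewness=skew,
        tail_flag=tail >= LONG_TAIL_MIN_FRACTION,
    )


def compute_arc(track, geometry: NucleusGeometry) -> ArcResult:
    """Arc angle subtended by a track's two most separated points.

    The extreme pair is found by exact O(n²) search.  With chord ``c``
    and nominal radius ``r``: for c ≤ 2r, β = arccos(1 − c²/2r²) on the
    nominal circle; a chord longer than r is flagged ``dashed``
    (extended-arc convention); a chord longer than the diameter cannot be
    circumscribed, so the radius is enlarged to the minimal
    circumscribing value c/2 and β = 180°.
    """
    r = geometry.radius_um
    xy = _track_xy(track)
    if len(xy) < 2:
        raise ValueError("track must have at least 2 samples to compute an arc")
    # exact max-separation pair
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    a = abs(xy[i, 0] - xy[j, 0])
    b = abs(xy[i, 1] - xy[j, 1])
    c = math.hypot(a, b)
    if c <= 2.0 * r:
        cos_beta = 1.0 - c**2 / (2.0 * r**2)
        beta = math.degrees(math.acos(min(1.0, max(-1.0, cos_beta))))
        eff_r = r
    else:
        eff_r = c / 2.0
        beta = 180.0
    return ArcResult(
        a_um=float(a),
        b_um=float(b),
        c_um=float(c),
        beta_deg=float(beta),
        effective_radius_um=float(eff_r),
        dashed=c > r,
    )


def reconstruct_3d(track, geometry: NucleusGeometry, frame_interval_s: float = 5.0) -> Trajectory3D:
    """Lift a projected track onto the nucleus hemisphere.

    For each sample (x, y) relative to the nucleus center,
    ``z = √(r² − x² − y²)``; when x² + y² > r² the previous z-coordinate
    is reused (z = 0 if the first sample is already out of the disk).
    """
    r = geometry.radius_um
    cx, cy = geometry.center
    xy = _track_xy(track) - np.array([cx, cy])
    t = _track_t(track, frame_interval_s)
    z = np.empty(len(xy))
    prev_z = 0.0
    for k, (x, y) in enumerate(xy):
        rho2 = x * x + y * y
        if rho2 <= r * r:
            prev_z = math.sqrt(r * r - rho2)
        z[k] = prev_z
    samples = pd.DataFrame({"t_s": t, "x_um": xy[:, 0], "y_um": xy[:, 1], "z_um": z})
    return Trajectory3D(samples=samples, radius_um=r)


# ---------------------------------------------------------------------------
# nucleus geometry estimation
# ---------------------------------------------------------------------------


def _circle_from(points: list[np.ndarray]) -> tuple[np.ndarray, float]:
    if len(points) == 0:
        return np.zeros(2), 0.0
    if len(points) == 1:
        return points[0], 0.0
    if len(points) == 2:
        c = (points[0] + points[1]) / 2.0
        return c, float(np.linalg.norm(points[0] - c))
    (ax, ay), (bx, by), (cx, cy) = points
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        # collinear: circle through the farthest pair
        pts = np.array(points)
        d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        return _circle_from([pts[i], pts[j]])
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(np.array([ax, ay]) - center))


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Minimal enclosing circle (Welzl's algorithm, iterative, shuffled)."""
    pts = points.copy()
    rng.shuffle(pts, axis=0)
    center, radius = np.zeros(2), 0.0
    for i, p in enumerate(pts):
        if np.linalg.norm(p - center) <= radius + 1e-12:
            continue
        center, radius = p, 0.0
        for j in range(i):
            q = pts[j]
            if np.linalg.norm(q - center) <= radius + 1e-12:
                continue
            center = (p + q) / 2.0
            radius = float(np.linalg.norm(p - center))
            for k in range(j):
                s = pts[k]
                if np.linalg.norm(s - center) <= radius + 1e-12:
                    continue
                center, radius = _circle_from([p, q, s])
    return center, radius


def _lsq_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) least-squares circle fit."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx**2 + cy**2, 0.0))
    return np.array([cx, cy]), r


def estimate_geometry(
    detections: pd.DataFrame | np.ndarray,
    method: str = "min_enclosing",
    min_radius_um: float = 1.0,
    seed: int = 0,
) -> NucleusGeometry:
    """Estimate the projected-nucleus circle from aggregate centroids.

    ``method='min_enclosing'`` (default) computes the minimal enclosing
    circle of all centroids across frames; ``'least_squares'`` fits an
    algebraic circle through them.  The radius is floored at
    ``min_radius_um``.  Fewer than 3 points, or collinear points, raise
    an error instructing manual geometry entry.
    """
    if isinstance(detections, pd.DataFrame):
        pts = detections[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(detections, dtype=float)
    pts = np.unique(pts, axis=0)
    if len(pts) < 3 or _collinear(pts):
        raise ValueError(
            "need at least 3 non-collinear centroids to estimate the nucleus "
            "circle; supply NucleusGeometry manually"
        )
    if method == "min_enclosing":
        center, radius = _welzl(pts, np.random.default_rng(seed))
    elif method == "least_squares":
        center, radius = _lsq_circle(pts)
    else:
        raise ValueError(f"unknown method {method!r}")
    radius = max(radius, min_radius_um)
    return NucleusGeometry(center=(float(center[0]), float(center[1])), radius_um=float(radius))


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    return bool(s[-1] / scale < tol)


def rayleigh_scale_from_mean(speeds_nm_s: np.ndarray) -> float:
    """Moment estimator of the Rayleigh scale: σ̂ = mean · √(2/π).

    For a Rayleigh-distributed speed the mean is σ√(π/2); inverting the
    first moment gives a simple consistent estimator of the scale of the
    bulk component of the step-speed law.
    """
    return float(np.mean(speeds_nm_s) * math.sqrt(2.0 / math.pi))
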