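"""Synthetic attachment-plaque trajectory and movie generator.

Chromosome-end attachment plaques move on (one hemisphere of) the nuclear
envelope, meet, transiently coalesce and disperse again.  This module
generates ground-truth trajectories for that process — a confined random
walk on a spherical cap with pairwise fusion and exponential-dwell
splitting — and can render them into noisy grayscale movies, so that
every downstream stage (segmentation, tracking, kinematics, event
analysis, statistics) can be tested against known truth.

Model summary
-------------
* Aggregates live on the upper side of a sphere of radius ``r`` (default
  2 µm), restricted to a spherical cap around the +z pole (default
  half-angle 90°, i.e. one hemisphere) with a reflecting boundary.
* Per frame, each aggregate takes an isotropic step of length
  ``speed × Δt`` in the projected (image) plane, lifted back onto the
  sphere via ``z = √(r² − x² − y²)``; the step speed is drawn from a
  two-component mixture: with probability ``1 − tail_fraction`` a
  Rayleigh bulk component of scale ``speed_scale_nm_s`` (the
  projected-speed law of an isotropic 2D Gaussian walk, hence the
  right-skewed, long-tailed — "Maxwellian" — shape), and with
  probability ``tail_fraction`` a uniform draw from ``tail_range_nm_s``.
  Defining the mixture in projection makes the *observed* per-step
  projected speeds follow it directly, which is the scale on which the
  speed bands (0–40, 40–160, >160 nm/s) are defined.
* Two aggregates closer than ``fuse_distance_um`` (chord distance) fuse
  with probability ``fuse_prob`` per contact frame; the merged aggregate
  carries the summed constituent count and splits again after an
  exponential (optionally lognormal) dwell with mean ``dwell_mean_s``,
  the larger fragment keeping the parent identity.
* Observation: the z-coordinate is dropped (top view) and isotropic
  Gaussian localization noise of SD ``localization_noise_nm`` is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenotypePreset",
    "GroundTruth",
    "GENOTYPE_PRESETS",
    "simulate_tracks",
    "project_and_noise",
    "render_movie",
    "simulate_planar_track",
]


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the hemisphere random-walk simulation.

    Parameters
    ----------
    nucleus_radius_um:
        Radius of the spherical nucleus, µm.
    cap_half_angle_deg:
        Half-angle of the spherical cap (measured from the +z pole) to
        which motion is confined; 90° confines to one hemisphere.
    frame_interval_s, n_frames:
        Time grid: frames are 5 s apart by default and a recording spans
        15 min (181 frames including frame 0).
    mean_aggregate_count:
        Target mean number of simultaneously visible aggregates per
        nucleus.  The initial count is an integer randomization of this
        value (see ``count_dispersion``).
    count_dispersion:
        ``"round"`` — stochastic rounding of ``mean_aggregate_count``
        (minimal across-nucleus variance; the default, so that recovered
        summary means are governed by the kinetics, not by a wide initial
        draw); ``"poisson"`` — Poisson-distributed initial counts
        (clipped to ≥1) for modelling across-nucleus heterogeneity.
    patch_fraction:
        Probability that an initial aggregate starts with two clustered
        chromosome ends (a patch) rather than one (a focus).
    speed_scale_nm_s:
        Rayleigh scale of the bulk speed component, nm/s.
    tail_fraction:
        Probability that a step speed is drawn from the heavy tail.
    tail_range_nm_s:
        (low, high) of the uniform tail component, nm/s.
    fuse_distance_um, fuse_prob:
        Chord distance defining a contact, and the per-contact-frame
        fusion probability.
    dwell_mean_s, dwell_model:
        Mean coalescence dwell before splitting; ``"exponential"``
        (default) or ``"lognormal"`` (same mean, shape ``dwell_lognorm_sigma``).
    localization_noise_nm:
        Isotropic Gaussian centroid localization noise SD, nm (applied by
        :func:`project_and_noise`).
    n_nuclei:
        Number of independent nuclei to simulate.
    seed:
        RNG seed (required; drives every random draw in the module).
    """

    seed: int
    nucleus_radius_um: float = 2.0
    cap_half_angle_deg: float = 90.0
    frame_interval_s: float = 5.0
    n_frames: int = 181
    mean_aggregate_count: float = 3.9
    count_dispersion: str = "round"
    patch_fraction: float = 0.2
    speed_scale_nm_s: float = 51.0
    tail_fraction: float = 0.10
    tail_range_nm_s: tuple[float, float] = (160.0, 260.0)
    fuse_distance_um: float = 0.45
    fuse_prob: float = 0.15
    dwell_mean_s: float = 40.0
    dwell_model: str = "exponential"
    dwell_lognorm_sigma: float = 0.8
    localization_noise_nm: float = 20.0
    n_nuclei: int = 1

    def __post_init__(self) -> None:
        if self.nucleus_radius_um <= 0:
            raise ConfigurationError("nucleus_radius_um must be > 0")
        if not (0 < self.cap_half_angle_deg <= 90):
            # one z-branch of the sphere: the projected walk is lifted via
            # z = +sqrt(r^2 - x^2 - y^2), so caps cannot cross the equator
            raise ConfigurationError("cap_half_angle_deg must be in (0, 90]")
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.mean_aggregate_count <= 0:
            raise ConfigurationError("mean_aggregate_count must be > 0")
        if not (0.0 <= self.tail_fraction <= 1.0):
            raise ConfigurationError("tail_fraction must be in [0, 1]")
        if self.speed_scale_nm_s < 0:
            raise ConfigurationError("speed_scale_nm_s must be >= 0")
        lo, hi = self.tail_range_nm_s
        if not (0 <= lo <= hi):
            raise ConfigurationError("tail_range_nm_s must satisfy 0 <= low <= high")
        if self.tail_fraction > 0 and lo < self.speed_scale_nm_s:
            raise ConfigurationError(
                "tail_range_nm_s low must be >= speed_scale_nm_s "
                "(the tail is the fast component)"
            )
        if self.fuse_distance_um <= 0:
            raise ConfigurationError("fuse_distance_um must be > 0")
        if not (0.0 <= self.fuse_prob <= 1.0):
            raise ConfigurationError("fuse_prob must be in [0, 1]")
        if self.dwell_mean_s <= 0:
            raise ConfigurationError("dwell_mean_s must be > 0")
        if self.dwell_model not in ("exponential", "lognormal"):
            raise ConfigurationError("dwell_model must be 'exponential' or 'lognormal'")
        if self.localization_noise_nm < 0:
            raise ConfigurationError("localization_noise_nm must be >= 0")
        if self.count_dispersion not in ("round", "poisson"):
            raise ConfigurationError("count_dispersion must be 'round' or 'poisson'")
        if not (0.0 <= self.patch_fraction <= 1.0):
            raise ConfigurationError("patch_fraction must be in [0, 1]")
        if self.n_nuclei < 1:
            raise ConfigurationError("n_nuclei must be >= 1")
        if self.seed is None:
            raise ConfigurationError("seed is required")


@dataclass(frozen=True)
class GenotypePreset:
    """Named simulation preset emulating one genotype's summary statistics."""

    name: str
    config: SimulationConfig
    target_mean_count: float


@dataclass
class GroundTruth:
    """True trajectories and kinetic events of one simulation run.

    ``tracks`` columns: nucleus_id, track_id, frame, t_s, x_um, y_um,
    z_um, constituents.  ``events`` columns: nucleus_id, frame, t_s,
    kind ('fusion'|'splitting'), parent_id, child_id.
    """

    tracks: pd.DataFrame
    events: pd.DataFrame
    config: SimulationConfig

    def live_counts(self, nucleus_id: int | None = None) -> np.ndarray:
        """Number of live aggregates per frame (bookkeeping oracle)."""
        df = self.tracks
        if nucleus_id is not None:
            df = df[df["nucleus_id"] == nucleus_id]
        counts = df.groupby("frame").size()
        out = np.zeros(self.config.n_frames, dtype=int)
        out[counts.index.to_numpy()] = counts.to_numpy()
        return out


# ---------------------------------------------------------------------------
# sphere helpers
# ---------------------------------------------------------------------------


def _uniform_cap_points(rng: np.random.Generator, n: int, cap_half_angle_rad: float) -> np.ndarray:
    """Uniform random unit vectors on the spherical cap around +z."""
    cos_min = math.cos(cap_half_angle_rad)
    cos_theta = rng.uniform(cos_min, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    return np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    )


def _reflect_into_disk(xy: np.ndarray, boundary_radius: float) -> np.ndarray:
    """Reflect a projected position radially back inside the cap circle."""
    rho = float(np.linalg.norm(xy))
    if rho <= boundary_radius or rho == 0.0:
        return xy
    rho_new = max(2.0 * boundary_radius - rho, 0.0)
    return xy * (rho_new / rho)


def _lift_z(xy: np.ndarray, r: float) -> float:
    return math.sqrt(max(r * r - float(xy @ xy), 0.0))


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


@dataclass
class _Aggregate:
    aid: int
    xy: np.ndarray  # projected position, µm, nucleus center at the origin
    constituents: int
    # one entry per unresolved fusion: (scheduled split time, absorbed
    # partner's constituent count); LIFO so nested coalescences unwind
    merge_stack: list[tuple[float, int]] = field(default_factory=list)


def _draw_dwell(rng: np.random.Generator, config: SimulationConfig) -> float:
    if config.dwell_model == "exponential":
        return float(rng.exponential(config.dwell_mean_s))
    sigma = config.dwell_lognorm_sigma
    mu = math.log(config.dwell_mean_s) - 0.5 * sigma**2  # mean-matched
    return float(rng.lognormal(mu, sigma))


def _draw_step_speeds(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Mixture step speeds in nm/s: Rayleigh bulk + uniform heavy tail."""
    speeds = rng.rayleigh(scale=config.speed_scale_nm_s, size=n) if config.speed_scale_nm_s > 0 else np.zeros(n)
    if config.tail_fraction > 0:
        is_tail = rng.random(n) < config.tail_fraction
        lo, hi = config.tail_range_nm_s
        speeds[is_tail] = rng.uniform(lo, hi, size=int(is_tail.sum()))
    return speeds


def _initial_count(rng: np.random.Generator, config: SimulationConfig) -> int:
    m = config.mean_aggregate_count
    if config.count_dispersion == "poisson":
        return max(1, int(rng.poisson(m)))
    lo = math.floor(m)
    frac = m - lo
    return max(1, lo + (1 if rng.random() < frac else 0))


def simulate_tracks(config: SimulationConfig) -> GroundTruth:
    """Simulate ground-truth aggregate trajectories with fusion/splitting.

    Returns a :class:`GroundTruth` whose ``tracks`` table has one row per
    live aggregate per frame (3D position on the sphere, in µm, nucleus
    centered at the origin) and whose ``events`` table logs every fusion
    and splitting.  Identical configs (including seed) give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    cap = math.radians(config.cap_half_angle_deg)
    r = config.nucleus_radius_um
    boundary = r * math.sin(cap)  # cap boundary circle in projection
    dt = config.frame_interval_s

    track_rows: list[tuple] = []
    event_rows: list[tuple] = []

    for nucleus_id in range(config.n_nuclei):
        n0 = _initial_count(rng, config)
        units = _uniform_cap_points(rng, n0, cap)
        aggregates: list[_Aggregate] = []
        next_id = 0
        for i in range(n0):
            c = 2 if rng.random() < config.patch_fraction else 1
            aggregates.append(_Aggregate(next_id, units[i, :2] * r, c))
            next_id += 1

        for frame in range(config.n_frames):
            t_s = frame * dt
            if frame > 0:
                # motion step in the projected plane
                speeds = _draw_step_speeds(rng, len(aggregates), config)
                azimuths = rng.uniform(0.0, 2.0 * math.pi, size=len(aggregates))
                for agg, s_nm, az in zip(aggregates, speeds, azimuths):
                    step_um = s_nm * 1e-3 * dt
                    if step_um > 0:
                        agg.xy = _reflect_into_disk(
                            agg.xy + step_um * np.array([math.cos(az), math.sin(az)]),
                            boundary,
                        )

                # scheduled splittings: unwind the most recent unresolved
                # fusion of any aggregate whose dwell has elapsed
                due = [a for a in aggregates if a.merge_stack and t_s >= a.merge_stack[-1][0]]
                for agg in due:
                    _, absorbed_c = agg.merge_stack.pop()
                    other_c = agg.constituents - absorbed_c
                    if other_c < 1:  # defensive; counts are conserved by construction
                        continue
                    # the larger fragment keeps the parent identity
                    parent_c = max(absorbed_c, other_c)
                    child_c = min(absorbed_c, other_c)
                    agg.constituents = parent_c
                    # place the child just outside fusion range
                    sep = 1.5 * config.fuse_distance_um
                    az = rng.uniform(0.0, 2.0 * math.pi)
                    cxy = _reflect_into_disk(
                        agg.xy + sep * np.array([math.cos(az), math.sin(az)]), boundary
                    )
                    child = _Aggregate(next_id, cxy, child_c)
                    next_id += 1
                    aggregates.append(child)
                    event_rows.append(
                        (nucleus_id, frame, t_s, "splitting", agg.aid, child.aid)
                    )

                # pairwise fusion: closest contacting pair first, each
                # aggregate in at most one event per frame; contact is
                # measured as the 3D chord distance on the sphere
                pos = np.array(
                    [[a.xy[0], a.xy[1], _lift_z(a.xy, r)] for a in aggregates]
                )
                n = len(aggregates)
                if n >= 2:
                    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
                    iu = np.triu_indices(n, k=1)
                    order = np.argsort(d[iu], kind="stable")
                    used: set[int] = set()
                    absorbed: set[int] = set()
                    for k in order:
                        i, j = iu[0][k], iu[1][k]
                        if d[i, j] > config.fuse_distance_um:
                            break
                        if i in used or j in used:
                            continue
                        if rng.random() >= config.fuse_prob:
                            continue
                        used.update((i, j))
                        a, b = aggregates[i], aggregates[j]
                        # the larger aggregate keeps its identity
                        if (b.constituents, -b.aid) > (a.constituents, -a.aid):
                            a, b = b, a
                        w = a.constituents + b.constituents
                        # constituent-weighted mean in projection (the disk
                        # is convex, so the merged position stays inside)
                        a.xy = (a.constituents * a.xy + b.constituents * b.xy) / w
                        a.merge_stack.append(
                            (t_s + _draw_dwell(rng, config), b.constituents)
                        )
                        a.constituents = w
                        absorbed.add(b.aid)
                        event_rows.append((nucleus_id, frame, t_s, "fusion", a.aid, b.aid))
                    if absorbed:
                        aggregates = [a for a in aggregates if a.aid not in absorbed]

            for agg in aggregates:
                x, y = agg.xy
                track_rows.append(
                    (nucleus_id, agg.aid, frame, t_s, float(x), float(y),
                     _lift_z(agg.xy, r), agg.constituents)
                )

    tracks = pd.DataFrame(
        track_rows,
        columns=["nucleus_id", "track_id", "frame", "t_s", "x_um", "y_um", "z_um", "constituents"],
    )
    events = pd.DataFrame(
        event_rows,
        columns=["nucleus_id", "frame", "t_s", "kind", "parent_id", "child_id"],
    )
    return GroundTruth(tracks=tracks, events=events, config=config)


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------


def project_and_noise(truth: GroundTruth, seed: int | None = None) -> pd.DataFrame:
    """Project ground truth to the image plane and add localization noise.

    Drops z (top view) and adds isotropic Gaussian noise of SD
    ``localization_noise_nm`` to x and y.  Returns a table with columns
    nucleus_id, track_id, frame, t_s, x_um, y_um, constituents.  The
    noise stream is derived deterministically from the simulation seed
    unless ``seed`` is given.
    """
    if seed is None:
        seed = int(np.random.SeedSequence(truth.config.seed, spawn_key=(1,)).generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)
    obs = truth.tracks[["nucleus_id", "track_id", "frame", "t_s", "x_um", "y_um", "constituents"]].copy()
    sd_um = truth.config.localization_noise_nm * 1e-3
    if sd_um > 0:
        obs["x_um"] = obs["x_um"] + rng.normal(0.0, sd_um, size=len(obs))
        obs["y_um"] = obs["y_um"] + rng.normal(0.0, sd_um, size=len(obs))
    return obs


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_movie(
    tracks: pd.DataFrame | GroundTruth,
    pixel_size_um: float = 0.1,
    image_shape: tuple[int, int] | None = None,
    spot_sigma_um: float = 0.26,
    amplitude: float = 150.0,
    background: float = 10.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render trajectories into a noisy grayscale image stack.

    Each aggregate is drawn as a 2D Gaussian spot whose amplitude scales
    linearly and whose footprint SD scales as √constituents, so that
    multi-constituent aggregates segment above the 2.15 µm² patch
    threshold while single-constituent ones stay below it.  Constant
    background and Poisson shot noise are added.

    Returns ``(stack, truth_table)`` where ``stack`` is float
    ``(n_frames, H, W)`` and ``truth_table`` gives per-frame true pixel
    coordinates (columns frame, track_id, x_um, y_um, row_px, col_px,
    constituents).  Positions are shifted so the origin maps to the image
    center; positions outside the field raise an error listing the
    offending frames.
    """
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be > 0")
    if isinstance(tracks, GroundTruth):
        df = tracks.tracks
    else:
        df = tracks
    df = df.copy()
    n_frames = int(df["frame"].max()) + 1 if len(df) else 1

    if image_shape is None:
        if len(df):
            extent = max(
                float(np.abs(df["x_um"]).max()), float(np.abs(df["y_um"]).max())
            )
        else:
            extent = 2.0
        half_px = int(math.ceil((extent + 1.0) / pixel_size_um))
        image_shape = (2 * half_px + 1, 2 * half_px + 1)
    h, w = image_shape
    center_row, center_col = (h - 1) / 2.0, (w - 1) / 2.0

    if len(df):
        col = df["x_um"].to_numpy() / pixel_size_um + center_col
        row = df["y_um"].to_numpy() / pixel_size_um + center_row
        out_of_field = (col < 0) | (col > w - 1) | (row < 0) | (row > h - 1)
        if out_of_field.any():
            bad_frames = sorted(df.loc[out_of_field, "frame"].unique().tolist())
            raise ValueError(
                f"positions outside the field in frames {bad_frames}; "
                "enlarge image_shape or shrink the trajectories"
            )
        df["col_px"] = col
        df["row_px"] = row
    else:
        df["col_px"] = pd.Series(dtype=float)
        df["row_px"] = pd.Series(dtype=float)

    rng = np.random.default_rng(seed)
    stack = np.full((n_frames, h, w), float(background))
    rows_grid, cols_grid = np.mgrid[0:h, 0:w]
    for frame, group in df.groupby("frame"):
        img = stack[int(frame)]
        for _, det in group.iterrows():
            c = int(det.get("constituents", 1))
            sigma_px = spot_sigma_um * math.sqrt(c) / pixel_size_um
            amp = amplitude * c
            d2 = (rows_grid - det["row_px"]) ** 2 + (cols_grid - det["col_px"]) ** 2
            img += amp * np.exp(-d2 / (2.0 * sigma_px**2))
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)

    cols = ["frame", "track_id", "x_um", "y_um", "row_px", "col_px"]
    if "constituents" in df:
        cols.append("constituents")
    if "nucleus_id" in df:
        cols.insert(0, "nucleus_id")
    truth_table = df[cols].reset_index(drop=True)
    return stack, truth_table


# ---------------------------------------------------------------------------
# planar step-statistics helper
# ---------------------------------------------------------------------------


def simulate_planar_track(
    n_steps: int,
    speed_scale_nm_s: float,
    frame_interval_s: float = 5.0,
    tail_fraction: float = 0.0,
    tail_range_nm_s: tuple[float, float] = (160.0, 260.0),
    localization_noise_nm: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a single unconfined planar track with mixture step speeds.

    Useful for validating step-speed statistics free of the geometric
    compression that projecting a spherical walk introduces.  Returns a
    track table (frame, t_s, x_um, y_um).
    """
    rng = np.random.default_rng(seed)
    speeds = rng.rayleigh(speed_scale_nm_s, size=n_steps) if speed_scale_nm_s > 0 else np.zeros(n_steps)
    if tail_fraction > 0:
        is_tail = rng.random(n_steps) < tail_fraction
        speeds[is_tail] = rng.uniform(*tail_range_nm_s, size=int(is_tail.sum()))
    angles = rng.uniform(0, 2 * math.pi, size=n_steps)
    step_um = speeds * 1e-3 * frame_interval_s
    dx = np.concatenate([[0.0], step_um * np.cos(angles)])
    dy = np.concatenate([[0.0], step_um * np.sin(angles)])
    x = np.cumsum(dx)
    y = np.cumsum(dy)
    if localization_noise_nm > 0:
        x = x + rng.normal(0, localization_noise_nm * 1e-3, size=len(x))
        y = y + rng.normal(0, localization_noise_nm * 1e-3, size=len(y))
    frames = np.arange(n_steps + 1)
    return pd.DataFrame(
        {"frame": frames, "t_s": frames * frame_interval_s, "x_um": x, "y_um": y}
    )


# ---------------------------------------------------------------------------
# genotype presets
# ---------------------------------------------------------------------------


def _preset(name: str, target: float, **overrides) -> GenotypePreset:
    base = SimulationConfig(seed=0, mean_aggregate_count=target, **overrides)
    return GenotypePreset(name=name, config=base, target_mean_count=target)


#: Named presets parameterized from the published per-genotype summary
#: statistics: mean simultaneous aggregate counts, speed-band structure
#: (wild type: 24% background, 66% in 40–160 nm/s, ~10% tail up to
#: 260 nm/s; the SUN-domain point mutant: sharp bell with 95% within
#: 10–100 nm/s and no aggregate exchange), and an azide-killed control
#: with zero true motion defining the 0–40 nm/s background band.
GENOTYPE_PRESETS: dict[str, GenotypePreset] = {
    "wild_type": _preset("wild_type", 3.9),
    "sun_domain_mutant": _preset(
        "sun_domain_mutant",
        7.8,
        speed_scale_nm_s=41.0,
        tail_fraction=0.0,
        fuse_prob=0.0,
    ),
    "axis_mutant": _preset(
        "axis_mutant",
        1.1,
        fuse_prob=0.0,
    ),
    "azide": _preset(
        "azide",
        3.9,
        speed_scale_nm_s=0.0,
        tail_fraction=0.0,
        fuse_prob=0.0,
    ),
}


def preset_config(name: str, seed: int, **overrides) -> SimulationConfig:
    """Return a preset's config rebound to ``seed`` with optional overrides."""
    if name not in GENOTYPE_PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(GENOTYPE_PRESETS)}")
    return replace(GENOTYPE_PRESETS[name].config, seed=seed, **overrides)


def presets_to_yaml(path) -> None:
    """Write all genotype presets to a YAML file (editable, reloadable)."""
    import yaml
    from dataclasses import asdict

    payload = {
        name: {
            "target_mean_count": p.target_mean_count,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(p.config).items()},
        }
        for name, p in GENOTYPE_PRESETS.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def presets_from_yaml(path) -> dict[str, GenotypePreset]:
    """Load genotype presets from a YAML file written by :func:`presets_to_yaml`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, entry in raw.items():
        cfg = dict(entry["config"])
        if "tail_range_nm_s" in cfg:
            cfg["tail_range_nm_s"] = tuple(cfg["tail_range_nm_s"])
        out[name] = GenotypePreset(
            name=name, config=SimulationConfig(**cfg), target_mean_count=entry["target_mean_count"]
        )
    return out
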