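"""Synthetic camera rigs, flight trajectories and observations.

The simulator emulates the study conditions of a multi-camera insect
tracking room at desk scale: 2-11 calibrated cameras on a ring viewing a
flight arena, one to a few targets flying smooth constant-speed segments
punctuated by saccades (brief, rapid turns), and per-camera detections
corrupted by Gaussian pixel noise, missed detections and Poisson
false-positive clutter. Ground truth (true states and per-feature
provenance) is returned alongside every output so trackers can be scored
exactly.

Defaults follow the small fruit-fly arena: 5 cameras at 100 fps viewing
a 0.3 x 0.3 x 1.5 m volume, mean flight speed 0.15 m/s. A large-arena
preset (11 cameras, 2 m diameter x 0.8 m cylinder footprint, 60 fps) is
available via :func:`SimulationConfig.large_arena`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .features import BackgroundModel, FeaturePoint
from .geometry import CameraModel, project
from .pipeline import FrameBundle

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_rig",
    "make_trajectory",
    "observe",
    "render_frames",
]

CLUTTER = -1  # provenance label for false-positive features


@dataclass
class SimulationConfig:
    """Study conditions for one simulated recording.

    ``arena`` is the (x, y, z) extent in metres of an axis-aligned box
    centred on the origin at z in [0, arena_z]. Rates: ``miss_rate`` is
    the per-camera per-frame probability of dropping a true detection;
    ``clutter_rate`` the mean number of uniform false positives per
    camera per frame.
    """

    n_cameras: int = 5
    arena: tuple[float, float, float] = (0.3, 0.3, 1.5)
    n_targets: int = 1
    n_frames: int = 200
    frame_rate: float = 100.0
    pixel_noise_sigma: float = 0.0
    miss_rate: float = 0.0
    clutter_rate: float = 0.0
    seed: int = 0
    # flight model
    speed_mean: float = 0.15      # m/s
    speed_sd: float = 0.03        # m/s
    saccade_rate: float = 0.5     # saccades per second (Poisson)
    saccade_angle_deg: tuple[float, float] = (90.0, 150.0)
    saccade_frames: tuple[int, int] = (2, 5)
    wall_margin: float = 0.02     # m, reflective confinement margin
    # imaging
    image_size: tuple[int, int] = (640, 480)
    blob_sigma: float = 2.0       # px
    blob_amplitude: float = 120.0  # luminance units
    blob_elongation: float = 0.0  # extra sigma along projected velocity, px

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be a probability")
        if self.clutter_rate < 0:
            raise ValueError("clutter_rate must be non-negative")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @classmethod
    def large_arena(cls, **kwargs) -> "SimulationConfig":
        """11-camera, 60 fps preset for a 2 m diameter x 0.8 m high volume."""
        defaults = dict(n_cameras=11, arena=(2.0, 2.0, 0.8), frame_rate=60.0)
        defaults.update(kwargs)
        return cls(**defaults)

    def arena_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        ax, ay, az = self.arena
        lo = np.array([-ax / 2, -ay / 2, 0.0])
        hi = np.array([ax / 2, ay / 2, az])
        return lo, hi


@dataclass
class GroundTruth:
    """True per-frame target states and per-feature provenance.

    ``states`` has shape (n_targets, n_frames, 6); ``provenance[t][c]``
    lists, per emitted feature in frame t camera c, the originating
    target index or ``CLUTTER`` (-1).
    """

    states: np.ndarray
    provenance: list[list[list[int]]] = field(default_factory=list)


def _arena_corners(config: SimulationConfig) -> np.ndarray:
    lo, hi = config.arena_bounds()
    return np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )


def _look_at_matrix(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation with rows (right, down, forward) for a camera at
    ``position`` looking at ``target`` (world z up)."""
    forward = target - position
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    if abs(forward @ up) > 0.999:  # looking straight up/down
        up = np.array([0.0, 1.0, 0.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    return np.vstack([right, down, forward])


def make_rig(config: SimulationConfig, ring_radius: float | None = None) -> list[CameraModel]:
    """Place ``n_cameras`` on a ring around the arena, all aimed at its
    centre, with a common focal length chosen so every arena corner
    projects inside every image (with a 5% margin)."""
    if config.n_cameras < 2:
        raise ValueError("a rig needs >= 2 cameras")
    lo, hi = config.arena_bounds()
    centre = (lo + hi) / 2
    diag = float(np.linalg.norm(hi - lo))
    radius = ring_radius if ring_radius is not None else 1.3 * diag
    W, H = config.image_size
    corners = _arena_corners(config)

    positions = []
    n = config.n_cameras
    for i in range(n):
        angle = 2 * np.pi * i / n
        # stagger camera heights so vertical structure is resolved
        height = centre[2] + (0.35 * diag) * np.sin(2.5 * angle + 0.7)
        positions.append(
            centre + np.array([radius * np.cos(angle), radius * np.sin(angle), 0.0])
            + np.array([0.0, 0.0, height - centre[2]])
        )

    # common focal length: tightest camera constrains it
    focal = np.inf
    rigs = []
    for pos in positions:
        R = _look_at_matrix(pos, centre)
        t = -R @ pos
        rigs.append((R, t))
        cam_pts = (R @ corners.T).T + t
        if np.any(cam_pts[:, 2] <= 0):
            raise ValueError("arena corner behind a camera; increase ring radius")
        xs = np.abs(cam_pts[:, 0] / cam_pts[:, 2])
        ys = np.abs(cam_pts[:, 1] / cam_pts[:, 2])
        focal = min(focal, 0.95 * (W / 2) / xs.max(), 0.95 * (H / 2) / ys.max())
    if not np.isfinite(focal) or focal <= 0:
        raise ValueError("cannot cover arena with requested rig")

    cameras = []
    K = np.array([[focal, 0.0, W / 2], [0.0, focal, H / 2], [0.0, 0.0, 1.0]])
    for i, (R, t) in enumerate(rigs):
        P = K @ np.hstack([R, t[:, None]])
        cameras.append(CameraModel(id=f"cam{i}", P=P, image_size=(W, H)))

    for cam in cameras:  # coverage guarantee
        px = np.array([project(cam, c) for c in corners])
        if px.min() < 0 or np.any(px[:, 0] >= W) or np.any(px[:, 1] >= H):
            raise ValueError("arena corners fall outside an image; rig invalid")
    return cameras


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_towards(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1 - np.cos(angle))
    )


def make_trajectory(config: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Simulate flight paths: straight constant-speed segments joined by
    saccades at Poisson-distributed times, confined to the arena by
    reflecting the velocity at a safety margin inside the walls.

    Returns a :class:`GroundTruth` with states (position, velocity) of
    shape (n_targets, n_frames, 6) and empty provenance.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.arena_bounds()
    lo_m, hi_m = lo + config.wall_margin, hi - config.wall_margin
    dt = config.dt
    states = np.zeros((config.n_targets, config.n_frames, 6))

    for k in range(config.n_targets):
        pos = rng.uniform(lo_m + 0.2 * (hi_m - lo_m), hi_m - 0.2 * (hi_m - lo_m))
        heading = _random_unit(rng)
        speed = max(rng.normal(config.speed_mean, config.speed_sd), 0.01)
        saccade_left = 0  # frames remaining in current saccade
        saccade_axis = np.zeros(3)
        saccade_step = 0.0
        if config.saccade_rate > 0:
            next_saccade = rng.exponential(1.0 / config.saccade_rate)
        else:
            next_saccade = np.inf

        for t in range(config.n_frames):
            states[k, t, :3] = pos
            states[k, t, 3:] = heading * speed
            # advance
            pos = pos + heading * speed * dt
            # reflective confinement
            for ax in range(3):
                if pos[ax] < lo_m[ax]:
                    pos[ax] = 2 * lo_m[ax] - pos[ax]
                    heading[ax] = abs(heading[ax])
                elif pos[ax] > hi_m[ax]:
                    pos[ax] = 2 * hi_m[ax] - pos[ax]
                    heading[ax] = -abs(heading[ax])
            heading /= np.linalg.norm(heading)
            # saccade dynamics
            if saccade_left > 0:
                heading = _rotate_towards(heading, saccade_axis, saccade_step)
                heading /= np.linalg.norm(heading)
                saccade_left -= 1
                if saccade_left == 0:
                    speed = max(rng.normal(config.speed_mean, config.speed_sd), 0.01)
            else:
                next_saccade -= dt
                if next_saccade <= 0:
                    total = np.deg2rad(rng.uniform(*config.saccade_angle_deg))
                    nfr = int(rng.integers(config.saccade_frames[0],
                                           config.saccade_frames[1] + 1))
                    axis = _random_unit(rng)
                    axis -= (axis @ heading) * heading  # turn, don't roll
                    nrm = np.linalg.norm(axis)
                    axis = axis / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
                    saccade_axis = axis
                    saccade_step = total / nfr
                    saccade_left = nfr
                    next_saccade = rng.exponential(1.0 / config.saccade_rate)
    return GroundTruth(states=states)


def _synthetic_blob_stats(rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Area/peak/shape stats for a simulated detection; clutter draws from
    the same distribution so area gating is a meaningful test."""
    alpha = float(rng.uniform(4.0, 20.0))
    beta = float(rng.uniform(50.0, 200.0))
    theta = float(rng.uniform(0.0, np.pi))
    eps = float(rng.uniform(0.0, 0.8))
    return alpha, beta, theta, eps


def observe(
    truth: GroundTruth,
    rig: list[CameraModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[FrameBundle], GroundTruth]:
    """Generate per-frame FeaturePoint bundles from true states.

    Each true position is projected into each camera; detections get
    isotropic Gaussian pixel noise, are dropped with ``miss_rate`` (or
    when projecting outside the image), and Poisson(``clutter_rate``)
    uniform false positives are appended per camera. The returned
    GroundTruth carries provenance labels aligned with each bundle.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_targets, n_frames, _ = truth.states.shape
    W, H = config.image_size
    bundles = []
    provenance: list[list[list[int]]] = []

    for t in range(n_frames):
        feats: list[list[FeaturePoint]] = [[] for _ in rig]
        prov_t: list[list[int]] = [[] for _ in rig]
        for ci, cam in enumerate(rig):
            for k in range(n_targets):
                pos = truth.states[k, t, :3]
                px = project(cam, pos)
                if config.pixel_noise_sigma > 0:
                    px = px + rng.normal(0.0, config.pixel_noise_sigma, size=2)
                if not (0 <= px[0] < W and 0 <= px[1] < H):
                    continue
                if config.miss_rate > 0 and rng.random() < config.miss_rate:
                    continue
                alpha, beta, theta, eps = _synthetic_blob_stats(rng)
                feats[ci].append(
                    FeaturePoint(u=float(px[0]), v=float(px[1]), alpha=alpha,
                                 beta=beta, theta=theta, epsilon=eps,
                                 camera_id=cam.id, frame_index=t)
                )
                prov_t[ci].append(k)
            n_clutter = rng.poisson(config.clutter_rate) if config.clutter_rate > 0 else 0
            for _ in range(n_clutter):
                alpha, beta, theta, eps = _synthetic_blob_stats(rng)
                feats[ci].append(
                    FeaturePoint(u=float(rng.uniform(0, W)), v=float(rng.uniform(0, H)),
                                 alpha=alpha, beta=beta, theta=theta, epsilon=eps,
                                 camera_id=cam.id, frame_index=t)
                )
                prov_t[ci].append(CLUTTER)
        bundles.append(FrameBundle(frame_index=t, features=feats))
        provenance.append(prov_t)
    return bundles, GroundTruth(states=truth.states, provenance=provenance)


def make_background(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth random texture standing in for a static scene."""
    W, H = config.image_size
    noise = rng.normal(size=(H, W))
    tex = ndimage.gaussian_filter(noise, sigma=15.0)
    tex = (tex - tex.min()) / (np.ptp(tex) + 1e-12)
    return 40.0 + 40.0 * tex


def render_frames(
    truth: GroundTruth,
    rig: list[CameraModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[list[np.ndarray]], list[BackgroundModel]]:
    """Render Gaussian target blobs over a static textured background.

    Returns ``(frames, backgrounds)`` where ``frames[t][c]`` is the image
    of camera c at frame t (float luminance) and ``backgrounds[c]`` is
    the true static background as a ready-to-use
    :class:`~flight3d.features.BackgroundModel`. When
    ``config.blob_elongation > 0`` blobs are stretched along the
    projected velocity direction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_targets, n_frames, _ = truth.states.shape
    W, H = config.image_size
    backgrounds = [make_background(config, rng) for _ in rig]
    frames: list[list[np.ndarray]] = []

    uu, vv = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    for t in range(n_frames):
        frame_row = []
        for ci, cam in enumerate(rig):
            img = backgrounds[ci].copy()
            for k in range(n_targets):
                pos = truth.states[k, t, :3]
                vel = truth.states[k, t, 3:]
                px = project(cam, pos)
                if not (-20 <= px[0] < W + 20 and -20 <= px[1] < H + 20):
                    continue
                du, dv = uu - px[0], vv - px[1]
                s = config.blob_sigma
                if config.blob_elongation > 0 and np.linalg.norm(vel) > 0:
                    tip = project(cam, pos + 1e-3 * vel)
                    d2 = tip - px
                    nrm = np.linalg.norm(d2)
                    if nrm > 1e-12:
                        e = d2 / nrm
                        along = du * e[0] + dv * e[1]
                        across = -du * e[1] + dv * e[0]
                        sa = s + config.blob_elongation
                        blob = np.exp(-0.5 * ((along / sa) ** 2 + (across / s) ** 2))
                    else:
                        blob = np.exp(-0.5 * (du**2 + dv**2) / s**2)
                else:
                    blob = np.exp(-0.5 * (du**2 + dv**2) / s**2)
                img = img + config.blob_amplitude * blob
            frame_row.append(img)
        frames.append(frame_row)
    bg_models = [BackgroundModel.from_frame(bg) for bg in backgrounds]
    return frames, bg_models
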