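"""Trajectory statistics: horizontal speed, angular velocity, approach
angle to a landmark, and per-condition speed histograms.

All derivatives use central differences (one-sided at the endpoints); an
optional moving-average window can pre-smooth positions. Frame times
come from the tracker frame rate: ``dt = 1 / frame_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import Trajectory

__all__ = [
    "LandmarkScene",
    "horizontal_speed",
    "angular_velocity",
    "approach_angle",
    "speed_histogram",
]


@dataclass(frozen=True)
class LandmarkScene:
    """A vertical post landmark: horizontal centre position and radius (m)."""

    post_position: tuple[float, float]
    post_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.post_radius < 0:
            raise ValueError("post radius must be >= 0")


def _positions(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.positions
    return np.asarray(traj, dtype=float)


def _central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    """Central differences along axis 0, one-sided at the endpoints."""
    return np.gradient(x, dt, axis=0)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, ((pad, pad), (0, 0)), mode="edge")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(xp[:, j], kernel, mode="valid")[: x.shape[0]]
    return out


def horizontal_speed(traj, dt: float, smooth_window: int = 1) -> np.ndarray:
    """Per-frame horizontal (XY) speed, m/s: the norm of the first
    derivative of the horizontal position."""
    pos = _positions(traj)
    if len(pos) < 2:
        raise ValueError("horizontal speed needs >= 2 frames")
    pos = _smooth(pos, smooth_window)
    vel = _central_diff(pos[:, :2], dt)
    return np.linalg.norm(vel, axis=1)


def angular_velocity(traj, dt: float, smooth_window: int = 1,
                     speed_floor: float = 1e-9) -> np.ndarray:
    """Per-frame angular velocity of the 3D flight direction, rad/s.

    Measured tangent to the trajectory: the rate of change of the unit
    tangent vector. Frames where the speed is below ``speed_floor``
    (stationary) are returned as NaN.
    """
    pos = _positions(traj)
    if len(pos) < 3:
        raise ValueError("angular velocity needs >= 3 frames")
    pos = _smooth(pos, smooth_window)
    vel = _central_diff(pos, dt)
    speed = np.linalg.norm(vel, axis=1)
    ok = speed > speed_floor
    tangent = np.full_like(vel, np.nan)
    tangent[ok] = vel[ok] / speed[ok, None]
    dtan = _central_diff(tangent, dt)
    omega = np.linalg.norm(dtan, axis=1)
    omega[~ok] = np.nan
    return omega


def approach_angle(traj, scene: LandmarkScene, dt: float,
                   smooth_window: int = 1) -> np.ndarray:
    """Per-frame approach angle psi to the post, radians in (-pi, pi].

    psi is the difference between the horizontal flight direction and the
    horizontal bearing to the post: 0 means flying straight at the post,
    pi flying directly away. Positive psi means the post lies to the left
    of the heading. Frames with zero horizontal speed are NaN.
    """
    pos = _positions(traj)
    if len(pos) < 2:
        raise ValueError("approach angle needs >= 2 frames")
    pos = _smooth(pos, smooth_window)
    rel = np.asarray(scene.post_position) - pos[:, :2]
    if np.any(np.linalg.norm(rel, axis=1) < 1e-12):
        raise ValueError("trajectory passes through the post centre")
    vel = _central_diff(pos[:, :2], dt)
    speed = np.linalg.norm(vel, axis=1)
    heading = np.arctan2(vel[:, 1], vel[:, 0])
    bearing = np.arctan2(rel[:, 1], rel[:, 0])
    psi = bearing - heading
    psi = np.mod(psi + np.pi, 2 * np.pi) - np.pi
    psi[psi == -np.pi] = np.pi
    psi[speed < 1e-12] = np.nan
    return psi


def speed_histogram(
    trajs,
    condition_labels,
    dt: float,
    arena_lo,
    arena_hi,
    margin: float = 0.05,
    bins=30,
    range_=None,
):
    """Per-condition normalized horizontal-speed histograms.

    Parameters
    ----------
    trajs:
        List of trajectories (or position arrays).
    condition_labels:
        One label per trajectory assigning it to an experimental
        condition.
    arena_lo, arena_hi:
        Axis-aligned arena bounds (m); frames closer than ``margin``
        (default 5 cm) to any wall, floor or ceiling are excluded.
    bins, range_:
        Passed to ``numpy.histogram``; histograms are normalized to unit
        area (``density=True``).

    Returns
    -------
    dict mapping condition label to a dict with keys ``hist``, ``edges``,
    ``mean``, ``sd``, ``n`` (empty conditions give ``n == 0`` and empty
    arrays rather than an error).
    """
    arena_lo = np.asarray(arena_lo, dtype=float)
    arena_hi = np.asarray(arena_hi, dtype=float)
    pooled: dict = {}
    for traj, label in zip(trajs, condition_labels):
        pos = _positions(traj)
        if len(pos) < 2:
            continue
        speeds = horizontal_speed(pos, dt)
        inside = np.all((pos >= arena_lo + margin) & (pos <= arena_hi - margin), axis=1)
        pooled.setdefault(label, []).append(speeds[inside])

    out = {}
    for label in dict.fromkeys(condition_labels):  # preserve order
        chunks = pooled.get(label, [])
        samples = np.concatenate(chunks) if chunks else np.empty(0)
        if samples.size == 0:
            out[label] = {"hist": np.empty(0), "edges": np.empty(0),
                          "mean": np.nan, "sd": np.nan, "n": 0}
            continue
        hist, edges = np.histogram(samples, bins=bins, range=range_, density=True)
        out[label] = {
            "hist": hist,
            "edges": edges,
            "mean": float(samples.mean()),
            "sd": float(samples.std()),
            "n": int(samples.size),
        }
    return out
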