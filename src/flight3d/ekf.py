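"""Per-target extended Kalman filter.

State is the 6-vector ``s = (x, y, z, vx, vy, vz)`` (metres, metres per
second) of an orientation-free particle. Dynamics are a constant-velocity
model with additive Gaussian process noise; manoeuvring shows up as
process noise rather than in the deterministic model. The observation is
the concatenation of the target's distortion-corrected image positions in
the contributing cameras, a nonlinear (projective) function of position
only, linearized analytically for the EKF update.

Default noise levels follow tracking of fruit-fly-sized targets at
~100 fps: process covariance Q diagonal with positional entries
100 mm^2 (stored as 1e-4 m^2) and velocity entries 0.25 m^2 s^-2;
observation covariance R = identity, i.e. one pixel of variance per
image coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CameraModel, project

__all__ = [
    "TargetModel",
    "ProcessModel",
    "ObservationModel",
    "predict",
    "observation_function",
    "observation_jacobian",
    "update",
]

# Paper-calibrated defaults (fruit flies, small arena, ~100 fps).
DEFAULT_Q_POS = 1e-4  # m^2       (100 mm^2)
DEFAULT_Q_VEL = 0.25  # m^2 s^-2
DEFAULT_R_PX = 1.0    # px^2
DEFAULT_INIT_POS_VAR = 0.01  # m^2      "relatively high" birth uncertainty
DEFAULT_INIT_VEL_VAR = 1.0   # m^2 s^-2


class FilterError(RuntimeError):
    """Numerical failure inside the filter (e.g. singular innovation)."""


@dataclass
class TargetModel:
    """One tracked target: state estimate, covariance and bookkeeping."""

    id: int
    state: np.ndarray                 # shape (6,)
    covariance: np.ndarray            # shape (6, 6), symmetric PSD
    frames_since_observation: int = 0
    birth_frame: int = 0

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float).reshape(6)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(6, 6)

    @property
    def position(self) -> np.ndarray:
        return self.state[:3]

    @property
    def velocity(self) -> np.ndarray:
        return self.state[3:]

    @property
    def position_covariance(self) -> np.ndarray:
        return self.covariance[:3, :3]

    def copy(self) -> "TargetModel":
        return TargetModel(
            id=self.id,
            state=self.state.copy(),
            covariance=self.covariance.copy(),
            frames_since_observation=self.frames_since_observation,
            birth_frame=self.birth_frame,
        )


def constant_velocity_transition(dt: float) -> np.ndarray:
    A = np.eye(6)
    A[:3, 3:] = dt * np.eye(3)
    return A


@dataclass
class ProcessModel:
    """Constant-velocity dynamics ``s' = A s + w``, ``w ~ N(0, Q)``."""

    dt: float = 0.01
    q_pos: float = DEFAULT_Q_POS
    q_vel: float = DEFAULT_Q_VEL
    A: np.ndarray = field(init=False)
    Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A = constant_velocity_transition(self.dt)
        self.Q = np.diag([self.q_pos] * 3 + [self.q_vel] * 3)


@dataclass
class ObservationModel:
    """Multi-camera projective observation with per-camera 2x2 noise.

    ``r_px`` is the pixel variance shared by every camera unless
    ``r_per_camera`` overrides it with one variance per camera.
    """

    cameras: list[CameraModel]
    r_px: float = DEFAULT_R_PX
    r_per_camera: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.cameras) < 1:
            raise ValueError("observation model needs >= 1 camera")
        if self.r_per_camera is not None and len(self.r_per_camera) != len(self.cameras):
            raise ValueError("r_per_camera length must match number of cameras")

    def r_for(self, camera_index: int) -> float:
        if self.r_per_camera is not None:
            return self.r_per_camera[camera_index]
        return self.r_px


def predict(target: TargetModel, process: ProcessModel) -> TargetModel:
    """Time-update: ``s <- A s``, ``P <- A P A^T + Q``."""
    out = target.copy()
    out.state = process.A @ target.state
    out.covariance = process.A @ target.covariance @ process.A.T + process.Q
    return out


def observation_function(state, cameras) -> np.ndarray:
    """``h(s)``: concatenated image points ``(u1, v1, ..., un, vn)`` of the
    position through each camera."""
    state = np.asarray(state, dtype=float).reshape(-1)
    pos = state[:3]
    out = np.empty(2 * len(cameras))
    for i, cam in enumerate(cameras):
        out[2 * i : 2 * i + 2] = project(cam, pos)
    return out


def observation_jacobian(state, cameras) -> np.ndarray:
    """Analytic Jacobian of :func:`observation_function`, shape (2n, 6).

    With ``P = [M | p4]`` and ``x = M p + p4``, the derivatives are
    ``d(u)/dp = (x3 M_row0 - x1 M_row2) / x3^2`` and analogously for v.
    The velocity block is zero: cameras see position only.
    """
    state = np.asarray(state, dtype=float).reshape(-1)
    pos = state[:3]
    H = np.zeros((2 * len(cameras), 6))
    for i, cam in enumerate(cameras):
        M = cam.P[:, :3]
        x = cam.P @ np.append(pos, 1.0)
        w = x[2]
        if abs(w) < 1e-12:
            raise FilterError(f"camera {cam.id!r}: Jacobian undefined in principal plane")
        H[2 * i] = np.concatenate([(w * M[0] - x[0] * M[2]) / w**2, np.zeros(3)])
        H[2 * i + 1] = np.concatenate([(w * M[1] - x[1] * M[2]) / w**2, np.zeros(3)])
    return H


def update(
    target: TargetModel,
    observed,
    obs_model: ObservationModel,
) -> TargetModel:
    """Measurement-update with the available views.

    ``observed`` is a list of ``(camera_index, (u, v))`` pairs; cameras
    without a gated detection are simply absent. With no observations at
    all the posterior is set to the prior (the missing-data rule) and the
    frames-without-observation counter is incremented. Otherwise a
    stacked EKF update over the contributing cameras is applied, with
    block-diagonal R and a Joseph-form covariance update that keeps P
    symmetric positive semidefinite.
    """
    observed = list(observed)
    if not observed:
        out = target.copy()
        out.frames_since_observation += 1
        return out

    cam_indices = [ci for ci, _ in observed]
    if len(set(cam_indices)) != len(cam_indices):
        raise ValueError("a camera may contribute at most one observation")
    cams = [obs_model.cameras[ci] for ci in cam_indices]
    y = np.concatenate([np.asarray(px, dtype=float) for _, px in observed])
    h = observation_function(target.state, cams)
    H = observation_jacobian(target.state, cams)
    R = np.diag(np.repeat([obs_model.r_for(ci) for ci in cam_indices], 2))

    P = target.covariance
    S = H @ P @ H.T + R
    try:
        K = np.linalg.solve(S, H @ P).T
    except np.linalg.LinAlgError as exc:
        raise FilterError(
            f"target {target.id}: singular innovation covariance "
            f"(cameras {cam_indices}, cond ~ {np.linalg.cond(S):.3g})"
        ) from exc

    innovation = y - h
    out = target.copy()
    out.state = target.state + K @ innovation
    IKH = np.eye(6) - K @ H
    P_new = IKH @ P @ IKH.T + K @ R @ K.T
    out.covariance = 0.5 * (P_new + P_new.T)
    out.frames_since_observation = 0
    return out
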