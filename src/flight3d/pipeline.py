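"""Per-frame tracking orchestration and batch runs.

Each frame is processed in a fixed order: predict every target, run NNSF
association, resolve shared assignments (merge prevention), EKF-update
each target with its claimed features (an empty assignment carries the
prior forward), spawn new targets from still-unclaimed features by
triangulation hypothesis testing, then retire targets whose uncertainty
has grown past threshold. The per-frame posterior states are assembled
into one :class:`Trajectory` per target identity.

Everything here is deterministic: re-running on identical inputs yields
bit-identical output, and re-tracking from saved 2D feature tables
reproduces the original 3D trajectories exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import ekf
from .association import GatingParams
from .ekf import ObservationModel, ProcessModel, TargetModel
from .features import FeaturePoint
from .geometry import CameraModel

__all__ = [
    "FrameBundle",
    "Trajectory",
    "TrackerConfig",
    "Tracker",
    "step",
    "run",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "load_feature_table",
    "save_feature_table",
    "bundles_from_table",
    "load_config",
    "save_config",
]

FEATURE_COLUMNS = ["frame", "camera_id", "u", "v", "alpha", "beta", "theta", "epsilon"]
TRAJECTORY_COLUMNS = ["target_id", "frame", "x", "y", "z", "vx", "vy", "vz", "ptrace", "ncams"]


@dataclass
class FrameBundle:
    """All features of one frame, keyed per camera (same order as the rig)."""

    frame_index: int
    features: list[list[FeaturePoint]]

    def n_features(self) -> int:
        return sum(len(f) for f in self.features)


@dataclass
class Trajectory:
    """Posterior track of one target identity.

    ``frames`` holds ``(frame_index, state, ptrace, ncams)`` tuples with
    strictly increasing, contiguous frame indices from birth to
    retirement; ``state`` is the posterior 6-vector.
    """

    target_id: int
    frames: list[tuple[int, np.ndarray, float, int]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=int)

    @property
    def states(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames])

    @property
    def positions(self) -> np.ndarray:
        return self.states[:, :3]


@dataclass
class TrackerConfig:
    """Every tunable of the tracker, in one serializable bundle."""

    dt: float = 0.01
    q_pos: float = ekf.DEFAULT_Q_POS
    q_vel: float = ekf.DEFAULT_Q_VEL
    r_px: float = ekf.DEFAULT_R_PX
    init_pos_var: float = ekf.DEFAULT_INIT_POS_VAR
    init_vel_var: float = ekf.DEFAULT_INIT_VEL_VAR
    max_pixel_dist: float = 20.0
    min_area: float = 1.0
    max_reproj_error_birth: float = 3.0
    max_covariance_trace_death: float = 0.1
    max_frames_unobserved: int = 20
    max_birth_combinations: int = 10_000

    def gating(self) -> GatingParams:
        return GatingParams(
            max_pixel_dist=self.max_pixel_dist,
            min_area=self.min_area,
            max_reproj_error_birth=self.max_reproj_error_birth,
            max_covariance_trace_death=self.max_covariance_trace_death,
            max_frames_unobserved=self.max_frames_unobserved,
            max_birth_combinations=self.max_birth_combinations,
        )

    def process(self) -> ProcessModel:
        return ProcessModel(dt=self.dt, q_pos=self.q_pos, q_vel=self.q_vel)


def step(
    targets: list[TargetModel],
    bundle: FrameBundle,
    cameras: list[CameraModel],
    process: ProcessModel,
    obs_model: ObservationModel,
    params: GatingParams,
    next_id: int,
    config: TrackerConfig | None = None,
):
    """Advance the tracker by one frame.

    Returns ``(targets, next_id, events, records)`` where ``events`` is a
    dict with ``births`` and ``deaths`` (lists of target ids) and
    ``records`` maps target id to ``(state, ptrace, ncams)`` posteriors
    for this frame (newborn targets included with their initial state).
    """
    config = config or TrackerConfig()
    # 1. predict
    predicted = [ekf.predict(t, process) for t in targets]

    # 2. associate + 3. resolve shared
    assignments = assoc.associate(predicted, bundle.features, cameras, params)
    assignments = assoc.resolve_shared(predicted, assignments, cameras, bundle.features)

    # 4. EKF update (empty assignment ==> prior carried forward)
    updated: list[TargetModel] = []
    records: dict[int, tuple[np.ndarray, float, int]] = {}
    claimed: set[tuple[int, int]] = set()
    for target, av in zip(predicted, assignments):
        observed = [
            (ci, bundle.features[ci][fi].pixel)
            for ci, fi in enumerate(av.entries)
            if fi is not None
        ]
        claimed |= av.claimed_set()
        post = ekf.update(target, observed, obs_model)
        updated.append(post)
        records[post.id] = (
            post.state.copy(),
            float(np.trace(post.position_covariance)),
            len(observed),
        )

    # 5. spawn from unclaimed features
    unclaimed = [
        [f for fi, f in enumerate(feats) if (ci, fi) not in claimed]
        for ci, feats in enumerate(bundle.features)
    ]
    born = assoc.spawn_targets(
        unclaimed,
        cameras,
        params,
        next_id,
        birth_frame=bundle.frame_index,
        init_pos_var=config.init_pos_var,
        init_vel_var=config.init_vel_var,
    )
    next_id += len(born)
    for t in born:
        records[t.id] = (
            t.state.copy(),
            float(np.trace(t.position_covariance)),
            0,
        )
    updated.extend(born)

    # 6. retire
    kept, retired = assoc.retire_targets(updated, params)
    events = {
        "births": [t.id for t in born],
        "deaths": [t.id for t in retired],
        "assignments": {
            t.id: av.claimed_set() for t, av in zip(predicted, assignments)
        },
    }
    # a retired target's final frame is still recorded above
    return kept, next_id, events, records


class Tracker:
    """Stateful frame-by-frame multi-target tracker over a fixed rig."""

    def __init__(self, cameras: list[CameraModel], config: TrackerConfig | None = None):
        self.cameras = cameras
        self.config = config or TrackerConfig()
        self.process = self.config.process()
        self.obs_model = ObservationModel(cameras=cameras, r_px=self.config.r_px)
        self.params = self.config.gating()
        self.targets: list[TargetModel] = []
        self.next_id = 0
        self.trajectories: dict[int, Trajectory] = {}
        self.log = {"frames": 0, "features": 0, "births": 0, "deaths": 0}

    def step(self, bundle: FrameBundle) -> dict:
        self.targets, self.next_id, events, records = step(
            self.targets,
            bundle,
            self.cameras,
            self.process,
            self.obs_model,
            self.params,
            self.next_id,
            self.config,
        )
        for tid, (state, ptrace, ncams) in sorted(records.items()):
            traj = self.trajectories.setdefault(tid, Trajectory(target_id=tid))
            traj.frames.append((bundle.frame_index, state, ptrace, ncams))
        self.log["frames"] += 1
        self.log["features"] += bundle.n_features()
        self.log["births"] += len(events["births"])
        self.log["deaths"] += len(events["deaths"])
        return events

    def run(self, bundles) -> list[Trajectory]:
        for bundle in bundles:
            self.step(bundle)
        return sorted(self.trajectories.values(), key=lambda t: t.target_id)


def run(
    feature_table: pd.DataFrame,
    cameras: list[CameraModel],
    config: TrackerConfig | None = None,
) -> tuple[list[Trajectory], dict]:
    """Track a whole feature table; returns (trajectories, run log)."""
    tracker = Tracker(cameras, config)
    trajectories = tracker.run(bundles_from_table(feature_table, cameras))
    return trajectories, dict(tracker.log)


# ---------------------------------------------------------------------------
# Tables and config I/O
# ---------------------------------------------------------------------------


def save_feature_table(features, path) -> None:
    """Write a feature CSV with columns frame,camera_id,u,v,alpha,beta,theta,epsilon."""
    rows = [
        (f.frame_index, f.camera_id, f.u, f.v, f.alpha, f.beta, f.theta, f.epsilon)
        for f in features
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"camera_id": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path}: missing columns {sorted(missing)}")
    return df


def bundles_from_table(df: pd.DataFrame, cameras: list[CameraModel]):
    """Yield dense FrameBundles (one per frame index, gaps included) from a
    feature table. Unknown camera ids fail fast."""
    cam_index = {c.id: i for i, c in enumerate(cameras)}
    unknown = set(df["camera_id"].astype(str)) - set(cam_index)
    if unknown:
        raise ValueError(f"feature table references unknown cameras: {sorted(unknown)}")
    if len(df) == 0:
        return
    by_frame = {int(k): g for k, g in df.groupby("frame")}
    first, last = min(by_frame), max(by_frame)
    for fidx in range(first, last + 1):
        feats: list[list[FeaturePoint]] = [[] for _ in cameras]
        g = by_frame.get(fidx)
        if g is not None:
            for row in g.itertuples(index=False):
                feats[cam_index[str(row.camera_id)]].append(
                    FeaturePoint(
                        u=float(row.u),
                        v=float(row.v),
                        alpha=float(row.alpha),
                        beta=float(row.beta),
                        theta=float(row.theta),
                        epsilon=float(row.epsilon),
                        camera_id=str(row.camera_id),
                        frame_index=fidx,
                    )
                )
        yield FrameBundle(frame_index=fidx, features=feats)


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    """Flatten trajectories into the output table
    ``target_id,frame,x,y,z,vx,vy,vz,ptrace,ncams``."""
    rows = []
    for traj in trajectories:
        for fidx, state, ptrace, ncams in traj.frames:
            rows.append((traj.target_id, fidx, *state, ptrace, ncams))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for tid, g in df.groupby("target_id"):
        g = g.sort_values("frame")
        traj = Trajectory(target_id=int(tid))
        for row in g.itertuples(index=False):
            state = np.array([row.x, row.y, row.z, row.vx, row.vy, row.vz])
            traj.frames.append((int(row.frame), state, float(row.ptrace), int(row.ncams)))
        out.append(traj)
    return out


def save_trajectories_hdf5(trajectories, path) -> None:
    """Optional HDF5 container mirroring the CSV schema."""
    import h5py

    df = trajectories_to_frame(trajectories)
    with h5py.File(path, "w") as fh:
        for col in TRAJECTORY_COLUMNS:
            fh.create_dataset(col, data=df[col].to_numpy())


def save_config(config: TrackerConfig, path) -> None:
    """Write the tracker config as ``key = value`` text."""
    with open(path, "w") as fh:
        for key, val in vars(config).items():
            fh.write(f"{key} = {val!r}\n")


def load_config(path) -> TrackerConfig:
    """Read a ``key = value`` (or ``key: value``) tracker config file."""
    values = {}
    fields = {f: type(getattr(TrackerConfig(), f)) for f in vars(TrackerConfig())}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            sep = "=" if "=" in line else ":"
            if sep not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split(sep, 1))
            if key not in fields:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            values[key] = fields[key](float(val)) if fields[key] in (int, float) else val
    return TrackerConfig(**values)
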