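"""Nearest-neighbour standard filter (NNSF) data association.

Each tracked target independently claims, per camera, the single feature
that maximizes a gated likelihood. The likelihood is a product of three
factors evaluated in order of cost: (1) an image-plane distance gate
around the predicted projection, (2) a blob-area gate, and (3) a
Gaussian kernel of the Mahalanobis distance — under the prior positional
covariance — from the prior 3D position to the closest point on the
feature's back-projected ray. If either cheap gate is zero the ray term
is never computed.

The module also handles track merging prevention (two targets may never
keep an identical non-empty feature set), track birth by exhaustive
triangulation hypothesis testing over camera combinations, and track
death when the positional covariance grows past a threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ekf import (
    DEFAULT_INIT_POS_VAR,
    DEFAULT_INIT_VEL_VAR,
    TargetModel,
)
from .features import FeaturePoint
from .geometry import CameraModel, GeometryError, Ray, project, ray_from_pixel, triangulate

__all__ = [
    "AssignmentVector",
    "GatingParams",
    "pixel_gate",
    "area_gate",
    "closest_point_on_ray",
    "mahalanobis_distance",
    "feature_likelihood",
    "associate",
    "resolve_shared",
    "spawn_targets",
    "retire_targets",
]


@dataclass
class AssignmentVector:
    """Per-target assignment ``d``: one entry per camera, each ``None``
    or the index of the claimed feature in that camera's feature list."""

    entries: list[int | None]

    @property
    def n_assigned(self) -> int:
        return sum(e is not None for e in self.entries)

    def claimed_set(self) -> frozenset[tuple[int, int]]:
        """The set of (camera_index, feature_index) pairs claimed."""
        return frozenset(
            (ci, fi) for ci, fi in enumerate(self.entries) if fi is not None
        )

    @classmethod
    def empty(cls, n_cameras: int) -> "AssignmentVector":
        return cls(entries=[None] * n_cameras)


@dataclass
class GatingParams:
    """Association and track-lifecycle thresholds.

    All "arbitrary threshold" knobs of the method live here: the pixel
    gate radius around the predicted projection, the minimum blob area,
    the maximum reprojection error for a birth hypothesis, the positional
    covariance trace and unobserved-frame count that kill a track, and a
    cap on birth combinations examined per frame.
    """

    max_pixel_dist: float = 20.0          # px
    min_area: float = 1.0                 # px^2
    max_reproj_error_birth: float = 3.0   # px
    max_covariance_trace_death: float = 0.1   # m^2 (positional 3x3 block)
    max_frames_unobserved: int = 20
    max_birth_combinations: int = 10_000

    def __post_init__(self) -> None:
        for name in ("max_pixel_dist", "min_area", "max_reproj_error_birth",
                     "max_covariance_trace_death"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def pixel_gate(feature: FeaturePoint, predicted_pixel, params: GatingParams) -> int:
    """1 iff the detection is within ``max_pixel_dist`` (inclusive) of the
    predicted image position."""
    d = np.linalg.norm(feature.pixel - np.asarray(predicted_pixel, dtype=float))
    return 1 if d <= params.max_pixel_dist else 0


def area_gate(feature: FeaturePoint, params: GatingParams) -> int:
    """1 iff the blob area strictly exceeds ``min_area``."""
    return 1 if feature.alpha > params.min_area else 0


def closest_point_on_ray(ray: Ray, mean, cov) -> np.ndarray:
    """Point on the ray minimizing Mahalanobis distance to ``mean``.

    The squared distance is quadratic in the ray parameter s, so the
    minimizer is closed-form: ``s* = d^T S^-1 (mean - o) / (d^T S^-1 d)``.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        Sinv_d = np.linalg.solve(cov, ray.direction)
        Sinv_r = np.linalg.solve(cov, mean - ray.origin)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance in ray-distance computation") from exc
    denom = ray.direction @ Sinv_d
    if denom <= 0:
        raise ValueError("covariance not positive-definite along ray direction")
    s_star = (ray.direction @ Sinv_r) / denom
    return ray.point_at(s_star)


def mahalanobis_distance(a, mean, cov) -> float:
    """``sqrt((a - mean)^T cov^-1 (a - mean))`` for positive-definite cov."""
    r = np.asarray(a, dtype=float) - np.asarray(mean, dtype=float)
    try:
        x = np.linalg.solve(np.asarray(cov, dtype=float), r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance in Mahalanobis distance") from exc
    d2 = float(r @ x)
    return float(np.sqrt(max(d2, 0.0)))


def feature_likelihood(
    feature: FeaturePoint,
    target_prior: TargetModel,
    camera: CameraModel,
    params: GatingParams,
    stats: dict | None = None,
) -> float:
    """Gated likelihood of one feature given one target's prior.

    Product of pixel gate, area gate and ``exp(-d_mahal^2 / 2)`` of the
    closest ray point to the prior mean under the prior's 3x3 positional
    covariance. Zero gates short-circuit: the ray term is only evaluated
    when both gates pass (pass a ``stats`` dict to count evaluations
    under key ``"ray_terms"``).
    """
    try:
        predicted = project(camera, target_prior.position)
    except GeometryError:
        return 0.0
    if pixel_gate(feature, predicted, params) == 0:
        return 0.0
    if area_gate(feature, params) == 0:
        return 0.0
    if stats is not None:
        stats["ray_terms"] = stats.get("ray_terms", 0) + 1
    ray = ray_from_pixel(camera, feature.pixel)
    closest = closest_point_on_ray(ray, target_prior.position,
                                   target_prior.position_covariance)
    d = mahalanobis_distance(closest, target_prior.position,
                             target_prior.position_covariance)
    return float(np.exp(-0.5 * d * d))


def associate(
    targets: list[TargetModel],
    features_by_camera: list[list[FeaturePoint]],
    cameras: list[CameraModel],
    params: GatingParams,
) -> list[AssignmentVector]:
    """NNSF assignment: independently per target and per camera, pick the
    feature index with the highest positive likelihood, else null."""
    assignments = []
    for target in targets:
        entries: list[int | None] = []
        for ci, cam in enumerate(cameras):
            best_idx, best_score = None, 0.0
            for fi, feat in enumerate(features_by_camera[ci]):
                score = feature_likelihood(feat, target, cam, params)
                if score > best_score:
                    best_idx, best_score = fi, score
            entries.append(best_idx)
        assignments.append(AssignmentVector(entries=entries))
    return assignments


def resolve_shared(
    targets: list[TargetModel],
    assignments: list[AssignmentVector],
    cameras: list[CameraModel],
    features_by_camera: list[list[FeaturePoint]],
) -> list[AssignmentVector]:
    """Prevent trajectory merging: when several targets claim the exact
    same non-empty feature set, only the target whose predicted
    observation is closest (summed image distance) keeps it; the others
    are updated without any observation. Ties go to the lowest target id.
    """
    groups: dict[frozenset, list[int]] = {}
    for ti, av in enumerate(assignments):
        key = av.claimed_set()
        if key:
            groups.setdefault(key, []).append(ti)

    out = list(assignments)
    for key, members in groups.items():
        if len(members) < 2:
            continue

        def summed_distance(ti: int) -> float:
            total = 0.0
            for ci, fi in key:
                feat = features_by_camera[ci][fi]
                predicted = project(cameras[ci], targets[ti].position)
                total += float(np.linalg.norm(feat.pixel - predicted))
            return total

        winner = min(members, key=lambda ti: (summed_distance(ti), targets[ti].id))
        for ti in members:
            if ti != winner:
                out[ti] = AssignmentVector.empty(len(cameras))
    return out


def spawn_targets(
    unclaimed_by_camera: list[list[FeaturePoint]],
    cameras: list[CameraModel],
    params: GatingParams,
    next_id: int,
    birth_frame: int = 0,
    init_pos_var: float = DEFAULT_INIT_POS_VAR,
    init_vel_var: float = DEFAULT_INIT_VEL_VAR,
    stats: dict | None = None,
) -> list[TargetModel]:
    """Unguided hypothesis testing for track birth.

    Every combination of 2..n cameras, with every choice of one unclaimed
    feature per chosen camera, is triangulated. Among hypotheses whose
    mean reprojection error is below ``max_reproj_error_birth``, the one
    using the greatest number of cameras wins (ties: lowest error); it
    becomes a new target at the triangulated point with zero velocity and
    a deliberately large initial covariance. Its features are removed and
    the search repeats until no valid hypothesis remains. The number of
    combinations examined per frame is capped at
    ``max_birth_combinations``; overflow is deferred to the next frame.
    """
    pools: list[list[tuple[int, FeaturePoint]]] = [
        [(fi, f) for fi, f in enumerate(feats)] for feats in unclaimed_by_camera
    ]
    born: list[TargetModel] = []
    budget = params.max_birth_combinations

    while True:
        best = None  # (n_cams, -err) maximized -> store (n_cams, err, combo, point)
        active = [ci for ci in range(len(cameras)) if pools[ci]]
        if len(active) < 2:
            break
        exhausted = False
        for k in range(2, len(active) + 1):
            for cam_combo in itertools.combinations(active, k):
                for choice in itertools.product(*(pools[ci] for ci in cam_combo)):
                    if budget <= 0:
                        exhausted = True
                        break
                    budget -= 1
                    if stats is not None:
                        stats["hypotheses"] = stats.get("hypotheses", 0) + 1
                    obs = [
                        (cameras[ci], feat.pixel)
                        for ci, (_, feat) in zip(cam_combo, choice)
                    ]
                    try:
                        point, err = triangulate(obs)
                    except GeometryError:
                        continue
                    if err >= params.max_reproj_error_birth:
                        continue
                    if best is None or (k, -err) > (best[0], -best[1]):
                        best = (k, err, cam_combo, choice, point)
                if exhausted:
                    break
            if exhausted:
                break
        if best is None:
            break
        k, err, cam_combo, choice, point = best
        state = np.concatenate([point, np.zeros(3)])
        cov = np.diag([init_pos_var] * 3 + [init_vel_var] * 3)
        born.append(
            TargetModel(
                id=next_id,
                state=state,
                covariance=cov,
                birth_frame=birth_frame,
            )
        )
        next_id += 1
        for ci, (fi, _) in zip(cam_combo, choice):
            pools[ci] = [(j, f) for (j, f) in pools[ci] if j != fi]
        if exhausted:
            break
    return born


def retire_targets(
    targets: list[TargetModel], params: GatingParams
) -> tuple[list[TargetModel], list[TargetModel]]:
    """Split targets into (kept, retired).

    A target dies when the trace of its positional covariance block
    exceeds ``max_covariance_trace_death`` or it has gone more than
    ``max_frames_unobserved`` frames without an observation. Retirement
    is permanent: a re-detected animal starts a new identity.
    """
    kept, retired = [], []
    for t in targets:
        trace = float(np.trace(t.position_covariance))
        if trace > params.max_covariance_trace_death or (
            t.frames_since_observation > params.max_frames_unobserved
        ):
            retired.append(t)
        else:
            kept.append(t)
    return kept, retired
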