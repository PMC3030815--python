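"""Two-dimensional feature extraction by background subtraction.

Moving targets are detected against a per-pixel running-Gaussian
background model: an absolute difference image is thresholded, each
connected suprathreshold region is analysed in a small window around its
brightest pixel, and image moments of the (noise-cleared) difference
mass yield the sub-pixel centre, area, orientation and eccentricity of
the blob. Each detection is summarized as the 6-vector
``z = (u, v, alpha, beta, theta, epsilon)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import CameraModel, undistort

__all__ = [
    "BackgroundModel",
    "FeaturePoint",
    "ExtractionParams",
    "update_background",
    "extract_features",
    "moment_statistics",
]

# 8-connectivity for connected-component labelling
_STRUCTURE8 = np.ones((3, 3), dtype=bool)


@dataclass
class BackgroundModel:
    """Per-pixel running-Gaussian estimate of the static scene.

    ``mean`` and ``variance`` are float images of the background
    luminance; they are refreshed from every ``update_interval``-th frame
    (default 500) with exponential forgetting rate ``learning_rate``,
    which lets the model follow slow illumination drift.
    """

    mean: np.ndarray
    variance: np.ndarray
    update_interval: int = 500
    learning_rate: float = 0.25

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean/variance shape mismatch")
        if np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")

    @classmethod
    def from_frame(cls, frame, **kwargs) -> "BackgroundModel":
        frame = np.asarray(frame, dtype=float)
        return cls(mean=frame.copy(), variance=np.zeros_like(frame), **kwargs)


@dataclass(frozen=True)
class FeaturePoint:
    """One detected blob: distortion-corrected centre ``(u, v)``, area
    ``alpha`` (0th moment of cleared difference mass, px^2-weighted
    luminance), peak absolute difference ``beta``, principal-axis angle
    ``theta`` in [0, pi) and eccentricity ``epsilon >= 0``."""

    u: float
    v: float
    alpha: float
    beta: float
    theta: float
    epsilon: float
    camera_id: str = ""
    frame_index: int = -1

    @property
    def pixel(self) -> np.ndarray:
        return np.array([self.u, self.v])


@dataclass(frozen=True)
class ExtractionParams:
    """Detection knobs.

    ``detect_threshold`` is the absolute-difference value a pixel must
    exceed to seed a candidate (or the multiple of the per-pixel
    background sigma when ``threshold_mode='sigma'``); ``clear_fraction``
    zeroes window pixels below that fraction of the blob peak before
    moments are taken; ``roi_radius`` is the half-size of the square
    analysis window.
    """

    detect_threshold: float = 10.0
    clear_fraction: float = 0.3
    roi_radius: int = 7
    max_features_per_camera: int = 10
    threshold_mode: str = "absolute"  # or "sigma"

    def __post_init__(self) -> None:
        if not (0.0 < self.clear_fraction < 1.0):
            raise ValueError("clear_fraction must be in (0, 1)")
        if self.detect_threshold <= 0:
            raise ValueError("detect_threshold must be positive")
        if self.threshold_mode not in ("absolute", "sigma"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def update_background(bg: BackgroundModel, frame, frame_index: int | None = None) -> BackgroundModel:
    """Return the background model refreshed with ``frame``.

    The exponential update ``mean <- (1 - lam) mean + lam frame`` (and the
    analogous update of the variance on squared residuals) is applied only
    when ``frame_index`` is a multiple of ``update_interval``; pass
    ``frame_index=None`` to force an update.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != bg.mean.shape:
        raise ValueError(f"frame shape {frame.shape} != background {bg.mean.shape}")
    if frame_index is not None and frame_index % bg.update_interval != 0:
        return bg
    lam = bg.learning_rate
    resid = frame - bg.mean
    new_mean = bg.mean + lam * resid
    new_var = (1.0 - lam) * bg.variance + lam * resid**2
    return replace(bg, mean=new_mean, variance=new_var)


def moment_statistics(patch, origin=(0.0, 0.0)):
    """Image-moment summary of a non-negative intensity patch.

    Parameters
    ----------
    patch:
        2D array indexed ``[v, u]`` (row = v, column = u), non-negative
        and not all zero.
    origin:
        ``(u0, v0)`` image coordinates of ``patch[0, 0]``; the returned
        centre is expressed in image coordinates.

    Returns
    -------
    alpha, centre, theta, epsilon:
        0th moment; intensity centroid ``(u, v)``; principal-axis angle
        ``theta = atan2(2 mu11, mu20 - mu02) / 2`` mapped to [0, pi);
        eccentricity ``sqrt(1 - l2/l1)`` from the eigenvalues
        ``l1 >= l2`` of the central second-moment matrix (0 for a blob
        that is symmetric or a single pixel).
    """
    patch = np.asarray(patch, dtype=float)
    if np.any(patch < 0):
        raise ValueError("patch must be non-negative")
    alpha = float(patch.sum())
    if alpha == 0:
        raise ValueError("all-zero patch has no moments")
    v_idx, u_idx = np.nonzero(patch)
    w = patch[v_idx, u_idx]
    uc = float((w * u_idx).sum() / alpha)
    vc = float((w * v_idx).sum() / alpha)
    du = u_idx - uc
    dv = v_idx - vc
    mu20 = float((w * du * du).sum() / alpha)
    mu02 = float((w * dv * dv).sum() / alpha)
    mu11 = float((w * du * dv).sum() / alpha)

    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    theta = float(np.mod(theta, np.pi))

    tr = mu20 + mu02
    det = mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + np.sqrt(disc)
    l2 = tr / 2.0 - np.sqrt(disc)
    if l1 <= 1e-12:
        epsilon = 0.0  # single pixel / degenerate: no shape information
    else:
        epsilon = float(np.sqrt(max(1.0 - l2 / l1, 0.0)))
    centre = np.array([uc + origin[0], vc + origin[1]])
    return alpha, centre, theta, epsilon


def extract_features(
    frame,
    bg: BackgroundModel,
    params: ExtractionParams,
    camera: CameraModel | None = None,
    frame_index: int = -1,
) -> list[FeaturePoint]:
    """Detect moving blobs in ``frame`` against the background model.

    Pipeline: absolute difference image -> threshold -> 8-connected
    components -> per component, analyse a square window of radius
    ``roi_radius`` around the brightest difference pixel, zeroing pixels
    below ``clear_fraction * beta`` -> image moments -> distortion
    correction of the centre through ``camera`` (identity if no camera
    or no distortion model). Features are returned sorted by peak
    difference ``beta`` descending, at most ``max_features_per_camera``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != bg.mean.shape:
        raise ValueError(f"frame shape {frame.shape} != background {bg.mean.shape}")
    absdiff = np.abs(frame - bg.mean)
    if params.threshold_mode == "sigma":
        thresh = params.detect_threshold * np.sqrt(bg.variance)
        mask = absdiff > np.maximum(thresh, 1e-12)
    else:
        mask = absdiff > params.detect_threshold
    if not mask.any():
        return []

    labels, n_labels = ndimage.label(mask, structure=_STRUCTURE8)
    h, w = frame.shape
    r = params.roi_radius
    feats: list[FeaturePoint] = []
    # Brightest difference pixel of each component seeds its analysis window.
    peaks = ndimage.maximum_position(absdiff, labels, range(1, n_labels + 1))
    for (pv, pu) in peaks:
        beta = float(absdiff[pv, pu])
        v0, v1 = max(pv - r, 0), min(pv + r + 1, h)
        u0, u1 = max(pu - r, 0), min(pu + r + 1, w)
        window = absdiff[v0:v1, u0:u1].copy()
        window[window < params.clear_fraction * beta] = 0.0
        if window.sum() == 0:
            continue
        alpha, centre, theta, eps = moment_statistics(window, origin=(u0, v0))
        if camera is not None:
            centre = undistort(camera, centre)
        feats.append(
            FeaturePoint(
                u=float(centre[0]),
                v=float(centre[1]),
                alpha=alpha,
                beta=beta,
                theta=theta,
                epsilon=eps,
                camera_id=camera.id if camera is not None else "",
                frame_index=frame_index,
            )
        )
    feats.sort(key=lambda f: -f.beta)
    return feats[: params.max_features_per_camera]
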