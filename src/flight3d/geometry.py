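"""Projective camera geometry: pinhole model, radial distortion, rays,
linear triangulation and DLT calibration.

Conventions
-----------
* Pixel coordinates are continuous, with (0, 0) at the centre of the
  top-left pixel, ``u`` increasing rightward and ``v`` downward.
* The world frame is right-handed, in metres, ``z`` up.
* A camera is a 3x4 projection matrix ``P`` (arbitrary scale) with an
  optional two-term radial distortion ``r_d = r (1 + k1 r^2 + k2 r^4)``
  about an explicit distortion centre. All geometric operations work in
  the *ideal* (distortion-corrected) pixel frame; :func:`distort` and
  :func:`undistort` move points between the raw and ideal frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "RadialDistortion",
    "CameraModel",
    "Ray",
    "project",
    "distort",
    "undistort",
    "ray_from_pixel",
    "triangulate",
    "dlt_calibrate",
    "load_cameras",
    "save_cameras",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric configurations."""


@dataclass(frozen=True)
class RadialDistortion:
    """Two-term radial lens distortion about an explicit centre.

    The model maps an *ideal* radius to a *distorted* radius,
    ``r_d = r (1 + k1 r^2 + k2 r^4)``, with ``r`` measured in pixels
    from the centre ``(cx, cy)``. With ``k1 = k2 = 0`` both directions
    are the identity.
    """

    k1: float = 0.0
    k2: float = 0.0
    cx: float = 0.0
    cy: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.k1 == 0.0 and self.k2 == 0.0


@dataclass
class CameraModel:
    """One calibrated camera: label, 3x4 projection matrix, optional
    radial distortion and image size ``(width, height)`` in pixels."""

    id: str
    P: np.ndarray
    distortion: RadialDistortion | None = None
    image_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (3, 4):
            raise ValueError(f"projection matrix must be 3x4, got {self.P.shape}")
        if np.linalg.matrix_rank(self.P, tol=1e-10 * np.linalg.norm(self.P)) < 3:
            raise GeometryError(f"camera {self.id!r}: projection matrix is rank-deficient")

    @property
    def center(self) -> np.ndarray:
        """Camera centre C (3-vector, metres): the null space of P."""
        _, _, vt = np.linalg.svd(self.P)
        c = vt[-1]
        if abs(c[3]) < 1e-14 * np.linalg.norm(c[:3]):
            raise GeometryError(f"camera {self.id!r}: centre at infinity")
        return c[:3] / c[3]


@dataclass(frozen=True)
class Ray:
    """Half-line ``L(s) = origin + s * direction`` with unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("ray direction must be nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction


def project(camera: CameraModel, point) -> np.ndarray:
    """Project a 3D world point to ideal (distortion-corrected) pixels.

    Returns the dehomogenized product ``P @ (x, y, z, 1)``. Raises
    :class:`GeometryError` when the point lies in the camera's principal
    plane (depth coordinate numerically zero), where projection is
    undefined.
    """
    point = np.asarray(point, dtype=float)
    x = camera.P @ np.append(point, 1.0)
    w = x[2]
    if abs(w) < 1e-12 * max(1.0, np.linalg.norm(x[:2])):
        raise GeometryError(
            f"camera {camera.id!r}: point {point} projects to infinity (principal plane)"
        )
    return x[:2] / w


def distort(camera: CameraModel, ideal) -> np.ndarray:
    """Map an ideal pixel position to the raw (distorted) image frame."""
    d = camera.distortion or RadialDistortion()
    p = np.asarray(ideal, dtype=float)
    dc = np.array([d.cx, d.cy])
    rel = p - dc
    r2 = float(rel @ rel)
    factor = 1.0 + d.k1 * r2 + d.k2 * r2 * r2
    return dc + rel * factor


def undistort(camera: CameraModel, raw, tol: float = 1e-8, max_iter: int = 20) -> np.ndarray:
    """Map a raw pixel position to the ideal frame by inverting the
    radial model with fixed-point iteration.

    Iterates ``rel <- raw_rel / (1 + k1 r^2 + k2 r^4)`` evaluated at the
    current ideal estimate, starting from the raw point. Converges for
    the mild distortions typical of machine-vision lenses; raises
    :class:`GeometryError` with diagnostics if ``max_iter`` iterations
    do not reach ``tol`` pixels.
    """
    d = camera.distortion or RadialDistortion()
    p = np.asarray(raw, dtype=float)
    if d.is_identity:
        return p.copy()
    dc = np.array([d.cx, d.cy])
    raw_rel = p - dc
    rel = raw_rel.copy()
    for _ in range(max_iter):
        r2 = float(rel @ rel)
        new = raw_rel / (1.0 + d.k1 * r2 + d.k2 * r2 * r2)
        step = np.linalg.norm(new - rel)
        rel = new
        if step < tol:
            return dc + rel
    raise GeometryError(
        f"camera {camera.id!r}: undistortion did not converge for {p} "
        f"(last step {step:.3g} px after {max_iter} iterations)"
    )


def ray_from_pixel(camera: CameraModel, pixel) -> Ray:
    """Back-project an ideal pixel to the 3D ray through the camera centre.

    The returned ray satisfies ``project(camera, ray.point_at(s)) == pixel``
    for every ``s > 0``.
    """
    pixel = np.asarray(pixel, dtype=float)
    origin = camera.center
    # Any finite point projecting to the pixel: pseudo-inverse solution.
    X = np.linalg.pinv(camera.P) @ np.append(pixel, 1.0)
    M = camera.P[:, :3]
    if abs(X[3]) > 1e-12 * np.linalg.norm(X[:3]):
        direction = X[:3] / X[3] - origin
    else:  # pseudo-inverse point at infinity: its first 3 coords are a direction
        direction = X[:3]
    # Orient so that depth along the ray is positive for the matrix as given.
    if (M @ direction)[2] < 0:
        direction = -direction
    return Ray(origin=origin, direction=direction)


def triangulate(observations) -> tuple[np.ndarray, float]:
    """Linear least-squares (DLT) triangulation from >= 2 camera views.

    Parameters
    ----------
    observations:
        Sequence of ``(CameraModel, (u, v))`` pairs with ideal pixel
        coordinates from distinct cameras.

    Returns
    -------
    point, error:
        The 3D point minimizing the stacked algebraic cross-product
        constraints, and the mean Euclidean reprojection error (pixels)
        across the contributing cameras.
    """
    observations = list(observations)
    if len(observations) < 2:
        raise GeometryError(f"triangulation needs >= 2 views, got {len(observations)}")
    rows = []
    for camera, pixel in observations:
        u, v = np.asarray(pixel, dtype=float)
        P = camera.P / np.linalg.norm(camera.P)
        rows.append(u * P[2] - P[0])
        rows.append(v * P[2] - P[1])
    A = np.asarray(rows)
    _, _, vt = np.linalg.svd(A)
    X = vt[-1]
    if abs(X[3]) < 1e-12 * np.linalg.norm(X[:3]):
        raise GeometryError("triangulation degenerate (parallel rays or point at infinity)")
    point = X[:3] / X[3]
    errs = [
        float(np.linalg.norm(project(camera, point) - np.asarray(pixel, dtype=float)))
        for camera, pixel in observations
    ]
    return point, float(np.mean(errs))


def dlt_calibrate(correspondences, camera_id: str = "dlt") -> CameraModel:
    """Estimate a 3x4 projection matrix from 3D-2D correspondences by the
    direct linear transformation with Hartley-style normalization.

    Requires at least 6 non-coplanar world points. The returned matrix is
    scaled to unit Frobenius norm.
    """
    correspondences = list(correspondences)
    n = len(correspondences)
    if n < 6:
        raise GeometryError(f"DLT calibration needs >= 6 correspondences, got {n}")
    X = np.asarray([np.asarray(p3, dtype=float) for p3, _ in correspondences])
    x = np.asarray([np.asarray(p2, dtype=float) for _, p2 in correspondences])

    scatter = np.cov(X.T)
    eigvals = np.linalg.eigvalsh(scatter)
    if eigvals[0] < 1e-10 * max(eigvals[-1], 1e-30):
        raise GeometryError("DLT calibration degenerate: world points are coplanar")

    # Similarity normalization of both point sets conditions the system.
    def _normalize(pts, target):
        centroid = pts.mean(axis=0)
        rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
        scale = target / rms if rms > 0 else 1.0
        dim = pts.shape[1]
        T = np.eye(dim + 1)
        T[:dim, :dim] *= scale
        T[:dim, dim] = -scale * centroid
        return (pts - centroid) * scale, T

    Xn, T3 = _normalize(X, np.sqrt(3.0))
    xn, T2 = _normalize(x, np.sqrt(2.0))

    rows = []
    for (Xi, xi) in zip(Xn, xn):
        Xh = np.append(Xi, 1.0)
        u, v = xi
        rows.append(np.concatenate([Xh, np.zeros(4), -u * Xh]))
        rows.append(np.concatenate([np.zeros(4), Xh, -v * Xh]))
    A = np.asarray(rows)
    _, _, vt = np.linalg.svd(A)
    Pn = vt[-1].reshape(3, 4)
    P = np.linalg.inv(T2) @ Pn @ T3
    P = P / np.linalg.norm(P)
    # Fix the scale sign so reconstructed depths are positive on average.
    depths = (P[2] @ np.hstack([X, np.ones((n, 1))]).T)
    if np.median(depths) < 0:
        P = -P
    return CameraModel(id=camera_id, P=P)


# ---------------------------------------------------------------------------
# Camera file format: plain text, one camera per block.
#
#   camera <id>
#   <p11> <p12> <p13> <p14>
#   <p21> <p22> <p23> <p24>
#   <p31> <p32> <p33> <p34>
#   [distortion <k1> <k2> <cx> <cy>]
#   [image_size <width> <height>]
# ---------------------------------------------------------------------------


def save_cameras(cameras, path) -> None:
    """Write cameras to the plain-text block format (decimal round-trip safe)."""
    lines = []
    for cam in cameras:
        lines.append(f"camera {cam.id}")
        for row in cam.P:
            lines.append(" ".join(repr(float(x)) for x in row))
        if cam.distortion is not None:
            d = cam.distortion
            lines.append(
                "distortion "
                + " ".join(repr(float(x)) for x in (d.k1, d.k2, d.cx, d.cy))
            )
        if cam.image_size is not None:
            lines.append(f"image_size {cam.image_size[0]} {cam.image_size[1]}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def load_cameras(path) -> list[CameraModel]:
    """Read cameras from the plain-text block format written by
    :func:`save_cameras`."""
    cameras: list[CameraModel] = []
    cur_id = None
    rows: list[list[float]] = []
    distortion = None
    image_size = None

    def _flush():
        nonlocal cur_id, rows, distortion, image_size
        if cur_id is None:
            return
        if len(rows) != 3:
            raise ValueError(f"camera {cur_id!r}: expected 3 matrix rows, got {len(rows)}")
        cameras.append(
            CameraModel(id=cur_id, P=np.asarray(rows), distortion=distortion,
                        image_size=image_size)
        )
        cur_id, rows, distortion, image_size = None, [], None, None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("camera "):
                _flush()
                cur_id = line.split(None, 1)[1]
            elif line.startswith("distortion "):
                vals = [float(t) for t in line.split()[1:]]
                if len(vals) != 4:
                    raise ValueError(f"line {lineno}: distortion needs k1 k2 cx cy")
                distortion = RadialDistortion(*vals)
            elif line.startswith("image_size "):
                w, h = line.split()[1:3]
                image_size = (int(w), int(h))
            else:
                vals = [float(t) for t in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"line {lineno}: expected 4 matrix entries")
                rows.append(vals)
    _flush()
    return cameras
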