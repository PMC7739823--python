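"""Rigid-body and 3-D line primitives shared across the package.

All lengths are millimetres unless noted.  Rotations are proper (det = +1)
3x3 matrices; lines are stored as a point plus a unit direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raise on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


def canonical_direction(d: np.ndarray) -> np.ndarray:
    """Orient a unit vector so its largest-magnitude component is positive.

    Line directions are sign-ambiguous; a fixed orientation rule keeps
    rotation angles about an axis reproducible across fits.
    """
    d = unit(d)
    i = int(np.argmax(np.abs(d)))
    return -d if d[i] < 0 else d


@dataclass(frozen=True)
class Line3D:
    """An infinite oriented line: ``point + s * direction``."""

    point: np.ndarray
    direction: np.ndarray

    @staticmethod
    def through(point, direction) -> "Line3D":
        return Line3D(np.asarray(point, dtype=float), unit(direction))

    def distance_to_point(self, p) -> float:
        w = np.asarray(p, dtype=float) - self.point
        return float(np.linalg.norm(np.cross(w, self.direction)))


def skew_line_distance(a: Line3D, b: Line3D) -> float:
    """Perpendicular distance between two lines.

    For skew or intersecting lines this is ``|(p_a - p_b) . (d_a x d_b)| /
    ||d_a x d_b||``; parallel lines fall back to the point-to-line distance.
    The result is symmetric in the two arguments.
    """
    n = np.cross(a.direction, b.direction)
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # parallel
        return a.distance_to_point(b.point)
    return float(abs(np.dot(a.point - b.point, n)) / nn)


@dataclass
class RigidPose:
    """Proper rigid transform ``x -> R x + t`` with its fit residual."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_residual_mm: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper orthonormal")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return ``self o other`` (apply *other* first)."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidPose":
        return RigidPose(np.eye(3), np.zeros(3))

    @staticmethod
    def from_rotvec(rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidPose":
        return RigidPose(
            Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix(),
            np.asarray(translation, dtype=float),
        )

    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()


def fit_rigid_pose(reference: np.ndarray, observed: np.ndarray) -> RigidPose:
    """Least-squares rigid pose mapping *reference* markers onto *observed*.

    Solves ``min_R,t sum_i ||R r_i + t - o_i||^2`` by the SVD (Kabsch)
    method with the reflection excluded.  Requires >= 3 matched,
    non-collinear markers.
    """
    ref = np.asarray(reference, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if ref.shape != obs.shape:
        raise ValueError(
            f"marker count mismatch: reference {ref.shape} vs observed {obs.shape}"
        )
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError("need at least 3 markers of dimension 3")
    rc = ref.mean(axis=0)
    oc = obs.mean(axis=0)
    a = ref - rc
    b = obs - oc
    # collinear clusters leave the rotation about the marker line unresolved
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
        raise ValueError("reference markers are collinear; pose is not unique")
    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = oc - R @ rc
    res = obs - (ref @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return RigidPose(R, t, rms)


def finite_helical_axis(pose: RigidPose) -> tuple[np.ndarray, float, np.ndarray]:
    """Screw decomposition of a rigid displacement.

    Returns ``(direction, angle_rad, point)`` where *point* is the point of
    the helical axis closest to the origin.  Raises if the rotation is
    numerically zero (the axis direction is then undefined).
    """
    rv = pose.rotvec()
    angle = float(np.linalg.norm(rv))
    if angle < 1e-10:
        raise ValueError("zero rotation: helical axis undefined")
    n = rv / angle
    # points x on the axis satisfy (R - I) x = d*n - t with d the axial slide
    d = float(np.dot(n, pose.translation))
    A = pose.rotation - np.eye(3)
    rhs = d * n - pose.translation
    # (R - I) has null space span{n}; the min-norm solution is normal to n
    x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return n, angle, x
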