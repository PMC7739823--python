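"""Achilles tendon moment arm from marker kinematics and tendon edge points.

The method mirrors the combined ultrasound/motion-capture protocol: the
foot's motion relative to the shank over a range-of-motion trial is reduced
to a best-fit functional (screw) axis; the tendon's line of action is fitted
through the midpoints of its superficial and deep edges; and the moment arm
in each frame is the perpendicular distance between the two lines.  The
moment arm at the neutral (0 deg) posture comes from a quadratic fit of
moment arm against ankle angle.

Angle convention: the ankle angle of a frame is the rotation about the
functional axis relative to the neutral calibration pose (frame 0 of the
trial), in degrees, with the axis direction canonically oriented
(:func:`tsmm.geometry.canonical_direction`).  Dorsiflexion is positive for
a medial-to-lateral oriented axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    Line3D,
    RigidPose,
    canonical_direction,
    finite_helical_axis,
    fit_rigid_pose,
    skew_line_distance,
)
from .trials import ROMTrial


@dataclass
class FunctionalAxis:
    """Best-fit single rotation axis summarizing a set of displacements."""

    line: Line3D
    direction_spread_deg: float
    n_pairs: int

    @property
    def direction(self) -> np.ndarray:
        return self.line.direction

    @property
    def point(self) -> np.ndarray:
        return self.line.point


@dataclass
class MomentArmCurve:
    angles_deg: np.ndarray
    moment_arms_mm: np.ndarray
    coefficients: tuple  # (c0 mm, c1 mm/deg, c2 mm/deg^2)
    moment_arm_0deg_mm: float


@dataclass
class ROMAnalysis:
    axis: FunctionalAxis
    frames: pd.DataFrame  # angle_deg, moment_arm_mm per frame
    curve: MomentArmCurve


def fit_functional_axis(
    poses: list, min_pair_angle_deg: float = 5.0
) -> FunctionalAxis:
    """Rotation-weighted least-squares axis from a sequence of rigid poses.

    *poses* are foot-in-shank displacements relative to a common neutral
    pose.  Finite helical axes are computed between every pair of poses at
    least ``min_pair_angle_deg`` apart (smaller displacements give
    noise-dominated axes); the axis direction is their rotation-weighted
    mean (renormalized) and the axis point the least-squares closest point
    to all the helical axes.
    """
    if len(poses) < 2:
        raise ValueError("need at least two poses")
    rotvecs = [p.rotvec() for p in poses]
    span = max(np.linalg.norm(rv) for rv in rotvecs)
    if np.degrees(span) < min_pair_angle_deg:
        raise ValueError("insufficient range of motion")

    min_rad = np.radians(min_pair_angle_deg)
    dirs, points, weights = [], [], []
    for i in range(len(poses) - 1):
        inv_i = poses[i].inverse()
        for j in range(i + 1, len(poses)):
            rel = poses[j].compose(inv_i)
            angle = np.linalg.norm(rel.rotvec())
            if angle < min_rad:
                continue
            n, ang, pt = finite_helical_axis(rel)
            dirs.append(n)
            points.append(pt)
            weights.append(ang)
    if not dirs:
        raise ValueError("insufficient range of motion")
    dirs = np.asarray(dirs)
    points = np.asarray(points)
    w = np.asarray(weights)

    # sign-align to the first helical direction before averaging
    signs = np.where(dirs @ dirs[0] < 0, -1.0, 1.0)
    dirs = dirs * signs[:, None]
    mean_dir = (w[:, None] * dirs).sum(axis=0)
    mean_dir = canonical_direction(mean_dir)

    # least-squares point: minimize sum_k w_k * dist(x, axis_k)^2
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for nk, ck, wk in zip(dirs, points, w):
        P = np.eye(3) - np.outer(nk, nk)
        A += wk * P
        b += wk * (P @ ck)
    # pure hinge data leaves the along-axis position unconstrained; the
    # minimum-norm solution picks the axis point closest to the origin
    point, *_ = np.linalg.lstsq(A, b, rcond=None)

    cosines = np.clip(dirs @ mean_dir, -1.0, 1.0)
    spread = float(
        np.degrees(np.sqrt(np.average(np.arccos(cosines) ** 2, weights=w)))
    )
    return FunctionalAxis(
        line=Line3D.through(point, mean_dir),
        direction_spread_deg=spread,
        n_pairs=len(w),
    )


def pose_angle_about_axis(pose: RigidPose, axis: FunctionalAxis) -> float:
    """Signed rotation angle (deg) of a pose about the functional axis."""
    return float(np.degrees(pose.rotvec() @ axis.direction))


def fit_tendon_line(
    superficial: np.ndarray,
    deep: np.ndarray,
    probe_pose: RigidPose,
    shank_pose: RigidPose,
) -> Line3D:
    """Tendon line of action in the shank frame.

    Midpoints of paired superficial/deep edge points (probe frame) are
    mapped probe -> lab -> shank, and the line is the total-least-squares
    fit through them (first principal direction).
    """
    sup = np.asarray(superficial, dtype=float)
    dee = np.asarray(deep, dtype=float)
    if sup.shape != dee.shape or sup.ndim != 2 or sup.shape[0] < 2:
        raise ValueError("need >= 2 paired superficial and deep edge points")
    mid = 0.5 * (sup + dee)
    mid_shank = shank_pose.inverse().apply(probe_pose.apply(mid))
    center = mid_shank.mean(axis=0)
    rel = mid_shank - center
    if np.linalg.norm(rel) < 1e-9:
        raise ValueError("tendon edge midpoints are coincident")
    _, _, vt = np.linalg.svd(rel)
    return Line3D.through(center, canonical_direction(vt[0]))


def compute_moment_arm(line: Line3D, axis) -> float:
    """Perpendicular (skew-line) distance between tendon line and axis, mm."""
    other = axis.line if isinstance(axis, FunctionalAxis) else axis
    return skew_line_distance(line, other)


def moment_arm_at_neutral(
    angles_deg: np.ndarray, moment_arms_mm: np.ndarray
) -> MomentArmCurve:
    """Quadratic fit of moment arm vs. ankle angle, evaluated at 0 deg.

    Requires >= 5 frames with >= 3 distinct angles, and an angle range that
    includes or brackets 0 deg within 5 deg (the constant term is otherwise
    an extrapolation).
    """
    angles = np.asarray(angles_deg, dtype=float)
    arms = np.asarray(moment_arms_mm, dtype=float)
    if angles.shape != arms.shape or angles.size < 5:
        raise ValueError("need at least 5 matched (angle, moment arm) frames")
    if np.unique(angles).size < 3:
        raise ValueError("need at least 3 distinct angles for a quadratic fit")
    if angles.min() > 5.0 or angles.max() < -5.0:
        raise ValueError("angle range must include or bracket 0 deg within 5 deg")
    c2, c1, c0 = np.polyfit(angles, arms, 2)
    return MomentArmCurve(
        angles_deg=angles,
        moment_arms_mm=arms,
        coefficients=(float(c0), float(c1), float(c2)),
        moment_arm_0deg_mm=float(c0),
    )


def analyze_rom_trial(
    trial: ROMTrial, min_pair_angle_deg: float = 5.0
) -> ROMAnalysis:
    """Full moment-arm analysis of a range-of-motion trial.

    Frame 0 is the neutral calibration: cluster poses are fitted relative to
    their frame-0 marker positions, so the shank frame is the lab frame at
    neutral.  Foot-in-shank poses feed the functional-axis fit; per-frame
    tendon lines (in the shank frame) give per-frame moment arms, and the
    neutral moment arm comes from the quadratic fit against ankle angle.
    """
    n = trial.n_frames
    poses = {}
    for name in ("shank", "foot", "probe"):
        ref = trial.markers[name][0]
        poses[name] = [fit_rigid_pose(ref, trial.markers[name][k]) for k in range(n)]

    foot_in_shank = [
        poses["shank"][k].inverse().compose(poses["foot"][k]) for k in range(n)
    ]
    axis = fit_functional_axis(foot_in_shank, min_pair_angle_deg)

    angles = np.empty(n)
    arms = np.empty(n)
    for k in range(n):
        angles[k] = pose_angle_about_axis(foot_in_shank[k], axis)
        line = fit_tendon_line(
            trial.edge_superficial[k],
            trial.edge_deep[k],
            probe_pose=poses["probe"][k],
            shank_pose=poses["shank"][k],
        )
        arms[k] = compute_moment_arm(line, axis)

    curve = moment_arm_at_neutral(angles, arms)
    frames = pd.DataFrame({"angle_deg": angles, "moment_arm_mm": arms})
    return ROMAnalysis(axis=axis, frames=frames, curve=curve)
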