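"""Hinge-like range-of-motion trials with a known functional axis and a
tendon line placed at a prescribed quadratic-in-angle moment arm.

Frame 0 is the neutral calibration (ankle angle 0 deg); the foot cluster
then rotates about the specified axis through a dorsiflexion-to-
plantarflexion sweep.  In every frame the tendon edge points are
constructed so that the perpendicular distance from the fitted tendon line
to the true axis equals ``c0 + c1*theta + c2*theta^2`` exactly (before
noise), making the downstream moment-arm analysis a round trip.

All coordinates in mm; the "shank frame" is the lab frame at neutral.
"""

from __future__ import annotations

import numpy as np

from ..geometry import Line3D, RigidPose, canonical_direction, unit
from ..trials import ROMTrial

# tetrahedral 4-marker cluster templates (mm), deliberately non-planar
_CLUSTER_TEMPLATE = np.array(
    [[0.0, 0.0, 0.0], [80.0, 0.0, 0.0], [0.0, 60.0, 0.0], [30.0, 20.0, 50.0]]
)

_SHANK_OFFSET = np.array([0.0, 150.0, 250.0])
_FOOT_OFFSET = np.array([0.0, 20.0, 20.0])
_PROBE_OFFSET = np.array([120.0, 80.0, 120.0])


def _rotation_about_axis(axis: Line3D, angle_rad: float) -> RigidPose:
    """Rigid rotation by ``angle_rad`` about an arbitrary axis line."""
    rot = RigidPose.from_rotvec(angle_rad * axis.direction)
    t = axis.point - rot.rotation @ axis.point
    return RigidPose(rot.rotation, t)


def generate_rom_trial(
    axis: Line3D,
    quad_coeffs_mm: tuple,
    marker_noise_sd_mm: float = 0.0,
    edge_noise_sd_mm: float = 0.0,
    n_frames: int = 121,
    sweep_deg: tuple = (20.0, -20.0),
    n_edge_pairs: int = 10,
    probe_drift_deg: float = 2.0,
    rng: np.random.Generator | None = None,
) -> ROMTrial:
    """Construct a ROM trial; ground truth is the inputs themselves.

    ``axis`` is the true functional axis in the shank (= neutral lab)
    frame; ``quad_coeffs_mm = (c0, c1, c2)`` prescribe the moment arm in mm
    as a quadratic in the ankle angle (deg, dorsiflexion positive).  The
    sweep runs from max dorsiflexion to max plantarflexion and must span at
    least [-15, +15] deg.  Gaussian noise of the given SDs is added iid to
    lab-frame markers and probe-frame edge points.
    """
    direction = canonical_direction(axis.direction)
    axis = Line3D(np.asarray(axis.point, dtype=float), direction)
    if sweep_deg[0] < 15.0 or sweep_deg[1] > -15.0:
        raise ValueError("angle sweep must cover at least [-15, +15] deg")
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    rng = rng or np.random.default_rng(0)
    c0, c1, c2 = quad_coeffs_mm

    # frame 0 neutral, then a linear dorsi -> plantar sweep
    angles = np.concatenate([[0.0], np.linspace(sweep_deg[0], sweep_deg[1], n_frames - 1)])

    # tendon line direction: roughly proximal-distal, not parallel to axis
    v = unit(np.array([0.15, 0.1, 1.0]))
    n_hat = unit(np.cross(direction, v))
    w_hat = unit(np.cross(v, n_hat))  # in-plane offset for the edge points
    s = np.linspace(-25.0, 25.0, n_edge_pairs)  # sample points along the line
    half_thickness = 2.5

    markers = {
        "shank": np.empty((n_frames, 4, 3)),
        "foot": np.empty((n_frames, 4, 3)),
        "probe": np.empty((n_frames, 4, 3)),
    }
    sup = np.empty((n_frames, n_edge_pairs, 3))
    dee = np.empty((n_frames, n_edge_pairs, 3))

    shank_pts = _CLUSTER_TEMPLATE + _SHANK_OFFSET
    foot_pts0 = _CLUSTER_TEMPLATE + _FOOT_OFFSET
    probe_pts0 = _CLUSTER_TEMPLATE * 0.5 + _PROBE_OFFSET

    for k, theta in enumerate(angles):
        foot_pose = _rotation_about_axis(axis, np.radians(theta))
        # mild probe drift over the sweep exercises the probe->shank chain
        probe_pose = _rotation_about_axis(
            Line3D.through(_PROBE_OFFSET, (0.0, 1.0, 0.2)),
            np.radians(probe_drift_deg) * k / max(n_frames - 1, 1),
        )
        markers["shank"][k] = shank_pts
        markers["foot"][k] = foot_pose.apply(foot_pts0)
        markers["probe"][k] = probe_pose.apply(probe_pts0)

        d = c0 + c1 * theta + c2 * theta**2
        q = axis.point + d * n_hat  # line through q with direction v is d away
        centers = q + s[:, None] * v
        sup_lab = centers + half_thickness * w_hat
        dee_lab = centers - half_thickness * w_hat
        inv = probe_pose.inverse()
        sup[k] = inv.apply(sup_lab)
        dee[k] = inv.apply(dee_lab)

    if marker_noise_sd_mm > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, marker_noise_sd_mm, markers[name].shape
            )
    if edge_noise_sd_mm > 0:
        sup = sup + rng.normal(0.0, edge_noise_sd_mm, sup.shape)
        dee = dee + rng.normal(0.0, edge_noise_sd_mm, dee.shape)

    time = np.arange(n_frames) / 30.0
    return ROMTrial(
        time_s=time,
        markers=markers,
        edge_superficial=sup,
        edge_deep=dee,
    )
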