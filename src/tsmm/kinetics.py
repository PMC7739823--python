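"""Ankle kinetics during treadmill walking: events, spatiotemporal
parameters, sagittal-plane inverse dynamics and tendon-force estimation.

The net ankle moment is computed by Newton-Euler reduction of the foot
segment in the sagittal plane (x anterior, y up), with plantarflexion
positive.  Taking moments about the foot center of mass C, with ankle
joint center A, center of pressure P, ground reaction force F, foot mass m,
moment of inertia I and angular acceleration alpha:

    M_pf = [(P - C) x F]_z + [(A - C) x J]_z - I * alpha,
    J = m * (a_C - g) - F                    (ankle joint reaction force)

which for a massless foot reduces to the familiar ``[(P - A) x F]_z``
(body weight applied anterior to the ankle produces a plantarflexion
moment).  Forces are low-pass filtered at 25 Hz and kinematics at 6 Hz
(4th-order zero-lag Butterworth) before differentiation; the center of
pressure, already a smooth ratio of force signals, is not filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .trials import FootParams, GaitTrial

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2

#: applied when a trial carries no foot anthropometrics: foot mass fraction
#: of body mass, COM offset from the ankle in the foot frame (m), and
#: radius of gyration (m) — conventional sagittal foot-segment values.
DEFAULT_FOOT_MASS_FRACTION = 0.0145
DEFAULT_COM_OFFSET_M = (0.06, -0.03)
DEFAULT_GYRATION_RADIUS_M = 0.05


@dataclass
class GaitEvents:
    heel_strikes_s: np.ndarray
    toe_offs_s: np.ndarray


@dataclass
class SpatiotemporalParams:
    stride_time_s: float
    stride_length_m: float
    step_length_m: float
    cadence_steps_per_min: float


@dataclass
class JointKinetics:
    """Per-cycle ankle moment waveforms and their peak summary."""

    cycle_percent: np.ndarray  # 101 points, 0..100
    moment_waveforms_nm: np.ndarray  # (n_cycles, 101), plantarflexion +
    peak_moments_nm: np.ndarray  # (n_cycles,)
    mean_peak_nm: float
    sd_peak_nm: float
    events: GaitEvents


def lowpass(x: np.ndarray, fs_hz: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth low-pass (applied forward and backward)."""
    b, a = butter(order, cutoff_hz / (fs_hz / 2.0), btype="low")
    return filtfilt(b, a, x)


def detect_gait_events(
    time_s: np.ndarray,
    vertical_grf_n: np.ndarray,
    threshold_n: float = 20.0,
    debounce_s: float = 0.05,
) -> GaitEvents:
    """Heel strikes and toe offs from threshold crossings of vertical GRF.

    Rising crossings of ``threshold_n`` are heel strikes, falling crossings
    toe offs; crossings closer than ``debounce_s`` to the previous kept
    event are discarded, so events strictly alternate.
    """
    t = np.asarray(time_s, dtype=float)
    fy = np.asarray(vertical_grf_n, dtype=float)
    above = fy > threshold_n
    changes = np.nonzero(np.diff(above.astype(np.int8)))[0]
    hs, to = [], []
    last = -np.inf
    for i in changes:
        # linear interpolation of the exact crossing time
        f0, f1 = fy[i], fy[i + 1]
        tc = t[i] + (threshold_n - f0) / (f1 - f0) * (t[i + 1] - t[i])
        if tc - last < debounce_s:
            continue
        last = tc
        (hs if above[i + 1] else to).append(tc)
    if len(hs) < 2:
        raise ValueError("fewer than 2 heel strikes detected")
    return GaitEvents(np.asarray(hs), np.asarray(to))


def spatiotemporal(
    events: GaitEvents,
    belt_speed_m_s: float,
    contralateral_heel_strikes_s: np.ndarray | None = None,
) -> SpatiotemporalParams:
    """Treadmill spatiotemporal parameters from ipsilateral heel strikes.

    Stride time is the mean inter-heel-strike interval; on a treadmill
    stride length is belt speed times stride time, and cadence 120 / stride
    time.  Step length defaults to half the stride length (symmetric gait)
    unless contralateral heel strikes are supplied.
    """
    hs = events.heel_strikes_s
    if len(hs) < 3:
        raise ValueError("need at least 3 ipsilateral heel strikes")
    intervals = np.diff(hs)
    cv = intervals.std() / intervals.mean()
    if cv > 0.5:
        logger.warning("irregular gait events (CV=%.0f%%); computing anyway", 100 * cv)
    stride_time = float(intervals.mean())
    stride_length = belt_speed_m_s * stride_time
    if contralateral_heel_strikes_s is None:
        step_length = stride_length / 2.0
    else:
        contra = np.asarray(contralateral_heel_strikes_s, dtype=float)
        lags = []
        for h in hs[:-1]:
            nxt = contra[contra > h]
            if len(nxt):
                lags.append(nxt[0] - h)
        step_length = belt_speed_m_s * float(np.mean(lags))
    return SpatiotemporalParams(
        stride_time_s=stride_time,
        stride_length_m=stride_length,
        step_length_m=step_length,
        cadence_steps_per_min=120.0 / stride_time,
    )


def _foot_params(trial: GaitTrial) -> FootParams:
    if trial.foot is not None:
        return trial.foot
    logger.warning(
        "trial has no foot anthropometrics; applying defaults "
        "(mass fraction %.4f of body mass)",
        DEFAULT_FOOT_MASS_FRACTION,
    )
    return FootParams(
        mass_kg=DEFAULT_FOOT_MASS_FRACTION * trial.body_mass_kg,
        com_offset_m=DEFAULT_COM_OFFSET_M,
        gyration_radius_m=DEFAULT_GYRATION_RADIUS_M,
    )


def ankle_inverse_dynamics(
    trial: GaitTrial,
    force_cutoff_hz: float = 25.0,
    kinematic_cutoff_hz: float = 6.0,
    events: GaitEvents | None = None,
) -> JointKinetics:
    """Per-cycle ankle plantarflexion moment from a gait trial.

    Filtered forces are resampled onto the kinematic time base; the foot
    COM position, its acceleration and the foot angular acceleration are
    obtained by differentiating filtered kinematics; and the sagittal
    Newton-Euler balance gives the plantarflexion moment, time-normalized
    to 101 points per gait cycle (heel strike to ipsilateral heel strike)
    with per-cycle peaks averaged across cycles.
    """
    foot = _foot_params(trial)
    fs_f = trial.force_rate_hz
    fs_m = trial.marker_rate_hz

    fx = lowpass(trial.grf_x_n, fs_f, force_cutoff_hz)
    fy = lowpass(trial.grf_y_n, fs_f, force_cutoff_hz)
    if events is None:
        events = detect_gait_events(trial.time_force_s, fy)

    tm = trial.time_marker_s
    fx_m = np.interp(tm, trial.time_force_s, fx)
    fy_m = np.interp(tm, trial.time_force_s, fy)
    cop_m = np.interp(tm, trial.time_force_s, trial.cop_x_m)

    ax_pos = lowpass(trial.ankle_x_m, fs_m, kinematic_cutoff_hz)
    ay_pos = lowpass(trial.ankle_y_m, fs_m, kinematic_cutoff_hz)
    phi = lowpass(trial.foot_angle_rad, fs_m, kinematic_cutoff_hz)

    # foot COM from the ankle and the foot-frame COM offset
    cx_loc, cy_loc = foot.com_offset_m
    cx = ax_pos + np.cos(phi) * cx_loc - np.sin(phi) * cy_loc
    cy = ay_pos + np.sin(phi) * cx_loc + np.cos(phi) * cy_loc

    def d2(x):
        return np.gradient(np.gradient(x, tm), tm)

    acx, acy = d2(cx), d2(cy)
    alpha = d2(phi)

    m = foot.mass_kg
    inertia = foot.moment_of_inertia
    # joint reaction force on the foot at the ankle
    jx = m * acx - fx_m
    jy = m * (acy + GRAVITY) - fy_m

    def cross_z(rx, ry, fx_, fy_):
        return rx * fy_ - ry * fx_

    moment = (
        cross_z(cop_m - cx, -cy, fx_m, fy_m)
        + cross_z(ax_pos - cx, ay_pos - cy, jx, jy)
        - inertia * alpha
    )

    grid = np.linspace(0.0, 100.0, 101)
    hs = events.heel_strikes_s
    waveforms = []
    for t0, t1 in zip(hs[:-1], hs[1:]):
        if t0 < tm[0] or t1 > tm[-1]:
            continue
        tq = t0 + (t1 - t0) * grid / 100.0
        waveforms.append(np.interp(tq, tm, moment))
    if not waveforms:
        raise ValueError("no complete gait cycle inside the kinematic time base")
    waveforms = np.asarray(waveforms)
    peaks = waveforms.max(axis=1)
    return JointKinetics(
        cycle_percent=grid,
        moment_waveforms_nm=waveforms,
        peak_moments_nm=peaks,
        mean_peak_nm=float(peaks.mean()),
        sd_peak_nm=float(peaks.std(ddof=1)) if len(peaks) > 1 else 0.0,
        events=events,
    )


def estimate_tendon_force(mean_peak_torque_nm: float, moment_arm_mm: float) -> float:
    """Peak Achilles tendon force: peak torque / moment arm (arm in m).

    Assumes the plantarflexion torque is generated entirely by the triceps
    surae acting through the Achilles tendon.
    """
    if moment_arm_mm <= 0:
        raise ValueError("moment arm must be positive")
    return mean_peak_torque_nm / (moment_arm_mm / 1000.0)
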