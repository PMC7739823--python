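"""Treadmill gait trials back-computed from a known ankle-torque waveform.

Each gait cycle gets a plantarflexion-torque target with a single
late-stance peak (at ~45% of the cycle, i.e. 75% of stance) equal to the
requested peak.  The foot kinematics are constructed so the foot is carried
backward at constant belt speed during stance (zero acceleration, zero
angular acceleration) and swings forward along a smooth quintic; the
vertical ground reaction force is a double-hump-free single-arch profile
and the center of pressure is then solved per sample so that the
sagittal-plane Newton-Euler ankle moment equals the target exactly.
Inverse dynamics on the generated trial is therefore a round trip up to
filtering and resampling error.

SI units throughout (N, m, s, rad).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..kinetics import GRAVITY
from ..trials import FootParams, GaitTrial

STANCE_FRACTION = 0.6
#: exponent placing the torque peak at 75% of stance: sin(pi * x^q)^2 with
#: x = fraction of stance peaks where x^q = 1/2
PEAK_SHAPE_EXPONENT = np.log(2.0) / np.log(4.0 / 3.0)


@dataclass
class GaitNoise:
    """Stride-to-stride and measurement noise for gait trials."""

    torque_peak_cv: float = 0.05  # per-cycle peak scatter, fraction of peak
    grf_sd_n: float = 0.0
    cop_sd_m: float = 0.0
    marker_sd_m: float = 0.0


def torque_shape(stance_fraction_x: np.ndarray) -> np.ndarray:
    """Unit-peak plantarflexion torque shape over the stance phase."""
    x = np.clip(stance_fraction_x, 0.0, 1.0)
    return np.sin(np.pi * x**PEAK_SHAPE_EXPONENT) ** 2


def _quintic(t, t0, t1, x0, x1, v0, v1):
    """Quintic with endpoint positions/velocities and zero end accelerations."""
    T = t1 - t0
    s = (t - t0) / T
    h = x1 - x0
    # boundary conditions in normalized time
    b0, b1 = v0 * T, v1 * T
    c3 = 10 * h - 6 * b0 - 4 * b1
    c4 = -15 * h + 8 * b0 + 7 * b1
    c5 = 6 * h - 3 * b0 - 3 * b1
    return x0 + b0 * s + c3 * s**3 + c4 * s**4 + c5 * s**5


def generate_gait_trial(
    peak_torque_nm: float,
    stride_time_s: float = 1.11,
    belt_speed_m_s: float = 1.25,
    n_strides: int = 12,
    body_mass_kg: float = 74.87,
    noise: GaitNoise | None = None,
    force_rate_hz: float = 1900.0,
    marker_rate_hz: float = 190.0,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Construct a treadmill trial; returns ``(GaitTrial, true_peaks_nm)``.

    ``true_peaks_nm`` holds the generated peak torque of every cycle in the
    trial, in order (two margin strides are added around the ``n_strides``
    requested, so the k-th detected gait cycle corresponds to
    ``true_peaks_nm[k]``); all peaks equal ``peak_torque_nm`` when the noise
    model is absent or has zero stride-to-stride scatter.  At least 10
    strides are required.
    """
    if peak_torque_nm <= 0:
        raise ValueError("peak torque must be positive")
    if stride_time_s <= 0:
        raise ValueError("stride time must be positive")
    if n_strides < 10:
        raise ValueError("a trial needs at least 10 strides")
    rng = rng or np.random.default_rng(0)
    noise = noise or GaitNoise(torque_peak_cv=0.0)

    weight = body_mass_kg * GRAVITY
    foot = FootParams(
        mass_kg=0.0145 * body_mass_kg,
        com_offset_m=(0.06, -0.03),
        gyration_radius_m=0.05,
    )
    T = stride_time_s
    t_stance = STANCE_FRACTION * T
    # one lead-in and one tail stride of margin for filter edge effects
    total_t = (n_strides + 2) * T
    tf = np.arange(0.0, total_t, 1.0 / force_rate_hz)
    tm = np.arange(0.0, total_t, 1.0 / marker_rate_hz)

    peaks = np.full(n_strides + 2, peak_torque_nm)
    if noise.torque_peak_cv > 0:
        peaks = peaks * (1.0 + noise.torque_peak_cv * rng.standard_normal(peaks.shape))
        peaks = np.clip(peaks, 0.2 * peak_torque_nm, None)

    ankle_h = 0.08
    hs_x = belt_speed_m_s * 0.3 * T  # ankle x at heel strike

    def ankle_x(t):
        cyc = np.floor(t / T).astype(int)
        s = t - cyc * T
        x = np.where(
            s <= t_stance,
            hs_x - belt_speed_m_s * s,
            _quintic(
                s, t_stance, T,
                hs_x - belt_speed_m_s * t_stance, hs_x,
                -belt_speed_m_s, -belt_speed_m_s,
            ),
        )
        return x

    def ankle_y(t):
        s = np.mod(t, T)
        swing = s > t_stance
        y = np.full_like(np.asarray(t, dtype=float), ankle_h)
        sw = (s[swing] - t_stance) / (T - t_stance)
        y[swing] = ankle_h + 0.04 * np.sin(np.pi * sw) ** 2
        return y

    def foot_angle(t):
        s = np.mod(t, T)
        swing = s > t_stance
        phi = np.zeros_like(np.asarray(t, dtype=float))
        sw = (s[swing] - t_stance) / (T - t_stance)
        phi[swing] = -0.35 * np.sin(np.pi * sw) ** 2  # toe-down during swing
        return phi

    # force-plate signals on the force time base
    cyc_f = np.floor(tf / T).astype(int)
    sf = tf - cyc_f * T
    in_stance = sf <= t_stance
    x_st = np.where(in_stance, sf / t_stance, 0.0)
    fy = np.where(in_stance, weight * 1.05 * np.sin(np.pi * x_st), 0.0)
    fx = np.where(in_stance, 0.15 * weight * np.sin(2.0 * np.pi * x_st), 0.0)
    torque = np.where(in_stance, peaks[np.clip(cyc_f, 0, len(peaks) - 1)], 0.0)
    torque = torque * torque_shape(x_st) * in_stance

    ax_f = ankle_x(tf)
    # during stance the foot translates at constant velocity and does not
    # rotate, so the only inertial contribution is the foot's weight
    cx_f = ax_f + foot.com_offset_m[0]
    grav_term = foot.mass_kg * GRAVITY * (ax_f - cx_f)
    cop = np.where(
        fy > 1.0,
        ax_f + (torque - ankle_h * fx - grav_term) / np.where(fy > 1.0, fy, 1.0),
        ax_f,
    )

    if noise.grf_sd_n > 0:
        fy = fy + rng.normal(0.0, noise.grf_sd_n, fy.shape)
        fx = fx + rng.normal(0.0, noise.grf_sd_n, fx.shape)
    if noise.cop_sd_m > 0:
        cop = cop + rng.normal(0.0, noise.cop_sd_m, cop.shape)

    ax_m = ankle_x(tm)
    ay_m = ankle_y(tm)
    phi_m = foot_angle(tm)
    if noise.marker_sd_m > 0:
        ax_m = ax_m + rng.normal(0.0, noise.marker_sd_m, ax_m.shape)
        ay_m = ay_m + rng.normal(0.0, noise.marker_sd_m, ay_m.shape)
        phi_m = phi_m + rng.normal(0.0, noise.marker_sd_m * 10.0, phi_m.shape)

    trial = GaitTrial(
        time_force_s=tf,
        grf_x_n=fx,
        grf_y_n=fy,
        cop_x_m=cop,
        time_marker_s=tm,
        ankle_x_m=ax_m,
        ankle_y_m=ay_m,
        foot_angle_rad=phi_m,
        belt_speed_m_s=belt_speed_m_s,
        body_mass_kg=body_mass_kg,
        foot=foot,
    )
    return trial, peaks
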