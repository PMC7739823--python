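"""Two-group synthetic cohorts with ground-truth muscle-tendon measures.

The generator encodes the study conditions under which the analysis is
exercised: a young group whose total triceps surae volume scales linearly
with body size (height * mass) with a steeper slope than the older group,
tendon cross-sectional area (CSA) coupled linearly to muscle volume in the
young group but drawn independently of it in the older group, and peak
walking plantarflexion torque proportional to body size.  Group structure
lives ONLY in these generator parameters; the analysis modules contain no
group-conditional logic.

Default parameter values reproduce the cohort scale of a young (n = 14)
vs. older (n = 7) adult comparison: anthropometry means/SDs per group,
normalized-volume slopes of 7.00 and 5.95 cm^3 per kg*m, muscle volume
fractions (PS, AS, MG, LG) of roughly (0.42, 0.09, 0.31, 0.18), moment
arms near 46.6 / 43.5 mm, and peak torques near 114 / 106 Nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("young", "older")
MUSCLES = ("PS", "AS", "MG", "LG")

#: maximum deviation (in SDs) accepted when rejection-sampling anthropometry
ANTHROPOMETRY_BOUND_SD = 4.0
MAX_REJECTIONS = 1000


def _per_group(value) -> dict:
    if isinstance(value, dict):
        return {g: float(value[g]) for g in GROUPS}
    return {g: float(value) for g in GROUPS}


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the study conditions."""

    n_young: int = 14
    n_older: int = 7
    seed: int = 0

    age_mean: dict = field(default_factory=lambda: {"young": 25.5, "older": 66.0})
    age_sd: dict = field(default_factory=lambda: {"young": 4.3, "older": 4.8})
    height_mean_m: dict = field(default_factory=lambda: {"young": 1.78, "older": 1.76})
    height_sd_m: dict = field(default_factory=lambda: {"young": 0.10, "older": 0.07})
    mass_mean_kg: dict = field(default_factory=lambda: {"young": 74.87, "older": 74.57})
    mass_sd_kg: dict = field(default_factory=lambda: {"young": 12.11, "older": 15.26})

    #: total-volume scaling slope, cm^3 per kg*m
    volume_slope: dict = field(default_factory=lambda: {"young": 7.00, "older": 5.95})
    #: Gaussian scatter of total volume about the scaling line, cm^3 —
    #: sized so normalized volume has SD ~0.60 (young) / ~0.93 (older)
    #: at the group-mean body size
    volume_noise_sd_cm3: dict = field(
        default_factory=lambda: {"young": 80.0, "older": 122.0}
    )
    #: mean volume fraction of each muscle (PS, AS, MG, LG); sums to 1
    muscle_fractions: tuple = (0.4194, 0.0883, 0.3091, 0.1832)
    #: per-subject Gaussian jitter of the fractions (renormalized to sum 1)
    fraction_noise_sd: float = 0.02

    #: when True (young), mid-tendon CSA = slope * total volume + intercept
    #: + noise; when False (older), CSA is drawn independently of volume
    tendon_coupling_young: bool = True
    tendon_csa_slope_mm2_per_cm3: float = 0.05
    tendon_csa_intercept_mm2: float = 16.56
    tendon_csa_noise_sd_mm2: float = 5.5
    tendon_csa_older_mean_mm2: float = 65.54
    tendon_csa_older_sd_mm2: float = 6.96
    #: end-of-tendon CSA relative to the mid CSA (distal calcaneus end,
    #: proximal MTJ end) per group, shaping the quadratic CSA profile
    tendon_end_ratios: dict = field(
        default_factory=lambda: {"young": (1.057, 0.811), "older": (0.787, 0.791)}
    )
    tendon_length_mean_mm: dict = field(
        default_factory=lambda: {"young": 50.95, "older": 45.26}
    )
    tendon_length_sd_mm: dict = field(
        default_factory=lambda: {"young": 17.94, "older": 20.39}
    )
    tendon_length_min_mm: float = 20.0

    moment_arm_mean_mm: dict = field(
        default_factory=lambda: {"young": 46.64, "older": 43.54}
    )
    moment_arm_sd_mm: dict = field(default_factory=lambda: {"young": 3.87, "older": 8.13})
    #: linear and quadratic moment-arm-vs-angle terms (mm/deg, mm/deg^2)
    moment_arm_c1: float = -0.10
    moment_arm_c2: float = -0.01

    #: peak walking torque per body size, Nm per kg*m, plus scatter
    torque_scale_nm_per_kgm: dict = field(
        default_factory=lambda: {"young": 0.857, "older": 0.808}
    )
    torque_noise_sd_nm: dict = field(default_factory=lambda: {"young": 6.5, "older": 9.1})

    stride_time_mean_s: dict = field(default_factory=lambda: {"young": 1.11, "older": 1.02})
    stride_time_sd_s: dict = field(default_factory=lambda: {"young": 0.07, "older": 0.08})
    belt_speed_m_s: float = 1.25

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_older < 2:
            raise ValueError("each group needs at least 2 subjects")
        for name in (
            "age_mean",
            "age_sd",
            "height_mean_m",
            "height_sd_m",
            "mass_mean_kg",
            "mass_sd_kg",
            "volume_slope",
            "volume_noise_sd_cm3",
            "tendon_length_mean_mm",
            "tendon_length_sd_mm",
            "moment_arm_mean_mm",
            "moment_arm_sd_mm",
            "torque_scale_nm_per_kgm",
            "torque_noise_sd_nm",
            "stride_time_mean_s",
            "stride_time_sd_s",
        ):
            setattr(self, name, _per_group(getattr(self, name)))
        for g in GROUPS:
            if self.volume_slope[g] <= 0:
                raise ValueError("volume slopes must be positive")
        sds = [self.fraction_noise_sd, self.tendon_csa_noise_sd_mm2,
               self.tendon_csa_older_sd_mm2]
        sds += [d[g] for g in GROUPS for d in (
            self.age_sd, self.height_sd_m, self.mass_sd_kg,
            self.volume_noise_sd_cm3, self.tendon_length_sd_mm,
            self.moment_arm_sd_mm, self.torque_noise_sd_nm,
            self.stride_time_sd_s)]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        fr = np.asarray(self.muscle_fractions, dtype=float)
        if fr.size != 4 or abs(fr.sum() - 1.0) > 1e-9 or (fr <= 0).any():
            raise ValueError("muscle_fractions must be 4 positive values summing to 1")


@dataclass
class GroundTruth:
    """Per-subject generating values, for recovery tests and sidecars."""

    subject_id: str
    group: str
    muscle_volumes_cm3: dict
    total_volume_cm3: float
    tendon_csa_mid_mm2: float
    tendon_csa_profile_coeffs: tuple  # quadratic in normalized length u
    tendon_length_mm: float
    moment_arm_coeffs_mm: tuple  # (c0, c1, c2) vs ankle angle in deg
    axis_point_mm: tuple
    axis_direction: tuple
    peak_torque_nm: float
    stride_time_s: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=list))

    @staticmethod
    def from_json(path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        for key in ("tendon_csa_profile_coeffs", "moment_arm_coeffs_mm",
                    "axis_point_mm", "axis_direction"):
            d[key] = tuple(d[key])
        return GroundTruth(**d)


def _bounded_normal(rng, mean, sd, lower, n_max=MAX_REJECTIONS):
    """Gaussian draw rejection-sampled to +/-4 SD and above *lower*."""
    if sd == 0:
        if mean <= lower:
            raise ValueError("degenerate distribution below the physical bound")
        return mean
    for _ in range(n_max):
        x = rng.normal(mean, sd)
        if x > lower and abs(x - mean) <= ANTHROPOMETRY_BOUND_SD * sd:
            return x
    raise RuntimeError(f"more than {n_max} rejections sampling N({mean}, {sd})")


def _subject_truth(rng: np.random.Generator, config: CohortConfig, group: str,
                   subject_id: str) -> tuple:
    age = _bounded_normal(rng, config.age_mean[group], config.age_sd[group], 18.0)
    height = _bounded_normal(rng, config.height_mean_m[group], config.height_sd_m[group], 1.2)
    mass = _bounded_normal(rng, config.mass_mean_kg[group], config.mass_sd_kg[group], 35.0)
    hm = height * mass

    total = config.volume_slope[group] * hm + rng.normal(0.0, config.volume_noise_sd_cm3[group])
    total = max(total, 0.2 * config.volume_slope[group] * hm)  # bound guard
    fractions = np.asarray(config.muscle_fractions, dtype=float)
    if config.fraction_noise_sd > 0:
        fractions = np.clip(
            fractions + rng.normal(0.0, config.fraction_noise_sd, 4), 0.01, None
        )
        fractions = fractions / fractions.sum()
    volumes = {m: float(total * f) for m, f in zip(MUSCLES, fractions)}

    if group == "young" and config.tendon_coupling_young:
        csa = (
            config.tendon_csa_slope_mm2_per_cm3 * total
            + config.tendon_csa_intercept_mm2
            + rng.normal(0.0, config.tendon_csa_noise_sd_mm2)
        )
    else:
        csa = rng.normal(config.tendon_csa_older_mean_mm2, config.tendon_csa_older_sd_mm2)
    csa = max(csa, 10.0)

    r0, r1 = config.tendon_end_ratios[group]
    # quadratic through CSA(0) = r0*csa, CSA(0.5) = csa, CSA(1) = r1*csa
    q0 = r0 * csa
    q2 = 2.0 * csa * (r0 + r1 - 2.0)
    q1 = csa * (r1 - r0) - q2
    tendon_length = _bounded_normal(
        rng,
        config.tendon_length_mean_mm[group],
        config.tendon_length_sd_mm[group],
        config.tendon_length_min_mm,
    )

    ma0 = _bounded_normal(rng, config.moment_arm_mean_mm[group],
                          config.moment_arm_sd_mm[group], 15.0)
    torque = config.torque_scale_nm_per_kgm[group] * hm + rng.normal(
        0.0, config.torque_noise_sd_nm[group]
    )
    torque = max(torque, 10.0)
    stride_time = _bounded_normal(
        rng, config.stride_time_mean_s[group], config.stride_time_sd_s[group], 0.5
    )

    truth = GroundTruth(
        subject_id=subject_id,
        group=group,
        muscle_volumes_cm3=volumes,
        total_volume_cm3=float(total),
        tendon_csa_mid_mm2=float(csa),
        tendon_csa_profile_coeffs=(float(q0), float(q1), float(q2)),
        tendon_length_mm=float(tendon_length),
        moment_arm_coeffs_mm=(float(ma0), config.moment_arm_c1, config.moment_arm_c2),
        axis_point_mm=(0.0, 60.0, 80.0),
        axis_direction=(1.0, 0.0, 0.0),  # medial-to-lateral hinge
        peak_torque_nm=float(torque),
        stride_time_s=float(stride_time),
    )
    row = {
        "subject_id": subject_id,
        "group": group,
        "age_years": age,
        "height_m": height,
        "mass_kg": mass,
        "height_mass_kgm": hm,
        **{f"vol_{m.lower()}_cm3": volumes[m] for m in MUSCLES},
        "vol_total_cm3": float(total),
        "tendon_csa_mm2": float(csa),
        "tendon_length_mm": float(tendon_length),
        "moment_arm_mm": float(ma0),
        "peak_torque_nm": float(torque),
        "tendon_force_n": float(torque) / (float(ma0) / 1000.0),
        "stride_time_s": float(stride_time),
        "stride_length_m": config.belt_speed_m_s * float(stride_time),
        "step_length_m": config.belt_speed_m_s * float(stride_time) / 2.0,
        "cadence_steps_per_min": 120.0 / float(stride_time),
    }
    return row, truth


def subject_seed_sequences(config: CohortConfig) -> list:
    """One child SeedSequence per subject (index-keyed, growth-stable)."""
    return np.random.SeedSequence(config.seed).spawn(config.n_young + config.n_older)


def generate_cohort(config: CohortConfig) -> tuple:
    """Generate the cohort; returns ``(subjects DataFrame, {id: GroundTruth})``.

    Reproducible for a fixed config and seed.  Each subject draws from its
    own spawned random stream, so increasing ``n_young``/``n_older`` leaves
    previously generated subjects untouched.
    """
    seqs = subject_seed_sequences(config)
    rows, truths = [], {}
    groups = ["young"] * config.n_young + ["older"] * config.n_older
    counters = {"young": 0, "older": 0}
    for seq, group in zip(seqs, groups):
        counters[group] += 1
        sid = f"{group[0].upper()}{counters[group]:02d}"
        # stream 0 of the subject's sequence generates the subject; further
        # streams are reserved for the subject's trials
        rng = np.random.default_rng(seq.spawn(1)[0])
        row, truth = _subject_truth(rng, config, group, sid)
        rows.append(row)
        truths[sid] = truth
    return pd.DataFrame(rows), truths
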