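"""End-to-end pipeline: simulate -> morph -> momentarm -> gait -> stats.

Every stage is a pure function of (inputs, config, seed); a run directory
receives each stage's outputs plus a manifest recording the seed, stage
order and a checksum per written file, so a fixed config and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Line3D
from .kinetics import ankle_inverse_dynamics, estimate_tendon_force, spatiotemporal
from .momentarm import analyze_rom_trial
from .morphometry import LabelVolume, compute_muscle_volumes, tendon_geometry, tendon_muscle_ratios
from .stats import build_tables
from .synthetic.cohort import CohortConfig, GroundTruth, generate_cohort, subject_seed_sequences
from .synthetic.gait import GaitNoise, generate_gait_trial
from .synthetic.phantom import TendonTubeSpec, generate_label_volume
from .synthetic.rom import generate_rom_trial
from .trials import GaitTrial, ROMTrial

logger = logging.getLogger(__name__)

STAGES = ("simulate", "morph", "momentarm", "gait", "stats")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: str = "tsmm_run"
    seed: int = 0
    cohort: CohortConfig = None  # filled from seed when absent
    spacing_mm: tuple = (0.72, 0.72, 2.0)
    n_strides: int = 10
    rom_marker_noise_sd_mm: float = 0.1
    rom_edge_noise_sd_mm: float = 0.1
    gait_noise: GaitNoise = field(default_factory=GaitNoise)
    alpha: float = 0.05
    cap_p: bool = False
    exact_test_cutoff: int = 25

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @staticmethod
    def from_yaml(path, seed: int | None = None, out_dir: str | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(raw, seed=seed, out_dir=out_dir)

    @staticmethod
    def from_dict(raw: dict, seed: int | None = None, out_dir: str | None = None) -> "RunConfig":
        raw = dict(raw)
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort_raw = raw.pop("cohort", None)
        noise_raw = raw.pop("gait_noise", None)
        if seed is not None:
            raw["seed"] = seed
        if out_dir is not None:
            raw["out_dir"] = str(out_dir)
        if "spacing_mm" in raw:
            raw["spacing_mm"] = tuple(raw["spacing_mm"])
        cfg = RunConfig(**raw)
        if cohort_raw:
            cohort_raw.setdefault("seed", cfg.seed)
            if "muscle_fractions" in cohort_raw:
                cohort_raw["muscle_fractions"] = tuple(cohort_raw["muscle_fractions"])
            cfg.cohort = CohortConfig(**cohort_raw)
        elif seed is not None:
            cfg.cohort = CohortConfig(seed=seed)
        if noise_raw:
            cfg.gait_noise = GaitNoise(**noise_raw)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    """Generate the cohort with one label volume, ROM trial and gait trial
    per subject, plus ground-truth sidecars."""
    subjects, truths = generate_cohort(cfg.cohort)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "subjects.csv", index=False)

    seqs = subject_seed_sequences(cfg.cohort)
    for (sid, truth), seq in zip(truths.items(), seqs):
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        truth.to_json(sdir / "ground_truth.json")
        # streams: 0 = subject scalars (used in generate_cohort),
        # 1 = ROM trial, 2 = gait trial
        _, rom_seq, gait_seq = seq.spawn(3)

        tendon = TendonTubeSpec(
            path_length_mm=truth.tendon_length_mm,
            csa_mm2=truth.tendon_csa_profile_coeffs,
        )
        vol, _ = generate_label_volume(
            truth.muscle_volumes_cm3, tendon, spacing_mm=cfg.spacing_mm
        )
        vol.to_nifti(sdir / "labels.nii")

        axis = Line3D.through(truth.axis_point_mm, truth.axis_direction)
        rom = generate_rom_trial(
            axis,
            truth.moment_arm_coeffs_mm,
            marker_noise_sd_mm=cfg.rom_marker_noise_sd_mm,
            edge_noise_sd_mm=cfg.rom_edge_noise_sd_mm,
            rng=np.random.default_rng(rom_seq),
        )
        rom.to_tsv(sdir / "rom.tsv")

        row = subjects.loc[subjects.subject_id == sid].iloc[0]
        gait, _ = generate_gait_trial(
            truth.peak_torque_nm,
            stride_time_s=truth.stride_time_s,
            belt_speed_m_s=cfg.cohort.belt_speed_m_s,
            n_strides=cfg.n_strides,
            body_mass_kg=float(row.mass_kg),
            noise=cfg.gait_noise,
            rng=np.random.default_rng(gait_seq),
        )
        gait.to_dir(sdir / "gait")
    return {"n_subjects": len(truths)}


def stage_morph(cfg: RunConfig, out: Path) -> dict:
    subjects = pd.read_csv(out / "subjects.csv")
    rows = []
    for _, s in subjects.iterrows():
        sdir = out / s.subject_id
        vol = LabelVolume.from_nifti(sdir / "labels.nii")
        morpho = compute_muscle_volumes(vol, s.height_m, s.mass_kg)
        tg = tendon_geometry(vol)
        ratios = tendon_muscle_ratios(tg.mid_csa_mm2, morpho)
        pd.DataFrame(
            {"percent": tg.profile_percent, "csa_mm2": tg.profile_csa_mm2}
        ).to_csv(sdir / "tendon_profile.csv", index=False)
        rows.append(
            {
                "subject_id": s.subject_id,
                **{f"vol_{m.lower()}_cm3": v for m, v in morpho.volumes_cm3.items()},
                "vol_total_cm3": morpho.total_cm3,
                **{
                    f"rel_{m.lower()}_pct": v
                    for m, v in morpho.relative_pct.items()
                },
                **{
                    f"norm_{k.lower()}": v
                    for k, v in morpho.normalized_cm3_per_kgm.items()
                },
                "tendon_csa_mm2": tg.mid_csa_mm2,
                "tendon_length_mm": tg.length_mm,
                "tendon_volume_cm3": tg.volume_cm3,
                **{
                    f"csa_per_vol_{k.lower()}_cm": v
                    for k, v in ratios.csa_per_volume_cm.items()
                },
                "csa_per_heightmass": ratios.csa_per_heightmass_mm2_per_kgm,
            }
        )
    pd.DataFrame(rows).to_csv(out / "measures_morph.csv", index=False)
    return {"n_subjects": len(rows)}


def stage_momentarm(cfg: RunConfig, out: Path) -> dict:
    subjects = pd.read_csv(out / "subjects.csv")
    rows = []
    for sid in subjects.subject_id:
        sdir = out / sid
        trial = ROMTrial.from_tsv(sdir / "rom.tsv")
        res = analyze_rom_trial(trial)
        payload = {
            "axis": {
                "point_mm": res.axis.point.tolist(),
                "direction": res.axis.direction.tolist(),
            },
            "quadratic_mm": list(res.curve.coefficients),
            "moment_arm_0deg_mm": res.curve.moment_arm_0deg_mm,
            "frames": res.frames.to_dict(orient="list"),
        }
        (sdir / "momentarm.json").write_text(json.dumps(payload, indent=2))
        rows.append(
            {"subject_id": sid, "moment_arm_mm": res.curve.moment_arm_0deg_mm}
        )
    pd.DataFrame(rows).to_csv(out / "measures_momentarm.csv", index=False)
    return {"n_subjects": len(rows)}


def stage_gait(cfg: RunConfig, out: Path) -> dict:
    subjects = pd.read_csv(out / "subjects.csv")
    arms = pd.read_csv(out / "measures_momentarm.csv").set_index("subject_id")
    rows = []
    for sid in subjects.subject_id:
        sdir = out / sid
        trial = GaitTrial.from_dir(sdir / "gait")
        kin = ankle_inverse_dynamics(trial)
        st = spatiotemporal(kin.events, trial.belt_speed_m_s)
        arm = float(arms.loc[sid, "moment_arm_mm"])
        pd.DataFrame(
            kin.moment_waveforms_nm.T, index=kin.cycle_percent
        ).to_csv(sdir / "ankle_moment_cycles.csv", index_label="percent")
        rows.append(
            {
                "subject_id": sid,
                "peak_torque_nm": kin.mean_peak_nm,
                "peak_torque_sd_nm": kin.sd_peak_nm,
                "n_cycles": len(kin.peak_moments_nm),
                "tendon_force_n": estimate_tendon_force(kin.mean_peak_nm, arm),
                "stride_time_s": st.stride_time_s,
                "stride_length_m": st.stride_length_m,
                "step_length_m": st.step_length_m,
                "cadence_steps_per_min": st.cadence_steps_per_min,
            }
        )
    pd.DataFrame(rows).to_csv(out / "measures_gait.csv", index=False)
    return {"n_subjects": len(rows)}


def assemble_measures(out: Path) -> pd.DataFrame:
    subjects = pd.read_csv(out / "subjects.csv")
    keep = ["subject_id", "group", "age_years", "height_m", "mass_kg", "height_mass_kgm"]
    df = subjects[keep]
    for name in ("measures_morph.csv", "measures_momentarm.csv", "measures_gait.csv"):
        df = df.merge(pd.read_csv(out / name), on="subject_id", how="left")
    return df


def stage_stats(cfg: RunConfig, out: Path) -> dict:
    measures = assemble_measures(out)
    measures.to_csv(out / "measures.csv", index=False)
    tables = build_tables(measures, alpha=cfg.alpha, cap_p=cfg.cap_p)
    fits = {}
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
        fits[name] = df.to_dict(orient="records")
    (out / "stats.json").write_text(json.dumps(fits, indent=2, default=str))
    return {"n_measures": int(len(measures))}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "morph": stage_morph,
    "momentarm": stage_momentarm,
    "gait": stage_gait,
    "stats": stage_stats,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> Path:
    """Run the requested stages in order and write the run manifest.

    On a stage failure, partial outputs are retained next to a ``FAILED``
    marker naming the stage, and the exception propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "config": {
            "spacing_mm": list(cfg.spacing_mm),
            "n_strides": cfg.n_strides,
            "alpha": cfg.alpha,
            "cap_p": cfg.cap_p,
            "cohort": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in cfg.cohort.__dict__.items()
            },
        },
    }
    before = {p for p in out.rglob("*") if p.is_file()}
    for name in stages:
        logger.info("stage %s starting", name)
        try:
            info = _STAGE_FUNCS[name](cfg, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise
        after = {p for p in out.rglob("*") if p.is_file()}
        new = sorted(str(p.relative_to(out)) for p in after - before)
        before = after
        manifest["stages"].append({"name": name, "outputs": new, **info})
        logger.info("stage %s done: %s", name, info)
    checks = {}
    for st in manifest["stages"]:
        for rel in st["outputs"]:
            checks[rel] = _sha256(out / rel)
    manifest["checksums"] = checks
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if (out / "FAILED").exists():
        (out / "FAILED").unlink()
    return out
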