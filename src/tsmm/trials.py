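"""Trial containers and their plain-text (TSV/JSON) serialization.

Two kinds of motion trials flow through the pipeline:

* :class:`ROMTrial` — a quasi-static range-of-motion trial used for
  Achilles moment-arm estimation: marker clusters on shank, foot and
  ultrasound probe, plus superficial/deep tendon edge points expressed in
  the probe frame.  Frame 0 is the neutral calibration posture; all poses
  downstream are expressed relative to it.
* :class:`GaitTrial` — a treadmill walking trial: ground reaction force and
  center of pressure sampled at a high rate (default 1,900 Hz) together
  with sagittal-plane foot kinematics at a lower rate (default 190 Hz).

Coordinates: ROM trials are in millimetres; gait trials use SI units
(newtons, metres, radians) as noted on each field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLUSTERS = ("shank", "foot", "probe")


@dataclass
class ROMTrial:
    """Range-of-motion trial for moment-arm estimation (lengths in mm)."""

    time_s: np.ndarray  # (n_frames,)
    markers: dict  # cluster name -> (n_frames, n_markers, 3) lab-frame mm
    edge_superficial: np.ndarray  # (n_frames, n_points, 3) probe frame mm
    edge_deep: np.ndarray  # (n_frames, n_points, 3) probe frame mm

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in CLUSTERS:
            if name not in self.markers:
                raise ValueError(f"missing marker cluster {name!r}")
            if self.markers[name].shape[0] != n:
                raise ValueError(f"cluster {name!r} frame count mismatch")
        if self.edge_superficial.shape != self.edge_deep.shape:
            raise ValueError("superficial/deep edge points must be paired")
        if self.edge_superficial.shape[0] != n:
            raise ValueError("edge point frame count mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def to_tsv(self, path) -> None:
        cols = {"time_s": self.time_s}
        for name in CLUSTERS:
            arr = self.markers[name]
            for m in range(arr.shape[1]):
                for k, ax in enumerate("xyz"):
                    cols[f"{name}_{m + 1}_{ax}"] = arr[:, m, k]
        for label, arr in (
            ("sup", self.edge_superficial),
            ("deep", self.edge_deep),
        ):
            for m in range(arr.shape[1]):
                for k, ax in enumerate("xyz"):
                    cols[f"{label}_{m + 1}_{ax}"] = arr[:, m, k]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.9g")

    @staticmethod
    def from_tsv(path) -> "ROMTrial":
        df = pd.read_csv(path, sep="\t")

        def gather(prefix: str) -> np.ndarray:
            idx = 1
            pts = []
            while f"{prefix}_{idx}_x" in df.columns:
                pts.append(
                    np.stack(
                        [df[f"{prefix}_{idx}_{ax}"].to_numpy() for ax in "xyz"],
                        axis=1,
                    )
                )
                idx += 1
            if not pts:
                raise ValueError(f"no columns found for {prefix!r} in {path}")
            return np.stack(pts, axis=1)

        return ROMTrial(
            time_s=df["time_s"].to_numpy(),
            markers={name: gather(name) for name in CLUSTERS},
            edge_superficial=gather("sup"),
            edge_deep=gather("deep"),
        )


@dataclass
class FootParams:
    """Sagittal-plane foot segment parameters for inverse dynamics."""

    mass_kg: float
    com_offset_m: tuple  # (x anterior, y up) from ankle, in the foot frame
    gyration_radius_m: float

    @property
    def moment_of_inertia(self) -> float:
        return self.mass_kg * self.gyration_radius_m**2


@dataclass
class GaitTrial:
    """Instrumented-treadmill walking trial (sagittal plane, SI units)."""

    time_force_s: np.ndarray
    grf_x_n: np.ndarray  # anteroposterior GRF, anterior positive
    grf_y_n: np.ndarray  # vertical GRF, upward positive
    cop_x_m: np.ndarray  # center of pressure along the belt, ground level
    time_marker_s: np.ndarray
    ankle_x_m: np.ndarray
    ankle_y_m: np.ndarray
    foot_angle_rad: np.ndarray  # foot segment angle, dorsiflexion positive
    belt_speed_m_s: float
    body_mass_kg: float
    foot: FootParams | None = None

    def __post_init__(self) -> None:
        if self.belt_speed_m_s <= 0:
            raise ValueError("belt speed must be positive")
        nf, nm = len(self.time_force_s), len(self.time_marker_s)
        for name in ("grf_x_n", "grf_y_n", "cop_x_m"):
            if len(getattr(self, name)) != nf:
                raise ValueError(f"{name} length must match force time base")
        for name in ("ankle_x_m", "ankle_y_m", "foot_angle_rad"):
            if len(getattr(self, name)) != nm:
                raise ValueError(f"{name} length must match marker time base")
        t0 = max(self.time_force_s[0], self.time_marker_s[0])
        t1 = min(self.time_force_s[-1], self.time_marker_s[-1])
        if t1 <= t0:
            raise ValueError("force and marker time bases do not overlap")

    @property
    def force_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_force_s)))

    @property
    def marker_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_marker_s)))

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "time_s": self.time_force_s,
                "grf_x_n": self.grf_x_n,
                "grf_y_n": self.grf_y_n,
                "cop_x_m": self.cop_x_m,
            }
        ).to_csv(path / "forces.tsv", sep="\t", index=False, float_format="%.9g")
        pd.DataFrame(
            {
                "time_s": self.time_marker_s,
                "ankle_x_m": self.ankle_x_m,
                "ankle_y_m": self.ankle_y_m,
                "foot_angle_rad": self.foot_angle_rad,
            }
        ).to_csv(path / "markers.tsv", sep="\t", index=False, float_format="%.9g")
        meta = {
            "belt_speed_m_s": self.belt_speed_m_s,
            "body_mass_kg": self.body_mass_kg,
        }
        if self.foot is not None:
            meta["foot"] = {
                "mass_kg": self.foot.mass_kg,
                "com_offset_m": list(self.foot.com_offset_m),
                "gyration_radius_m": self.foot.gyration_radius_m,
            }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def from_dir(path) -> "GaitTrial":
        path = Path(path)
        forces = pd.read_csv(path / "forces.tsv", sep="\t")
        markers = pd.read_csv(path / "markers.tsv", sep="\t")
        meta = json.loads((path / "meta.json").read_text())
        foot = None
        if "foot" in meta:
            f = meta["foot"]
            foot = FootParams(
                mass_kg=f["mass_kg"],
                com_offset_m=tuple(f["com_offset_m"]),
                gyration_radius_m=f["gyration_radius_m"],
            )
        return GaitTrial(
            time_force_s=forces["time_s"].to_numpy(),
            grf_x_n=forces["grf_x_n"].to_numpy(),
            grf_y_n=forces["grf_y_n"].to_numpy(),
            cop_x_m=forces["cop_x_m"].to_numpy(),
            time_marker_s=markers["time_s"].to_numpy(),
            ankle_x_m=markers["ankle_x_m"].to_numpy(),
            ankle_y_m=markers["ankle_y_m"].to_numpy(),
            foot_angle_rad=markers["foot_angle_rad"].to_numpy(),
            belt_speed_m_s=meta["belt_speed_m_s"],
            body_mass_kg=meta["body_mass_kg"],
            foot=foot,
        )
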