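"""Muscle volumetry and Achilles free-tendon geometry from 3-D label maps.

The triceps surae is segmented into four muscles — posterior soleus (PS),
anterior soleus (AS), medial gastrocnemius (MG) and lateral gastrocnemius
(LG) — sharing the Achilles tendon.  Volumes are voxel counts times the
voxel volume; the free tendon runs between the most proximal slice where
the calcaneus is visible and the soleus muscle-tendon junction (MTJ), with
cross-sectional area (CSA) measured slice-wise in the axial plane.

Unit conventions, fixed at ingestion: voxel spacing and all lengths in mm,
CSA in mm^2, volumes in cm^3, anthropometry in m and kg.  World coordinates
are ``index * spacing`` (0-based indices, voxels owned by their centers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0

#: canonical label dictionary: 0 background, four muscles, free tendon and
#: the two landmark labels bounding the free tendon.
DEFAULT_LABELS = {
    "background": 0,
    "PS": 1,
    "AS": 2,
    "MG": 3,
    "LG": 4,
    "tendon": 5,
    "calcaneus_top": 6,
    "soleus_mtj": 7,
}

MUSCLES = ("PS", "AS", "MG", "LG")


@dataclass
class LabelVolume:
    """Integer label grid with voxel spacing.

    ``axial_axis`` indexes the proximal–distal (slice) direction; imaging
    slices are planes normal to it.
    """

    data: np.ndarray
    spacing_mm: tuple
    axial_axis: int = 2
    labels: dict = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive lengths (mm)")
        declared = set(self.labels.values())
        present = set(np.unique(self.data).tolist())
        extra = present - declared
        if extra:
            raise ValueError(f"undeclared labels present in volume: {sorted(extra)}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    @property
    def in_plane_area_mm2(self) -> float:
        areas = [
            s for i, s in enumerate(self.spacing_mm) if i != self.axial_axis
        ]
        return areas[0] * areas[1]

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.data == self.labels[name]))

    def slice_mask(self, name: str, k: int) -> np.ndarray:
        sl = [slice(None)] * 3
        sl[self.axial_axis] = k
        return self.data[tuple(sl)] == self.labels[name]

    def slices_containing(self, name: str) -> np.ndarray:
        axes = tuple(i for i in range(3) if i != self.axial_axis)
        return np.nonzero((self.data == self.labels[name]).any(axis=axes))[0]

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing_mm) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.int16), affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @staticmethod
    def from_nifti(path, labels: dict | None = None, axial_axis: int = 2) -> "LabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.int32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return LabelVolume(
            data=data,
            spacing_mm=spacing,
            axial_axis=axial_axis,
            labels=dict(labels or DEFAULT_LABELS),
        )


@dataclass
class MuscleMorphometry:
    """Per-muscle, total, relative (%) and body-size-normalized volumes."""

    volumes_cm3: dict
    total_cm3: float
    relative_pct: dict
    normalized_cm3_per_kgm: dict  # per muscle plus "total"
    height_m: float
    mass_kg: float


def compute_muscle_volumes(vol: LabelVolume, height_m: float, mass_kg: float) -> MuscleMorphometry:
    """Voxel-sum muscle volumes with relative and normalized variants.

    volume(label) = count(label) * dx*dy*dz, reported in cm^3;
    relative = individual / total * 100 (%); normalized = volume /
    (height * mass) in cm^3 per kg*m.
    """
    if height_m <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    missing = [m for m in MUSCLES if vol.count(m) == 0]
    if missing:
        raise ValueError(f"missing muscle label(s): {', '.join(missing)}")
    volumes = {
        m: vol.count(m) * vol.voxel_volume_mm3 / MM3_PER_CM3 for m in MUSCLES
    }
    total = sum(volumes.values())
    if total <= 0:
        raise ValueError("total muscle volume is zero")
    hm = height_m * mass_kg
    normalized = {m: v / hm for m, v in volumes.items()}
    normalized["total"] = total / hm
    return MuscleMorphometry(
        volumes_cm3=volumes,
        total_cm3=total,
        relative_pct={m: 100.0 * v / total for m, v in volumes.items()},
        normalized_cm3_per_kgm=normalized,
        height_m=height_m,
        mass_kg=mass_kg,
    )


@dataclass
class TendonGeometry:
    """Slice-wise Achilles free-tendon geometry.

    The CSA profile is indexed by normalized centroid-path length: 0% at the
    calcaneus-top slice, 100% at the soleus-MTJ slice.
    """

    slice_indices: np.ndarray
    slice_z_mm: np.ndarray
    csa_mm2: np.ndarray
    centroids_mm: np.ndarray  # (n_slices, 3) world coordinates
    length_mm: float
    volume_cm3: float
    mid_csa_mm2: float
    mid_slice_index: int
    profile_percent: np.ndarray  # 101 points, 0..100
    profile_csa_mm2: np.ndarray


def tendon_geometry(vol: LabelVolume, landmarks: tuple | None = None) -> TendonGeometry:
    """Measure the free tendon between its two landmark slices.

    ``landmarks`` may supply (calcaneus_top_slice, soleus_mtj_slice) indices
    directly (e.g. from a sidecar file); otherwise they are located from the
    landmark labels in the volume.  Per-slice CSA is the in-plane voxel
    count times the in-plane voxel area; tendon volume is the summed CSA
    times the slice thickness, and tendon length the summed distance between
    centroids of adjacent cross sections.  The representative mid-length CSA
    comes from the first slice whose cumulative centroid-path length reaches
    50% of the total.
    """
    ax = vol.axial_axis
    dz = vol.spacing_mm[ax]
    if landmarks is None:
        lo_slices = vol.slices_containing("calcaneus_top")
        hi_slices = vol.slices_containing("soleus_mtj")
        if len(lo_slices) == 0 or len(hi_slices) == 0:
            raise ValueError(
                "landmark labels (calcaneus_top, soleus_mtj) not found; "
                "pass explicit landmark slice indices"
            )
        k0, k1 = int(lo_slices[0]), int(hi_slices[-1])
    else:
        k0, k1 = int(landmarks[0]), int(landmarks[1])
    k0, k1 = min(k0, k1), max(k0, k1)

    spacing = np.asarray(vol.spacing_mm)
    in_plane_axes = [i for i in range(3) if i != ax]
    ks = np.arange(k0, k1 + 1)
    csa = np.empty(len(ks))
    centroids = np.empty((len(ks), 3))
    gaps = []
    for j, k in enumerate(ks):
        mask = vol.slice_mask("tendon", int(k))
        n = int(mask.sum())
        if n == 0:
            gaps.append(int(k))
            continue
        csa[j] = n * vol.in_plane_area_mm2
        idx = np.nonzero(mask)
        centroids[j, ax] = k
        centroids[j, in_plane_axes[0]] = idx[0].mean()
        centroids[j, in_plane_axes[1]] = idx[1].mean()
    if gaps:
        raise ValueError(f"gap in tendon label between landmarks at slice(s) {gaps}")
    centroids *= spacing

    steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    length = float(cum[-1])
    volume = float(csa.sum() * dz / MM3_PER_CM3)

    if length == 0.0:  # single slice (or perfectly stacked centroids)
        mid_j = 0
        percent = np.zeros(len(ks))
    else:
        mid_j = int(np.argmax(cum >= 0.5 * length))
        percent = 100.0 * cum / length
    grid = np.linspace(0.0, 100.0, 101)
    if length == 0.0:
        profile = np.full(101, csa[0])
    else:
        profile = np.interp(grid, percent, csa)
    return TendonGeometry(
        slice_indices=ks,
        slice_z_mm=ks * dz,
        csa_mm2=csa,
        centroids_mm=centroids,
        length_mm=length,
        volume_cm3=volume,
        mid_csa_mm2=float(csa[mid_j]),
        mid_slice_index=int(ks[mid_j]),
        profile_percent=grid,
        profile_csa_mm2=profile,
    )


@dataclass
class TendonMuscleRatios:
    """Tendon size per muscle size and per body size."""

    csa_per_volume_cm: dict  # cm^-1, per muscle plus "total"
    csa_per_heightmass_mm2_per_kgm: float


def tendon_muscle_ratios(
    csa_mid_mm2: float, morpho: MuscleMorphometry
) -> TendonMuscleRatios:
    """Ratios of mid-length tendon CSA to muscle volumes and body size.

    CSA is converted to cm^2 before dividing by cm^3 volumes, yielding
    cm^-1; the body-size ratio stays in mm^2 per kg*m.
    """
    if csa_mid_mm2 <= 0:
        raise ValueError("tendon CSA must be positive")
    csa_cm2 = csa_mid_mm2 / MM2_PER_CM2
    ratios = {}
    for m, v in morpho.volumes_cm3.items():
        if v <= 0:
            raise ValueError(f"zero volume for muscle {m}")
        ratios[m] = csa_cm2 / v
    ratios["total"] = csa_cm2 / morpho.total_cm3
    hm = morpho.height_m * morpho.mass_kg
    return TendonMuscleRatios(
        csa_per_volume_cm=ratios,
        csa_per_heightmass_mm2_per_kgm=csa_mid_mm2 / hm,
    )
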