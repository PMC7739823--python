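"""Voxelized phantoms: ellipsoid muscles and a tube tendon on an imaging
grid, with analytic ground truth for every measured quantity.

Rasterization rule: a voxel carries a label iff its center lies inside the
analytic shape (no partial-volume weighting), matching the voxel-counting
measurement model.  World coordinates are ``index * spacing`` in mm; the
axial (slice) axis is z.

The tendon is a sheared tube: every axial slice is a disc of prescribed
cross-sectional area whose center drifts linearly in x when the tube is
inclined, so the analytic axial-plane CSA equals the prescription exactly,
the analytic volume is the CSA integral times slice thickness, and the
centroid path length is the axial extent divided by cos(incline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..morphometry import DEFAULT_LABELS, MUSCLES, LabelVolume

PAPER_SPACING_MM = (0.72, 0.72, 2.0)


@dataclass
class EllipsoidSpec:
    """Ellipsoid with semi-axes (a, b, c), optionally rotated about z."""

    center_mm: tuple
    semi_axes_mm: tuple
    rotation_deg: float = 0.0

    @property
    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class TendonTubeSpec:
    """Free-tendon tube with a prescribed axial CSA profile.

    ``csa_mm2`` is either a constant or quadratic coefficients
    ``(q0, q1, q2)`` in normalized length u in [0, 1] (0 = distal/calcaneus
    end, 1 = proximal/MTJ end): ``CSA(u) = q0 + q1 u + q2 u^2``.
    """

    path_length_mm: float = 50.0
    csa_mm2: float | tuple = 50.0
    incline_deg: float = 0.0

    def csa_at(self, u: float | np.ndarray) -> np.ndarray:
        if np.isscalar(self.csa_mm2):
            return np.full_like(np.asarray(u, dtype=float), float(self.csa_mm2))
        q = np.asarray(self.csa_mm2, dtype=float)
        u = np.asarray(u, dtype=float)
        return q[0] + q[1] * u + q[2] * u**2

    @property
    def axial_extent_mm(self) -> float:
        return self.path_length_mm * np.cos(np.radians(self.incline_deg))

    def analytic_volume_mm3(self) -> float:
        u = np.linspace(0.0, 1.0, 10001)
        return float(np.trapezoid(self.csa_at(u), u) * self.axial_extent_mm)


@dataclass
class PhantomTruth:
    """Analytic ground truth of a generated label volume."""

    muscle_volumes_cm3: dict
    ellipsoids: dict
    tendon: TendonTubeSpec | None
    tendon_length_mm: float | None
    #: slab-model volume: the phantom is a stack of discs each owning one
    #: slice thickness, so its true volume is sum(CSA_k) * dz
    tendon_volume_cm3: float | None
    tendon_mid_csa_mm2: float | None


def _semi_axes_for_volume(volume_mm3: float) -> tuple:
    """Muscle-like elongated ellipsoid semi-axes (a, 0.7a, 3a) of a given
    volume."""
    a = (volume_mm3 / (4.0 / 3.0 * np.pi * 0.7 * 3.0)) ** (1.0 / 3.0)
    return (a, 0.7 * a, 3.0 * a)


def _rasterize_ellipsoid(
    grid: np.ndarray, spacing: np.ndarray, spec: EllipsoidSpec, value: int
) -> list:
    """Label voxels whose centers fall inside the ellipsoid.

    Returns the labels already present in the claimed voxels (collisions).
    """
    c = np.asarray(spec.center_mm, dtype=float)
    ax = np.asarray(spec.semi_axes_mm, dtype=float)
    r = max(ax)
    lo = np.maximum(0, np.floor((c - r) / spacing).astype(int))
    hi = np.minimum(np.array(grid.shape) - 1, np.ceil((c + r) / spacing).astype(int))
    if (lo > hi).any():
        return []
    ix = np.arange(lo[0], hi[0] + 1)
    iy = np.arange(lo[1], hi[1] + 1)
    iz = np.arange(lo[2], hi[2] + 1)
    X, Y, Z = np.meshgrid(ix * spacing[0], iy * spacing[1], iz * spacing[2], indexing="ij")
    dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
    th = np.radians(spec.rotation_deg)
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    inside = (u / ax[0]) ** 2 + (v / ax[1]) ** 2 + (dz / ax[2]) ** 2 <= 1.0
    sub = grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    collisions = np.unique(sub[inside & (sub != 0)]).tolist()
    sub[inside] = value
    return collisions


def generate_label_volume(
    true_volumes: dict,
    tendon: TendonTubeSpec | None = None,
    spacing_mm: tuple = PAPER_SPACING_MM,
    orientations_deg: dict | None = None,
) -> tuple:
    """Build a labeled limb phantom; returns ``(LabelVolume, PhantomTruth)``.

    ``true_volumes`` maps muscle names (any subset of PS/AS/MG/LG) to their
    analytic volumes in cm^3; each muscle becomes an ellipsoid of exactly
    that analytic volume.  The tendon tube sits distal to the muscles along
    z, with single-voxel landmark labels marking its most distal slice
    (calcaneus top) and most proximal slice (soleus MTJ).  Overlapping
    shapes raise with the colliding labels listed.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    unknown = set(true_volumes) - set(MUSCLES)
    if unknown:
        raise ValueError(f"unknown muscle names: {sorted(unknown)}")
    orientations_deg = orientations_deg or {}
    margin = 4.0 * spacing  # mm per axis

    dz = spacing[2]
    z0 = margin[2]
    ellipsoids = {}
    if tendon is not None:
        n_slices = int(round(tendon.axial_extent_mm / dz)) + 1
        k0 = int(round(z0 / dz))
        k1 = k0 + n_slices - 1
        z_muscle_base = (k1 + 1) * dz + margin[2]
        shift_per_mm = np.tan(np.radians(tendon.incline_deg))
    else:
        n_slices = 0
        z_muscle_base = z0
        shift_per_mm = 0.0

    # lay the muscles side by side along x, all starting at the same base z
    x_cursor = margin[0]
    max_b = 0.0
    max_top = z_muscle_base
    for name in MUSCLES:
        if name not in true_volumes:
            continue
        v_mm3 = float(true_volumes[name]) * 1000.0
        if v_mm3 <= 0:
            raise ValueError(f"volume for {name} must be positive")
        a, b, c = _semi_axes_for_volume(v_mm3)
        half_xy = max(a, b)  # in-plane bound regardless of rotation
        center = (x_cursor + half_xy, margin[1] + half_xy, z_muscle_base + c)
        ellipsoids[name] = EllipsoidSpec(
            center_mm=center,
            semi_axes_mm=(a, b, c),
            rotation_deg=float(orientations_deg.get(name, 0.0)),
        )
        x_cursor += 2 * half_xy + margin[0]
        max_b = max(max_b, half_xy)
        max_top = max(max_top, z_muscle_base + 2 * c)

    if tendon is not None:
        max_r = float(np.sqrt(tendon.csa_at(np.linspace(0, 1, 101)).max() / np.pi))
        tendon_cx0 = margin[0] + max_r
        drift = shift_per_mm * (n_slices - 1) * dz
        tendon_x_max = tendon_cx0 + max(0.0, drift) + max_r
        tendon_cx0 -= min(0.0, drift)  # keep a negatively inclined tube inside
        tendon_y_extent = 2 * (max_r + margin[1])
    else:
        tendon_cx0 = 0.0
        tendon_x_max = 0.0
        tendon_y_extent = 0.0
    nx = int(np.ceil(max(x_cursor, tendon_x_max + margin[0]) / spacing[0])) + 1
    ny = int(np.ceil(max(2 * max_b + 2 * margin[1], tendon_y_extent) / spacing[1])) + 1
    nz = int(np.ceil((max_top + margin[2]) / spacing[2])) + 1
    grid = np.zeros((nx, ny, nz), dtype=np.int16)
    labels = dict(DEFAULT_LABELS)

    collisions = {}
    tendon_slab_volume_cm3 = None
    tendon_mid_csa = None
    if tendon is not None:
        ks = np.arange(k0, k1 + 1)
        u = (ks - k0) / max(n_slices - 1, 1)
        radii = np.sqrt(tendon.csa_at(u) / np.pi)
        tendon_slab_volume_cm3 = float(tendon.csa_at(u).sum() * dz / 1000.0)
        tendon_mid_csa = float(tendon.csa_at(0.5))
        # snap the tube center to a half-voxel x offset and a voxel-center y:
        # this sampling phase makes disc voxel counts near-unbiased over the
        # tendon-like radius range
        tendon_cx0 = (np.round(tendon_cx0 / spacing[0]) + 0.5) * spacing[0]
        cy = np.round(ny / 2.0) * spacing[1]
        ix = np.arange(nx) * spacing[0]
        iy = np.arange(ny) * spacing[1]
        X, Y = np.meshgrid(ix, iy, indexing="ij")
        for k, uk, r in zip(ks, u, radii):
            cx = tendon_cx0 + shift_per_mm * (k - k0) * dz
            disc = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
            sl = grid[:, :, k]
            hit = np.unique(sl[disc & (sl != 0)])
            if hit.size:
                collisions.setdefault("tendon", set()).update(hit.tolist())
            sl[disc] = labels["tendon"]
        grid[0, 0, k0] = labels["calcaneus_top"]
        grid[0, 1, k1] = labels["soleus_mtj"]

    for name, spec in ellipsoids.items():
        hit = _rasterize_ellipsoid(grid, spacing, spec, labels[name])
        if hit:
            collisions.setdefault(name, set()).update(hit)
    if collisions:
        names = {v: k for k, v in labels.items()}
        listing = {
            k: sorted(names.get(int(v), str(v)) for v in hits)
            for k, hits in collisions.items()
        }
        raise ValueError(f"overlapping phantom shapes: {listing}")

    vol = LabelVolume(data=grid, spacing_mm=tuple(spacing), axial_axis=2, labels=labels)
    truth = PhantomTruth(
        muscle_volumes_cm3={k: float(v) for k, v in true_volumes.items()},
        ellipsoids=ellipsoids,
        tendon=tendon,
        tendon_length_mm=(
            None
            if tendon is None
            else float((n_slices - 1) * dz / np.cos(np.radians(tendon.incline_deg)))
        ),
        tendon_volume_cm3=tendon_slab_volume_cm3,
        tendon_mid_csa_mm2=tendon_mid_csa,
    )
    return vol, truth
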