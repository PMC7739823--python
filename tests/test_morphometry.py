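"""Voxel-sum volumetry and free-tendon geometry."""

import numpy as np
import pytest

from tsmm.morphometry import (
    DEFAULT_LABELS,
    MUSCLES,
    LabelVolume,
    compute_muscle_volumes,
    tendon_geometry,
    tendon_muscle_ratios,
)
from tsmm.synthetic.phantom import TendonTubeSpec, generate_label_volume

PAPER_SPACING = (0.72, 0.72, 2.0)


def block_volume(counts, spacing=(1.0, 1.0, 1.0)):
    """Label volume with one rectangular block per muscle, sized by voxel
    count tuples {muscle: (nx, ny, nz)} stacked along x."""
    shape_x = sum(c[0] for c in counts.values()) + 5 * len(counts)
    ny = max(c[1] for c in counts.values()) + 2
    nz = max(c[2] for c in counts.values()) + 2
    data = np.zeros((shape_x, ny, nz), dtype=np.int16)
    x = 0
    for name, (cx, cy, cz) in counts.items():
        data[x : x + cx, :cy, :cz] = DEFAULT_LABELS[name]
        x += cx + 5
    return LabelVolume(data=data, spacing_mm=spacing)


class TestMuscleVolumes:
    def test_block_count_times_voxel_volume(self):
        vol = block_volume(
            {"PS": (100, 100, 50), "AS": (5, 5, 5), "MG": (5, 5, 5), "LG": (5, 5, 5)},
            spacing=PAPER_SPACING,
        )
        m = compute_muscle_volumes(vol, 1.78, 74.87)
        assert m.volumes_cm3["PS"] == pytest.approx(518.4, abs=1e-9)

    def test_relative_and_total(self):
        # (400, 80, 300, 170) cm^3 at 1 mm isotropic spacing
        vol = block_volume(
            {
                "PS": (100, 80, 50),
                "AS": (80, 20, 50),
                "MG": (100, 60, 50),
                "LG": (100, 34, 50),
            }
        )
        m = compute_muscle_volumes(vol, 1.78, 74.87)
        assert m.total_cm3 == pytest.approx(950.0)
        assert m.relative_pct["PS"] == pytest.approx(100 * 400 / 950, rel=1e-12)
        assert sum(m.relative_pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_normalized_volume(self):
        vol = block_volume(
            {"PS": (100, 70, 100), "AS": (5, 5, 5), "MG": (5, 5, 5), "LG": (5, 5, 5)}
        )
        m = compute_muscle_volumes(vol, 1.75, 80.0)
        assert m.normalized_cm3_per_kgm["PS"] == pytest.approx(700.0 / 140.0, rel=1e-12)

    def test_missing_muscle_label_named(self):
        vol = block_volume({"PS": (5, 5, 5), "AS": (5, 5, 5), "MG": (5, 5, 5)})
        with pytest.raises(ValueError, match="LG"):
            compute_muscle_volumes(vol, 1.78, 74.87)

    def test_volume_additivity_when_splitting_a_label(self):
        vol = block_volume(
            {"PS": (20, 20, 20), "AS": (5, 5, 5), "MG": (5, 5, 5), "LG": (5, 5, 5)}
        )
        total_before = compute_muscle_volumes(vol, 1.8, 70.0).volumes_cm3["PS"]
        data = vol.data.copy()
        ps_mask = data == DEFAULT_LABELS["PS"]
        idx = np.nonzero(ps_mask)
        half = len(idx[0]) // 2
        data[idx[0][:half], idx[1][:half], idx[2][:half]] = DEFAULT_LABELS["MG"]
        split = LabelVolume(data=data, spacing_mm=vol.spacing_mm)
        after = compute_muscle_volumes(split, 1.8, 70.0)
        merged = after.volumes_cm3["PS"] + after.volumes_cm3["MG"]
        assert merged == pytest.approx(
            total_before + compute_muscle_volumes(vol, 1.8, 70.0).volumes_cm3["MG"]
        )

    def test_relative_volumes_scale_invariant(self):
        counts = {
            "PS": (20, 20, 20),
            "AS": (6, 6, 6),
            "MG": (15, 15, 15),
            "LG": (11, 11, 11),
        }
        rel1 = compute_muscle_volumes(block_volume(counts), 1.8, 70.0).relative_pct
        rel2 = compute_muscle_volumes(
            block_volume(counts, spacing=(2.5, 2.5, 2.5)), 1.8, 70.0
        ).relative_pct
        for m in MUSCLES:
            assert rel1[m] == pytest.approx(rel2[m], rel=1e-12)

    def test_rotation_about_axial_axis_changes_volumes_little(self):
        vols = {"PS": 391.4, "AS": 83.8, "MG": 291.6, "LG": 175.1}
        v0, _ = generate_label_volume(vols, spacing_mm=PAPER_SPACING)
        v37, _ = generate_label_volume(
            vols,
            spacing_mm=PAPER_SPACING,
            orientations_deg={m: 37.0 for m in MUSCLES},
        )
        m0 = compute_muscle_volumes(v0, 1.78, 74.87).volumes_cm3
        m37 = compute_muscle_volumes(v37, 1.78, 74.87).volumes_cm3
        for m in MUSCLES:
            assert abs(m37[m] / m0[m] - 1.0) < 0.015


class TestTendonGeometry:
    def test_straight_cylinder(self):
        # r = 4 mm, 26 slices of 2 mm
        vol, truth = generate_label_volume(
            {}, TendonTubeSpec(path_length_mm=50.0, csa_mm2=np.pi * 16.0),
            spacing_mm=PAPER_SPACING,
        )
        tg = tendon_geometry(vol)
        assert len(tg.slice_indices) == 26
        assert tg.length_mm == pytest.approx(50.0, abs=1e-9)
        assert tg.mid_csa_mm2 == pytest.approx(np.pi * 16.0, rel=0.03)
        assert tg.volume_cm3 == pytest.approx(truth.tendon_volume_cm3, rel=0.03)

    def test_inclined_tube_path_length(self):
        vol, truth = generate_label_volume(
            {}, TendonTubeSpec(50.0, 50.0, incline_deg=30.0), spacing_mm=PAPER_SPACING
        )
        tg = tendon_geometry(vol)
        axial = (len(tg.slice_indices) - 1) * 2.0
        assert truth.tendon_length_mm == pytest.approx(axial / np.cos(np.radians(30)))
        assert tg.length_mm == pytest.approx(truth.tendon_length_mm, rel=0.02)

    def test_collinear_centroids_equal_straight_distance(self):
        vol, _ = generate_label_volume({}, TendonTubeSpec(40.0, 50.0), PAPER_SPACING)
        tg = tendon_geometry(vol)
        straight = np.linalg.norm(tg.centroids_mm[-1] - tg.centroids_mm[0])
        assert tg.length_mm == pytest.approx(straight, abs=1e-9)

    def test_single_slice_degenerate(self):
        vol, _ = generate_label_volume({}, TendonTubeSpec(0.0, 50.27), PAPER_SPACING)
        tg = tendon_geometry(vol)
        assert tg.length_mm == 0.0
        assert tg.volume_cm3 == pytest.approx(tg.csa_mm2[0] * 2.0 / 1000.0)
        assert tg.mid_csa_mm2 == tg.csa_mm2[0]
        assert np.ptp(tg.profile_csa_mm2) == 0.0

    def test_gap_between_landmarks_reported(self):
        vol, _ = generate_label_volume({}, TendonTubeSpec(40.0, 50.0), PAPER_SPACING)
        data = vol.data.copy()
        gap_k = int(tendon_geometry(vol).slice_indices[5])
        sl = data[:, :, gap_k]
        sl[sl == DEFAULT_LABELS["tendon"]] = 0
        broken = LabelVolume(data=data, spacing_mm=vol.spacing_mm)
        with pytest.raises(ValueError, match=str(gap_k)):
            tendon_geometry(broken)

    def test_missing_landmarks_rejected(self):
        data = np.zeros((10, 10, 10), dtype=np.int16)
        data[4:6, 4:6, 2:8] = DEFAULT_LABELS["tendon"]
        with pytest.raises(ValueError, match="landmark"):
            tendon_geometry(LabelVolume(data=data, spacing_mm=(1, 1, 1)))

    def test_explicit_landmark_slices_equivalent_to_labels(self):
        vol, _ = generate_label_volume({}, TendonTubeSpec(40.0, 50.0), PAPER_SPACING)
        tg = tendon_geometry(vol)
        k0, k1 = int(tg.slice_indices[0]), int(tg.slice_indices[-1])
        tg2 = tendon_geometry(vol, landmarks=(k0, k1))
        assert tg2.length_mm == tg.length_mm
        np.testing.assert_array_equal(tg2.csa_mm2, tg.csa_mm2)

    def test_profile_resampled_to_101_points(self):
        vol, _ = generate_label_volume(
            {}, TendonTubeSpec(50.0, (64.0, -40.0, 26.0)), PAPER_SPACING
        )
        tg = tendon_geometry(vol)
        assert tg.profile_percent.shape == (101,)
        assert tg.profile_csa_mm2[0] == pytest.approx(tg.csa_mm2[0])
        assert tg.profile_csa_mm2[-1] == pytest.approx(tg.csa_mm2[-1])


class TestRatios:
    def test_units_consistent_ratio(self):
        vol = block_volume(
            {"PS": (98, 98, 98), "AS": (5, 5, 5), "MG": (5, 5, 5), "LG": (5, 5, 5)}
        )
        m = compute_muscle_volumes(vol, 1.78, 74.87)
        r = tendon_muscle_ratios(61.35, m)
        # 0.6135 cm^2 over the total volume in cm^3
        assert r.csa_per_volume_cm["total"] == pytest.approx(
            0.6135 / m.total_cm3, rel=1e-12
        )

    def test_round_numbers(self):
        vol = block_volume(
            {"PS": (100, 100, 10), "AS": (5, 4, 5), "MG": (5, 4, 5), "LG": (5, 4, 5)}
        )
        m = compute_muscle_volumes(vol, 1.5, 80.0)
        r = tendon_muscle_ratios(100.0, m)
        assert r.csa_per_volume_cm["PS"] == pytest.approx(1.0 / 100.0, rel=1e-12)
        assert r.csa_per_heightmass_mm2_per_kgm == pytest.approx(100.0 / 120.0)

    def test_zero_volume_rejected(self):
        vol = block_volume(
            {"PS": (10, 10, 10), "AS": (5, 5, 5), "MG": (5, 5, 5), "LG": (5, 5, 5)}
        )
        m = compute_muscle_volumes(vol, 1.78, 74.87)
        m.volumes_cm3["AS"] = 0.0
        with pytest.raises(ValueError, match="AS"):
            tendon_muscle_ratios(60.0, m)


def test_rasterized_volume_error_shrinks_with_spacing():
    """Halving the voxel spacing roughly halves the volume error."""
    vols = {"PS": 120.0, "AS": 40.0, "MG": 90.0, "LG": 60.0}
    errs = []
    for spacing in ((1.44, 1.44, 4.0), (0.72, 0.72, 2.0)):
        vol, _ = generate_label_volume(vols, spacing_mm=spacing)
        m = compute_muscle_volumes(vol, 1.78, 74.87)
        errs.append(
            sum(abs(m.volumes_cm3[k] - v) / v for k, v in vols.items())
        )
    assert errs[1] < 0.8 * errs[0]
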