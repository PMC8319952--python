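"""Ring expansion and sub-OAR volume features: unit and oracle tests."""

import numpy as np
import pytest

from brachyqa.geometry import (
    N_FEATURE_RINGS,
    build_feature_vector,
    derive_rings,
    distance_map,
    sub_oar_volumes,
)
from brachyqa.structures import HRCTV, StructureError, StructureSet


def sphere_mask(radius_mm, voxel_mm, margin_mm=45.0):
    """Digitized sphere centered on the grid; returns (mask, coords-from-center)."""
    half = int(np.ceil((radius_mm + margin_mm) / voxel_mm))
    ax = voxel_mm * (np.arange(2 * half + 1) - half)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    return r <= radius_mm, r


class TestDistanceMap:
    # A single marked voxel is too small for a smoothed surface, so these
    # two tests exercise the voxel-cell fallback: distance to the cell's
    # rectangular extent, i.e. center gap minus half a voxel per axis.
    def test_zero_inside_and_axis_aligned_outside(self):
        mask = np.zeros((5, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        d = distance_map(mask, (1.0, 1.0, 1.0))
        assert d[0, 0, 0] == 0.0
        assert d[3, 0, 0] == pytest.approx(2.5)
        assert d[3, 4 - 1, 0] == pytest.approx(np.hypot(2.5, 2.5))

    def test_anisotropic_spacing_respected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        d = distance_map(mask, (1.0, 2.0, 5.0))
        assert d[0, 2, 0] == pytest.approx(2.0 * 2.0 - 1.0)
        assert d[0, 0, 1] == pytest.approx(5.0 - 2.5)

    def test_sphere_surface_distance(self):
        # analytic distance from a 20 mm sphere at a point 25 mm out is
        # 5 mm; the level-set surface estimate is well inside half a voxel
        mask, r = sphere_mask(20.0, 1.0, margin_mm=10.0)
        d = distance_map(mask, (1.0, 1.0, 1.0))
        center = tuple(s // 2 for s in mask.shape)
        probe = (center[0] + 25, center[1], center[2])
        assert abs(d[probe] - 5.0) <= 0.5

    def test_empty_mask_rejected(self):
        with pytest.raises(StructureError, match="empty structure"):
            distance_map(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestDeriveRings:
    def _structures(self, voxel=2.0):
        mask, _ = sphere_mask(20.0, voxel, margin_mm=60.0)
        return StructureSet(masks={HRCTV: mask}, spacing=(voxel,) * 3)

    def test_defaults_and_shell_assignment(self):
        s = self._structures()
        rings = derive_rings(s)
        assert rings.width_mm == 5.0 and rings.n_max == 10
        d = distance_map(s.masks[HRCTV], s.spacing)
        # half-open shells: (k-1)*5 < d <= k*5
        for k in (1, 2):
            sel = rings.ring_index == k
            assert d[sel].min() > (k - 1) * 5.0
            assert d[sel].max() <= k * 5.0
        assert (rings.ring_index[d > 50.0] == 0).all()
        assert (rings.ring_index[s.masks[HRCTV]] == 0).all()

    def test_rings_partition_the_expansion_margin(self):
        s = self._structures()
        rings = derive_rings(s)
        d = distance_map(s.masks[HRCTV], s.spacing)
        in_margin = (d > 0) & (d <= 50.0)
        assert (rings.ring_index > 0).sum() == in_margin.sum()
        # pairwise disjoint by construction: each voxel has one index
        counts = np.bincount(rings.ring_index.ravel())[1:]
        assert counts.sum() == in_margin.sum()

    @pytest.mark.parametrize("bad", [{"width_mm": 0.0}, {"width_mm": -1.0}, {"n_max": 0}])
    def test_parameter_validation(self, bad):
        with pytest.raises(ValueError):
            derive_rings(self._structures(), **bad)


def shell_volume_cm3(r_in_mm, r_out_mm):
    return 4.0 / 3.0 * np.pi * (r_out_mm**3 - r_in_mm**3) / 1000.0


class TestSubOARVolumes:
    def test_concentric_shell_matches_closed_form(self):
        # HR-CTV sphere r=20 mm, organ = shell 20-40 mm: ring k holds the
        # spherical shell (20+5(k-1), 20+5k] up to 40 mm
        voxel = 1.0
        mask, r = sphere_mask(20.0, voxel)
        organ = (r > 20.0) & (r <= 40.0)
        s = StructureSet(masks={HRCTV: mask, "rectum": organ}, spacing=(voxel,) * 3)
        sub = sub_oar_volumes(derive_rings(s), s, "rectum")
        for k in range(1, 5):
            expected = shell_volume_cm3(20 + 5 * (k - 1), 20 + 5 * k)
            assert sub.volumes_cm3[k - 1] == pytest.approx(expected, rel=0.02)
        assert sub.total_cm3 == pytest.approx(shell_volume_cm3(20, 40), rel=0.02)

    def test_distant_organ_has_zero_ring_volumes(self):
        mask, r = sphere_mask(10.0, 2.0, margin_mm=80.0)
        organ = r > 70.0  # beyond n_max * width = 50 mm from the surface
        s = StructureSet(masks={HRCTV: mask, "bladder": organ}, spacing=(2.0,) * 3)
        sub = sub_oar_volumes(derive_rings(s), s, "bladder")
        assert all(v == 0.0 for v in sub.volumes_cm3)

    def test_offset_sphere_matches_fine_grid_oracle(self):
        # organ sphere r=15 at (30,0,0) next to HR-CTV sphere r=20 at origin;
        # oracle counts 0.5 mm cells using the *analytic* surface distance
        voxel = 1.0
        mask, r = sphere_mask(20.0, voxel, margin_mm=30.0)
        half = mask.shape[0] // 2
        ax = voxel * (np.arange(mask.shape[0]) - half)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        organ = ((xx - 30.0) ** 2 + yy**2 + zz**2 <= 15.0**2) & ~mask
        s = StructureSet(masks={HRCTV: mask, "bladder": organ}, spacing=(voxel,) * 3)
        sub = sub_oar_volumes(derive_rings(s), s, "bladder")

        fine = 0.5
        fx = np.arange(15.0, 45.0 + fine, fine)
        fyz = np.arange(-15.0, 15.0 + fine, fine)
        gx, gy, gz = np.meshgrid(fx, fyz, fyz, indexing="ij")
        in_organ = (gx - 30.0) ** 2 + gy**2 + gz**2 <= 15.0**2
        dist = np.sqrt(gx**2 + gy**2 + gz**2) - 20.0
        cell = fine**3 / 1000.0
        for k in range(1, 6):
            shell = in_organ & (dist > 5.0 * (k - 1)) & (dist <= 5.0 * k)
            expected = shell.sum() * cell
            assert sub.volumes_cm3[k - 1] == pytest.approx(expected, rel=0.02)

    def test_volume_conservation(self, small_plans):
        for rec in small_plans:
            s = rec.structures
            rings = derive_rings(s)
            d = distance_map(s.masks[HRCTV], s.spacing)
            for organ in s.organ_names():
                sub = sub_oar_volumes(rings, s, organ)
                beyond = (s.masks[organ] & (d > 50.0)).sum() * s.voxel_volume_cm3
                assert sum(sub.volumes_cm3) + beyond == pytest.approx(
                    sub.total_cm3, rel=1e-9
                )

    def test_unknown_organ_rejected(self, small_plans):
        s = small_plans[0].structures
        with pytest.raises(KeyError):
            sub_oar_volumes(derive_rings(s), s, "liver")


class TestFeatureVector:
    def _set_with(self, organs):
        mask, r = sphere_mask(10.0, 2.0, margin_mm=40.0)
        masks = {HRCTV: mask}
        for name, lo, hi in organs:
            masks[name] = (r > lo) & (r <= hi)
        return StructureSet(masks=masks, spacing=(2.0,) * 3)

    def test_pelvic_organs_lead_with_hrctv_volume(self):
        s = self._set_with([("rectum", 12.0, 25.0)])
        sub = sub_oar_volumes(derive_rings(s), s, "rectum")
        fv = build_feature_vector(sub, s, "rectum")
        assert len(fv.values) == 1 + N_FEATURE_RINGS
        assert fv.values[0] == pytest.approx(s.volume_cm3(HRCTV))
        assert fv.names[0] == "V_hrctv"

    def test_small_intestine_leads_with_bladder_volume(self):
        s = self._set_with([("bladder", 12.0, 25.0), ("small_intestine", 30.0, 45.0)])
        sub = sub_oar_volumes(derive_rings(s), s, "small_intestine")
        fv = build_feature_vector(sub, s, "small_intestine")
        assert fv.values[0] == pytest.approx(s.volume_cm3("bladder"))
        assert fv.names[0] == "V_bladder"

    def test_small_intestine_requires_bladder(self):
        s = self._set_with([("small_intestine", 30.0, 45.0)])
        sub = sub_oar_volumes(derive_rings(s), s, "small_intestine")
        with pytest.raises(StructureError, match="bladder"):
            build_feature_vector(sub, s, "small_intestine")

    def test_all_zero_sub_volumes_keep_global_volume(self):
        s = self._set_with([("rectum", 70.0, 78.0)])
        sub = sub_oar_volumes(derive_rings(s), s, "rectum")
        fv = build_feature_vector(sub, s, "rectum")
        assert fv.values[0] > 0
        assert np.all(fv.values[1:] == 0.0)


class TestStructureSetInvariants:
    def test_overlap_with_hrctv_is_an_error(self):
        mask, r = sphere_mask(10.0, 2.0, margin_mm=10.0)
        overlapping = r <= 12.0
        with pytest.raises(StructureError, match="overlaps"):
            StructureSet(
                masks={HRCTV: mask, "bladder": overlapping}, spacing=(2.0,) * 3
            )

    def test_bad_spacing_and_empty_target(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(StructureError):
            StructureSet(masks={HRCTV: mask}, spacing=(1.0, -1.0, 1.0))
        with pytest.raises(StructureError, match="empty"):
            StructureSet(
                masks={HRCTV: np.zeros((3, 3, 3), dtype=bool)}, spacing=(1, 1, 1)
            )
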