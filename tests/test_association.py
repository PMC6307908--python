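import numpy as np
import pytest

from xenovasc import (
    FrameScore,
    RegionSpec,
    angiogenic_region,
    association_summary,
    disc_pixel_mask,
    place_control_region,
    score_frame,
    threshold_objects,
)
from xenovasc.exceptions import NoAdmissibleControlError, TipOutOfBoundsError

from _oracles import disc_pixels_bruteforce
from conftest import make_stack

VOXEL = (8.0, 0.5, 0.5)


def _vessel_objects(mask):
    stack = make_stack({"vessel": np.where(mask, 200.0, 0.0)}, voxel_size=VOXEL)
    return threshold_objects(stack, "vessel", 100, float(np.prod(VOXEL)))


def _macrophage_objects(positions_um, shape=(6, 120, 120), radius=4.0):
    """Render small spheres and segment them back into an ObjectSet."""
    arr = np.zeros(shape)
    vs = np.array(VOXEL)
    for p in positions_um:
        lo = np.maximum(((np.asarray(p) - radius) / vs).astype(int), 0)
        hi = np.minimum(((np.asarray(p) + radius) / vs).astype(int) + 2, shape)
        for z in range(lo[0], hi[0]):
            for y in range(lo[1], hi[1]):
                for x in range(lo[2], hi[2]):
                    c = (np.array([z, y, x]) + 0.5) * vs
                    if np.linalg.norm(c - p) <= radius:
                        arr[z, y, x] = 250.0
    stack = make_stack({"macrophage": arr}, voxel_size=VOXEL)
    return threshold_objects(stack, "macrophage", 100, float(np.prod(VOXEL)))


class TestDiscGeometry:
    def test_pixel_mask_matches_bruteforce(self):
        mask = disc_pixel_mask((80, 80), (0.5, 0.5), (20.0, 20.0), 10.0)
        expected = disc_pixels_bruteforce((80, 80), (0.5, 0.5), (20.0, 20.0), 10.0)
        assert {tuple(v) for v in np.argwhere(mask)} == expected


class TestAngiogenicRegion:
    def test_z_slices_from_vessel_under_disc(self):
        mask = np.zeros((6, 120, 120), dtype=bool)
        mask[1:4, 38:42, 38:42] = True  # vessel spanning z 1..3 under the tip
        objs = _vessel_objects(mask)
        region = angiogenic_region((2.5 * 8, 20.0, 20.0), objs, 10.0, (6, 120, 120), VOXEL)
        assert region.z_slices == frozenset({1, 2, 3})
        assert region.centre_yx == (20.0, 20.0)

    def test_fallback_to_tip_slice_without_vessel(self):
        objs = _vessel_objects(np.zeros((6, 120, 120), dtype=bool))
        region = angiogenic_region((2.5 * 8, 20.0, 20.0), objs, 10.0, (6, 120, 120), VOXEL)
        assert region.z_slices == frozenset({2})

    def test_tip_outside_bounds(self):
        objs = _vessel_objects(np.zeros((6, 120, 120), dtype=bool))
        with pytest.raises(TipOutOfBoundsError):
            angiogenic_region((100.0, 20.0, 20.0), objs, 10.0, (6, 120, 120), VOXEL)


class TestControlPlacement:
    def test_only_admissible_angle_chosen(self):
        angio = RegionSpec((40.0, 40.0), 10.0, frozenset({2}), "angiogenic")
        graft = np.zeros((6, 160, 160), dtype=bool)
        # graft covers the angio disc and a corridor at angle 90 deg (+y)
        graft[2] = disc_pixel_mask((160, 160), (0.5, 0.5), (40.0, 40.0), 12.0)
        graft[2] |= disc_pixel_mask((160, 160), (0.5, 0.5), (65.0, 40.0), 11.0)
        control = place_control_region(angio, graft, np.zeros_like(graft), 25.0, VOXEL)
        assert control.centre_yx == pytest.approx((65.0, 40.0))
        assert control.kind == "control"
        assert control.z_slices == angio.z_slices

    def test_tie_broken_by_smallest_angle(self):
        angio = RegionSpec((40.0, 40.0), 10.0, frozenset({2}), "angiogenic")
        graft = np.ones((6, 160, 160), dtype=bool)  # whole field
        control = place_control_region(angio, graft, np.zeros_like(graft), 25.0, VOXEL)
        # no vessels: every admissible angle ties; angle 0 (+x) wins
        assert control.centre_yx == pytest.approx((40.0, 65.0))

    def test_farthest_from_vessels_wins(self):
        angio = RegionSpec((40.0, 40.0), 10.0, frozenset({2}), "angiogenic")
        graft = np.ones((6, 160, 160), dtype=bool)
        vessels = np.zeros_like(graft)
        vessels[2, :, 140:] = True  # vessels on the +x side
        control = place_control_region(angio, graft, vessels, 25.0, VOXEL)
        # farthest candidate from the vessel wall is at angle 180 (-x)
        assert control.centre_yx == pytest.approx((40.0, 15.0))

    def test_no_admissible_candidate(self):
        angio = RegionSpec((30.0, 30.0), 10.0, frozenset({2}), "angiogenic")
        graft = np.zeros((6, 120, 120), dtype=bool)
        graft[2] = disc_pixel_mask((120, 120), (0.5, 0.5), (30.0, 30.0), 12.0)
        with pytest.raises(NoAdmissibleControlError):
            place_control_region(angio, graft, np.zeros_like(graft), 25.0, VOXEL)

    def test_admissibility_matches_per_pixel_scan(self):
        angio = RegionSpec((30.0, 30.0), 6.0, frozenset({2}), "angiogenic")
        rng = np.random.default_rng(5)
        graft = np.zeros((6, 120, 120), dtype=bool)
        graft[2] = rng.random((120, 120)) < 0.9
        vessels = np.zeros_like(graft)
        import math

        admissible = []
        for angle in range(0, 360, 15):
            cy = 30.0 + 20.0 * math.sin(math.radians(angle))
            cx = 30.0 + 20.0 * math.cos(math.radians(angle))
            pixels = disc_pixels_bruteforce((120, 120), (0.5, 0.5), (cy, cx), 6.0)
            inside_grid = cy - 6.0 >= 0 and cx - 6.0 >= 0 and cy + 6.0 <= 60 and cx + 6.0 <= 60
            if inside_grid and all(graft[2][p] for p in pixels):
                admissible.append(angle)
        if admissible:
            control = place_control_region(angio, graft, vessels, 20.0, VOXEL)
            expected_angle = admissible[0]  # all tie (no vessels) -> smallest angle
            cy = 30.0 + 20.0 * math.sin(math.radians(expected_angle))
            cx = 30.0 + 20.0 * math.cos(math.radians(expected_angle))
            assert control.centre_yx == pytest.approx((cy, cx))
        else:
            with pytest.raises(NoAdmissibleControlError):
                place_control_region(angio, graft, vessels, 20.0, VOXEL)


class TestScoreFrame:
    def test_inside_radius_and_z_counted(self):
        region = RegionSpec((30.0, 30.0), 10.0, frozenset({2}), "angiogenic")
        objs = _macrophage_objects([(2.5 * 8, 30.0, 39.9)])  # 9.9 µm from centre
        score = score_frame(objs, region)
        assert score.count == 1 and score.present

    def test_wrong_z_sections_not_counted(self):
        """A macrophage inside the disc but on other optical sections than
        the vessel is excluded by the same-z-section co-localisation rule."""
        region = RegionSpec((30.0, 30.0), 10.0, frozenset({5}), "angiogenic")
        objs = _macrophage_objects([(2.5 * 8, 30.0, 30.0)])  # z sections ~2 only
        score = score_frame(objs, region)
        assert score.count == 0 and not score.present

    def test_outside_radius_not_counted(self):
        region = RegionSpec((30.0, 30.0), 10.0, frozenset({2}), "angiogenic")
        objs = _macrophage_objects([(2.5 * 8, 30.0, 40.6)])
        # rendered centroid sits within 0.25 µm of the requested position;
        # 10.6 µm from the centre stays outside even with that quantisation
        score = score_frame(objs, region)
        assert score.count == 0

    def test_counts_match_allpairs_bruteforce(self, rng):
        region = RegionSpec((30.0, 30.0), 10.0, frozenset({1, 2}), "control")
        positions = [(rng.uniform(8, 40), rng.uniform(15, 45), rng.uniform(15, 45)) for _ in range(6)]
        objs = _macrophage_objects(positions)
        expected = 0
        for k in range(1, len(objs) + 1):
            cz, cy, cx = objs.centroids[k - 1]
            in_disc = np.hypot(cy - 30.0, cx - 30.0) <= 10.0 + 1e-9
            zs = {int(z) for z in np.unique(np.nonzero((objs.labels == k).any(axis=(1, 2)))[0])}
            expected += in_disc and bool(zs & {1, 2})
        assert score_frame(objs, region).count == expected


class TestAssociationSummary:
    def test_percent_and_mean(self):
        scores = [
            FrameScore(0, "angiogenic", True, 1),
            FrameScore(1, "angiogenic", True, 2),
            FrameScore(2, "angiogenic", False, 0),
            FrameScore(3, "angiogenic", False, 0),
            FrameScore(0, "control", False, 0),
            FrameScore(1, "control", True, 1),
            FrameScore(2, "control", True, 2),
            FrameScore(3, "control", True, 1),
        ]
        s = association_summary(scores)
        assert s["angiogenic"]["percent_frames_present"] == pytest.approx(50.0)
        assert s["control"]["mean_count_per_frame"] == pytest.approx(1.0)

    def test_present_consistency_enforced(self):
        with pytest.raises(ValueError):
            FrameScore(0, "control", True, 0)
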