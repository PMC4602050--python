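"""Colour-threshold signal extraction and landmark-mesh warping."""

import numpy as np
import pytest

from emas.intervals import Frame, IntervalDomain, from_mask, is_subset, to_mask
from emas.mapping import (
    ColourThresholds,
    HSVBand,
    LandmarkSet,
    apply_warp,
    build_warp,
    extract_signal,
    map_entry,
)
from emas.similarity import jaccard
from emas.synthetic import default_thresholds, make_assay_case


class TestColourThresholds:
    def test_nesting_enforced_at_load(self):
        with pytest.raises(ValueError, match="nesting"):
            ColourThresholds(
                {
                    "detected": HSVBand(hue=(250, 290), sat_min=0.5),
                    "strong": HSVBand(hue=(200, 320), sat_min=0.1),
                }
            )

    def test_detected_required(self):
        with pytest.raises(ValueError, match="detected"):
            ColourThresholds({"strong": HSVBand(hue=(250, 290))})

    def test_json_roundtrip(self, tmp_path):
        th = default_thresholds()
        th.to_json(tmp_path / "th.json")
        th2 = ColourThresholds.from_json(tmp_path / "th.json")
        assert th2.bands == th.bands

    def test_wrapping_hue_band_matches_both_sides(self):
        band = HSVBand(hue=(350, 10), sat_min=0.0)
        h = np.array([355.0, 5.0, 180.0])
        ones = np.ones(3)
        assert band.match(h, ones, ones).tolist() == [True, True, False]


class TestExtractSignal:
    def test_pure_signal_disc_recovered_exactly(self):
        img = np.full((40, 40, 3), (235, 228, 214), dtype=np.uint8)
        yy, xx = np.ogrid[:40, :40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        img[disc] = (95, 40, 135)
        levels = extract_signal(img, default_thresholds())
        assert levels["detected"] == from_mask(disc)

    def test_no_matching_pixels_gives_all_empty(self):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        levels = extract_signal(img, default_thresholds())
        assert all(d.is_empty for d in levels.values())

    def test_nesting_holds_on_random_images(self, rng):
        img = rng.integers(0, 256, size=(30, 30, 3), dtype=np.uint8)
        levels = extract_signal(img, default_thresholds())
        assert is_subset(levels["strong"], levels["moderate"])
        assert is_subset(levels["moderate"], levels["weak"])
        assert is_subset(levels["weak"], levels["detected"])

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            extract_signal(np.zeros((5, 5)), default_thresholds())

    def test_exclusion_region_subtracted(self):
        img = np.full((20, 20, 3), (95, 40, 135), dtype=np.uint8)
        excl = from_mask(np.pad(np.ones((5, 20), bool), ((0, 15), (0, 0))))
        levels = extract_signal(img, default_thresholds(), exclusion=excl)
        assert levels["detected"].size == 15 * 20


class TestWarp:
    def test_too_few_or_collinear_landmarks_rejected(self):
        with pytest.raises(ValueError, match="3"):
            LandmarkSet([[0, 0], [1, 1]], [[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="collinear"):
            LandmarkSet([[0, 0], [1, 1], [2, 2]], [[0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="duplicate"):
            LandmarkSet([[0, 0], [0, 0], [2, 1]], [[0, 0], [1, 1], [2, 1]])

    def test_identity_landmarks_fix_probe_points(self, rng):
        pts = np.array([[0, 0], [20, 0], [0, 20], [20, 20], [10, 5]], float)
        warp = build_warp(LandmarkSet(pts, pts))
        probes = rng.uniform(1, 19, size=(200, 2))
        assert np.allclose(warp.forward(probes), probes, atol=1e-9)

    def test_translation_landmarks_translate_probes(self, rng):
        pts = np.array([[0, 0], [20, 0], [0, 20], [20, 20]], float)
        shift = np.array([3.5, -2.0])
        warp = build_warp(LandmarkSet(pts, pts + shift))
        probes = rng.uniform(1, 19, size=(100, 2))
        assert np.allclose(warp.forward(probes), probes + shift, atol=1e-9)

    def test_exact_landmark_interpolation(self, rng):
        src = rng.uniform(0, 50, size=(12, 2))
        dst = src + rng.uniform(-4, 4, size=(12, 2))
        lm = LandmarkSet(src, dst)
        warp = build_warp(lm)
        assert np.allclose(warp.forward(src), dst, atol=1e-9)

    def test_reproduces_known_affine_at_interior_probes(self, rng):
        aff = np.array([[1.05, 0.1, 2.0], [-0.08, 0.95, -1.0], [0, 0, 1.0]])
        src = np.array(
            [[0, 0], [40, 0], [0, 40], [40, 40], [20, 20], [10, 30], [30, 10], [5, 20]],
            float,
        )
        dst = (aff @ np.vstack([src.T, np.ones(len(src))]))[:2].T
        warp = build_warp(LandmarkSet(src, dst))
        probes = rng.uniform(1, 39, size=(1000, 2))
        want = (aff @ np.vstack([probes.T, np.ones(len(probes))]))[:2].T
        assert np.allclose(warp.forward(probes), want, atol=1e-8)

    def test_outside_hull_is_nan(self):
        pts = np.array([[0, 0], [10, 0], [0, 10]], float)
        warp = build_warp(LandmarkSet(pts, pts))
        out = warp.forward(np.array([[50.0, 50.0]]))
        assert np.isnan(out).all()


class TestApplyWarp:
    def _frame(self):
        return Frame("model", (40, 40))

    def test_identity_warp_preserves_domain(self):
        pts = np.array([[0, 0], [39, 0], [0, 39], [39, 39]], float)
        warp = build_warp(LandmarkSet(pts, pts))
        mask = np.zeros((40, 40), bool)
        mask[10:20, 5:25] = True
        dom = from_mask(mask)
        out = apply_warp(dom, warp, self._frame())
        assert np.array_equal(to_mask(out, (40, 40)), mask)

    def test_translation_warp_translates_block(self):
        pts = np.array([[0, 0], [39, 0], [0, 39], [39, 39]], float)
        warp = build_warp(LandmarkSet(pts, pts + [4.0, 3.0]))
        mask = np.zeros((40, 40), bool)
        mask[10:15, 5:10] = True
        out = apply_warp(from_mask(mask), warp, self._frame())
        assert np.array_equal(to_mask(out, (40, 40)), np.roll(mask, (3, 4), (0, 1)))

    def test_affine_disc_matches_dense_resample_oracle(self, rng):
        from scipy import ndimage

        aff2 = np.array([[0.95, 0.12], [-0.1, 1.02]])
        off = np.array([2.0, -1.0])
        corners = np.array([[0, 0], [39, 0], [0, 39], [39, 39], [20, 10], [10, 30]], float)
        dst = corners @ aff2.T + off
        warp = build_warp(LandmarkSet(corners, dst))
        yy, xx = np.ogrid[:40, :40]
        mask = (yy - 18) ** 2 + (xx - 20) ** 2 <= 100
        out = apply_warp(from_mask(mask), warp, self._frame())
        # oracle: inverse-map the dense mask with the same affine
        inv = np.linalg.inv(aff2)
        gy, gx = np.mgrid[0:40, 0:40]
        src = (np.stack([gx.ravel(), gy.ravel()], 1) - off) @ inv.T
        sx, sy = np.rint(src[:, 0]).astype(int), np.rint(src[:, 1]).astype(int)
        ok = (sx >= 0) & (sx < 40) & (sy >= 0) & (sy < 40)
        want = np.zeros(1600, bool)
        want[ok] = mask[sy[ok], sx[ok]]
        want = want.reshape(40, 40)
        got = to_mask(out, (40, 40))
        agree = (got == want).mean()
        assert agree >= 0.99

    def test_warped_levels_keep_nesting(self):
        case = make_assay_case(seed=4)
        pat = map_entry(
            case.image, case.landmarks, case.thresholds, case.model_frame, entry_id="E"
        )
        assert is_subset(pat.levels["strong"], pat.levels["detected"])


class TestMapEntry:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_end_to_end_recovery(self, seed):
        case = make_assay_case(seed=seed)
        pat = map_entry(
            case.image,
            case.landmarks,
            case.thresholds,
            case.model_frame,
            entry_id=f"E{seed}",
            gene="Foxc2",
        )
        assert jaccard(pat.detected, case.truth) >= 0.95

    def test_identity_case_detected_equals_threshold_domain(self):
        case = make_assay_case(seed=11, deformation="identity")
        pat = map_entry(
            case.image, case.landmarks, case.thresholds, case.model_frame, entry_id="E"
        )
        direct = extract_signal(case.image, case.thresholds)
        got = to_mask(pat.detected, case.model_frame.shape)
        want = to_mask(direct["detected"], case.model_frame.shape)
        # identical inside the landmark hull (signal sits well inside it)
        assert np.array_equal(got, want)
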