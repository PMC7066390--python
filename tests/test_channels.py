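"""Channel recipes: DAPI two-run nuclei, Pax5 gating, macrophages, masks."""

import dataclasses

import numpy as np
import pytest

from lymphoseg.channels import (
    DAPI_CONFIG,
    MACROPHAGE_CONFIG,
    PAX5_CONFIG,
    ChannelConfig,
    EvalMaskParams,
    double_stain_masks,
    segment_bcells_pax5,
    segment_macrophages,
    segment_nuclei_dapi,
    tissue_eval_mask,
)
from lymphoseg.engine import floating_threshold_detect
from lymphoseg.features import RuleParams
from lymphoseg.imgio import BinaryMask, GreyImage
from lymphoseg.synthetic import score_against_truth

from conftest import draw_disk


def draw_ellipse_img(shape, center, a, b, value, canvas=None):
    img = np.zeros(shape, dtype=np.uint8) if canvas is None else canvas
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = ((yy - center[0]) / a) ** 2 + ((xx - center[1]) / b) ** 2 <= 1
    img[inside] = value
    return img


class TestDapiNuclei:
    def test_blank_dapi_is_empty(self):
        res = segment_nuclei_dapi(GreyImage(np.zeros((60, 60), dtype=np.uint8)))
        assert res.n_features == 0

    def test_two_nuclei_of_different_size_windows(self):
        img = np.zeros((120, 120), dtype=np.uint8)
        draw_ellipse_img((120, 120), (30, 30), 5.4, 5.4, 170, img)   # ~90 px
        draw_ellipse_img((120, 120), (85, 85), 7.0, 7.0, 150, img)   # ~150 px
        res = segment_nuclei_dapi(GreyImage(img))
        assert res.n_features == 2
        # merged output features are pairwise disjoint
        seen = set()
        for f in res.features:
            px = set(map(tuple, f.coords))
            assert not (px & seen)
            seen |= px

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChannelConfig(channel="DAPI", runs=(DAPI_CONFIG.runs[0],))

    def test_run2_disjointness_on_synthetic(self, dapi_cartoon):
        res = segment_nuclei_dapi(dapi_cartoon)
        union = np.zeros(res.segment.shape, dtype=np.int64)
        for f in res.features:
            union[f.coords[:, 0], f.coords[:, 1]] += 1
        assert union.max() <= 1


class TestPax5Gating:
    @pytest.fixture()
    def nuclei_and_shape(self):
        shape = (140, 140)
        img = np.zeros(shape, dtype=np.uint8)
        draw_ellipse_img(shape, (40, 40), 5.4, 5.4, 170, img)
        nuclei = segment_nuclei_dapi(GreyImage(img))
        assert nuclei.n_features == 1
        return nuclei, shape

    def test_blob_on_nucleus_kept_far_blob_dropped(self, nuclei_and_shape):
        nuclei, shape = nuclei_and_shape
        pax = np.zeros(shape, dtype=np.uint8)
        draw_ellipse_img(shape, (40, 40), 6.0, 6.0, 160, pax)    # on the nucleus
        draw_ellipse_img(shape, (110, 110), 6.0, 6.0, 160, pax)  # 50+ px away
        res = segment_bcells_pax5(GreyImage(pax), nuclei)
        assert res.n_features == 1
        f = res.features[0]
        assert abs(f.coords[:, 0].mean() - 40) < 5
        # every surviving feature touches a nucleus hull
        hulls = nuclei.convhull.astype_bool()
        for f in res.features:
            assert hulls[f.coords[:, 0], f.coords[:, 1]].any()

    def test_shape_mismatch_raises(self, nuclei_and_shape):
        nuclei, _ = nuclei_and_shape
        with pytest.raises(ValueError):
            segment_bcells_pax5(GreyImage(np.zeros((60, 60), dtype=np.uint8)), nuclei)

    def test_three_blobs_two_over_nuclei(self, clean_tile):
        images, truth = clean_tile
        nuclei = segment_nuclei_dapi(images["DAPI"])
        bcells = segment_bcells_pax5(images["Pax5"], nuclei)
        sc = score_against_truth(bcells.segment, truth.bcell_mask)
        assert sc.precision == 1.0  # artifact blobs all gated out
        assert sc.recall >= 0.9


class TestMacrophages:
    def test_blank_channel_empty_masks(self):
        res = segment_macrophages(GreyImage(np.zeros((80, 80), dtype=np.uint8)))
        assert not res.segment.pixels.any()
        assert not res.convhull.pixels.any()

    def test_star_shape_fails_hull_excess(self):
        # a plus/star of thin arms: hull area far exceeds pixel area
        img = np.zeros((100, 100), dtype=np.uint8)
        img[48:52, 10:90] = 180
        img[10:90, 48:52] = 180
        rules = RuleParams(s_min=150, s_max=2000, r_max=4.0, c_max=100)
        cfg = ChannelConfig(channel="CD14", runs=(rules,))
        res = segment_macrophages(GreyImage(img), cfg)
        assert res.n_features == 0

    def test_well_separated_blobs_recovered(self, clean_tile):
        images, truth = clean_tile
        res = segment_macrophages(images["CD14"])
        sc = score_against_truth(res.segment, truth.cd14_mask)
        assert sc.recall >= 0.9


class TestDoubleStain:
    def run_channel(self, img):
        return segment_macrophages(GreyImage(img))

    def test_identical_feature_in_both_channels(self):
        img = draw_disk((100, 100), (50, 50), 9, value=180)
        a = self.run_channel(img)
        b = self.run_channel(img.copy())
        mul_a, mul_b = double_stain_masks(a, b)
        np.testing.assert_array_equal(mul_a.pixels, a.segment.pixels)
        np.testing.assert_array_equal(mul_b.pixels, b.segment.pixels)

    def test_disjoint_channels_empty_masks(self):
        a = self.run_channel(draw_disk((100, 100), (25, 25), 9, value=180))
        b = self.run_channel(draw_disk((100, 100), (75, 75), 9, value=180))
        mul_a, mul_b = double_stain_masks(a, b)
        assert not mul_a.pixels.any()
        assert not mul_b.pixels.any()

    def test_partial_hull_overlap_counts(self):
        a = self.run_channel(draw_disk((100, 100), (50, 44), 9, value=180))
        b = self.run_channel(draw_disk((100, 100), (50, 58), 9, value=180))
        mul_a, mul_b = double_stain_masks(a, b)
        np.testing.assert_array_equal(mul_a.pixels, a.segment.pixels)
        np.testing.assert_array_equal(mul_b.pixels, b.segment.pixels)

    def test_multiple_subset_of_segment(self, small_tile):
        images, _ = small_tile
        a = segment_macrophages(images["CD14"])
        b = segment_macrophages(
            images["CD163"], dataclasses.replace(MACROPHAGE_CONFIG, channel="CD163")
        )
        mul_a, mul_b = double_stain_masks(a, b)
        assert not (mul_a.pixels & (1 - a.segment.pixels)).any()
        assert not (mul_b.pixels & (1 - b.segment.pixels)).any()

    def test_shape_mismatch_raises(self):
        a = self.run_channel(draw_disk((100, 100), (50, 50), 9))
        b = self.run_channel(draw_disk((80, 80), (40, 40), 9))
        with pytest.raises(ValueError):
            double_stain_masks(a, b)


class TestEvalMask:
    def test_blank_dapi_empty_mask(self):
        mask = tissue_eval_mask(GreyImage(np.zeros((50, 50), dtype=np.uint8)))
        assert not mask.pixels.any()

    def test_covers_tissue_and_excludes_glass(self, dapi_cartoon, small_tile):
        _, truth = small_tile
        ev = tissue_eval_mask(dapi_cartoon)
        tissue = truth.tissue_mask.astype_bool()
        glass = ~tissue
        assert (ev.astype_bool() & tissue).sum() / tissue.sum() >= 0.9
        assert (ev.astype_bool() & glass).sum() / glass.sum() <= 0.05

    def test_every_nucleus_inside_evalmask(self, dapi_cartoon):
        ev = tissue_eval_mask(dapi_cartoon)
        nuclei = segment_nuclei_dapi(dapi_cartoon, region=ev)
        assert not (nuclei.segment.pixels & (1 - ev.pixels)).any()
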