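"""I/O, naming-convention and tiling behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from lymphoseg.imgio import (
    CHANNELS,
    VALID_CHANNEL_TYPES,
    BinaryMask,
    GreyImage,
    TileRecord,
    build_filename,
    logfile_name,
    parse_filename,
    read_png,
    rgb_to_grey_modulus,
    tile_slide,
    write_logfile,
    write_png,
)


class TestRgbToGreyModulus:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((0, 0, 0), 0),        # zero vector
            ((200, 0, 0), 200),    # single nonzero channel is preserved
            ((0, 0, 200), 200),
            ((200, 200, 200), 255),  # round(200*sqrt(3)) = 346 clips to 255
            ((100, 100, 100), 173),  # round(100*sqrt(3))
        ],
    )
    def test_pixel_values(self, rgb, expected):
        grid = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        assert rgb_to_grey_modulus(grid).pixels[0, 0] == expected

    def test_unclipped_variant_rescales(self):
        grid = np.full((1, 1, 3), 255, dtype=np.uint8)
        assert rgb_to_grey_modulus(grid, clip=False).pixels[0, 0] == 255
        grid = np.zeros((1, 1, 3), dtype=np.uint8)
        grid[0, 0, 0] = 255
        # a single saturated channel shrinks by 1/sqrt(3) when rescaling
        assert rgb_to_grey_modulus(grid, clip=False).pixels[0, 0] == 147

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_grey_modulus(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            rgb_to_grey_modulus(np.zeros((4, 4)))


class TestTileSlide:
    def test_exact_fit_single_tile(self):
        slide = GreyImage(np.arange(1_000_000, dtype=np.int64).reshape(1000, 1000) % 256)
        tiles = list(tile_slide(slide))
        assert len(tiles) == 1
        assert tiles[0][0] == (1, 1)
        np.testing.assert_array_equal(tiles[0][1].pixels, slide.pixels)

    def test_border_bands(self):
        slide = GreyImage(np.zeros((2500, 1800), dtype=np.uint8))
        tiles = dict(tile_slide(slide))
        assert len(tiles) == 6
        assert set(tiles) == {(r, c) for r in (1, 2, 3) for c in (1, 2)}
        assert tiles[(1, 1)].shape == (1000, 1000)
        assert tiles[(3, 1)].shape == (500, 1000)   # bottom band
        assert tiles[(1, 2)].shape == (1000, 800)   # right band
        assert tiles[(3, 2)].shape == (500, 800)

    def test_one_pixel_remainder(self):
        slide = GreyImage(np.zeros((999, 1001), dtype=np.uint8))
        tiles = dict(tile_slide(slide))
        assert set(tiles) == {(1, 1), (1, 2)}
        assert tiles[(1, 1)].shape == (999, 1000)
        assert tiles[(1, 2)].shape == (999, 1)

    def test_invalid_tile_dims(self):
        slide = GreyImage(np.zeros((10, 10), dtype=np.uint8))
        with pytest.raises(ValueError):
            list(tile_slide(slide, tile_h=0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        h=st.integers(1, 90), w=st.integers(1, 90),
        th=st.integers(1, 40), tw=st.integers(1, 40),
        seed=st.integers(0, 2**16),
    )
    def test_partition_reassembles_and_counts(self, h, w, th, tw, seed):
        rng = np.random.default_rng(seed)
        slide = GreyImage(rng.integers(0, 256, size=(h, w), dtype=np.uint8))
        tiles = list(tile_slide(slide, th, tw))
        assert len(tiles) == -(-h // th) * -(-w // tw)
        out = np.full((h, w), 255, dtype=np.int16)
        for (r, c), t in tiles:
            r0, c0 = (r - 1) * th, (c - 1) * tw
            out[r0 : r0 + t.shape[0], c0 : c0 + t.shape[1]] = t.pixels
        np.testing.assert_array_equal(out, slide.pixels)


class TestFilenames:
    def test_published_example(self):
        rec = TileRecord(2, 1, 6, "CD14", "original")
        assert build_filename(rec) == (
            "specimen_02_tile_01_06_channel_CD14_type_original_mode_gs.png"
        )

    def test_logfile_double_underscore(self):
        assert logfile_name(2, 1, 6) == "specimen_02_tile_01_06__logfile.txt"

    @pytest.mark.parametrize(
        "channel,img_type",
        [("DAPI", "multiple"), ("Pax5", "multiple"), ("Pax5", "evalmask"),
         ("CD14", "evalmask"), ("CD163", "evalmask")],
    )
    def test_invalid_channel_type_combos(self, channel, img_type):
        with pytest.raises(ValueError):
            TileRecord(1, 1, 1, channel, img_type)

    def test_mode_is_forced_by_type(self):
        assert TileRecord(1, 1, 1, "DAPI", "cartoon").mode == "gs"
        assert TileRecord(1, 1, 1, "DAPI", "segment").mode == "bw"
        with pytest.raises(ValueError):
            TileRecord(1, 1, 1, "DAPI", "segment", mode="gs")

    def test_table_inventory_is_nineteen(self):
        assert len(VALID_CHANNEL_TYPES) == 19

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        spec=st.integers(1, 44), row=st.integers(1, 9), col=st.integers(1, 8),
        combo=st.sampled_from(sorted(VALID_CHANNEL_TYPES)),
    )
    def test_parse_inverts_build(self, spec, row, col, combo):
        channel, img_type = combo
        rec = TileRecord(spec, row, col, channel, img_type)
        assert parse_filename(build_filename(rec)) == rec

    def test_parse_rejects_nonconforming(self):
        with pytest.raises(ValueError):
            parse_filename("specimen_01_tile_01_01_channel_GFP_type_original_mode_gs.png")


class TestPngRoundTrip:
    def test_grey_roundtrip_and_depth(self, tmp_path):
        rng = np.random.default_rng(3)
        img = GreyImage(rng.integers(0, 256, size=(37, 53), dtype=np.uint8))
        p = tmp_path / "g.png"
        write_png(img, p)
        with Image.open(p) as pil:
            assert pil.mode == "L"  # 8-bit greyscale
        back = read_png(p)
        assert isinstance(back, GreyImage)
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_mask_roundtrip_and_depth(self, tmp_path):
        rng = np.random.default_rng(4)
        mask = BinaryMask((rng.random((41, 29)) < 0.4).astype(np.uint8))
        p = tmp_path / "m.png"
        write_png(mask, p)
        with Image.open(p) as pil:
            assert pil.mode == "1"  # 1-bit bilevel
        back = read_png(p)
        assert isinstance(back, BinaryMask)
        np.testing.assert_array_equal(back.pixels, mask.pixels)

    def test_type_decided_by_depth_not_content(self, tmp_path):
        img = GreyImage(np.where(np.eye(8, dtype=bool), 255, 0).astype(np.uint8))
        p = tmp_path / "binaryish.png"
        write_png(img, p)
        assert isinstance(read_png(p), GreyImage)

    def test_rgb_file_converted_by_modulus(self, tmp_path):
        arr = np.zeros((5, 5, 3), dtype=np.uint8)
        arr[0, 0] = (0, 0, 200)
        arr[1, 1] = (3, 4, 0)
        p = tmp_path / "rgb.png"
        Image.fromarray(arr, mode="RGB").save(p)
        grey = read_png(p)
        assert isinstance(grey, GreyImage)
        assert grey.pixels[0, 0] == 200
        assert grey.pixels[1, 1] == 5

    def test_non_png_rejected(self, tmp_path):
        p = tmp_path / "x.tiff"
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8)).save(p, format="TIFF")
        with pytest.raises(ValueError):
            read_png(p)


def test_logfile_contains_blocks_and_counts(tmp_path):
    blocks = [
        {"channel": ch, "s_min": 60, "s_max": 119, "n_accept": 0, "n_reject": 0}
        for ch in CHANNELS
    ]
    p = tmp_path / logfile_name(3, 2, 1)
    write_logfile((3, 2, 1), blocks, p)
    text = p.read_text()
    assert text.startswith("tile: specimen_03_tile_02_01")
    assert text.count("channel:") == 4
    assert "n_accept: 0" in text
    assert "pixel_size_um: 0.45" in text
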