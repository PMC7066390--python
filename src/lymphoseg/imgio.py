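"""Image I/O, tiling and the dataset naming convention.

Single-channel fluorescence images travel through the pipeline as 8-bit
greyscale :class:`GreyImage` objects; every segmentation output is a 1-bit
:class:`BinaryMask`.  Files on disk follow the published dataset layout:
``specimen_xx/specimen_xx_tile_yy_zz/`` folders holding losslessly
compressed PNGs named

    specimen_xx_tile_yy_zz_channel_<C>_type_<T>_mode_<gs|bw>.png

plus one plain-text logfile ``specimen_xx_tile_yy_zz__logfile.txt`` per
tile.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "GreyImage",
    "BinaryMask",
    "TileRecord",
    "CHANNELS",
    "IMG_TYPES",
    "VALID_CHANNEL_TYPES",
    "rgb_to_grey_modulus",
    "tile_slide",
    "build_filename",
    "parse_filename",
    "logfile_name",
    "read_png",
    "write_png",
    "write_logfile",
]

#: Fluorescence channels of the dataset, in canonical order.
CHANNELS = ("CD14", "CD163", "Pax5", "DAPI")

#: File types occurring in a tile folder.
IMG_TYPES = ("original", "cartoon", "segment", "convhull", "multiple", "evalmask")

#: The 19 valid (channel, type) combinations of a tile folder: macrophage
#: channels carry a double-stain ("multiple") mask, the nucleus channel
#: carries the tissue evaluation mask, and only originals/cartoons are
#: greyscale.
VALID_CHANNEL_TYPES: frozenset[tuple[str, str]] = frozenset(
    [(ch, t) for ch in ("CD14", "CD163") for t in ("original", "cartoon", "segment", "convhull", "multiple")]
    + [("Pax5", t) for t in ("original", "cartoon", "segment", "convhull")]
    + [("DAPI", t) for t in ("original", "cartoon", "segment", "convhull", "evalmask")]
)

#: Physical pixel edge length of the slide scans, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.45


@dataclass
class GreyImage:
    """A 2-D 8-bit greyscale image with physical pixel size metadata."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GreyImage requires a nonempty 2-D pixel grid")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("grey intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass
class BinaryMask:
    """A 2-D {0, 1} mask annotating an image of the same shape."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("BinaryMask requires a nonempty 2-D pixel grid")
        if px.dtype == bool:
            px = px.astype(np.uint8)
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "BinaryMask":
        return cls(np.zeros(shape, dtype=np.uint8))

    @classmethod
    def ones(cls, shape: tuple[int, int]) -> "BinaryMask":
        return cls(np.ones(shape, dtype=np.uint8))


@dataclass(frozen=True)
class TileRecord:
    """The naming identity of one file of the dataset.

    ``specimen_idx`` and the 1-based tile grid position identify the tile
    folder; ``channel``/``img_type``/``mode`` identify the file within it.
    """

    specimen_idx: int
    tile_row: int
    tile_col: int
    channel: str
    img_type: str
    mode: str = ""

    def __post_init__(self) -> None:
        if self.specimen_idx < 1 or self.tile_row < 1 or self.tile_col < 1:
            raise ValueError("specimen and tile indices are 1-based positive integers")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if (self.channel, self.img_type) not in VALID_CHANNEL_TYPES:
            raise ValueError(
                f"invalid (channel, type) combination ({self.channel!r}, {self.img_type!r})"
            )
        expected_mode = "gs" if self.img_type in ("original", "cartoon") else "bw"
        if self.mode == "":
            object.__setattr__(self, "mode", expected_mode)
        elif self.mode != expected_mode:
            raise ValueError(
                f"type {self.img_type!r} requires mode {expected_mode!r}, got {self.mode!r}"
            )


def rgb_to_grey_modulus(rgb: np.ndarray, clip: bool = True) -> GreyImage:
    """Convert an RGB grid to greyscale via the Euclidean norm of the RGB vector.

    Single-channel fluorescence scans stored as RGB have at most one
    nonzero channel per pixel, on which the modulus is the identity.  For
    bright multi-channel pixels the norm exceeds 255; with ``clip`` (the
    default) the result is clipped there, otherwise it is rescaled by
    255/sqrt(3·255²).
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB grid")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    norm = np.sqrt((rgb ** 2).sum(axis=2))
    if clip:
        grey = np.minimum(255.0, np.round(norm))
    else:
        grey = np.round(norm * (255.0 / np.sqrt(3.0) / 255.0))
    return GreyImage(grey.astype(np.uint8))


def tile_slide(
    slide: GreyImage, tile_h: int = 1000, tile_w: int = 1000
) -> Iterator[tuple[tuple[int, int], GreyImage]]:
    """Partition a whole-slide image into tiles in reading order.

    All tiles are ``tile_h x tile_w`` except possibly the last row/column
    band, which may be smaller.  Yields 1-based ``(row, col)`` positions.
    """
    if tile_h < 1 or tile_w < 1:
        raise ValueError("tile dimensions must be >= 1")
    H, W = slide.shape
    for r0 in range(0, H, tile_h):
        for c0 in range(0, W, tile_w):
            pos = (r0 // tile_h + 1, c0 // tile_w + 1)
            block = slide.pixels[r0 : r0 + tile_h, c0 : c0 + tile_w]
            yield pos, GreyImage(block.copy(), pixel_size_um=slide.pixel_size_um)


def build_filename(rec: TileRecord) -> str:
    """Dataset filename for one record (zero-padded 2-digit indices)."""
    return (
        f"specimen_{rec.specimen_idx:02d}_tile_{rec.tile_row:02d}_{rec.tile_col:02d}"
        f"_channel_{rec.channel}_type_{rec.img_type}_mode_{rec.mode}.png"
    )


def logfile_name(specimen_idx: int, tile_row: int, tile_col: int) -> str:
    """Per-tile logfile name (note the double underscore)."""
    return f"specimen_{specimen_idx:02d}_tile_{tile_row:02d}_{tile_col:02d}__logfile.txt"


_FILENAME_RE = re.compile(
    r"specimen_(\d{2,})_tile_(\d{2,})_(\d{2,})"
    r"_channel_(CD14|CD163|Pax5|DAPI)"
    r"_type_(original|cartoon|segment|convhull|multiple|evalmask)"
    r"_mode_(gs|bw)\.png$"
)


def parse_filename(name: str) -> TileRecord:
    """Inverse of :func:`build_filename`; raises ``ValueError`` on mismatch."""
    m = _FILENAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(f"filename does not follow the dataset convention: {name!r}")
    rec = TileRecord(
        specimen_idx=int(m.group(1)),
        tile_row=int(m.group(2)),
        tile_col=int(m.group(3)),
        channel=m.group(4),
        img_type=m.group(5),
        mode=m.group(6),
    )
    return rec


def write_png(img: GreyImage | BinaryMask, path: str | Path) -> None:
    """Write a greyscale image as 8-bit PNG or a mask as 1-bit PNG (lossless)."""
    path = Path(path)
    if isinstance(img, BinaryMask):
        pil = Image.fromarray(img.pixels.astype(bool))  # mode "1" -> 1-bit PNG
    elif isinstance(img, GreyImage):
        pil = Image.fromarray(img.pixels, mode="L")
    else:
        raise TypeError(f"cannot write object of type {type(img).__name__}")
    pil.save(path, format="PNG", optimize=True)


def read_png(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> GreyImage | BinaryMask:
    """Read a PNG: 1-bit files load as masks, 8-bit greyscale as images.

    The type is decided by the stored bit depth, never by pixel content;
    RGB files are converted to greyscale via :func:`rgb_to_grey_modulus`.
    """
    path = Path(path)
    with Image.open(path) as pil:
        if pil.format != "PNG":
            raise ValueError(f"not a PNG file: {path}")
        if pil.mode == "1":
            return BinaryMask(np.asarray(pil, dtype=np.uint8))
        if pil.mode == "L":
            return GreyImage(np.asarray(pil, dtype=np.uint8), pixel_size_um=pixel_size_um)
        if pil.mode in ("RGB", "RGBA"):
            arr = np.asarray(pil.convert("RGB"), dtype=np.float64)
            return rgb_to_grey_modulus(arr)
        raise ValueError(f"unsupported PNG mode {pil.mode!r} in {path}")


def write_logfile(
    rec_base: tuple[int, int, int],
    channel_blocks: Sequence[Mapping[str, object]],
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> None:
    """Write the per-tile plain-text logfile.

    ``channel_blocks`` holds one mapping per processed channel with keys
    such as ``channel``, enhancement parameters, rule bounds and
    accept/grow/reject counts; values are written as line-oriented
    ``key: value`` pairs under one header line naming the tile.
    """
    spec, row, col = rec_base
    lines = [f"tile: specimen_{spec:02d}_tile_{row:02d}_{col:02d}"]
    lines.append(f"pixel_size_um: {pixel_size_um}")
    for block in channel_blocks:
        lines.append("")
        for key, value in block.items():
            lines.append(f"{key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")
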