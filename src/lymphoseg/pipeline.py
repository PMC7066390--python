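"""Pipeline orchestration: per-tile runs, batch runs, scoring, overlays.

``process_tile`` turns one co-registered 4-channel tile into the full
published folder inventory — 19 PNG files (4 originals, 4 cartoons,
4 segment masks, 4 convex-hull masks, 2 double-stain masks, 1 tissue
evaluation mask) plus one plain-text logfile.  ``process_specimen`` tiles
whole-slide channel images identically and processes every position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import channels as ch
from .channels import ChannelConfig, EvalMaskParams
from .enhance import EnhanceParams
from .engine import SegmentationResult
from .features import RuleParams
from .imgio import (
    DEFAULT_PIXEL_SIZE_UM,
    BinaryMask,
    GreyImage,
    TileRecord,
    build_filename,
    logfile_name,
    tile_slide,
    write_logfile,
    write_png,
)
from .rof import RofParams, rof_denoise

__all__ = [
    "PipelineConfig",
    "Bcl2Grade",
    "process_tile",
    "process_specimen",
    "bcl2_score",
    "render_overlay",
    "load_config",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a pipeline run, loadable from YAML."""

    rof: RofParams = field(default_factory=RofParams)
    dapi: ChannelConfig = ch.DAPI_CONFIG
    pax5: ChannelConfig = ch.PAX5_CONFIG
    cd14: ChannelConfig = ch.MACROPHAGE_CONFIG
    cd163: ChannelConfig = replace(ch.MACROPHAGE_CONFIG, channel="CD163")
    evalmask: EvalMaskParams = field(default_factory=EvalMaskParams)
    tile_h: int = 1000
    tile_w: int = 1000
    threshold_step: int = 1
    restrict_to_evalmask: bool = True
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_h < 1 or self.tile_w < 1:
            raise ValueError("tile dimensions must be >= 1")


@dataclass(frozen=True)
class Bcl2Grade:
    """Semi-quantitative 0-4 grade of BCL2-positive tumor cells."""

    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3, 4):
            raise ValueError("BCL2 score must be an integer in [0, 4]")


def bcl2_score(percent_positive: float, all_negative: bool = False) -> Bcl2Grade:
    """Grade a percentage of positive tumor cells into the 0-4 score.

    0 — all cells negative; 1 — <=25% positive; 2 — 26-50%; 3 — 51-75%;
    4 — >75%.  ``all_negative`` is an explicit flag because a slide with
    very few positive cells still scores 1, not 0.  Real-valued inputs in
    (25, 26) and (50, 51) fall into the higher interval.
    """
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError("percent_positive must lie in [0, 100]")
    if all_negative:
        return Bcl2Grade(0)
    if percent_positive <= 25:
        return Bcl2Grade(1)
    if percent_positive <= 50:
        return Bcl2Grade(2)
    if percent_positive <= 75:
        return Bcl2Grade(3)
    return Bcl2Grade(4)


def _rule_block(name: str, run_idx: int, p: RuleParams, res_counts: Mapping[str, int]) -> dict:
    return {
        "channel": name,
        "run": run_idx,
        "s_min": p.s_min,
        "s_max": p.s_max,
        "r_max": p.r_max,
        "c_max": p.c_max,
        **{f"n_{k}": v for k, v in res_counts.items()},
    }


def process_tile(
    channel_images: Mapping[str, GreyImage],
    rec_base: tuple[int, int, int],
    cfg: PipelineConfig,
    out_root: str | Path,
) -> Path:
    """Process one co-registered 4-channel tile into its dataset folder.

    ``channel_images`` maps CD14/CD163/Pax5/DAPI to same-shape images;
    ``rec_base`` is (specimen_idx, tile_row, tile_col).  Returns the tile
    folder path, which afterwards holds exactly 19 PNGs and 1 logfile.
    """
    required = {"CD14", "CD163", "Pax5", "DAPI"}
    if set(channel_images) != required:
        raise ValueError(f"need exactly the channels {sorted(required)}")
    shapes = {im.shape for im in channel_images.values()}
    if len(shapes) != 1:
        raise ValueError("channel images are misaligned: shapes differ")

    spec, row, col = rec_base
    folder = Path(out_root) / f"specimen_{spec:02d}" / f"specimen_{spec:02d}_tile_{row:02d}_{col:02d}"
    folder.mkdir(parents=True, exist_ok=True)

    def save(channel: str, img_type: str, img: GreyImage | BinaryMask) -> None:
        rec = TileRecord(spec, row, col, channel, img_type)
        write_png(img, folder / build_filename(rec))

    cartoons: dict[str, GreyImage] = {}
    for channel, img in channel_images.items():
        save(channel, "original", img)
        cartoons[channel] = rof_denoise(img, cfg.rof)
        save(channel, "cartoon", cartoons[channel])

    evalmask = ch.tissue_eval_mask(cartoons["DAPI"], cfg.evalmask)
    save("DAPI", "evalmask", evalmask)
    region = evalmask if cfg.restrict_to_evalmask else None

    step = cfg.threshold_step
    nuclei = ch.segment_nuclei_dapi(cartoons["DAPI"], cfg.dapi, region=region, step=step)
    bcells = ch.segment_bcells_pax5(cartoons["Pax5"], nuclei, cfg.pax5, region=region, step=step)
    cd14 = ch.segment_macrophages(cartoons["CD14"], cfg.cd14, region=region, step=step)
    cd163 = ch.segment_macrophages(cartoons["CD163"], cfg.cd163, region=region, step=step)
    multiple14, multiple163 = ch.double_stain_masks(cd14, cd163)

    results: dict[str, SegmentationResult] = {
        "DAPI": nuclei, "Pax5": bcells, "CD14": cd14, "CD163": cd163,
    }
    for channel, res in results.items():
        save(channel, "segment", res.segment)
        save(channel, "convhull", res.convhull)
    save("CD14", "multiple", multiple14)
    save("CD163", "multiple", multiple163)

    blocks = []
    for channel in ("CD14", "CD163", "Pax5", "DAPI"):
        conf: ChannelConfig = {"CD14": cfg.cd14, "CD163": cfg.cd163, "Pax5": cfg.pax5, "DAPI": cfg.dapi}[channel]
        block = {
            "channel": channel,
            "rof_fidelity_weight": cfg.rof.fidelity_weight,
            "threshold_step": step,
        }
        if conf.enhance is not None:
            block["enhance_c"] = conf.enhance.c
            block["enhance_window"] = conf.enhance.window
        for i, p in enumerate(conf.runs, start=1):
            prefix = f"run{i}_" if len(conf.runs) > 1 else ""
            block.update({f"{prefix}{k}": v for k, v in
                          _rule_block(channel, i, p, {}).items() if k.startswith(("s_", "r_", "c_"))})
        block.update({f"n_{k}": v for k, v in results[channel].counts().items()})
        block["n_features_accepted"] = results[channel].n_features
        blocks.append(block)
    write_logfile((spec, row, col), blocks, folder / logfile_name(spec, row, col),
                  pixel_size_um=cfg.pixel_size_um)
    return folder


def process_specimen(
    slide_images: Mapping[str, GreyImage],
    specimen_idx: int,
    cfg: PipelineConfig,
    out_root: str | Path,
) -> list[Path]:
    """Tile whole-slide channel images identically and process every tile."""
    shapes = {im.shape for im in slide_images.values()}
    if len(shapes) != 1:
        raise ValueError("slide channel images differ in size")
    tilings = {
        channel: dict(tile_slide(img, cfg.tile_h, cfg.tile_w))
        for channel, img in slide_images.items()
    }
    positions = sorted(next(iter(tilings.values())))
    folders = []
    for (row, col) in positions:
        channel_images = {channel: tiles[(row, col)] for channel, tiles in tilings.items()}
        folders.append(process_tile(channel_images, (specimen_idx, row, col), cfg, out_root))
    return folders


def render_overlay(
    base: GreyImage,
    masks: list[tuple[BinaryMask, tuple[int, int, int]]] | None = None,
    contrast_factor: float = 1.0,
    invert: bool = False,
    alpha: float = 0.5,
) -> np.ndarray:
    """Render a documentation overlay: scaled/inverted base plus colored masks.

    Returns an (H, W, 3) uint8 RGB array.  The base is multiplied by
    ``contrast_factor`` and clipped, optionally inverted; each mask is
    alpha-blended in its RGB color (full replacement at alpha 1).
    """
    g = np.minimum(255.0, base.astype_float() * contrast_factor)
    if invert:
        g = 255.0 - g
    rgb = np.repeat(g[:, :, None], 3, axis=2)
    for mask, color in masks or []:
        if mask.shape != base.shape:
            raise ValueError("overlay mask shape does not match base image")
        m = mask.astype_bool()
        for k in range(3):
            layer = rgb[:, :, k]
            layer[m] = (1 - alpha) * layer[m] + alpha * color[k]
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _rules_from_dict(d: Mapping) -> RuleParams:
    return RuleParams(s_min=int(d["s_min"]), s_max=int(d["s_max"]),
                      r_max=float(d["r_max"]), c_max=float(d["c_max"]))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Only keys present in the file override the defaults.  Channel
    sections accept ``enhance: {c, window}`` and ``runs: [{s_min, s_max,
    r_max, c_max}, ...]``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "rof" in raw:
        kwargs["rof"] = RofParams(**raw["rof"])
    if "evalmask" in raw:
        kwargs["evalmask"] = EvalMaskParams(**raw["evalmask"])
    for key, name in (("dapi", "DAPI"), ("pax5", "Pax5"), ("cd14", "CD14"), ("cd163", "CD163")):
        if key in raw:
            sec = raw[key]
            enh = EnhanceParams(**sec["enhance"]) if sec.get("enhance") else None
            runs = tuple(_rules_from_dict(r) for r in sec["runs"])
            gate = sec.get("gate", "nucleus_hull" if key == "pax5" else None)
            kwargs[key] = ChannelConfig(channel=name, runs=runs, enhance=enh, gate=gate)
    for key in ("tile_h", "tile_w", "threshold_step", "restrict_to_evalmask",
                "pixel_size_um", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)
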