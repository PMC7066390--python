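"""Channel-specific segmentation recipes.

Each fluorescence channel answers a different biological question and gets
its own recipe on top of the shared floating-threshold engine:

* **DAPI** (all nuclei): contrast enhancement, then two detection runs
  with complementary size windows — small nuclei (60-119 px) first, large
  nuclei (120-180 px) second, keeping from the second run only features
  completely disjoint from the first.
* **Pax5** (B-cells): gentle contrast enhancement, one detection run,
  then gating — only features touching the convex hull of some detected
  nucleus survive, which removes the numerous staining artifacts of this
  channel.
* **CD14 / CD163** (macrophage populations): one detection run on the
  cartoon directly; macrophages are large, irregular and inhomogeneously
  stained, so no enhancement is applied and the convexity/elongation
  bounds are loose.
* Double-stained macrophages ("multiple" masks) are features of one
  macrophage channel whose convex hull overlaps the other channel's hull
  mask.
* The tissue evaluation mask marks where there is tissue at all, inferred
  from the DAPI cartoon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .enhance import EnhanceParams, narendra_fitch_enhance
from .engine import SegmentationResult, floating_threshold_detect
from .features import Feature, RuleParams
from .imgio import BinaryMask, GreyImage

__all__ = [
    "ChannelConfig",
    "DAPI_CONFIG",
    "PAX5_CONFIG",
    "MACROPHAGE_CONFIG",
    "segment_nuclei_dapi",
    "segment_bcells_pax5",
    "segment_macrophages",
    "double_stain_masks",
    "tissue_eval_mask",
    "EvalMaskParams",
]


@dataclass(frozen=True)
class ChannelConfig:
    """Enhancement settings and detection run(s) for one channel."""

    channel: str
    runs: tuple[RuleParams, ...]
    enhance: EnhanceParams | None = None
    gate: str | None = None  # "nucleus_hull" for Pax5

    def __post_init__(self) -> None:
        if self.channel == "DAPI" and len(self.runs) != 2:
            raise ValueError("the DAPI recipe uses exactly 2 runs")
        if self.channel in ("Pax5", "CD14", "CD163") and len(self.runs) != 1:
            raise ValueError(f"the {self.channel} recipe uses exactly 1 run")


#: Nucleus detection: two size windows covering areas 60-180 px.
DAPI_CONFIG = ChannelConfig(
    channel="DAPI",
    enhance=EnhanceParams(c=0.75, window=11),
    runs=(
        RuleParams(s_min=60, s_max=119, r_max=2.5, c_max=150),
        RuleParams(s_min=120, s_max=180, r_max=2.5, c_max=150),
    ),
)

#: B-cell detection, gated by the nucleus hulls.
PAX5_CONFIG = ChannelConfig(
    channel="Pax5",
    enhance=EnhanceParams(c=0.1, window=15),
    runs=(RuleParams(s_min=80, s_max=159, r_max=2.5, c_max=150),),
    gate="nucleus_hull",
)

#: Macrophage detection defaults: large size window, loose shape bounds.
MACROPHAGE_CONFIG = ChannelConfig(
    channel="CD14",
    enhance=None,
    runs=(RuleParams(s_min=150, s_max=2000, r_max=4.0, c_max=300),),
)


def _merge_results(a: SegmentationResult, b: SegmentationResult) -> SegmentationResult:
    segment = BinaryMask(a.segment.pixels | b.segment.pixels)
    convhull = BinaryMask(a.convhull.pixels | b.convhull.pixels)
    log = {**{(1, k): v for k, v in a.log.items()}, **{(2, k): v for k, v in b.log.items()}}
    return SegmentationResult(segment, convhull, a.features + b.features, log)


def segment_nuclei_dapi(
    cartoon: GreyImage,
    cfg: ChannelConfig = DAPI_CONFIG,
    region: BinaryMask | None = None,
    step: int = 1,
) -> SegmentationResult:
    """Two-run nucleus segmentation of the DAPI cartoon.

    Run 1 detects small nuclei, run 2 large ones; a run-2 feature sharing
    even a single pixel with a run-1 acceptance is discarded, so the
    merged output features are pairwise disjoint.
    """
    enhanced = narendra_fitch_enhance(cartoon, cfg.enhance) if cfg.enhance else cartoon
    run1 = floating_threshold_detect(enhanced, cfg.runs[0], region=region, step=step)
    run2_raw = floating_threshold_detect(enhanced, cfg.runs[1], region=region, step=step)

    run1_px = run1.segment.astype_bool()
    kept: list[Feature] = []
    seg2 = np.zeros(cartoon.shape, dtype=bool)
    hull2 = np.zeros(cartoon.shape, dtype=bool)
    for feat in run2_raw.features:
        rr, cc = feat.coords[:, 0], feat.coords[:, 1]
        if run1_px[rr, cc].any():
            continue  # not completely disjoint from run 1
        kept.append(feat)
        seg2[rr, cc] = True
        h = feat.hull_coords
        ok = (h[:, 0] >= 0) & (h[:, 0] < cartoon.shape[0]) & (h[:, 1] >= 0) & (h[:, 1] < cartoon.shape[1])
        hull2[h[ok, 0], h[ok, 1]] = True
    run2 = SegmentationResult(BinaryMask(seg2), BinaryMask(hull2), kept, run2_raw.log)
    return _merge_results(run1, run2)


def segment_bcells_pax5(
    cartoon: GreyImage,
    nuclei: SegmentationResult,
    cfg: ChannelConfig = PAX5_CONFIG,
    region: BinaryMask | None = None,
    step: int = 1,
) -> SegmentationResult:
    """B-cell segmentation of the Pax5 cartoon, gated by nucleus hulls.

    A Pax5 feature is kept iff its pixel set intersects the convex hull of
    some detected nucleus; isolated staining artifacts are thereby
    excluded.
    """
    if nuclei.convhull.shape != cartoon.shape:
        raise ValueError("nucleus result shape does not match Pax5 cartoon shape")
    enhanced = narendra_fitch_enhance(cartoon, cfg.enhance) if cfg.enhance else cartoon
    raw = floating_threshold_detect(enhanced, cfg.runs[0], region=region, step=step)

    nucleus_hulls = nuclei.convhull.astype_bool()
    kept: list[Feature] = []
    seg = np.zeros(cartoon.shape, dtype=bool)
    hull = np.zeros(cartoon.shape, dtype=bool)
    for feat in raw.features:
        rr, cc = feat.coords[:, 0], feat.coords[:, 1]
        if not nucleus_hulls[rr, cc].any():
            continue
        kept.append(feat)
        seg[rr, cc] = True
        h = feat.hull_coords
        ok = (h[:, 0] >= 0) & (h[:, 0] < cartoon.shape[0]) & (h[:, 1] >= 0) & (h[:, 1] < cartoon.shape[1])
        hull[h[ok, 0], h[ok, 1]] = True
    return SegmentationResult(BinaryMask(seg), BinaryMask(hull), kept, raw.log)


def segment_macrophages(
    cartoon: GreyImage,
    cfg: ChannelConfig = MACROPHAGE_CONFIG,
    region: BinaryMask | None = None,
    step: int = 1,
) -> SegmentationResult:
    """Single-run macrophage segmentation of a CD14 or CD163 cartoon."""
    enhanced = narendra_fitch_enhance(cartoon, cfg.enhance) if cfg.enhance else cartoon
    return floating_threshold_detect(enhanced, cfg.runs[0], region=region, step=step)


def double_stain_masks(
    cd14: SegmentationResult, cd163: SegmentationResult
) -> tuple[BinaryMask, BinaryMask]:
    """Masks of macrophages bearing the *other* channel's staining as well.

    The first mask holds the CD14 features whose convex hull intersects
    the CD163 hull mask; the second is symmetric.  Both are subsets of the
    respective segment masks.
    """
    if cd14.segment.shape != cd163.segment.shape:
        raise ValueError("CD14 and CD163 results have different shapes")
    shape = cd14.segment.shape

    def one_side(own: SegmentationResult, other_hull: np.ndarray) -> BinaryMask:
        out = np.zeros(shape, dtype=bool)
        for feat in own.features:
            h = feat.hull_coords
            ok = (h[:, 0] >= 0) & (h[:, 0] < shape[0]) & (h[:, 1] >= 0) & (h[:, 1] < shape[1])
            if other_hull[h[ok, 0], h[ok, 1]].any():
                out[feat.coords[:, 0], feat.coords[:, 1]] = True
        return BinaryMask(out)

    return (
        one_side(cd14, cd163.convhull.astype_bool()),
        one_side(cd163, cd14.convhull.astype_bool()),
    )


@dataclass(frozen=True)
class EvalMaskParams:
    """Tissue evaluation mask construction constants.

    A low intensity threshold on the DAPI cartoon separates stained or
    autofluorescent tissue from dark glass; morphological closing (via
    Euclidean distance transforms) bridges gaps between nuclei; holes are
    filled and specks below ``min_area`` discarded.  The default
    threshold sits above the denoised dark-glass level (a few grey
    levels once clipped sensor noise is averaged) but well below any
    tissue autofluorescence.
    """

    threshold: int = 10
    closing_radius: float = 20.0
    min_area: int = 2000


def tissue_eval_mask(dapi_cartoon: GreyImage, params: EvalMaskParams | None = None) -> BinaryMask:
    """Mask of the tissue-bearing subregion of a tile, from the DAPI cartoon."""
    params = params or EvalMaskParams()
    raw = dapi_cartoon.pixels >= params.threshold
    if not raw.any():
        return BinaryMask.zeros(dapi_cartoon.shape)
    r = params.closing_radius
    # closing = erosion(dilation); both via distance transforms for speed
    dilated = ndimage.distance_transform_edt(~raw) <= r
    closed = ndimage.distance_transform_edt(dilated) > r
    closed |= raw  # closing is extensive; guard discretization artifacts
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = sizes >= params.min_area
        filled = keep[labels]
        if not filled.any():  # tiny tissue patch: keep the largest component
            filled = labels == int(np.argmax(sizes))
    return BinaryMask(filled)
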