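"""The floating-threshold detection loop.

Rather than binarizing at one fixed cutoff, the detector sweeps an
intensity threshold i downward from 255 to 1.  At each level the working
image is binarized at >= i (restricted to an optional region of interest
and excluding already-masked pixels) and its connected components are
classified by the geometric rules:

* accepted features are saved to the output and masked, so they cannot be
  re-detected or absorbed at lower thresholds;
* rejected features (too large, too elongated, too non-convex) are masked
  without being saved;
* undersized features are left in place — as the threshold drops they
  grow and may re-enter the size window later;
* components touching (8-adjacent to) already-masked pixels belong to an
  object that has been processed — typically the dim rim of an accepted
  cell — and are skipped, so every object is classified at most once.

Bright cell cores therefore surface first and accrete dimmer rim pixels
until they fit the size window, which is the "floating" part of the
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import STRUCTURE_8, Feature, RuleParams, classify_feature
from .imgio import BinaryMask, GreyImage

__all__ = ["SegmentationResult", "floating_threshold_detect"]


@dataclass
class SegmentationResult:
    """Accepted features plus their paired output masks.

    ``segment`` is exactly the union of the accepted features' pixels;
    ``convhull`` the union of their filled convex hulls.  ``log`` records
    accept/grow/reject counts per visited threshold.
    """

    segment: BinaryMask
    convhull: BinaryMask
    features: list[Feature]
    log: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def counts(self) -> dict[str, int]:
        """Total accept/grow/reject tallies over the whole sweep."""
        total = {"accept": 0, "grow": 0, "reject": 0, "skip": 0}
        for c in self.log.values():
            for k in total:
                total[k] += c.get(k, 0)
        return total


def _touches_border(coords: np.ndarray, shape: tuple[int, int]) -> bool:
    r, c = coords[:, 0], coords[:, 1]
    return bool((r == 0).any() or (c == 0).any() or (r == shape[0] - 1).any() or (c == shape[1] - 1).any())


def floating_threshold_detect(
    enhanced: GreyImage,
    rules: RuleParams,
    region: BinaryMask | None = None,
    step: int = 1,
) -> SegmentationResult:
    """Run the descending threshold sweep on an enhanced cartoon.

    Parameters
    ----------
    enhanced
        The channel image after denoising (and, for some channels,
        contrast enhancement).
    rules
        Acceptance bounds for this run.
    region
        Optional mask restricting detection (e.g. the tissue evaluation
        mask); pixels outside it are never binarized.
    step
        Threshold decrement on the 8-bit scale.  1 reproduces the full
        sweep; larger values trade fidelity for speed.

    Features touching the image border are kept but flagged in the log.
    Deterministic: components are visited top-left first at every level.
    """
    if region is not None and region.shape != enhanced.shape:
        raise ValueError("region mask shape does not match image shape")
    if step < 1:
        raise ValueError("step must be >= 1")

    shape = enhanced.shape
    working = enhanced.pixels.astype(np.int16)
    if region is not None:
        working[~region.astype_bool()] = 0

    segment = np.zeros(shape, dtype=bool)
    convhull = np.zeros(shape, dtype=bool)
    masked = np.zeros(shape, dtype=bool)
    accepted: list[Feature] = []
    log: dict[int, dict[str, int]] = {}
    border_flags = 0

    top = int(working.max())
    thresholds = range(min(255, top), 0, -step)
    for i in thresholds:
        binary = working >= i
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=STRUCTURE_8)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        counts = {"accept": 0, "grow": 0, "reject": 0, "skip": 0}
        counts["grow"] = int((sizes < rules.s_min).sum())
        # only components at or above s_min need inspection / masking
        candidates = np.flatnonzero(sizes >= rules.s_min) + 1
        if candidates.size:
            near_masked = (
                ndimage.binary_dilation(masked, structure=STRUCTURE_8)
                if masked.any()
                else None
            )
            objects = ndimage.find_objects(labels)
            for lab in candidates:
                sl = objects[lab - 1]
                inside = labels[sl] == lab
                if near_masked is not None and (near_masked[sl] & inside).any():
                    # grown rim of an already-processed object: leave it
                    counts["skip"] += 1
                    continue
                local = np.argwhere(inside)
                coords = local + [sl[0].start, sl[1].start]
                feat = Feature(coords)
                decision = classify_feature(feat, rules)
                counts[decision] += 1
                # accept or reject: mask the feature out of the sweep
                working[coords[:, 0], coords[:, 1]] = 0
                masked[coords[:, 0], coords[:, 1]] = True
                if decision == "accept":
                    accepted.append(feat)
                    segment[coords[:, 0], coords[:, 1]] = True
                    hull = feat.hull_coords
                    ok = (
                        (hull[:, 0] >= 0)
                        & (hull[:, 0] < shape[0])
                        & (hull[:, 1] >= 0)
                        & (hull[:, 1] < shape[1])
                    )
                    convhull[hull[ok, 0], hull[ok, 1]] = True
                    if _touches_border(coords, shape):
                        border_flags += 1
        log[i] = counts

    if border_flags:
        log[-1] = {"border_touching_accepted": border_flags}
    return SegmentationResult(
        segment=BinaryMask(segment),
        convhull=BinaryMask(convhull),
        features=accepted,
        log=log,
    )
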