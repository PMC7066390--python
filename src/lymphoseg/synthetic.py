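"""Synthetic 4-channel immunofluorescence tiles with ground truth.

The generator emulates the staining semantics of the real tissue scans on
a dark background with a smooth intensity gradient and Gaussian sensor
noise:

* **DAPI** — elliptical nuclei, pixel areas in [60, 180] and axis ratio
  <= 2, drawn as intensity plateaus (120-200 grey levels);
* **Pax5** — bright blobs centered on a subset of nuclei (B-cells) plus a
  configurable number of off-nucleus artifact blobs mimicking the
  nonspecific staining of this channel;
* **CD14 / CD163** — macrophages as unions of 3-6 overlapping disks with
  per-disk intensity jitter, reproducing the within-cell staining
  inhomogeneity; a fraction ``double_frac`` of them is drawn identically
  in both channels (double-stained).

Cells sit inside dimly autofluorescent tissue patches on an otherwise
dark glass background, so the tissue evaluation mask has something real
to discriminate.  Cells are placed well separated by rejection sampling,
so object-level scoring against the returned truth masks is unambiguous.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import STRUCTURE_8
from .imgio import BinaryMask, GreyImage

__all__ = ["CellRecord", "SyntheticTruth", "MatchScore", "generate_tile", "score_against_truth"]


@dataclass(frozen=True)
class CellRecord:
    """Ground-truth bookkeeping for one generated cell."""

    center: tuple[float, float]
    area: int
    axis_ratio: float
    channels: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Ground-truth masks and per-cell records of one generated tile."""

    nuclei_mask: BinaryMask
    bcell_mask: BinaryMask
    cd14_mask: BinaryMask
    cd163_mask: BinaryMask
    tissue_mask: BinaryMask
    cells: list[CellRecord]
    seed: int


@dataclass(frozen=True)
class MatchScore:
    """Object-level precision/recall from greedy IoU matching."""

    precision: float
    recall: float
    n_pred: int
    n_truth: int
    n_matched: int


def _draw_ellipse(
    canvas: np.ndarray,
    mask: np.ndarray,
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
    value: float,
) -> int:
    """Rasterize a rotated filled ellipse; returns its pixel count."""
    cy, cx = center
    rad = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - rad), min(canvas.shape[0], int(cy) + rad + 1)
    x0, x1 = max(0, int(cx) - rad), min(canvas.shape[1], int(cx) + rad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][inside] = np.maximum(canvas[y0:y1, x0:x1][inside], value)
    mask[y0:y1, x0:x1] |= inside
    return int(inside.sum())


def _draw_ellipse_in_window(
    canvas: np.ndarray,
    mask: np.ndarray,
    center: tuple[float, float],
    target_area: float,
    ratio: float,
    theta: float,
    value: float,
    s_lo: int,
    s_hi: int,
) -> int:
    """Draw an ellipse whose *realized* pixel count lands in [s_lo, s_hi].

    Discretization shifts the pixel count a few px off the continuous
    area pi*a*b; the target area is nudged until the drawn count fits.
    """
    area = float(target_area)
    for _ in range(60):
        a = np.sqrt(area * ratio / np.pi)
        b = np.sqrt(area / (np.pi * ratio))
        scratch_c = canvas.copy()
        scratch_m = mask.copy()
        n = _draw_ellipse(scratch_c, scratch_m, center, a, b, theta, value)
        if s_lo <= n <= s_hi:
            canvas[:] = scratch_c
            mask[:] = scratch_m
            return n
        area += 2.0 if n < s_lo else -2.0
    raise RuntimeError("could not rasterize an ellipse inside the requested size window")


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_dist: float,
    existing: list[tuple[float, float]],
    min_dist_existing: float | None = None,
    inside=None,
    max_tries: int = 20_000,
) -> list[tuple[float, float]]:
    """Rejection-sample n centers: >= min_dist apart, >= min_dist_existing
    (default min_dist) from previously placed cells of other kinds, and
    satisfying the optional ``inside(y, x)`` predicate (tissue region)."""
    if min_dist_existing is None:
        min_dist_existing = min_dist
    centers: list[tuple[float, float]] = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        if inside is not None and not inside(cy, cx):
            continue
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist ** 2 for y, x in centers) and all(
            (cy - y) ** 2 + (cx - x) ** 2 >= min_dist_existing ** 2 for y, x in existing
        ):
            centers.append((cy, cx))
    if len(centers) < n:
        raise ValueError(
            f"could only place {len(centers)} of {n} cells at separation {min_dist}"
            f" on a {shape[0]}x{shape[1]} tile; reduce counts or separation"
        )
    return centers


def _background(
    rng: np.random.Generator, shape: tuple[int, int], base: float, gradient_amp: float
) -> np.ndarray:
    bg = np.full(shape, base, dtype=np.float64)
    if gradient_amp > 0:
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        ramp = np.cos(phi) * yy + np.sin(phi) * xx
        ramp = (ramp - ramp.min()) / max(float(np.ptp(ramp)), 1.0)
        bg += gradient_amp * ramp
    return bg


def _finish(
    rng: np.random.Generator, clean: np.ndarray, noise_sigma: float, edge_sigma: float
) -> GreyImage:
    img = clean
    if edge_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=edge_sigma)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return GreyImage(np.clip(np.round(img), 0, 255).astype(np.uint8))


def generate_tile(
    n_nuclei: int = 20,
    n_bcells: int = 8,
    n_macrophages: int = 6,
    double_frac: float = 0.5,
    noise_sigma: float = 10.0,
    shape: tuple[int, int] = (1000, 1000),
    seed: int = 0,
    n_artifacts: int = 3,
    gradient_amp: float = 3.0,
    edge_sigma: float = 0.7,
    glass_level: float = 2.0,
    tissue_level: float = 10.0,
) -> tuple[dict[str, GreyImage], SyntheticTruth]:
    """Generate one synthetic 4-channel tile plus its ground truth.

    Returns a dict keyed by channel name (CD14, CD163, Pax5, DAPI) and the
    :class:`SyntheticTruth`.  ``n_bcells`` must not exceed ``n_nuclei``
    (every B-cell sits on a nucleus); ``n_artifacts`` extra Pax5 blobs are
    placed far from every nucleus.  All cells sit inside one large
    elliptical tissue section that autofluoresces at ``tissue_level``
    above the ``glass_level`` background in every channel; a smooth
    illumination gradient of amplitude ``gradient_amp`` plus Gaussian
    noise covers the whole tile.
    """
    if min(n_nuclei, n_bcells, n_macrophages, n_artifacts) < 0:
        raise ValueError("cell counts must be >= 0")
    if n_bcells > n_nuclei:
        raise ValueError("n_bcells cannot exceed n_nuclei")
    if not 0.0 <= double_frac <= 1.0:
        raise ValueError("double_frac must lie in [0, 1]")
    if shape[0] < 100 or shape[1] < 100:
        raise ValueError("tile shape must be at least 100 x 100")

    rng = np.random.default_rng(seed)
    cells: list[CellRecord] = []

    # -- one contiguous elliptical tissue section -------------------------
    # real tissue is a connected sheet far larger than any cell-size
    # window, so detection rejects it as a giant instead of mistaking
    # isolated autofluorescent patches for cells
    t_cy = shape[0] * rng.uniform(0.45, 0.55)
    t_cx = shape[1] * rng.uniform(0.45, 0.55)
    t_a = shape[0] * rng.uniform(0.34, 0.42)
    t_b = shape[1] * rng.uniform(0.34, 0.42)
    t_theta = rng.uniform(0, np.pi)

    def _tissue_q(y: float, x: float) -> float:
        dy, dx = y - t_cy, x - t_cx
        u = dy * np.cos(t_theta) + dx * np.sin(t_theta)
        v = -dy * np.sin(t_theta) + dx * np.cos(t_theta)
        return (u / t_a) ** 2 + (v / t_b) ** 2

    tissue_mask = np.zeros(shape, dtype=bool)
    _draw_ellipse(np.zeros(shape), tissue_mask, (t_cy, t_cx), t_a, t_b, t_theta, 1.0)

    def inside_tissue(y: float, x: float) -> bool:
        # keep cells away from the tissue border so their whole footprint
        # (plus detection halo) stays on tissue
        return _tissue_q(y, x) <= 0.85 ** 2

    # -- placement --------------------------------------------------------
    nuc_centers = _place_centers(rng, n_nuclei, shape, margin=30, min_dist=34,
                                 existing=[], inside=inside_tissue)
    artifact_centers = _place_centers(
        rng, n_artifacts, shape, margin=30, min_dist=40, existing=nuc_centers,
        min_dist_existing=45, inside=inside_tissue,
    )
    mac_centers = _place_centers(
        rng, n_macrophages, shape, margin=40, min_dist=70,
        existing=nuc_centers + artifact_centers, min_dist_existing=45,
        inside=inside_tissue,
    )


    def background() -> np.ndarray:
        bg = _background(rng, shape, glass_level, gradient_amp)
        bg[tissue_mask] += tissue_level
        return bg

    dapi = background()
    pax5 = background()
    cd14 = background()
    cd163 = background()
    nuclei_mask = np.zeros(shape, dtype=bool)
    bcell_mask = np.zeros(shape, dtype=bool)
    cd14_mask = np.zeros(shape, dtype=bool)
    cd163_mask = np.zeros(shape, dtype=bool)

    # -- nuclei (DAPI), well separated ------------------------------------
    for cy, cx in nuc_centers:
        ratio = rng.uniform(1.0, 2.0)
        theta = rng.uniform(0, np.pi)
        target = rng.uniform(60, 180)
        value = rng.uniform(120, 200)
        area = _draw_ellipse_in_window(
            dapi, nuclei_mask, (cy, cx), target, ratio, theta, value, 60, 180
        )
        cells.append(CellRecord((cy, cx), area, ratio, ("DAPI",)))

    # -- B-cells (Pax5) on a subset of nuclei + off-nucleus artifacts -----
    order = rng.permutation(n_nuclei)[:n_bcells] if n_nuclei else []
    for idx in order:
        cy, cx = nuc_centers[idx]
        ratio = rng.uniform(1.0, 1.6)
        theta = rng.uniform(0, np.pi)
        target = rng.uniform(90, 150)
        value = rng.uniform(130, 200)
        area = _draw_ellipse_in_window(
            pax5, bcell_mask, (cy, cx), target, ratio, theta, value, 80, 159
        )
        cells.append(CellRecord((cy, cx), area, ratio, ("Pax5",)))
    artifact_scratch = np.zeros(shape, dtype=bool)
    for cy, cx in artifact_centers:
        ratio = rng.uniform(1.0, 1.6)
        theta = rng.uniform(0, np.pi)
        _draw_ellipse_in_window(
            pax5, artifact_scratch, (cy, cx), rng.uniform(90, 150), ratio, theta,
            rng.uniform(130, 200), 80, 159,
        )

    # -- macrophages (CD14/CD163), blobs of 3-6 jittered disks ------------
    n_double = int(round(double_frac * n_macrophages))
    for k, (cy, cx) in enumerate(mac_centers):
        n_disks = int(rng.integers(3, 7))
        base = rng.uniform(110, 180)
        if k < n_double:
            targets = [(cd14, cd14_mask), (cd163, cd163_mask)]
            chans: tuple[str, ...] = ("CD14", "CD163")
        elif (k - n_double) % 2 == 0:
            targets = [(cd14, cd14_mask)]
            chans = ("CD14",)
        else:
            targets = [(cd163, cd163_mask)]
            chans = ("CD163",)
        blob = np.zeros(shape, dtype=bool)
        for _ in range(n_disks):
            dy, dx = rng.uniform(-5, 5, size=2)
            radius = rng.uniform(11.0, 14.0)
            value = np.clip(base + rng.uniform(-12, 12), 60, 255)
            for canvas, m in targets:
                _draw_ellipse(canvas, m, (cy + dy, cx + dx), radius, radius, 0.0, value)
            _draw_ellipse(np.zeros_like(blob, dtype=np.float64), blob, (cy + dy, cx + dx),
                          radius, radius, 0.0, 1.0)
        cells.append(CellRecord((cy, cx), int(blob.sum()), 1.0, chans))

    images = {
        "CD14": _finish(rng, cd14, noise_sigma, edge_sigma),
        "CD163": _finish(rng, cd163, noise_sigma, edge_sigma),
        "Pax5": _finish(rng, pax5, noise_sigma, edge_sigma),
        "DAPI": _finish(rng, dapi, noise_sigma, edge_sigma),
    }
    truth = SyntheticTruth(
        nuclei_mask=BinaryMask(nuclei_mask),
        bcell_mask=BinaryMask(bcell_mask),
        cd14_mask=BinaryMask(cd14_mask),
        cd163_mask=BinaryMask(cd163_mask),
        tissue_mask=BinaryMask(tissue_mask),
        cells=cells,
        seed=seed,
    )
    return images, truth


def score_against_truth(
    pred: BinaryMask, truth: BinaryMask, match_iou: float = 0.3
) -> MatchScore:
    """Object-level precision/recall by greedy best-IoU matching.

    Components (8-connected) of the two masks are matched greedily in
    order of decreasing IoU; a pair counts as a match iff its IoU reaches
    ``match_iou``.  An empty prediction has precision 1 by convention (no
    false positives); an empty truth has recall 1.
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks differ in shape")
    if not 0.0 < match_iou <= 1.0:
        raise ValueError("match_iou must lie in (0, 1]")
    lp, n_pred = ndimage.label(pred.astype_bool(), structure=STRUCTURE_8)
    lt, n_truth = ndimage.label(truth.astype_bool(), structure=STRUCTURE_8)
    if n_pred == 0 or n_truth == 0:
        return MatchScore(
            precision=1.0 if n_pred == 0 else 0.0,
            recall=1.0 if n_truth == 0 else 0.0,
            n_pred=n_pred,
            n_truth=n_truth,
            n_matched=0,
        )
    sizes_p = np.bincount(lp.ravel())[1:]
    sizes_t = np.bincount(lt.ravel())[1:]
    both = (lp > 0) & (lt > 0)
    pairs, inter = np.unique(
        np.stack([lp[both], lt[both]]), axis=1, return_counts=True
    )
    ious = []
    for (p, t), n_int in zip(pairs.T, inter):
        union = sizes_p[p - 1] + sizes_t[t - 1] - n_int
        ious.append((n_int / union, int(p), int(t)))
    ious.sort(reverse=True)
    used_p: set[int] = set()
    used_t: set[int] = set()
    n_matched = 0
    for iou, p, t in ious:
        if iou < match_iou:
            break
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        n_matched += 1
    return MatchScore(
        precision=n_matched / n_pred,
        recall=n_matched / n_truth,
        n_pred=n_pred,
        n_truth=n_truth,
        n_matched=n_matched,
    )
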