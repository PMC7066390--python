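"""Connected components and the geometric acceptance rules.

A detection candidate is a connected component (a *feature*) of a
binarized image, described by three numbers:

* ``s`` — its pixel count,
* ``c`` — the pixel count of its filled convex hull,
* ``r`` — the ratio of the principal axes of the smallest ellipse
  covering it (>= 1; +inf for degenerate, collinear features).

A feature whose size lies inside the window [s_min, s_max] is accepted as
a cell iff it is not too elongated (r <= r_max) and not too far from
convex (c/s <= 1 + c_max/100).  Features below the window are left to grow
as the detection threshold drops; everything else is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Feature",
    "RuleParams",
    "extract_components",
    "convex_hull_fill",
    "min_ellipse_ratio",
    "classify_feature",
]

#: 8-connectivity: diagonal neighbours belong to the same blob.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)

#: Rasterization tolerance — pixel centers on a hull edge count as inside.
_EDGE_TOL = 1e-9

Decision = Literal["accept", "grow", "reject"]


@dataclass(frozen=True)
class RuleParams:
    """Acceptance-rule bounds for one detection run.

    s_min, s_max
        Feature size window in pixels.
    r_max
        Maximal axis ratio of the smallest covering ellipse (elongation
        bound).
    c_max
        Maximal area excess of the convex hull, in percent: a feature
        passes iff c/s <= 1 + c_max/100 (convexity bound).
    """

    s_min: int
    s_max: int
    r_max: float
    c_max: float

    def __post_init__(self) -> None:
        if not (1 <= self.s_min <= self.s_max):
            raise ValueError("require 1 <= s_min <= s_max")
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")
        if self.c_max < 0:
            raise ValueError("c_max must be >= 0")


@dataclass
class Feature:
    """One connected component with lazily computed shape descriptors.

    ``coords`` is an (s, 2) integer array of (row, col) pixel positions.
    """

    coords: np.ndarray
    _hull_coords: np.ndarray | None = field(default=None, repr=False)
    _r: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ValueError("coords must be a nonempty (s, 2) array")
        self.coords = coords.astype(np.int64)

    @property
    def s(self) -> int:
        """Feature size in pixels."""
        return self.coords.shape[0]

    @property
    def hull_coords(self) -> np.ndarray:
        """Pixel coordinates of the filled convex hull (superset of coords)."""
        if self._hull_coords is None:
            self._hull_coords = convex_hull_fill(self.coords)
        return self._hull_coords

    @property
    def c(self) -> int:
        """Pixel count of the filled convex hull."""
        return self.hull_coords.shape[0]

    @property
    def r(self) -> float:
        """Axis ratio of the smallest covering ellipse (+inf if degenerate)."""
        if self._r is None:
            self._r = min_ellipse_ratio(self.coords)
        return self._r


def extract_components(binary) -> list[Feature]:
    """8-connected components of a mask, ordered top-left first.

    Accepts a :class:`~lymphoseg.imgio.BinaryMask` or any 2-D boolean-like
    array.  The ordering follows the raster-scan position of each
    component's first pixel, so downstream logs are reproducible.
    """
    arr = np.asarray(getattr(binary, "pixels", binary)).astype(bool)
    labels, n = ndimage.label(arr, structure=STRUCTURE_8)
    if n == 0:
        return []
    coords = np.argwhere(labels > 0)
    order = labels[coords[:, 0], coords[:, 1]]
    # scipy assigns labels in raster order of first occurrence
    split = np.argsort(order, kind="stable")
    coords = coords[split]
    counts = np.bincount(order)[1:]
    out: list[Feature] = []
    start = 0
    for cnt in counts:
        out.append(Feature(coords[start : start + cnt]))
        start += cnt
    return out


def _hull_vertices(coords: np.ndarray) -> np.ndarray | None:
    """Convex hull vertices of pixel centers, or None if degenerate."""
    pts = np.asarray(coords, dtype=np.float64)
    if pts.shape[0] < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None  # collinear
    return pts[hull.vertices]


def convex_hull_fill(coords: np.ndarray) -> np.ndarray:
    """Rasterized filled convex hull of a feature's pixel centers.

    A pixel belongs to the fill iff its center lies inside or on the hull
    polygon (ties broken toward inclusion), which guarantees c >= s.
    Degenerate features (all pixel centers collinear) fill the pixels
    whose centers lie on the segment between the extremes.
    """
    coords = np.asarray(coords, dtype=np.int64)
    verts = _hull_vertices(coords)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)

    if verts is None:
        # collinear: keep centers within tol of the extreme-point segment
        p0 = coords[np.lexsort((coords[:, 1], coords[:, 0]))][0].astype(np.float64)
        p1 = coords[np.lexsort((coords[:, 1], coords[:, 0]))][-1].astype(np.float64)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            return coords[:1].copy()
        t = ((pts - p0) @ d) / L2
        proj = p0 + np.clip(t, 0, 1)[:, None] * d
        on_seg = np.linalg.norm(pts - proj, axis=1) <= 1e-6
        inside = pts[on_seg]
    else:
        # CCW hull: inside = left of (or on) every edge
        keep = np.ones(pts.shape[0], dtype=bool)
        n = verts.shape[0]
        for i in range(n):
            a = verts[i]
            b = verts[(i + 1) % n]
            cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
            keep &= cross >= -_EDGE_TOL
        inside = pts[keep]
    hull_px = inside.astype(np.int64)
    # union with the feature itself so c >= s holds unconditionally
    return np.unique(np.concatenate([hull_px, coords]), axis=0)


def min_ellipse_ratio(coords: np.ndarray, tol: float = 1e-3, max_iter: int = 2000) -> float:
    """Axis ratio of the minimum-area ellipse covering the pixel centers.

    Uses Khachiyan's iteration on the convex-hull vertices.  The ratio
    (major/minor axis length, >= 1) is scale-invariant, so no inflation of
    the converged ellipse is needed.  Features whose pixel centers are
    collinear have a degenerate covering ellipse and return +inf.
    """
    coords = np.asarray(coords, dtype=np.float64)
    verts = _hull_vertices(coords)
    if verts is None:
        return float("inf")
    P = verts.T  # 2 x m
    m = P.shape[1]
    Q = np.vstack([P, np.ones(m)])  # 3 x m
    u = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        X = Q @ (u[:, None] * Q.T)
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j = int(np.argmax(M))
        maximum = M[j]
        # dual optimality: all M_j <= d + 1 = 3 at the optimum
        if maximum <= 3.0 * (1.0 + tol):
            break
        step = (maximum - 3.0) / (3.0 * (maximum - 1.0))
        u *= 1.0 - step
        u[j] += step
    center = P @ u
    S = P @ np.diag(u) @ P.T - np.outer(center, center)
    # shape matrix A = inv(S)/2 defines (x-c)' A (x-c) <= 1
    eigvals = np.linalg.eigvalsh(S)
    if eigvals[0] <= 0:
        return float("inf")
    # axis lengths are proportional to sqrt(eigvals of S)
    return float(np.sqrt(eigvals[-1] / eigvals[0]))


def classify_feature(feature: Feature, p: RuleParams) -> Decision:
    """Modified Rule 3: accept, leave to grow, or reject one feature.

    * ``accept`` — s in [s_min, s_max] and r <= r_max and
      c/s <= 1 + c_max/100;
    * ``grow``   — s < s_min: the feature may still merge and re-enter at
      a lower threshold;
    * ``reject`` — s > s_max, or in-window but failing a geometric
      criterion.

    Size is tested first so the (costlier) hull and ellipse descriptors
    are only evaluated for features inside the window.
    """
    s = feature.s
    if s < p.s_min:
        return "grow"
    if s > p.s_max:
        return "reject"
    if feature.r > p.r_max:
        return "reject"
    if feature.c / s > 1.0 + p.c_max / 100.0:
        return "reject"
    return "accept"
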