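"""Independent brute-force oracles used to validate the geometric kernels.

Each oracle deliberately takes a different computational route than the
implementation it checks: hull rasterization is verified with a shapely
point-in-polygon test, the minimum covering ellipse with an exhaustive
grid search over orientation/anisotropy reduced to exact minimum
enclosing circles, and ROF denoising with a general-purpose optimizer on
the discrete energy.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from shapely.geometry import MultiPoint, Point


def hull_pixel_count_oracle(coords: np.ndarray) -> int:
    """Pixels of the bounding box whose centers lie in the convex hull.

    Uses shapely's convex hull and point containment with a small
    inclusion buffer so boundary centers count as inside.
    """
    coords = np.asarray(coords)
    hull = MultiPoint([tuple(p) for p in coords]).convex_hull
    region = hull.buffer(1e-9)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    count = 0
    for r in range(rmin, rmax + 1):
        for c in range(cmin, cmax + 1):
            if region.covers(Point(r, c)):
                count += 1
    return count


def _min_enclosing_circle(pts: np.ndarray) -> float:
    """Exact minimum enclosing circle radius by checking pairs and triples."""
    pts = np.asarray(pts, dtype=np.float64)
    n = len(pts)
    if n == 1:
        return 0.0
    best = None
    eps = 1e-9

    def covers(c, r):
        return (np.linalg.norm(pts - c, axis=1) <= r + eps).all()

    for i, j in combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2
        r = np.linalg.norm(pts[i] - c)
        if covers(c, r) and (best is None or r < best):
            best = r
    for i, j, k in combinations(range(n), 3):
        a, b, cc = pts[i], pts[j], pts[k]
        d = 2 * (a[0] * (b[1] - cc[1]) + b[0] * (cc[1] - a[1]) + cc[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        ux = ((a @ a) * (b[1] - cc[1]) + (b @ b) * (cc[1] - a[1]) + (cc @ cc) * (a[1] - b[1])) / d
        uy = ((a @ a) * (cc[0] - b[0]) + (b @ b) * (a[0] - cc[0]) + (cc @ cc) * (b[0] - a[0])) / d
        c = np.array([ux, uy])
        r = np.linalg.norm(a - c)
        if covers(c, r) and (best is None or r < best):
            best = r
    return float(best if best is not None else 0.0)


def cover_ellipse_ratio_oracle(
    coords: np.ndarray, n_theta: int = 48, ratios: np.ndarray | None = None
) -> float:
    """Axis ratio of the minimum-area covering ellipse by grid search.

    For each candidate orientation theta and axis ratio rho, points are
    rotated and compressed by rho along one axis; the smallest covering
    ellipse with that (theta, rho) corresponds to the minimum enclosing
    circle of the transformed points, with area proportional to
    rho * r^2.  The grid minimizer's rho approximates the optimum.  Only
    hull vertices matter for covering, which keeps the exact enclosing-
    circle subproblem tiny.
    """
    from scipy.spatial import ConvexHull, QhullError

    coords = np.asarray(coords, dtype=np.float64)
    try:
        coords = coords[ConvexHull(coords).vertices]
    except QhullError:
        return float("inf")
    if ratios is None:
        ratios = np.geomspace(1.0, 12.0, 60)

    def area_of(theta: float, log_rho: float) -> float:
        rho = np.exp(log_rho)
        ct, st = np.cos(theta), np.sin(theta)
        rot = coords @ np.array([[ct, -st], [st, ct]])
        r = _min_enclosing_circle(rot / [rho, 1.0])
        return rho * r * r

    candidates = []
    for theta in np.linspace(0, np.pi, n_theta, endpoint=False):
        for rho in ratios:
            candidates.append((area_of(theta, np.log(rho)), theta, np.log(rho)))
    candidates.sort()

    # the area surface is a shallow curved valley in (theta, rho); polish
    # the best grid points continuously so the ratio is identifiable
    best_area, best_log_rho = np.inf, 0.0
    for area0, theta0, lr0 in candidates[:3]:
        res = minimize(
            lambda x: area_of(x[0], x[1]), [theta0, lr0],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-13, "maxiter": 4000},
        )
        if res.fun < best_area:
            best_area, best_log_rho = res.fun, res.x[1]
    return float(np.exp(abs(best_log_rho)))


def rof_descent_oracle(f: np.ndarray, fidelity_weight: float) -> np.ndarray:
    """Direct minimization of the discrete ROF energy on a tiny image.

    Runs a smoothed-TV quasi-Newton descent (eps-regularized gradient
    magnitude, eps -> 1e-8) over all pixels; only feasible for very small
    grids, which is the point: it shares no code path with the dual
    projection solver.
    """
    f = np.asarray(f, dtype=np.float64)
    shape = f.shape
    eps = 1e-8

    def energy(x):
        u = x.reshape(shape)
        gx = np.zeros_like(u)
        gy = np.zeros_like(u)
        gx[:-1, :] = u[1:, :] - u[:-1, :]
        gy[:, :-1] = u[:, 1:] - u[:, :-1]
        tv = np.sqrt(gx ** 2 + gy ** 2 + eps).sum()
        return tv + 0.5 * fidelity_weight * ((u - f) ** 2).sum()

    res = minimize(energy, f.ravel(), method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-14, "gtol": 1e-12})
    return res.x.reshape(shape)
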