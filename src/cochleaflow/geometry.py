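"""Curvature and thickness morphometry of traced epithelial layers.

The epithelial layer is traced as an apical and a basal contour (µm, (x, y)
columns).  Its medial curve is obtained by skeletonization of the enclosed
ribbon, resampled at regular arc-length intervals, and fitted with an
interpolating cubic spline; signed curvature follows

    kappa(x) = S''(x) / (1 + S'(x)^2)^{3/2}

evaluated from the per-interval cubic coefficients in graph mode, or its
parametric equivalent for curves that are not single-valued in x (the coiled
duct).  Curvature is positive where the curve is locally convex toward the
duct lumen.  Layer thickness is the length of the normal segment through
each sampling point clipped by the two contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import polygon as draw_polygon
from skimage.morphology import skeletonize

__all__ = [
    "TracedLayer",
    "SplineCurve",
    "CurvatureProfile",
    "midline",
    "resample",
    "fit_spline",
    "curvature_profile",
    "thickness_profile",
    "total_curvature",
    "local_edge_curvature",
]


@dataclass
class TracedLayer:
    """Manually traced apical and basal contours of an epithelial layer (µm)."""

    apical: np.ndarray            # (n, 2) (x, y), lumen side
    basal: np.ndarray             # (m, 2)
    lumen_point: np.ndarray | None = None   # a point on the lumen side
    apex_point: np.ndarray | None = None    # apex tip landmark

    def __post_init__(self) -> None:
        self.apical = np.asarray(self.apical, dtype=float)
        self.basal = np.asarray(self.basal, dtype=float)
        for name, c in (("apical", self.apical), ("basal", self.basal)):
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 2:
                raise ValueError(f"{name} contour needs >= 2 (x, y) points")
        if self.lumen_point is not None:
            self.lumen_point = np.asarray(self.lumen_point, dtype=float)
        if self.apex_point is not None:
            self.apex_point = np.asarray(self.apex_point, dtype=float)


def _arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample(points: np.ndarray, interval: float = 15.0, closed: bool = False) -> np.ndarray:
    """Points equally spaced in arc length along a polyline.

    Open curves start exactly at the first point (the apex tip) and include
    the end point when the length is a multiple of the interval; closed
    curves return ``floor(length/interval)`` points without duplicating the
    start.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    if closed and not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    arc = _arc_length(pts)
    total = arc[-1]
    if total < interval:
        raise ValueError("curve shorter than the sampling interval")
    if closed:
        # tolerate the slight chordal shortfall of densely sampled rings
        n = int(np.floor(total / interval + 1e-4))
        s = np.arange(n) * interval
    else:
        s = np.arange(0.0, total + 1e-9, interval)
    x = np.interp(s, arc, pts[:, 0])
    y = np.interp(s, arc, pts[:, 1])
    return np.column_stack([x, y])


@dataclass
class SplineCurve:
    """Interpolating cubic spline with exposed per-interval coefficients.

    In graph mode a single spline ``S(x)`` holds coefficients
    ``(a_i, b_i, c_i, d_i)`` with
    ``S_i(x) = a_i (x-x_i)^3 + b_i (x-x_i)^2 + c_i (x-x_i) + d_i``.
    In parametric mode two splines x(u), y(u) share chord-length knots ``u``.
    """

    mode: str                        # "parametric" | "graph"
    knots: np.ndarray                # parameter values (u, or x in graph mode)
    _sx: CubicSpline | None = None   # x(u) (parametric)
    _sy: CubicSpline | None = None   # y(u) (parametric) or S(x) (graph)

    @property
    def coefficients(self):
        """Per-interval (a, b, c, d) arrays; a dict of both coordinates in
        parametric mode."""
        def unpack(cs: CubicSpline):
            a, b, c, d = cs.c
            return a, b, c, d
        if self.mode == "graph":
            return unpack(self._sy)
        return {"x": unpack(self._sx), "y": unpack(self._sy)}

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Points on the curve, (len(u), 2)."""
        u = np.asarray(u, dtype=float)
        if self.mode == "graph":
            return np.column_stack([u, self._sy(u)])
        return np.column_stack([self._sx(u), self._sy(u)])

    def derivatives(self, u: np.ndarray):
        u = np.asarray(u, dtype=float)
        if self.mode == "graph":
            one = np.ones_like(u)
            return (one, self._sy(u, 1)), (np.zeros_like(u), self._sy(u, 2))
        return (
            (self._sx(u, 1), self._sy(u, 1)),
            (self._sx(u, 2), self._sy(u, 2)),
        )

    def curvature(self, u: np.ndarray, lumen_point=None) -> np.ndarray:
        """Signed curvature; positive where the centre of curvature lies
        toward the lumen (if a lumen point is given)."""
        u = np.asarray(u, dtype=float)
        if self.mode == "graph":
            kappa = _graph_curvature(self._sy, u)
        else:
            (x1, y1), (x2, y2) = self.derivatives(u)
            denom = (x1**2 + y1**2) ** 1.5
            kappa = np.where(denom > 0, (x1 * y2 - y1 * x2) / np.where(denom > 0, denom, 1.0), 0.0)
        if lumen_point is not None:
            kappa = kappa * _lumen_sign(self, u, np.asarray(lumen_point, dtype=float))
        return kappa


def _graph_curvature(cs: CubicSpline, x: np.ndarray) -> np.ndarray:
    """The per-interval curvature formula evaluated from (a, b, c)."""
    a, b, c, _ = cs.c
    xi = cs.x
    idx = np.clip(np.searchsorted(xi, x, side="right") - 1, 0, len(a) - 1)
    t = x - xi[idx]
    num = 6 * a[idx] * t + 2 * b[idx]
    slope = 3 * a[idx] * t**2 + 2 * b[idx] * t + c[idx]
    return num / (1 + slope**2) ** 1.5


def _lumen_sign(spline: SplineCurve, u: np.ndarray, lumen_point: np.ndarray) -> np.ndarray:
    pts = spline(u)
    (x1, y1), _ = spline.derivatives(u)
    speed = np.hypot(x1, y1)
    speed[speed == 0] = 1.0
    # leftward unit normal of the travel direction
    nx, ny = -y1 / speed, x1 / speed
    dot = nx * (lumen_point[0] - pts[:, 0]) + ny * (lumen_point[1] - pts[:, 1])
    return np.where(dot >= 0, 1.0, -1.0)


def fit_spline(
    points: np.ndarray,
    mode: str = "parametric",
    closed: bool = False,
    bc_type: str | None = None,
) -> SplineCurve:
    """Interpolating cubic spline through sampled curve points.

    Parametric mode (default) uses the chord-length parameter and fits each
    coordinate; graph mode fits y = S(x) and requires strictly increasing x.
    Open curves use natural end conditions; ``closed=True`` joins the curve
    with a periodic spline (the appropriate choice for rings such as circle
    phantoms, avoiding end-condition curvature bias).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 4:
        raise ValueError("need at least 4 points for a cubic spline")
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise ValueError("duplicate consecutive points")
    if mode == "graph":
        if closed:
            raise ValueError("graph mode cannot represent a closed curve")
        x, y = pts[:, 0], pts[:, 1]
        if np.any(np.diff(x) <= 0):
            raise ValueError("graph mode requires strictly increasing x")
        return SplineCurve(mode="graph", knots=x.copy(),
                           _sy=CubicSpline(x, y, bc_type=bc_type or "natural"))
    if mode != "parametric":
        raise ValueError(f"unknown mode: {mode!r}")
    if closed:
        if not np.allclose(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[:1]])
        else:
            pts = pts.copy()
            pts[-1] = pts[0]  # periodic fit requires exact closure
        bc = bc_type or "periodic"
    else:
        bc = bc_type or "natural"
    u = _arc_length(pts)
    return SplineCurve(
        mode="parametric",
        knots=u,
        _sx=CubicSpline(u, pts[:, 0], bc_type=bc),
        _sy=CubicSpline(u, pts[:, 1], bc_type=bc),
    )


@dataclass
class CurvatureProfile:
    """Signed curvature (and optionally thickness) along the layer."""

    arc: np.ndarray          # µm from the apex tip
    s: np.ndarray            # arc / total, in [0, 1]
    kappa: np.ndarray        # µm^-1, signed per the lumen convention
    thickness: np.ndarray | None = None


def curvature_profile(
    spline: SplineCurve,
    lumen_point=None,
    n_samples: int = 400,
) -> CurvatureProfile:
    """Sample signed curvature densely along the spline.

    Arc length is accumulated by trapezoidal integration of the parametric
    speed; ``s`` is the arc length normalized by the total.
    """
    u = np.linspace(spline.knots[0], spline.knots[-1], n_samples)
    (x1, y1), _ = spline.derivatives(u)
    speed = np.hypot(x1, y1)
    arc = np.concatenate([[0.0], cumulative_trapezoid(speed, u)])
    kappa = spline.curvature(u, lumen_point=lumen_point)
    total = arc[-1]
    if total <= 0:
        raise ValueError("degenerate curve")
    return CurvatureProfile(arc=arc, s=arc / total, kappa=kappa)


def total_curvature(profile: CurvatureProfile) -> float:
    """Integral of signed curvature over the normalized arc length (µm⁻¹)."""
    if len(profile.s) == 0:
        raise ValueError("empty profile")
    return float(np.trapezoid(profile.kappa, profile.s))


def midline(layer: TracedLayer, resolution: float = 1.0) -> np.ndarray:
    """Medial curve of the layer by skeletonizing the enclosed ribbon.

    The apical and basal contours are joined into a polygon, rasterized at
    ``resolution`` µm/px, thinned to a one-pixel skeleton, and the longest
    skeleton path is returned ordered from the apex tip (the end nearest
    ``layer.apex_point``, or the first apical point).
    """
    ring = np.vstack([layer.apical, layer.basal[::-1]])
    poly = Polygon(ring)
    if not poly.is_valid or LineString(layer.apical).crosses(LineString(layer.basal)):
        raise ValueError("contours cross: invalid layer")
    minx, miny, maxx, maxy = poly.bounds
    pad = 2 * resolution
    origin = np.array([minx - pad, miny - pad])
    W = int(np.ceil((maxx - minx + 2 * pad) / resolution)) + 1
    H = int(np.ceil((maxy - miny + 2 * pad) / resolution)) + 1
    cols = (ring[:, 0] - origin[0]) / resolution
    rows = (ring[:, 1] - origin[1]) / resolution
    mask = np.zeros((H, W), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    if mask.sum() < 4:
        raise ValueError("layer ribbon too thin to skeletonize")
    skel = skeletonize(mask)
    path = _longest_skeleton_path(skel)
    if len(path) < 2:
        raise ValueError("degenerate skeleton")
    pts = np.column_stack([
        origin[0] + path[:, 1] * resolution,
        origin[1] + path[:, 0] * resolution,
    ])
    anchor = layer.apex_point if layer.apex_point is not None else layer.apical[0]
    if np.linalg.norm(pts[-1] - anchor) < np.linalg.norm(pts[0] - anchor):
        pts = pts[::-1]
    return pts


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest simple path through an 8-connected skeleton (tree diameter)."""
    pix = np.argwhere(skel)
    if len(pix) == 0:
        raise ValueError("empty skeleton")
    pixset = {tuple(p) for p in map(tuple, pix)}
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def bfs(start):
        seen = {start: None}
        order = [start]
        qi = 0
        while qi < len(order):
            cur = order[qi]
            qi += 1
            for dy, dx in nbrs:
                nxt = (cur[0] + dy, cur[1] + dx)
                if nxt in pixset and nxt not in seen:
                    seen[nxt] = cur
                    order.append(nxt)
        return order[-1], seen

    e1, _ = bfs(tuple(pix[0]))
    e2, parents = bfs(e1)
    path = [e2]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    return np.array(path)


def thickness_profile(
    midline_points: np.ndarray,
    layer: TracedLayer,
) -> tuple[np.ndarray, np.ndarray]:
    """Layer thickness at each midline sampling point.

    The thickness is the length of the straight segment through the point,
    normal to the midline, clipped by the apical and basal contours.  Where
    the normal misses a contour the sum of nearest-point distances is used
    instead and the point is flagged.  Returns (thickness, fallback_flags).
    """
    pts = np.asarray(midline_points, dtype=float)
    if len(pts) < 2:
        raise ValueError("midline needs at least two points")
    ap = LineString(layer.apical)
    ba = LineString(layer.basal)
    tx = np.gradient(pts[:, 0])
    ty = np.gradient(pts[:, 1])
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm
    out = np.empty(len(pts))
    flagged = np.zeros(len(pts), dtype=bool)
    span = 4.0 * (ap.distance(ba) + max(ap.length, ba.length) * 0.05 + 1.0)
    for i, p in enumerate(pts):
        d_ap = ap.distance(Point(p))
        d_ba = ba.distance(Point(p))
        ray = LineString([
            (p[0] - nx[i] * span, p[1] - ny[i] * span),
            (p[0] + nx[i] * span, p[1] + ny[i] * span),
        ])
        qa = _nearest_intersection(ray, ap, p)
        qb = _nearest_intersection(ray, ba, p)
        if qa is None or qb is None:
            out[i] = d_ap + d_ba
            flagged[i] = True
        else:
            out[i] = float(np.hypot(qa[0] - qb[0], qa[1] - qb[1]))
    return out, flagged


def _nearest_intersection(ray: LineString, contour: LineString, p) -> tuple | None:
    inter = ray.intersection(contour)
    if inter.is_empty:
        return None
    geoms = getattr(inter, "geoms", [inter])
    best, bd = None, np.inf
    for g in geoms:
        for q in getattr(g, "coords", []):
            d = (q[0] - p[0]) ** 2 + (q[1] - p[1]) ** 2
            if d < bd:
                best, bd = q, d
    return best


def local_edge_curvature(
    edge_points: np.ndarray,
    reference_point: np.ndarray,
    spacing: float = 19.0,
    lumen_point=None,
) -> float:
    """Curvature at a reference point from four 19-µm-spaced edge samples.

    Four points bracketing the reference (two on each side, at arc offsets
    ±0.5 and ±1.5 times ``spacing``) are sampled along the traced edge and
    fitted with a parametric cubic (not-a-knot ends, so the four points
    define a single cubic per coordinate); the signed curvature at the
    reference is the mean of the spline curvature at the two knots flanking
    it, where the interpolant is most accurate.  Returns NaN when the edge
    is too short around the reference.
    """
    pts = np.asarray(edge_points, dtype=float)
    ref = np.asarray(reference_point, dtype=float)
    arc = _arc_length(pts)
    # arc position of the projection of the reference onto the polyline
    line = LineString(pts)
    s_ref = float(line.project(Point(ref)))
    offsets = np.array([-1.5, -0.5, 0.5, 1.5]) * spacing
    s_samples = s_ref + offsets
    if s_samples[0] < -1e-9 or s_samples[-1] > arc[-1] + 1e-9:
        return float("nan")
    s_samples = np.clip(s_samples, 0.0, arc[-1])
    x = np.interp(s_samples, arc, pts[:, 0])
    y = np.interp(s_samples, arc, pts[:, 1])
    sp = fit_spline(np.column_stack([x, y]), mode="parametric", bc_type="not-a-knot")
    u_eval = sp.knots[1:3]
    kappa = sp.curvature(u_eval, lumen_point=lumen_point)
    return float(kappa.mean())
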