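"""FRET ratiometrics, PIV tissue-flow fields and windowed ERK/strain series.

This module turns two-channel (FRET, CFP) time-lapse stacks into the
quantities the wave analysis consumes: per-pixel ERK activity (FRET/CFP
ratio), gridded tissue velocity by window cross-correlation between
consecutive frames, flow speed projected on the apex-base line, the
extension-shrinkage rate (the diagonal strain-rate component along that
line), and windowed mean ERK activity with its time derivative.

Pixel coordinates are 0-based ``(row, col)``; physical conversion uses the
stack's ``pixel_size`` (µm/px) and ``frame_interval`` (min).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelStack",
    "RatioStack",
    "PIVField",
    "ApexBaseLine",
    "fret_ratio",
    "piv_pair",
    "median_filter_field",
    "project_onto_line",
    "extension_shrinkage_rate",
    "window_erk_series",
    "moving_average",
]


@dataclass
class ChannelStack:
    """A timed single-channel image sequence with physical calibration."""

    frames: np.ndarray        # (T, H, W)
    pixel_size: float         # µm / px
    frame_interval: float     # min

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RatioStack:
    """Per-pixel FRET/CFP ratio (NaN where CFP is at or below background)."""

    ratio: np.ndarray         # (T, H, W), NaN where undefined
    intensity: np.ndarray     # FRET-channel brightness after filtering
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.ratio.shape[0]


def _background_value(frame: np.ndarray, background) -> float:
    """Resolve a background specification for one frame of one channel.

    ``None``: mean of the darkest 1% of pixels; scalar: used directly;
    boolean mask: mean within the region.
    """
    if background is None:
        flat = np.sort(frame.ravel())
        k = max(1, flat.size // 100)
        return float(flat[:k].mean())
    if np.isscalar(background):
        return float(background)
    mask = np.asarray(background, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError("background region mask must match the frame shape")
    return float(frame[mask].mean())


def fret_ratio(
    fret: ChannelStack,
    cfp: ChannelStack,
    background=None,
) -> RatioStack:
    """3x3 median filter, background subtraction and FRET/CFP per pixel.

    ``background`` may be None (per-frame darkest-1% estimate), a scalar, a
    (fret_bg, cfp_bg) pair of scalars, or a boolean region mask evaluated per
    frame per channel.  Pixels whose background-subtracted CFP is <= 0 are
    undefined (NaN) in the ratio.
    """
    if fret.frames.shape != cfp.frames.shape:
        raise ValueError("FRET and CFP stacks must have identical shapes")
    if (fret.pixel_size, fret.frame_interval) != (cfp.pixel_size, cfp.frame_interval):
        raise ValueError("FRET and CFP stacks must share calibration")
    if isinstance(background, (tuple, list)) and len(background) == 2:
        bg_f, bg_c = background
    else:
        bg_f = bg_c = background

    T = fret.n_frames
    ratio = np.empty(fret.frames.shape, dtype=np.float64)
    inten = np.empty_like(ratio)
    for i in range(T):
        f = ndimage.median_filter(np.asarray(fret.frames[i], dtype=float), size=3)
        c = ndimage.median_filter(np.asarray(cfp.frames[i], dtype=float), size=3)
        f = f - _background_value(f, bg_f)
        c = c - _background_value(c, bg_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(c > 0, f / np.where(c > 0, c, 1.0), np.nan)
        ratio[i] = r
        inten[i] = f
    return RatioStack(ratio=ratio, intensity=inten,
                      pixel_size=fret.pixel_size, frame_interval=fret.frame_interval)


@dataclass
class PIVField:
    """Gridded displacement field between two consecutive frames.

    ``u`` is the column (x) displacement and ``v`` the row (y) displacement
    in px per frame pair on a regular grid of window centers; ``valid`` flags
    windows with measurable texture.
    """

    rows: np.ndarray          # (ny,) window-center rows, px
    cols: np.ndarray          # (nx,) window-center cols, px
    u: np.ndarray             # (ny, nx) px / frame pair, +x = +col
    v: np.ndarray             # (ny, nx) px / frame pair, +y = +row
    valid: np.ndarray         # (ny, nx) bool
    window_size: int
    overlap: float
    pixel_size: float
    frame_interval: float

    @property
    def grid_spacing(self) -> float:
        return self.window_size * (1.0 - self.overlap)

    def velocities_um_min(self) -> tuple[np.ndarray, np.ndarray]:
        f = self.pixel_size / self.frame_interval
        return self.u * f, self.v * f


def _subpixel_offset(c_m: float, c_0: float, c_p: float) -> float:
    """3-point Gaussian peak interpolation (parabolic fallback)."""
    if c_m > 0 and c_0 > 0 and c_p > 0 and not (c_m == c_0 == c_p):
        lm, l0, lp = np.log(c_m), np.log(c_0), np.log(c_p)
        den = lm - 2 * l0 + lp
        if den < 0:
            return float(0.5 * (lm - lp) / den)
    den = c_m - 2 * c_0 + c_p
    if den < 0:
        return float(0.5 * (c_m - c_p) / den)
    return 0.0


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_size: int = 40,
    overlap: float = 0.5,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    max_displacement: int | None = None,
) -> PIVField:
    """Window cross-correlation PIV between two frames.

    Each interrogation window of ``frame_a`` is matched by normalized
    cross-correlation against a search region of ``frame_b`` extended by
    ``max_displacement`` px on every side; the correlation peak with 3-point
    Gaussian sub-pixel refinement gives the displacement of the texture from
    A to B.  Windows with (near-)zero variance in either frame are flagged
    invalid.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share shape")
    if window_size % 2 != 0:
        raise ValueError("window_size must be even")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    ws = window_size
    step = int(round(ws * (1 - overlap)))
    if max_displacement is None:
        max_displacement = ws // 3
    H, W = a.shape
    m = max_displacement
    # keep the full symmetric search range inside the frame where possible
    row0s = np.arange(m, H - ws - m + 1, step)
    col0s = np.arange(m, W - ws - m + 1, step)
    if len(row0s) == 0:
        row0s = np.arange(0, H - ws + 1, step)
    if len(col0s) == 0:
        col0s = np.arange(0, W - ws + 1, step)
    ny, nx = len(row0s), len(col0s)
    if ny == 0 or nx == 0:
        raise ValueError("frames smaller than one interrogation window")
    u = np.zeros((ny, nx))
    v = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    for iy, r0 in enumerate(row0s):
        for ix, c0 in enumerate(col0s):
            wa = a[r0 : r0 + ws, c0 : c0 + ws]
            if wa.std() < 1e-12:
                continue
            # search region of frame B around the window, clipped at the frame
            rs0, rs1 = max(0, r0 - m), min(H, r0 + ws + m)
            cs0, cs1 = max(0, c0 - m), min(W, c0 + ws + m)
            search = b[rs0:rs1, cs0:cs1]
            if search.std() < 1e-12:
                continue
            ncc = match_template(search, wa)  # (sr, sc) -> top-left alignment
            pk = np.unravel_index(np.argmax(ncc), ncc.shape)
            # a peak on the border of a clipped search range is unreliable
            clipped = (rs0 > r0 - m or rs1 < r0 + ws + m
                       or cs0 > c0 - m or cs1 < c0 + ws + m)
            on_border = (pk[0] in (0, ncc.shape[0] - 1)
                         or pk[1] in (0, ncc.shape[1] - 1))
            if clipped and on_border and not (ncc.shape[0] == 1 and ncc.shape[1] == 1):
                continue
            dy = pk[0] + rs0 - r0
            dx = pk[1] + cs0 - c0
            off_y = off_x = 0.0
            if 0 < pk[0] < ncc.shape[0] - 1:
                off_y = _subpixel_offset(
                    ncc[pk[0] - 1, pk[1]], ncc[pk], ncc[pk[0] + 1, pk[1]]
                )
            if 0 < pk[1] < ncc.shape[1] - 1:
                off_x = _subpixel_offset(
                    ncc[pk[0], pk[1] - 1], ncc[pk], ncc[pk[0], pk[1] + 1]
                )
            v[iy, ix] = dy + off_y
            u[iy, ix] = dx + off_x
            valid[iy, ix] = True
    return PIVField(
        rows=row0s + (ws - 1) / 2.0,
        cols=col0s + (ws - 1) / 2.0,
        u=u, v=v, valid=valid,
        window_size=ws, overlap=overlap,
        pixel_size=pixel_size, frame_interval=frame_interval,
    )


def median_filter_field(field: PIVField, radius: int = 1) -> PIVField:
    """Componentwise median over the (2r+1)^2 window neighborhood.

    Invalid vectors are excluded from the medians and replaced by their
    neighborhood median (and marked valid if any valid neighbor exists).
    """
    ny, nx = field.u.shape
    u2 = field.u.copy()
    v2 = field.v.copy()
    ok2 = field.valid.copy()
    r = radius
    for iy in range(ny):
        for ix in range(nx):
            ys = slice(max(0, iy - r), min(ny, iy + r + 1))
            xs = slice(max(0, ix - r), min(nx, ix + r + 1))
            m = field.valid[ys, xs]
            if not m.any():
                ok2[iy, ix] = False
                continue
            u2[iy, ix] = np.median(field.u[ys, xs][m])
            v2[iy, ix] = np.median(field.v[ys, xs][m])
            ok2[iy, ix] = True
    return replace(field, u=u2, v=v2, valid=ok2)


@dataclass
class ApexBaseLine:
    """Ordered polyline from the apex tip toward the base, in pixels."""

    points: np.ndarray        # (n, 2) as (row, col)
    pixel_size: float         # µm / px

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("need at least two (row, col) points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("polyline has duplicate consecutive points")
        self._seg_px = seg

    @property
    def arc_length_um(self) -> np.ndarray:
        """Cumulative arc length from the apex tip, µm."""
        return np.concatenate([[0.0], np.cumsum(self._seg_px)]) * self.pixel_size

    @property
    def total_length_um(self) -> float:
        return float(self.arc_length_um[-1])

    def nearest(self, point_rc: np.ndarray) -> tuple[float, float, np.ndarray]:
        """(arc position µm, distance px, unit tangent) nearest to a point."""
        p = np.asarray(point_rc, dtype=float)
        best = (np.inf, 0.0, None)
        arc_px = np.concatenate([[0.0], np.cumsum(self._seg_px)])
        for i in range(len(self.points) - 1):
            a, b = self.points[i], self.points[i + 1]
            ab = b - a
            L2 = ab @ ab
            t = float(np.clip((p - a) @ ab / L2, 0.0, 1.0))
            q = a + t * ab
            d = float(np.linalg.norm(p - q))
            if d < best[0]:
                best = (d, arc_px[i] + t * self._seg_px[i], ab / np.sqrt(L2))
        d, s_px, tan = best
        return s_px * self.pixel_size, d, tan


def project_onto_line(
    field: PIVField, line: ApexBaseLine, max_distance_px: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project window velocities onto the apex-base line.

    Windows whose centers lie within ``max_distance_px`` (default: one grid
    spacing) of the polyline are selected and ordered by arc length from the
    apex.  Returns (arc positions µm, speeds µm/min positive toward the apex,
    selected flat indices).  The line tangent points base-ward, so the
    projected speed is the negative tangential velocity component.
    """
    if max_distance_px is None:
        max_distance_px = field.grid_spacing
    uu, vv = field.velocities_um_min()
    sel_pos, sel_speed, sel_idx = [], [], []
    for iy in range(len(field.rows)):
        for ix in range(len(field.cols)):
            if not field.valid[iy, ix]:
                continue
            center = np.array([field.rows[iy], field.cols[ix]])
            s_um, d_px, tan = line.nearest(center)
            if d_px > max_distance_px:
                continue
            # tangent is (d_row, d_col); velocity (v, u) in (row, col) axes
            v_along_base = vv[iy, ix] * tan[0] + uu[iy, ix] * tan[1]
            sel_pos.append(s_um)
            sel_speed.append(-v_along_base)  # positive toward the apex
            sel_idx.append(iy * len(field.cols) + ix)
    if not sel_pos:
        raise ValueError("apex-base line does not pass near the PIV grid")
    pos = np.asarray(sel_pos)
    spd = np.asarray(sel_speed)
    idx = np.asarray(sel_idx)
    order = np.argsort(pos)
    pos, spd, idx = pos[order], spd[order], idx[order]
    # windows from different grid rows can project to the same arc position;
    # merge them (band average) so positions are strictly increasing
    tol = 0.25 * field.grid_spacing * field.pixel_size
    merged_pos, merged_spd, merged_idx = [], [], []
    i = 0
    while i < len(pos):
        j = i + 1
        while j < len(pos) and pos[j] - pos[i] < tol:
            j += 1
        merged_pos.append(pos[i:j].mean())
        merged_spd.append(spd[i:j].mean())
        merged_idx.append(idx[i])
        i = j
    return np.asarray(merged_pos), np.asarray(merged_spd), np.asarray(merged_idx)


def moving_average(y: np.ndarray, span: int = 5, axis: int = -1) -> np.ndarray:
    """Centered moving average whose window shrinks at the ends.

    Matches the common smoothing convention for short biological series
    (span-5 default).
    """
    y = np.asarray(y, dtype=float)
    if span <= 1:
        return y
    return np.apply_along_axis(_ma_1d, axis, y, span)


def _ma_1d(y: np.ndarray, span: int) -> np.ndarray:
    out = np.empty_like(y)
    n = len(y)
    h = span // 2
    for i in range(n):
        hh = min(h, i, n - 1 - i)
        out[i] = y[i - hh : i + hh + 1].mean()
    return out


def extension_shrinkage_rate(
    speeds: np.ndarray,
    positions: np.ndarray,
    smooth_span: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial derivative of the projected flow speed between adjacent windows.

    ``speeds`` is either a spatial profile ``(n,)`` or a time-by-window array
    ``(T, n)``; ``positions`` are the matching arc-length positions (µm).
    The raw rate between windows ``i`` and ``i+1`` is
    ``(speed[i+1]-speed[i]) / (pos[i+1]-pos[i])`` (min⁻¹), reported at the
    midpoint positions.  A centered ``smooth_span`` moving average (applied
    along time for 2D input, along the profile for 1D input) gives the
    smoothed rate.  Returns (midpoint positions, smoothed rate, raw rate).
    """
    speeds = np.asarray(speeds, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or len(positions) < 2:
        raise ValueError("need at least two windows along the line")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    dx = np.diff(positions)
    mid = 0.5 * (positions[:-1] + positions[1:])
    if speeds.ndim == 1:
        raw = np.diff(speeds) / dx
        smoothed = moving_average(raw, smooth_span)
    elif speeds.ndim == 2:
        raw = np.diff(speeds, axis=1) / dx[None, :]
        smoothed = moving_average(raw, smooth_span, axis=0)
    else:
        raise ValueError("speeds must be 1D or 2D")
    return mid, smoothed, raw


def window_erk_series(
    ratio: RatioStack,
    cfp: ChannelStack,
    centers: Sequence[tuple[float, float]],
    window_size: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean ERK activity and its time derivative.

    Within each window, each frame's cytoplasmic region is segmented by
    Otsu's threshold on the CFP channel and the ERK activity is the mean
    FRET/CFP ratio over that region.  Frames whose mask is empty (or whose
    window has no contrast) are NaN and linearly interpolated when isolated.
    Returns (activities, rates), both (T, n_windows); rates are central
    differences over the frame interval.
    """
    T = ratio.n_frames
    if cfp.n_frames != T:
        raise ValueError("ratio and CFP stacks must have the same length")
    h = window_size // 2
    H, W = cfp.shape
    acts = np.full((T, len(centers)), np.nan)
    for j, (r, c) in enumerate(centers):
        r0, c0 = int(round(r - h)), int(round(c - h))
        r1, c1 = r0 + window_size, c0 + window_size
        if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
            raise ValueError(f"window {j} at ({r},{c}) out of bounds")
        for i in range(T):
            cw = np.asarray(cfp.frames[i, r0:r1, c0:c1], dtype=float)
            rw = ratio.ratio[i, r0:r1, c0:c1]
            if cw.max() - cw.min() < 1e-12:
                continue
            try:
                thr = threshold_otsu(cw)
            except ValueError:
                continue
            m = (cw > thr) & np.isfinite(rw)
            if m.any():
                acts[i, j] = rw[m].mean()
        acts[:, j] = _interp_isolated_nans(acts[:, j])
    rates = np.gradient(acts, ratio.frame_interval, axis=0)
    return acts, rates


def _interp_isolated_nans(y: np.ndarray) -> np.ndarray:
    """Fill NaNs by linear interpolation where valid neighbors exist."""
    y = y.copy()
    bad = ~np.isfinite(y)
    if bad.any() and (~bad).sum() >= 2:
        idx = np.arange(len(y))
        y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
    return y
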