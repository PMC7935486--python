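"""Seeded generators for synthetic imaging data with attached ground truth.

Real two-photon movies of the developing cochlear duct are not distributable,
so every input class the quantification pipeline consumes can be generated
here with known ground truth: textured two-channel FRET/CFP movies carrying a
prescribed tissue flow and a retrograde ERK intensity wave, geometric
phantoms (circles, annuli, spirals, duct-shaped masks, gradient volumes,
point fields) with closed-form curvature/thickness/intensity/density, and
paired time series with a built-in lag.

All generators are deterministic functions of their spec plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .flow import ChannelStack

__all__ = [
    "WaveMovieSpec",
    "PhantomSpec",
    "make_wave_movie",
    "make_phantom",
    "make_lagged_series",
]


@dataclass(frozen=True)
class WaveMovieSpec:
    """Parameters of a synthetic FRET/CFP movie.

    The image x-axis (columns) is the apex-base axis with the apex at column
    zero, so a physical position equals ``column * pixel_size`` µm from the
    apex.  The tissue texture is advected toward the apex at ``flow_speed``
    while the multiplicative ERK wave on the FRET channel travels toward the
    base at ``wave_speed``.  ``strain_amplitude`` adds a traveling sinusoidal
    modulation to the displacement field whose strain rate the ERK wave
    follows with a delay of ``erk_lag`` minutes.

    Defaults mirror the measured study conditions: 0.625 µm pixels (a 40-px
    PIV window is about 25 µm), 12-min frames, flow 0.24 µm/min, wave
    0.42 µm/min, wavelength 168 µm, deformation-to-ERK lag 24 min.
    """

    shape: tuple[int, int] = (128, 512)   # rows, cols
    pixel_size: float = 0.625             # µm / px
    frame_interval: float = 12.0          # min
    n_frames: int = 100
    flow_speed: float = 0.24              # µm/min toward apex (-x)
    wave_speed: float = 0.42              # µm/min toward base (+x)
    wavelength: float = 168.0             # µm
    erk_lag: float = 24.0                 # min, deformation precedes ERK
    wave_amplitude: float = 0.2           # FRET modulation depth
    strain_amplitude: float = 0.0         # µm displacement oscillation
    texture_grain: float = 3.0            # px
    noise_sd: float = 0.0                 # fraction of base intensity
    base_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength <= 2 * self.pixel_size:
            raise ValueError("wavelength under-resolved by the pixel grid")
        for name in ("pixel_size", "frame_interval", "base_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        for name in ("flow_speed", "wave_speed", "wave_amplitude",
                     "strain_amplitude", "noise_sd", "erk_lag"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


def make_wave_movie(
    spec: WaveMovieSpec,
) -> tuple[ChannelStack, ChannelStack, dict[str, Any]]:
    """Render the (FRET, CFP) stacks of a flowing, ERK-wave-carrying tissue.

    CFP is a band-limited random texture advected by the displacement field

        D(x, t) = -flow_speed * t + strain_amplitude * sin(k (x - c t))

    (µm, positive toward the base; ``k = 2π/wavelength``, ``c = wave_speed``)
    and FRET = CFP * (1 + A cos(k (x - c t) + k c τ)), whose activity rate
    equals the local strain rate delayed by ``τ = erk_lag``.  Returns the two
    stacks and a ground-truth record.
    """
    s = spec
    rows, cols = s.shape
    rng = np.random.default_rng(s.seed)
    total_t = (s.n_frames - 1) * s.frame_interval
    # padded texture canvas: material entering from the base side over time
    max_shift_px = int(np.ceil(
        (s.flow_speed * total_t + 2 * s.strain_amplitude) / s.pixel_size
    )) + 4
    canvas = rng.standard_normal((rows, cols + max_shift_px))
    canvas = ndimage.gaussian_filter(canvas, s.texture_grain)
    canvas -= canvas.min()
    canvas /= max(canvas.max(), 1e-12)
    canvas = 0.25 + 0.75 * canvas  # keep texture strictly positive

    k = 2 * np.pi / s.wavelength
    xs = np.arange(cols) * s.pixel_size  # µm from apex, per column
    col_idx = np.arange(cols, dtype=float)

    fret = np.empty((s.n_frames, rows, cols), dtype=np.float32)
    cfp = np.empty_like(fret)
    for f in range(s.n_frames):
        t = f * s.frame_interval
        disp = -s.flow_speed * t + s.strain_amplitude * np.sin(k * (xs - s.wave_speed * t))
        src_cols = col_idx - disp / s.pixel_size  # inverse warp, µm -> px
        src_cols = np.clip(src_cols, 0, canvas.shape[1] - 1)
        frame = np.stack([np.interp(src_cols, np.arange(canvas.shape[1]), canvas[r])
                          for r in range(rows)])
        wave = 1.0 + s.wave_amplitude * np.cos(
            k * (xs - s.wave_speed * t) + k * s.wave_speed * s.erk_lag
        )
        c_img = s.base_intensity * frame
        f_img = c_img * wave[None, :]
        if s.noise_sd > 0:
            f_img = f_img + s.noise_sd * s.base_intensity * rng.standard_normal(f_img.shape)
            c_img = c_img + s.noise_sd * s.base_intensity * rng.standard_normal(c_img.shape)
        fret[f] = f_img
        cfp[f] = c_img

    truth = {
        "flow_speed_toward_apex": s.flow_speed,
        "wave_speed_toward_base": s.wave_speed,
        "wavelength": s.wavelength,
        "erk_lag": s.erk_lag,
        "displacement_per_frame_um": -s.flow_speed * s.frame_interval,
        "erk_activity_amplitude": s.wave_amplitude,
    }
    make = lambda a: ChannelStack(frames=a, pixel_size=s.pixel_size,
                                  frame_interval=s.frame_interval)
    return make(fret), make(cfp), truth


@dataclass(frozen=True)
class PhantomSpec:
    """A geometric phantom request: ``kind`` plus its parameters (µm)."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


def make_phantom(spec: PhantomSpec) -> dict[str, Any]:
    """Dispatch to the phantom generators; each returns data + ground truth."""
    makers = {
        "circle": _circle,
        "annulus": _annulus,
        "spiral": _spiral,
        "rect_duct": _rect_duct,
        "sector_duct": _sector_duct,
        "gradient_volume": _gradient_volume,
        "poisson_points": _poisson_points,
    }
    if spec.kind not in makers:
        raise ValueError(f"unknown phantom kind: {spec.kind!r}")
    return makers[spec.kind](spec)


def _circle_points(R: float, n: int, center=(0.0, 0.0), theta0=0.0, theta1=2 * np.pi):
    th = np.linspace(theta0, theta1, n)
    return np.column_stack([center[0] + R * np.cos(th), center[1] + R * np.sin(th)])


def _circle(spec: PhantomSpec) -> dict[str, Any]:
    p = dict(spec.params)
    R = float(p.get("radius", 100.0))
    if R <= 0:
        raise ValueError("radius must be > 0")
    n = int(p.get("n_points", max(64, int(2 * np.pi * R))))
    center = tuple(p.get("center", (0.0, 0.0)))
    pts = _circle_points(R, n, center)
    return {
        "kind": "circle",
        "points": pts,
        "center": np.asarray(center, dtype=float),
        "truth": {"kappa": 1.0 / R, "radius": R, "circumference": 2 * np.pi * R},
    }


def _annulus(spec: PhantomSpec) -> dict[str, Any]:
    p = dict(spec.params)
    R_in = float(p.get("r_inner", 90.0))
    R_out = float(p.get("r_outer", 110.0))
    if not 0 < R_in < R_out:
        raise ValueError("need 0 < r_inner < r_outer")
    sweep = float(p.get("sweep", 2 * np.pi))
    n = int(p.get("n_points", 256))
    center = tuple(p.get("center", (0.0, 0.0)))
    inner = _circle_points(R_in, n, center, 0.0, sweep)
    outer = _circle_points(R_out, n, center, 0.0, sweep)
    return {
        "kind": "annulus",
        "apical": inner,   # lumen side
        "basal": outer,
        "lumen_point": np.asarray(center, dtype=float),
        "truth": {
            "thickness": R_out - R_in,
            "midline_radius": 0.5 * (R_in + R_out),
            "midline_kappa": 2.0 / (R_in + R_out),
        },
    }


def _spiral(spec: PhantomSpec) -> dict[str, Any]:
    """Archimedean spiral r = a + b*theta with closed-form curvature."""
    p = dict(spec.params)
    a = float(p.get("a", 50.0))
    b = float(p.get("b", 20.0))
    turns = float(p.get("turns", 1.5))
    n = int(p.get("n_points", 800))
    if a <= 0 or b <= 0 or turns <= 0:
        raise ValueError("a, b, turns must be > 0")
    th = np.linspace(0.0, 2 * np.pi * turns, n)
    r = a + b * th
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    kappa = (r**2 + 2 * b**2) / (r**2 + b**2) ** 1.5
    ds = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    arc = np.concatenate([[0.0], np.cumsum(ds)])
    return {
        "kind": "spiral",
        "points": pts,
        "truth": {"theta": th, "kappa": kappa, "arc_length": arc},
    }


def _rect_duct(spec: PhantomSpec) -> dict[str, Any]:
    """A straight duct mask (rectangle with a pointed apex tip at the left)
    with landmarks and a mediolateral EdU gradient (columns: along-duct from
    the apex; rows: mediolateral, medial at top).  The pointed tip makes the
    apex a sharp convex perimeter point, as in the real duct, so the medial
    and lateral curves separate immediately."""
    p = dict(spec.params)
    length = int(p.get("length_px", 200))
    width = int(p.get("width_px", 100))
    tip = int(p.get("tip_px", 20))
    pad = int(p.get("pad", 20))
    lo = float(p.get("edu_min", 40.0))
    hi = float(p.get("edu_max", 200.0))
    from skimage.draw import polygon as draw_polygon

    H, W = width + 2 * pad, length + tip + 2 * pad
    rows = [pad + width / 2.0, pad, pad, pad + width - 1, pad + width - 1]
    cols = [pad, pad + tip, pad + tip + length - 1, pad + tip + length - 1, pad + tip]
    mask = np.zeros((H, W), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    grad = np.zeros((H, W), dtype=float)
    ml = lo + (hi - lo) * (np.arange(H) - pad) / max(width - 1, 1)
    grad[:] = np.clip(ml, lo, hi)[:, None]
    grad[~mask] = 0.0
    landmarks = {
        "apex": (pad + width / 2.0, float(pad)),
        "medial_end": (float(pad), float(pad + tip + length - 1)),
        "lateral_end": (float(pad + width - 1), float(pad + tip + length - 1)),
    }
    return {
        "kind": "rect_duct",
        "mask": mask,
        "edu": grad,
        "landmarks": landmarks,
        "truth": {
            "edu_range": (lo, hi),
            "gradient_axis": "mediolateral",
            "row_means_increase_toward_lateral": True,
        },
    }


def _sector_duct(spec: PhantomSpec) -> dict[str, Any]:
    """An annular-sector duct mask (a bent duct) with landmarks."""
    p = dict(spec.params)
    R_in = float(p.get("r_inner_px", 60.0))
    R_out = float(p.get("r_outer_px", 120.0))
    sweep = float(p.get("sweep_deg", 150.0)) * np.pi / 180.0
    pad = int(p.get("pad", 10))
    size = int(np.ceil(R_out)) + pad
    H = W = 2 * size
    yy, xx = np.mgrid[0:H, 0:W]
    cy = cx = float(size)
    rr = np.hypot(yy - cy, xx - cx)
    th = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    mask = (rr >= R_in) & (rr <= R_out) & (th <= sweep)
    R_mid = 0.5 * (R_in + R_out)
    # pointed apex cap on the theta=0 end (sharp convex tip, as in the duct)
    tip_depth = float(p.get("tip_px", 15.0))
    from skimage.draw import polygon as draw_polygon

    tri_r = [cy, cy, cy - tip_depth]
    tri_c = [cx + R_in, cx + R_out, cx + R_mid]
    rr2, cc2 = draw_polygon(tri_r, tri_c, shape=mask.shape)
    mask[rr2, cc2] = True
    landmarks = {
        "apex": (cy - tip_depth, cx + R_mid),
        "medial_end": (cy + R_in * np.sin(sweep), cx + R_in * np.cos(sweep)),
        "lateral_end": (cy + R_out * np.sin(sweep), cx + R_out * np.cos(sweep)),
    }
    return {
        "kind": "sector_duct",
        "mask": mask,
        "landmarks": landmarks,
        "truth": {"r_inner": R_in, "r_outer": R_out, "sweep_rad": sweep},
    }


def _gradient_volume(spec: PhantomSpec) -> dict[str, Any]:
    """A 3-channel z-stack (marker, EdU, nuclei) over a rectangular duct."""
    p = dict(spec.params)
    nz = int(p.get("n_z", 8))
    base = _rect_duct(PhantomSpec("rect_duct", p, spec.seed))
    mask, edu = base["mask"], base["edu"]
    marker = np.where(mask, 200.0, 5.0)
    rng = np.random.default_rng(spec.seed)
    vol_marker = np.repeat(marker[None], nz, axis=0)
    vol_edu = np.repeat(edu[None], nz, axis=0)
    vol_nuc = np.where(mask, 120.0, 3.0)[None] * np.ones((nz, 1, 1))
    return {
        "kind": "gradient_volume",
        "marker": vol_marker.astype(np.uint8),
        "edu": np.clip(vol_edu, 0, 255).astype(np.uint8),
        "nuclei": np.clip(vol_nuc, 0, 255).astype(np.uint8),
        "mask": mask,
        "landmarks": base["landmarks"],
        "truth": base["truth"] | {"n_z": nz},
    }


def _poisson_points(spec: PhantomSpec) -> dict[str, Any]:
    """Homogeneous Poisson point field of intensity rho over a rectangle."""
    p = dict(spec.params)
    rho = float(p.get("rho", 0.01))        # points / µm^2
    width = float(p.get("width", 500.0))   # µm, mediolateral extent
    height = float(p.get("height", 200.0))
    if rho <= 0 or width <= 0 or height <= 0:
        raise ValueError("rho, width, height must be > 0")
    rng = np.random.default_rng(spec.seed)
    n = rng.poisson(rho * width * height)
    pts = np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])
    return {
        "kind": "poisson_points",
        "points": pts,
        "width": width,
        "height": height,
        "truth": {"rho": rho, "area": width * height, "n": int(n)},
    }


def make_lagged_series(
    lag: float,
    period: float,
    n: int,
    sampling: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, Any]]:
    """Periodic series ``a`` and its delayed noisy copy ``b(t) = a(t-lag)+noise``.

    Returns ``(t, a, b, truth)``.  Requires the sampling to resolve the lag
    (``sampling <= lag`` unless ``lag == 0``) and the record to span at least
    three periods.
    """
    if lag != 0 and sampling > lag:
        raise ValueError("sampling must be <= lag to resolve it")
    if n * sampling < 3 * period:
        raise ValueError("series span must cover at least 3 periods")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * sampling
    a = np.sin(2 * np.pi * t / period)
    b = np.sin(2 * np.pi * (t - lag) / period)
    if noise_sd > 0:
        b = b + noise_sd * rng.standard_normal(n)
    return t, a, b, {"lag": lag, "period": period, "sampling": sampling}
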