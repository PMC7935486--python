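"""1D mechanochemical cell-chain model of ERK activation waves and cell flow.

The developing cochlear duct epithelium is abstracted as a chain of ``N``
cells (springs) whose junctions ``i = 1..N+1`` move through viscous friction.
Each cell carries a strain ``eps_j``, an ERK activity ``E_j`` and a
contractile/motile force ``F_j`` generated at the rear junction of the cell:

    eta_c * dx_i/dt = k * (eps_i - eps_{i-1}) + F_{j=i}
    eta_E * dE_j/dt = tanh(alpha * eps_j) - E_j
    eta_F * dF_j/dt = lam * E_j - F_j

with ``eps_j = (x_{j+1} - x_j)/L - 1``.  The base junction (i=1) is fixed and
the apical tip junction (i=N+1) is propelled by a constant force ``F_tip``.
Stretch activates ERK (delay ``eta_E``); ERK drives force (delay ``eta_F``);
the force pulls the rear neighbour, stretching it in turn.  This closed loop
("coupled" mode) self-organises trains of ERK activity waves that travel
tip-to-base while the cells flow base-to-tip — the retrograde pattern seen in
live imaging.  In the "uncoupled" control mode the feedback from strain to
ERK is severed and ERK is prescribed as a retrograde traveling wave

    E(X, t) = 0.5 * (sin(pi * (X + v*t) / w) + 1)

of half-wavelength ``w`` and speed ``v``, while forces still relax toward
``lam * E``.

Notes on conventions
--------------------
The elastic term is the standard spring-chain force balance
``k*(eps_i - eps_{i-1})`` (the ahead spring pulls forward, the behind spring
pulls back).  The index-flipped variant ``k*(eps_i - eps_{i+1})`` is
anti-diffusive and numerically blows up within minutes of simulated time with
the default parameters; it is available as ``orientation="flipped"`` for
demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "ChainState",
    "Trajectory",
    "CrossCorrResult",
    "ChainInstabilityError",
    "default_params",
    "init_chain",
    "euler_step",
    "imposed_erk",
    "run",
    "model_rate_series",
    "xcorr_lag",
    "rate_lag_analysis",
]

Mode = Literal["coupled", "uncoupled"]


class ChainInstabilityError(RuntimeError):
    """Junction ordering was violated (numerical instability).

    Carries the simulation time of failure in ``.time``.
    """

    def __init__(self, time: float):
        super().__init__(
            f"junction order violated at t={time:.2f} min: the integration is "
            "unstable (check dt, parameters and elastic orientation)"
        )
        self.time = time


@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical parameters of the cell chain.

    Units: forces nN, lengths µm, times min; ``eta_c`` nN·min·µm⁻¹.
    Defaults are the biologically plausible set used for the cochlear duct.
    """

    eta_c: float = 40.0   # junction viscous friction
    k: float = 20.0       # spring constant
    L: float = 5.0        # rest cell length
    F_tip: float = 6.0    # tip self-propelling force
    alpha: float = 3.0    # strain-to-ERK sensitivity (dimensionless)
    eta_E: float = 30.0   # ERK relaxation timescale
    eta_F: float = 10.0   # force relaxation timescale
    lam: float = 9.0      # ERK-to-force amplitude (λ)
    N: int = 1000         # number of cells
    dt: float = 0.01      # forward-Euler step
    mode: Mode = "coupled"
    w: float | None = None  # imposed half-wavelength (uncoupled)
    v: float | None = None  # imposed wave speed (uncoupled)

    def __post_init__(self) -> None:
        for name in ("eta_c", "k", "L", "alpha", "eta_E", "eta_F", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.F_tip < 0 or self.lam < 0:
            raise ValueError("F_tip and lam must be >= 0")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.dt >= min(self.eta_E, self.eta_F):
            raise ValueError("dt must be smaller than the relaxation timescales")
        if self.mode not in ("coupled", "uncoupled"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.mode == "uncoupled":
            if self.w is None or self.v is None:
                raise ValueError("uncoupled mode requires w and v")
            if self.w <= 0 or self.v <= 0:
                raise ValueError("w and v must be > 0")


def default_params(mode: Mode = "coupled") -> ModelParams:
    """Printed default parameter set; uncoupled mode adds w=84 µm, v=0.42 µm/min."""
    if mode == "coupled":
        return ModelParams(mode="coupled")
    if mode == "uncoupled":
        return ModelParams(mode="uncoupled", w=84.0, v=0.42)
    raise ValueError(f"unknown mode: {mode!r}")


@dataclass
class ChainState:
    """Instantaneous state: junction positions and per-cell strain/ERK/force."""

    t: float
    x: np.ndarray    # (N+1,) junction positions, strictly increasing
    eps: np.ndarray  # (N,) cell strain
    E: np.ndarray    # (N,) ERK activity
    F: np.ndarray    # (N,) contractile force

    def validate(self, params: ModelParams) -> None:
        if len(self.x) != params.N + 1:
            raise ValueError("x must have N+1 junctions")
        if not (len(self.eps) == len(self.E) == len(self.F) == params.N):
            raise ValueError("eps, E, F must have N entries")
        if np.any(np.diff(self.x) <= 0):
            raise ChainInstabilityError(self.t)
        expected = np.diff(self.x) / params.L - 1.0
        if not np.allclose(self.eps, expected, atol=1e-9):
            raise ValueError("eps inconsistent with junction positions")

    @property
    def cell_centers(self) -> np.ndarray:
        return 0.5 * (self.x[:-1] + self.x[1:])


def init_chain(params: ModelParams) -> ChainState:
    """Rest state: junctions at rest spacing, zero strain, ERK and force."""
    x = np.arange(params.N + 1, dtype=float) * params.L
    z = np.zeros(params.N)
    return ChainState(t=0.0, x=x, eps=z.copy(), E=z.copy(), F=z.copy())


def imposed_erk(X: np.ndarray | float, t: float, params: ModelParams) -> np.ndarray | float:
    """Prescribed retrograde ERK wave of the uncoupled regime.

    ``E(X,t) = 0.5*(sin(pi*(X + v t)/w) + 1)``: spatial period ``2w``,
    crests travel toward the base (decreasing X) at speed ``v``.
    """
    if params.mode != "uncoupled":
        raise ValueError("imposed_erk applies to uncoupled mode only")
    return 0.5 * (np.sin(np.pi * (np.asarray(X, dtype=float) + params.v * t) / params.w) + 1.0)


def _velocities(
    x: np.ndarray, eps: np.ndarray, F: np.ndarray, p: ModelParams, orientation: str
) -> np.ndarray:
    """Junction velocities; base fixed, tip propelled against the last spring."""
    xdot = np.empty_like(x)
    xdot[0] = 0.0
    if orientation == "conventional":
        elastic = p.k * (eps[1:] - eps[:-1])
    elif orientation == "flipped":
        elastic = p.k * (eps[:-1] - eps[1:])
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    xdot[1:-1] = (elastic + F[1:]) / p.eta_c
    xdot[-1] = (-p.k * eps[-1] + p.F_tip) / p.eta_c
    return xdot


def euler_step(
    state: ChainState, params: ModelParams, orientation: str = "conventional"
) -> ChainState:
    """One forward-Euler update of the chain.

    Sequential update order (identical to the :func:`run` integrator):
    junction positions from the current force balance, strain refreshed from
    the new positions, then the ERK relaxation driven by the fresh strain
    and the force relaxation driven by the fresh ERK.  Raises
    :class:`ChainInstabilityError` if junctions cross.
    """
    p = params
    xdot = _velocities(state.x, state.eps, state.F, p, orientation)
    x = state.x + p.dt * xdot
    if np.any(np.diff(x) <= 0):
        raise ChainInstabilityError(state.t)
    eps = np.diff(x) / p.L - 1.0
    if p.mode == "coupled":
        E = state.E + p.dt * (np.tanh(p.alpha * eps) - state.E) / p.eta_E
    else:
        centers = 0.5 * (x[:-1] + x[1:])
        E = np.asarray(imposed_erk(centers, state.t + p.dt, p))
    F = state.F + p.dt * (p.lam * E - state.F) / p.eta_F
    return ChainState(t=state.t + p.dt, x=x, eps=eps, E=E, F=F)


@dataclass
class Trajectory:
    """Recorded snapshots of a chain simulation on a uniform time grid."""

    record_times: np.ndarray   # (n,) min, uniformly spaced
    record_interval: float     # min
    x: np.ndarray              # (n, N+1)
    eps: np.ndarray            # (n, N)
    E: np.ndarray              # (n, N)
    F: np.ndarray              # (n, N)
    params: ModelParams

    def __len__(self) -> int:
        return len(self.record_times)

    @property
    def states(self) -> Iterator[ChainState]:
        for i, t in enumerate(self.record_times):
            yield ChainState(t=float(t), x=self.x[i], eps=self.eps[i],
                             E=self.E[i], F=self.F[i])


def run(
    params: ModelParams,
    duration: float = 3000.0,
    record_interval: float = 1.0,
    discard: float = 1000.0,
    init: str = "noise",
    noise_amp: float = 0.02,
    seed: int = 0,
    orientation: str = "conventional",
    strict: bool = False,
) -> Trajectory:
    """Integrate the chain and record snapshots after a transient discard.

    In coupled mode the default initial condition perturbs the rest state
    with small seeded Gaussian noise on E (sd ``noise_amp``); the feedback
    amplifies it into sustained retrograde wave trains across the whole
    chain.  ``init="rest"`` starts exactly at rest, in which case waves only
    invade from the tip (seeded by ``F_tip``).  The uncoupled mode always
    starts at rest (its ERK field is prescribed).

    The saturated coupled wave trains intermittently drive a cell through
    zero length (a transient junction inversion) regardless of how small dt
    is; the forward-Euler update integrates through these events and the
    pattern recovers.  With ``strict=True`` the first inversion instead
    raises :class:`ChainInstabilityError` carrying the failure time.
    """
    p = params
    if not duration > discard >= 0:
        raise ValueError("need duration > discard >= 0")
    if record_interval < p.dt:
        raise ValueError("record_interval must be >= dt")
    if init not in ("noise", "rest"):
        raise ValueError(f"unknown init: {init!r}")

    x = np.arange(p.N + 1, dtype=float) * p.L
    eps = np.zeros(p.N)
    E = np.zeros(p.N)
    F = np.zeros(p.N)
    if p.mode == "coupled" and init == "noise":
        rng = np.random.default_rng(seed)
        E = noise_amp * rng.standard_normal(p.N)
    elif p.mode == "uncoupled":
        E = np.asarray(imposed_erk(0.5 * (x[:-1] + x[1:]), 0.0, p))

    n_steps = int(round(duration / p.dt))
    rec_every = int(round(record_interval / p.dt))
    times, rx, reps, rE, rF = [], [], [], [], []
    t = 0.0
    for step in range(n_steps + 1):
        if step % rec_every == 0 and t >= discard - 1e-9:
            times.append(t)
            rx.append(x.copy())
            reps.append(eps.copy())
            rE.append(E.copy())
            rF.append(F.copy())
        xdot = _velocities(x, eps, F, p, orientation)
        x = x + p.dt * xdot
        d = np.diff(x)
        if strict and np.any(d <= 0):
            raise ChainInstabilityError(t)
        if not np.all(np.isfinite(x)):
            raise ChainInstabilityError(t)
        eps = d / p.L - 1.0
        if p.mode == "coupled":
            E = E + p.dt * (np.tanh(p.alpha * eps) - E) / p.eta_E
        else:
            E = np.asarray(imposed_erk(0.5 * (x[:-1] + x[1:]), t + p.dt, p))
        F = F + p.dt * (p.lam * E - F) / p.eta_F
        t += p.dt

    return Trajectory(
        record_times=np.array(times),
        record_interval=record_interval,
        x=np.array(rx),
        eps=np.array(reps),
        E=np.array(rE),
        F=np.array(rF),
        params=p,
    )


def model_rate_series(
    traj: Trajectory, kind: str = "strain_rate"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (extension-shrinkage rate, ERK activity rate) time series.

    ``kind="strain_rate"`` (default) returns the diagonal strain-rate
    component, the spatial derivative of the junction velocity over the cell:
    ``(v_{j+1}-v_j)/(x_{j+1}-x_j) = d ln(1+eps_j)/dt`` — the same quantity the
    imaging pipeline measures from PIV.  ``kind="eps_rate"`` returns plain
    ``d eps_j/dt``.  Both use central differences on the recorded grid
    (one-sided at the ends); the ERK activity rate is ``dE_j/dt``.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 recorded snapshots")
    h = traj.record_interval
    if kind == "strain_rate":
        ext = np.gradient(np.log1p(np.maximum(traj.eps, -0.999999)), h, axis=0)
    elif kind == "eps_rate":
        ext = np.gradient(traj.eps, h, axis=0)
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    erk = np.gradient(traj.E, h, axis=0)
    return ext, erk


@dataclass
class CrossCorrResult:
    """Normalized cross-correlogram and its peak.

    ``peak_lag < 0`` means the first input series leads (precedes) the second.
    """

    lags: np.ndarray
    corr: np.ndarray
    peak_lag: float
    peak_corr: float


def xcorr_lag(
    a: Sequence[float], b: Sequence[float], max_lag: float, dt: float = 1.0
) -> CrossCorrResult:
    """Peak of the normalized cross-correlation between two series.

    Both series are z-scored; ``corr(l) = (1/n) sum_t a(t+l) b(t)`` (the
    constant-denominator normalization, as in MATLAB's ``xcorr`` with the
    ``coeff`` option), evaluated for lags in ``[-max_lag, +max_lag]``.  If
    ``b`` is a delayed copy of ``a``, the peak lag is negative (a leads).
    Grid ties are broken toward smaller ``|lag|``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D arrays of equal length")
    n = len(a)
    m = int(round(max_lag / dt))
    if m >= n:
        raise ValueError("max_lag must be smaller than the series span")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance series")
    az = (a - a.mean()) / sa
    bz = (b - b.mean()) / sb
    # full linear cross-correlation, then cut the +/- m window
    full = np.correlate(az, bz, mode="full")  # index n-1+l <-> sum_t az[t+l]*bz[t]
    ls = np.arange(-m, m + 1)
    corr = full[n - 1 + ls] / n
    best = np.max(corr)
    candidates = np.flatnonzero(corr >= best - 1e-12)
    i = candidates[np.argmin(np.abs(ls[candidates]))]
    return CrossCorrResult(
        lags=ls * dt, corr=corr, peak_lag=float(ls[i] * dt), peak_corr=float(corr[i])
    )


def rate_lag_analysis(
    traj: Trajectory,
    max_lag: float = 100.0,
    kind: str = "strain_rate",
    smooth_window_min: float = 60.0,
    activity_fraction: float = 0.25,
    edge_cells: int = 20,
    max_cells: int = 64,
) -> dict:
    """Cross-correlation lag between deformation rate and ERK rate, per cell.

    Cells within ``edge_cells`` of either boundary are excluded, as are cells
    whose ERK temporal standard deviation is below ``activity_fraction`` of
    the maximum (quiescent chain regions).  Both rate series are smoothed
    with a centered moving average spanning ``smooth_window_min`` minutes
    (the timescale of the imaging pipeline's span-5 smoothing at 12-min
    frames) before correlation.  Returns per-cell peak lags and their
    median/mean/sd; negative lags mean deformation precedes ERK.
    """
    ext, erk = model_rate_series(traj, kind=kind)
    smooth_span = max(1, int(round(smooth_window_min / traj.record_interval)) | 1)
    sd = traj.E.std(axis=0)
    active = np.flatnonzero(sd > activity_fraction * sd.max())
    active = active[(active >= edge_cells) & (active < traj.eps.shape[1] - edge_cells)]
    if len(active) == 0:
        raise ValueError("no active cells to analyse")
    stride = max(1, len(active) // max_cells)
    cells = active[::stride]
    lags, corrs = [], []
    for j in cells:
        a = _moving_average(ext[:, j], smooth_span)
        b = _moving_average(erk[:, j], smooth_span)
        if a.std() == 0 or b.std() == 0:
            continue
        r = xcorr_lag(a, b, max_lag, dt=traj.record_interval)
        lags.append(r.peak_lag)
        corrs.append(r.peak_corr)
    lags = np.array(lags)
    return {
        "cells": cells[: len(lags)],
        "lags": lags,
        "peak_corrs": np.array(corrs),
        "mean_lag": float(lags.mean()),
        "median_lag": float(np.median(lags)),
        "sd_lag": float(lags.std()),
    }


def _moving_average(y: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average with a window that shrinks near the ends."""
    if span <= 1:
        return np.asarray(y, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    n = len(y)
    h = span // 2
    for i in range(n):
        hh = min(h, i, n - 1 - i)
        out[i] = y[i - hh : i + hh + 1].mean()
    return out
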