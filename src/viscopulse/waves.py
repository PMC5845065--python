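"""Method-of-lines simulation of pressure pulses in viscoelastic tubes.

Space is discretized with second-order centered differences on ``N``
interior nodes (step ``h = L/(N+1)``); the resulting ODE system is
integrated with the adaptive Dormand-Prince 4(5) pair.  A heartbeat-like
raised-cosine pulse enters at ``x = 0`` and the far end is held at zero
pressure; simulations are normally stopped before the pulse reaches the
outlet so that reflections never contaminate the decay measurement.

State layout: Maxwell runs carry ``(p_i, r_i)`` with ``r = dp/dt``
(2N equations); Zener runs carry ``(p_i, r_i, s_i)`` with
``s = d2p/dt2`` (3N equations) because its PDE is third order in time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from viscopulse.constitutive import MaxwellMaterial, ZenerMaterial
from viscopulse.spectral import (
    TubeGeometry,
    wave_speed_maxwell,
    wave_speeds_zener,
)

__all__ = [
    "PulseSpec", "SimulationGrid", "PressureField", "DecayFit",
    "inlet_pulse", "inlet_pulse_rate",
    "simulate_maxwell", "simulate_zener", "measure_decay",
]


@dataclass(frozen=True)
class PulseSpec:
    """Inlet pulse: peak pressure ``p_max`` (Pa) over one period ``T`` (s)."""

    p_max: float
    T: float

    def __post_init__(self):
        if self.p_max <= 0 or self.T <= 0:
            raise ValueError("p_max and T must be positive")


def inlet_pulse(t, pulse: PulseSpec):
    """Raised-cosine heartbeat pulse
    ``f(t) = (p_max/2)(1 - cos(2 pi t / T))`` for ``0 <= t <= T``, zero
    after; continuous at ``t = T``."""
    t = np.asarray(t, dtype=float)
    f = 0.5 * pulse.p_max * (1.0 - np.cos(2.0 * np.pi * t / pulse.T))
    out = np.where(t <= pulse.T, f, 0.0)
    return out if out.ndim else float(out)


def inlet_pulse_rate(t, pulse: PulseSpec):
    """Analytic ``f'(t)``, needed as the inlet condition on ``dp/dt``
    for the third-order (Zener) system."""
    t = np.asarray(t, dtype=float)
    w = 2.0 * np.pi / pulse.T
    df = 0.5 * pulse.p_max * w * np.sin(w * t)
    out = np.where(t <= pulse.T, df, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimulationGrid:
    """Spatial resolution, time horizon and solver tolerances.

    ``N`` interior nodes give space step ``h = L/(N+1)``.  ``t_end``
    defaults to ``0.9 L / c`` (pre-reflection window); ``snapshot_dt``
    is the cadence at which the field is recorded.
    """

    N: int = 512
    t_end: Optional[float] = None
    snapshot_dt: float = 0.15
    rtol: float = 1e-8
    atol: float = 1e-9

    def __post_init__(self):
        if self.N < 10:
            raise ValueError("N must be >= 10")
        if self.snapshot_dt <= 0:
            raise ValueError("snapshot_dt must be positive")


@dataclass(frozen=True)
class PressureField:
    """Space-time pressure solution: ``p[j, i]`` at time ``t[j]``,
    position ``x[i]`` (boundary nodes included)."""

    x: np.ndarray
    t: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        if self.p.shape != (self.t.size, self.x.size):
            raise ValueError("p must have shape (len(t), len(x))")


def _resolve_times(grid: SimulationGrid, L: float, c: float, T: float):
    t_end = grid.t_end if grid.t_end is not None else 0.9 * L / c
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n_snap = int(math.floor(t_end / grid.snapshot_dt + 1e-9))
    t_eval = np.unique(np.concatenate([
        grid.snapshot_dt * np.arange(n_snap + 1), [t_end]]))
    if grid.snapshot_dt > T:
        warnings.warn(
            f"snapshot cadence {grid.snapshot_dt} s under-resolves the "
            f"pulse period {T} s", stacklevel=3)
    return t_end, t_eval


def _assemble_field(geom: TubeGeometry, grid: SimulationGrid,
                    t: np.ndarray, p_int: np.ndarray,
                    pulse: PulseSpec) -> PressureField:
    x = np.linspace(0.0, geom.L, grid.N + 2)
    p = np.zeros((t.size, grid.N + 2))
    p[:, 0] = inlet_pulse(t, pulse)
    p[:, 1:-1] = p_int
    return PressureField(x=x, t=t, p=p)


def simulate_maxwell(material: MaxwellMaterial, geom: TubeGeometry,
                     pulse: PulseSpec,
                     grid: SimulationGrid = SimulationGrid()) -> PressureField:
    """Damped wave equation
    ``p_tt + p_t / tau = c^2 p_xx`` with inlet ``p(0,t) = f(t)``,
    outlet ``p(L,t) = 0`` and a quiescent initial state, via the method
    of lines: ``dp_i/dt = r_i``,
    ``dr_i/dt = c^2 (p_{i+1} - 2 p_i + p_{i-1})/h^2 - r_i / tau``.
    """
    c = wave_speed_maxwell(material, geom).c
    tau = material.tau
    N = grid.N
    h = geom.L / (N + 1)
    c2h2 = c * c / (h * h)
    t_end, t_eval = _resolve_times(grid, geom.L, c, pulse.T)
    inv_tau = 1.0 / tau

    def rhs(ti, y):
        p, r = y[:N], y[N:]
        lap = -2.0 * p
        lap[:-1] += p[1:]
        lap[1:] += p[:-1]
        lap[0] += inlet_pulse(ti, pulse)   # p_0 = f(t); p_{N+1} = 0
        dr = c2h2 * lap - inv_tau * r
        return np.concatenate([r, dr])

    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(2 * N), t_eval=t_eval,
                    method="RK45", rtol=grid.rtol,
                    atol=grid.atol * pulse.p_max)
    if not sol.success:
        raise RuntimeError(f"Maxwell simulation failed: {sol.message}")
    return _assemble_field(geom, grid, sol.t, sol.y[:N].T, pulse)


def simulate_zener(material: ZenerMaterial, geom: TubeGeometry,
                   pulse: PulseSpec,
                   grid: SimulationGrid = SimulationGrid()) -> PressureField:
    """Third-order pressure PDE
    ``c^2 p_txx + (c0^2/tau) p_xx = p_ttt + p_tt / tau`` via the method
    of lines (states ``p_i, r_i = dp_i/dt, s_i = d2p_i/dt2``):

        ds_i/dt = (c0^2 / (tau h^2)) (p_{i+1} - 2 p_i + p_{i-1})
                + ((c0^2+c1^2)/h^2) (r_{i+1} - 2 r_i + r_{i-1}) - s_i / tau

    with boundary values ``p_0 = f(t)``, ``p_{N+1} = 0``,
    ``r_0 = f'(t)`` and the mirrored outlet derivative
    ``r_{N+1} = r_{N-1}``.
    """
    speeds = wave_speeds_zener(material, geom)
    tau = material.tau
    N = grid.N
    h = geom.L / (N + 1)
    a_p = speeds.c0 ** 2 / (tau * h * h)
    a_r = (speeds.c0 ** 2 + speeds.c1 ** 2) / (h * h)
    t_end, t_eval = _resolve_times(grid, geom.L, speeds.c, pulse.T)
    inv_tau = 1.0 / tau

    def rhs(ti, y):
        p, r, s = y[:N], y[N:2 * N], y[2 * N:]
        lap_p = -2.0 * p
        lap_p[:-1] += p[1:]
        lap_p[1:] += p[:-1]
        lap_p[0] += inlet_pulse(ti, pulse)  # p_0 = f(t); p_{N+1} = 0
        lap_r = -2.0 * r
        lap_r[:-1] += r[1:]
        lap_r[1:] += r[:-1]
        lap_r[0] += inlet_pulse_rate(ti, pulse)  # r_0 = f'(t)
        lap_r[-1] += r[N - 2]                    # r_{N+1} = r_{N-1}
        ds = a_p * lap_p + a_r * lap_r - inv_tau * s
        return np.concatenate([r, s, ds])

    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(3 * N), t_eval=t_eval,
                    method="RK45", rtol=grid.rtol,
                    atol=grid.atol * pulse.p_max)
    if not sol.success:
        raise RuntimeError(f"Zener simulation failed: {sol.message}")
    return _assemble_field(geom, grid, sol.t, sol.y[:N].T, pulse)


@dataclass(frozen=True)
class DecayFit:
    """Exponential spatial envelope fitted to travelling-pulse peaks:
    peak pressure ~ exp(-x/d).  ``tau_fit = d/c`` converts the decay
    length to an equivalent time constant.  ``low_confidence`` is set
    when R^2 < 0.9, which happens when no single exponential describes
    the decay (strong mixtures of modal rates)."""

    d: float
    tau_fit: float
    r_squared: float
    n_peaks: int
    low_confidence: bool
    positions: np.ndarray
    amplitudes: np.ndarray


def measure_decay(field: PressureField, c: float, *,
                  pulse_T: Optional[float] = None) -> DecayFit:
    """Fit ``log(peak amplitude)`` against peak position by least squares.

    Per snapshot, the pulse amplitude is the global maximum over
    ``x > 2h`` (excluding the inlet region) and its position the argmax,
    both refined by a parabola through the peak cell and its neighbours
    to remove grid quantization.  Snapshots are used only once the pulse
    has fully entered the tube (``t >= pulse_T`` when given) and while
    its peak is away from the outlet, keeping the fit inside the
    pre-reflection window.
    """
    h = field.x[1] - field.x[0]
    interior = field.x > 2.0 * h
    x_int = field.x[interior]
    xs, amps = [], []
    for j, tj in enumerate(field.t):
        if pulse_T is not None and tj < pulse_T:
            continue
        row = field.p[j, interior]
        i = int(np.argmax(row))
        amp = row[i]
        pos = x_int[i]
        if 0 < i < row.size - 1:
            y0, y1, y2 = row[i - 1], row[i], row[i + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:  # concave: refine peak inside the cell
                delta = 0.5 * (y0 - y2) / denom
                pos += delta * h
                amp = y1 - 0.25 * (y0 - y2) * delta
        if amp <= 0 or pos >= field.x[-1] - 2.0 * h:
            continue
        xs.append(pos)
        amps.append(amp)
    if len(xs) < 3:
        raise ValueError(
            f"need at least 3 usable pulse peaks, found {len(xs)}")
    xs = np.asarray(xs)
    amps = np.asarray(amps)
    slope, intercept = np.polyfit(xs, np.log(amps), 1)
    pred = slope * xs + intercept
    resid = np.log(amps) - pred
    ss_tot = np.sum((np.log(amps) - np.log(amps).mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    if slope >= 0:
        raise ValueError("peak amplitudes do not decay along the tube")
    d = float(-1.0 / slope)
    r2 = float(r2)
    return DecayFit(d=d, tau_fit=d / c, r_squared=r2,
                    n_peaks=int(xs.size), low_confidence=bool(r2 < 0.9),
                    positions=xs, amplitudes=amps)
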