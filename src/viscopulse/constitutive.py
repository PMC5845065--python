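"""Differential viscoelastic material models (Maxwell, Zener).

The Maxwell element is a spring ``E1`` and a dashpot ``eta`` in series,
with relaxation time ``tau = eta / E1``.  Its stress obeys

    d(sigma)/dt = E1 * d(eps)/dt - sigma / tau

The Zener element (standard linear solid) adds a parallel spring ``E0``:

    d(sigma)/dt + sigma / tau = (E0 + E1) * d(eps)/dt + (E0 / tau) * eps

Both are linear first-order ODEs in the stress, driven by an imposed
strain history.  For tabulated strain the piecewise-linear strain model
makes the ODE exactly solvable segment by segment, so responses are
propagated with a closed-form exponential update (exact for that strain
model, and far cheaper than stepping an adaptive solver across the
slope discontinuities of the interpolant).  When an analytic
``strain_rate(t)`` callback is supplied the response is instead
integrated with an adaptive embedded Runge-Kutta pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MaxwellMaterial",
    "ZenerMaterial",
    "StrainHistory",
    "StressHistory",
    "maxwell_stress_response",
    "zener_stress_response",
]

#: relative agreement required between redundantly stored tau and eta/E1
_TAU_CONSISTENCY_RTOL = 1e-12


@dataclass(frozen=True)
class MaxwellMaterial:
    """Maxwell (spring + dashpot in series) material parameters.

    Parameters
    ----------
    E1 : float
        Elastic modulus of the series spring, Pa.
    eta : float, optional
        Viscous factor of the dashpot, Pa*s.  Exactly one of ``eta`` or
        ``tau`` may be omitted; the other is derived from ``tau = eta/E1``.
    tau : float, optional
        Relaxation time, s.
    """

    E1: float
    eta: Optional[float] = None
    tau: Optional[float] = None

    def __post_init__(self):
        if self.E1 <= 0:
            raise ValueError(f"E1 must be positive, got {self.E1}")
        if self.eta is None and self.tau is None:
            raise ValueError("provide at least one of eta or tau")
        if self.eta is None:
            object.__setattr__(self, "eta", self.tau * self.E1)
        if self.tau is None:
            object.__setattr__(self, "tau", self.eta / self.E1)
        if self.eta <= 0 or self.tau <= 0:
            raise ValueError("eta and tau must be positive")
        if not np.isclose(self.tau, self.eta / self.E1,
                          rtol=_TAU_CONSISTENCY_RTOL, atol=0.0):
            raise ValueError(
                f"inconsistent parameters: tau={self.tau} but eta/E1="
                f"{self.eta / self.E1}")


@dataclass(frozen=True)
class ZenerMaterial:
    """Zener / standard-linear-solid parameters.

    ``E0`` is the parallel (equilibrium) spring, Pa; ``E1`` the series
    spring of the Maxwell branch, Pa; ``tau`` the relaxation time, s.
    The viscous factor ``eta = tau * E1`` is derived.  Instantaneous
    modulus is ``E0 + E1``; equilibrium modulus is ``E0``.
    """

    E0: float
    E1: float
    tau: float
    eta: float = field(init=False)

    def __post_init__(self):
        if self.E0 <= 0 or self.E1 <= 0 or self.tau <= 0:
            raise ValueError(
                f"E0, E1, tau must be positive, got "
                f"({self.E0}, {self.E1}, {self.tau})")
        object.__setattr__(self, "eta", self.tau * self.E1)

    def maxwell_branch(self) -> MaxwellMaterial:
        """The series branch as a stand-alone Maxwell element."""
        return MaxwellMaterial(E1=self.E1, tau=self.tau)


@dataclass(frozen=True)
class StrainHistory:
    """Tabulated strain record eps(t) on a strictly increasing time grid."""

    t: np.ndarray
    eps: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        eps = np.asarray(self.eps, dtype=float)
        if t.ndim != 1 or eps.ndim != 1 or t.size != eps.size:
            raise ValueError("t and eps must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a strain history needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "eps", eps)

    def interpolator(self) -> Callable[[float], float]:
        """Piecewise-linear eps(t) clamped at the record ends."""
        t, eps = self.t, self.eps

        def f(ti):
            return np.interp(ti, t, eps)

        return f

    def slope(self) -> Callable[[float], float]:
        """Piecewise-constant d(eps)/dt with exact per-segment slopes."""
        t, eps = self.t, self.eps
        slopes = np.diff(eps) / np.diff(t)

        def df(ti):
            idx = np.clip(np.searchsorted(t, ti, side="right") - 1,
                          0, slopes.size - 1)
            return slopes[idx]

        return df


@dataclass(frozen=True)
class StressHistory:
    """Stress record sigma(t), aligned with the driving strain grid."""

    t: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if t.shape != sigma.shape or t.ndim != 1:
            raise ValueError("t and sigma must be 1-D arrays of equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "sigma", sigma)


def _integrate_stress(rhs, t: np.ndarray, sigma0: float,
                      rtol: float, atol: float) -> StressHistory:
    sol = solve_ivp(rhs, (t[0], t[-1]), [float(sigma0)], t_eval=t,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"stress-response integration failed: {sol.message} "
            f"(nfev={sol.nfev}, status={sol.status})")
    return StressHistory(t=t, sigma=sol.y[0])


def _propagate_linear_forcing(t: np.ndarray, a: np.ndarray, b: np.ndarray,
                              tau: float, sigma0: float) -> np.ndarray:
    """Exact solution of ``d(sigma)/dt = A(t) - sigma/tau`` where the
    forcing is ``A = a_i + b_i (t - t_i)`` on each segment.

    Per segment of width ``dt`` with ``E = exp(-dt/tau)``:

        sigma_{i+1} = sigma_i E + a_i tau (1 - E)
                      + b_i (tau dt - tau^2 (1 - E))
    """
    dt = np.diff(t)
    decay = np.exp(-dt / tau)
    drive = a * tau * (1.0 - decay) + b * (tau * dt - tau * tau * (1.0 - decay))
    sigma = np.empty(t.size)
    sigma[0] = sigma0
    s = sigma0
    for i in range(dt.size):
        s = s * decay[i] + drive[i]
        sigma[i + 1] = s
    return sigma


def maxwell_stress_response(
    material: MaxwellMaterial,
    strain: StrainHistory,
    sigma0: float = 0.0,
    *,
    strain_rate: Optional[Callable] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> StressHistory:
    """Stress of a Maxwell element under an imposed strain history.

    Solves ``d(sigma)/dt = E1 * d(eps)/dt - sigma/tau`` from
    ``sigma(t0) = sigma0``.  Tabulated strain is treated as exactly
    piecewise linear and propagated with the closed-form per-segment
    update; an analytic ``strain_rate(t)`` callback switches to the
    adaptive Runge-Kutta path.
    """
    E1, tau = material.E1, material.tau
    if strain_rate is None:
        slopes = np.diff(strain.eps) / np.diff(strain.t)
        sigma = _propagate_linear_forcing(
            strain.t, E1 * slopes, np.zeros_like(slopes), tau, sigma0)
        return StressHistory(t=strain.t, sigma=sigma)

    def rhs(ti, y):
        return [E1 * strain_rate(ti) - y[0] / tau]

    return _integrate_stress(rhs, strain.t, sigma0, rtol, atol)


def zener_stress_response(
    material: ZenerMaterial,
    strain: StrainHistory,
    sigma0: float = 0.0,
    *,
    strain_rate: Optional[Callable] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> StressHistory:
    """Stress of a Zener element under an imposed strain history.

    Solves
    ``d(sigma)/dt = (E0+E1) * d(eps)/dt + (E0/tau) * eps - sigma/tau``
    from ``sigma(t0) = sigma0``, with the same tabulated-vs-analytic
    strain handling as :func:`maxwell_stress_response`.
    """
    E0, E1, tau = material.E0, material.E1, material.tau
    if strain_rate is None:
        slopes = np.diff(strain.eps) / np.diff(strain.t)
        a = (E0 + E1) * slopes + (E0 / tau) * strain.eps[:-1]
        b = (E0 / tau) * slopes
        sigma = _propagate_linear_forcing(strain.t, a, b, tau, sigma0)
        return StressHistory(t=strain.t, sigma=sigma)

    eps_f = strain.interpolator()

    def rhs(ti, y):
        return [(E0 + E1) * strain_rate(ti) + (E0 / tau) * eps_f(ti)
                - y[0] / tau]

    return _integrate_stress(rhs, strain.t, sigma0, rtol, atol)
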