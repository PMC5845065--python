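"""Analytic decay-rate machinery for pressure pulses in viscoelastic tubes.

A pressure pulse in a fluid-filled thin-walled tube propagates at a
Moens-Korteweg-type speed ``c^2 = e*E/(2*rho*r)`` set by the wall
modulus ``E``, thickness ``e``, inner radius ``r`` and fluid density
``rho``.  With a Maxwell wall the pressure obeys a damped wave
equation; with a Zener wall a third-order (Moore-Gibson-Thompson-type)
PDE.  Expanding in spatial Fourier modes ``sin(n*pi*x/L)`` with
eigenvalues ``lambda_n = (n*pi/L)^2`` turns each mode into a small
constant-coefficient ODE whose characteristic roots give the modal
decay rates computed here, together with the essential spectrum
(the ``n -> inf`` limiting rate), single-exponential equivalent time
constants, and attenuation / required-length formulae built on them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from viscopulse.constitutive import MaxwellMaterial, ZenerMaterial

__all__ = [
    "TubeGeometry", "WaveSpeeds", "Mode", "DecaySpectrum",
    "AttenuationPrediction",
    "wave_speed_maxwell", "wave_speeds_zener",
    "maxwell_spectrum", "maxwell_tau_eq",
    "zener_mode_roots", "zener_decay_constant",
    "zener_essential_spectrum", "zener_tau_eq", "zener_spectrum",
    "validity_condition", "attenuation", "required_length",
]

#: square of tau*c (in m^2) above which a single-exponential envelope
#: based on the essential spectrum is considered trustworthy
VALIDITY_THRESHOLD_M2 = 1.0

#: relative window for classifying a discriminant as exactly critical
_CRITICAL_RTOL = 1e-12

#: required relative agreement between Cardano and companion-matrix roots
_ROOT_XCHECK_RTOL = 1e-9


@dataclass(frozen=True)
class TubeGeometry:
    """Thin-walled tube: inner radius ``r``, wall thickness ``e``,
    length ``L`` (all m) and fluid density ``rho`` (kg/m^3)."""

    r: float
    e: float
    L: float
    rho: float

    def __post_init__(self):
        for name in ("r", "e", "L", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got "
                                 f"{getattr(self, name)}")
        ratio = self.e / (2.0 * self.r)
        if ratio > 0.25:
            raise ValueError(
                f"thickness-to-diameter ratio {ratio:.3f} outside the "
                "thin-wall regime (limit 0.25)")
        if ratio > 0.2:
            warnings.warn(
                f"thickness-to-diameter ratio {ratio:.3f} > 0.2: "
                "thin-wall pressure/stress relation becoming inaccurate",
                stacklevel=2)

    def lambda_n(self, n: int) -> float:
        """Spatial eigenvalue (n*pi/L)^2, 1/m^2."""
        return (n * math.pi / self.L) ** 2


@dataclass(frozen=True)
class WaveSpeeds:
    """Pulse speeds, m/s.  For a Zener wall ``c^2 = c0^2 + c1^2`` with
    ``c0`` from the equilibrium spring and ``c1`` from the Maxwell
    branch; for a Maxwell wall ``c0`` is absent and ``c = c1``."""

    c: float
    c1: float
    c0: Optional[float] = None


def wave_speed_maxwell(material: MaxwellMaterial,
                       geom: TubeGeometry) -> WaveSpeeds:
    """Pulse speed ``c = sqrt(e*E1/(2*rho*r))`` for a Maxwell wall."""
    c = math.sqrt(geom.e * material.E1 / (2.0 * geom.rho * geom.r))
    return WaveSpeeds(c=c, c1=c, c0=None)


def wave_speeds_zener(material: ZenerMaterial,
                      geom: TubeGeometry) -> WaveSpeeds:
    """Branch speeds ``c0, c1`` and pulse speed ``c = sqrt(c0^2+c1^2)``."""
    scale = geom.e / (2.0 * geom.rho * geom.r)
    c0 = math.sqrt(scale * material.E0)
    c1 = math.sqrt(scale * material.E1)
    return WaveSpeeds(c=math.hypot(c0, c1), c1=c1, c0=c0)


@dataclass(frozen=True)
class Mode:
    """Temporal characteristic roots of one spatial Fourier mode.

    ``rates`` are the decay exponents (1/s): the pair ``mu_1n, mu_2n``
    for Maxwell (solutions grow like exp(mu*t), mu <= 0) or the three
    Zener roots ``1/tau_{n,k}`` (solutions decay like exp(-t/tau_n),
    Re >= 0).  ``omega_n`` is the modal angular frequency when the mode
    oscillates.
    """

    n: int
    lambda_n: float
    rates: Tuple[complex, ...]
    regime: str  # "underdamped" | "critical" | "overdamped"
    omega_n: Optional[float] = None


@dataclass(frozen=True)
class DecaySpectrum:
    """Per-mode decay rates plus the summary constants of the model."""

    model: str  # "maxwell" | "zener"
    modes: List[Mode]
    tau_eq: float
    k_critical: Optional[int] = None     # Maxwell: largest overdamped index
    tau_inf: Optional[float] = None      # Zener: essential-spectrum time
    validity_m2: Optional[float] = None  # Zener: tau^2 * c^2
    validity: Optional[bool] = None      # Zener: tau^2 * c^2 >= 1 m^2


# ----------------------------------------------------------------- Maxwell

def maxwell_spectrum(material: MaxwellMaterial, geom: TubeGeometry,
                     n_max: int = 200) -> DecaySpectrum:
    """Modal decay rates of the damped wave equation (Maxwell wall).

    Each mode has discriminant ``Delta_n = 1/(4 tau^2) - lambda_n c^2``.
    Underdamped modes (``Delta_n < 0``) decay at ``-1/(2 tau)`` while
    oscillating at ``omega_n = sqrt(-Delta_n)``; overdamped modes
    (``Delta_n > 0``) have the real pair
    ``mu_{1n,2n} = -1/(2 tau) +/- sqrt(Delta_n)``, both negative, the
    slower of which (``mu_11`` for n=1) controls the overdamped tail.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    c = wave_speed_maxwell(material, geom).c
    tau = material.tau
    half_rate = 1.0 / (2.0 * tau)
    modes = []
    for n in range(1, n_max + 1):
        lam = geom.lambda_n(n)
        delta = half_rate ** 2 - lam * c * c
        if abs(delta) < _CRITICAL_RTOL * half_rate ** 2:
            modes.append(Mode(n=n, lambda_n=lam,
                              rates=(complex(-half_rate), complex(-half_rate)),
                              regime="critical"))
        elif delta > 0:
            root = math.sqrt(delta)
            modes.append(Mode(n=n, lambda_n=lam,
                              rates=(complex(-half_rate + root),
                                     complex(-half_rate - root)),
                              regime="overdamped"))
        else:
            omega = math.sqrt(-delta)
            modes.append(Mode(n=n, lambda_n=lam,
                              rates=(complex(-half_rate, omega),
                                     complex(-half_rate, -omega)),
                              regime="underdamped", omega_n=omega))
    k_critical = math.floor(geom.L / (2.0 * c * math.pi * tau))
    return DecaySpectrum(model="maxwell", modes=modes,
                         tau_eq=maxwell_tau_eq(material, geom),
                         k_critical=k_critical)


def maxwell_tau_eq(material: MaxwellMaterial, geom: TubeGeometry) -> float:
    """Equivalent envelope time constant for a Maxwell wall.

    ``2 tau`` when every mode is underdamped
    (``4 tau^2 pi^2 c^2 / L^2 >= 1``); otherwise the slower overdamped
    n=1 rate dominates and
    ``tau_eq = 2 tau / (1 - sqrt(1 - 4 tau^2 pi^2 c^2 / L^2)) > 2 tau``
    (identically ``-1/mu_11``).
    """
    c = wave_speed_maxwell(material, geom).c
    tau = material.tau
    q = 4.0 * tau * tau * math.pi ** 2 * c * c / geom.L ** 2
    if q >= 1.0:
        return 2.0 * tau
    return 2.0 * tau / (1.0 - math.sqrt(1.0 - q))


# ------------------------------------------------------------------- Zener

def _cardano_roots(tau: float, lam: float, c0sq: float,
                   c1sq: float) -> Tuple[complex, complex, complex]:
    """Roots of ``x^3 - x^2/tau + lam*(c0^2+c1^2)*x - lam*c0^2/tau = 0``
    in closed form.

    In reduced variables ``R = (9/2) tau^2 lam (2 c0^2 - c1^2) + 1`` and
    ``Q = 3 tau^2 lam (c0^2 + c1^2) - 1`` the roots are
    ``1/(3 tau) + S1 + S2`` and the conjugate pair
    ``1/(3 tau) - (S1+S2)/2 +/- i sqrt(3)(S2-S1)/2`` with
    ``S_{1,2} = cbrt(R +/- sqrt(R^2+Q^3))/(3 tau)``.  When
    ``R^2 + Q^3 < 0`` (casus irreducibilis: three real roots) the
    literal surds need complex cube roots and cancel catastrophically,
    so the trigonometric three-real-root form is used instead.
    """
    R = 4.5 * tau * tau * lam * (2.0 * c0sq - c1sq) + 1.0
    Q = 3.0 * tau * tau * lam * (c0sq + c1sq) - 1.0
    disc = R * R + Q ** 3
    shift = 1.0 / (3.0 * tau)
    if disc >= 0.0:
        sq = math.sqrt(disc)
        S1 = shift * math.copysign(abs(R + sq) ** (1.0 / 3.0), R + sq)
        S2 = shift * math.copysign(abs(R - sq) ** (1.0 / 3.0), R - sq)
        s, d = S1 + S2, S2 - S1
        return (complex(shift + s),
                complex(shift - 0.5 * s, 0.5 * math.sqrt(3.0) * d),
                complex(shift - 0.5 * s, -0.5 * math.sqrt(3.0) * d))
    # three real roots: t_k = 2 sqrt(-p/3) cos(theta/3 - 2 pi k/3) with the
    # depressed-cubic p = Q/(3 tau^2), cos(theta) = R / (-Q)^{3/2}
    p = Q / (3.0 * tau * tau)
    m = 2.0 * math.sqrt(-p / 3.0)
    theta = math.acos(max(-1.0, min(1.0, R / (-Q) ** 1.5)))
    return tuple(complex(shift + m * math.cos((theta - 2.0 * math.pi * k) / 3.0))
                 for k in range(3))


def zener_mode_roots(material: ZenerMaterial, geom: TubeGeometry,
                     n: int) -> Tuple[complex, complex, complex]:
    """Three characteristic roots ``1/tau_{n,k}`` of mode ``n``.

    Computed in closed (Cardano / trigonometric) form and cross-checked
    against a companion-matrix eigenvalue solve of the same cubic; any
    disagreement beyond 1e-9 relative raises, since the closed form is
    cancellation-prone precisely where the slowest rates live.
    """
    if n < 1:
        raise ValueError("mode index n must be >= 1")
    speeds = wave_speeds_zener(material, geom)
    tau = material.tau
    lam = geom.lambda_n(n)
    c0sq, c1sq = speeds.c0 ** 2, speeds.c1 ** 2
    roots = _cardano_roots(tau, lam, c0sq, c1sq)

    numeric = np.roots([1.0, -1.0 / tau, lam * (c0sq + c1sq),
                        -lam * c0sq / tau])
    scale = max(abs(z) for z in roots)
    closed = sorted(roots, key=lambda z: (z.real, z.imag))
    num = sorted((complex(z) for z in numeric), key=lambda z: (z.real, z.imag))
    err = max(abs(a - b) for a, b in zip(closed, num)) / scale
    if err > _ROOT_XCHECK_RTOL:
        raise ArithmeticError(
            f"closed-form and companion-matrix roots disagree "
            f"(relative error {err:.3e}) for n={n}, tau={tau}")
    if any(z.real < -_ROOT_XCHECK_RTOL * scale for z in roots):
        raise ArithmeticError(f"negative-real-part root found: {roots}")
    return roots


def zener_decay_constant(material: ZenerMaterial, geom: TubeGeometry,
                         n: int) -> float:
    """Modal decay time ``tau_n = 1 / min(Re(1/tau_{n,k}))``: the
    slowest-decaying component controls the mode envelope."""
    roots = zener_mode_roots(material, geom, n)
    return 1.0 / min(z.real for z in roots)


def zener_essential_spectrum(material: ZenerMaterial) -> float:
    """Essential-spectrum decay time ``tau_inf``: the ``n -> inf`` limit
    of the modal decay times,

        1/tau_inf = min( (1/tau) E0/(E0+E1), (1/(2 tau)) E1/(E0+E1) ).

    Sharp pulses, dominated by high modes, decay at this rate.
    """
    E0, E1, tau = material.E0, material.E1, material.tau
    inv = min(E0 / (E0 + E1) / tau, 0.5 * E1 / (E0 + E1) / tau)
    return 1.0 / inv


def zener_tau_eq(material: ZenerMaterial) -> float:
    """Equivalent envelope time constant for a Zener wall,

        tau_eq = max( tau (E0+E1)/E0, 2 tau (E0+E1)/E1 ),

    identically the essential-spectrum time ``tau_inf`` (the same
    min/max pair seen from the time side).
    """
    E0, E1, tau = material.E0, material.E1, material.tau
    tau_eq = max(tau * (E0 + E1) / E0, 2.0 * tau * (E0 + E1) / E1)
    tau_inf = zener_essential_spectrum(material)
    assert math.isclose(tau_eq, tau_inf, rel_tol=1e-12)
    return tau_eq


def validity_condition(material: ZenerMaterial,
                       geom: TubeGeometry) -> Tuple[float, bool]:
    """``tau^2 c^2`` in m^2 and whether it clears the 1 m^2 threshold.

    The single-exponential envelope built on ``tau_eq`` is only a good
    model of the pulse decay when ``tau^2 c^2 >= 1 m^2``; below that,
    modal decay times spread out and the envelope is a weighted mixture
    bracketed by ``tau_1`` and ``tau_inf``.
    """
    c = wave_speeds_zener(material, geom).c
    value = (material.tau * c) ** 2
    return value, value >= VALIDITY_THRESHOLD_M2


def zener_spectrum(material: ZenerMaterial, geom: TubeGeometry,
                   n_max: int = 200) -> DecaySpectrum:
    """Modal root triples for ``n = 1..n_max`` plus summary constants."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    modes = []
    for n in range(1, n_max + 1):
        roots = zener_mode_roots(material, geom, n)
        imag = [z for z in roots if abs(z.imag) > 0]
        regime = "underdamped" if imag else "overdamped"
        omega = abs(imag[0].imag) if imag else None
        modes.append(Mode(n=n, lambda_n=geom.lambda_n(n), rates=roots,
                          regime=regime, omega_n=omega))
    value, ok = validity_condition(material, geom)
    return DecaySpectrum(model="zener", modes=modes,
                         tau_eq=zener_tau_eq(material),
                         tau_inf=zener_essential_spectrum(material),
                         validity_m2=value, validity=ok)


# ------------------------------------------------------------- attenuation

@dataclass(frozen=True)
class AttenuationPrediction:
    """Fractional peak-pressure loss over a tube length.

    ``a = 1 - p_OUT/p_IN`` with ``p_OUT/p_IN = exp(-L/(c tau_eq))``.
    """

    a: float
    p_ratio: float
    L: float
    c: float
    tau_eq: float


def attenuation(tau_eq: float, c: float, L: float) -> AttenuationPrediction:
    """Attenuation of the envelope ``exp(-x/(c tau_eq))`` over length L."""
    if tau_eq <= 0 or c <= 0 or L < 0:
        raise ValueError("tau_eq and c must be positive, L non-negative")
    ratio = math.exp(-L / (c * tau_eq))
    return AttenuationPrediction(a=1.0 - ratio, p_ratio=ratio, L=L, c=c,
                                 tau_eq=tau_eq)


def required_length(tau_eq: float, c: float, a: float) -> float:
    """Tube length achieving attenuation ``a``:
    ``L = c tau_eq ln(1/(1-a))`` (exact inverse of :func:`attenuation`)."""
    if not 0.0 < a < 1.0:
        raise ValueError(f"target attenuation must be in (0, 1), got {a}")
    if tau_eq <= 0 or c <= 0:
        raise ValueError("tau_eq and c must be positive")
    return c * tau_eq * math.log(1.0 / (1.0 - a))
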