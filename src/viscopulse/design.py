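"""Inverse design of Zener material properties for a target attenuation.

For every modulus pair (E0, E1) on a grid there is exactly one
relaxation time tau for which the envelope attenuation over a device of
length L equals the target: with kappa = tau_eq / tau fixed by the
moduli ratio, tau = L / (c * kappa * ln(1/(1-a))).  The pair is
*feasible* only if the resulting tau satisfies tau^2 c^2 >= 1 m^2 —
otherwise the single-exponential envelope the design relies on does not
describe the pulse decay and the target cannot be certified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from viscopulse.constitutive import ZenerMaterial
from viscopulse.spectral import (
    VALIDITY_THRESHOLD_M2,
    TubeGeometry,
    attenuation,
    wave_speeds_zener,
)

__all__ = ["DesignQuery", "DesignMap", "required_tau", "build_design_map",
           "tau_eq_ratio"]


def tau_eq_ratio(E0: float, E1: float) -> float:
    """kappa = tau_eq / tau from the moduli alone:
    ``2 (E0+E1)/E1`` when E1 < 2 E0, else ``(E0+E1)/E0`` (continuous at
    the branch boundary E1 = 2 E0, where both equal 3)."""
    if E0 <= 0 or E1 <= 0:
        raise ValueError("moduli must be positive")
    if E1 < 2.0 * E0:
        return 2.0 * (E0 + E1) / E1
    return (E0 + E1) / E0


def required_tau(E0: float, E1: float, geom: TubeGeometry, a: float,
                 L_device: float) -> float:
    """Relaxation time achieving attenuation ``a`` over ``L_device``
    for a tube with Zener moduli (E0, E1):
    ``tau = L / (c * kappa * ln(1/(1-a)))``."""
    if not 0.0 < a < 1.0:
        raise ValueError(f"target attenuation must be in (0, 1), got {a}")
    if L_device <= 0:
        raise ValueError("L_device must be positive")
    # speeds depend only on moduli and geometry, not on tau
    c = wave_speeds_zener(ZenerMaterial(E0=E0, E1=E1, tau=1.0), geom).c
    kappa = tau_eq_ratio(E0, E1)
    tau = L_device / (c * kappa * math.log(1.0 / (1.0 - a)))
    assert abs(attenuation(kappa * tau, c, L_device).a - a) < 1e-10
    return tau


@dataclass(frozen=True)
class DesignQuery:
    """Design-map request: geometry, target attenuation fraction ``a``,
    device length and the (E0, E1) grid to scan.  Default grid:
    100 x 100 log-spaced over 0.01-10 MPa."""

    geom: TubeGeometry
    a: float
    L_device: float
    E0_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(4, 7, 100))
    E1_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(4, 7, 100))

    def __post_init__(self):
        if not 0.0 < self.a < 1.0:
            raise ValueError("a must be in (0, 1)")
        if self.L_device <= 0:
            raise ValueError("L_device must be positive")
        for name in ("E0_grid", "E1_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.ndim != 1 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be positive and sorted")
            object.__setattr__(self, name, g)


@dataclass(frozen=True)
class DesignMap:
    """Required tau and feasibility over the (E0, E1) grid.

    ``tau_required[i, j]`` corresponds to ``E0_grid[i], E1_grid[j]``;
    ``validity_m2`` holds tau^2 c^2 and ``feasible`` its comparison
    against the 1 m^2 threshold.
    """

    E0_grid: np.ndarray
    E1_grid: np.ndarray
    tau_required: np.ndarray
    validity_m2: np.ndarray
    feasible: np.ndarray
    query: Optional[DesignQuery] = None

    @property
    def any_feasible(self) -> bool:
        return bool(self.feasible.any())


def build_design_map(query: DesignQuery) -> DesignMap:
    """Evaluate :func:`required_tau` and the validity product on the
    full grid (vectorized closed forms)."""
    geom = query.geom
    E0, E1 = np.meshgrid(query.E0_grid, query.E1_grid, indexing="ij")
    scale = geom.e / (2.0 * geom.rho * geom.r)
    c = np.sqrt(scale * (E0 + E1))
    kappa = np.where(E1 < 2.0 * E0, 2.0 * (E0 + E1) / E1, (E0 + E1) / E0)
    tau = query.L_device / (c * kappa * math.log(1.0 / (1.0 - query.a)))
    validity = (tau * c) ** 2
    feasible = np.isfinite(tau) & (validity >= VALIDITY_THRESHOLD_M2)
    return DesignMap(E0_grid=query.E0_grid, E1_grid=query.E1_grid,
                     tau_required=tau, validity_m2=validity,
                     feasible=feasible, query=query)
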