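"""Constitutive parameter identification from cyclic stress/strain tests.

The misfit between an experimental record and a simulated stress
response is the mean orthogonal (point-to-curve) distance in the
stress/strain plane, with both axes z-scored by the experimental
record's mean and standard deviation so that Pa and dimensionless
strain become commensurable.  The misfit is minimized over
log-transformed parameters with the Nelder-Mead simplex, restarted from
seeded jittered initial points.

A synthetic generator emulates a uniaxial cyclic test: sinusoidal
strain (default 1 Hz, 7% amplitude) driving a Maxwell or Zener stress
response, with optional Gaussian stress noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from viscopulse.constitutive import (
    MaxwellMaterial,
    ZenerMaterial,
    StrainHistory,
    StressHistory,
    maxwell_stress_response,
    zener_stress_response,
)

__all__ = [
    "StressStrainRecord", "FitResult",
    "orthogonal_error", "fit_material", "generate_synthetic_record",
]


@dataclass(frozen=True)
class StressStrainRecord:
    """Aligned time / strain / stress samples from a cyclic test,
    with the generating protocol (frequency, amplitude, offset, noise,
    seed) kept as metadata."""

    t: np.ndarray
    eps: np.ndarray
    sigma: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        eps = np.asarray(self.eps, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not (t.shape == eps.shape == sigma.shape) or t.ndim != 1:
            raise ValueError("t, eps, sigma must be 1-D of equal length")
        if t.size < 2:
            raise ValueError("record needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "sigma", sigma)

    @property
    def strain(self) -> StrainHistory:
        return StrainHistory(t=self.t, eps=self.eps)


@dataclass(frozen=True)
class FitResult:
    """Best constitutive parameters for a record.

    ``error`` is the mean orthogonal distance in normalized
    stress/strain units; ``restart_errors`` records every restart so
    the spread is visible.
    """

    model: str
    params: Dict[str, float]
    error: float
    iterations: int
    converged: bool
    restart_errors: Sequence[float]

    def material(self) -> Union[MaxwellMaterial, ZenerMaterial]:
        if self.model == "maxwell":
            return MaxwellMaterial(E1=self.params["E1"],
                                   tau=self.params["tau"])
        return ZenerMaterial(E0=self.params["E0"], E1=self.params["E1"],
                             tau=self.params["tau"])


def _point_polyline_distances(points: np.ndarray,
                              verts: np.ndarray) -> np.ndarray:
    """Min distance from each point to a piecewise-linear curve.

    points: (M, 2); verts: (K, 2) polyline vertices.  Each point is
    projected onto every segment (clamped to the segment) and the
    minimum distance taken.  Vectorized; M*K memory.
    """
    a = verts[:-1]                       # (K-1, 2)
    d = verts[1:] - a                    # segment vectors
    len2 = np.einsum("ij,ij->i", d, d)
    len2[len2 == 0.0] = 1.0              # degenerate segment -> endpoint
    w = points[:, None, :] - a[None, :, :]          # (M, K-1, 2)
    s = np.clip(np.einsum("mkj,kj->mk", w, d) / len2, 0.0, 1.0)
    proj = a[None, :, :] + s[..., None] * d[None, :, :]
    dist2 = np.sum((points[:, None, :] - proj) ** 2, axis=-1)
    return np.sqrt(dist2.min(axis=1))


def orthogonal_error(experimental: StressStrainRecord,
                     simulated: StressHistory) -> float:
    """Mean orthogonal distance from each experimental stress/strain
    point to the simulated stress/strain curve.

    Both curves are mapped to the (strain, stress) plane; each axis is
    z-scored by the *experimental* mean and standard deviation so the
    metric is scale-free.  The simulated curve (same time grid, strain
    axis shared with the record) is treated as a piecewise-linear
    polyline and each experimental point projected onto it.
    """
    if experimental.t.size == 0:
        raise ValueError("empty record")
    if simulated.t[0] > experimental.t[0] or simulated.t[-1] < experimental.t[-1]:
        raise ValueError("simulated curve does not cover the record's span")
    mu_e, sd_e = experimental.eps.mean(), experimental.eps.std()
    mu_s, sd_s = experimental.sigma.mean(), experimental.sigma.std()
    if sd_e == 0 or sd_s == 0:
        raise ValueError("degenerate record: zero variance on an axis")
    pts = np.column_stack([(experimental.eps - mu_e) / sd_e,
                           (experimental.sigma - mu_s) / sd_s])
    sim_eps = np.interp(simulated.t, experimental.t, experimental.eps)
    verts = np.column_stack([(sim_eps - mu_e) / sd_e,
                             (simulated.sigma - mu_s) / sd_s])
    return float(_point_polyline_distances(pts, verts).mean())


def _response(model: str, params: np.ndarray, strain: StrainHistory,
              sigma0: float) -> StressHistory:
    if model == "maxwell":
        mat = MaxwellMaterial(E1=params[0], tau=params[1])
        return maxwell_stress_response(mat, strain, sigma0)
    mat = ZenerMaterial(E0=params[0], E1=params[1], tau=params[2])
    return zener_stress_response(mat, strain, sigma0)


def _default_init(model: str, record: StressStrainRecord) -> np.ndarray:
    # modulus scale from the data; tau scale from the record span
    scale = record.sigma.std() / max(record.eps.std(), 1e-12)
    tau0 = (record.t[-1] - record.t[0]) / 10.0
    if model == "maxwell":
        return np.array([scale, tau0])
    return np.array([scale, scale, tau0])


def fit_material(record: StressStrainRecord, model: str,
                 init: Optional[Sequence[float]] = None,
                 restarts: int = 5, seed: int = 0, *,
                 maxiter: int = 2000, fatol: float = 1e-8) -> FitResult:
    """Recover constitutive parameters by Nelder-Mead.

    Parameters are log-transformed (positivity without constraints);
    restart 0 starts at ``init`` (Maxwell: ``(E1, tau)``; Zener:
    ``(E0, E1, tau)``), further restarts jitter each parameter by a
    seeded uniform factor in [0.5, 1.5].  The best restart wins;
    results are deterministic for a given seed.
    """
    if model not in ("maxwell", "zener"):
        raise ValueError(f"unknown model {model!r}")
    x0 = np.asarray(init, dtype=float) if init is not None \
        else _default_init(model, record)
    if np.any(x0 <= 0):
        raise ValueError("initial parameters must be strictly positive")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    strain = record.strain
    sigma0 = float(record.sigma[0])

    def objective(log_theta):
        theta = np.exp(log_theta)
        try:
            sim = _response(model, theta, strain, sigma0)
        except (ValueError, RuntimeError):
            return 1e6
        return orthogonal_error(record, sim)

    rng = np.random.default_rng(seed)
    best = None
    errors = []
    for k in range(restarts):
        start = x0 if k == 0 else x0 * rng.uniform(0.5, 1.5, size=x0.size)
        res = minimize(objective, np.log(start), method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": fatol,
                                "xatol": 1e-8})
        errors.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all {restarts} restarts failed: {errors}")
    theta = np.exp(best.x)
    names = ("E1", "tau") if model == "maxwell" else ("E0", "E1", "tau")
    return FitResult(model=model, params=dict(zip(names, map(float, theta))),
                     error=float(best.fun), iterations=int(best.nit),
                     converged=bool(best.success), restart_errors=errors)


def generate_synthetic_record(
    material: Union[MaxwellMaterial, ZenerMaterial],
    frequency: float = 1.0,
    amplitude: float = 0.035,
    offset: float = 0.035,
    duration: float = 6.0,
    sample_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StressStrainRecord:
    """Synthetic cyclic uniaxial test record.

    Strain is ``eps(t) = offset + amplitude * sin(2 pi f t)``.  The
    defaults emulate a gripped uniaxial tensile test cycling between 0
    and 7% strain at 1 Hz (offset = amplitude = 0.035), 6 s at 100 Hz
    sampling.  The nonzero mean strain matters: a zero-mean sinusoid at
    a single frequency only exposes the storage and loss moduli, leaving
    a one-parameter family of Zener models indistinguishable, whereas a
    nonzero mean makes the equilibrium modulus E0 directly observable.
    Stress comes from the constitutive response with the exact analytic
    strain rate; ``noise_sd`` adds seeded Gaussian noise expressed as a
    fraction of the noiseless stress standard deviation.
    """
    if amplitude + abs(offset) > 0.2:
        raise ValueError("amplitude + |offset| must stay <= 0.2 "
                         "(small-strain regime)")
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    w = 2.0 * math.pi * frequency
    eps = offset + amplitude * np.sin(w * t)
    strain = StrainHistory(t=t, eps=eps)

    def deps(ti):
        return amplitude * w * np.cos(w * ti)

    if isinstance(material, ZenerMaterial):
        sigma = zener_stress_response(material, strain,
                                      strain_rate=deps).sigma
        kind = "zener"
    else:
        sigma = maxwell_stress_response(material, strain,
                                        strain_rate=deps).sigma
        kind = "maxwell"
    sigma = sigma.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma += rng.normal(0.0, noise_sd * sigma.std(), size=sigma.size)
    meta = {"model": kind, "frequency_Hz": frequency,
            "amplitude": amplitude, "offset": offset,
            "duration_s": duration, "sample_rate_Hz": sample_rate,
            "noise_sd": noise_sd, "seed": seed}
    return StressStrainRecord(t=t, eps=eps, sigma=sigma, meta=meta)
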