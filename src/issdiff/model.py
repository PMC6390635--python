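"""Closed-form solutions of the anisotropic diffusion-clearance equation.

The model describes a tracer released into the brain interstitial space (ISS)
and transported by diffusion with axis-aligned effective coefficients
``Dx, Dy, Dz`` while being removed by first-order clearance at rate ``k``:

    dC/dt = Dx d2C/dx2 + Dy d2C/dy2 + Dz d2C/dz2 - k C + Q / alpha

``alpha`` is the ISS volume fraction (V_ISS / V_tissue); a source released
into the ISS is confined to that fraction of the tissue volume, hence the
``Q / alpha`` scaling.  For an instantaneous point source of mass ``M`` the
free-space solution is an anisotropic Gaussian with exponential decay:

    C(x, y, z, t) = M / (8 alpha (pi t)^{3/2} sqrt(Dx Dy Dz))
                    * exp(-x^2/(4 Dx t) - y^2/(4 Dy t) - z^2/(4 Dz t))
                    * exp(-k t)

A continuous infusion is the Duhamel superposition of instantaneous releases
at mass rate ``C0 * q`` over the active-infusion window.

Units convention (used throughout the package, no implicit conversion):
lengths mm, time s, diffusion mm^2/s, clearance 1/s, concentration mM
(equivalently nmol/mm^3), amount nmol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, Union

import numpy as np
from scipy import integrate

from .errors import InvalidInputError, NumericalError

__all__ = [
    "DiffusionParameters",
    "InstantaneousSource",
    "ContinuousSource",
    "SpacetimePoint",
    "concentration_instantaneous",
    "concentration_continuous",
    "total_dissolved_mass",
    "average_diffusion",
    "half_life",
    "tortuosity",
]

# log-space guard: exponents below this underflow to 0 rather than evaluating exp()
_LOG_UNDERFLOW = -745.0


@dataclass(frozen=True)
class DiffusionParameters:
    """Constants of the diffusion-clearance model.

    Parameters
    ----------
    d_x, d_y, d_z : float
        Effective diffusion coefficients along the image axes (mm^2/s).
        Must be strictly positive.
    k : float
        First-order clearance rate constant (1/s), >= 0.
    alpha : float
        ISS volume fraction V_ISS / V_tissue, in (0, 1].  Brain grey matter
        is typically 0.15-0.20.
    """

    d_x: float
    d_y: float
    d_z: float
    k: float = 0.0
    alpha: float = 1.0

    def __post_init__(self):
        for name in ("d_x", "d_y", "d_z"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be finite and > 0, got {v!r}")
        if not (np.isfinite(self.k) and self.k >= 0):
            raise InvalidInputError(f"k must be finite and >= 0, got {self.k!r}")
        if not (np.isfinite(self.alpha) and 0 < self.alpha <= 1):
            raise InvalidInputError(f"alpha must be in (0, 1], got {self.alpha!r}")

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([self.d_x, self.d_y, self.d_z])

    def to_dict(self) -> dict:
        return {
            "d_x_mm2_per_s": self.d_x,
            "d_y_mm2_per_s": self.d_y,
            "d_z_mm2_per_s": self.d_z,
            "k_per_s": self.k,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusionParameters":
        return cls(
            d_x=float(d["d_x_mm2_per_s"]),
            d_y=float(d["d_y_mm2_per_s"]),
            d_z=float(d["d_z_mm2_per_s"]),
            k=float(d.get("k_per_s", 0.0)),
            alpha=float(d.get("alpha", 1.0)),
        )


@dataclass(frozen=True)
class InstantaneousSource:
    """Bolus point source: mass ``M`` released at one instant and position.

    mass : nmol; position : (x, y, z) mm in the image/world frame;
    release_time : s.
    """

    mass: float
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    release_time: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.mass) and self.mass > 0):
            raise InvalidInputError(f"mass must be finite and > 0, got {self.mass!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InvalidInputError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", tuple(float(p) for p in pos))

    def to_dict(self) -> dict:
        return {
            "kind": "instantaneous",
            "mass_nmol": self.mass,
            "position_mm": list(self.position),
            "release_time_s": self.release_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InstantaneousSource":
        return cls(
            mass=float(d["mass_nmol"]),
            position=tuple(float(p) for p in d["position_mm"]),
            release_time=float(d.get("release_time_s", 0.0)),
        )


@dataclass(frozen=True)
class ContinuousSource:
    """Constant-rate infusion: concentration ``c0`` delivered at volume rate ``q``.

    c0 : infusate concentration (mM); q : infusion rate (mm^3/s);
    position : mm; start_time, duration : s.  Total delivered mass is
    ``c0 * q * duration`` (nmol).
    """

    c0: float
    q: float
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    start_time: float = 0.0
    duration: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.c0) and self.c0 > 0):
            raise InvalidInputError(f"c0 must be finite and > 0, got {self.c0!r}")
        if not (np.isfinite(self.q) and self.q >= 0):
            raise InvalidInputError(f"q must be finite and >= 0, got {self.q!r}")
        if not (np.isfinite(self.duration) and self.duration >= 0):
            raise InvalidInputError(f"duration must be >= 0, got {self.duration!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InvalidInputError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", tuple(float(p) for p in pos))

    @property
    def total_mass(self) -> float:
        return self.c0 * self.q * self.duration

    def to_dict(self) -> dict:
        return {
            "kind": "continuous",
            "c0_mM": self.c0,
            "q_mm3_per_s": self.q,
            "position_mm": list(self.position),
            "start_time_s": self.start_time,
            "duration_s": self.duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContinuousSource":
        return cls(
            c0=float(d["c0_mM"]),
            q=float(d["q_mm3_per_s"]),
            position=tuple(float(p) for p in d["position_mm"]),
            start_time=float(d.get("start_time_s", 0.0)),
            duration=float(d.get("duration_s", 0.0)),
        )


Source = Union[InstantaneousSource, ContinuousSource]


def source_from_dict(d: dict) -> Source:
    kind = d.get("kind")
    if kind == "instantaneous":
        return InstantaneousSource.from_dict(d)
    if kind == "continuous":
        return ContinuousSource.from_dict(d)
    raise InvalidInputError(f"unknown source kind {kind!r}")


@dataclass(frozen=True)
class SpacetimePoint:
    """Evaluation point in the source-centred frame: x, y, z (mm), t (s since release)."""

    x: float
    y: float
    z: float
    t: float

    def __post_init__(self):
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z, self.t)):
            raise InvalidInputError("spacetime point coordinates must be finite")


def _as_point_arrays(points: Iterable[SpacetimePoint] | np.ndarray):
    """Coerce points to (x, y, z, t) float arrays; accepts an (n, 4) array too."""
    if isinstance(points, np.ndarray):
        arr = np.atleast_2d(np.asarray(points, dtype=float))
        if arr.shape[1] != 4:
            raise InvalidInputError("point array must have shape (n, 4): x, y, z, t")
    else:
        pts = list(points)
        arr = np.array([[p.x, p.y, p.z, p.t] for p in pts], dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 4)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("non-finite coordinate in evaluation points")
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


def _log_kernel(params: DiffusionParameters, x, y, z, t):
    """log of the unit-mass (M/alpha = 1) instantaneous kernel at elapsed time t > 0."""
    dx, dy, dz = params.d_x, params.d_y, params.d_z
    norm = -np.log(8.0) - 1.5 * np.log(np.pi * t) - 0.5 * math.log(dx * dy * dz)
    quad = -(x * x) / (4 * dx * t) - (y * y) / (4 * dy * t) - (z * z) / (4 * dz * t)
    return norm + quad - params.k * t


def point_source_kernel(params: DiffusionParameters, x, y, z, t):
    """Instantaneous unit-mass kernel C(x,y,z,t) for M/alpha = 1; vectorised.

    Evaluated in log-space so deep-tail values underflow to 0 instead of NaN.
    """
    logc = _log_kernel(params, np.asarray(x, float), np.asarray(y, float),
                       np.asarray(z, float), np.asarray(t, float))
    out = np.where(logc < _LOG_UNDERFLOW, 0.0, np.exp(np.maximum(logc, _LOG_UNDERFLOW)))
    return out


def concentration_instantaneous(
    params: DiffusionParameters,
    source: InstantaneousSource,
    points: Sequence[SpacetimePoint] | np.ndarray,
) -> np.ndarray:
    """Concentration (mM) of an instantaneous point source at spacetime points.

    Point coordinates are relative to the source position; ``t`` is time since
    ``release_time``.  All point times must be strictly positive.
    """
    x, y, z, t = _as_point_arrays(points)
    if np.any(t <= 0):
        raise InvalidInputError("all point times must be strictly after the release time")
    return (source.mass / params.alpha) * point_source_kernel(params, x, y, z, t)


def concentration_continuous(
    params: DiffusionParameters,
    source: ContinuousSource,
    points: Sequence[SpacetimePoint] | np.ndarray,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Concentration (mM) of a constant-rate infusion at spacetime points.

    Duhamel superposition: releases of mass rate ``c0 * q`` at times
    tau in [0, min(t, duration)] each evolve for elapsed time t - tau, so

        C(x, t) = (c0 q / alpha) * int_{max(0, t - duration)}^{t}
                  kernel(x, s) ds        with s = t - tau.

    Integrated by adaptive quadrature to relative tolerance ``rtol``.
    """
    x, y, z, t = _as_point_arrays(points)
    if np.any(t <= 0):
        raise InvalidInputError("all point times must be strictly after the start time")
    if source.q == 0.0 or source.duration == 0.0:
        return np.zeros_like(t)

    rate = source.c0 * source.q / params.alpha  # nmol/s scaled by 1/alpha
    out = np.empty_like(t)
    for i in range(t.size):
        ti = t[i]
        lo = max(ti - source.duration, 0.0)
        xi, yi, zi = x[i], y[i], z[i]

        def integrand(s, xi=xi, yi=yi, zi=zi):
            logc = _log_kernel(params, xi, yi, zi, s)
            return 0.0 if logc < _LOG_UNDERFLOW else math.exp(logc)

        val, abserr = integrate.quad(integrand, lo, ti, epsrel=rtol, epsabs=0.0, limit=200)
        if val > 0 and abserr / val > max(rtol * 100, 1e-6):
            raise NumericalError(
                f"continuous-source quadrature did not converge at point {i}",
                achieved_tolerance=abserr / val,
            )
        out[i] = rate * val
    return out


def total_dissolved_mass(
    params: DiffusionParameters, source: InstantaneousSource, t: float
) -> float:
    """Whole-space spatial integral of the bolus field at time ``t`` (nmol).

    Closed form (M / alpha) * exp(-k (t - release)).  Serves as the analytic
    conservation oracle: the Gaussian integrates to M/alpha exactly and
    clearance removes mass at rate k.
    """
    if not np.isfinite(t) or t <= source.release_time:
        raise InvalidInputError("t must be strictly after the release time")
    elapsed = t - source.release_time
    return (source.mass / params.alpha) * math.exp(-params.k * elapsed)


_AVG_CONVENTIONS = ("rss", "rms", "mean")


def average_diffusion(params: DiffusionParameters, convention: str = "rss") -> float:
    """Scalar average of the three axis diffusivities (mm^2/s).

    Conventions:

    - ``"rss"`` (default): sqrt(Dx^2 + Dy^2 + Dz^2) -- the magnitude of the
      diffusivity vector; for an isotropic medium this is sqrt(3) * D.
    - ``"rms"``: sqrt((Dx^2 + Dy^2 + Dz^2) / 3) -- equals D when isotropic.
    - ``"mean"``: (Dx + Dy + Dz) / 3.
    """
    d = params.diffusivities
    if convention == "rss":
        return float(np.sqrt(np.sum(d**2)))
    if convention == "rms":
        return float(np.sqrt(np.mean(d**2)))
    if convention == "mean":
        return float(np.mean(d))
    raise InvalidInputError(
        f"unknown average-diffusion convention {convention!r}; expected one of {_AVG_CONVENTIONS}"
    )


def half_life(k: float) -> float:
    """Clearance half-life t_1/2 = ln(2) / k (s).  Requires k > 0."""
    if not (np.isfinite(k) and k > 0):
        raise InvalidInputError(f"half-life requires k > 0, got {k!r}")
    return math.log(2.0) / k


def tortuosity(d_free: float, d_effective: float) -> float:
    """Tortuosity lambda = sqrt(D_free / D_effective), dimensionless.

    Quantifies the hindrance of diffusion by ISS geometry; >= 1 whenever the
    tissue slows the tracer relative to free solution.
    """
    if not (np.isfinite(d_free) and d_free > 0):
        raise InvalidInputError(f"d_free must be > 0, got {d_free!r}")
    if not (np.isfinite(d_effective) and d_effective > 0):
        raise InvalidInputError(f"d_effective must be > 0, got {d_effective!r}")
    return math.sqrt(d_free / d_effective)
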