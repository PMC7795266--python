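"""Lubricated squeezing flow (LSF): biaxial extensional rheology of soft solids.

A cylindrical sample is compressed between lubricated plates at constant
platen speed, so the material undergoes (approximately frictionless)
equibiaxial extension.  This module converts the recorded force-time trace
plus the test geometry into biaxial strain, strain rate, stress and
apparent biaxial extensional viscosity, and fits the resulting flow curve
with a power law.

Sign convention: compression of the sample stretches the material
biaxially, and all kinematic quantities are stored as positive magnitudes:

    eps_b   = 1/2 * ln(h0 / h_t)        (biaxial Hencky strain)
    deps_b  = v / (2 * h_t)             (biaxial strain rate, 1/s)
    sigma   = F / (pi * r_p^2)          (normal stress, Pa)
    eta_b*  = sigma / deps_b            (apparent biaxial viscosity, Pa s)

Geometry is accepted in the units instruments report (mm, mm/s) and
converted to SI once at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import LinFit, linfit

__all__ = [
    "LSFTrace",
    "ProcessedLSF",
    "FlowCurveFit",
    "PlatenOvertravelError",
    "NoUsableSamplesError",
    "height_at_time",
    "biaxial_strain",
    "biaxial_strain_rate",
    "stress",
    "biaxial_viscosity",
    "process_trace",
    "extract_at_strain",
    "fit_flow_curve",
]

_MM = 1e-3  # metres per millimetre


class PlatenOvertravelError(ValueError):
    """Raised when the platen kinematics would drive the gap to <= 0."""


class NoUsableSamplesError(ValueError):
    """Raised when trace cleaning leaves no samples to process."""


@dataclass(frozen=True)
class LSFTrace:
    """Raw constant-speed compression record plus test geometry.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing from the start of
        platen motion.
    force
        Compressive force in newtons at each time.
    platen_speed
        Constant downward platen speed v in mm/s (> 0).
    initial_height
        Sample height h0 at t = 0 in mm (> 0).
    plate_radius
        Radius r_p of the lubricated plates in mm (> 0).
    label
        Free-text sample identifier / condition.
    """

    time: np.ndarray
    force: np.ndarray
    platen_speed: float
    initial_height: float
    plate_radius: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float).ravel()
        f = np.asarray(self.force, dtype=float).ravel()
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)
        if t.size == 0 or t.size != f.size:
            raise ValueError("time and force must be non-empty arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if t[0] < 0:
            raise ValueError("time must start at >= 0")
        for name in ("platen_speed", "initial_height", "plate_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.initial_height - self.platen_speed * t[-1] <= 0:
            raise PlatenOvertravelError(
                "trace runs past platen contact: h0 - v * max(time) <= 0"
            )


@dataclass(frozen=True)
class ProcessedLSF:
    """Per-sample kinematics and stress derived from one :class:`LSFTrace`.

    All arrays share one length; ``strain`` is non-decreasing in time,
    ``rate`` strictly increasing (constant speed into a shrinking gap) and
    ``viscosity`` equals ``stress / rate`` elementwise.
    """

    time: np.ndarray  # s
    height: np.ndarray  # mm
    strain: np.ndarray  # dimensionless biaxial Hencky strain >= 0
    rate: np.ndarray  # 1/s
    stress: np.ndarray  # Pa
    viscosity: np.ndarray  # Pa s
    platen_speed: float  # mm/s
    initial_height: float  # mm
    plate_radius: float  # mm
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "height_mm": self.height,
                "strain": self.strain,
                "rate_per_s": self.rate,
                "stress_Pa": self.stress,
                "viscosity_Pa_s": self.viscosity,
            }
        )


@dataclass(frozen=True)
class FlowCurveFit:
    """Power-law flow curve eta_b(rate) = K * rate**(n - 1).

    K is the consistency index (Pa s^n), n the flow index; n < 1 means
    extension thinning.  Standard errors come from the log-log OLS fit
    (delta method for K).
    """

    K: float
    n: float
    stderr_K: float
    stderr_n: float
    r2_adj: float
    fit: LinFit = field(repr=False)

    @property
    def is_extension_thinning(self) -> bool:
        return self.n < 1.0

    def predict(self, rate):
        return self.K * np.asarray(rate, dtype=float) ** (self.n - 1.0)


def height_at_time(t, h0: float, v: float):
    """Gap height h(t) = h0 - v*t (mm) for constant platen speed.

    Raises :class:`PlatenOvertravelError` if any height would be <= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    h = h0 - v * t
    if np.any(h <= 0):
        raise PlatenOvertravelError("platen overtravel: h0 - v*t <= 0")
    return h if h.ndim else float(h)


def biaxial_strain(h_t, h0: float):
    """Biaxial Hencky strain magnitude 1/2 * ln(h0 / h_t)."""
    h_t = np.asarray(h_t, dtype=float)
    if np.any(h_t <= 0):
        raise ValueError("height must be positive")
    if np.any(h_t > h0 * (1 + 1e-12)):
        raise ValueError("height above initial height: strain undefined for h_t > h0")
    e = 0.5 * np.log(h0 / h_t)
    # clip the tiny negative values the tolerance above can admit
    e = np.maximum(e, 0.0)
    return e if e.ndim else float(e)


def biaxial_strain_rate(v: float, h_t):
    """Biaxial strain rate magnitude v / (2 * h_t) in 1/s.

    Unit-agnostic as long as ``v`` and ``h_t`` share a length unit
    (mm/s with mm, or m/s with m).
    """
    if v < 0:
        raise ValueError("platen speed must be >= 0")
    h_t = np.asarray(h_t, dtype=float)
    if np.any(h_t <= 0):
        raise ValueError("height must be positive")
    r = v / (2.0 * h_t)
    return r if r.ndim else float(r)


def stress(F, r_p: float):
    """Normal stress F / (pi * r_p^2) in Pa; F in N, r_p in mm."""
    if r_p <= 0:
        raise ValueError("plate radius must be positive")
    F = np.asarray(F, dtype=float)
    s = F / (np.pi * (r_p * _MM) ** 2)
    return s if s.ndim else float(s)


def biaxial_viscosity(F, r_p: float, rate):
    """Apparent biaxial viscosity stress / rate in Pa s."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("strain rate must be positive")
    eta = stress(F, r_p) / rate
    return eta if eta.ndim else float(eta)


def process_trace(
    trace: LSFTrace,
    *,
    height_floor: float = 2.0,
    force_floor: float = 0.01,
) -> ProcessedLSF:
    """Convert a raw LSF trace into strain, rate, stress and viscosity.

    Cleaning: samples before the force first exceeds ``force_floor`` (N)
    are discarded as instrument settle, as are samples with gap height
    below ``height_floor`` (mm) — by default the protocol's 2 mm endpoint
    (90 % engineering deformation from 20 mm).
    """
    h = trace.initial_height - trace.platen_speed * trace.time
    keep = h >= height_floor * (1 - 1e-12)
    above = np.nonzero(trace.force > force_floor)[0]
    if above.size == 0:
        raise NoUsableSamplesError("no usable samples: force never exceeds the noise floor")
    keep &= np.arange(trace.time.size) >= above[0]
    if not np.any(keep):
        raise NoUsableSamplesError("no usable samples after cleaning")

    t = trace.time[keep]
    f = trace.force[keep]
    h = h[keep]
    eps = biaxial_strain(h, trace.initial_height)
    rate = biaxial_strain_rate(trace.platen_speed, h)
    sig = stress(f, trace.plate_radius)
    return ProcessedLSF(
        time=t,
        height=h,
        strain=np.asarray(eps),
        rate=np.asarray(rate),
        stress=np.asarray(sig),
        viscosity=np.asarray(sig) / np.asarray(rate),
        platen_speed=trace.platen_speed,
        initial_height=trace.initial_height,
        plate_radius=trace.plate_radius,
        label=trace.label,
    )


def extract_at_strain(p: ProcessedLSF, targets: Sequence[float]) -> pd.DataFrame:
    """Interpolate stress and strain rate at target biaxial strains.

    Interpolation is piecewise linear in (strain, ln stress) and
    (strain, ln rate): log space preserves power-law structure exactly,
    so on constitutive behaviour of the form
    sigma = C * rate**m * exp(S * strain) the interpolants are exact.

    Returns a frame with columns ``strain``, ``rate``, ``stress``,
    ``viscosity`` and ``in_range``; out-of-range targets get NaN values
    and ``in_range = False`` rather than raising.
    """
    targets = np.asarray(list(targets), dtype=float)
    eps = p.strain
    lo, hi = float(eps.min()), float(eps.max())
    in_range = (targets >= lo) & (targets <= hi)
    if np.any(p.stress <= 0):
        raise ValueError("log-space interpolation requires positive stresses")
    ln_sig = np.interp(targets, eps, np.log(p.stress))
    ln_rate = np.interp(targets, eps, np.log(p.rate))
    sig = np.where(in_range, np.exp(ln_sig), np.nan)
    rate = np.where(in_range, np.exp(ln_rate), np.nan)
    return pd.DataFrame(
        {
            "strain": targets,
            "rate": rate,
            "stress": sig,
            "viscosity": sig / rate,
            "in_range": in_range,
        }
    )


def fit_flow_curve(rates: Sequence[float], viscosities: Sequence[float]) -> FlowCurveFit:
    """Fit eta_b(rate) = K * rate**(n-1) by OLS on log10 eta vs log10 rate.

    Requires >= 3 points at distinct positive rates with positive
    viscosities; slope = n - 1, intercept = log10 K.
    """
    rates = np.asarray(rates, dtype=float).ravel()
    eta = np.asarray(viscosities, dtype=float).ravel()
    if rates.size < 3:
        raise ValueError("flow-curve fit refused: need at least 3 points")
    if np.unique(rates).size < rates.size:
        warnings.warn("duplicate strain rates in flow-curve fit", stacklevel=2)
    if np.unique(rates).size < 3:
        raise ValueError("flow-curve fit refused: need at least 3 distinct rates")
    if np.any(rates <= 0) or np.any(eta <= 0):
        raise ValueError("rates and viscosities must be positive")
    fit = linfit(np.log10(rates), np.log10(eta))
    K = 10.0 ** fit.intercept
    return FlowCurveFit(
        K=K,
        n=fit.slope + 1.0,
        stderr_K=np.log(10.0) * K * fit.stderr_intercept,
        stderr_n=fit.stderr_slope,
        r2_adj=fit.r2_adj,
        fit=fit,
    )
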