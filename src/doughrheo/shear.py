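"""Small-deformation shear: power-law fit of the complex modulus.

A frequency sweep inside the linear viscoelastic region probes the
short-range interactions of the starch-gluten network.  The frequency
dependence of the complex modulus is summarised by

    G*(omega) = A_f * omega**(1/z)

where A_f (Pa s^(1/z)) is the network strength and z (dimensionless) the
network connectivity — a weak frequency dependence (large z) indicates an
extensively connected network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import LinFit, linfit

__all__ = ["FrequencySweep", "GstarFit", "fit_gstar"]


@dataclass(frozen=True)
class FrequencySweep:
    """Complex-modulus magnitudes over a frequency sweep.

    ``frequency`` is in Hz unless ``angular=True``, in which case it is
    already an angular frequency in rad/s.  Frequencies must be strictly
    increasing and positive; moduli positive.
    """

    frequency: np.ndarray
    g_star: np.ndarray  # Pa
    angular: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float).ravel()
        g = np.asarray(self.g_star, dtype=float).ravel()
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "g_star", g)
        if f.size != g.size or f.size == 0:
            raise ValueError("frequency and g_star must be non-empty and equal length")
        if np.any(f <= 0) or not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(g <= 0):
            raise ValueError("complex moduli must be positive")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency in rad/s."""
        return self.frequency if self.angular else 2.0 * np.pi * self.frequency


@dataclass(frozen=True)
class GstarFit:
    """Power-law parameters of G*(omega) = A_f * omega**(1/z).

    ``z_defined`` is False when the fitted slope is numerically zero
    (frequency-independent modulus), in which case z is NaN.
    """

    A_f: float
    z: float
    stderr_A_f: float
    stderr_z: float
    r2_adj: float
    z_defined: bool = True
    fit: LinFit = field(repr=False, default=None)

    def predict(self, omega):
        return self.A_f * np.asarray(omega, dtype=float) ** (1.0 / self.z)


def fit_gstar(sweep: FrequencySweep) -> GstarFit:
    """Fit G* = A_f * omega**(1/z) by OLS on log10 G* vs log10 omega.

    Sweeps recorded in Hz are converted to angular frequency
    (omega = 2 pi f) before fitting; slope = 1/z, intercept = log10 A_f.
    Standard errors: delta method for A_f and z from the intercept and
    slope errors.  Requires >= 3 points.
    """
    if sweep.frequency.size < 3:
        raise ValueError("need at least 3 sweep points")
    fit = linfit(np.log10(sweep.omega), np.log10(sweep.g_star))
    A_f = 10.0 ** fit.intercept
    stderr_A_f = np.log(10.0) * A_f * fit.stderr_intercept
    if abs(fit.slope) < 1e-12:
        return GstarFit(
            A_f=A_f,
            z=np.nan,
            stderr_A_f=stderr_A_f,
            stderr_z=np.nan,
            r2_adj=fit.r2_adj,
            z_defined=False,
            fit=fit,
        )
    z = 1.0 / fit.slope
    return GstarFit(
        A_f=A_f,
        z=z,
        stderr_A_f=stderr_A_f,
        stderr_z=fit.stderr_slope / fit.slope**2,
        r2_adj=fit.r2_adj,
        z_defined=True,
        fit=fit,
    )
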