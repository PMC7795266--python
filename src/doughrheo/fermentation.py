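"""Lamella strain rates during fermentation from gas-volume trajectories.

As gas cells grow, the dough matrix in the lamellae around them is
biaxially extended.  Two classical models convert the relative dough
volume V_rel(t) = (V_gas + V_matrix) / V_matrix into an extensional
strain rate of the matrix:

* Bloksma (gas-filled cylinders, uniaxial extension of the matrix):
  rate = (dV_rel/dt) / V_rel — the logarithmic volume derivative;
* van Vliet (constant number of growing cells, biaxial lamella strain):
  rate = (dV_rel/dt) / (3 * (V_rel - 1)), undefined at V_rel = 1.

The two are linked by the algebraic identity
rate_bloksma / rate_vanvliet = 3 (V_rel - 1) / V_rel, which tends to 3 as
the gas phase dominates.  For typical proofing, both land in the
1e-4 to 1e-3 1/s decade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VolumeTrajectory",
    "StrainRateSeries",
    "dvrel_dt",
    "bloksma_rate",
    "vanvliet_rate",
    "strain_rates",
]


@dataclass(frozen=True)
class VolumeTrajectory:
    """Relative dough volume over fermentation time.

    ``time`` in seconds, strictly increasing, at least 3 points (needed
    for derivative estimation); ``v_rel`` dimensionless and >= 1
    everywhere (the matrix alone has V_rel = 1).
    """

    time: np.ndarray
    v_rel: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float).ravel()
        v = np.asarray(self.v_rel, dtype=float).ravel()
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "v_rel", v)
        if t.size != v.size or t.size < 3:
            raise ValueError("need >= 3 (time, v_rel) points of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time stamps must be strictly increasing (no duplicates)")
        if np.any(v < 1.0):
            raise ValueError("relative volume below 1 is unphysical")


@dataclass(frozen=True)
class StrainRateSeries:
    """Elementwise Bloksma and van Vliet strain rates for one trajectory.

    ``vanvliet_defined`` is False where V_rel = 1, where the van Vliet
    model is genuinely singular; the rate is NaN there.
    """

    time: np.ndarray
    rate_bloksma: np.ndarray
    rate_vanvliet: np.ndarray
    vanvliet_defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "rate_bloksma_per_s": self.rate_bloksma,
                "rate_vanvliet_per_s": self.rate_vanvliet,
                "vanvliet_defined": self.vanvliet_defined,
            }
        )


def dvrel_dt(traj: VolumeTrajectory) -> np.ndarray:
    """Numerical dV_rel/dt: second-order central differences in the
    interior, one-sided at the ends (exact on linear trajectories)."""
    return np.gradient(traj.v_rel, traj.time)


def bloksma_rate(traj: VolumeTrajectory) -> np.ndarray:
    """Matrix extension rate (dV_rel/dt) / V_rel in 1/s."""
    return dvrel_dt(traj) / traj.v_rel


def vanvliet_rate(traj: VolumeTrajectory) -> np.ndarray:
    """Biaxial lamella strain rate (dV_rel/dt) / (3 (V_rel - 1)) in 1/s.

    Points with V_rel = 1 are returned as NaN (model singular there),
    not raised: a trajectory legitimately starts gas-free.
    """
    d = dvrel_dt(traj)
    denom = 3.0 * (traj.v_rel - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), np.nan)
    return rate


def strain_rates(traj: VolumeTrajectory) -> StrainRateSeries:
    """Both model rates plus a validity flag for the van Vliet points."""
    return StrainRateSeries(
        time=traj.time,
        rate_bloksma=bloksma_rate(traj),
        rate_vanvliet=vanvliet_rate(traj),
        vanvliet_defined=traj.v_rel > 1.0,
    )
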