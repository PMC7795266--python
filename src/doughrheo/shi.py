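"""Strain-hardening index (SHI) from multi-speed squeezing-flow tests.

Strain hardening — an over-proportional rise of stress with extensional
strain at constant strain rate — is what lets a dough lamella stabilise a
growing gas cell.  Because a constant-platen-speed test sweeps through
strain rates as the gap closes, the constant-rate stress curve has to be
reconstructed by regression across tests run at several speeds:

1. at each deformation on a fixed strain grid, extract (stress, rate)
   from every speed's processed trace and fit log stress vs log rate;
2. evaluate each of those per-deformation lines at the target strain
   rate, giving a constant-rate stress-strain curve;
3. the slope of ln(stress) against biaxial strain on that curve is the
   SHI; SHI > 1 classifies the material as strain hardening.

On constitutive behaviour sigma = C * rate**m * exp(S * strain) the whole
cascade is exact: every per-deformation slope equals m and the recovered
SHI equals S, independent of the speed set and grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lsf import ProcessedLSF, extract_at_strain
from .stats import LinFit, linfit

__all__ = [
    "DEFAULT_STRAIN_GRID",
    "DEFAULT_TARGET_RATES",
    "RateRegression",
    "RateRegressionSet",
    "SHIResult",
    "build_rate_regressions",
    "stress_at_rate",
    "compute_shi",
    "shi_from_processed",
    "shi_time_course",
]

#: Deformation grid at which stresses are extracted from each trace.
DEFAULT_STRAIN_GRID: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

#: Slow and fast target strain rates (1/s) bracketing proofing and oven rise.
DEFAULT_TARGET_RATES: tuple[float, ...] = (0.01, 1.0)


@dataclass(frozen=True)
class RateRegression:
    """log10(stress) vs log10(rate) line at one fixed deformation."""

    strain: float
    fit: LinFit
    rate_min: float
    rate_max: float

    def stress_at(self, rate: float) -> float:
        return float(10.0 ** self.fit.predict(np.log10(rate)))

    def is_extrapolation(self, rate: float) -> bool:
        return not (self.rate_min <= rate <= self.rate_max)


@dataclass(frozen=True)
class RateRegressionSet:
    """One cross-speed regression per reachable grid deformation."""

    records: tuple[RateRegression, ...]
    dropped: tuple[float, ...] = ()

    @property
    def strains(self) -> np.ndarray:
        return np.array([r.strain for r in self.records])


@dataclass(frozen=True)
class SHIResult:
    """Strain-hardening index at one target strain rate.

    ``shi`` is the slope of ln(stress) on biaxial strain at constant
    rate; ``is_strain_hardening`` is True iff shi > 1.
    """

    target_rate: float
    shi: float
    intercept: float
    stderr_shi: float
    r2: float
    strain_grid: tuple[float, ...]
    is_strain_hardening: bool
    extrapolated: bool = False
    fit: LinFit | None = field(default=None, repr=False)


def build_rate_regressions(
    samples: Sequence[ProcessedLSF],
    grid: Sequence[float] = DEFAULT_STRAIN_GRID,
) -> RateRegressionSet:
    """Cross-speed log-log regressions of stress on strain rate.

    ``samples`` must hold processed traces from >= 3 distinct platen
    speeds.  Grid deformations reachable in fewer than three samples are
    dropped with a warning rather than failing the whole set.
    """
    samples = list(samples)
    speeds = {s.platen_speed for s in samples}
    if len(speeds) < 3:
        raise ValueError(
            f"need traces at >= 3 distinct platen speeds, got {len(speeds)}"
        )
    grid = [float(g) for g in grid]
    tables = [extract_at_strain(s, grid) for s in samples]

    records: list[RateRegression] = []
    dropped: list[float] = []
    for i, eps in enumerate(grid):
        rates = np.array([t["rate"].iloc[i] for t in tables])
        sig = np.array([t["stress"].iloc[i] for t in tables])
        ok = np.array([bool(t["in_range"].iloc[i]) for t in tables])
        if ok.sum() < 3:
            dropped.append(eps)
            warnings.warn(
                f"deformation {eps:g} reachable in only {int(ok.sum())} trace(s); dropped",
                stacklevel=2,
            )
            continue
        rates, sig = rates[ok], sig[ok]
        fit = linfit(np.log10(rates), np.log10(sig))
        records.append(
            RateRegression(
                strain=eps,
                fit=fit,
                rate_min=float(rates.min()),
                rate_max=float(rates.max()),
            )
        )
    return RateRegressionSet(records=tuple(records), dropped=tuple(dropped))


def stress_at_rate(regs: RateRegressionSet, rate: float) -> pd.DataFrame:
    """Constant-rate stress-strain curve predicted by the regressions.

    Returns a frame with columns ``strain``, ``stress`` and
    ``extrapolated``; extrapolation beyond a deformation's observed rate
    span is flagged, not forbidden (a fast target rate genuinely lies
    above the span of the slowest-speed test).
    """
    if rate <= 0:
        raise ValueError("target strain rate must be positive")
    rows = [
        (r.strain, r.stress_at(rate), r.is_extrapolation(rate)) for r in regs.records
    ]
    return pd.DataFrame(rows, columns=["strain", "stress", "extrapolated"])


def compute_shi(
    strain: Sequence[float],
    stress: Sequence[float],
    rate: float,
    *,
    extrapolated: bool = False,
) -> SHIResult:
    """SHI as the semilog slope of ln(stress) on biaxial strain.

    Requires >= 3 (strain, stress) pairs with positive stresses.
    """
    strain = np.asarray(strain, dtype=float).ravel()
    sig = np.asarray(stress, dtype=float).ravel()
    if strain.size < 3:
        raise ValueError("need at least 3 (strain, stress) pairs for the SHI fit")
    if np.any(sig <= 0):
        raise ValueError("stresses must be positive for the semilog SHI fit")
    fit = linfit(strain, np.log(sig))
    shi = fit.slope
    return SHIResult(
        target_rate=float(rate),
        shi=shi,
        intercept=fit.intercept,
        stderr_shi=fit.stderr_slope,
        r2=fit.r2,
        strain_grid=tuple(strain.tolist()),
        is_strain_hardening=bool(shi > 1.0),
        extrapolated=bool(extrapolated),
        fit=fit,
    )


def shi_from_processed(
    samples: Sequence[ProcessedLSF],
    target_rates: Sequence[float] = DEFAULT_TARGET_RATES,
    grid: Sequence[float] = DEFAULT_STRAIN_GRID,
) -> list[SHIResult]:
    """Full cascade: multi-speed samples -> one SHIResult per target rate."""
    regs = build_rate_regressions(samples, grid)
    out = []
    for rate in target_rates:
        curve = stress_at_rate(regs, rate)
        out.append(
            compute_shi(
                curve["strain"],
                curve["stress"],
                rate,
                extrapolated=bool(curve["extrapolated"].any()),
            )
        )
    return out


def shi_time_course(series: Iterable[tuple[float, SHIResult]]) -> pd.DataFrame:
    """Tidy long-format table (time, rate, shi, stderr, hardening) for export."""
    rows = [
        {
            "time": float(t),
            "rate": r.target_rate,
            "shi": r.shi,
            "stderr": r.stderr_shi,
            "is_strain_hardening": r.is_strain_hardening,
        }
        for t, r in series
    ]
    if not rows:
        raise ValueError("empty SHI series")
    return pd.DataFrame(rows)
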