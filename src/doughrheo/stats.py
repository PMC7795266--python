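"""Shared regression and uncertainty machinery.

Every model fit in the package reduces to an ordinary least-squares line in
some transformed space (log-log for power laws, semilog for strain
hardening), so a single well-tested ``linfit`` backs them all.  First-order
(Gaussian) error propagation with finite-difference partials covers the
uncertainty arithmetic for derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = ["LinFit", "PropagatedError", "linfit", "propagate_error", "percent_change"]


@dataclass(frozen=True)
class LinFit:
    """Ordinary least-squares line ``y = slope * x + intercept``.

    ``stderr_slope``/``stderr_intercept`` are NaN when fewer than three
    points are available (zero residual degrees of freedom); ``r2_adj`` is
    the adjusted coefficient of determination 1 - (1-R^2)(n-1)/(n-2).
    """

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    r2: float
    r2_adj: float
    n_points: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class PropagatedError:
    """First-order propagated uncertainty of ``f`` at ``values``.

    ``std**2`` equals the sum of the per-variable ``contributions``
    (partial derivative squared times variance), assuming independent
    measurands.
    """

    value: float
    std: float
    contributions: dict[str, float] = field(default_factory=dict)


def linfit(x: Sequence[float], y: Sequence[float]) -> LinFit:
    """Fit a straight line by ordinary least squares.

    Parameters
    ----------
    x, y
        Equal-length 1-D sequences; ``x`` must contain at least two
        distinct values.

    Raises
    ------
    ValueError
        On fewer than two points, mismatched lengths, non-finite input or
        degenerate (constant) ``x``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"x and y lengths differ: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 points for a line fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate fit: all x values identical")

    res = _scipy_stats.linregress(x, y)
    n = x.size
    r2 = float(res.rvalue) ** 2
    if n > 2:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        se_slope = float(res.stderr)
        se_intercept = float(res.intercept_stderr)
    else:
        # a line through two points has no residual degrees of freedom
        r2_adj = np.nan
        se_slope = np.nan
        se_intercept = np.nan
    return LinFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=se_slope,
        stderr_intercept=se_intercept,
        r2=r2,
        r2_adj=float(r2_adj),
        n_points=int(n),
    )


def propagate_error(
    f: Callable[..., float],
    values: Mapping[str, float],
    stds: Mapping[str, float],
    *,
    rel_step: float = 1e-6,
    abs_step_floor: float = 1e-12,
) -> PropagatedError:
    """Gaussian (first-order) uncertainty of ``f(**values)``.

    Partial derivatives are taken by central finite differences with a
    relative step of ``rel_step`` (absolute floor ``abs_step_floor``), and
    combined as std^2 = sum_i (df/dx_i)^2 * std_i^2 — measurands are
    treated as independent.

    Parameters
    ----------
    f
        Callable accepting the variables in ``values`` as keyword
        arguments and returning a scalar.
    values, stds
        Central values and standard deviations keyed by variable name;
        the key sets must match and every std must be >= 0.
    """
    if set(values) != set(stds):
        raise ValueError("values and stds must cover the same variables")
    for name, s in stds.items():
        if s < 0:
            raise ValueError(f"negative standard deviation for {name!r}")

    centre = dict(values)
    try:
        f0 = float(f(**centre))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"function evaluation failed at the central values: {exc}") from exc

    var_total = 0.0
    contributions: dict[str, float] = {}
    for name, v in values.items():
        h = max(rel_step * abs(v), abs_step_floor)
        hi = dict(centre, **{name: v + h})
        lo = dict(centre, **{name: v - h})
        try:
            dfdx = (float(f(**hi)) - float(f(**lo))) / (2.0 * h)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"function evaluation failed when perturbing {name!r}: {exc}") from exc
        contrib = dfdx**2 * stds[name] ** 2
        contributions[name] = contrib
        var_total += contrib
    return PropagatedError(value=f0, std=float(np.sqrt(var_total)), contributions=contributions)


def percent_change(before: float, after: float) -> float:
    """Relative change from ``before`` to ``after`` in percent.

    ``(after - before) / before * 100``; negative for a decrease.
    """
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return (after - before) / before * 100.0
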