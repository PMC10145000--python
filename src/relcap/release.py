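"""Release limits and expiry time from capability and degradation rate.

The lower release limit guarantees, at confidence 1 - alpha, that a batch
released at concentration LRL still meets the lower specification limit
after T months of degradation at slope b:

    LRL(T) = LSL + |b| T + t_{1-alpha, df} * sqrt(T^2 s_b^2 + s^2)

where s_b is the standard error of the estimated slope and s is the SD of
a single new observation from a new batch at time zero (from the process
capability analysis).  LRL(T) is strictly increasing in T, so instead of
fixing T and checking whether LRL is attainable, the procedure fixes
LRL at the lower capability limit mu - 3 sigma_total and inverts the
equation for T by bisection: the expiry time is the longest shelf life the
process capability can support.

Note the sign of the allowance: an uncertainty buffer must *raise* the
release floor above the deterministic requirement LSL + |b| T; the variant
that subtracts it (exposed via ``literal_printed_sign=True`` for
comparison) would release batches with less content than the point estimate
requires and is not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .capability import CapabilityResult
from .datamodel import NumericalError, SpecLimits, ValidationError

__all__ = [
    "ReleasePlan",
    "lrl_adg",
    "solve_expiry",
    "lrl_curve",
    "release_interval",
    "plan_release",
]


def _check(alpha: float, df: int, T: float, slope: float) -> None:
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValidationError("df must be >= 1")
    if T < 0:
        raise ValidationError("T must be >= 0")
    if slope > 0:
        raise ValidationError("slope must be <= 0 (degradation)")


def lrl_adg(
    spec: SpecLimits,
    slope: float,
    slope_se: float,
    s_process: float,
    T: float,
    alpha: float = 0.05,
    df: int = 10,
    literal_printed_sign: bool = False,
) -> float:
    """Lower release limit for expiry time T (strictly increasing in T)."""
    _check(alpha, df, T, slope)
    if slope_se < 0 or s_process < 0:
        raise ValidationError("slope_se and s_process must be >= 0")
    tq = stats.t.ppf(1.0 - alpha, df)
    allowance = tq * np.sqrt(T**2 * slope_se**2 + s_process**2)
    if literal_printed_sign:
        allowance = -allowance
    return spec.lsl + abs(slope) * T + allowance


def solve_expiry(
    spec: SpecLimits,
    lcl: float,
    slope: float,
    slope_se: float,
    s_process: float,
    alpha: float = 0.05,
    df: int = 10,
    bracket: tuple[float, float] = (0.01, 60.0),
) -> float:
    """Expiry time T with LRL(T) = lcl, by bisection to |residual| <= 1e-8.

    ``lcl`` is the lower capability limit the release limit is pinned to.
    Raises when the process leaves no room for degradation (lcl below the
    release floor at T=0) or when no crossing occurs within the bracket.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValidationError("bracket must satisfy 0 < low < high")

    def g(T: float) -> float:
        return lrl_adg(spec, slope, slope_se, s_process, T, alpha, df) - lcl

    if g(lo) > 0:
        raise NumericalError(
            "no room for degradation: lower capability limit is below the "
            "release floor LRL(T~0); the process is not capable enough"
        )
    if g(hi) < 0:
        raise NumericalError(
            f"LRL does not reach the capability limit within {hi} months"
        )
    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        if g(mid) <= 0:
            a = mid
        else:
            b = mid
        if abs(g(0.5 * (a + b))) <= 1e-8:
            break
    T = 0.5 * (a + b)
    if abs(g(T)) > 1e-8:
        # monotone and continuous, so brentq polishes any leftover residual
        T = float(optimize.brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16))
    if abs(g(T)) > 1e-8:
        raise NumericalError("bisection failed to reach residual 1e-8")
    return float(T)


def lrl_curve(
    spec: SpecLimits,
    slope: float,
    slope_se: float,
    s_process: float,
    alpha: float,
    df: int,
    t_grid,
) -> list[tuple[float, float]]:
    """Pointwise LRL over an increasing grid of candidate expiry times."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValidationError("t_grid must be a non-empty 1-D sequence")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValidationError("t_grid must be strictly increasing")
    return [
        (float(t), lrl_adg(spec, slope, slope_se, s_process, float(t), alpha, df))
        for t in t_grid
    ]


def release_interval(
    capability: CapabilityResult, spec: SpecLimits | None = None
) -> tuple[float, float, bool]:
    """Release interval [LRL, URL] = [LCL, UCL]; flag an incapable process.

    Returns ``(lrl, url, capable)`` where ``capable`` is False when the
    capability limits stick out of the specification interval (the process
    cannot guarantee specification-conforming release).  With ``spec=None``
    the flag is always True.
    """
    capable = True
    if spec is not None:
        capable = capability.lcl >= spec.lsl and capability.ucl <= spec.usl
    return capability.lcl, capability.ucl, capable


@dataclass(frozen=True)
class ReleasePlan:
    """Release limits, solved expiry time and the quantities behind them."""

    lrl: float
    url: float
    expiry_t: float
    alpha: float
    df: int
    slope: float
    slope_se: float
    s_process: float
    capable: bool = True


def plan_release(
    capability: CapabilityResult,
    spec: SpecLimits,
    slope: float,
    slope_se: float,
    s_process: float,
    alpha: float = 0.05,
    df: int = 10,
    bracket: tuple[float, float] = (0.01, 60.0),
) -> ReleasePlan:
    """Pin LRL to the lower capability limit and solve for the expiry time."""
    lrl, url = capability.lcl, capability.ucl
    capable = lrl >= spec.lsl and url <= spec.usl
    T = solve_expiry(spec, lrl, slope, slope_se, s_process, alpha, df, bracket)
    return ReleasePlan(
        lrl=lrl,
        url=url,
        expiry_t=T,
        alpha=alpha,
        df=df,
        slope=slope,
        slope_se=slope_se,
        s_process=s_process,
        capable=capable,
    )
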