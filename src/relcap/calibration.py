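"""Linear HPLC calibration and back-calculation uncertainty.

A straight-line calibration ``response = b0 + b1 * concentration`` is fitted
by ordinary least squares.  An unknown sample's concentration is recovered
from its peak area as ``x0 = f * (y - b0) / b1`` where ``f`` is the dilution
factor of the sample preparation.  The standard deviation of ``x0`` is
propagated to first order (delta method) through the gradient of that
transform with respect to ``(y, b0, b1)``, using the full OLS coefficient
covariance matrix — including the intercept/slope covariance, which is not
negligible for calibration designs whose mean concentration is far from 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import DesignError, ValidationError


@dataclass(frozen=True)
class CalibrationFit:
    """OLS straight-line calibration with its design summary.

    The design summary ``(n, x_bar, sxx)`` together with the residual SD
    ``s_r`` fully determines the coefficient covariance matrix:

    * ``var(b1) = s_r^2 / sxx``
    * ``var(b0) = s_r^2 (1/n + x_bar^2 / sxx)``
    * ``cov(b0, b1) = -x_bar s_r^2 / sxx``
    """

    b0: float
    b1: float
    s_r: float
    n: int
    x_bar: float
    sxx: float

    def __post_init__(self) -> None:
        if self.b1 == 0:
            raise ValidationError("calibration slope must be nonzero")
        if self.s_r < 0 or self.sxx <= 0 or self.n < 3:
            raise ValidationError("invalid calibration summary")

    @property
    def var_b1(self) -> float:
        return self.s_r**2 / self.sxx

    @property
    def var_b0(self) -> float:
        return self.s_r**2 * (1.0 / self.n + self.x_bar**2 / self.sxx)

    @property
    def cov_b0b1(self) -> float:
        return -self.x_bar * self.s_r**2 / self.sxx

    @property
    def df(self) -> int:
        return self.n - 2


def fit_calibration(
    concentrations: np.ndarray, responses: np.ndarray
) -> CalibrationFit:
    """Fit the straight-line calibration by ordinary least squares."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("concentrations and responses must be equal-length 1-D")
    if len(np.unique(x)) < 3:
        raise DesignError("need at least 3 distinct concentration levels")
    n = len(x)
    x_bar = float(x.mean())
    sxx = float(np.sum((x - x_bar) ** 2))
    if sxx == 0:
        raise DesignError("all concentrations equal: singular design")
    res = stats.linregress(x, y)
    b0, b1 = float(res.intercept), float(res.slope)
    sse = float(np.sum((y - b0 - b1 * x) ** 2))
    s_r = float(np.sqrt(max(sse, 0.0) / (n - 2)))
    return CalibrationFit(b0=b0, b1=b1, s_r=s_r, n=n, x_bar=x_bar, sxx=sxx)


def back_calculate(response: float, fit: CalibrationFit, f: float = 1.0) -> float:
    """Concentration of an unknown from its response: ``f (y - b0) / b1``."""
    if f <= 0:
        raise ValidationError("dilution factor must be > 0")
    return f * (response - fit.b0) / fit.b1


def back_calc_uncertainty(
    response: float,
    fit: CalibrationFit,
    f: float = 1.0,
    response_var: float | None = None,
) -> float:
    """Delta-method SD of the back-calculated concentration.

    ``response_var`` is the variance of the new response measurement; the
    default ``s_r^2`` treats it as a single observation with the calibration
    residual variance.  Pass ``fit.s_r**2 / m`` for the mean of ``m``
    replicate injections.
    """
    if f <= 0:
        raise ValidationError("dilution factor must be > 0")
    if response_var is None:
        response_var = fit.s_r**2
    if response_var < 0:
        raise ValidationError("response_var must be >= 0")
    g_y = f / fit.b1
    g_b0 = -f / fit.b1
    g_b1 = -f * (response - fit.b0) / fit.b1**2
    var = (
        g_y**2 * response_var
        + g_b0**2 * fit.var_b0
        + g_b1**2 * fit.var_b1
        + 2.0 * g_b0 * g_b1 * fit.cov_b0b1
    )
    return float(np.sqrt(max(var, 0.0)))


def back_calc_cv_percent(
    response: float,
    fit: CalibrationFit,
    f: float = 1.0,
    response_var: float | None = None,
) -> float:
    """Coefficient of variation (%) of the back-calculated concentration."""
    x0 = back_calculate(response, fit, f)
    if x0 == 0:
        raise ValidationError("CV undefined at concentration 0")
    return 100.0 * back_calc_uncertainty(response, fit, f, response_var) / abs(x0)
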