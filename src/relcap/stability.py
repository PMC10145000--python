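"""Stability regression, ICH poolability testing and shelf-life estimation.

Each batch's concentration is modelled as a straight line in storage time.
Whether batches may be pooled is decided by a type III ANCOVA of the
full-interaction fixed-effects model

    y_ij = a0 + a_i + (b0 + b_i) t_ij + e_ij,   sum(a_i) = sum(b_i) = 0,

testing the time-by-batch interaction (equal slopes) and the batch main
effect (equal intercepts) at the permissive 25% level the ICH stability
guideline prescribes.  The shelf life is the first time at which a
one-sided lower 95% band of the (pooled) regression crosses the lower
specification limit — either the confidence band for the mean (the ICH
definition) or the prediction band for a single future reportable value,
which is uniformly lower and protects individual units when within-batch
variability matters.

A Ruberg–Stegeman "critical alpha" guards the poolability decision against
lack of power: it is the significance level at which the interaction F-test
would attain a prescribed power against a stated slope-difference
alternative, computed from the noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import optimize, stats
from statsmodels.stats.anova import anova_lm

from .datamodel import (
    DesignError,
    SpecLimits,
    StabilityTable,
    ValidationError,
)

__all__ = [
    "BatchFit",
    "PooledStabilityFit",
    "AncovaTable",
    "ShelfLifeResult",
    "CriticalAlpha",
    "fit_batch",
    "fit_pooled",
    "ancova_type3",
    "poolability",
    "critical_alpha",
    "confidence_band",
    "prediction_band",
    "shelf_life",
    "stability_analysis",
]


@dataclass(frozen=True)
class BatchFit:
    """Straight-line OLS fit for one batch (or for the fully pooled data)."""

    batch_id: str
    b0: float
    b1: float
    rsd: float
    n: int
    x_bar: float
    sxx: float

    def __post_init__(self) -> None:
        if self.sxx <= 0:
            raise DesignError(f"batch {self.batch_id!r}: all times equal")

    @property
    def slope_se(self) -> float:
        # var(b1) = rsd^2 / sum((t - tbar)^2)
        return self.rsd / np.sqrt(self.sxx)

    @property
    def df(self) -> int:
        return self.n - 2

    def predict(self, t):
        return self.b0 + self.b1 * np.asarray(t, dtype=float)


def _ols_line(batch_id: str, t: np.ndarray, y: np.ndarray) -> BatchFit:
    n = len(t)
    x_bar = float(t.mean())
    sxx = float(np.sum((t - x_bar) ** 2))
    if sxx == 0:
        raise DesignError(f"batch {batch_id!r}: all times equal (singular design)")
    b1 = float(np.sum((t - x_bar) * (y - y.mean())) / sxx)
    b0 = float(y.mean() - b1 * x_bar)
    sse = float(np.sum((y - b0 - b1 * t) ** 2))
    rsd = float(np.sqrt(max(sse, 0.0) / (n - 2))) if n > 2 else 0.0
    return BatchFit(batch_id=batch_id, b0=b0, b1=b1, rsd=rsd, n=n, x_bar=x_bar, sxx=sxx)


def fit_batch(data: StabilityTable, batch_id: str) -> BatchFit:
    """OLS degradation line for a single batch."""
    sub = data.batch_frame(batch_id)
    if len(sub) < 3:
        raise DesignError(f"batch {batch_id!r}: need >= 3 points for a residual SD")
    return _ols_line(
        batch_id, sub["time_months"].to_numpy(), sub["value"].to_numpy()
    )


@dataclass(frozen=True)
class PooledStabilityFit:
    """Full-interaction fixed-effects fit plus the one-line pooled fit.

    ``alpha_dev``/``beta_dev`` are the per-batch intercept/slope deviations
    under the sum-to-zero constraint; ``single_line`` ignores batch entirely
    and is the fit used for the pooled shelf life.
    """

    alpha0: float
    beta0: float
    alpha_dev: dict[str, float]
    beta_dev: dict[str, float]
    rsd: float
    df_resid: int
    single_line: BatchFit
    model: object = field(default=None, repr=False, compare=False)


def _interaction_model(data: StabilityTable):
    df = data.df.copy()
    df["batch"] = pd.Categorical(df["batch_id"], categories=data.batches)
    model = smf.ols("value ~ C(batch, Sum) * time_months", data=df).fit()
    return model


def fit_pooled(data: StabilityTable) -> PooledStabilityFit:
    """Fit the sum-zero full-interaction model and the one-line pooled fit."""
    batches = data.batches
    if len(batches) < 2:
        raise DesignError("need >= 2 batches to assess poolability")
    for b in batches:
        if len(data.batch_frame(b)) < 3:
            raise DesignError(f"batch {b!r}: too few points for the pooled model")
    model = _interaction_model(data)
    if model.df_resid <= 0:
        raise DesignError("saturated design: no residual degrees of freedom")
    params = model.params
    alpha0 = float(params["Intercept"])
    beta0 = float(params["time_months"])
    alpha_dev: dict[str, float] = {}
    beta_dev: dict[str, float] = {}
    for i, b in enumerate(batches[:-1]):
        alpha_dev[b] = float(params[f"C(batch, Sum)[S.{b}]"])
        beta_dev[b] = float(params[f"C(batch, Sum)[S.{b}]:time_months"])
    last = batches[-1]
    alpha_dev[last] = -sum(alpha_dev.values())
    beta_dev[last] = -sum(beta_dev.values())
    rsd = float(np.sqrt(model.mse_resid))
    single = _ols_line(
        "pooled", data.df["time_months"].to_numpy(), data.df["value"].to_numpy()
    )
    return PooledStabilityFit(
        alpha0=alpha0,
        beta0=beta0,
        alpha_dev=alpha_dev,
        beta_dev=beta_dev,
        rsd=rsd,
        df_resid=int(model.df_resid),
        single_line=single,
        model=model,
    )


_SOURCE_MAP = {
    "Intercept": "Intercept",
    "time_months": "Times",
    "C(batch, Sum)": "Batch",
    "C(batch, Sum):time_months": "Times × Batch",
    "Residual": "Residuals",
}
_SOURCE_ORDER = ["Intercept", "Times", "Batch", "Times × Batch", "Residuals"]


@dataclass(frozen=True)
class AncovaTable:
    """Type III ANCOVA of the full-interaction stability model."""

    table: pd.DataFrame = field(repr=False)

    def row(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def interaction_p(self) -> float:
        return float(self.row("Times × Batch")["p"])

    @property
    def batch_p(self) -> float:
        return float(self.row("Batch")["p"])

    @property
    def residual_ms(self) -> float:
        return float(self.row("Residuals")["mean_sq"])

    @property
    def residual_df(self) -> int:
        return int(self.row("Residuals")["df"])


def ancova_type3(data: StabilityTable) -> AncovaTable:
    """Type III (marginal) sums of squares under sum-to-zero coding."""
    model = _interaction_model(data)
    if model.df_resid <= 0:
        raise DesignError("no residual degrees of freedom for ANCOVA")
    raw = anova_lm(model, typ=3)
    rows = {}
    for src, pretty in _SOURCE_MAP.items():
        r = raw.loc[src]
        ms = float(r["sum_sq"]) / float(r["df"])
        rows[pretty] = {
            "sum_sq": float(r["sum_sq"]),
            "df": int(r["df"]),
            "mean_sq": ms,
            "F": float(r["F"]) if np.isfinite(r["F"]) else float("nan"),
            "p": float(r["PR(>F)"]) if np.isfinite(r["PR(>F)"]) else float("nan"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[_SOURCE_ORDER]
    table.index.name = "source"
    return AncovaTable(table=table)


def poolability(table: AncovaTable, alpha_pool: float = 0.25) -> str:
    """ICH stepwise poolability decision.

    Interaction (slopes) first: p < alpha keeps batches ``separate``.
    Otherwise the batch main effect decides between ``pool_all`` and
    ``common_slope_only``.
    """
    if not (0 < alpha_pool < 1):
        raise ValidationError("alpha_pool must lie in (0, 1)")
    if table.interaction_p < alpha_pool:
        return "separate"
    if table.batch_p < alpha_pool:
        return "common_slope_only"
    return "pool_all"


@dataclass(frozen=True)
class CriticalAlpha:
    """Significance level at which the slope-homogeneity test attains power."""

    alpha: float
    noncentrality: float
    df_num: int
    df_den: int
    attainable: bool


def critical_alpha(
    design: StabilityTable, delta: float, beta_power: float = 0.10
) -> CriticalAlpha:
    """Ruberg–Stegeman critical significance level for slope poolability.

    Against the alternative in which all batch slopes are 0 except the last,
    which differs by ``delta``, the time-by-batch F-test has noncentrality

        lambda = sum_i w_i (beta_i - beta_bar_w)^2 / sigma^2,
        w_i = sum_j (t_ij - tbar_i)^2,

    with sigma^2 the residual mean square of the interaction model.  The
    critical alpha solves power(alpha) = 1 - beta_power on the noncentral F.
    """
    if delta == 0:
        raise ValidationError("delta must be nonzero")
    if not (0 < beta_power < 1):
        raise ValidationError("beta_power must lie in (0, 1)")
    batches = design.batches
    k = len(batches)
    if k < 2:
        raise DesignError("need >= 2 batches")
    table = ancova_type3(design)
    sigma2 = table.residual_ms
    df1, df2 = k - 1, table.residual_df
    w = np.array(
        [
            float(
                np.sum(
                    (
                        design.batch_frame(b)["time_months"]
                        - design.batch_frame(b)["time_months"].mean()
                    )
                    ** 2
                )
            )
            for b in batches
        ]
    )
    slopes = np.zeros(k)
    slopes[-1] = delta
    beta_bar = float((w * slopes).sum() / w.sum())
    lam = float((w * (slopes - beta_bar) ** 2).sum() / sigma2)

    def power(alpha: float) -> float:
        crit = stats.f.isf(alpha, df1, df2)
        return float(stats.ncf.sf(crit, df1, df2, lam))

    target = 1.0 - beta_power
    lo, hi = 1e-12, 1.0 - 1e-9
    if power(hi) < target:
        return CriticalAlpha(
            alpha=1.0, noncentrality=lam, df_num=df1, df_den=df2, attainable=False
        )
    if power(lo) >= target:
        return CriticalAlpha(
            alpha=lo, noncentrality=lam, df_num=df1, df_den=df2, attainable=True
        )
    alpha = optimize.brentq(lambda a: power(a) - target, lo, hi, xtol=1e-14, rtol=1e-12)
    return CriticalAlpha(
        alpha=float(alpha), noncentrality=lam, df_num=df1, df_den=df2, attainable=True
    )


# ---------------------------------------------------------------------------
# Bands and shelf life


def _band(fit: BatchFit, t, alpha: float, prediction: bool):
    if fit.n <= 2:
        raise DesignError("bands need n > 2 (positive residual df)")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    t = np.asarray(t, dtype=float)
    extra = 1.0 if prediction else 0.0
    half = (
        stats.t.ppf(1.0 - alpha, fit.df)
        * fit.rsd
        * np.sqrt(extra + 1.0 / fit.n + (t - fit.x_bar) ** 2 / fit.sxx)
    )
    out = fit.predict(t) - half
    return float(out) if out.ndim == 0 else out


def confidence_band(fit: BatchFit, t, alpha: float = 0.05):
    """One-sided lower confidence limit for the mean regression line."""
    return _band(fit, t, alpha, prediction=False)


def prediction_band(fit: BatchFit, t, alpha: float = 0.05):
    """One-sided lower prediction limit for a single future reportable value."""
    return _band(fit, t, alpha, prediction=True)


@dataclass(frozen=True)
class ShelfLifeResult:
    """Crossing time of a lower regression band with the LSL."""

    t_months: float
    method: str  # "ich" | "prediction"
    basis: str  # "pooled" | "batch:<id>" | "worst-batch"
    censored: bool = False
    below_at_t0: bool = False


def shelf_life(
    fit: BatchFit,
    spec: SpecLimits,
    alpha: float = 0.05,
    method: str = "ich",
    horizon: float = 60.0,
    basis: str | None = None,
) -> ShelfLifeResult:
    """Smallest T > 0 with lower band(T) = LSL, to 1e-4 months.

    ``method="ich"`` uses the confidence band for the mean (the regulatory
    definition); ``method="prediction"`` uses the prediction band for a
    future individual value.  Censored at ``horizon`` if no crossing occurs.
    """
    if method not in ("ich", "prediction"):
        raise ValueError("method must be 'ich' or 'prediction'")
    if horizon <= 0:
        raise ValidationError("horizon must be > 0")
    band = confidence_band if method == "ich" else prediction_band
    basis = basis or f"batch:{fit.batch_id}"

    def g(t: float) -> float:
        return float(band(fit, t, alpha)) - spec.lsl

    if fit.rsd == 0.0:
        # exact line: closed-form crossing
        if fit.b1 >= 0:
            return ShelfLifeResult(horizon, method, basis, censored=True)
        t_cross = (fit.b0 - spec.lsl) / -fit.b1
        if t_cross <= 0:
            return ShelfLifeResult(0.0, method, basis, below_at_t0=True)
        if t_cross > horizon:
            return ShelfLifeResult(horizon, method, basis, censored=True)
        return ShelfLifeResult(float(t_cross), method, basis)

    if g(0.0) <= 0:
        return ShelfLifeResult(0.0, method, basis, below_at_t0=True)
    grid = np.linspace(0.0, horizon, 513)
    vals = band(fit, grid, alpha) - spec.lsl
    below = np.nonzero(vals <= 0)[0]
    if len(below) == 0:
        return ShelfLifeResult(float(horizon), method, basis, censored=True)
    i = below[0]
    t_root = optimize.brentq(g, grid[i - 1], grid[i], xtol=1e-6)
    return ShelfLifeResult(float(t_root), method, basis)


@dataclass(frozen=True)
class StabilityReport:
    """One-stop stability analysis: fits, ANCOVA, decision, shelf lives."""

    batch_fits: list[BatchFit]
    pooled: PooledStabilityFit
    ancova: AncovaTable
    decision: str
    t_ich: ShelfLifeResult
    t_pred: ShelfLifeResult
    critical: CriticalAlpha | None = None


def stability_analysis(
    data: StabilityTable,
    spec: SpecLimits,
    alpha_shelf: float = 0.05,
    alpha_pool: float = 0.25,
    beta_power: float = 0.10,
    delta_slope: float | None = None,
    horizon: float = 60.0,
) -> StabilityReport:
    """Run the full stability stage and return a structured report.

    When batches pool, shelf lives come from the one-line fit; when they do
    not, the worst (shortest) per-batch shelf life is reported, the usual
    conservative fallback in stability practice.
    """
    batch_fits = [fit_batch(data, b) for b in data.batches]
    pooled = fit_pooled(data)
    table = ancova_type3(data)
    decision = poolability(table, alpha_pool)
    if decision == "separate":
        per_ich = [
            shelf_life(f, spec, alpha_shelf, "ich", horizon) for f in batch_fits
        ]
        per_pred = [
            shelf_life(f, spec, alpha_shelf, "prediction", horizon) for f in batch_fits
        ]
        t_ich = min(per_ich, key=lambda r: r.t_months)
        t_pred = min(per_pred, key=lambda r: r.t_months)
        t_ich = ShelfLifeResult(
            t_ich.t_months, "ich", "worst-batch", t_ich.censored, t_ich.below_at_t0
        )
        t_pred = ShelfLifeResult(
            t_pred.t_months,
            "prediction",
            "worst-batch",
            t_pred.censored,
            t_pred.below_at_t0,
        )
    else:
        t_ich = shelf_life(
            pooled.single_line, spec, alpha_shelf, "ich", horizon, basis="pooled"
        )
        t_pred = shelf_life(
            pooled.single_line, spec, alpha_shelf, "prediction", horizon, basis="pooled"
        )
    crit = (
        critical_alpha(data, delta_slope, beta_power)
        if delta_slope is not None
        else None
    )
    return StabilityReport(
        batch_fits=batch_fits,
        pooled=pooled,
        ancova=table,
        decision=decision,
        t_ich=t_ich,
        t_pred=t_pred,
        critical=crit,
    )
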