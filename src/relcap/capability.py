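"""Process-capability analysis under a batch effect.

Capability indices (Cp, Cpk, K), sigma-level/DPMO conversions and
defective-fraction bounds are computed from the process mean and SD.  When
several manufacturing batches contribute to the time-zero data, the process
SD is not the pooled sample SD: the one-way random-effects model

    y_ij = mu + a_i + e_ij,   a_i ~ N(0, sigma_batch^2),  e_ij ~ N(0, sigma_within^2)

separates between-batch from within-batch/analytical variation, and the
capability index uses sigma_total = sqrt(sigma_batch^2 + sigma_within^2).
Confidence intervals for the model-based Cpk come from a seeded parametric
bootstrap of the fitted model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import AssayTable, DesignError, SpecLimits, ValidationError

logger = logging.getLogger("relcap")

__all__ = [
    "VarianceComponents",
    "CapabilityResult",
    "natural_cpk",
    "cp_index",
    "k_factor",
    "defect_bounds",
    "dpmo_sigma_level",
    "dpmo_empirical",
    "fit_variance_components",
    "model_cpk",
    "bootstrap_cpk_ci",
    "descriptive_stats",
]


# ---------------------------------------------------------------------------
# Capability indices


def natural_cpk(mean: float, sd: float, spec: SpecLimits) -> float:
    """Cpk = min((USL - mean)/(3 sd), (mean - LSL)/(3 sd)).

    Negative when the mean falls outside the specification interval.
    """
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    return min((spec.usl - mean) / (3.0 * sd), (mean - spec.lsl) / (3.0 * sd))


def cp_index(sd: float, spec: SpecLimits) -> float:
    """Cp = (USL - LSL)/(6 sd): capability ignoring centering."""
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    return (spec.usl - spec.lsl) / (6.0 * sd)


def k_factor(mean: float, spec: SpecLimits) -> float:
    """Relative off-centering K = |center - mean| / half-width.

    For a mean inside the limits, Cpk = Cp (1 - K).
    """
    return abs(spec.center - mean) / spec.half_width


def defect_bounds(cpk: float) -> tuple[float, float]:
    """Bounds on the defective fraction implied by a Cpk value.

    Returns ``(lower_quality, upper_quality)`` = ``(2 (1 - Phi(3 Cpk)),
    1 - Phi(3 Cpk))``: the worst case for a maximally off-centre process and
    the centred-process case.  The first is exactly twice the second.
    """
    if not np.isfinite(cpk):
        if cpk > 0:
            return (0.0, 0.0)
        raise ValidationError("cpk must be finite or +inf")
    tail = float(stats.norm.sf(3.0 * cpk))
    return (2.0 * tail, tail)


def dpmo_sigma_level(sigma_level: float) -> float:
    """Defects per million at a given sigma level (1.5-sigma-shift convention).

    ``10^6 (1 - Phi(sigma_level - 1.5))``; a six-sigma process yields 3.4.
    """
    if sigma_level <= 0:
        raise ValidationError("sigma_level must be > 0")
    return 1e6 * float(stats.norm.sf(sigma_level - 1.5))


def dpmo_empirical(defects: int, units: int, opportunities_per_unit: int) -> float:
    """Observed defects per million opportunities."""
    if defects < 0 or units < 0 or opportunities_per_unit < 0:
        raise ValidationError("counts must be >= 0")
    denom = units * opportunities_per_unit
    if denom == 0:
        raise ValidationError("units * opportunities_per_unit must be > 0")
    return 1e6 * defects / denom


# ---------------------------------------------------------------------------
# Variance components


@dataclass(frozen=True)
class VarianceComponents:
    """REML (or moment) estimates of the one-way random-effects model."""

    mu: float
    sigma_batch: float
    sigma_within: float
    ci_mu: tuple[float, float] | None = None
    ci_sigma_batch: tuple[float, float] | None = None
    ci_sigma_within: tuple[float, float] | None = None
    method: str = "reml"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma_batch < 0 or self.sigma_within < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.sigma_within == 0 and not self.degenerate:
            raise ValidationError("sigma_within = 0 only allowed when degenerate")

    @property
    def sigma_total(self) -> float:
        return float(np.hypot(self.sigma_batch, self.sigma_within))


def _group_summaries(data: AssayTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = data.df.groupby("batch_id")["value"]
    n_i = g.count().to_numpy(dtype=float)
    means = g.mean().to_numpy()
    ssw = ((data.df["value"] - g.transform("mean")) ** 2).sum()
    ssw_i = (
        data.df.assign(dev2=(data.df["value"] - g.transform("mean")) ** 2)
        .groupby("batch_id")["dev2"]
        .sum()
        .to_numpy()
    )
    assert np.isclose(ssw_i.sum(), ssw)
    return n_i, means, ssw_i


def _moment_from_summaries(
    n_i: np.ndarray, means: np.ndarray, ssw: np.ndarray | float
) -> tuple[float, float, float]:
    """Unbalanced one-way ANOVA method-of-moments estimates.

    Works on per-batch means and the total within-batch sum of squares,
    which are sufficient for this estimator; vectorises over a leading
    replicate axis of ``means``/``ssw`` for bootstrap use.
    """
    n_i = np.asarray(n_i, dtype=float)
    k = len(n_i)
    N = n_i.sum()
    grand = (means * n_i).sum(axis=-1) / N
    msw = np.asarray(ssw, dtype=float) / (N - k)
    ssb = (n_i * (means - np.expand_dims(grand, -1)) ** 2).sum(axis=-1)
    msb = ssb / (k - 1)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    sa2 = np.maximum((msb - msw) / n0, 0.0)
    return grand, np.sqrt(sa2), np.sqrt(np.maximum(msw, 0.0))


def _reml_fit(data: AssayTable) -> tuple[float, float, float, float]:
    """Returns (mu, sigma_batch, sigma_within, se_mu) from a REML fit."""
    endog = data.df["value"].to_numpy()
    exog = np.ones((len(endog), 1))
    model = sm.MixedLM(endog, exog, groups=data.df["batch_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
        try:  # polish: the default optimizer stops ~1e-5 from the optimum
            res = model.fit(
                reml=True, start_params=res.params_object, method="powell"
            )
        except Exception:  # noqa: BLE001 - keep the unpolished fit
            pass
    mu = float(res.params[0])
    sa2 = float(np.asarray(res.cov_re)[0, 0])
    se2 = float(res.scale)
    se_mu = float(res.bse[0])
    if not all(np.isfinite([mu, sa2, se2, se_mu])) or se2 < 0 or sa2 < 0:
        raise FloatingPointError("REML produced non-finite estimates")
    return mu, float(np.sqrt(max(sa2, 0.0))), float(np.sqrt(se2)), se_mu


def fit_variance_components(
    data: AssayTable,
    method: str = "reml",
    ci: bool = True,
    ci_reps: int = 1000,
    seed: int = 0,
) -> VarianceComponents:
    """Estimate (mu, sigma_batch, sigma_within) from time-zero assay data.

    REML by default; ``method="moment"`` uses the closed-form unbalanced
    ANOVA estimator (also the fallback when REML fails).  The CI for mu is
    t-based with k-1 degrees of freedom; CIs for the two SDs are percentile
    intervals from a seeded parametric bootstrap of the fitted model.
    """
    batches = data.batches
    k = len(batches)
    if k < 2:
        raise DesignError("need >= 2 batches to separate variance components")
    n_i, means, ssw_i = _group_summaries(data)
    if (n_i < 2).any():
        raise DesignError("every batch needs >= 2 observations")

    values = data.df["value"].to_numpy()
    if np.allclose(values, values[0]):
        return VarianceComponents(
            mu=float(values[0]),
            sigma_batch=0.0,
            sigma_within=0.0,
            method="degenerate",
            degenerate=True,
        )

    used = method
    if method == "reml":
        try:
            mu, sa, se, se_mu = _reml_fit(data)
        except Exception:  # noqa: BLE001 - any optimizer failure falls back
            logger.warning("REML failed; falling back to moment estimator")
            used = "moment(fallback)"
            mu, sa, se = _moment_from_summaries(n_i, means, float(ssw_i.sum()))
            se_mu = float(np.sqrt((n_i**2 * (sa**2 + se**2 / n_i)).sum()) / n_i.sum())
    elif method == "moment":
        mu, sa, se = _moment_from_summaries(n_i, means, float(ssw_i.sum()))
        se_mu = float(np.sqrt((n_i**2 * (sa**2 + se**2 / n_i)).sum()) / n_i.sum())
    else:
        raise ValueError(f"unknown method {method!r}")

    ci_mu = ci_sa = ci_se = None
    if ci:
        tq = stats.t.ppf(0.975, k - 1)
        ci_mu = (mu - tq * se_mu, mu + tq * se_mu)
        rng = np.random.default_rng(seed)
        _, sa_b, se_b = _bootstrap_draws(mu, sa, se, n_i, ci_reps, rng)
        ci_sa = tuple(np.percentile(sa_b, [2.5, 97.5]))
        ci_se = tuple(np.percentile(se_b, [2.5, 97.5]))
    return VarianceComponents(
        mu=mu,
        sigma_batch=sa,
        sigma_within=se,
        ci_mu=ci_mu,
        ci_sigma_batch=ci_sa,
        ci_sigma_within=ci_se,
        method=used,
    )


def _bootstrap_draws(
    mu: float,
    sigma_batch: float,
    sigma_within: float,
    n_i: np.ndarray,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parametric-bootstrap draws of the moment estimates, vectorised.

    The moment estimator depends on the data only through the batch means
    (Gaussian) and the within-batch sum of squares (scaled chi-square,
    independent of the means), so replicates are simulated directly from
    those sufficient statistics instead of materialising every observation.
    """
    k = len(n_i)
    N = n_i.sum()
    means = mu + rng.normal(
        scale=np.sqrt(sigma_batch**2 + sigma_within**2 / n_i), size=(reps, k)
    )
    ssw = sigma_within**2 * rng.chisquare(df=N - k, size=reps)
    return _moment_from_summaries(n_i, means, ssw)


# ---------------------------------------------------------------------------
# Model-based capability


@dataclass(frozen=True)
class CapabilityResult:
    """Capability summary computed from variance-component estimates."""

    cp: float
    cpk: float
    k: float
    lcl: float
    ucl: float
    defect_lower: float
    defect_upper: float
    cpk_ci: tuple[float, float] | None = None
    vc: VarianceComponents | None = field(default=None, repr=False)


def model_cpk(
    vc: VarianceComponents,
    spec: SpecLimits,
    cpk_ci: tuple[float, float] | None = None,
) -> CapabilityResult:
    """Capability from the random-effects fit: sigma = sigma_total, mu = mu_hat.

    Control (capability) limits are mu +/- 3 sigma_total.
    """
    st = vc.sigma_total
    if st <= 0:
        raise ValidationError("sigma_total must be > 0 for capability analysis")
    cpk = natural_cpk(vc.mu, st, spec)
    lower, upper = defect_bounds(cpk)
    return CapabilityResult(
        cp=cp_index(st, spec),
        cpk=cpk,
        k=k_factor(vc.mu, spec),
        lcl=vc.mu - 3.0 * st,
        ucl=vc.mu + 3.0 * st,
        defect_lower=lower,
        defect_upper=upper,
        cpk_ci=cpk_ci,
        vc=vc,
    )


def bootstrap_cpk_ci(
    data: AssayTable,
    spec: SpecLimits,
    reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "reml",
) -> tuple[float, float]:
    """Percentile bootstrap CI for the model-based Cpk.

    Parametric bootstrap: batch effects and residuals are redrawn from the
    fitted one-way model on the observed design; each replicate is refit
    with the closed-form moment estimator and its Cpk recorded.
    """
    if reps < 100:
        raise ValidationError("reps must be >= 100")
    vc = fit_variance_components(data, method=method, ci=False)
    if vc.degenerate:
        raise ValidationError("degenerate data: no variability to bootstrap")
    n_i, _, _ = _group_summaries(data)
    rng = np.random.default_rng(seed)
    mu_b, sa_b, se_b = _bootstrap_draws(
        vc.mu, vc.sigma_batch, vc.sigma_within, n_i, reps, rng
    )
    st_b = np.hypot(sa_b, se_b)
    ok = st_b > 0
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d degenerate bootstrap replicates", dropped)
    cpk_b = np.minimum(
        (spec.usl - mu_b[ok]) / (3.0 * st_b[ok]),
        (mu_b[ok] - spec.lsl) / (3.0 * st_b[ok]),
    )
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(cpk_b, [tail, 100.0 - tail])
    return float(lo), float(hi)


def descriptive_stats(data: AssayTable, spec: SpecLimits) -> pd.DataFrame:
    """Per-batch n/min/max/mean/sd and natural Cpk (release-report table)."""
    rows = []
    for batch in data.batches:
        v = data.batch_values(batch)
        sd = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
        rows.append(
            {
                "batch_id": batch,
                "n": len(v),
                "min": float(v.min()),
                "max": float(v.max()),
                "mean": float(v.mean()),
                "sd": sd,
                "cpk": natural_cpk(float(v.mean()), sd, spec) if sd > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
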