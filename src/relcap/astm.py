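"""ASTM E2709-12 style acceptance regions for batch release.

Given a sample of n units from a batch, the batch is released when the data
demonstrate, with confidence C, that at least a proportion p (the coverage)
of the batch distribution lies inside the release limits [LRL, URL].  The
demonstration uses the Bergum-type confidence-region construction: the
joint level C is split sqrt(C) x sqrt(C) between a two-sided t-interval for
the batch mean and a one-sided chi-square upper bound for the batch SD, and
the conforming fraction is minimised over that rectangle.  For a normal
batch the minimum sits at the SD upper bound and at whichever mean endpoint
is farther from the centre of the limits, giving a closed form.

The practical deliverable is the acceptance-limit table: for each possible
sample mean, the largest sample SD that still releases the batch.  Plotted,
it is a symmetric dome over [LRL, URL] that vanishes at the limits and
widens with n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import ValidationError

__all__ = [
    "AcceptanceRegion",
    "BatchDecision",
    "min_conforming_fraction",
    "acceptance_region",
    "accept_batch",
    "simulate_operating_characteristic",
]


def _check_inputs(n: int, confidence: float, coverage: float | None, lrl: float, url: float):
    if n < 2:
        raise ValidationError("sample size n must be >= 2")
    if not (0 < confidence < 1):
        raise ValidationError("confidence must lie in (0, 1)")
    if coverage is not None and not (0 < coverage < 1):
        raise ValidationError("coverage must lie in (0, 1)")
    if not (lrl < url):
        raise ValidationError("release limits must satisfy lrl < url")


def _region_constants(n: int, confidence: float) -> tuple[float, float]:
    """(t multiplier for the mean, sigma inflation factor for the SD)."""
    root_c = np.sqrt(confidence)
    t_mult = float(stats.t.ppf(0.5 * (1.0 + root_c), n - 1))
    chi2_q = float(stats.chi2.ppf(1.0 - root_c, n - 1))
    return t_mult, np.sqrt((n - 1) / chi2_q)


def min_conforming_fraction(
    mean, sd, n: int, confidence: float, lrl: float, url: float
):
    """Lower confidence bound on the batch fraction inside [lrl, url].

    Vectorised over ``mean``/``sd``.  The bound minimises
    ``Phi((url-mu)/sigma) - Phi((lrl-mu)/sigma)`` over the joint confidence
    rectangle for (mu, sigma); the minimum is attained at the sigma upper
    bound and the mu endpoint farther from the interval centre.
    """
    _check_inputs(n, confidence, None, lrl, url)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValidationError("sd must be > 0")
    t_mult, s_infl = _region_constants(n, confidence)
    half = t_mult * sd / np.sqrt(n)
    sigma_max = s_infl * sd
    frac = np.inf
    for mu in (mean - half, mean + half):
        frac = np.minimum(
            frac,
            stats.norm.cdf((url - mu) / sigma_max)
            - stats.norm.cdf((lrl - mu) / sigma_max),
        )
    return float(frac) if np.ndim(frac) == 0 else frac


@dataclass(frozen=True)
class AcceptanceRegion:
    """Acceptance-limit table: max admissible sample SD per sample mean."""

    n: int
    confidence: float
    coverage: float
    lrl: float
    url: float
    means: np.ndarray = field(repr=False)
    s_max: np.ndarray = field(repr=False)

    def contains(self, mean: float, sd: float) -> bool:
        """Exact membership test (re-evaluates the criterion, no interpolation)."""
        return bool(
            min_conforming_fraction(
                mean, sd, self.n, self.confidence, self.lrl, self.url
            )
            >= self.coverage
        )


def acceptance_region(
    n: int,
    confidence: float,
    coverage: float,
    lrl: float,
    url: float,
    grid_points: int = 201,
) -> AcceptanceRegion:
    """Max sample SD meeting the release criterion, on an even mean grid.

    The criterion is monotone decreasing in the sample SD, so each s_max is
    found by bisection (tolerance 1e-7 in concentration units).
    """
    _check_inputs(n, confidence, coverage, lrl, url)
    if grid_points < 3:
        raise ValidationError("grid_points must be >= 3")
    means = np.linspace(lrl, url, grid_points)
    width = url - lrl
    tiny = 1e-12 * width
    s_max = np.zeros_like(means)
    for i, m in enumerate(means):
        if (
            min_conforming_fraction(m, tiny, n, confidence, lrl, url)
            < coverage
        ):
            continue  # even a vanishing SD fails: s_max = 0
        lo, hi = tiny, width
        while (
            min_conforming_fraction(m, hi, n, confidence, lrl, url) >= coverage
        ):  # only reachable for very low coverage demands
            lo, hi = hi, 2.0 * hi
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if min_conforming_fraction(m, mid, n, confidence, lrl, url) >= coverage:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-7:
                break
        s_max[i] = 0.5 * (lo + hi)
    return AcceptanceRegion(
        n=n,
        confidence=confidence,
        coverage=coverage,
        lrl=lrl,
        url=url,
        means=means,
        s_max=s_max,
    )


@dataclass(frozen=True)
class BatchDecision:
    """Release decision for one batch sample."""

    accept: bool
    fraction: float
    margin: float
    mean: float
    sd: float
    n: int


def accept_batch(
    values=None,
    *,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    confidence: float,
    coverage: float,
    lrl: float,
    url: float,
) -> BatchDecision:
    """Test one batch sample against the acceptance criterion.

    Pass either raw ``values`` or the summary triple ``(mean, sd, n)``.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValidationError("need >= 2 observations for a sample SD")
        mean, sd, n = float(v.mean()), float(v.std(ddof=1)), len(v)
    if mean is None or sd is None or n is None:
        raise ValidationError("provide values or all of (mean, sd, n)")
    frac = float(min_conforming_fraction(mean, sd, n, confidence, lrl, url))
    return BatchDecision(
        accept=frac >= coverage,
        fraction=frac,
        margin=frac - coverage,
        mean=mean,
        sd=sd,
        n=n,
    )


def simulate_operating_characteristic(
    true_mu: float,
    true_sigma: float,
    n: int,
    reps: int,
    seed: int,
    confidence: float,
    coverage: float,
    lrl: float,
    url: float,
) -> float:
    """Monte-Carlo acceptance probability for a given true batch (mu, sigma)."""
    _check_inputs(n, confidence, coverage, lrl, url)
    if reps < 1000:
        raise ValidationError("reps must be >= 1000")
    rng = np.random.default_rng(seed)
    samples = rng.normal(true_mu, true_sigma, size=(reps, n))
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    frac = min_conforming_fraction(means, sds, n, confidence, lrl, url)
    return float(np.mean(frac >= coverage))
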