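"""Synthetic manufacturing and stability data.

Emulates the data structure of a multi-batch drug-product study: k batches
whose time-zero content carries a normal batch effect (sigma_batch) on top
of within-batch/analytical noise (sigma_within), and a linear degradation
over the standard long-term sampling times 0, 3, 6, 9, 12 months with a
common mean slope and optional between-batch slope variation.

Default constants describe a well-controlled insulin solution process:
mean 1.4625 µg/mL against a 1.454 µg/mL label claim, batch SD 0.0016,
within-batch SD 0.0087 and degradation -8.708e-3 µg/mL per month.  The
default between-batch slope SD is 0: the per-batch slope spread seen in
such data is consistent with residual noise alone.

Random streams are split per stage and per batch with ``SeedSequence`` so
adding batches never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .astm import accept_batch
from .capability import fit_variance_components, model_cpk
from .datamodel import (
    AnalysisConfig,
    AssayTable,
    NumericalError,
    StabilityTable,
    ValidationError,
)
from .release import solve_expiry
from .stability import _ols_line

__all__ = ["ProcessScenario", "gen_time_zero", "gen_stability", "end_to_end_risk"]

ICH_TIMES = (0.0, 3.0, 6.0, 9.0, 12.0)


@dataclass(frozen=True)
class ProcessScenario:
    """True process and degradation parameters for data generation."""

    mu: float = 1.4625
    sigma_batch: float = 0.0016
    sigma_within: float = 0.0087
    slope_mean: float = -8.708e-3
    slope_sd_between_batch: float = 0.0
    times: tuple[float, ...] = ICH_TIMES
    n_batches: int = 3
    n_per_batch_t0: int = 24
    n_per_timepoint: int = 1
    seed: int = 12345

    def __post_init__(self) -> None:
        if min(self.sigma_batch, self.sigma_within, self.slope_sd_between_batch) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if 0.0 not in self.times:
            raise ValidationError("times must include 0")
        if min(self.n_batches, self.n_per_batch_t0, self.n_per_timepoint) < 1:
            raise ValidationError("counts must be >= 1")
        if len(self.times) < 2:
            raise ValidationError("need >= 2 sampling times")


def _stage_children(seed: int, stage: int, n: int) -> list[np.random.Generator]:
    stage_seq = np.random.SeedSequence(seed).spawn(4)[stage]
    return [np.random.default_rng(s) for s in stage_seq.spawn(n)]


def _batch_ids(n: int) -> list[str]:
    return [f"b{i + 1:02d}" for i in range(n)]


def gen_time_zero(scenario: ProcessScenario) -> AssayTable:
    """Simulate the time-zero release assays: y_ij = mu + a_i + e_ij."""
    rows = []
    rngs = _stage_children(scenario.seed, 0, scenario.n_batches)
    for batch, rng in zip(_batch_ids(scenario.n_batches), rngs):
        a_i = rng.normal(0.0, scenario.sigma_batch) if scenario.sigma_batch else 0.0
        eps = (
            rng.normal(0.0, scenario.sigma_within, size=scenario.n_per_batch_t0)
            if scenario.sigma_within
            else np.zeros(scenario.n_per_batch_t0)
        )
        for e in eps:
            rows.append((batch, scenario.mu + a_i + e))
    return AssayTable.from_records(rows)


def gen_stability(scenario: ProcessScenario) -> StabilityTable:
    """Simulate per-batch degradation lines over the scenario's times."""
    rows = []
    rngs = _stage_children(scenario.seed, 1, scenario.n_batches)
    times = np.repeat(scenario.times, scenario.n_per_timepoint)
    for batch, rng in zip(_batch_ids(scenario.n_batches), rngs):
        a_i = rng.normal(0.0, scenario.sigma_batch) if scenario.sigma_batch else 0.0
        b_i = (
            rng.normal(0.0, scenario.slope_sd_between_batch)
            if scenario.slope_sd_between_batch
            else 0.0
        )
        eps = (
            rng.normal(0.0, scenario.sigma_within, size=len(times))
            if scenario.sigma_within
            else np.zeros(len(times))
        )
        values = scenario.mu + a_i + (scenario.slope_mean + b_i) * times + eps
        rows.extend((batch, float(t), float(v)) for t, v in zip(times, values))
    return StabilityTable.from_records(rows)


@dataclass(frozen=True)
class RiskEstimate:
    """Operating characteristics of the full release procedure."""

    consumer_risk: float
    producer_risk: float
    n_released: int
    n_conforming: int
    n_failed_replicates: int
    mean_expiry_months: float


def end_to_end_risk(
    scenario: ProcessScenario,
    config: AnalysisConfig,
    reps: int = 200,
    seed: int = 0,
    n_new_batches: int = 3,
    n_sample: int = 10,
) -> RiskEstimate:
    """Simulate the whole pipeline and measure both release risks.

    Per replicate: simulate a study, run capability -> stability ->
    expiry-time inversion, then release ``n_new_batches`` fresh batches via
    the ASTM criterion against [LCL, UCL].  Consumer risk is the fraction of
    *released* batches whose true mean content at the solved expiry time is
    below the LSL; producer risk is the fraction of batches that would have
    conformed at expiry but were rejected.
    """
    if reps < 200:
        raise ValidationError("reps must be >= 200")
    spec = config.spec
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    released_bad = released = conforming = conforming_rejected = 0
    failed = 0
    expiries = []
    for r in range(reps):
        sub = replace(scenario, seed=int(rng.integers(2**31 - 1)))
        try:
            assays = gen_time_zero(sub)
            vc = fit_variance_components(assays, method="moment", ci=False)
            cap = model_cpk(vc, spec)
            stab = gen_stability(sub)
            pooled = _ols_line(
                "pooled",
                stab.df["time_months"].to_numpy(),
                stab.df["value"].to_numpy(),
            )
            try:
                T = solve_expiry(
                    spec,
                    cap.lcl,
                    min(pooled.b1, 0.0),
                    pooled.slope_se,
                    vc.sigma_total,
                    config.alpha_shelf,
                    pooled.df,
                    bracket=(0.01, config.horizon_months),
                )
            except NumericalError:
                # LRL never reaches LCL inside the horizon (e.g. no
                # degradation): the horizon itself is the expiry time
                T = config.horizon_months
        except Exception:  # noqa: BLE001 - a failed replicate is logged, not fatal
            failed += 1
            continue
        expiries.append(T)
        # fresh batches from the same process
        for a_i, mean_sample, sd_sample in _new_batch_samples(
            sub, rng, n_new_batches, n_sample
        ):
            true_mean_at_expiry = scenario.mu + a_i + scenario.slope_mean * T
            conforms = true_mean_at_expiry >= spec.lsl
            decision = accept_batch(
                mean=mean_sample,
                sd=sd_sample,
                n=n_sample,
                confidence=config.astm_confidence,
                coverage=config.astm_coverage,
                lrl=cap.lcl,
                url=cap.ucl,
            )
            if decision.accept:
                released += 1
                if not conforms:
                    released_bad += 1
            if conforms:
                conforming += 1
                if not decision.accept:
                    conforming_rejected += 1
    return RiskEstimate(
        consumer_risk=released_bad / released if released else 0.0,
        producer_risk=conforming_rejected / conforming if conforming else 0.0,
        n_released=released,
        n_conforming=conforming,
        n_failed_replicates=failed,
        mean_expiry_months=float(np.mean(expiries)) if expiries else float("nan"),
    )


def _new_batch_samples(scenario, rng, n_batches: int, n_sample: int):
    for _ in range(n_batches):
        a_i = rng.normal(0.0, scenario.sigma_batch) if scenario.sigma_batch else 0.0
        sample = scenario.mu + a_i + rng.normal(
            0.0, scenario.sigma_within, size=n_sample
        )
        yield a_i, float(sample.mean()), float(sample.std(ddof=1))
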