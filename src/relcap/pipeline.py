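"""Five-step release pipeline: capability -> stability -> release -> ASTM.

1. Verify the manufacturing process is under statistical control and
   capable (model-based Cpk above a floor, default 1.33).
2. Set the capability limits mu +/- 3 sigma_total.
3. Analyse stability: per-batch and pooled fits, ICH poolability, shelf
   lives by both the confidence-band and prediction-band definitions.
4. Pin the lower release limit to the lower capability limit and invert
   the release-limit equation for the expiry time.
5. Build the ASTM acceptance region for the release limits and test any
   candidate batches against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .astm import AcceptanceRegion, BatchDecision, accept_batch, acceptance_region
from .capability import (
    CapabilityResult,
    bootstrap_cpk_ci,
    descriptive_stats,
    fit_variance_components,
    model_cpk,
)
from .datamodel import (
    AnalysisConfig,
    AssayTable,
    CapabilityFailure,
    StabilityTable,
)
from .release import ReleasePlan, plan_release
from .stability import StabilityReport, stability_analysis

logger = logging.getLogger("relcap")

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineReport:
    """Combined report of the five-step procedure."""

    capability: CapabilityResult
    batch_stats: pd.DataFrame = field(repr=False)
    stability: StabilityReport
    release: ReleasePlan
    astm_region: AcceptanceRegion
    astm_decisions: dict[str, BatchDecision]
    warnings: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        from .io import to_jsonable

        d = {
            "schema_version": 1,
            "capability": to_jsonable(self.capability),
            "batch_stats": to_jsonable(self.batch_stats),
            "stability": {
                "batch_fits": to_jsonable(self.stability.batch_fits),
                "ancova": to_jsonable(self.stability.ancova.table.reset_index()),
                "pooled": {
                    "alpha0": self.stability.pooled.alpha0,
                    "beta0": self.stability.pooled.beta0,
                    "alpha_dev": self.stability.pooled.alpha_dev,
                    "beta_dev": self.stability.pooled.beta_dev,
                    "rsd": self.stability.pooled.rsd,
                    "df_resid": self.stability.pooled.df_resid,
                    "single_line": to_jsonable(self.stability.pooled.single_line),
                },
                "decision": self.stability.decision,
                "t_ich": to_jsonable(self.stability.t_ich),
                "t_pred": to_jsonable(self.stability.t_pred),
                "critical_alpha": to_jsonable(self.stability.critical),
            },
            "release": to_jsonable(self.release),
            "astm": {
                "n": self.astm_region.n,
                "confidence": self.astm_region.confidence,
                "coverage": self.astm_region.coverage,
                "lrl": self.astm_region.lrl,
                "url": self.astm_region.url,
                "region": [
                    {"mean": float(m), "s_max": float(s)}
                    for m, s in zip(self.astm_region.means, self.astm_region.s_max)
                ],
                "decisions": to_jsonable(self.astm_decisions),
            },
            "warnings": list(self.warnings),
            "provenance": to_jsonable(self.provenance),
        }
        return d

    def to_text(self) -> str:
        cap, rel, stab = self.capability, self.release, self.stability
        lines = [
            "Release-limit analysis report",
            "=============================",
            f"Model-based Cpk: {cap.cpk:.3f}"
            + (
                f"  (95% CI [{cap.cpk_ci[0]:.2f}, {cap.cpk_ci[1]:.2f}])"
                if cap.cpk_ci
                else ""
            ),
            f"Capability limits (mu +/- 3 sigma): [{cap.lcl:.4f}, {cap.ucl:.4f}]",
            f"Poolability decision: {stab.decision}",
            f"Shelf life T_ICH: {stab.t_ich.t_months:.2f} months"
            f" ({stab.t_ich.basis})",
            f"Shelf life (prediction band): {stab.t_pred.t_months:.2f} months",
            f"Release interval [LRL, URL]: [{rel.lrl:.4f}, {rel.url:.4f}]",
            f"Expiry time (LRL = LCL): {rel.expiry_t:.2f} months",
        ]
        if self.astm_decisions:
            lines.append("ASTM batch decisions:")
            for batch, d in self.astm_decisions.items():
                verdict = "ACCEPT" if d.accept else "REJECT"
                lines.append(
                    f"  {batch}: {verdict}  (conforming fraction >= "
                    f"{d.fraction:.4f}, margin {d.margin:+.4f})"
                )
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines) + "\n"


def run_pipeline(
    assays: AssayTable,
    stability_data: StabilityTable,
    config: AnalysisConfig,
    new_batches: AssayTable | None = None,
) -> PipelineReport:
    """Execute the five steps in order and return a combined report.

    Raises :class:`CapabilityFailure` when the model-based Cpk is below
    ``config.cpk_floor``: an incapable process leaves no room to trade
    capability against degradation, so the later steps are meaningless.
    """
    warnings_: list[str] = []
    spec = config.spec

    vc = fit_variance_components(assays, ci=True, seed=config.seed)
    cpk_ci = bootstrap_cpk_ci(
        assays, spec, reps=config.bootstrap_reps, seed=config.seed
    )
    cap = model_cpk(vc, spec, cpk_ci=cpk_ci)
    if cap.cpk < config.cpk_floor:
        raise CapabilityFailure(
            f"model-based Cpk {cap.cpk:.3f} is below the floor "
            f"{config.cpk_floor}: process not capable enough for release-limit "
            "analysis"
        )
    if cap.lcl < spec.lsl or cap.ucl > spec.usl:
        warnings_.append(
            "capability limits extend beyond the specification interval; "
            "the release interval cannot guarantee conforming batches"
        )

    stab = stability_analysis(
        stability_data,
        spec,
        alpha_shelf=config.alpha_shelf,
        alpha_pool=config.alpha_pool,
        beta_power=config.beta_power,
        delta_slope=config.delta_slope,
        horizon=config.horizon_months,
    )
    if stab.decision == "separate":
        warnings_.append(
            "batches are NOT poolable: shelf lives use the worst batch; "
            "review the process before setting release limits"
        )
    line = stab.pooled.single_line
    slope = min(line.b1, 0.0)
    if line.b1 > 0:
        warnings_.append("pooled slope is positive; treated as no degradation")
    rel = plan_release(
        cap,
        spec,
        slope=slope,
        slope_se=line.slope_se,
        s_process=vc.sigma_total,
        alpha=config.alpha_shelf,
        df=line.df,
        bracket=(0.01, config.horizon_months),
    )

    region = acceptance_region(
        config.astm_n,
        config.astm_confidence,
        config.astm_coverage,
        rel.lrl,
        rel.url,
    )
    decisions: dict[str, BatchDecision] = {}
    if new_batches is not None:
        for batch in new_batches.batches:
            decisions[batch] = accept_batch(
                new_batches.batch_values(batch),
                confidence=config.astm_confidence,
                coverage=config.astm_coverage,
                lrl=rel.lrl,
                url=rel.url,
            )

    import numpy as np
    import scipy
    import statsmodels

    provenance = {
        "relcap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "seed": config.seed,
        "config": {
            "label_conc": spec.label_conc,
            "lower_frac": spec.lower_frac,
            "upper_frac": spec.upper_frac,
            "alpha_shelf": config.alpha_shelf,
            "alpha_pool": config.alpha_pool,
            "beta_power": config.beta_power,
            "astm_confidence": config.astm_confidence,
            "astm_coverage": config.astm_coverage,
            "bootstrap_reps": config.bootstrap_reps,
            "cpk_floor": config.cpk_floor,
            "horizon_months": config.horizon_months,
            "astm_n": config.astm_n,
            "delta_slope": config.delta_slope,
        },
    }
    return PipelineReport(
        capability=cap,
        batch_stats=descriptive_stats(assays, spec),
        stability=stab,
        release=rel,
        astm_region=region,
        astm_decisions=decisions,
        warnings=warnings_,
        provenance=provenance,
    )
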