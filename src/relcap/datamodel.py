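"""Core domain types shared by every analysis stage.

The workflow couples three inputs: a time-zero release-assay table
(drug concentration by batch), a long-term stability table (concentration
by batch and storage time) and an analytical calibration table.  All
concentrations are carried in the unit of the input data (µg/mL for the
insulin data the defaults describe) and times are in months; no unit
conversion is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class RelcapError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RelcapError):
    """An input file is malformed (missing column, unparseable number)."""


class ValidationError(RelcapError):
    """Parsed data violates a documented invariant."""


class DesignError(RelcapError):
    """The experimental design cannot support the requested estimate."""


class NumericalError(RelcapError):
    """A numerical routine failed (no bracket, no convergence)."""


class CapabilityFailure(RelcapError):
    """The process capability is below the configured floor."""


@dataclass(frozen=True)
class SpecLimits:
    """Registered specification interval for drug content.

    The limits are derived from the labeled concentration and two
    dimensionless fractions, e.g. 95%/105% of label claim.
    """

    label_conc: float
    lower_frac: float = 0.95
    upper_frac: float = 1.05

    def __post_init__(self) -> None:
        if not (self.label_conc > 0 and np.isfinite(self.label_conc)):
            raise ValidationError("label_conc must be a positive finite number")
        if not (0 < self.lower_frac < self.upper_frac):
            raise ValidationError(
                "specification fractions must satisfy 0 < lower_frac < upper_frac "
                f"(got {self.lower_frac}, {self.upper_frac})"
            )

    @property
    def lsl(self) -> float:
        return self.label_conc * self.lower_frac

    @property
    def usl(self) -> float:
        return self.label_conc * self.upper_frac

    @property
    def center(self) -> float:
        return 0.5 * (self.lsl + self.usl)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.usl - self.lsl)


def _as_clean_frame(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    out = df.loc[:, list(columns)].reset_index(drop=True)
    out["batch_id"] = out["batch_id"].astype(str)
    return out


@dataclass(frozen=True)
class AssayTable:
    """Time-zero release-assay results: one concentration per vial, by batch."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = _as_clean_frame(self.df, ["batch_id", "value"])
        if len(df) == 0:
            raise ValidationError("assay table has no records")
        if (df["batch_id"].str.len() == 0).any():
            raise ValidationError("batch_id must be a non-empty string")
        values = pd.to_numeric(df["value"], errors="raise").astype(float)
        if not np.isfinite(values).all() or (values <= 0).any():
            raise ValidationError("assay values must be finite and > 0")
        df["value"] = values
        object.__setattr__(self, "df", df)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, float]]) -> "AssayTable":
        return cls(pd.DataFrame(records, columns=["batch_id", "value"]))

    @property
    def batches(self) -> list[str]:
        return sorted(self.df["batch_id"].unique())

    @property
    def n(self) -> int:
        return len(self.df)

    def batch_values(self, batch_id: str) -> np.ndarray:
        return self.df.loc[self.df["batch_id"] == batch_id, "value"].to_numpy()

    def subset(self, batch_ids: Sequence[str]) -> "AssayTable":
        keep = self.df["batch_id"].isin([str(b) for b in batch_ids])
        return AssayTable(self.df.loc[keep])


@dataclass(frozen=True)
class StabilityTable:
    """Long-term stability results: concentration by batch and time (months)."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = _as_clean_frame(self.df, ["batch_id", "time_months", "value"])
        if len(df) == 0:
            raise ValidationError("stability table has no records")
        times = pd.to_numeric(df["time_months"], errors="raise").astype(float)
        values = pd.to_numeric(df["value"], errors="raise").astype(float)
        if not np.isfinite(times).all() or (times < 0).any():
            raise ValidationError("times must be finite and >= 0 months")
        if not np.isfinite(values).all():
            raise ValidationError("stability values must be finite")
        df["time_months"], df["value"] = times, values
        for batch, sub in df.groupby("batch_id"):
            if sub["time_months"].nunique() < 2:
                raise ValidationError(
                    f"batch {batch!r} has fewer than 2 distinct time points"
                )
        object.__setattr__(self, "df", df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float, float]]
    ) -> "StabilityTable":
        return cls(
            pd.DataFrame(records, columns=["batch_id", "time_months", "value"])
        )

    @property
    def batches(self) -> list[str]:
        return sorted(self.df["batch_id"].unique())

    @property
    def n(self) -> int:
        return len(self.df)

    def batch_frame(self, batch_id: str) -> pd.DataFrame:
        sub = self.df[self.df["batch_id"] == batch_id]
        if len(sub) == 0:
            raise ValidationError(f"batch {batch_id!r} not present")
        return sub


_LEVEL_FIELDS = (
    "alpha_shelf",
    "alpha_pool",
    "beta_power",
    "astm_confidence",
    "astm_coverage",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable levels and sizes of the five-step release-limit procedure.

    Defaults follow common practice for drug-product stability work:
    one-sided 5% for shelf-life bands, 25% for ICH poolability testing,
    10% type-II error for the critical-alpha power calculation, and a
    90%-confidence / 95%-coverage ASTM E2709-12 region.
    """

    spec: SpecLimits
    alpha_shelf: float = 0.05
    alpha_pool: float = 0.25
    beta_power: float = 0.10
    astm_confidence: float = 0.90
    astm_coverage: float = 0.95
    bootstrap_reps: int = 2000
    seed: int = 12345
    cpk_floor: float = 1.33
    horizon_months: float = 60.0
    astm_n: int = 10
    delta_slope: float | None = None

    def __post_init__(self) -> None:
        for name in _LEVEL_FIELDS:
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.bootstrap_reps < 100:
            raise ValidationError("bootstrap_reps must be >= 100")
        if self.horizon_months <= 0:
            raise ValidationError("horizon_months must be > 0")
        if self.astm_n < 2:
            raise ValidationError("astm_n must be >= 2")

    def with_spec(self, spec: SpecLimits) -> "AnalysisConfig":
        return replace(self, spec=spec)
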