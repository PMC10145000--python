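"""CSV readers/writers and flat key=value config parsing.

Dialect: comma-separated, UTF-8, mandatory header, '.' decimal separator.
Extra columns are ignored with a logged warning; unknown config keys warn
rather than fail, so configs stay forward compatible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import (
    AnalysisConfig,
    AssayTable,
    FormatError,
    SpecLimits,
    StabilityTable,
)

logger = logging.getLogger("relcap")


def _read_csv(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no records") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, ", ".join(extra))
    if len(df) == 0:
        raise FormatError(f"{path}: no records")
    for col in numeric:
        parsed = np.empty(len(df), dtype=float)
        # row-wise float(): correctly-rounded parsing plus exact line numbers
        for i, raw in enumerate(df[col].tolist()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                raise FormatError(
                    f"{path}: empty value in column {col!r} at line {i + 2}"
                )
            try:
                parsed[i] = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {raw!r} in column {col!r} "
                    f"at line {i + 2}"
                ) from None
        df[col] = parsed
    return df[required]


def read_assay_csv(path: str | Path) -> AssayTable:
    """Read a time-zero assay table (columns ``batch_id,value``)."""
    return AssayTable(_read_csv(path, ["batch_id", "value"], ["value"]))


def write_assay_csv(table: AssayTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_stability_csv(path: str | Path) -> StabilityTable:
    """Read a stability table (columns ``batch_id,time_months,value``)."""
    return StabilityTable(
        _read_csv(path, ["batch_id", "time_months", "value"], ["time_months", "value"])
    )


def write_stability_csv(table: StabilityTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a calibration table (columns ``concentration,response``)."""
    df = _read_csv(
        path, ["concentration", "response"], ["concentration", "response"]
    )
    return df["concentration"].to_numpy(), df["response"].to_numpy()


_CONFIG_FLOAT_KEYS = {
    "label_conc",
    "lower_frac",
    "upper_frac",
    "alpha_shelf",
    "alpha_pool",
    "beta_power",
    "astm_confidence",
    "astm_coverage",
    "cpk_floor",
    "horizon_months",
    "delta_slope",
}
_CONFIG_INT_KEYS = {"bootstrap_reps", "seed", "astm_n"}


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse a flat ``key = value`` config file into an :class:`AnalysisConfig`.

    Unset keys take their documented defaults; the specification limits are
    computed from ``label_conc`` and the two fractions.  Unknown keys are
    logged and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    raw: dict[str, Any] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = stripped.partition("=")
        key, value = key.strip(), value.strip()
        if key in _CONFIG_FLOAT_KEYS:
            try:
                raw[key] = float(value)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value for {key!r}"
                ) from None
        elif key in _CONFIG_INT_KEYS:
            try:
                raw[key] = int(value)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer value for {key!r}"
                ) from None
        else:
            logger.warning("%s:%d: unknown config key %r ignored", path, lineno, key)
    spec = SpecLimits(
        label_conc=raw.pop("label_conc", 1.454),
        lower_frac=raw.pop("lower_frac", 0.95),
        upper_frac=raw.pop("upper_frac", 1.05),
    )
    return AnalysisConfig(spec=spec, **raw)


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy / pandas objects to JSON types."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return to_jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def dump_report(report: Any, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(to_jsonable(report), indent=2, sort_keys=False) + "\n",
        encoding="utf-8",
    )
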