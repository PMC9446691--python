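"""Readers and writers for panels, death records, results and configs.

All tables are delimited text (comma by default, tab accepted), dates are
ISO-8601 strings in files and proper datetimes in memory. Readers validate
and reject rather than silently coerce: every error message carries the
(1-based, header-exclusive) row number and the offending field.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .config import (
    CAUSE_CLASSES,
    DEFAULT_COVARIATE_LEVELS,
    AnalysisConfig,
    ConfigError,
    SimulationConfig,
)
from .simulate import SimTruth

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("date", "region", "pm25", "o3", "no2", "temperature", "humidity")
DEATH_COLUMNS = (
    "event_date",
    "region",
    "cause_class",
    "sex",
    "race",
    "age_group",
    "education",
    "urbanicity",
)
RESULT_COLUMNS = (
    "model",
    "pollutant",
    "percent_increase",
    "ci_low",
    "ci_high",
    "p_value",
    "n_strata",
    "n_cases",
)

_DELIMS = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}

#: Daily pollutant concentrations must be nonnegative; humidity too.
_NONNEGATIVE_PANEL_FIELDS = ("pm25", "o3", "no2", "humidity")


class TableFormatError(ValueError):
    """Malformed input table; message carries row numbers and fields."""


def _delim(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise TableFormatError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'") from None


def _parse_dates(raw: pd.Series, field: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        rows = [f"row {i + 1}: {field}={raw.iloc[i]!r}" for i in np.nonzero(bad.to_numpy())[0][:5]]
        raise TableFormatError(f"non-ISO dates in column {field!r}: " + "; ".join(rows))
    if parsed.isna().any():
        i = int(np.nonzero(parsed.isna().to_numpy())[0][0])
        raise TableFormatError(f"row {i + 1}: missing value in field {field!r}")
    return parsed


def _parse_floats(raw: pd.Series, field: str, nonnegative: bool = False) -> pd.Series:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna()
    if bad.any():
        rows = [f"row {i + 1}: {field}={raw.iloc[i]!r}" for i in np.nonzero(bad.to_numpy())[0][:5]]
        raise TableFormatError(f"unparseable values in column {field!r}: " + "; ".join(rows))
    # numpy's parser is correctly rounded (write -> read round-trips exactly)
    vals = pd.Series(raw.to_numpy().astype(np.float64), index=raw.index)
    if nonnegative and (vals < 0).any():
        i = int(np.nonzero((vals < 0).to_numpy())[0][0])
        raise TableFormatError(f"row {i + 1}: negative value in field {field!r}: {vals.iloc[i]}")
    return vals.astype(float)


def _read_raw(path, columns, dialect) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delim(dialect), dtype=str, keep_default_na=True)
    missing = set(columns) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_panel(path, dialect: str = "comma") -> pd.DataFrame:
    """Read and validate a daily exposure panel.

    Raises :class:`TableFormatError` on missing columns, unparseable values
    (row-numbered), negative pollutant/humidity values, or duplicate
    (date, region) keys.
    """
    raw = _read_raw(path, PANEL_COLUMNS, dialect)
    if raw.empty:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "date" else object) for c in PANEL_COLUMNS})
    out = pd.DataFrame({"date": _parse_dates(raw["date"], "date"), "region": raw["region"].astype(object)})
    if out["region"].isna().any():
        i = int(np.nonzero(out["region"].isna().to_numpy())[0][0])
        raise TableFormatError(f"row {i + 1}: missing value in field 'region'")
    for c in PANEL_COLUMNS[2:]:
        out[c] = _parse_floats(raw[c], c, nonnegative=c in _NONNEGATIVE_PANEL_FIELDS)
    dup = out.duplicated(subset=["date", "region"])
    if dup.any():
        i = int(np.nonzero(dup.to_numpy())[0][0])
        key = (out["date"].iloc[i].date().isoformat(), out["region"].iloc[i])
        raise TableFormatError(f"duplicate (date, region) key {key} at row {i + 1}")
    return out.sort_values(["date", "region"], kind="stable").reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path, dialect: str = "comma") -> None:
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[list(PANEL_COLUMNS)].to_csv(path, sep=_delim(dialect), index=False)


def read_deaths(
    path,
    dialect: str = "comma",
    covariate_levels: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Read and validate death records.

    ``cause_class`` must come from the closed vocabulary; categorical
    covariates are checked against ``covariate_levels`` (defaults to the
    package-wide level sets) and unknown levels raise an error listing the
    allowed ones.
    """
    levels = {k: tuple(v) for k, v in (covariate_levels or DEFAULT_COVARIATE_LEVELS).items()}
    raw = _read_raw(path, DEATH_COLUMNS, dialect)
    if raw.empty:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "event_date" else object) for c in DEATH_COLUMNS})
    out = pd.DataFrame({"event_date": _parse_dates(raw["event_date"], "event_date")})
    out["region"] = raw["region"].astype(object)
    cause = raw["cause_class"]
    bad = ~cause.isin(CAUSE_CLASSES)
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise TableFormatError(
            f"row {i + 1}: unknown cause_class {cause.iloc[i]!r}; allowed: {list(CAUSE_CLASSES)}"
        )
    out["cause_class"] = cause.astype(object)
    for cov, allowed in levels.items():
        if cov not in raw.columns:
            continue
        vals = raw[cov]
        bad = ~vals.isin(allowed)
        if bad.any():
            i = int(np.nonzero(bad.to_numpy())[0][0])
            raise TableFormatError(
                f"row {i + 1}: unknown {cov} level {vals.iloc[i]!r}; allowed: {list(allowed)}"
            )
        out[cov] = vals.astype(object)
    return out


def write_deaths(deaths: pd.DataFrame, path, dialect: str = "comma") -> None:
    out = deaths.copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    out[list(DEATH_COLUMNS)].to_csv(path, sep=_delim(dialect), index=False)


def map_icd10_to_cause_class(codes: Iterable[str], nafld_codes: Iterable[str] = ()) -> list[str]:
    """Map raw ICD-10 strings to the analysis cause classes.

    I00-I99 -> cardiovascular, J00-J99 -> respiratory; membership in the
    (config-supplied) ``nafld_codes`` set -> nafld_control; anything else is
    an all-cause component.
    """
    nafld = {c.upper().strip() for c in nafld_codes}
    out = []
    for code in codes:
        c = str(code).upper().strip()
        if c in nafld:
            out.append("nafld_control")
        elif c[:1] == "I" and c[1:3].isdigit():
            out.append("cardiovascular")
        elif c[:1] == "J" and c[1:3].isdigit():
            out.append("respiratory")
        else:
            out.append("all_cause_component")
    return out


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, dialect: str = "comma") -> list[Path]:
    """Write one delimited result file per model family; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for family, df in tables.items():
        missing = set(RESULT_COLUMNS) - set(df.columns)
        if missing:
            raise TableFormatError(f"results table {family!r}: missing columns {sorted(missing)}")
        path = out_dir / f"{family}.csv"
        df[list(RESULT_COLUMNS)].to_csv(path, sep=_delim(dialect), index=False)
        paths.append(path)
    return paths


def read_results(path, dialect: str = "comma") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delim(dialect))
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Config files (YAML key-value with schema validation)


def save_config(config, path) -> None:
    data = asdict(config)
    data["__type__"] = type(config).__name__
    for k in ("start_date", "end_date"):
        if k in data:
            data[k] = data[k].isoformat()
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path):
    """Load a SimulationConfig or AnalysisConfig from YAML; unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kind = data.pop("__type__", None)
    cls = {"SimulationConfig": SimulationConfig, "AnalysisConfig": AnalysisConfig}.get(kind)
    if cls is None:
        raise ConfigError(f"{path}: missing or unknown __type__ {kind!r}")
    import dataclasses

    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    for key in ("lag_windows", "weather_ma_window"):
        if key in data and data[key] is not None:
            if key == "weather_ma_window":
                data[key] = tuple(data[key])
            else:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
    if "pollutants" in data and data["pollutants"] is not None:
        data["pollutants"] = tuple(data["pollutants"])
    return cls(**data)


# ---------------------------------------------------------------------------
# SimTruth sidecar


def write_truth(truth: SimTruth, path) -> None:
    """Structured key-value sidecar; the realized U series is inlined as rows."""
    data = {
        "true_log_rr": {k: float(v) for k, v in truth.true_log_rr.items()},
        "seed": int(truth.seed),
        "exposure_centering": {k: float(v) for k, v in truth.exposure_centering.items()},
        "confounder": {
            "date": [pd.Timestamp(d).date().isoformat() for d in truth.confounder["date"]],
            "region": list(truth.confounder["region"]),
            "u": [float(v) for v in truth.confounder["u"]],
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    conf = pd.DataFrame(
        {
            "date": pd.to_datetime(data["confounder"]["date"]),
            "region": data["confounder"]["region"],
            "u": data["confounder"]["u"],
        }
    )
    return SimTruth(
        true_log_rr=data["true_log_rr"],
        confounder=conf,
        seed=data["seed"],
        exposure_centering=data.get("exposure_centering", {}),
    )


def configure_logging(level: int = logging.INFO) -> None:
    """Route package log output to stderr with the given level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("casecross")
    root.handlers[:] = [handler]
    root.setLevel(level)
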