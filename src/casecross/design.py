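"""Time-stratified case-crossover design construction.

The case-crossover design compares exposure on the day of death (the case
day) with exposure on referent days for the same person, so that every
covariate that is constant within the referent window — age, sex, smoking,
neighbourhood, season — is removed by matching. Referents here are
*time-stratified and bidirectional*: all calendar days in the same month and
year that share the case day's day of week, before and after the event.
Every month of length 28-31 yields exactly 3 or 4 referents per case.

Exposure enters the model through derived features (lags, moving averages,
leads, squares) declared in a :class:`FeatureSpec`; :func:`assemble_strata`
joins deaths to the daily panel and emits a :class:`StratumSet`, the packed
design consumed by the conditional-logistic fitter.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import POLLUTANTS, AnalysisConfig

logger = logging.getLogger(__name__)

_REFERENT_OFFSETS = np.array([-28, -21, -14, -7, 7, 14, 21, 28])


class DesignError(ValueError):
    """Invalid inputs to stratum construction."""


def select_referents(case_date: dt.date) -> list[dt.date]:
    """All same-weekday days in the case day's calendar month, case excluded.

    Pure calendar function; the result is sorted ascending and always has
    3 or 4 elements (months have 28-31 days, hence 4 or 5 same-weekday days).
    """
    if isinstance(case_date, (pd.Timestamp, dt.datetime)):
        case_date = case_date.date()
    out = []
    for off in (-28, -21, -14, -7, 7, 14, 21, 28):
        d = case_date + dt.timedelta(days=int(off))
        if d.month == case_date.month and d.year == case_date.year:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# Feature specification


@dataclass(frozen=True)
class Feature:
    """One derived column: a transform of a daily panel variable.

    transform is one of ``lag`` (value at date-k, param=k), ``ma``
    (unweighted mean over lags a..b, param=(a, b)), ``lead`` (value at
    date+k, param=k) or ``square_of`` (square of another feature,
    param=its label; source is ignored).
    """

    source: str
    transform: str
    param: object
    label: str


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered collection of features; labels must be unique."""

    features: tuple[Feature, ...]

    def __post_init__(self):
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise DesignError("FeatureSpec: duplicate feature labels")
        for f in self.features:
            if f.transform not in ("lag", "ma", "lead", "square_of"):
                raise DesignError(f"FeatureSpec: unknown transform {f.transform!r}")
            if f.transform in ("lag", "lead"):
                if not (isinstance(f.param, int) and f.param >= 0):
                    raise DesignError(f"{f.label}: lag/lead offset must be a nonnegative int")
            elif f.transform == "ma":
                a, b = f.param
                if not (isinstance(a, int) and isinstance(b, int) and 0 <= a <= b):
                    raise DesignError(f"{f.label}: ma window must be 0 <= a <= b")
            elif f.transform == "square_of":
                if f.param not in labels:
                    raise DesignError(f"{f.label}: square_of target {f.param!r} not in spec")

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    def __iter__(self):
        return iter(self.features)


def default_feature_spec(config: AnalysisConfig | None = None) -> FeatureSpec:
    """The final-model feature set.

    Per pollutant: the lag-window moving average and (optionally) the lead-1
    negative exposure control. Weather: same-day temperature, its square, the
    lag 1-3 temperature moving average; same-day humidity and its lag 1-3
    moving average.
    """
    config = config or AnalysisConfig()
    feats: list[Feature] = []
    for p in config.pollutants:
        a, b = config.lag_windows.get(p, (0, 2))
        feats.append(Feature(p, "ma", (a, b), config.ma_label(p)))
    if config.include_lead_controls:
        for p in config.pollutants:
            feats.append(Feature(p, "lead", config.lead_days, config.lead_label(p)))
    if config.temperature_terms:
        a, b = config.weather_ma_window
        feats.append(Feature("temperature", "lag", 0, "temp_lag0"))
        feats.append(Feature("temperature", "square_of", "temp_lag0", "temp_lag0_sq"))
        feats.append(Feature("temperature", "ma", (a, b), f"temp_ma{a}{b}"))
    if config.humidity_terms:
        a, b = config.weather_ma_window
        feats.append(Feature("humidity", "lag", 0, "humid_lag0"))
        feats.append(Feature("humidity", "ma", (a, b), f"humid_ma{a}{b}"))
    return FeatureSpec(tuple(feats))


# ---------------------------------------------------------------------------
# Feature computation on the daily panel


def _panel_wide(panel: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Pivot one variable to a (contiguous daily date) x region frame.

    Calendar gaps become NaN rows, so lag/lead shifts stay day-accurate.
    """
    wide = panel.pivot(index="date", columns="region", values=variable)
    full = pd.date_range(wide.index.min(), wide.index.max(), freq="D")
    return wide.reindex(full)


def compute_feature_table(panel: pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    """Feature matrix indexed by (date, region) for every panel day.

    Days whose lag/lead requirements fall outside panel coverage (or hit a
    gap) carry NaN in the affected feature; callers decide whether a NaN row
    disqualifies a case (stratum dropped) or a referent (row dropped).
    """
    wides: dict[str, pd.DataFrame] = {}
    out: dict[str, pd.DataFrame] = {}
    for f in spec:
        if f.transform == "square_of":
            out[f.label] = out[f.param] ** 2
            continue
        if f.source not in wides:
            wides[f.source] = _panel_wide(panel, f.source)
        w = wides[f.source]
        if f.transform == "lag":
            out[f.label] = w.shift(f.param)
        elif f.transform == "lead":
            out[f.label] = w.shift(-f.param)
        elif f.transform == "ma":
            a, b = f.param
            out[f.label] = w.shift(a).rolling(b - a + 1, min_periods=b - a + 1).mean()
    table = pd.concat({k: v.stack(future_stack=True) for k, v in out.items()}, axis=1)
    table = table[spec.labels]
    table.index.names = ["date", "region"]
    return table


def build_features(
    panel: pd.DataFrame, region: str, date, spec: FeatureSpec
) -> pd.Series:
    """Feature vector for one (region, date); NaN marks incomplete features."""
    date = pd.Timestamp(date)
    table = compute_feature_table(panel, spec)
    try:
        return table.loc[(date, region)]
    except KeyError:
        return pd.Series(np.nan, index=spec.labels, name=(date, region))


# ---------------------------------------------------------------------------
# Stratum container


@dataclass
class StratumSet:
    """Packed case-crossover design: all strata, rows contiguous per stratum.

    ``X`` holds one row per (case or referent) day; rows of stratum ``i``
    occupy ``starts[i] : starts[i] + counts[i]`` with the case row first.
    ``meta`` has one row per stratum (decedent): stratum_id, region,
    case_date, cause_class and the modifier covariates. ``aux`` carries
    per-row day-level pollutant concentrations (used by the low-exposure
    restriction, never by the likelihood).
    """

    X: np.ndarray
    feature_labels: list[str]
    starts: np.ndarray
    counts: np.ndarray
    row_dates: np.ndarray
    meta: pd.DataFrame
    aux: np.ndarray = None
    aux_labels: list[str] = field(default_factory=list)

    @property
    def n_strata(self) -> int:
        return len(self.starts)

    @property
    def n_cases(self) -> int:
        return len(self.starts)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def case_rows(self) -> np.ndarray:
        return self.starts

    @property
    def row_stratum(self) -> np.ndarray:
        """Stratum index of every row."""
        return np.repeat(np.arange(self.n_strata), self.counts)

    def select_features(self, labels: Sequence[str]) -> "StratumSet":
        """New StratumSet restricted to the given feature columns."""
        missing = [l for l in labels if l not in self.feature_labels]
        if missing:
            raise DesignError(f"unknown feature labels: {missing}")
        idx = [self.feature_labels.index(l) for l in labels]
        return replace(self, X=self.X[:, idx], feature_labels=list(labels))

    def with_feature(self, label: str, values: np.ndarray) -> "StratumSet":
        """New StratumSet with one extra per-row feature column appended."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_rows,):
            raise DesignError(f"with_feature: expected {self.n_rows} values")
        return replace(
            self,
            X=np.column_stack([self.X, values]),
            feature_labels=self.feature_labels + [label],
        )

    def subset(self, stratum_mask: np.ndarray) -> "StratumSet":
        """New StratumSet keeping only strata where mask is True."""
        stratum_mask = np.asarray(stratum_mask, dtype=bool)
        if stratum_mask.shape != (self.n_strata,):
            raise DesignError("subset: mask length != n_strata")
        row_mask = np.repeat(stratum_mask, self.counts)
        counts = self.counts[stratum_mask]
        starts = (np.cumsum(counts) - counts).astype(np.int64)
        return replace(
            self,
            X=self.X[row_mask],
            starts=starts,
            counts=counts,
            row_dates=self.row_dates[row_mask],
            meta=self.meta.loc[stratum_mask].reset_index(drop=True),
            aux=self.aux[row_mask] if self.aux is not None else None,
        )

    def informative_mask(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """True for strata where at least one selected feature varies across rows."""
        labels = labels or self.feature_labels
        idx = [self.feature_labels.index(l) for l in labels]
        Xs = self.X[:, idx]
        hi = np.maximum.reduceat(Xs, self.starts, axis=0)
        lo = np.minimum.reduceat(Xs, self.starts, axis=0)
        return ((hi - lo) > 1e-12).any(axis=1)


# ---------------------------------------------------------------------------
# Assembly

_AUX_VARS = list(POLLUTANTS)


def assemble_strata(
    deaths: pd.DataFrame,
    panel: pd.DataFrame,
    spec: FeatureSpec,
) -> StratumSet:
    """Build one case-crossover stratum per usable death record.

    Dropping rules (missing data is never imputed):

    * a referent row with any incomplete feature is dropped individually;
    * a death whose *case* row is incomplete is dropped (logged with count);
    * a stratum left with no referent is dropped;
    * a stratum in which every feature is constant across rows is dropped as
      non-informative (it contributes nothing to the conditional likelihood).

    Raises :class:`DesignError` if deaths reference regions absent from the
    panel.
    """
    if deaths.empty:
        raise DesignError("no death records supplied")
    panel_regions = set(panel["region"].unique())
    bad = sorted(set(deaths["region"].unique()) - panel_regions)
    if bad:
        raise DesignError(f"death records reference regions absent from panel: {bad}")

    table = compute_feature_table(panel, spec)
    # day-level pollutant values for the low-exposure restriction
    aux_spec = FeatureSpec(tuple(Feature(v, "lag", 0, f"__day_{v}") for v in _AUX_VARS))
    aux_table = compute_feature_table(panel, aux_spec)

    deaths = deaths.reset_index(drop=True)
    case_dates = pd.to_datetime(deaths["event_date"]).to_numpy().astype("datetime64[D]")
    n = len(deaths)

    # candidate rows: case day (offset 0) + the eight +-k*7 offsets filtered
    # to the case month
    offsets = np.concatenate([[0], _REFERENT_OFFSETS])
    cand = case_dates[:, None] + offsets[None, :].astype("timedelta64[D]")
    same_month = (cand.astype("datetime64[M]") == case_dates[:, None].astype("datetime64[M]"))
    stratum_idx, off_idx = np.nonzero(same_month)
    row_dates = cand[stratum_idx, off_idx]
    is_case = off_idx == 0

    rows = pd.DataFrame(
        {
            "stratum": stratum_idx,
            "date": row_dates.astype("datetime64[ns]"),
            "region": deaths["region"].to_numpy()[stratum_idx],
            "is_case": is_case,
        }
    )
    rows = rows.join(table, on=["date", "region"])
    rows = rows.join(aux_table, on=["date", "region"])

    feat_cols = spec.labels
    complete = rows[feat_cols].notna().all(axis=1).to_numpy()

    case_complete = np.zeros(n, dtype=bool)
    case_complete[rows.loc[rows["is_case"].to_numpy() & complete, "stratum"]] = True
    n_dropped_case = int(n - case_complete.sum())
    if n_dropped_case:
        logger.info(
            "assemble_strata: dropped %d of %d deaths with feature-incomplete case days",
            n_dropped_case,
            n,
        )

    keep_rows = complete & case_complete[rows["stratum"].to_numpy()]
    rows = rows.loc[keep_rows]

    # strata need at least one surviving referent
    ref_counts = np.bincount(
        rows.loc[~rows["is_case"], "stratum"].to_numpy(), minlength=n
    )
    ok = case_complete & (ref_counts >= 1)
    n_no_ref = int(case_complete.sum() - ok.sum())
    if n_no_ref:
        logger.info("assemble_strata: dropped %d strata left without referents", n_no_ref)
    rows = rows.loc[ok[rows["stratum"].to_numpy()]]
    if rows.empty:
        raise DesignError("no usable strata: all deaths feature-incomplete")

    # order: stratum, case first, then referents by date
    rows = rows.sort_values(
        ["stratum", "is_case", "date"], ascending=[True, False, True], kind="stable"
    )
    strat = rows["stratum"].to_numpy()
    uniq, starts_pos, counts = np.unique(strat, return_index=True, return_counts=True)

    X = rows[feat_cols].to_numpy(dtype=float)
    aux = rows[[f"__day_{v}" for v in _AUX_VARS]].to_numpy(dtype=float)

    meta_cols = [
        c
        for c in ("region", "cause_class", "sex", "race", "age_group", "education", "urbanicity")
        if c in deaths.columns
    ]
    meta = deaths.loc[uniq, meta_cols].reset_index(drop=True)
    meta.insert(0, "stratum_id", uniq)
    meta.insert(2, "case_date", pd.to_datetime(deaths.loc[uniq, "event_date"]).to_numpy())

    out = StratumSet(
        X=X,
        feature_labels=list(feat_cols),
        starts=(np.cumsum(counts) - counts).astype(np.int64),
        counts=counts.astype(np.int64),
        row_dates=rows["date"].to_numpy(),
        meta=meta,
        aux=aux,
        aux_labels=[f"day_{v}" for v in _AUX_VARS],
    )

    info = out.informative_mask()
    n_noninf = int((~info).sum())
    if n_noninf:
        logger.info("assemble_strata: dropped %d non-informative strata", n_noninf)
        out = out.subset(info)
    if out.n_strata == 0:
        raise DesignError("no informative strata remain")
    return out


def strata_to_frame(strata: StratumSet) -> pd.DataFrame:
    """Long-format view: (stratum_id, row_type, date, features...)."""
    srow = strata.row_stratum
    df = pd.DataFrame(strata.X, columns=strata.feature_labels)
    df.insert(0, "stratum_id", strata.meta["stratum_id"].to_numpy()[srow])
    is_case = np.zeros(strata.n_rows, dtype=bool)
    is_case[strata.starts] = True
    df.insert(1, "row_type", np.where(is_case, "case", "referent"))
    df.insert(2, "date", strata.row_dates)
    return df
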