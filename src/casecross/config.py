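"""Configuration objects for simulation and analysis.

Two dataclasses are defined here: :class:`SimulationConfig`, which fixes every
knob of the synthetic world (pollutant climatology, the planted effect sizes,
and the planted unmeasured confounder), and :class:`AnalysisConfig`, which
fixes the analysis model (pollutants, lag windows, weather terms, negative
exposure controls, reporting increments).

Both validate eagerly in ``__post_init__`` and raise :class:`ConfigError`
naming the offending field, so that downstream code never has to defend
against half-formed configuration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

POLLUTANTS = ("pm25", "o3", "no2")

#: Closed vocabulary of cause-of-death classes.
CAUSE_CLASSES = ("all_cause_component", "cardiovascular", "respiratory", "nafld_control")

#: Covariates carried on each death record, with their allowed levels.
#: Distributions below roughly match large US multi-state death-certificate
#: populations (majority female among decedents, ~77% aged 65+, ~75% urban).
DEFAULT_COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "race": ("white", "black", "other"),
    "age_group": ("le45", "45_65", "65_75", "ge75"),
    "education": ("lt_hs", "hs", "gt_hs"),
    "urbanicity": ("urban", "rural"),
}

DEFAULT_COVARIATE_PROBS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.469, "female": 0.531},
    "race": {"white": 0.872, "black": 0.108, "other": 0.020},
    "age_group": {"le45": 0.08, "45_65": 0.15, "65_75": 0.20, "ge75": 0.57},
    "education": {"lt_hs": 0.23, "hs": 0.49, "gt_hs": 0.28},
    "urbanicity": {"urban": 0.751, "rural": 0.249},
}

#: WHO Air Quality Guideline daily limits on the analysis units
#: (25 ug/m3 PM2.5; 100 ug/m3 O3 = 50 ppb; 200 ug/m3 NO2 = 106.4 ppb).
WHO_AQG_THRESHOLDS = {"pm25": 25.0, "o3": 50.0, "no2": 106.4}


class ConfigError(ValueError):
    """A configuration field failed validation; message names the field."""


def _as_date(value, name: str) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        try:
            return dt.date.fromisoformat(value)
        except ValueError as exc:
            raise ConfigError(f"{name}: not an ISO date: {value!r}") from exc
    raise ConfigError(f"{name}: expected a date, got {type(value).__name__}")


def _check_simplex(probs: Mapping[str, float], name: str) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-12:
        raise ConfigError(f"{name}: probabilities sum to {total!r}, not 1")
    for level, p in probs.items():
        if p < 0:
            raise ConfigError(f"{name}[{level}]: negative probability {p}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-region exposure/mortality world.

    Defaults define a desk-scale study: 50 regions x 3 years at a baseline of
    2 expected deaths per region-day (~110k deaths), with pollutant
    climatology (means, SDs, seasonality) matched to multi-state US daily
    surfaces: PM2.5 ~10 ug/m3, O3 ~38 ppb peaking in summer, NO2 ~21 ppb
    peaking in winter, temperature ~284 K, absolute humidity ~0.0073 g/cm3.

    ``true_log_rr`` are per-unit log rate ratios applied to the lag 0-2
    moving average of each pollutant; the default plants
    ``ln(1.0073)/10`` on PM2.5, i.e. a 0.73% increase per 10 ug/m3, and no
    effect for the gases.

    The unmeasured confounder U is a slow AR(1) series per region
    (``confounder_ar1`` default 0.9, weather-like persistence). It loads on
    every pollutant on the same day with ``confounder_exposure_loading`` and
    on the next day's pollutant with that loading times
    ``confounder_lead_loading_ratio`` (default 1: equal lag/lead loadings,
    the assumption under which the coefficient-difference correction is
    exact; set the ratio away from 1 to violate it). It loads on the log
    mortality rate with ``confounder_mortality_loading``, including the
    negative-control (NAFLD) rate, which carries no pollutant term.
    """

    n_regions: int = 50
    start_date: dt.date = dt.date(2010, 1, 1)
    end_date: dt.date = dt.date(2012, 12, 31)

    pollutant_means: dict[str, float] = field(
        default_factory=lambda: {"pm25": 10.4, "o3": 37.7, "no2": 21.2}
    )
    #: Seasonal (annual sinusoid) amplitudes; temperature included.
    seasonal_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"pm25": 2.0, "o3": 10.0, "no2": 4.0, "temperature": 12.0}
    )
    #: Day-of-year of the seasonal peak per series (O3 peaks midsummer,
    #: NO2 and PM2.5 in winter, temperature late July).
    seasonal_peak_doy: dict[str, float] = field(
        default_factory=lambda: {"pm25": 15.0, "o3": 200.0, "no2": 15.0, "temperature": 205.0}
    )
    ar1_coefficients: dict[str, float] = field(
        default_factory=lambda: {"pm25": 0.7, "o3": 0.6, "no2": 0.6, "temperature": 0.8}
    )
    cross_correlation: float = 0.4
    #: AR(1) innovation SDs (marginal SD = noise_sd / sqrt(1 - ar1^2)).
    noise_sds: dict[str, float] = field(
        default_factory=lambda: {
            "pm25": 3.5,
            "o3": 6.0,
            "no2": 6.5,
            "temperature": 2.5,
            "humidity": 0.0008,
        }
    )

    baseline_rate: float = 2.0
    true_log_rr: dict[str, float] = field(
        default_factory=lambda: {"pm25": 7.273483966498469e-4, "o3": 0.0, "no2": 0.0}
    )
    #: Winter-peaking annual sinusoid amplitude on the log mortality rate.
    mortality_seasonal_amplitude: float = 0.1

    confounder_sd: float = 1.0
    confounder_ar1: float = 0.9
    confounder_exposure_loading: float = 0.0
    confounder_mortality_loading: float = 0.0
    confounder_lead_loading_ratio: float = 1.0

    #: Cause-of-death mixture among pollutant-responsive deaths, and the
    #: multiplier applied to every pollutant log rate ratio for that cause
    #: (respiratory deaths respond more strongly than average).
    cause_shares: dict[str, float] = field(
        default_factory=lambda: {"cardiovascular": 0.344, "respiratory": 0.106}
    )
    cause_effect_multipliers: dict[str, float] = field(
        default_factory=lambda: {"cardiovascular": 1.1, "respiratory": 1.6}
    )

    covariate_category_probabilities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PROBS.items()}
    )
    #: Negative-control cause rate as a fraction of baseline_rate.
    nafld_fraction: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        self.start_date = _as_date(self.start_date, "start_date")
        self.end_date = _as_date(self.end_date, "end_date")
        if self.n_regions < 1:
            raise ConfigError("n_regions: must be >= 1")
        if (self.end_date - self.start_date).days <= 35:
            raise ConfigError(
                "end_date: date range too short; need end_date > start_date + 35 days "
                "(at least one full referent month)"
            )
        for p in POLLUTANTS:
            if p not in self.pollutant_means:
                raise ConfigError(f"pollutant_means: missing {p}")
            if p not in self.true_log_rr:
                raise ConfigError(f"true_log_rr: missing {p}")
        for name, rho in self.ar1_coefficients.items():
            if not (0.0 <= rho < 1.0):
                raise ConfigError(f"ar1_coefficients[{name}]: {rho} not in [0, 1)")
        if not (0.0 <= self.confounder_ar1 < 1.0):
            raise ConfigError(f"confounder_ar1: {self.confounder_ar1} not in [0, 1)")
        if not (-1.0 < self.cross_correlation < 1.0):
            raise ConfigError(f"cross_correlation: {self.cross_correlation} not in (-1, 1)")
        for name, sd in self.noise_sds.items():
            if sd < 0:
                raise ConfigError(f"noise_sds[{name}]: negative SD {sd}")
        if self.confounder_sd < 0:
            raise ConfigError(f"confounder_sd: negative SD {self.confounder_sd}")
        if self.baseline_rate <= 0:
            raise ConfigError(f"baseline_rate: must be > 0, got {self.baseline_rate}")
        if not (0.0 <= self.nafld_fraction <= 1.0):
            raise ConfigError(f"nafld_fraction: {self.nafld_fraction} not in [0, 1]")
        share_sum = sum(self.cause_shares.values())
        if share_sum > 1.0 + 1e-12:
            raise ConfigError(f"cause_shares: shares sum to {share_sum} > 1")
        for cov, probs in self.covariate_category_probabilities.items():
            _check_simplex(probs, f"covariate_category_probabilities[{cov}]")

    @property
    def dates(self) -> "pd.DatetimeIndex":  # noqa: F821 - lazy import
        import pandas as pd

        return pd.date_range(self.start_date, self.end_date, freq="D")

    @property
    def regions(self) -> list[str]:
        width = len(str(self.n_regions))
        return [f"R{i:0{width}d}" for i in range(1, self.n_regions + 1)]


@dataclass
class AnalysisConfig:
    """Model specification for the case-crossover analysis.

    The default reproduces the final model structure: per-pollutant lag 0-2
    moving averages, lead-1 negative exposure controls, same-day temperature
    with a quadratic term plus its lag 1-3 moving average, same-day humidity
    plus its lag 1-3 moving average, effects reported as the percent increase
    per 10-unit (ug/m3 or ppb) exposure increment.
    """

    pollutants: tuple[str, ...] = POLLUTANTS
    #: Inclusive (a, b) lag window of the exposure moving average, per pollutant.
    lag_windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {p: (0, 2) for p in POLLUTANTS}
    )
    include_lead_controls: bool = True
    lead_days: int = 1
    temperature_terms: bool = True
    humidity_terms: bool = True
    weather_ma_window: tuple[int, int] = (1, 3)
    increments: dict[str, float] = field(default_factory=lambda: {p: 10.0 for p in POLLUTANTS})
    low_exposure_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(WHO_AQG_THRESHOLDS)
    )
    subgroup_variable: str | None = None
    tol: float = 1e-8
    max_iter: int = 50

    def __post_init__(self) -> None:
        self.pollutants = tuple(self.pollutants)
        if not self.pollutants:
            raise ConfigError("pollutants: empty pollutant set")
        for p in self.pollutants:
            if p not in POLLUTANTS:
                raise ConfigError(f"pollutants: unknown pollutant {p!r}")
            a, b = self.lag_windows.get(p, (0, 2))
            if not (isinstance(a, int) and isinstance(b, int) and 0 <= a <= b):
                raise ConfigError(f"lag_windows[{p}]: invalid window {(a, b)!r}")
        if self.lead_days < 1:
            raise ConfigError("lead_days: must be >= 1")
        for p, inc in self.increments.items():
            if inc <= 0:
                raise ConfigError(f"increments[{p}]: must be > 0, got {inc}")
        for p, thr in self.low_exposure_thresholds.items():
            if thr <= 0:
                raise ConfigError(f"low_exposure_thresholds[{p}]: must be > 0, got {thr}")
        if self.tol <= 0:
            raise ConfigError("tol: must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter: must be >= 1")

    def ma_label(self, pollutant: str) -> str:
        a, b = self.lag_windows.get(pollutant, (0, 2))
        return f"{pollutant}_ma{a}{b}"

    def lead_label(self, pollutant: str) -> str:
        return f"{pollutant}_lead{self.lead_days}"


def _require_keys(mapping: Mapping, allowed: Sequence[str], context: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
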