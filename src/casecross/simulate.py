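"""Synthetic multi-region daily exposure and mortality generator.

Emulates the study's data-generating world with known ground truth:

* Pollutant series per region: annual sinusoidal mean plus AR(1) deviations
  whose innovations are correlated across the three pollutants, plus a
  loading on the planted unmeasured confounder U; floored at zero.
* Temperature: annual sinusoid + AR(1) noise. Absolute humidity: a
  Clausius-Clapeyron-like increasing exponential of same-day temperature
  plus noise (documented deterministic form), floored at a small positive.
* U: a slow AR(1) series per region (weather-like persistence) entering each
  pollutant at lag 0 and at lead 1 (coefficient ratio configurable) and the
  log mortality rate directly — the classic omitted time-varying confounder.
* Deaths: region-day counts are Poisson with log-rate
  ``log(baseline) + sum_p beta_p * (MA02_p - mean) + lambda_m * U + seasonal``,
  expanded to individual records with covariates drawn independently of
  day-within-month (subject covariates are stratum-constant by design).
  Cardiovascular/respiratory records come from parallel Poisson streams with
  configurable effect multipliers; the negative-control cause (NAFLD) stream
  carries the U term and the seasonal term but no pollutant term.

Identical ``SimulationConfig`` (including seed) reproduces panels and
records bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import POLLUTANTS, SimulationConfig

logger = logging.getLogger(__name__)

_DAYS_PER_YEAR = 365.25
_REFERENCE_TEMP_K = 284.0
_REFERENCE_HUMIDITY = 0.0073  # g/cm3 at the reference temperature
_HUMIDITY_TEMP_COEF = 0.06  # per Kelvin, Clausius-Clapeyron-like slope
_MORTALITY_PEAK_DOY = 15.0  # winter-peaking mortality seasonality


@dataclass
class SimTruth:
    """Ground truth of one generating run, stored verbatim."""

    true_log_rr: dict[str, float]
    confounder: pd.DataFrame  # columns: date, region, u
    seed: int
    exposure_centering: dict[str, float]


def _seasonal(doy: np.ndarray, amplitude: float, peak_doy: float) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / _DAYS_PER_YEAR)


def _ar1(innovations: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) along axis 0. innovations: (n_days, n_regions)."""
    if rho == 0.0:
        return innovations
    x = lfilter([1.0], [1.0, -rho], innovations, axis=0)
    # stationary initial state: x_{-1} with marginal variance
    n = innovations.shape[0]
    sd_inn = innovations.std() if innovations.size else 0.0
    x0 = rng.normal(0.0, 1.0, size=innovations.shape[1])
    marg = np.sqrt(max(np.var(innovations, axis=0).mean(), 0.0) / (1.0 - rho**2))
    decay = rho ** np.arange(1, n + 1)
    return x + decay[:, None] * (x0[None, :] * marg)


def _confounder_series(config: SimulationConfig, n_days: int, rng) -> np.ndarray:
    """(n_days + 1, n_regions) AR(1) confounder; row 0 is the day before start."""
    rho = config.confounder_ar1
    sd_inn = config.confounder_sd * np.sqrt(1.0 - rho**2)
    innov = rng.normal(0.0, sd_inn, size=(n_days + 1, config.n_regions))
    return _ar1(innov, rho, rng)


def simulate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Daily exposure/weather panel: one row per (date, region).

    Returns a long-format DataFrame with columns date, region, pm25, o3,
    no2, temperature, humidity, sorted by (date, region).
    """
    panel, _ = _simulate_panel_with_u(config)
    return panel


def _simulate_panel_with_u(config: SimulationConfig):
    rng = np.random.default_rng(config.seed)
    dates = config.dates
    regions = config.regions
    n_days, n_reg = len(dates), len(regions)
    doy = dates.dayofyear.to_numpy().astype(float)

    u_full = _confounder_series(config, n_days, rng)
    u = u_full[1:]  # aligned to dates
    u_lag1 = u_full[:-1]

    # cross-correlated pollutant innovations
    rho_x = config.cross_correlation
    corr = np.full((3, 3), rho_x)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)
    z = rng.normal(size=(n_days, n_reg, 3))
    z = z @ L.T

    lam = config.confounder_exposure_loading
    ratio = config.confounder_lead_loading_ratio
    cols: dict[str, np.ndarray] = {}
    for j, p in enumerate(POLLUTANTS):
        sd = config.noise_sds.get(p, 0.0)
        rho = config.ar1_coefficients.get(p, 0.0)
        dev = _ar1(z[:, :, j] * sd, rho, rng)
        series = (
            config.pollutant_means[p]
            + _seasonal(doy, config.seasonal_amplitudes.get(p, 0.0), config.seasonal_peak_doy.get(p, 0.0))[:, None]
            + dev
            + lam * (u + ratio * u_lag1)
        )
        cols[p] = np.maximum(series, 0.0)

    t_sd = config.noise_sds.get("temperature", 0.0)
    t_rho = config.ar1_coefficients.get("temperature", 0.0)
    t_dev = _ar1(rng.normal(0.0, t_sd, size=(n_days, n_reg)), t_rho, rng)
    temperature = (
        _REFERENCE_TEMP_K
        + _seasonal(
            doy,
            config.seasonal_amplitudes.get("temperature", 0.0),
            config.seasonal_peak_doy.get("temperature", 205.0),
        )[:, None]
        + t_dev
    )
    h_sd = config.noise_sds.get("humidity", 0.0)
    humidity = _REFERENCE_HUMIDITY * np.exp(
        _HUMIDITY_TEMP_COEF * (temperature - _REFERENCE_TEMP_K)
    ) + rng.normal(0.0, h_sd, size=(n_days, n_reg))
    humidity = np.maximum(humidity, 1e-6)

    panel = pd.DataFrame(
        {
            "date": np.repeat(dates.to_numpy(), n_reg),
            "region": np.tile(np.array(regions, dtype=object), n_days),
            "pm25": cols["pm25"].ravel(),
            "o3": cols["o3"].ravel(),
            "no2": cols["no2"].ravel(),
            "temperature": temperature.ravel(),
            "humidity": humidity.ravel(),
        }
    )
    u_df = pd.DataFrame(
        {
            "date": np.repeat(dates.to_numpy(), n_reg),
            "region": np.tile(np.array(regions, dtype=object), n_days),
            "u": u.ravel(),
        }
    )
    return panel, u_df


def _ma02(values: np.ndarray) -> np.ndarray:
    """Lag 0-2 moving average along axis 0; first two rows are NaN."""
    out = np.full_like(values, np.nan, dtype=float)
    out[2:] = (values[2:] + values[1:-1] + values[:-2]) / 3.0
    return out


def simulate_deaths(
    panel: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Individual death records plus the run's ground truth.

    The exposure term of the log-rate uses each pollutant's lag 0-2 moving
    average centred at its grand mean, so ``baseline_rate`` stays the
    expected deaths/region/day at average exposure. The first two days of
    the range have no computable moving average and generate no deaths
    (logged).
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of the panel stream
    dates = config.dates
    regions = config.regions
    n_days, n_reg = len(dates), len(regions)
    doy = dates.dayofyear.to_numpy().astype(float)

    wide = {
        p: panel.pivot(index="date", columns="region", values=p)
        .reindex(index=dates, columns=regions)
        .to_numpy()
        for p in POLLUTANTS
    }
    # regenerate U deterministically from the same seed as the panel
    _, u_df = _simulate_panel_with_u(config)
    u = u_df["u"].to_numpy().reshape(n_days, n_reg)

    centering: dict[str, float] = {}
    exposure_term = np.zeros((n_days, n_reg))
    for p in POLLUTANTS:
        ma = _ma02(wide[p])
        centering[p] = float(np.nanmean(ma))
        exposure_term += config.true_log_rr[p] * (ma - centering[p])

    seasonal = _seasonal(doy, config.mortality_seasonal_amplitude, _MORTALITY_PEAK_DOY)[:, None]
    base_log = np.log(config.baseline_rate) + seasonal + config.confounder_mortality_loading * u

    valid = ~np.isnan(exposure_term).any(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info(
            "simulate_deaths: %d leading days excluded (lag 0-2 moving average not computable)",
            n_skipped,
        )

    share_cvd = config.cause_shares.get("cardiovascular", 0.0)
    share_resp = config.cause_shares.get("respiratory", 0.0)
    streams = [
        ("cardiovascular", share_cvd, config.cause_effect_multipliers.get("cardiovascular", 1.0)),
        ("respiratory", share_resp, config.cause_effect_multipliers.get("respiratory", 1.0)),
        ("all_cause_component", 1.0 - share_cvd - share_resp, 1.0),
    ]

    frames = []
    for cause, share, mult in streams:
        if share <= 0:
            continue
        rate = share * np.exp(base_log + mult * exposure_term)
        rate[~valid] = 0.0
        counts = rng.poisson(rate)
        frames.append(_expand_counts(counts, dates, regions, cause, config, rng))
    # negative-control stream: U and season, no pollutant term
    if config.nafld_fraction > 0:
        rate = config.nafld_fraction * np.exp(base_log)
        rate[~valid] = 0.0
        counts = rng.poisson(rate)
        frames.append(_expand_counts(counts, dates, regions, "nafld_control", config, rng))

    frames = [f for f in frames if not f.empty]
    if frames:
        deaths = pd.concat(frames, ignore_index=True)
        deaths = deaths.sort_values(["event_date", "region", "cause_class"], kind="stable")
        deaths = deaths.reset_index(drop=True)
    else:
        deaths = _empty_deaths()

    truth = SimTruth(
        true_log_rr=dict(config.true_log_rr),
        confounder=u_df,
        seed=config.seed,
        exposure_centering=centering,
    )
    return deaths, truth


def _empty_deaths() -> pd.DataFrame:
    cols = ["event_date", "region", "cause_class", "sex", "race", "age_group", "education", "urbanicity"]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def _expand_counts(counts, dates, regions, cause, config, rng) -> pd.DataFrame:
    day_idx, reg_idx = np.nonzero(counts)
    reps = counts[day_idx, reg_idx]
    total = int(reps.sum())
    if total == 0:
        return _empty_deaths()
    event_date = np.repeat(dates.to_numpy()[day_idx], reps)
    region = np.repeat(np.array(regions, dtype=object)[reg_idx], reps)
    out = pd.DataFrame({"event_date": event_date, "region": region})
    out["cause_class"] = cause
    for cov, probs in config.covariate_category_probabilities.items():
        levels = np.array(list(probs.keys()), dtype=object)
        p = np.array(list(probs.values()), dtype=float)
        out[cov] = rng.choice(levels, size=total, p=p / p.sum())
    return out
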