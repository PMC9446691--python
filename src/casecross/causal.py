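"""Negative-control causal machinery.

Four estimators address unmeasured time-varying confounding:

* **Negative exposure control (NEC)** — pollution on the day *after* death
  cannot have caused it, but shares time-varying confounders with the
  exposure of interest. Including lead-1 terms in the joint fit
  (:func:`nec_adjusted_fit`) both partially adjusts for, and diagnoses, such
  confounding: a non-null lead coefficient flags an omitted confounder.
* **Coefficient-difference correction** (:func:`difference_correction`) —
  if the omitted confounder loads equally on same-day and next-day
  pollution, beta_exposure - beta_lead is unconfounded. The variance uses
  the joint covariance: Var = V_ee + V_ll - 2 V_el.
* **Negative outcome control (NOC)** — deaths from a cause the exposure
  does not affect (NAFLD). :func:`noc_fit` runs the standard model on those
  strata; non-null estimates flag shared omitted confounders.
* **Double negative control / two-stage** — stage 1
  (:func:`fit_surrogate`) models daily regional NAFLD counts with an
  in-repo IRLS Poisson log-linear fit; its fitted mean W-hat is a surrogate
  for the omitted confounder. Stage 2 (:func:`two_stage_fit`) adds W-hat to
  the conditional-logistic model alongside the leads, relaxing the
  equal-loading assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clogit
from .clogit import EffectEstimate, FitResult
from .config import POLLUTANTS, AnalysisConfig
from .design import StratumSet

logger = logging.getLogger(__name__)


class NegativeControlError(ValueError):
    """Invalid inputs to a negative-control estimator."""


# ---------------------------------------------------------------------------
# Negative exposure control


def nec_adjusted_fit(strata: StratumSet, config: AnalysisConfig | None = None) -> FitResult:
    """Joint fit of exposure moving averages, lead-1 controls and weather.

    The strata must have been assembled with lead features for every
    pollutant in the model; the lead coefficients are the negative-exposure-
    control diagnostics.
    """
    config = config or AnalysisConfig()
    missing = [
        config.lead_label(p) for p in config.pollutants
        if config.lead_label(p) not in strata.feature_labels
    ]
    if missing:
        raise NegativeControlError(f"strata lack lead columns: {missing}")
    return clogit.fit(strata, tol=config.tol, max_iter=config.max_iter)


def lead_diagnostics(fit: FitResult, config: AnalysisConfig | None = None) -> dict[str, EffectEstimate]:
    """Percent-scale lead-1 estimates per pollutant from a joint fit."""
    config = config or AnalysisConfig()
    out = {}
    for p in config.pollutants:
        lab = config.lead_label(p)
        if lab in fit.beta.index:
            out[p] = clogit.percent_increase(fit, lab, config.increments.get(p, 10.0))
    return out


# ---------------------------------------------------------------------------
# Coefficient-difference correction


@dataclass
class CorrectionResult:
    """Exposure coefficient minus lead coefficient, with joint-fit variance."""

    pollutant: str
    beta_exposure: float
    beta_lead: float
    beta_corrected: float
    variance: float
    estimate: EffectEstimate
    independence_approximation: bool = False


def difference_correction(
    fit: FitResult,
    exposure_label: str,
    lead_label: str,
    delta: float = 10.0,
    pollutant: str | None = None,
    independence_approximation: bool = False,
) -> CorrectionResult:
    """Bias-corrected estimate beta_exposure - beta_lead from one joint fit.

    Both labels must come from the same fit so the covariance V_el is
    available; ``independence_approximation=True`` explicitly requests
    Var = V_ee + V_ll (labelled as such in the result).
    """
    for lab in (exposure_label, lead_label):
        if lab not in fit.beta.index:
            raise NegativeControlError(
                f"label {lab!r} not in fit (labels from different fits have no joint covariance); "
                f"fitted: {list(fit.beta.index)}"
            )
    b_e = float(fit.beta[exposure_label])
    b_l = float(fit.beta[lead_label])
    v_ee = float(fit.cov.loc[exposure_label, exposure_label])
    v_ll = float(fit.cov.loc[lead_label, lead_label])
    v_el = 0.0 if independence_approximation else float(fit.cov.loc[exposure_label, lead_label])
    var = v_ee + v_ll - 2.0 * v_el
    if var < 0:
        raise NegativeControlError(f"negative corrected variance {var}")
    b_c = b_e - b_l
    est = clogit.effect_from_beta(
        b_c, math.sqrt(var), pollutant or exposure_label, delta, fit.n_strata, fit.n_cases
    )
    return CorrectionResult(
        pollutant=pollutant or exposure_label,
        beta_exposure=b_e,
        beta_lead=b_l,
        beta_corrected=b_c,
        variance=var,
        estimate=est,
        independence_approximation=independence_approximation,
    )


def corrected_percent_from_printed(
    percent_exposure: float, percent_lead: float, delta: float = 10.0
) -> float:
    """Worked-example arithmetic on printed percent effects.

    Converts each percent to a per-``delta`` log coefficient via
    ``ln(1 + p/100)``, subtracts, and re-expresses as a percent:
    ``100 * ((1 + pe/100) / (1 + pl/100) - 1)``. With the published 0.73%
    exposure and -0.36% lead effects this yields 1.09%.
    """
    b_e = math.log1p(percent_exposure / 100.0) / delta
    b_l = math.log1p(percent_lead / 100.0) / delta
    return 100.0 * (math.exp(delta * (b_e - b_l)) - 1.0)


# ---------------------------------------------------------------------------
# Negative outcome control


@dataclass
class NocResult:
    """Negative-outcome-control diagnostic fit."""

    fit: FitResult
    estimates: dict[str, EffectEstimate]
    consistent_with_null: bool


def noc_fit(nafld_strata: StratumSet, config: AnalysisConfig | None = None) -> NocResult:
    """Standard multi-pollutant fit on the negative-control outcome.

    Diagnostic contract: returns the per-pollutant estimates plus a flag
    that is True iff every pollutant CI covers 0.
    """
    config = config or AnalysisConfig()
    if nafld_strata.n_strata == 0:
        raise NegativeControlError("no negative-control-outcome strata (0 records)")
    try:
        fit = clogit.fit(nafld_strata, tol=config.tol, max_iter=config.max_iter)
    except clogit.CollinearityError as exc:
        raise NegativeControlError(
            f"too few negative-control strata ({nafld_strata.n_strata}) for an "
            f"invertible information matrix: {exc}"
        ) from exc
    estimates = {}
    for p in config.pollutants:
        lab = config.ma_label(p)
        if lab in fit.beta.index:
            estimates[p] = clogit.percent_increase(fit, lab, config.increments.get(p, 10.0))
    flag = all(e.covers_zero() for e in estimates.values())
    return NocResult(fit=fit, estimates=estimates, consistent_with_null=flag)


# ---------------------------------------------------------------------------
# Two-stage surrogate-confounder estimator


@dataclass
class SurrogateSeries:
    """Stage-1 expected negative-control-outcome value per (date, region)."""

    values: pd.DataFrame  # columns: date, region, w_hat
    coefficients: pd.Series
    description: str

    def lookup(self, dates: np.ndarray, regions: np.ndarray) -> np.ndarray:
        idx = pd.MultiIndex.from_arrays(
            [pd.to_datetime(dates), pd.Index(regions, dtype=object)]
        )
        ser = self.values.set_index(["date", "region"])["w_hat"]
        out = ser.reindex(idx)
        if out.isna().any():
            missing = sorted({(d.date().isoformat(), r) for d, r in out.index[out.isna()][:10]})
            raise NegativeControlError(
                f"surrogate does not cover {int(out.isna().sum())} (date, region) pairs, "
                f"e.g. {missing[:5]}"
            )
        return out.to_numpy()


def aggregate_daily_counts(
    deaths: pd.DataFrame, panel: pd.DataFrame, cause_class: str = "nafld_control"
) -> pd.DataFrame:
    """Daily counts of one cause per (date, region), zero-filled over the panel."""
    sub = deaths.loc[deaths["cause_class"] == cause_class]
    counts = (
        sub.groupby([pd.to_datetime(sub["event_date"]), "region"], observed=True)
        .size()
        .rename("count")
    )
    base = panel[["date", "region"]].copy()
    base["date"] = pd.to_datetime(base["date"])
    idx = pd.MultiIndex.from_frame(base)
    out = counts.reindex(idx, fill_value=0).reset_index()
    out.columns = ["date", "region", "count"]
    return out


def _seasonal_harmonics(dates: pd.Series, n_harmonics: int) -> np.ndarray:
    doy = pd.to_datetime(dates).dt.dayofyear.to_numpy().astype(float)
    cols = []
    for h in range(1, n_harmonics + 1):
        ang = 2.0 * np.pi * h * doy / 365.25
        cols.append(np.sin(ang))
        cols.append(np.cos(ang))
    return np.column_stack(cols) if cols else np.empty((len(doy), 0))


def poisson_irls(
    X: np.ndarray,
    y: np.ndarray,
    labels: list[str],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-link Poisson regression by iteratively reweighted least squares.

    ``X`` must contain exactly one constant column labelled ``intercept``.
    Non-constant columns are centred and scaled internally for conditioning;
    the returned (beta, covariance) are on the native scale. Raises on
    non-convergence (message carries the gradient norm) or a singular
    weighted Gram matrix.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    const = X.std(axis=0) < 1e-12
    bad_const = [labels[i] for i in np.nonzero(const)[0] if labels[i] != "intercept"]
    if bad_const:
        raise NegativeControlError(f"constant columns in stage-1 design: {bad_const}")
    if "intercept" not in labels or not const[labels.index("intercept")]:
        raise NegativeControlError("stage-1 design must contain a constant 'intercept' column")
    ii = labels.index("intercept")
    nonint = [i for i in range(k) if i != ii]

    center = X.mean(axis=0)
    scale = np.where(const, 1.0, X.std(axis=0))
    Z = (X[:, nonint] - center[nonint]) / scale[nonint]
    m = len(nonint)

    b = np.zeros(m)
    b0 = math.log(max(y.mean(), 1e-12))
    eta = Z @ b + b0
    gnorm = np.inf
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        grad = Z.T @ (y - mu)
        g0 = float(np.sum(y - mu))
        gnorm = max(np.max(np.abs(grad)) if m else 0.0, abs(g0))
        if gnorm < tol * max(1.0, y.sum()):
            break
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = (Z.T * mu) @ Z
        A[:m, m] = Z.T @ mu
        A[m, :m] = A[:m, m]
        A[m, m] = mu.sum()
        rhs = np.concatenate([grad, [g0]])
        try:
            delta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise NegativeControlError(f"singular stage-1 information matrix: {exc}") from exc
        step = 1.0
        ll_old = float(y @ eta - np.exp(np.clip(eta, -30, 30)).sum())
        for _ in range(30):
            b_new = b + step * delta[:m]
            b0_new = b0 + step * delta[m]
            eta_new = Z @ b_new + b0_new
            ll_new = float(y @ eta_new - np.exp(np.clip(eta_new, -30, 30)).sum())
            if ll_new >= ll_old - 1e-10:
                break
            step *= 0.5
        b, b0, eta = b_new, b0_new, eta_new
    else:
        raise NegativeControlError(
            f"stage-1 IRLS did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.3g})"
        )

    mu = np.exp(np.clip(eta, -30, 30))
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = (Z.T * mu) @ Z
    A[:m, m] = Z.T @ mu
    A[m, :m] = A[:m, m]
    A[m, m] = mu.sum()
    cov_aug = np.linalg.inv(A)

    # native beta is a linear map of (b, b0): slopes divide by scale, the
    # intercept absorbs the centring terms
    T = np.zeros((k, m + 1))
    for pos, i in enumerate(nonint):
        T[i, pos] = 1.0 / scale[i]
        T[ii, pos] = -center[i] / scale[i]
    T[ii, m] = 1.0
    beta_native = T @ np.concatenate([b, [b0]])
    cov = T @ cov_aug @ T.T
    return beta_native, cov


def fit_surrogate(
    panel: pd.DataFrame,
    nafld_daily_counts: pd.DataFrame,
    config: AnalysisConfig | None = None,
    n_harmonics: int = 2,
    include_region_effects: bool = True,
    include_covariates: bool = True,
) -> SurrogateSeries:
    """Stage-1 log-linear model of daily regional negative-control counts.

    Design: intercept + pollutant lag-MAs + lead-1 terms + weather terms +
    periodic seasonal harmonics (+ region intercepts). Fit by in-repo IRLS;
    W-hat is the fitted mean per (date, region), always finite and >= 0.

    With ``include_covariates=False`` and ``n_harmonics=0`` and
    ``include_region_effects=False`` this degenerates to an intercept-only
    fit whose W-hat is the sample mean.
    """
    from .design import compute_feature_table, default_feature_spec

    config = config or AnalysisConfig()
    counts = nafld_daily_counts.copy()
    counts["date"] = pd.to_datetime(counts["date"])
    if (counts["count"] < 0).any():
        raise NegativeControlError("negative daily counts")
    if counts["count"].sum() == 0:
        raise NegativeControlError("degenerate outcome: all daily counts are zero")

    cols: list[np.ndarray] = [np.ones(len(counts))]
    labels: list[str] = ["intercept"]
    if include_covariates:
        spec = default_feature_spec(config)
        table = compute_feature_table(panel, spec)
        idx = pd.MultiIndex.from_arrays(
            [counts["date"], pd.Index(counts["region"], dtype=object)]
        )
        feats = table.reindex(idx).reset_index(drop=True)
        keep = feats.notna().all(axis=1).to_numpy()
        counts = counts.loc[keep].reset_index(drop=True)
        feats = feats.loc[keep].reset_index(drop=True)
        cols = [np.ones(len(counts))]
        for lab in spec.labels:
            cols.append(feats[lab].to_numpy())
            labels.append(lab)
    if n_harmonics > 0:
        H = _seasonal_harmonics(counts["date"], n_harmonics)
        for h in range(H.shape[1]):
            cols.append(H[:, h])
            labels.append(f"season_{h}")
    if include_region_effects:
        regions = sorted(counts["region"].unique())
        for r in regions[1:]:
            cols.append((counts["region"] == r).to_numpy().astype(float))
            labels.append(f"region_{r}")

    X = np.column_stack(cols)
    y = counts["count"].to_numpy(float)
    beta, _ = poisson_irls(X, y, labels)
    w_hat = np.exp(np.clip(X @ beta, -30, 30))

    values = pd.DataFrame(
        {"date": counts["date"], "region": counts["region"], "w_hat": w_hat}
    )
    desc = (
        f"Poisson log-linear IRLS fit of daily negative-control counts; "
        f"{len(labels)} terms: {labels[: min(len(labels), 12)]}..."
    )
    return SurrogateSeries(
        values=values, coefficients=pd.Series(beta, index=labels), description=desc
    )


def two_stage_fit(
    strata: StratumSet,
    surrogate: SurrogateSeries,
    config: AnalysisConfig | None = None,
    log_surrogate: bool = False,
    keep_leads: bool = False,
) -> tuple[FitResult, dict[str, EffectEstimate]]:
    """Stage-2 conditional-logistic fit adding the surrogate W-hat (lag 0).

    By default the lead terms are *excluded* from stage 2: the fitted
    surrogate is (log-)linear in exposure and lead, so retaining the lead
    alongside W-hat leaves the design without an identifying direction for
    the confounder proxy (in the linear analogue the three columns are
    collinear). ``keep_leads=True`` retains them anyway; ``log_surrogate``
    enters log(W-hat) instead of W-hat (the surrogate scale is a modelling
    choice). Raises if the surrogate misses any stratum (date, region).
    """
    config = config or AnalysisConfig()
    regions = strata.meta["region"].to_numpy()[strata.row_stratum]
    w = surrogate.lookup(strata.row_dates, regions)
    if log_surrogate:
        w = np.log(np.maximum(w, 1e-12))
    # a surrogate that is constant within every stratum cancels from the
    # conditional likelihood; drop it so stage 2 equals the NEC fit exactly
    hi = np.maximum.reduceat(w, strata.starts)
    lo = np.minimum.reduceat(w, strata.starts)
    if np.all(hi - lo < 1e-12):
        logger.info("two_stage_fit: surrogate is stratum-constant; it drops out of stage 2")
        s2 = strata
    else:
        s2 = strata.with_feature("noc_surrogate", w)
    if not keep_leads:
        keep = [l for l in s2.feature_labels if not any(
            l == config.lead_label(p) for p in config.pollutants
        )]
        s2 = s2.select_features(keep)
    fit = clogit.fit(s2, tol=config.tol, max_iter=config.max_iter)
    estimates = {
        p: clogit.percent_increase(fit, config.ma_label(p), config.increments.get(p, 10.0))
        for p in config.pollutants
        if config.ma_label(p) in fit.beta.index
    }
    return fit, estimates
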