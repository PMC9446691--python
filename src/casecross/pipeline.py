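"""Orchestration of the model families and secondary analyses.

Given one assembled :class:`~casecross.design.StratumSet` carrying features
for all three pollutants, this module runs the single-, double- and
three-pollutant conditional-logistic families, the negative-control layer,
the low-exposure (WHO guideline) restriction, cause-specific and subgroup
analyses, the state-by-temperature sensitivity model, and the descriptive
cohort summary — emitting tidy result tables in the shape written by
:func:`casecross.io.write_results`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import causal, clogit
from .clogit import EffectEstimate, FitResult
from .config import CAUSE_CLASSES, POLLUTANTS, AnalysisConfig
from .design import StratumSet

logger = logging.getLogger(__name__)

MODEL_FAMILIES = (
    "single",
    "double",
    "triple",
    "triple+two-stage",
    "low-exposure",
    "cause-specific",
    "subgroup",
    "sensitivity-state-temp",
)


class PipelineError(ValueError):
    """Invalid pipeline request."""


@dataclass(frozen=True)
class ModelFamily:
    """One named analysis: which pollutants, which restriction, which subgroup."""

    name: str
    pollutants: tuple[str, ...]
    restriction: str | None = None
    subgroup_variable: str | None = None

    def __post_init__(self):
        if self.name not in MODEL_FAMILIES:
            raise PipelineError(f"unknown model family {self.name!r}; allowed: {MODEL_FAMILIES}")


def _weather_labels(strata: StratumSet, config: AnalysisConfig) -> list[str]:
    model_labels = {config.ma_label(p) for p in config.pollutants} | {
        config.lead_label(p) for p in config.pollutants
    }
    return [l for l in strata.feature_labels if l not in model_labels and l != "noc_surrogate"]


def _family_labels(
    strata: StratumSet, config: AnalysisConfig, pollutants: tuple[str, ...]
) -> list[str]:
    labels = [config.ma_label(p) for p in pollutants]
    if config.include_lead_controls:
        labels += [config.lead_label(p) for p in pollutants]
    labels += _weather_labels(strata, config)
    return labels


def _row(model: str, pollutant: str, est: EffectEstimate) -> dict:
    return {
        "model": model,
        "pollutant": pollutant,
        "percent_increase": est.percent,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p_value": est.p_value,
        "n_strata": est.n_strata,
        "n_cases": est.n_cases,
    }


def fit_family(
    strata: StratumSet, config: AnalysisConfig, pollutants: tuple[str, ...]
) -> FitResult:
    """Conditional-logistic fit of one pollutant subset plus weather terms."""
    sub = strata.select_features(_family_labels(strata, config, pollutants))
    info = sub.informative_mask()
    if not info.all():
        sub = sub.subset(info)
    return clogit.fit(sub, tol=config.tol, max_iter=config.max_iter)


def run_models(strata: StratumSet, config: AnalysisConfig | None = None) -> dict[str, pd.DataFrame]:
    """Single-, double- and three-pollutant families plus the causal layer.

    Returns result tables keyed by family: ``single``, ``double``,
    ``triple``, ``triple_lead`` (negative-exposure-control diagnostics) and
    ``triple_corrected`` (coefficient-difference corrections).
    """
    config = config or AnalysisConfig()
    if not config.pollutants:
        raise PipelineError("empty pollutant set")
    rows_single, rows_double, rows_triple = [], [], []
    rows_lead, rows_corr = [], []

    for p in config.pollutants:
        fit = fit_family(strata, config, (p,))
        rows_single.append(_row("single", p, clogit.percent_increase(fit, config.ma_label(p), config.increments.get(p, 10.0))))

    if len(config.pollutants) >= 2:
        for pair in itertools.combinations(config.pollutants, 2):
            fit = fit_family(strata, config, pair)
            for p in pair:
                est = clogit.percent_increase(fit, config.ma_label(p), config.increments.get(p, 10.0))
                rows_double.append(_row(f"double[{'+'.join(pair)}]", p, est))

    fit = fit_family(strata, config, config.pollutants)
    for p in config.pollutants:
        est = clogit.percent_increase(fit, config.ma_label(p), config.increments.get(p, 10.0))
        rows_triple.append(_row("triple", p, est))
    if config.include_lead_controls:
        for p, est in causal.lead_diagnostics(fit, config).items():
            rows_lead.append(_row("triple_lead", p, est))
        for p in config.pollutants:
            corr = causal.difference_correction(
                fit,
                config.ma_label(p),
                config.lead_label(p),
                delta=config.increments.get(p, 10.0),
                pollutant=p,
            )
            rows_corr.append(_row("triple_corrected", p, corr.estimate))

    out = {
        "single": pd.DataFrame(rows_single),
        "double": pd.DataFrame(rows_double),
        "triple": pd.DataFrame(rows_triple),
    }
    if rows_lead:
        out["triple_lead"] = pd.DataFrame(rows_lead)
        out["triple_corrected"] = pd.DataFrame(rows_corr)
    return out


# ---------------------------------------------------------------------------
# Low-exposure restriction


def restrict_low_exposure(
    strata: StratumSet,
    thresholds: dict[str, float],
    rule: str = "all_days",
) -> StratumSet:
    """Subset of strata below the given day-level pollutant thresholds.

    ``rule='all_days'`` (default): a stratum is retained iff *every* case and
    referent row's day-level value of each restricted pollutant is below its
    threshold; rows are never dropped individually, preserving the matched
    set. ``rule='case_day'`` restricts on the case day only.
    """
    for p, thr in thresholds.items():
        if thr <= 0:
            raise PipelineError(f"threshold for {p} must be > 0, got {thr}")
        if f"day_{p}" not in strata.aux_labels:
            raise PipelineError(f"strata carry no day-level values for {p!r}")
    if rule not in ("all_days", "case_day"):
        raise PipelineError(f"unknown restriction rule {rule!r}")

    keep = np.ones(strata.n_strata, dtype=bool)
    for p, thr in thresholds.items():
        col = strata.aux[:, strata.aux_labels.index(f"day_{p}")]
        if rule == "case_day":
            keep &= col[strata.starts] < thr
        else:
            row_max = np.maximum.reduceat(col, strata.starts)
            keep &= row_max < thr
    return strata.subset(keep)


def fraction_days_below(panel: pd.DataFrame, thresholds: dict[str, float]) -> dict[str, float]:
    """Fraction of panel days below each threshold (accounting report)."""
    out = {}
    for p, thr in thresholds.items():
        if p not in panel.columns:
            raise PipelineError(f"panel has no column {p!r}")
        vals = panel[p].to_numpy(float)
        out[p] = float((vals < thr).mean())
    return out


# ---------------------------------------------------------------------------
# Cause-specific and subgroup analyses


def cause_specific(
    strata: StratumSet, cause: str, config: AnalysisConfig | None = None
) -> dict[str, pd.DataFrame]:
    """run_models on the strata of one cause class."""
    if cause not in CAUSE_CLASSES:
        raise PipelineError(f"unknown cause class {cause!r}; allowed: {list(CAUSE_CLASSES)}")
    mask = (strata.meta["cause_class"] == cause).to_numpy()
    if not mask.any():
        raise PipelineError(f"no strata with cause_class {cause!r}")
    sub = strata.subset(mask)
    tables = run_models(sub, config)
    return {f"{cause}_{k}": v.assign(model=lambda d, k=k: cause + ":" + d["model"]) for k, v in tables.items()}


@dataclass
class SubgroupContrast:
    """Wald contrast between two independent stratified fits."""

    pollutant: str
    level_a: str
    level_b: str
    beta_diff: float
    se_diff: float
    z: float
    p_value: float


def subgroup_analysis(
    strata: StratumSet, modifier: str, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, list[SubgroupContrast]]:
    """Per-level three-pollutant fits plus pairwise contrast z-tests.

    Stratified fits on disjoint subgroups are independent, so the contrast
    ``z = (b1 - b2) / sqrt(se1^2 + se2^2)`` has a standard normal null.
    """
    config = config or AnalysisConfig()
    if modifier not in strata.meta.columns:
        raise PipelineError(
            f"unknown modifier {modifier!r}; available: "
            f"{[c for c in strata.meta.columns if c not in ('stratum_id', 'case_date')]}"
        )
    levels = sorted(strata.meta[modifier].dropna().unique())
    rows = []
    level_fits: dict[str, FitResult] = {}
    for lev in levels:
        sub = strata.subset((strata.meta[modifier] == lev).to_numpy())
        fit = fit_family(sub, config, config.pollutants)
        level_fits[lev] = fit
        for p in config.pollutants:
            est = clogit.percent_increase(fit, config.ma_label(p), config.increments.get(p, 10.0))
            rows.append(_row(f"subgroup[{modifier}={lev}]", p, est))
    contrasts = []
    for a, b in itertools.combinations(levels, 2):
        fa, fb = level_fits[a], level_fits[b]
        for p in config.pollutants:
            lab = config.ma_label(p)
            d = float(fa.beta[lab] - fb.beta[lab])
            se = float(np.sqrt(fa.se(lab) ** 2 + fb.se(lab) ** 2))
            z = d / se if se > 0 else 0.0
            contrasts.append(
                SubgroupContrast(
                    pollutant=p,
                    level_a=a,
                    level_b=b,
                    beta_diff=d,
                    se_diff=se,
                    z=z,
                    p_value=float(2.0 * stats.norm.sf(abs(z))),
                )
            )
    return pd.DataFrame(rows), contrasts


def classify_urbanicity(
    region_densities: dict[str, float], deaths_per_region: dict[str, int] | None = None
) -> dict[str, str]:
    """Urban/rural labels by the death-weighted 25th density percentile.

    The percentile is taken over the study *population*: each region's
    density is weighted by its death count (equal weights if none given),
    interpolating linearly as in the conventional sample percentile of the
    weight-expanded vector. A region is urban iff its density strictly
    exceeds that percentile — with all densities equal, everything is rural.
    """
    if not region_densities:
        raise PipelineError("empty region density input")
    regions = list(region_densities)
    d = np.array([region_densities[r] for r in regions], float)
    w = np.array(
        [1.0 if deaths_per_region is None else float(deaths_per_region.get(r, 0)) for r in regions]
    )
    if w.sum() <= 0:
        raise PipelineError("total weight is zero")
    order = np.argsort(d, kind="stable")
    ds, ws = d[order], w[order]
    W = float(ws.sum())
    # linear-interpolation percentile of the weight-expanded sample: the
    # expanded vector has ws[i] copies of ds[i]; its (0-based) entry j is
    # ds[searchsorted(cumsum, j, 'right')]
    pos = 0.25 * (W - 1.0)
    j0 = np.floor(pos)
    frac = pos - j0
    cum = np.cumsum(ws)
    v0 = ds[min(int(np.searchsorted(cum, j0, side="right")), len(ds) - 1)]
    v1 = ds[min(int(np.searchsorted(cum, j0 + 1.0, side="right")), len(ds) - 1)]
    q25 = v0 + frac * (v1 - v0)
    return {r: ("urban" if region_densities[r] > q25 else "rural") for r in regions}


# ---------------------------------------------------------------------------
# Sensitivity: region-group-specific temperature effects


def state_temperature_sensitivity(
    strata: StratumSet,
    config: AnalysisConfig | None = None,
    region_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Re-fit with temperature terms interacted with region group (state).

    Each temperature feature column is expanded into one column per group,
    nonzero only for strata in that group (stratum rows share a region, so
    the interaction is stratum-consistent). With a single group this is the
    main model exactly.
    """
    config = config or AnalysisConfig()
    temp_labels = [l for l in strata.feature_labels if l.startswith("temp")]
    if not temp_labels:
        raise PipelineError("strata carry no temperature features")
    regions = strata.meta["region"].astype(str)
    groups = regions.map(region_groups) if region_groups else regions
    if groups.isna().any():
        missing = sorted(regions[groups.isna()].unique())
        raise PipelineError(f"regions without group assignment: {missing}")
    group_names = sorted(groups.unique())

    keep = [l for l in strata.feature_labels if l not in temp_labels]
    s = strata.select_features(keep)
    if len(group_names) > 1:
        row_group = groups.to_numpy()[strata.row_stratum]
        for g in group_names:
            gmask = (row_group == g).astype(float)
            for lab in temp_labels:
                col = strata.X[:, strata.feature_labels.index(lab)]
                s = s.with_feature(f"{lab}[{g}]", col * gmask)
    else:
        for lab in temp_labels:
            s = s.with_feature(lab, strata.X[:, strata.feature_labels.index(lab)])

    fit = clogit.fit(s, tol=config.tol, max_iter=config.max_iter)
    rows = [
        _row(
            "sensitivity-state-temp",
            p,
            clogit.percent_increase(fit, config.ma_label(p), config.increments.get(p, 10.0)),
        )
        for p in config.pollutants
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Descriptives


def cohort_summary(deaths: pd.DataFrame, panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Descriptive table: covariate counts/percentages, cause shares,
    mean (SD) of case-day exposures when a panel is supplied.

    Percentages are rounded to one decimal at this reporting layer only.
    """
    rows = []
    n = len(deaths)
    rows.append({"variable": "total", "level": "", "count": n, "percent": 100.0 if n else np.nan, "mean": np.nan, "sd": np.nan})
    if n == 0:
        return pd.DataFrame(rows)
    for var in ("sex", "race", "age_group", "education", "urbanicity", "cause_class"):
        if var not in deaths.columns:
            continue
        counts = deaths[var].value_counts()
        for level, c in counts.items():
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "count": int(c),
                    "percent": round(100.0 * c / n, 1),
                    "mean": np.nan,
                    "sd": np.nan,
                }
            )
    if panel is not None:
        joined = deaths.merge(
            panel,
            left_on=["event_date", "region"],
            right_on=["date", "region"],
            how="left",
        )
        for var in ("pm25", "o3", "no2", "temperature", "humidity"):
            if var in joined.columns:
                rows.append(
                    {
                        "variable": "case_day_exposure",
                        "level": var,
                        "count": int(joined[var].notna().sum()),
                        "percent": np.nan,
                        "mean": float(joined[var].mean()),
                        "sd": float(joined[var].std()),
                    }
                )
    return pd.DataFrame(rows)


def cause_shares(deaths: pd.DataFrame) -> dict[str, float]:
    """Cause-class shares as percentages rounded to one decimal."""
    n = len(deaths)
    if n == 0:
        return {}
    counts = deaths["cause_class"].value_counts()
    return {str(k): round(100.0 * v / n, 1) for k, v in counts.items()}
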