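import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import casecross as cc
from casecross.design import StratumSet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_panel(start="2010-05-25", end="2010-07-05", regions=("R1",), fill=None, seed=0):
    """Small deterministic panel; `fill` overrides pm25 with a constant."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, end, freq="D")
    rows = []
    for r in regions:
        pm = np.full(len(dates), fill) if fill is not None else 10.0 + rng.normal(0, 3, len(dates)).cumsum() * 0.1 + rng.normal(0, 2, len(dates))
        pm = np.maximum(pm, 0.1)
        rows.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "region": r,
                    "pm25": pm,
                    "o3": np.maximum(37.0 + rng.normal(0, 5, len(dates)), 0.1),
                    "no2": np.maximum(21.0 + rng.normal(0, 5, len(dates)), 0.1),
                    "temperature": 284.0 + rng.normal(0, 3, len(dates)),
                    "humidity": np.maximum(0.0073 + rng.normal(0, 0.0005, len(dates)), 1e-5),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def make_deaths(dates, regions=None, cause="all_cause_component"):
    dates = pd.to_datetime(list(dates))
    regions = regions or ["R1"] * len(dates)
    return pd.DataFrame(
        {
            "event_date": dates,
            "region": regions,
            "cause_class": cause,
            "sex": "female",
            "race": "white",
            "age_group": "ge75",
            "education": "hs",
            "urbanicity": "urban",
        }
    )


def pm25_only_spec(window=(0, 2), lead=False):
    feats = [cc.Feature("pm25", "ma", window, f"pm25_ma{window[0]}{window[1]}")]
    if lead:
        feats.append(cc.Feature("pm25", "lead", 1, "pm25_lead1"))
    return cc.FeatureSpec(tuple(feats))


def random_strata(rng, n_strata=(8, 21), rows=(2, 5), k=(1, 4)):
    """Random small conditional-logistic problem for oracle comparisons."""
    ns = int(rng.integers(*n_strata))
    nk = int(rng.integers(*k))
    counts = rng.integers(rows[0], rows[1], size=ns)
    X = rng.normal(size=(int(counts.sum()), nk))
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
    meta = pd.DataFrame({"stratum_id": np.arange(ns)})
    return StratumSet(
        X=X,
        feature_labels=[f"x{i}" for i in range(nk)],
        starts=starts,
        counts=counts.astype(np.int64),
        row_dates=np.zeros(int(counts.sum()), "datetime64[s]"),
        meta=meta,
    )


@pytest.fixture(scope="session")
def small_world():
    """One simulated world reused by structural tests (no confounder)."""
    cfg = cc.SimulationConfig(
        n_regions=6,
        start_date="2010-01-01",
        end_date="2010-12-31",
        baseline_rate=1.0,
        nafld_fraction=0.05,
        seed=42,
    )
    panel = cc.simulate_panel(cfg)
    deaths, truth = cc.simulate_deaths(panel, cfg)
    return cfg, panel, deaths, truth


@pytest.fixture(scope="session")
def small_strata(small_world):
    cfg, panel, deaths, truth = small_world
    spec = cc.default_feature_spec()
    main = deaths[deaths["cause_class"] != "nafld_control"]
    return cc.assemble_strata(main, panel, spec)
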