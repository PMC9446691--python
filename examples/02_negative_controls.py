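"""Diagnose and correct unmeasured time-varying confounding.

Simulates a world with a slow unmeasured confounder U loading equally on
same-day and next-day pollution and on mortality (including the
negative-control cause), then compares: the naive estimate, the lead-1
negative-exposure-control diagnostic, the negative-outcome-control fit,
the coefficient-difference correction, and the two-stage surrogate model.
"""

import casecross as cc
from casecross import causal

cfg = cc.SimulationConfig(
    n_regions=25,
    start_date="2010-01-01",
    end_date="2011-12-31",
    baseline_rate=1.5,
    confounder_exposure_loading=2.0,
    confounder_mortality_loading=0.4,
    nafld_fraction=0.15,
    seed=99,
)
panel = cc.simulate_panel(cfg)
deaths, truth = cc.simulate_deaths(panel, cfg)

spec = cc.default_feature_spec()
ac = cc.AnalysisConfig()
main = deaths[deaths["cause_class"] != "nafld_control"]
strata = cc.assemble_strata(main, panel, spec)

naive = cc.fit(strata.select_features([l for l in strata.feature_labels if "lead" not in l]))
print(f"naive (no lead control):   {cc.percent_increase(naive, 'pm25_ma02').percent:+.2f}%")

joint = cc.nec_adjusted_fit(strata, ac)
lead = cc.percent_increase(joint, "pm25_lead1")
print(f"lead-1 diagnostic:         {lead.percent:+.2f}% (z={lead.beta / lead.se:+.1f}) "
      "<- non-zero flags an omitted confounder")

corr = cc.difference_correction(joint, "pm25_ma02", "pm25_lead1", pollutant="pm25")
print(f"difference correction:     {corr.estimate.percent:+.2f}%")

nafld = deaths[deaths["cause_class"] == "nafld_control"]
noc = cc.noc_fit(cc.assemble_strata(nafld, panel, spec), ac)
print(f"negative-outcome control:  {noc.estimates['pm25'].percent:+.2f}% "
      f"(consistent with null: {noc.consistent_with_null})")

counts = causal.aggregate_daily_counts(deaths, panel)
surrogate = cc.fit_surrogate(panel, counts, ac)
_, two_stage = cc.two_stage_fit(strata, surrogate, ac)
print(f"two-stage surrogate model: {two_stage['pm25'].percent:+.2f}%")

print(f"\nPlanted truth: +0.73%. The naive estimate absorbs the confounder "
      "bias; both corrections should land far closer to the truth.")
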