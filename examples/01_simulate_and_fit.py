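"""Simulate a small multi-region world and fit the three-pollutant model.

Builds a synthetic daily exposure panel and death records with a planted
PM2.5 effect of 0.73% per 10 ug/m3, assembles time-stratified case-crossover
strata, and fits the conditional-logistic model with lag 0-2 pollutant
moving averages, lead-1 negative exposure controls and weather terms.
"""

import casecross as cc

cfg = cc.SimulationConfig(seed=20)  # desk-scale default: 50 regions x 3 years
panel = cc.simulate_panel(cfg)
deaths, truth = cc.simulate_deaths(panel, cfg)
print(f"panel: {len(panel):,} region-days; deaths: {len(deaths):,}")

spec = cc.default_feature_spec()
strata = cc.assemble_strata(deaths, panel, spec)
print(f"strata: {strata.n_strata:,} (one per decedent, 3-4 referent days each)")

fit = cc.fit(strata)
print(f"converged in {fit.iterations} Newton steps, log-likelihood {fit.loglik:,.1f}\n")

for p in ("pm25", "o3", "no2"):
    est = cc.percent_increase(fit, f"{p}_ma02", 10.0)
    print(
        f"{p:>4}: {est.percent:+.2f}% per 10 units "
        f"(95% CI {est.ci_low:+.2f} to {est.ci_high:+.2f}, p={est.p_value:.3f})"
    )

print(
    "\nThe PM2.5 row estimates the planted 0.73% increase per 10 ug/m3 "
    "(lag 0-2 moving average); O3 and NO2 were simulated with no effect, so "
    "their intervals should cover 0. Detecting a sub-percent rate change "
    "needs a lot of deaths: ~110k still leave the CI a couple of points wide."
)
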