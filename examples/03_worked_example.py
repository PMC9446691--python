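"""Audit the published worked-example arithmetic on printed numbers.

Two computations that need no data: (1) combining the printed exposure and
lead-1 percent effects into the coefficient-difference corrected percent;
(2) cause-of-death shares from the printed counts.
"""

import numpy as np
import pandas as pd

import casecross as cc
from casecross import pipeline

corrected = cc.corrected_percent_from_printed(0.73, -0.36, delta=10.0)
print(f"exposure +0.73% and lead -0.36% per 10 ug/m3")
print(f"=> corrected percent increase: {corrected:.4f}% (rounds to {round(corrected, 2)}%)")
print("Each percent is converted to a per-10 log coefficient via ln(1+p/100),")
print("the lead coefficient is subtracted, and the result re-expressed.\n")

n_total, n_cvd, n_resp = 3_063_192, 1_053_304, 323_309
codes = np.concatenate(
    [
        np.zeros(n_cvd, np.int8),
        np.ones(n_resp, np.int8),
        np.full(n_total - n_cvd - n_resp, 2, np.int8),
    ]
)
deaths = pd.DataFrame(
    {
        "cause_class": pd.Categorical.from_codes(
            codes, ["cardiovascular", "respiratory", "all_cause_component"]
        )
    }
)
shares = pipeline.cause_shares(deaths)
print(f"of {n_total:,} deaths: {n_cvd:,} cardiovascular = {shares['cardiovascular']}%,")
print(f"{n_resp:,} respiratory = {shares['respiratory']}%")
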