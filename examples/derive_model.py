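"""Re-derive the workload model from a simulated study by stepwise OLS.

Simulates the full external-validation setting (4 sites x 90 days x 5
daily timepoints) with mean staff ratings linked to normalized patient
hours and time-to-MD through the mSEAL coefficients, then runs backward
elimination starting from the three-candidate set (patient hours,
occupancy rate, time to MD). Occupancy rate carries no workload signal
beyond patient hours, so it is usually eliminated, and the retained
coefficients land close to the generating values (1.49, 9.72, 0.18).
"""

import pandas as pd

from edload import build_panel, mean_ratings, stepwise_backward
from edload.simulate import SimConfig, simulate_dataset

config = SimConfig(seed=17, n_days=90)
result = simulate_dataset(config)
panel = pd.concat(
    [
        build_panel(
            [r for r in result.records if r.site_id == p.site_id],
            result.grid.timepoints(),
            p,
        )
        for p in config.sites
    ],
    ignore_index=True,
)
merged = panel.merge(mean_ratings(result.assessments), on=["site_id", "timepoint"])

fit = stepwise_backward(
    merged[["patient_hours", "occupancy_rate", "time_to_md"]],
    merged["mean_rating"],
    alpha=0.05,
)
print(f"n = {fit.n} timepoints, r^2 = {fit.r_squared:.3f}")
print(f"eliminated: {list(fit.eliminated)}")
for term in ("intercept", *fit.retained_terms):
    print(
        f"  {term:15s} {fit.coefficients[term]:+7.3f}"
        f"  (se {fit.std_errors[term]:.3f}, p {fit.p_values[term]:.2g})"
    )
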