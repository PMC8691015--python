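"""Structure-specific variability estimates from a tidy value table.

The log-normal model turns the within-(structure x patient) spread of
positive quantities into a CV with an exact credible interval; the beta
model gives the SD of the V5GY fraction; ICC(2) measures absolute
agreement between observers across patients.
"""

import numpy as np
import pandas as pd

from heartatlas import beta_precision_sd, icc2, lognormal_cv

rng = np.random.default_rng(7)

# simulated volumes: 8 patients x 5 observers, true CV 8%
patients = np.repeat([f"p{i}" for i in range(8)], 5)
observers = np.tile([f"o{j}" for j in range(5)], 8)
true_means = rng.uniform(600, 800, 8)
volumes = pd.DataFrame(
    {
        "structure": "heart",
        "patient": patients,
        "observer": observers,
        "value": np.repeat(true_means, 5) * np.exp(rng.normal(0, 0.08, 40)),
    }
)

cv = lognormal_cv(volumes)[0]
print(f"volume CV : {cv.estimate:.1%} "
      f"(95% credible {cv.interval_low:.1%} - {cv.interval_high:.1%})")

icc = icc2(volumes)[0]
print(f"ICC(2)    : {icc.estimate:.2f} "
      f"(95% CI {icc.interval_low:.2f} - {icc.interval_high:.2f})")

v5 = volumes.assign(value=rng.beta(2.0, 12.0, 40))
sd = beta_precision_sd(v5, n_boot=200, seed=1)[0]
print(f"V5GY SD   : {sd.estimate:.3f} "
      f"(95% bootstrap {sd.interval_low:.3f} - {sd.interval_high:.3f})")

# The CV answers: by how much (relatively) do observers disagree on the
# same patient's structure?  The ICC answers: how well does the metric
# still separate patients despite that disagreement?
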