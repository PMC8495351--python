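"""Compare the KFSD equation with the published alternatives.

Evaluates each model variant on one shared synthetic evaluation dataset
(generated from the KFSD equation, so KFSD should win).  Columns: the
observed-on-predicted regression (intercept/slope/R^2), RMSPE (kg/d), and
the mean and slope biases with their p-values — a model is unbiased when
both p-values exceed 0.05.
"""

from dmintake import compare_models
from dmintake.synthetic_data import LiteratureGenConfig, generate_literature

ev = generate_literature(LiteratureGenConfig(n_studies=42, n_obs_total=168, seed=30))
table = compare_models(ev, ["kfsd", "nrc", "nrc_lag2", "cncps", "cncps_lag3", "jfs"])
print(table.round(3).to_string())
print(f"\nlowest RMSPE: {table['rmspe'].idxmin()} "
      f"({table['rmspe'].min():.2f} kg/d)")
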