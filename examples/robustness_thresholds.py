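"""Is the negative error dependence an artifact of the obesity cutoff?

The treatment is a thresholded BMI. This script redefines obesity at the
WHO class limits and midpoints (30, 32.5, 35, 37.5, 40, 42.45), and also
drops the underweight (BMI < 18.5), refitting the model each time. If the
negative dependence between the equations' errors is real, the estimated
Kendall's tau keeps its sign in every scenario.

Run:  python examples/robustness_thresholds.py   (~40 s)
"""

import warnings

from rebicop import generate, model_spec_for, run_robustness, simple_config

warnings.simplefilter("ignore", RuntimeWarning)

cfg = simple_config(n=8000, seed=12, family="N", tau=-0.30, gamma=1.0)
ds = generate(cfg)
spec = model_spec_for(cfg, num_basis=8)
table = run_robustness(spec, ds.data, n_draws=300, seed=5)
cols = ["scenario", "n", "treated_share", "tau", "tau_lower", "tau_upper",
        "sate_pct"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"""
Data were generated with tau = -0.30. All scenarios should report a negative
tau: redefining the cutoff changes the treated share ({table.treated_share.min():.3f}
to {table.treated_share.max():.3f}) but not the sign of the error dependence.""")
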