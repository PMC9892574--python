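"""Compare copula families and link functions on one dataset.

Fits a small grid of models (copula family x link pair), ranks them by AIC
and prints the comparison table: each row shows the dependence (Kendall's
tau) and the treatment effect (SATE, in percentage points) that family
implies, with 95% posterior intervals.

Run:  python examples/model_grid.py   (~30 s)
"""

import warnings

from rebicop import AnalysisConfig, generate, run_grid, simple_config

warnings.simplefilter("ignore", RuntimeWarning)

ds = generate(simple_config(n=4000, seed=3, family="PL", tau=-0.29, gamma=1.0))
config = AnalysisConfig(
    outcome="disease", treatment="obesity", instrument="limitation",
    parametric_treatment=("gender", "limitation"),
    parametric_outcome=("gender",),
    smooth_treatment=("age",), smooth_outcome=("age",),
    num_basis=8,
    copulas=("PL", "N", "F"),
    link_pairs=(("probit", "probit"), ("probit", "logit")),
    n_draws=400, seed=7,
)
result = run_grid(config, ds.data)
print(result.text())
print(f"\nbest model: {result.best.spec.label}  "
      f"(generator: PL with tau = -0.29, SATE = "
      f"{100 * ds.truth['true_sate']:.1f}%)")
print("""
Lower AIC/BIC means better fit after penalizing complexity. Families with
similar AIC typically give overlapping SATE intervals; the dependence
estimate tau is the part that shifts most across families.""")
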