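"""Plain-text and tabular reports of fitted models.

The single-fit summary mirrors the conventional layout of semiparametric
joint-regression software: a parametric coefficient block per equation
(estimate, standard error, z, p), a smooth-term block (EDF against the
reference degrees of freedom), and the dependence summary (theta, Kendall's
tau, optionally with a posterior interval).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy.special import ndtr

__all__ = ["fit_summary", "coefficient_table", "grid_table_text"]


def coefficient_table(fitted) -> pd.DataFrame:
    """Estimates, SEs, z-values and two-sided normal p-values per coefficient."""
    se = fitted.se()
    est = fitted.coef
    z = est / se
    p = 2.0 * (1.0 - ndtr(np.abs(z)))
    return pd.DataFrame({
        "estimate": est, "std_error": se, "z_value": z, "p_value": p,
    }, index=list(fitted.coef_names))


def _equation_block(fitted, tag: str, title: str, lines: list):
    tab = coefficient_table(fitted)
    parametric = [n for n in tab.index
                  if n.startswith(f"{tag}:") and not n.startswith(f"{tag}:s(")]
    smooth_names = [n for n in fitted.edf_by_smooth if n.startswith(f"{tag}:")]
    lines.append(title)
    lines.append("-" * len(title))
    sub = tab.loc[parametric].copy()
    sub.index = [n.split(":", 1)[1] for n in sub.index]
    lines.append(sub.to_string(float_format=lambda v: f"{v: .3f}"))
    if smooth_names:
        sm = pd.DataFrame({
            "edf": [fitted.edf_by_smooth[n] for n in smooth_names],
            "ref_df": [fitted.ref_df_by_smooth[n] for n in smooth_names],
        }, index=[n.split(":", 1)[1] for n in smooth_names])
        lines.append("")
        lines.append(sm.to_string(float_format=lambda v: f"{v: .3f}"))
    lines.append("")


def fit_summary(fitted, tau_result=None, sate_result=None) -> str:
    """Human-readable model summary in the two-equation table layout."""
    lines: list = []
    spec = fitted.spec
    lines.append(f"Recursive bivariate copula model: {spec.label}")
    lines.append(f"n = {fitted.n_obs}, logLik = {fitted.loglik:.2f}, "
                 f"total EDF = {fitted.edf_total:.2f}, "
                 f"AIC = {fitted.aic:.2f}, BIC = {fitted.bic:.2f}")
    lines.append("")
    _equation_block(fitted, "eq1",
                    f"Treatment equation ({spec.treatment_eq.response}, "
                    f"{spec.link_treatment} link)", lines)
    _equation_block(fitted, "eq2",
                    f"Outcome equation ({spec.outcome_eq.response}, "
                    f"{spec.link_outcome} link)", lines)
    if tau_result is not None and tau_result.lower is not None:
        lines.append(f"Kendall tau = {tau_result.tau: .3f}  "
                     f"({tau_result.lower: .3f}, {tau_result.upper: .3f})"
                     f"  [{int(tau_result.level * 100)}% posterior interval]")
    else:
        lines.append(f"Kendall tau = {fitted.tau: .3f}  (theta = {fitted.theta: .3f})")
    if sate_result is not None and sate_result.lower is not None:
        lines.append(f"SATE = {sate_result.percent: .1f}%  "
                     f"({100 * sate_result.lower: .1f}%, {100 * sate_result.upper: .1f}%)")
    return "\n".join(lines)


def grid_table_text(table: pd.DataFrame) -> str:
    """Model-comparison table: family(links), tau (CI), SATE% (CI), AIC, BIC."""
    out = table.copy()
    if {"tau", "tau_lower", "tau_upper"} <= set(out.columns):
        out["tau (95% CI)"] = out.apply(
            lambda r: f"{r['tau']: .3f} ({r['tau_lower']: .3f},{r['tau_upper']: .3f})"
            if np.isfinite(r.get("tau_lower", np.nan)) else f"{r['tau']: .3f}",
            axis=1)
    if {"sate_pct", "sate_lower_pct", "sate_upper_pct"} <= set(out.columns):
        out["SATE% (95% CI)"] = out.apply(
            lambda r: f"{r['sate_pct']: .1f} ({r['sate_lower_pct']: .1f},{r['sate_upper_pct']: .1f})"
            if np.isfinite(r.get("sate_lower_pct", np.nan)) else f"{r['sate_pct']: .1f}",
            axis=1)
    cols = [c for c in ("model", "tau (95% CI)", "SATE% (95% CI)", "aic", "bic",
                        "converged") if c in out.columns]
    return out[cols].to_string(index=False,
                               float_format=lambda v: f"{v:.2f}")
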