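"""Treatment-effect and dependence summaries with posterior intervals.

The sample average treatment effect (SATE) is the average over the sample of
the difference in model-implied outcome probabilities with the treatment
indicator set to 1 versus 0 for every individual, all other covariates held
fixed — an intervention quantity, not a conditional-on-observed contrast.
Intervals for SATE and for Kendall's tau come from simulating coefficient
vectors from the large-sample posterior N(phi_hat, H_p^{-1}) and reading off
equal-tailed empirical quantiles; these intervals need not be symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .copulas import CopulaSpec, theta_to_tau
from .model import FittedBicopula, posterior_draws

__all__ = ["SateResult", "TauResult", "sate", "sate_interval", "tau_interval"]


@dataclass(frozen=True)
class SateResult:
    estimate: float
    lower: float | None = None
    upper: float | None = None
    level: float = 0.95
    n_draws: int = 0
    seed: int | None = None

    @property
    def percent(self) -> float:
        """The effect as a percentage-point difference in probability."""
        return 100.0 * self.estimate


@dataclass(frozen=True)
class TauResult:
    tau: float
    lower: float | None = None
    upper: float | None = None
    family: str = ""
    level: float = 0.95
    n_draws: int = 0
    seed: int | None = None


def _toggled_designs(fitted: FittedBicopula, data: pd.DataFrame):
    """Outcome design matrices with the treatment set to 1 and to 0."""
    frame = fitted.frame
    treated = data.copy()
    treated[fitted.spec.treatment] = 1.0
    untreated = data.copy()
    untreated[fitted.spec.treatment] = 0.0
    X1 = frame.design2.matrix(treated)
    X0 = frame.design2.matrix(untreated)
    return X1, X0


def _sate_values(fitted: FittedBicopula, X1, X0, coefs: np.ndarray) -> np.ndarray:
    """SATE for each coefficient row (vectorized over posterior draws)."""
    frame = fitted.frame
    phi2 = coefs[:, frame.d1: frame.d1 + frame.d2]
    p1 = frame.link2.prob(X1 @ phi2.T)
    p0 = frame.link2.prob(X0 @ phi2.T)
    return np.mean(p1 - p0, axis=0)


def sate(fitted: FittedBicopula, data: pd.DataFrame) -> SateResult:
    """Point estimate of the sample average treatment effect."""
    X1, X0 = _toggled_designs(fitted, data)
    val = _sate_values(fitted, X1, X0, fitted.coef[None, :])[0]
    return SateResult(estimate=float(val))


def sate_interval(fitted: FittedBicopula, data: pd.DataFrame,
                  n_draws: int = 1000, level: float = 0.95,
                  seed=None) -> SateResult:
    """SATE with an equal-tailed posterior-simulation interval."""
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100 for quantile intervals")
    X1, X0 = _toggled_designs(fitted, data)
    point = float(_sate_values(fitted, X1, X0, fitted.coef[None, :])[0])
    draws = posterior_draws(fitted, n_draws, seed=seed)
    vals = _sate_values(fitted, X1, X0, draws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return SateResult(estimate=point, lower=float(lo), upper=float(hi),
                      level=level, n_draws=n_draws, seed=seed)


def tau_interval(fitted: FittedBicopula, n_draws: int = 1000,
                 level: float = 0.95, seed=None) -> TauResult:
    """Kendall's tau with an equal-tailed posterior-simulation interval.

    Each posterior draw of the unconstrained association parameter is mapped
    through the family link and the theta -> tau conversion.
    """
    fam = fitted.spec.family
    if fitted.frame.fix_theta is not None:
        return TauResult(tau=fitted.tau, lower=fitted.tau, upper=fitted.tau,
                         family=fam.value, level=level, n_draws=0, seed=seed)
    draws = posterior_draws(fitted, n_draws, seed=seed)
    stars = draws[:, -1]
    thetas = fitted.frame.tlink.to_theta(stars)
    taus = np.empty(thetas.size)
    cache: dict = {}
    for i, th in enumerate(np.asarray(thetas, dtype=float)):
        if th not in cache:
            cache[th] = theta_to_tau(fitted.frame.copula_spec(th))
        taus[i] = cache[th]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(taus, [alpha, 1.0 - alpha])
    return TauResult(tau=fitted.tau, lower=float(lo), upper=float(hi),
                     family=fam.value, level=level, n_draws=n_draws, seed=seed)
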