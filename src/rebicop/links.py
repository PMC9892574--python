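"""Margin link functions for the binary equations.

Each link maps a linear/additive predictor ``eta`` to the success probability
``P(y=1)``.  The latent-variable reading is ``P(y=1) = 1 - F(-eta)`` for an
error CDF ``F``: standard normal (probit), standard logistic (logit), and a
Gumbel error giving the complementary log-log mean function
``1 - exp(-exp(eta))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit, logit as _logit_fn, ndtr, ndtri

__all__ = ["LinkFunction", "get_link", "LINKS"]

_ETA_CLIP = 37.0  # keeps exp() in range; probabilities saturate well before


@dataclass(frozen=True)
class LinkFunction:
    """A binary-margin link: success probability, its density, and inverse."""

    code: str
    prob: Callable          # eta -> P(y=1)
    density: Callable       # eta -> d P(y=1) / d eta
    inverse: Callable       # p -> eta


def _probit_prob(eta):
    return ndtr(eta)


def _probit_density(eta):
    return np.exp(-0.5 * np.square(eta)) / np.sqrt(2.0 * np.pi)


def _logit_prob(eta):
    return expit(eta)


def _logit_density(eta):
    p = expit(eta)
    return p * (1.0 - p)


def _cloglog_prob(eta):
    return -np.expm1(-np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def _cloglog_density(eta):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return np.exp(eta - np.exp(eta))


def _cloglog_inverse(p):
    return np.log(-np.log1p(-np.asarray(p, dtype=float)))


LINKS = {
    "probit": LinkFunction("probit", _probit_prob, _probit_density, ndtri),
    "logit": LinkFunction("logit", _logit_prob, _logit_density, _logit_fn),
    "cloglog": LinkFunction("cloglog", _cloglog_prob, _cloglog_density, _cloglog_inverse),
}


def get_link(code) -> LinkFunction:
    if isinstance(code, LinkFunction):
        return code
    try:
        return LINKS[str(code)]
    except KeyError as exc:
        raise ValueError(
            f"unknown link {code!r}; choose one of {sorted(LINKS)}"
        ) from exc
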