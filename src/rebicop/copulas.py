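"""Bivariate copula families for binary-margin regression.

Six one-parameter families are supported (the Student-t carries an extra,
fixed degrees-of-freedom setting): Ali-Mikhail-Haq ("AMH"),
Farlie-Gumbel-Morgenstern ("FGM"), Plackett ("PL"), Frank ("F"),
Gaussian ("N") and Student-t ("T").  Each family provides

* the CDF ``C_theta(p1, p2)``,
* the partial derivatives ``dC/dp1`` and ``dC/dp2`` (conditional CDFs),
* the derivative in the association parameter ``dC/dtheta`` (used by the
  likelihood score),
* the Kendall's tau map ``theta_to_tau`` and its inverse,
* exact sampling, and
* a smooth bijection between theta's native range and the real line so the
  association parameter can be optimised without constraints.

The Gaussian CDF is assembled from Owen's T function; the Student-t CDF uses
a fixed Gauss-Legendre rule on the exact conditional representation
``C(u,v) = int_0^u F_{z+1}(g(t_z^{-1}(w))) dw`` with a cusp-absorbing change
of variables, so that the implemented ``dC/du``, ``dC/dv`` and ``dC/dtheta``
are the exact derivatives of the implemented CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate, optimize
from scipy.special import expit, ndtr, ndtri, owens_t, stdtr, stdtrit

__all__ = [
    "CopulaFamily",
    "CopulaSpec",
    "copula_cdf",
    "copula_partials",
    "copula_dtheta",
    "copula_density",
    "theta_to_tau",
    "tau_to_theta",
    "tau_range",
    "sample_copula",
    "theta_link",
    "ThetaLink",
]

_PROB_EPS = 1e-12  # probability clipping used inside partials / likelihoods
_T_NODES = 16      # Gauss-Legendre nodes for the Student-t CDF (the angle
                   # substitution makes the rule converge by ~8 nodes)


class CopulaFamily(str, Enum):
    """Family codes, serialized exactly as the short strings below."""

    AMH = "AMH"
    FGM = "FGM"
    PL = "PL"
    F = "F"
    N = "N"
    T = "T"


def _as_family(family) -> CopulaFamily:
    if isinstance(family, CopulaFamily):
        return family
    try:
        return CopulaFamily(str(family))
    except ValueError as exc:
        raise ValueError(
            f"unknown copula family {family!r}; choose one of "
            f"{[f.value for f in CopulaFamily]}"
        ) from exc


# native theta ranges (closed where the endpoint is admissible)
_THETA_RANGE = {
    CopulaFamily.AMH: (-1.0, 1.0),
    CopulaFamily.FGM: (-1.0, 1.0),
    CopulaFamily.PL: (0.0, math.inf),
    CopulaFamily.F: (-math.inf, math.inf),
    CopulaFamily.N: (-1.0, 1.0),
    CopulaFamily.T: (-1.0, 1.0),
}


@dataclass(frozen=True)
class CopulaSpec:
    """A copula family together with its association parameter.

    Parameters
    ----------
    family : CopulaFamily or str
        One of "AMH", "FGM", "PL", "F", "N", "T".
    theta : float
        Association parameter, inside the family's native range.
    zeta : float, default 3.0
        Degrees of freedom, used only by the Student-t family; must
        exceed 2 so that the correlation parameterisation is valid.
    """

    family: CopulaFamily
    theta: float
    zeta: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "family", _as_family(self.family))
        theta = float(self.theta)
        if not np.isfinite(theta):
            raise ValueError("theta must be finite")
        lo, hi = _THETA_RANGE[self.family]
        if self.family is CopulaFamily.PL:
            if theta <= 0.0:
                raise ValueError("Plackett theta must lie in (0, inf)")
        elif not (lo <= theta <= hi):
            raise ValueError(
                f"theta={theta} outside the {self.family.value} range [{lo}, {hi}]"
            )
        object.__setattr__(self, "theta", theta)
        zeta = float(self.zeta)
        if self.family is CopulaFamily.T and not zeta > 2.0:
            raise ValueError("Student-t degrees of freedom zeta must exceed 2")
        object.__setattr__(self, "zeta", zeta)


def _check_probs(p1, p2, open_interval=False):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any(np.isnan(p1)) or np.any(np.isnan(p2)):
        raise ValueError("probability inputs contain NaN")
    lo, hi = (0.0, 1.0)
    if np.any(p1 < lo) or np.any(p1 > hi) or np.any(p2 < lo) or np.any(p2 > hi):
        raise ValueError("probability inputs must lie in [0, 1]")
    if open_interval:
        p1 = np.clip(p1, _PROB_EPS, 1.0 - _PROB_EPS)
        p2 = np.clip(p2, _PROB_EPS, 1.0 - _PROB_EPS)
    return p1, p2


# ---------------------------------------------------------------------------
# Gaussian copula: Owen's T assembly of the bivariate normal CDF
# ---------------------------------------------------------------------------

def _bvn_cdf(x, y, rho):
    """Standard bivariate normal CDF P(X<=x, Y<=y) with correlation rho."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return ndtr(np.minimum(x, y))
        return np.maximum(ndtr(x) + ndtr(y) - 1.0, 0.0)
    # nudge exact zeros so the Owen's T arguments are well defined
    x = np.where(x == 0.0, 1e-15, x)
    y = np.where(y == 0.0, 1e-15, y)
    denom = math.sqrt(1.0 - rho * rho)
    ax = (y - rho * x) / (x * denom)
    ay = (x - rho * y) / (y * denom)
    beta = np.where((x * y > 0.0) | ((x * y == 0.0) & (x + y >= 0.0)), 0.0, 0.5)
    out = 0.5 * (ndtr(x) + ndtr(y)) - owens_t(x, ax) - owens_t(y, ay) - beta
    return np.clip(out, 0.0, 1.0)


def _bvn_pdf(x, y, rho):
    q = 1.0 - rho * rho
    z = (x * x - 2.0 * rho * x * y + y * y) / q
    return np.exp(-0.5 * z) / (2.0 * math.pi * math.sqrt(q))


# ---------------------------------------------------------------------------
# Student-t copula: differentiable fixed quadrature of the conditional form
# ---------------------------------------------------------------------------

def _t_const(df: float) -> float:
    return math.exp(math.lgamma((df + 1.0) / 2.0) - math.lgamma(df / 2.0)) \
        / math.sqrt(df * math.pi)


def _t_pdf(x, df):
    t = 1.0 + x * x / df
    e2 = (df + 1.0) / 2.0
    if float(e2).is_integer():
        core = t ** (-int(e2))
    elif float(2.0 * e2).is_integer():
        core = t ** (-int(e2 - 0.5)) / np.sqrt(t)
    else:
        core = np.exp(-e2 * np.log1p(x * x / df))
    return _t_const(df) * core


_T_CDF_CACHE: dict = {}


def _t_cdf_fast(df: float):
    """Vectorized t CDF, cheap enough to sit inside quadrature loops.

    For integer degrees of freedom the CDF is exact and elementary: with
    ``phi = arctan(x / sqrt(df))`` it equals ``1/2 + I_{df-1}(phi) /
    (2 I_{df-1}(pi/2))`` where ``I_k(phi) = int_0^phi cos^k`` follows the
    classical reduction ``I_k = cos^{k-1}(phi) sin(phi)/k + (k-1)/k I_{k-2}``.
    Non-integer df falls back to a cubic spline of the cephes CDF tabulated
    in the angle coordinate (absolute accuracy ~1e-10).
    """
    key = round(float(df), 9)
    if key in _T_CDF_CACHE:
        return _T_CDF_CACHE[key]
    sq = math.sqrt(df)
    if float(df).is_integer() and df <= 40:
        k_top = int(df) - 1

        def cos_int(phi, k):
            # I_k(phi) = int_0^phi cos^k t dt by downward reduction
            if k == 0:
                return phi
            if k == 1:
                return np.sin(phi)
            c, s = np.cos(phi), np.sin(phi)
            return (c ** (k - 1)) * s / k + (k - 1) / k * cos_int(phi, k - 2)

        half = float(np.asarray(cos_int(np.array(math.pi / 2.0), k_top)))

        def F(z):
            phi = np.arctan(z / sq)
            return 0.5 + cos_int(phi, k_top) / (2.0 * half)
    else:
        from scipy.interpolate import CubicSpline

        phi_grid = np.linspace(-math.pi / 2.0, math.pi / 2.0, 4001)
        x = sq * np.tan(np.clip(phi_grid, -math.pi / 2 + 1e-12, math.pi / 2 - 1e-12))
        vals = stdtr(df, x)
        vals[0], vals[-1] = 0.0, 1.0
        spl = CubicSpline(phi_grid, vals)

        def F(z):
            return np.clip(spl(np.arctan(z / sq)), 0.0, 1.0)

    _T_CDF_CACHE[key] = F
    return F


_T_NODE_CACHE: dict = {}


def _t_quad_nodes(n=_T_NODES):
    if n not in _T_NODE_CACHE:
        nodes, weights = leggauss(n)
        _T_NODE_CACHE[n] = (0.5 * (nodes + 1.0), 0.5 * weights)
    return _T_NODE_CACHE[n]


def _t_copula_terms(u, v, theta, zeta, what):
    """Shared quadrature for the Student-t copula CDF and its derivatives.

    The conditional representation C(u,v) = int_{-inf}^{x_u} f_z(x)
    F_{z+1}(g(x)) dx is integrated in the compactified variable
    psi = arctan(x / c) with psi = -pi/2 + L t^2 on Gauss-Legendre nodes t
    (L = psi_u + pi/2); the squared map absorbs the boundary cusp of the
    heavy-tailed weight, and the scale c = min(sqrt(z), 4) keeps the
    integrand well spread for any degrees of freedom.  ``what`` in
    {"cdf", "du", "dv", "dtheta", "all"}; all outputs are derivatives of the
    same fixed rule, hence mutually consistent to rounding error.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    u, v = np.broadcast_arrays(u, v)
    nu = float(zeta)
    c0 = min(math.sqrt(nu), 4.0)
    Fnu1 = _t_cdf_fast(nu + 1.0)
    t, wts = _t_quad_nodes()
    xu = stdtrit(nu, np.clip(u, _PROB_EPS, 1 - _PROB_EPS))
    y = stdtrit(nu, np.clip(v, _PROB_EPS, 1 - _PROB_EPS))[..., None]
    L = (np.arctan(xu / c0) + math.pi / 2.0)[..., None]       # (..., 1)
    psi = -math.pi / 2.0 + L * (t * t)                        # (..., K)
    tpsi = np.tan(np.clip(psi, -math.pi / 2 + 1e-12, None))
    sec2 = 1.0 + tpsi * tpsi
    x = c0 * tpsi
    w = _t_pdf(x, nu) * c0 * sec2                             # f_z(x) dx/dpsi
    q = math.sqrt(1.0 - theta * theta)
    r = np.sqrt((nu + 1.0) / (nu + x * x))
    g = (y - theta * x) * r / q
    base = 2.0 * t * wts                                      # GL weights x t^2 jac
    if what == "cdf":
        return (L * w * Fnu1(g)) @ base
    fg = _t_pdf(g, nu + 1.0)

    def du_val(F):
        # d/dL of  L * sum_k base_k w(psi_k(L)) F(g(x(psi_k)))
        wprime = w * (-(nu + 1.0) * x / (nu + x * x) * c0 * sec2 + 2.0 * tpsi)
        gp = (-theta * r + (y - theta * x) * (-x * r / (nu + x * x))) / q
        inner = w * F + L * (t * t) * (wprime * F + w * fg * gp * c0 * sec2)
        dCdL = inner @ base
        dLdu = (np.cos(np.squeeze(L, -1) - math.pi / 2.0) ** 2 / c0) / _t_pdf(xu, nu)
        return dCdL * dLdu

    if what == "dv":
        return ((L * w * fg * r / q) @ base) / _t_pdf(np.squeeze(y, -1), nu)
    if what == "dtheta":
        return (L * w * fg * r * (theta * y - x) / q ** 3) @ base
    if what == "du":
        return du_val(Fnu1(g))
    if what == "all":
        F = Fnu1(g)
        cdf = (L * w * F) @ base
        dv = ((L * w * fg * r / q) @ base) / _t_pdf(np.squeeze(y, -1), nu)
        dth = (L * w * fg * r * (theta * y - x) / q ** 3) @ base
        return cdf, du_val(F), dv, dth
    raise ValueError(what)


def _t_cdf(u, v, theta, zeta):
    if abs(theta) >= 1.0 - 1e-9:
        if theta > 0:
            return np.minimum(u, v)
        return np.maximum(u + v - 1.0, 0.0)
    return _t_copula_terms(u, v, theta, zeta, "cdf")


# ---------------------------------------------------------------------------
# CDFs
# ---------------------------------------------------------------------------

def copula_cdf(spec: CopulaSpec, p1, p2):
    """Evaluate ``C_theta(p1, p2)``; vectorized over probability inputs."""
    u, v = _check_probs(p1, p2)
    th = spec.theta
    fam = spec.family
    scalar = np.ndim(u) == 0 and np.ndim(v) == 0
    u = np.atleast_1d(u)
    v = np.atleast_1d(v)
    if fam is CopulaFamily.AMH:
        out = u * v / (1.0 - th * (1.0 - u) * (1.0 - v))
    elif fam is CopulaFamily.FGM:
        out = u * v * (1.0 + th * (1.0 - u) * (1.0 - v))
    elif fam is CopulaFamily.PL:
        if abs(th - 1.0) < 1e-6:
            out = u * v * (1.0 + (th - 1.0) * (1.0 - u) * (1.0 - v))
        else:
            Q = 1.0 + (th - 1.0) * (u + v)
            R = Q * Q - 4.0 * th * (th - 1.0) * u * v
            out = (Q - np.sqrt(R)) / (2.0 * (th - 1.0))
    elif fam is CopulaFamily.F:
        if abs(th) < 1e-6:
            out = u * v * (1.0 + 0.5 * th * (1.0 - u) * (1.0 - v))
        else:
            a = np.expm1(-th * u)
            b = np.expm1(-th * v)
            d = math.expm1(-th)
            out = -np.log1p(a * b / d) / th
    elif fam is CopulaFamily.N:
        if abs(th) < 1e-12:
            out = u * v
        else:
            uc = np.clip(u, _PROB_EPS, 1 - _PROB_EPS)
            vc = np.clip(v, _PROB_EPS, 1 - _PROB_EPS)
            out = _bvn_cdf(ndtri(uc), ndtri(vc), th)
            out = np.where((u == 0) | (v == 0), 0.0, out)
            out = np.where(u == 1.0, v, np.where(v == 1.0, u, out))
    elif fam is CopulaFamily.T:
        out = _t_cdf(np.clip(u, _PROB_EPS, 1 - _PROB_EPS),
                     np.clip(v, _PROB_EPS, 1 - _PROB_EPS), th, spec.zeta)
        out = np.where((u == 0) | (v == 0), 0.0, out)
        out = np.where(u == 1.0, v, np.where(v == 1.0, u, out))
    else:  # pragma: no cover
        raise ValueError(fam)
    out = np.clip(out, np.maximum(u + v - 1.0, 0.0), np.minimum(u, v))
    return float(out[0]) if scalar else out


def copula_density(spec: CopulaSpec, p1, p2):
    """Copula density c(u, v) for the absolutely continuous families.

    Implemented analytically for AMH, FGM, Plackett and Frank (used by the
    Plackett tau quadrature and by Monte-Carlo cross-checks); the Gaussian
    and Student-t densities follow from their latent elliptical forms.
    """
    u, v = _check_probs(p1, p2, open_interval=True)
    th = spec.theta
    fam = spec.family
    if fam is CopulaFamily.FGM:
        return 1.0 + th * (1.0 - 2.0 * u) * (1.0 - 2.0 * v)
    if fam is CopulaFamily.AMH:
        # c = d/dv [ v(1 - th(1-v)) / D^2 ],  D = 1 - th(1-u)(1-v)
        D = 1.0 - th * (1.0 - u) * (1.0 - v)
        return ((1.0 - th + 2.0 * th * v) * D
                - 2.0 * th * (1.0 - u) * v * (1.0 - th * (1.0 - v))) / D ** 3
    if fam is CopulaFamily.PL:
        Q = 1.0 + (th - 1.0) * (u + v)
        R = Q * Q - 4.0 * th * (th - 1.0) * u * v
        return th * (1.0 + (th - 1.0) * (u + v - 2.0 * u * v)) / np.power(R, 1.5)
    if fam is CopulaFamily.F:
        if abs(th) < 1e-6:
            return 1.0 + th * (1.0 - 2.0 * u) * (1.0 - 2.0 * v) / 2.0
        d = math.expm1(-th)
        e = np.exp(-th * (u + v))
        a = np.expm1(-th * u)
        b = np.expm1(-th * v)
        return -th * e * d / (d + a * b) ** 2
    if fam is CopulaFamily.N:
        x, y = ndtri(u), ndtri(v)
        q = 1.0 - th * th
        z = (th * th * (x * x + y * y) - 2.0 * th * x * y) / q
        return np.exp(-0.5 * z) / math.sqrt(q)
    if fam is CopulaFamily.T:
        nu = spec.zeta
        x, y = stdtrit(nu, u), stdtrit(nu, v)
        q = 1.0 - th * th
        lg = (math.lgamma((nu + 2.0) / 2.0) + math.lgamma(nu / 2.0)
              - 2.0 * math.lgamma((nu + 1.0) / 2.0))
        core = np.power(1.0 + (x * x - 2.0 * th * x * y + y * y) / (nu * q),
                        -(nu + 2.0) / 2.0)
        marg = np.power((1.0 + x * x / nu) * (1.0 + y * y / nu), (nu + 1.0) / 2.0)
        return math.exp(lg) / math.sqrt(q) * core * marg
    raise ValueError(fam)  # pragma: no cover


# ---------------------------------------------------------------------------
# Partial derivatives
# ---------------------------------------------------------------------------

def copula_partials(spec: CopulaSpec, p1, p2):
    """Return ``(dC/dp1, dC/dp2)``.

    ``dC/dp1`` is the conditional distribution of the second uniform given the
    first; probabilities are clipped away from {0, 1} for numerical stability.
    """
    u, v = _check_probs(p1, p2, open_interval=True)
    th = spec.theta
    fam = spec.family
    if fam is CopulaFamily.AMH:
        den = 1.0 - th * (1.0 - u) * (1.0 - v)
        d1 = v * (1.0 - th * (1.0 - v)) / den ** 2
        d2 = u * (1.0 - th * (1.0 - u)) / den ** 2
    elif fam is CopulaFamily.FGM:
        d1 = v + th * v * (1.0 - v) * (1.0 - 2.0 * u)
        d2 = u + th * u * (1.0 - u) * (1.0 - 2.0 * v)
    elif fam is CopulaFamily.PL:
        if abs(th - 1.0) < 1e-6:
            dl = th - 1.0
            d1 = v + dl * v * (1.0 - v) * (1.0 - 2.0 * u)
            d2 = u + dl * u * (1.0 - u) * (1.0 - 2.0 * v)
        else:
            Q = 1.0 + (th - 1.0) * (u + v)
            R = Q * Q - 4.0 * th * (th - 1.0) * u * v
            sR = np.sqrt(R)
            d1 = 0.5 * (1.0 - (Q - 2.0 * th * v) / sR)
            d2 = 0.5 * (1.0 - (Q - 2.0 * th * u) / sR)
    elif fam is CopulaFamily.F:
        if abs(th) < 1e-6:
            d1 = v + 0.5 * th * v * (1.0 - v) * (1.0 - 2.0 * u)
            d2 = u + 0.5 * th * u * (1.0 - u) * (1.0 - 2.0 * v)
        else:
            a = np.expm1(-th * u)
            b = np.expm1(-th * v)
            d = math.expm1(-th)
            d1 = np.exp(-th * u) * b / (d + a * b)
            d2 = np.exp(-th * v) * a / (d + a * b)
    elif fam is CopulaFamily.N:
        if abs(th) >= 1.0 - 1e-12:
            # comonotone / countermonotone limits
            d1 = np.where(v >= u, 1.0, 0.0) if th > 0 else np.where(u + v >= 1.0, 1.0, 0.0)
            d2 = np.where(u >= v, 1.0, 0.0) if th > 0 else np.where(u + v >= 1.0, 1.0, 0.0)
        else:
            x, y = ndtri(u), ndtri(v)
            q = math.sqrt(1.0 - th * th)
            d1 = ndtr((y - th * x) / q)
            d2 = ndtr((x - th * y) / q)
    elif fam is CopulaFamily.T:
        nu = spec.zeta
        if abs(th) >= 1.0 - 1e-9:
            d1 = np.where(v >= u, 1.0, 0.0) if th > 0 else np.where(u + v >= 1.0, 1.0, 0.0)
            d2 = np.where(u >= v, 1.0, 0.0) if th > 0 else np.where(u + v >= 1.0, 1.0, 0.0)
        else:
            x, y = stdtrit(nu, u), stdtrit(nu, v)
            q = math.sqrt(1.0 - th * th)
            d1 = stdtr(nu + 1.0, (y - th * x) * np.sqrt((nu + 1.0) / (nu + x * x)) / q)
            d2 = stdtr(nu + 1.0, (x - th * y) * np.sqrt((nu + 1.0) / (nu + y * y)) / q)
    else:  # pragma: no cover
        raise ValueError(fam)
    return np.clip(d1, 0.0, 1.0), np.clip(d2, 0.0, 1.0)


def copula_dtheta(spec: CopulaSpec, p1, p2):
    """Derivative of the CDF in theta, used by the likelihood score."""
    u, v = _check_probs(p1, p2, open_interval=True)
    th = spec.theta
    fam = spec.family
    if fam is CopulaFamily.AMH:
        den = 1.0 - th * (1.0 - u) * (1.0 - v)
        return u * v * (1.0 - u) * (1.0 - v) / den ** 2
    if fam is CopulaFamily.FGM:
        return u * v * (1.0 - u) * (1.0 - v)
    if fam is CopulaFamily.PL:
        if abs(th - 1.0) < 1e-6:
            return u * v * (1.0 - u) * (1.0 - v)
        s = u + v
        Q = 1.0 + (th - 1.0) * s
        R = Q * Q - 4.0 * th * (th - 1.0) * u * v
        sR = np.sqrt(R)
        dR = 2.0 * Q * s - 4.0 * (2.0 * th - 1.0) * u * v
        return (s - dR / (2.0 * sR)) / (2.0 * (th - 1.0)) \
            - (Q - sR) / (2.0 * (th - 1.0) ** 2)
    if fam is CopulaFamily.F:
        if abs(th) < 1e-6:
            return u * v * (1.0 - u) * (1.0 - v) / 2.0
        a = np.expm1(-th * u)
        b = np.expm1(-th * v)
        d = math.expm1(-th)
        da = -u * np.exp(-th * u)
        db = -v * np.exp(-th * v)
        dd = -math.exp(-th)
        C = -np.log1p(a * b / d) / th
        return -C / th - ((dd + da * b + a * db) / (d + a * b) - dd / d) / th
    if fam is CopulaFamily.N:
        return _bvn_pdf(ndtri(u), ndtri(v), th)
    if fam is CopulaFamily.T:
        return _t_copula_terms(u, v, th, spec.zeta, "dtheta")
    raise ValueError(fam)  # pragma: no cover


def _t_partial_u_quadrature(spec: CopulaSpec, p1, p2):
    """dC/dp1 of the *implemented* Student-t quadrature rule (internal)."""
    u, v = _check_probs(p1, p2, open_interval=True)
    return _t_copula_terms(u, v, spec.theta, spec.zeta, "du")


def _t_partial_v_quadrature(spec: CopulaSpec, p1, p2):
    u, v = _check_probs(p1, p2, open_interval=True)
    return _t_copula_terms(u, v, spec.theta, spec.zeta, "dv")


# ---------------------------------------------------------------------------
# Kendall's tau
# ---------------------------------------------------------------------------

def _debye1(theta: float) -> float:
    """First Debye function D1(theta) = (1/theta) * int_0^theta t/(e^t - 1) dt."""

    def integrand(t):
        t = np.asarray(t, dtype=float)
        small = np.abs(t) < 1e-8
        safe = np.where(small, 1.0, t)
        return np.where(small, 1.0 - t / 2.0, safe / np.expm1(safe))

    val, err = integrate.quad(integrand, 0.0, theta, limit=200)
    if not np.isfinite(val) or err > 1e-7 * max(1.0, abs(val)):
        raise RuntimeError(
            f"Debye quadrature did not converge for theta={theta}: value={val}, err={err}"
        )
    return val / theta


_PL_TAU_NODES = 64


def _plackett_tau(theta: float) -> float:
    """Kendall's tau for the Plackett family by 2-D Gauss-Legendre quadrature.

    tau = 4 * int int C(u,v) c(u,v) du dv - 1 with the analytic density;
    no closed form exists for this family.
    """
    if abs(theta - 1.0) < 1e-10:
        return 0.0
    nodes, weights = leggauss(_PL_TAU_NODES)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    U, V = np.meshgrid(x, x)
    spec = CopulaSpec(CopulaFamily.PL, theta)
    vals = copula_cdf(spec, U.ravel(), V.ravel()) * copula_density(spec, U.ravel(), V.ravel())
    integral = w @ vals.reshape(U.shape) @ w
    tau = 4.0 * integral - 1.0
    if not np.isfinite(tau):
        raise RuntimeError(f"Plackett tau quadrature failed for theta={theta}")
    return float(np.clip(tau, -1.0, 1.0))


def theta_to_tau(spec: CopulaSpec) -> float:
    """Kendall's tau implied by the spec (closed form except Plackett)."""
    th = spec.theta
    fam = spec.family
    if fam is CopulaFamily.AMH:
        if abs(th) < 1e-4:
            return 2.0 * th / 9.0 + th * th / 18.0
        return float(1.0 - (2.0 / (3.0 * th * th))
                     * (th + (1.0 - th) ** 2 * np.log1p(-th)))
    if fam is CopulaFamily.FGM:
        return 2.0 * th / 9.0
    if fam is CopulaFamily.PL:
        return _plackett_tau(th)
    if fam is CopulaFamily.F:
        if abs(th) < 1e-5:
            return th / 9.0 - th ** 3 / 900.0
        return 1.0 - (4.0 / th) * (1.0 - _debye1(th))
    if fam in (CopulaFamily.N, CopulaFamily.T):
        return (2.0 / math.pi) * math.asin(th)
    raise ValueError(fam)  # pragma: no cover


def tau_range(family) -> tuple[float, float]:
    """Attainable Kendall's tau interval for the family."""
    family = _as_family(family)
    if family is CopulaFamily.AMH:
        return ((5.0 - 8.0 * math.log(2.0)) / 3.0, 1.0 / 3.0)
    if family is CopulaFamily.FGM:
        return (-2.0 / 9.0, 2.0 / 9.0)
    if family in (CopulaFamily.PL, CopulaFamily.F):
        return (-1.0, 1.0)
    return (-1.0, 1.0)


def tau_to_theta(family, tau: float, zeta: float = 3.0) -> float:
    """Invert the tau map; monotone root-finding where no closed form exists."""
    family = _as_family(family)
    tau = float(tau)
    lo, hi = tau_range(family)
    if not (lo <= tau <= hi):
        raise ValueError(
            f"tau={tau} is not attainable by {family.value}: its range is "
            f"[{lo:.6f}, {hi:.6f}]"
        )
    if family in (CopulaFamily.N, CopulaFamily.T):
        return math.sin(math.pi * tau / 2.0)
    if family is CopulaFamily.FGM:
        return 4.5 * tau
    if abs(tau) < 1e-12:
        return 1.0 if family is CopulaFamily.PL else 0.0

    def f(th):
        return theta_to_tau(CopulaSpec(family, th, zeta)) - tau

    if family is CopulaFamily.AMH:
        theta = optimize.brentq(f, -1.0 + 1e-12, 1.0 - 1e-12, xtol=1e-13)
    elif family is CopulaFamily.F:
        hi_b = 1.0
        sign = math.copysign(1.0, tau)
        while f(sign * hi_b) * sign < 0 and hi_b < 1e4:
            hi_b *= 2.0
        a, b = (1e-10, hi_b) if tau > 0 else (-hi_b, -1e-10)
        theta = optimize.brentq(f, a, b, xtol=1e-13)
    else:  # Plackett: search on log-theta
        def flog(s):
            return f(math.exp(s))

        hi_b = 1.0
        while flog(math.copysign(hi_b, tau)) * math.copysign(1.0, tau) < 0 and hi_b < 60:
            hi_b *= 2.0
        a, b = (0.0, hi_b) if tau > 0 else (-hi_b, 0.0)
        theta = math.exp(optimize.brentq(flog, a, b, xtol=1e-12))
    return float(theta)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_copula(spec: CopulaSpec, n: int, seed=None):
    """Draw ``n`` pairs (u, v) from the copula.

    Gaussian and Student-t pairs come from their latent elliptical
    representations; the remaining families use conditional inversion of
    dC/du by vectorized bisection (the conditional CDF is monotone in v).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    th = spec.theta
    if spec.family is CopulaFamily.N:
        z1 = rng.standard_normal(n)
        z2 = th * z1 + math.sqrt(max(0.0, 1.0 - th * th)) * rng.standard_normal(n)
        return ndtr(z1), ndtr(z2)
    if spec.family is CopulaFamily.T:
        nu = spec.zeta
        z1 = rng.standard_normal(n)
        z2 = th * z1 + math.sqrt(max(0.0, 1.0 - th * th)) * rng.standard_normal(n)
        s = np.sqrt(rng.chisquare(nu, n) / nu)
        return stdtr(nu, z1 / s), stdtr(nu, z2 / s)
    u = rng.uniform(size=n)
    w = rng.uniform(size=n)
    lo = np.full(n, _PROB_EPS)
    hi = np.full(n, 1.0 - _PROB_EPS)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        cond, _ = copula_partials(spec, u, mid)
        take_hi = cond < w
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return u, 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Unconstrained reparameterisation of theta
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThetaLink:
    """Smooth bijection between theta's native range and the real line."""

    family: CopulaFamily
    kind: str = field(init=False)

    def __post_init__(self):
        fam = _as_family(self.family)
        object.__setattr__(self, "family", fam)
        if fam is CopulaFamily.PL:
            kind = "log"
        elif fam is CopulaFamily.F:
            kind = "identity"
        else:
            kind = "tanh"
        object.__setattr__(self, "kind", kind)

    def to_theta(self, star):
        if self.kind == "log":
            return np.exp(np.clip(star, -25.0, 25.0))
        if self.kind == "identity":
            return np.clip(star, -35.0, 35.0)
        return np.tanh(star)

    def to_unconstrained(self, theta):
        if self.kind == "log":
            return np.log(theta)
        if self.kind == "identity":
            return np.asarray(theta, dtype=float)
        return np.arctanh(np.clip(theta, -1.0 + 1e-15, 1.0 - 1e-15))

    def dtheta_dstar(self, star):
        if self.kind == "log":
            return np.exp(np.clip(star, -25.0, 25.0))
        if self.kind == "identity":
            return np.ones_like(np.asarray(star, dtype=float))
        return 1.0 / np.cosh(star) ** 2


def theta_link(family) -> ThetaLink:
    """The default unconstrained link for a family (log / identity / tanh)."""
    return ThetaLink(_as_family(family))
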