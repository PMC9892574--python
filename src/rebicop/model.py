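"""Recursive bivariate copula model for a binary outcome with a binary
endogenous treatment.

Two latent-variable equations

    y1* = eta1(x1) + e1          (treatment; contains the instrument)
    y2* = gamma*y1 + eta2(x2) + e2   (outcome; excludes the instrument)

with y_j = 1{y_j* > 0} and the dependence between the margins captured by a
parametric copula C_theta joining the marginal success probabilities.  The
log-likelihood decomposes over the four observable configurations

    p11 = C_theta(P1, P2),  p10 = P1 - p11,  p01 = P2 - p11,
    p00 = 1 - P1 - P2 + p11,

where P1 = P(y1=1) and P2 = P(y2=1) use the observed treatment in eta2.
Smooth terms carry quadratic difference penalties; the penalized
log-likelihood l_p = l - 0.5 * phi' Lambda(lambda) phi is maximised over the
coefficients with automatic multiple smoothing-parameter selection by
generalized Fellner-Schall updates.  The association parameter is estimated
jointly on an unconstrained scale and left unpenalized.

Inference is Bayesian-flavoured: phi ~ N(phi_hat, H_p^{-1}) with H_p the
penalized Hessian at the optimum, which yields intervals for nonlinear
functionals (Kendall's tau, treatment effects) by posterior simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .copulas import (
    CopulaFamily,
    CopulaSpec,
    ThetaLink,
    copula_cdf,
    copula_dtheta,
    copula_partials,
    theta_link,
    theta_to_tau,
)
from .copulas import _t_copula_terms
from .links import LinkFunction, get_link
from .splines import AdditivePredictorDesign, EquationSpec, build_design

__all__ = [
    "BicopulaModelSpec",
    "CellProbabilities",
    "FitOptions",
    "FittedBicopula",
    "ModelFrame",
    "cell_probabilities",
    "fit",
    "posterior_draws",
    "information_criteria",
]

_CELL_EPS = 1e-12


# ---------------------------------------------------------------------------
# Specs and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BicopulaModelSpec:
    """The two-equation recursive model.

    The treatment equation must contain the instrument; the outcome equation
    must exclude it (exclusion restriction) and automatically receives the
    treatment indicator as its first non-intercept regressor, whose
    coefficient is the structural effect gamma.
    """

    treatment_eq: EquationSpec
    outcome_eq: EquationSpec
    instrument: str
    family: str = "N"
    link_treatment: str = "probit"
    link_outcome: str = "probit"
    zeta: float = 3.0

    def __post_init__(self):
        fam = CopulaFamily(str(self.family)) if not isinstance(self.family, CopulaFamily) \
            else self.family
        object.__setattr__(self, "family", fam)
        if self.instrument not in self.treatment_eq.columns:
            raise ValueError(
                f"instrument {self.instrument!r} must enter the treatment equation"
            )
        if self.instrument in self.outcome_eq.columns:
            raise ValueError(
                f"instrument {self.instrument!r} must be excluded from the outcome equation"
            )
        if self.treatment_eq.response in self.outcome_eq.columns:
            raise ValueError(
                "the treatment indicator is added to the outcome equation "
                "automatically; do not list it among its terms"
            )
        get_link(self.link_treatment)
        get_link(self.link_outcome)

    @property
    def treatment(self) -> str:
        return self.treatment_eq.response

    @property
    def label(self) -> str:
        """Family(outcome-treatment link initials) label, e.g. 'PL (p-l)'."""
        ini = {"probit": "p", "logit": "l", "cloglog": "c"}
        return f"{self.family.value} ({ini[self.link_outcome]}-{ini[self.link_treatment]})"


@dataclass(frozen=True)
class CellProbabilities:
    """Per-observation probabilities of the four outcome configurations."""

    p11: np.ndarray
    p10: np.ndarray
    p01: np.ndarray
    p00: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.p11, self.p10, self.p01, self.p00])


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 200
    tol: float = 1e-6            # max-norm of the penalized gradient
    max_outer: int = 8           # Fellner-Schall smoothing iterations
    lambda_init: float = 1.0
    select_smoothing: bool = True
    fix_theta: float | None = None   # hold theta fixed (e.g. independence)
    seed: int | None = None          # unused; kept for interface stability


@dataclass
class FittedBicopula:
    """Fitted state: coefficients, smoothing, curvature and fit summaries."""

    spec: BicopulaModelSpec
    frame: "ModelFrame"
    coef: np.ndarray
    coef_names: tuple
    lambdas: np.ndarray
    loglik: float
    penalized_loglik: float
    hessian_penalized: np.ndarray      # H_p = -d2 l_p (positive definite)
    edf_by_smooth: dict
    ref_df_by_smooth: dict
    edf_total: float
    aic: float
    bic: float
    theta: float
    tau: float
    converged: bool
    n_obs: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def gamma(self) -> float:
        return float(self.coef[self.frame.gamma_index])

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.hessian_penalized)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance()))

    def summary(self) -> str:
        from .report import fit_summary
        return fit_summary(self)


# ---------------------------------------------------------------------------
# Cell probabilities
# ---------------------------------------------------------------------------

def cell_probabilities(eta1, eta2, copula: CopulaSpec, link1, link2) -> CellProbabilities:
    """Four-cell probabilities from the two additive predictors.

    ``eta2`` must already include the treatment contribution gamma*y1 for the
    margin being evaluated.
    """
    link1, link2 = get_link(link1), get_link(link2)
    eta1 = np.asarray(eta1, dtype=float)
    eta2 = np.asarray(eta2, dtype=float)
    if not (np.all(np.isfinite(eta1)) and np.all(np.isfinite(eta2))):
        raise ValueError("additive predictors must be finite")
    P1 = np.clip(link1.prob(eta1), _CELL_EPS, 1 - _CELL_EPS)
    P2 = np.clip(link2.prob(eta2), _CELL_EPS, 1 - _CELL_EPS)
    p11 = np.asarray(copula_cdf(copula, P1, P2))
    p10 = P1 - p11
    p01 = P2 - p11
    p00 = 1.0 - P1 - P2 + p11
    return CellProbabilities(p11=np.atleast_1d(p11), p10=np.atleast_1d(p10),
                             p01=np.atleast_1d(p01), p00=np.atleast_1d(p00))


# ---------------------------------------------------------------------------
# Model frame: prepared designs + likelihood machinery
# ---------------------------------------------------------------------------

class ModelFrame:
    """Designs, responses and coefficient layout prepared from data.

    Coefficient vector: [phi1 | phi2 (treatment coefficient first after the
    intercept) | theta_star], with theta_star absent when theta is fixed.
    """

    def __init__(self, spec: BicopulaModelSpec, data: pd.DataFrame,
                 fix_theta: float | None = None):
        self.spec = spec
        self.link1: LinkFunction = get_link(spec.link_treatment)
        self.link2: LinkFunction = get_link(spec.link_outcome)
        self.tlink: ThetaLink = theta_link(spec.family)
        self.fix_theta = fix_theta
        y1 = np.asarray(data[spec.treatment_eq.response], dtype=float)
        y2 = np.asarray(data[spec.outcome_eq.response], dtype=float)
        for name, y in ((spec.treatment_eq.response, y1), (spec.outcome_eq.response, y2)):
            vals = np.unique(y)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"response {name!r} must be binary 0/1")
        self.y1, self.y2 = y1, y2
        self.design1 = build_design(spec.treatment_eq, data)
        self.design2 = build_design(spec.outcome_eq, data,
                                    extra_parametric=(spec.treatment,))
        self.n = len(data)
        self.d1 = self.design1.n_coef
        self.d2 = self.design2.n_coef
        self.n_coef = self.d1 + self.d2 + (0 if fix_theta is not None else 1)
        self.gamma_index = self.d1 + 1  # treatment coef follows eq-2 intercept
        names = [f"eq1:{c}" for c in self.design1.column_names]
        names += [f"eq2:{c}" for c in self.design2.column_names]
        if fix_theta is None:
            names.append("theta_star")
        self.coef_names = tuple(names)
        # embedded full-size penalty matrices, eq1 smooths then eq2 smooths
        self.smooth_names: list[str] = []
        self.smooth_slices: list[slice] = []
        self.penalties: list[np.ndarray] = []
        self.penalty_ranks: list[int] = []
        for eq_tag, design, off in (("eq1", self.design1, 0),
                                    ("eq2", self.design2, self.d1)):
            for b in design.smooth_blocks:
                S = np.zeros((self.n_coef, self.n_coef))
                sl = slice(off + b.sl.start, off + b.sl.stop)
                S[sl, sl] = b.penalty
                self.smooth_names.append(f"{eq_tag}:{b.name}")
                self.smooth_slices.append(sl)
                self.penalties.append(S)
                self.penalty_ranks.append(int(np.linalg.matrix_rank(b.penalty)))
        self.n_smooth = len(self.penalties)

    # -- parameter bookkeeping ------------------------------------------------

    def split(self, phi: np.ndarray):
        phi = np.asarray(phi, dtype=float)
        phi1 = phi[: self.d1]
        phi2 = phi[self.d1: self.d1 + self.d2]
        if self.fix_theta is not None:
            theta = self.fix_theta
            dtheta_dstar = 0.0
        else:
            star = phi[-1]
            theta = float(self.tlink.to_theta(star))
            dtheta_dstar = float(self.tlink.dtheta_dstar(star))
        return phi1, phi2, theta, dtheta_dstar

    def copula_spec(self, theta: float) -> CopulaSpec:
        # nudge values that fall exactly on a closed boundary of the range
        fam = self.spec.family
        if fam in (CopulaFamily.N, CopulaFamily.T, CopulaFamily.AMH, CopulaFamily.FGM):
            theta = float(np.clip(theta, -1.0, 1.0))
        return CopulaSpec(fam, theta, self.spec.zeta)

    def penalty_matrix(self, lambdas: np.ndarray) -> np.ndarray:
        Lam = np.zeros((self.n_coef, self.n_coef))
        for lam, S in zip(np.atleast_1d(lambdas), self.penalties):
            Lam += lam * S
        return Lam

    # -- likelihood -----------------------------------------------------------

    def _margins(self, phi1, phi2):
        eta1 = self.design1.X @ phi1
        eta2 = self.design2.X @ phi2
        P1 = np.clip(self.link1.prob(eta1), _CELL_EPS, 1 - _CELL_EPS)
        P2 = np.clip(self.link2.prob(eta2), _CELL_EPS, 1 - _CELL_EPS)
        return eta1, eta2, P1, P2

    def cells(self, phi: np.ndarray) -> CellProbabilities:
        phi1, phi2, theta, _ = self.split(phi)
        _, _, P1, P2 = self._margins(phi1, phi2)
        cop = self.copula_spec(theta)
        p11 = np.asarray(copula_cdf(cop, P1, P2))
        return CellProbabilities(
            p11=p11, p10=P1 - p11, p01=P2 - p11, p00=1.0 - P1 - P2 + p11
        )

    def value_and_grad(self, phi: np.ndarray, lambdas=None):
        """(Penalized) log-likelihood and its analytic score in one pass."""
        phi = np.asarray(phi, dtype=float)
        phi1, phi2, theta, dtheta_dstar = self.split(phi)
        eta1, eta2, P1, P2 = self._margins(phi1, phi2)
        cop = self.copula_spec(theta)
        if self.spec.family is CopulaFamily.T and abs(theta) < 1 - 1e-9:
            # CDF and derivatives of the implemented quadrature rule itself
            C, Cu, Cv, Ct = _t_copula_terms(P1, P2, theta, self.spec.zeta, "all")
        else:
            C = np.asarray(copula_cdf(cop, P1, P2))
            Cu, Cv = copula_partials(cop, P1, P2)
            Ct = copula_dtheta(cop, P1, P2)
        p11 = np.maximum(C, _CELL_EPS)
        p10 = np.maximum(P1 - C, _CELL_EPS)
        p01 = np.maximum(P2 - C, _CELL_EPS)
        p00 = np.maximum(1.0 - P1 - P2 + C, _CELL_EPS)
        y1, y2 = self.y1, self.y2
        w11 = y1 * y2
        w10 = y1 * (1 - y2)
        w01 = (1 - y1) * y2
        w00 = (1 - y1) * (1 - y2)
        ll = float(w11 @ np.log(p11) + w10 @ np.log(p10)
                   + w01 @ np.log(p01) + w00 @ np.log(p00))
        a11, a10, a01, a00 = w11 / p11, w10 / p10, w01 / p01, w00 / p00
        dl_dP1 = a11 * Cu + a10 * (1.0 - Cu) - a01 * Cu + a00 * (Cu - 1.0)
        dl_dP2 = a11 * Cv - a10 * Cv + a01 * (1.0 - Cv) + a00 * (Cv - 1.0)
        dl_dtheta = (a11 - a10 - a01 + a00) * Ct
        g1 = self.design1.X.T @ (dl_dP1 * self.link1.density(eta1))
        g2 = self.design2.X.T @ (dl_dP2 * self.link2.density(eta2))
        parts = [g1, g2]
        if self.fix_theta is None:
            parts.append(np.array([np.sum(dl_dtheta) * dtheta_dstar]))
        grad = np.concatenate(parts)
        if lambdas is not None:
            Lam = self.penalty_matrix(np.asarray(lambdas, dtype=float))
            ll = ll - 0.5 * phi @ Lam @ phi
            grad = grad - Lam @ phi
        return ll, grad

    def log_likelihood(self, phi: np.ndarray) -> float:
        c = self.cells(phi)
        y1, y2 = self.y1, self.y2
        chosen = (y1 * y2 * c.p11 + y1 * (1 - y2) * c.p10
                  + (1 - y1) * y2 * c.p01 + (1 - y1) * (1 - y2) * c.p00)
        if np.any(chosen < _CELL_EPS):
            warnings.warn("cell probabilities clipped at 1e-12 inside the "
                          "log-likelihood", RuntimeWarning, stacklevel=2)
        return float(np.sum(np.log(np.maximum(chosen, _CELL_EPS))))

    def penalized_log_likelihood(self, phi: np.ndarray, lambdas) -> float:
        phi = np.asarray(phi, dtype=float)
        Lam = self.penalty_matrix(np.asarray(lambdas, dtype=float))
        return self.log_likelihood(phi) - 0.5 * phi @ Lam @ phi

    def gradient(self, phi: np.ndarray, lambdas=None) -> np.ndarray:
        """Analytic score of the (penalized) log-likelihood."""
        return self.value_and_grad(phi, lambdas)[1]

    def hessian_fd(self, phi: np.ndarray, lambdas=None, step: float = 1e-5,
                   central: bool = True) -> np.ndarray:
        """Finite-difference Hessian of the analytic gradient.

        Central differences (2p gradient calls) by default; the forward
        variant (p+1 calls) is used inside the smoothing loop where cheaper,
        slightly less accurate curvature suffices.
        """
        phi = np.asarray(phi, dtype=float)
        p = phi.size
        H = np.empty((p, p))
        g0 = None if central else self.gradient(phi, lambdas)
        for i in range(p):
            h = step * max(1.0, abs(phi[i]))
            e = np.zeros(p)
            e[i] = h
            if central:
                H[i] = (self.gradient(phi + e, lambdas)
                        - self.gradient(phi - e, lambdas)) / (2 * h)
            else:
                H[i] = (self.gradient(phi + e, lambdas) - g0) / h
        return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Univariate penalized binary fit (initialisation and factorization checks)
# ---------------------------------------------------------------------------

def fit_univariate(design: AdditivePredictorDesign, y: np.ndarray, link,
                   lambdas=None, tol: float = 1e-8, max_iter: int = 200):
    """Penalized ML for a single binary additive model; returns (coef, ll)."""
    link = get_link(link)
    X = design.X
    y = np.asarray(y, dtype=float)
    S_full = design.penalty_matrices()
    if lambdas is None:
        lambdas = np.ones(len(S_full))
    Lam = np.zeros((X.shape[1], X.shape[1]))
    for lam, S in zip(np.atleast_1d(lambdas), S_full):
        Lam += lam * S

    def negpll(beta):
        eta = X @ beta
        p = np.clip(link.prob(eta), _CELL_EPS, 1 - _CELL_EPS)
        ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        return -(ll - 0.5 * beta @ Lam @ beta)

    def grad(beta):
        eta = X @ beta
        p = np.clip(link.prob(eta), _CELL_EPS, 1 - _CELL_EPS)
        w = (y - p) / (p * (1 - p)) * link.density(eta)
        return -(X.T @ w - Lam @ beta)

    beta0 = np.zeros(X.shape[1])
    beta0[0] = link.inverse(np.clip(y.mean(), 0.01, 0.99))
    res = optimize.minimize(negpll, beta0, jac=grad, method="L-BFGS-B",
                            options={"maxiter": max_iter, "gtol": tol,
                                     "ftol": 1e-14})
    # Newton polish: the curvature of a penalized Bernoulli fit is cheap
    beta = res.x
    for _ in range(8):
        g = -grad(beta)
        if np.max(np.abs(g)) < max(tol, 1e-9):
            break
        eta = X @ beta
        p = np.clip(link.prob(eta), _CELL_EPS, 1 - _CELL_EPS)
        d = link.density(eta)
        # expected-information weights for the Bernoulli margin
        wgt = d * d / (p * (1 - p))
        H = X.T @ (X * wgt[:, None]) + Lam
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        new = beta + step
        if negpll(new) <= negpll(beta) + 1e-12:
            beta = new
        else:
            break
    return beta, -negpll(beta)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _newton_polish(frame: ModelFrame, phi, lambdas, tol, max_steps=12):
    """Damped Newton steps on the penalized likelihood until the score is small.

    The finite-difference Hessian is reused across steps and refreshed only
    when a step fails to improve; near the optimum stale curvature is fine.
    """
    f, g = frame.value_and_grad(phi, lambdas)
    H = None
    for _ in range(max_steps):
        if np.max(np.abs(g)) < tol:
            break
        if H is None:
            H = -frame.hessian_fd(phi, lambdas)
        ridge = 0.0
        for _try in range(12):
            try:
                step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), g)
                break
            except np.linalg.LinAlgError:
                ridge = max(1e-6, ridge * 10 + 1e-6)
        alpha, improved = 1.0, False
        for _ls in range(30):
            cand = phi + alpha * step
            fc, gc = frame.value_and_grad(cand, lambdas)
            if fc > f - 1e-12:
                phi, f, g, improved = cand, fc, gc, True
                break
            alpha *= 0.5
        if not improved:
            if H is not None and _try == 0:
                H = None      # refresh curvature once, then give up
                continue
            break
    return np.asarray(phi, dtype=float)


def _edf_quantities(frame: ModelFrame, phi, lambdas, central: bool = True):
    """Penalized Hessian, per-smooth EDF and total EDF at the optimum."""
    Hp = -frame.hessian_fd(phi, lambdas, central=central)
    # ensure positive definiteness (tiny ridge if needed: near-flat directions)
    jitter = 0.0
    for _ in range(12):
        try:
            np.linalg.cholesky(Hp + jitter * np.eye(Hp.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(1e-8, 10 * jitter)
    if jitter:
        Hp = Hp + jitter * np.eye(Hp.shape[0])
    H_unpen = Hp - frame.penalty_matrix(lambdas)
    F = np.linalg.solve(Hp, H_unpen)
    edf_diag = np.diag(F)
    edf_by = {}
    for name, sl in zip(frame.smooth_names, frame.smooth_slices):
        edf_by[name] = float(np.sum(edf_diag[sl]))
    return Hp, edf_by, float(np.trace(F))


def _fs_update(frame: ModelFrame, phi, lambdas, Hp):
    """Generalized Fellner-Schall update of the smoothing parameters."""
    new = np.array(lambdas, dtype=float)
    Vinv = np.linalg.inv(Hp)
    for k, (S, rank) in enumerate(zip(frame.penalties, frame.penalty_ranks)):
        quad = float(phi @ S @ phi)
        num = rank / lambdas[k] - float(np.sum(Vinv * S))  # tr(Hp^-1 S)
        if quad < 1e-10 or num <= 0.0:
            new[k] = min(lambdas[k] * 10.0, 1e7)
        else:
            new[k] = num / quad
    # damp: at most two decades per sweep
    new = lambdas * np.clip(new / lambdas, 1e-2, 1e2)
    return np.clip(new, 1e-4, 1e7)


def fit(spec: BicopulaModelSpec, data: pd.DataFrame,
        options: FitOptions | None = None) -> FittedBicopula:
    """Penalized maximum likelihood for the recursive copula model.

    Coefficients are initialised from two univariate penalized fits (treatment
    margin; outcome margin including the observed treatment) with the
    dependence started at independence.  At fixed smoothing the penalized
    likelihood is maximised by quasi-Newton iterations polished with damped
    Newton steps; smoothing parameters are updated in an outer
    Fellner-Schall loop.  Deterministic given data and options.
    """
    options = options or FitOptions()
    frame = ModelFrame(spec, data, fix_theta=options.fix_theta)
    if frame.n <= frame.n_coef:
        raise ValueError("more coefficients than observations")
    lambdas = np.full(frame.n_smooth, float(options.lambda_init))

    b1, _ = fit_univariate(frame.design1, frame.y1, frame.link1,
                           lambdas[: len(frame.design1.smooth_blocks)]
                           if frame.n_smooth else None)
    b2, _ = fit_univariate(frame.design2, frame.y2, frame.link2,
                           lambdas[len(frame.design1.smooth_blocks):]
                           if frame.n_smooth else None)
    phi = np.concatenate([b1, b2, [] if options.fix_theta is not None else [0.0]])

    def lbfgs(p0):
        def negboth(p):
            f, g = frame.value_and_grad(p, lambdas)
            return -f, -g
        res = optimize.minimize(negboth, p0, jac=True, method="L-BFGS-B",
                                options={"maxiter": options.max_iter,
                                         "gtol": 1e-9, "ftol": 1e-12})
        return res.x

    history = []
    phi = lbfgs(phi)
    if options.select_smoothing and frame.n_smooth:
        # outer Fellner-Schall sweeps with cheap forward-difference curvature
        for it in range(options.max_outer):
            Hp, _, _ = _edf_quantities(frame, phi, lambdas, central=False)
            proposal = _fs_update(frame, phi, lambdas, Hp)
            delta = np.max(np.abs(np.log(proposal) - np.log(lambdas)))
            # half-step in log space damps the fixed-point oscillation
            new_lam = np.exp(0.5 * (np.log(lambdas) + np.log(proposal)))
            history.append({"iter": it, "lambdas": new_lam.copy(), "delta": float(delta)})
            if delta < 0.2:
                break
            lambdas = new_lam
            phi = lbfgs(phi)
    phi = _newton_polish(frame, phi, lambdas, options.tol)
    Hp, edf_by, edf_tot = _edf_quantities(frame, phi, lambdas)

    grad_norm = float(np.max(np.abs(frame.gradient(phi, lambdas))))
    converged = grad_norm <= max(options.tol, 1e-4)
    if not converged:
        warnings.warn(f"fit did not fully converge: max |score| = {grad_norm:.2e}",
                      RuntimeWarning, stacklevel=2)
    ll = frame.log_likelihood(phi)
    pll = frame.penalized_log_likelihood(phi, lambdas)
    _, _, theta, _ = frame.split(phi)
    tau = theta_to_tau(frame.copula_spec(theta))
    aic = -2.0 * ll + 2.0 * edf_tot
    bic = -2.0 * ll + np.log(frame.n) * edf_tot
    ref_df = {}
    for name, sl in zip(frame.smooth_names, frame.smooth_slices):
        ref_df[name] = sl.stop - sl.start
    # crude separation screen
    if np.max(np.abs(phi[:-1] if options.fix_theta is None else phi)) > 15:
        warnings.warn("very large coefficient detected; possible separation "
                      "(standard errors may be inflated)", RuntimeWarning,
                      stacklevel=2)
    return FittedBicopula(
        spec=spec, frame=frame, coef=phi, coef_names=frame.coef_names,
        lambdas=lambdas, loglik=ll, penalized_loglik=pll,
        hessian_penalized=Hp, edf_by_smooth=edf_by, ref_df_by_smooth=ref_df,
        edf_total=edf_tot, aic=float(aic), bic=float(bic), theta=theta,
        tau=float(tau), converged=converged, n_obs=frame.n,
        diagnostics={"grad_norm": grad_norm, "outer_history": history},
    )


# ---------------------------------------------------------------------------
# Post-fit quantities
# ---------------------------------------------------------------------------

def posterior_draws(fitted: FittedBicopula, n_draws: int, seed=None) -> np.ndarray:
    """Draws from the large-sample posterior N(phi_hat, H_p^{-1})."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    Hp = fitted.hessian_penalized
    try:
        L = np.linalg.cholesky(Hp)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "penalized Hessian is not positive definite; consider a small "
            "ridge stabilization"
        ) from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, Hp.shape[0]))
    # solve L^T x = z  => x ~ N(0, Hp^{-1})
    return fitted.coef + np.linalg.solve(L.T, z.T).T


def information_criteria(fitted: FittedBicopula):
    """(AIC, BIC, EDF table) for a converged fit."""
    table = pd.DataFrame({
        "edf": pd.Series(fitted.edf_by_smooth, dtype=float),
        "ref_df": pd.Series(fitted.ref_df_by_smooth, dtype=float),
    })
    return fitted.aic, fitted.bic, table
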