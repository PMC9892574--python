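"""Likelihood, gradient, fitting, EDF and posterior machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, ndtri

from rebicop.copulas import CopulaSpec, sample_copula, tau_to_theta
from rebicop.links import get_link
from rebicop.model import (
    BicopulaModelSpec,
    FitOptions,
    ModelFrame,
    cell_probabilities,
    fit,
    fit_univariate,
    information_criteria,
    posterior_draws,
)
from rebicop.splines import EquationSpec, SmoothSpec
from rebicop.synthdata import generate, model_spec_for, simple_config


def tiny_spec(family="FGM", smooths=False, links=("probit", "probit")):
    sm = (SmoothSpec("x", num_basis=6),) if smooths else ()
    return BicopulaModelSpec(
        treatment_eq=EquationSpec("t", parametric=("z",), smooths=sm),
        outcome_eq=EquationSpec("y", parametric=("w",), smooths=sm),
        instrument="z",
        family=family, link_treatment=links[0], link_outcome=links[1],
    )


def tiny_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "t": rng.integers(0, 2, n).astype(float),
        "y": rng.integers(0, 2, n).astype(float),
        "z": rng.integers(0, 2, n).astype(float),
        "w": rng.integers(0, 2, n).astype(float),
        "x": rng.uniform(0, 1, n),
    })


# ---------------------------------------------------------------------------
# Model spec validation
# ---------------------------------------------------------------------------

def test_spec_validation():
    with pytest.raises(ValueError, match="instrument"):
        BicopulaModelSpec(EquationSpec("t"), EquationSpec("y"), instrument="z")
    with pytest.raises(ValueError, match="excluded"):
        BicopulaModelSpec(EquationSpec("t", parametric=("z",)),
                          EquationSpec("y", parametric=("z",)), instrument="z")
    with pytest.raises(ValueError, match="treatment indicator"):
        BicopulaModelSpec(EquationSpec("t", parametric=("z",)),
                          EquationSpec("y", parametric=("t",)), instrument="z")


# ---------------------------------------------------------------------------
# Cell probabilities
# ---------------------------------------------------------------------------

def test_cells_independence_product():
    eta1 = ndtri(0.4)
    eta2 = ndtri(0.25)
    c = cell_probabilities(eta1, eta2, CopulaSpec("FGM", 0.0), "probit", "probit")
    assert c.p11[0] == pytest.approx(0.10, abs=1e-10)
    assert c.p10[0] == pytest.approx(0.30, abs=1e-10)
    assert c.p01[0] == pytest.approx(0.15, abs=1e-10)
    assert c.p00[0] == pytest.approx(0.45, abs=1e-10)


def test_cells_comonotone_limit():
    eta = ndtri(0.37)
    c = cell_probabilities(eta, eta, CopulaSpec("N", 1.0), "probit", "probit")
    assert c.p11[0] == pytest.approx(0.37, abs=1e-9)
    assert c.p10[0] == pytest.approx(0.0, abs=1e-9)


def test_cells_sum_to_one_random_sweep(rng):
    for fam, theta in [("AMH", -0.7), ("FGM", 0.6), ("PL", 3.0), ("F", -5.0),
                       ("N", 0.7), ("T", -0.6)]:
        eta1 = rng.normal(size=50)
        eta2 = rng.normal(size=50)
        for l1, l2 in (("probit", "logit"), ("cloglog", "probit")):
            c = cell_probabilities(eta1, eta2, CopulaSpec(fam, theta), l1, l2)
            total = c.p11 + c.p10 + c.p01 + c.p00
            assert np.max(np.abs(total - 1.0)) < 1e-10
            assert np.all(c.stack() >= -1e-12)


def test_cells_match_latent_simulation():
    """Four-cell probabilities agree with simulating the generative mechanism."""
    fam_theta = ("F", 3.0)
    eta1, eta2 = 0.2, -0.5
    spec = CopulaSpec(*fam_theta)
    c = cell_probabilities(eta1, eta2, spec, "probit", "probit")
    n = 400_000
    u, v = sample_copula(spec, n, seed=9)
    link = get_link("probit")
    y1 = u <= link.prob(eta1)
    y2 = v <= link.prob(eta2)
    for emp_p, model_p in [
        (np.mean(y1 & y2), c.p11[0]), (np.mean(y1 & ~y2), c.p10[0]),
        (np.mean(~y1 & y2), c.p01[0]), (np.mean(~y1 & ~y2), c.p00[0]),
    ]:
        se = np.sqrt(model_p * (1 - model_p) / n)
        assert abs(emp_p - model_p) <= 3 * se


def test_cell_probabilities_rejects_nonfinite():
    with pytest.raises(ValueError):
        cell_probabilities(np.array([np.inf]), np.array([0.0]),
                           CopulaSpec("N", 0.2), "probit", "probit")


# ---------------------------------------------------------------------------
# Log-likelihood
# ---------------------------------------------------------------------------

def test_loglik_enumeration_four_configurations():
    """n=4 dataset covering all cells: ll equals the sum of four log cells."""
    df = pd.DataFrame({
        "t": [1.0, 1.0, 0.0, 0.0], "y": [1.0, 0.0, 1.0, 0.0],
        "z": [1.0, 0.0, 1.0, 0.0], "w": [0.0, 1.0, 0.0, 1.0],
        "x": [0.1, 0.4, 0.6, 0.9],
    })
    spec = tiny_spec("PL")
    frame = ModelFrame(spec, df)
    phi = np.array([0.3, 0.5, -0.2, 0.8, 0.1, 0.4])  # [phi1 | phi2(g first)| th*]
    eta1 = frame.design1.X @ phi[:2]
    eta2 = frame.design2.X @ phi[2:5]
    theta = float(frame.tlink.to_theta(phi[-1]))
    c = cell_probabilities(eta1, eta2, CopulaSpec("PL", theta), "probit", "probit")
    by_hand = (np.log(c.p11[0]) + np.log(c.p10[1])
               + np.log(c.p01[2]) + np.log(c.p00[3]))
    assert frame.log_likelihood(phi) == pytest.approx(by_hand, abs=1e-12)


def test_loglik_independence_factorizes(rng):
    """At theta = 0 the joint ll is the sum of two univariate Bernoulli lls."""
    df = tiny_data(500, seed=3)
    spec = tiny_spec("FGM")
    frame = ModelFrame(spec, df, fix_theta=0.0)
    phi = rng.normal(scale=0.5, size=frame.n_coef)
    eta1 = frame.design1.X @ phi[:2]
    eta2 = frame.design2.X @ phi[2:]
    link = get_link("probit")
    p1, p2 = link.prob(eta1), link.prob(eta2)
    ll1 = np.sum(df.t * np.log(p1) + (1 - df.t) * np.log1p(-p1))
    ll2 = np.sum(df.y * np.log(p2) + (1 - df.y) * np.log1p(-p2))
    assert frame.log_likelihood(phi) == pytest.approx(ll1 + ll2, rel=1e-12)


def test_penalized_ll_reduces_and_nullspace(rng):
    df = tiny_data(300, seed=1)
    spec = tiny_spec("N", smooths=True)
    frame = ModelFrame(spec, df)
    phi = rng.normal(scale=0.3, size=frame.n_coef)
    lam = np.array([2.0, 3.0])
    assert frame.penalized_log_likelihood(phi, np.zeros(2)) == \
        pytest.approx(frame.log_likelihood(phi), abs=1e-12)
    # a coefficient vector whose smooth blocks sit in the penalty null space
    phi0 = np.zeros(frame.n_coef)
    for sl, S in zip(frame.smooth_slices, frame.penalties):
        # null space of the centered 2nd-order penalty
        w, V = np.linalg.eigh(S[sl, sl])
        phi0[sl] = V[:, 0] * (w[0] < 1e-10)
    pen = frame.log_likelihood(phi0) - frame.penalized_log_likelihood(phi0, lam)
    assert pen == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("family,links", [
    ("AMH", ("probit", "probit")), ("FGM", ("logit", "probit")),
    ("PL", ("probit", "logit")), ("F", ("logit", "logit")),
    ("N", ("probit", "cloglog")), ("T", ("cloglog", "probit")),
])
def test_gradient_matches_finite_differences(family, links, rng):
    """Analytic score vs central differences, relative error <= 1e-6."""
    df = tiny_data(300, seed=2)
    spec = tiny_spec(family, smooths=True, links=links)
    frame = ModelFrame(spec, df)
    phi = rng.normal(scale=0.3, size=frame.n_coef)
    lam = np.array([1.3, 0.6])
    g = frame.gradient(phi, lam)
    fd = np.zeros_like(g)
    for i in range(phi.size):
        h = 1e-6 * max(1.0, abs(phi[i]))
        e = np.zeros_like(phi)
        e[i] = h
        fd[i] = (frame.penalized_log_likelihood(phi + e, lam)
                 - frame.penalized_log_likelihood(phi - e, lam)) / (2 * h)
    assert np.linalg.norm(g - fd) / np.linalg.norm(fd) <= 1e-6


def test_outcome_relabel_invariance(rng):
    """Flipping y2's categories with a symmetric link mirrors the outcome
    coefficients and reflects theta, leaving the likelihood unchanged."""
    df = tiny_data(400, seed=5)
    spec = tiny_spec("N")
    frame = ModelFrame(spec, df)
    phi = rng.normal(scale=0.4, size=frame.n_coef)
    df2 = df.copy()
    df2["y"] = 1.0 - df2["y"]
    frame2 = ModelFrame(spec, df2)
    phi2 = phi.copy()
    phi2[frame.d1: frame.d1 + frame.d2] *= -1.0   # outcome equation mirrored
    phi2[-1] *= -1.0                               # dependence reflected
    assert frame2.log_likelihood(phi2) == pytest.approx(
        frame.log_likelihood(phi), rel=1e-10)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def test_fit_independence_reproduces_univariate_fits():
    """With the dependence fixed at independence the joint fit equals two
    separate penalized binary regressions."""
    cfg = simple_config(n=2500, seed=21, family="FGM", tau=0.0)
    ds = generate(cfg)
    spec = model_spec_for(cfg, num_basis=8, family="FGM")
    lam = 1.0
    opts = FitOptions(fix_theta=0.0, select_smoothing=False, lambda_init=lam,
                      tol=1e-7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fitted = fit(spec, ds.data, opts)
    frame = fitted.frame
    b1, _ = fit_univariate(frame.design1, frame.y1, "probit", [lam], tol=1e-10)
    b2, _ = fit_univariate(frame.design2, frame.y2, "probit", [lam], tol=1e-10)
    joint = fitted.coef
    assert np.max(np.abs(joint[:frame.d1] - b1)) <= 1e-4
    assert np.max(np.abs(joint[frame.d1:] - b2)) <= 1e-4


def test_fit_recovers_gamma_within_3se():
    cfg = simple_config(n=4000, seed=31, family="N", tau=-0.3, gamma=1.0)
    ds = generate(cfg)
    spec = model_spec_for(cfg, num_basis=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fitted = fit(spec, ds.data)
    assert fitted.converged
    se = fitted.se()[fitted.frame.gamma_index]
    assert abs(fitted.gamma - 1.0) <= 3 * se


def test_fit_gamma_zero_independence_covers_zero():
    cfg = simple_config(n=3000, seed=17, family="N", tau=0.0, gamma=0.0)
    ds = generate(cfg)
    spec = model_spec_for(cfg, num_basis=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fitted = fit(spec, ds.data)
    se = fitted.se()[fitted.frame.gamma_index]
    assert abs(fitted.gamma) <= 2.6 * se


def test_fit_requires_enough_observations():
    df = tiny_data(5)
    with pytest.raises(ValueError, match="coefficients"):
        fit(tiny_spec("N", smooths=True), df)


def test_fit_is_deterministic(gaussian_dataset):
    cfg, ds = gaussian_dataset
    spec = model_spec_for(cfg, num_basis=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f1 = fit(spec, ds.data)
        f2 = fit(spec, ds.data)
    assert np.array_equal(f1.coef, f2.coef)
    assert f1.aic == f2.aic


# ---------------------------------------------------------------------------
# EDF / information criteria
# ---------------------------------------------------------------------------

def test_parametric_model_edf_equals_coefficient_count():
    cfg = simple_config(n=2000, seed=4, family="N", tau=0.0,
                        smooth_treatment={"age": ("zero", 0.0)},
                        smooth_outcome={"age": ("zero", 0.0)})
    ds = generate(cfg)
    spec = BicopulaModelSpec(
        treatment_eq=EquationSpec("obesity", parametric=("gender", "limitation")),
        outcome_eq=EquationSpec("disease", parametric=("gender",)),
        instrument="limitation", family="N",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fitted = fit(spec, ds.data)
    k = fitted.coef.size
    assert fitted.edf_total == pytest.approx(k, abs=1e-3)
    assert fitted.aic == pytest.approx(-2 * fitted.loglik + 2 * k, abs=1e-2)
    assert fitted.bic == pytest.approx(
        -2 * fitted.loglik + np.log(fitted.n_obs) * k, abs=1e-2)


def test_edf_limits_in_lambda(gaussian_dataset):
    cfg, ds = gaussian_dataset
    spec = model_spec_for(cfg, num_basis=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        loose = fit(spec, ds.data, FitOptions(select_smoothing=False,
                                              lambda_init=1e-4))
        stiff = fit(spec, ds.data, FitOptions(select_smoothing=False,
                                              lambda_init=1e7))
    for v in loose.edf_by_smooth.values():
        assert v == pytest.approx(7.0, abs=0.05)   # J-1 after centering
    for v in stiff.edf_by_smooth.values():
        # 2nd-order penalty: centered null space is one-dimensional (linear)
        assert v == pytest.approx(1.0, abs=0.05)
    aic, bic, table = information_criteria(stiff)
    assert set(table.index) == set(stiff.edf_by_smooth)
    assert aic == stiff.aic and bic == stiff.bic


def test_edf_matches_dense_trace(gaussian_fit):
    """Trace formula recomputed from explicitly assembled dense matrices."""
    f = gaussian_fit
    frame = f.frame
    Hp = f.hessian_penalized
    Lam = frame.penalty_matrix(f.lambdas)
    F = np.linalg.solve(Hp, Hp - Lam)
    assert f.edf_total == pytest.approx(np.trace(F), rel=1e-10)
    for name, sl in zip(frame.smooth_names, frame.smooth_slices):
        assert f.edf_by_smooth[name] == pytest.approx(
            np.sum(np.diag(F)[sl]), rel=1e-10)


# ---------------------------------------------------------------------------
# Posterior draws
# ---------------------------------------------------------------------------

def test_posterior_draws_moments_and_reproducibility(gaussian_fit):
    f = gaussian_fit
    draws = posterior_draws(f, 100_000, seed=2024)
    cov = f.covariance()
    sd = np.sqrt(np.diag(cov))
    mc_se = sd / np.sqrt(draws.shape[0])
    assert np.all(np.abs(draws.mean(axis=0) - f.coef) <= 4 * mc_se)
    emp_cov = np.cov(draws.T)
    assert np.linalg.norm(emp_cov - cov) / np.linalg.norm(cov) < 0.05
    again = posterior_draws(f, 100_000, seed=2024)
    assert np.array_equal(draws, again)
    with pytest.raises(ValueError):
        posterior_draws(f, 0, seed=1)
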