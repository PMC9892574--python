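"""Copula families: CDFs, partials, tau maps, sampling, links."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import kendalltau, kstest

from rebicop.copulas import (
    CopulaFamily,
    CopulaSpec,
    copula_cdf,
    copula_density,
    copula_dtheta,
    copula_partials,
    sample_copula,
    tau_range,
    tau_to_theta,
    theta_link,
    theta_to_tau,
)

FAMILY_THETAS = {
    "AMH": (-0.9, -0.3, 0.4, 0.95),
    "FGM": (-0.9, -0.3, 0.4, 0.95),
    "PL": (0.05, 0.4, 2.0, 12.0),
    "F": (-8.0, -1.5, 2.0, 7.0),
    "N": (-0.85, -0.3, 0.45, 0.9),
    "T": (-0.85, -0.3, 0.45, 0.9),
}


def specs(mid_only=False):
    out = []
    for fam, thetas in FAMILY_THETAS.items():
        use = thetas[1:3] if mid_only else thetas
        out += [CopulaSpec(fam, th) for th in use]
    return out


# ---------------------------------------------------------------------------
# CDF values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("family,theta,p1,p2,expected", [
    ("FGM", 0.0, 0.3, 0.5, 0.15),          # independence reduction
    ("N", 0.0, 0.3, 0.5, 0.15),            # zero-correlation normal factorizes
    ("PL", 2.0, 0.5, 0.5, (2.0 - math.sqrt(2.0)) / 2.0),  # (Q - sqrt(R)) / (2(th-1))
    ("AMH", 0.5, 0.4, 0.6, 0.4 * 0.6 / (1 - 0.5 * 0.6 * 0.4)),
])
def test_cdf_closed_form_values(family, theta, p1, p2, expected):
    assert copula_cdf(CopulaSpec(family, theta), p1, p2) == pytest.approx(expected, abs=1e-12)


def test_plackett_cdf_matches_density_integration():
    """C(0.5, 0.5) equals the integral of the Plackett density over [0,.5]^2."""
    spec = CopulaSpec("PL", 2.0)
    val, err = integrate.dblquad(
        lambda v, u: float(copula_density(spec, u, v)), 1e-9, 0.5, 1e-9, 0.5,
        epsabs=1e-10)
    assert copula_cdf(spec, 0.5, 0.5) == pytest.approx(val, abs=1e-6)


def test_frank_cdf_matches_monte_carlo():
    spec = CopulaSpec("F", 5.0)
    u, v = sample_copula(spec, 100_000, seed=11)
    emp = np.mean((u <= 0.4) & (v <= 0.7))
    se = math.sqrt(emp * (1 - emp) / u.size)
    assert abs(copula_cdf(spec, 0.4, 0.7) - emp) <= 3 * se


@pytest.mark.parametrize("spec", specs(), ids=lambda s: f"{s.family.value}_{s.theta}")
def test_uniform_margins_and_frechet_bounds(spec):
    g = np.linspace(0.0, 1.0, 21)
    U, V = np.meshgrid(g, g)
    c = copula_cdf(spec, U.ravel(), V.ravel())
    lower = np.maximum(U.ravel() + V.ravel() - 1.0, 0.0)
    upper = np.minimum(U.ravel(), V.ravel())
    assert np.all(c >= lower - 1e-9) and np.all(c <= upper + 1e-9)
    p = np.linspace(0, 1, 11)
    assert np.allclose(copula_cdf(spec, p, np.ones_like(p)), p, atol=1e-7)
    assert np.allclose(copula_cdf(spec, np.ones_like(p), p), p, atol=1e-7)
    assert np.allclose(copula_cdf(spec, p, np.zeros_like(p)), 0.0, atol=1e-9)


def test_nan_and_domain_errors():
    with pytest.raises(ValueError):
        copula_cdf(CopulaSpec("N", 0.3), np.nan, 0.5)
    with pytest.raises(ValueError):
        copula_cdf(CopulaSpec("N", 0.3), -0.1, 0.5)
    with pytest.raises(ValueError):
        CopulaSpec("N", 1.5)
    with pytest.raises(ValueError):
        CopulaSpec("PL", -1.0)
    with pytest.raises(ValueError):
        CopulaSpec("T", 0.5, zeta=2.0)
    with pytest.raises(ValueError):
        CopulaSpec("XX", 0.5)


# ---------------------------------------------------------------------------
# Partial derivatives
# ---------------------------------------------------------------------------

def test_fgm_independence_partials():
    d1, d2 = copula_partials(CopulaSpec("FGM", 0.0), 0.3, 0.8)
    assert d1 == pytest.approx(0.8) and d2 == pytest.approx(0.3)


def test_gaussian_exchangeable_partials():
    d1, d2 = copula_partials(CopulaSpec("N", 0.5), 0.5, 0.5)
    assert d1 == pytest.approx(d2, abs=1e-12)


@pytest.mark.parametrize("spec", specs(mid_only=True),
                         ids=lambda s: f"{s.family.value}_{s.theta}")
def test_partials_match_finite_differences(spec, rng):
    u = rng.uniform(0.05, 0.95, 12)
    v = rng.uniform(0.05, 0.95, 12)
    h = 1e-6
    fd1 = (copula_cdf(spec, u + h, v) - copula_cdf(spec, u - h, v)) / (2 * h)
    fd2 = (copula_cdf(spec, u, v + h) - copula_cdf(spec, u, v - h)) / (2 * h)
    d1, d2 = copula_partials(spec, u, v)
    assert np.max(np.abs(d1 - fd1)) <= 1e-5
    assert np.max(np.abs(d2 - fd2)) <= 1e-5
    assert np.all((d1 >= 0) & (d1 <= 1) & (d2 >= 0) & (d2 <= 1))


@pytest.mark.parametrize("spec", specs(mid_only=True),
                         ids=lambda s: f"{s.family.value}_{s.theta}")
def test_dtheta_matches_finite_differences(spec, rng):
    u = rng.uniform(0.05, 0.95, 12)
    v = rng.uniform(0.05, 0.95, 12)
    h = 1e-6
    up = CopulaSpec(spec.family, spec.theta + h, spec.zeta)
    dn = CopulaSpec(spec.family, spec.theta - h, spec.zeta)
    fd = (copula_cdf(up, u, v) - copula_cdf(dn, u, v)) / (2 * h)
    assert np.max(np.abs(copula_dtheta(spec, u, v) - fd)) <= 1e-5


# ---------------------------------------------------------------------------
# Kendall's tau
# ---------------------------------------------------------------------------

def test_tau_closed_forms():
    assert theta_to_tau(CopulaSpec("N", 1.0)) == pytest.approx(1.0)
    assert theta_to_tau(CopulaSpec("PL", 1.0)) == pytest.approx(0.0, abs=1e-12)
    assert theta_to_tau(CopulaSpec("FGM", 0.9)) == pytest.approx(2 * 0.9 / 9)
    assert theta_to_tau(CopulaSpec("F", 1e-7)) == pytest.approx(0.0, abs=1e-7)
    # AMH boundary: tau(-1) = (5 - 8 ln 2) / 3
    assert theta_to_tau(CopulaSpec("AMH", -1.0)) == pytest.approx(
        (5 - 8 * math.log(2)) / 3, abs=1e-10)


@pytest.mark.parametrize("family", [f.value for f in CopulaFamily])
def test_tau_monotone_in_theta(family):
    lo, hi = {"PL": (0.01, 50.0), "F": (-20.0, 20.0)}.get(family, (-0.999, 0.999))
    thetas = np.linspace(lo, hi, 21)
    taus = [theta_to_tau(CopulaSpec(family, t)) for t in thetas]
    assert np.all(np.diff(taus) >= -1e-9)


def test_tau_to_theta_closed_and_roundtrip():
    assert tau_to_theta("N", 0.5) == pytest.approx(math.sin(math.pi / 4))
    with pytest.raises(ValueError, match="range"):
        tau_to_theta("FGM", 0.3)    # beyond 2/9
    with pytest.raises(ValueError, match="range"):
        tau_to_theta("AMH", -0.3)
    # Plackett negative-dependence value in the reported range: theta < 1
    th = tau_to_theta("PL", -0.286)
    assert th < 1.0
    assert theta_to_tau(CopulaSpec("PL", th)) == pytest.approx(-0.286, abs=1e-8)
    for fam in CopulaFamily:
        lo, hi = tau_range(fam)
        for tau in (0.8 * lo, 0.05, 0.8 * hi):
            th = tau_to_theta(fam, tau)
            assert theta_to_tau(CopulaSpec(fam, th)) == pytest.approx(tau, abs=1e-8)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("family,theta", [
    ("AMH", 0.7), ("FGM", 0.8), ("PL", 3.0), ("F", -4.0), ("N", 0.8), ("T", 0.6),
])
def test_sampling_margins_and_tau(family, theta):
    spec = CopulaSpec(family, theta)
    u, v = sample_copula(spec, 10_000, seed=5)
    assert kstest(u, "uniform").pvalue > 0.01
    assert kstest(v, "uniform").pvalue > 0.01
    emp = kendalltau(u, v).statistic
    se = math.sqrt(2 * (2 * u.size + 5) / (9 * u.size * (u.size - 1)))
    assert abs(emp - theta_to_tau(spec)) <= max(3 * se, 0.02)


def test_sampling_reproducible_and_validated():
    spec = CopulaSpec("F", 3.0)
    a = sample_copula(spec, 100, seed=42)
    b = sample_copula(spec, 100, seed=42)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    with pytest.raises(ValueError):
        sample_copula(spec, 0, seed=1)


# ---------------------------------------------------------------------------
# Unconstrained theta links
# ---------------------------------------------------------------------------

def test_theta_link_pinned_points():
    assert theta_link("PL").to_unconstrained(1.0) == pytest.approx(0.0)
    assert theta_link("N").to_unconstrained(0.0) == pytest.approx(0.0)


@pytest.mark.parametrize("family", [f.value for f in CopulaFamily])
def test_theta_link_roundtrip(family, rng):
    link = theta_link(family)
    if family == "PL":
        thetas = np.exp(rng.uniform(-3, 3, 100))
    elif family == "F":
        thetas = rng.uniform(-20, 20, 100)
    else:
        thetas = rng.uniform(-0.999, 0.999, 100)
    back = link.to_theta(link.to_unconstrained(thetas))
    assert np.max(np.abs(back - thetas)) <= 1e-10
    # finite-difference check of the link derivative
    star = link.to_unconstrained(thetas)
    h = 1e-7
    fd = (link.to_theta(star + h) - link.to_theta(star - h)) / (2 * h)
    assert np.allclose(link.dtheta_dstar(star), fd, atol=1e-6)


# ---------------------------------------------------------------------------
# Student-t specifics and property-based invariants
# ---------------------------------------------------------------------------

def test_student_t_converges_to_gaussian():
    g = np.linspace(0.05, 0.95, 10)
    U, V = np.meshgrid(g, g)
    for th in (-0.6, 0.5):
        t_vals = copula_cdf(CopulaSpec("T", th, zeta=1e4), U.ravel(), V.ravel())
        n_vals = copula_cdf(CopulaSpec("N", th), U.ravel(), V.ravel())
        assert np.max(np.abs(t_vals - n_vals)) <= 1e-3


def test_student_t_cdf_against_density_integration():
    spec = CopulaSpec("T", -0.45, zeta=3.0)
    from scipy.special import stdtrit

    def density(x, y, rho=-0.45, nu=3.0):
        q = 1 - rho * rho
        return (1 / (2 * math.pi * math.sqrt(q))) * (
            1 + (x * x - 2 * rho * x * y + y * y) / (nu * q)) ** (-(nu + 2) / 2)

    x, y = stdtrit(3, 0.3), stdtrit(3, 0.7)
    val, _ = integrate.dblquad(lambda yy, xx: density(xx, yy), -250, x, -250, y,
                               epsabs=1e-11)
    assert copula_cdf(spec, 0.3, 0.7) == pytest.approx(val, abs=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    fam=st.sampled_from([f.value for f in CopulaFamily]),
    z=st.floats(-0.95, 0.95),
    u=st.floats(0.01, 0.99),
    v=st.floats(0.01, 0.99),
)
def test_property_bounds_and_monotonicity(fam, z, u, v):
    """Fréchet bounds and conditional-CDF range hold at arbitrary points."""
    if fam == "PL":
        theta = math.exp(3 * z)
    elif fam == "F":
        theta = 10 * z if abs(z) > 1e-3 else 0.5
    else:
        theta = z
    spec = CopulaSpec(fam, theta)
    c = copula_cdf(spec, u, v)
    assert max(u + v - 1, 0) - 1e-9 <= c <= min(u, v) + 1e-9
    d1, d2 = copula_partials(spec, u, v)
    assert 0 <= d1 <= 1 and 0 <= d2 <= 1
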