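"""Generalized gamma distribution in the (mu, sigma, nu) parameterization.

The three-parameter generalized gamma used for normative modelling of
regional grey-matter volumes:

    mu    > 0   location (the distribution's median-scale parameter, mm^3)
    sigma > 0   relative scale (unitless)
    nu   != 0   shape / power parameter (unitless)

With z = (y / mu)^nu and theta = 1 / (sigma^2 nu^2):

    f(y) = |nu| * theta^theta * z^theta * exp(-theta z) / (Gamma(theta) * y)
    F(y) = P(theta, theta z)            for nu > 0
         = 1 - P(theta, theta z)        for nu < 0

where P is the regularized lower incomplete gamma function.  The family
nests the gamma (nu = 1) and, in the limit nu -> 0, the log-normal with
log-location log(mu) and log-scale sigma.  All computation is in log space;
|nu| below ``_NU_EPS`` switches to the log-normal limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

_NU_EPS = 1e-4

__all__ = [
    "GGParams",
    "gg_logpdf",
    "gg_pdf",
    "gg_cdf",
    "gg_ppf",
    "gg_rvs",
    "gg_mean",
    "gg_var",
    "gg_density_cdf",
]


@dataclass(frozen=True)
class GGParams:
    """Parameter triple of the generalized gamma distribution."""

    mu: float
    sigma: float
    nu: float

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.mu) > 0):
            raise ValueError("mu must be positive")
        if not np.all(np.asarray(self.sigma) > 0):
            raise ValueError("sigma must be positive")
        if np.any(np.asarray(self.nu) == 0):
            raise ValueError("nu must be nonzero")

    @property
    def theta(self) -> float:
        return 1.0 / (self.sigma**2 * self.nu**2)


def _check_y(y):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("volumes must be strictly positive")
    return y


def gg_logpdf(y, mu, sigma, nu):
    """Log density, elementwise over broadcastable arguments."""
    y = _check_y(y)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)

    theta = 1.0 / (sigma**2 * nu_safe**2)
    logz = nu_safe * (np.log(y) - np.log(mu))
    # log f = log|nu| + theta log theta + theta log z - theta e^{log z}
    #         - lgamma(theta) - log y
    lp_gg = (
        np.log(np.abs(nu_safe))
        + theta * np.log(theta)
        + theta * logz
        - theta * np.exp(logz)
        - special.gammaln(theta)
        - np.log(y)
    )
    # log-normal limit: log Y ~ N(log mu, sigma^2)
    lp_ln = (
        -np.log(y)
        - np.log(sigma)
        - 0.5 * np.log(2 * np.pi)
        - 0.5 * ((np.log(y) - np.log(mu)) / sigma) ** 2
    )
    return np.where(small, lp_ln, lp_gg)


def gg_pdf(y, mu, sigma, nu):
    return np.exp(gg_logpdf(y, mu, sigma, nu))


def gg_cdf(y, mu, sigma, nu):
    """Cumulative probability, elementwise."""
    y = _check_y(y)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)

    theta = 1.0 / (sigma**2 * nu_safe**2)
    z = np.exp(nu_safe * (np.log(y) - np.log(mu)))
    lower = special.gammainc(theta, theta * z)
    cdf_gg = np.where(nu_safe > 0, lower, 1.0 - lower)
    cdf_ln = stats.norm.cdf((np.log(y) - np.log(mu)) / sigma)
    return np.where(small, cdf_ln, cdf_gg)


def gg_ppf(q, mu, sigma, nu):
    """Quantile function (inverse CDF)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)

    theta = 1.0 / (sigma**2 * nu_safe**2)
    q_eff = np.where(nu_safe > 0, q, 1.0 - q)
    gz = special.gammaincinv(theta, q_eff) / theta
    y_gg = mu * np.exp(np.log(gz) / nu_safe)
    y_ln = mu * np.exp(sigma * stats.norm.ppf(q))
    return np.where(small, y_ln, y_gg)


def gg_rvs(mu, sigma, nu, size=None, rng=None):
    """Draw samples: z = G/theta with G ~ Gamma(theta), y = mu * z^(1/nu)."""
    rng = np.random.default_rng(rng)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if size is None:
        size = np.broadcast(mu, sigma, nu).shape or None
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    theta = 1.0 / (sigma**2 * nu_safe**2)
    g = rng.gamma(np.broadcast_to(theta, size) if size else theta, 1.0, size=size)
    y_gg = mu * np.exp(np.log(g / theta) / nu_safe)
    y_ln = mu * np.exp(sigma * rng.standard_normal(size=size))
    return np.where(small, y_ln, y_gg)


def _raw_moment(k, mu, sigma, nu):
    """E[Y^k] = mu^k theta^(-k/nu) Gamma(theta + k/nu) / Gamma(theta).

    Finite only when theta + k/nu > 0.
    """
    theta = 1.0 / (np.asarray(sigma, float) ** 2 * np.asarray(nu, float) ** 2)
    a = theta + k / np.asarray(nu, float)
    if np.any(a <= 0):
        raise ValueError("moment does not exist for these parameters")
    logm = (
        k * np.log(mu)
        - (k / nu) * np.log(theta)
        + special.gammaln(a)
        - special.gammaln(theta)
    )
    return np.exp(logm)


def gg_mean(mu, sigma, nu):
    nu = np.asarray(nu, dtype=float)
    if np.any(np.abs(nu) < _NU_EPS):
        return np.asarray(mu) * np.exp(np.asarray(sigma) ** 2 / 2)
    return _raw_moment(1, mu, sigma, nu)


def gg_var(mu, sigma, nu):
    nu = np.asarray(nu, dtype=float)
    if np.any(np.abs(nu) < _NU_EPS):
        s2 = np.asarray(sigma, float) ** 2
        return np.asarray(mu, float) ** 2 * np.exp(s2) * (np.exp(s2) - 1)
    m1 = _raw_moment(1, mu, sigma, nu)
    m2 = _raw_moment(2, mu, sigma, nu)
    return m2 - m1**2


def gg_density_cdf(y, params: GGParams):
    """Density and cumulative probability at ``y`` for one parameter triple."""
    return (
        gg_pdf(y, params.mu, params.sigma, params.nu),
        gg_cdf(y, params.mu, params.sigma, params.nu),
    )
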