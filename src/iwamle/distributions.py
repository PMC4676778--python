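"""Inverse Weibull and standard Gumbel (extreme-value) probability functions.

The two-parameter inverse Weibull distribution has cdf

    G(x; sigma, lambda) = exp[-(x * sigma)^(-lambda)],   x > 0,

with scale ``sigma > 0`` and shape ``lambda > 0``.  If ``X`` follows this law
then ``Y = ln X`` follows the Gumbel (extreme-value, maximum) distribution
with location ``mu = -ln(sigma)`` and scale ``theta = 1/lambda``.  All
logarithms in this package are natural.

This module provides the density/cdf/quantile of the inverse Weibull law, the
standard (mu=0, theta=1) Gumbel density, cdf and density derivative, the
order-statistic plotting positions ``p_i = i/(n+1)`` with their standard
Gumbel quantiles ``xi_i = -ln(-ln p_i)``, and the bijection between the two
parameterisations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IWParams",
    "EVParams",
    "iw_pdf",
    "iw_cdf",
    "iw_quantile",
    "ev_std_pdf",
    "ev_std_cdf",
    "ev_std_pdf_prime",
    "plotting_positions",
]

# exp(-e^{-z}) is numerically 0/1 beyond this band; guards overflow of e^{-z}
_Z_GUARD = 30.0


@dataclass(frozen=True)
class IWParams:
    """Inverse Weibull parameters: scale ``sigma`` and shape ``lambda``.

    ``lambda`` is a Python keyword, hence the trailing underscore.
    """

    sigma: float
    lambda_: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"sigma must be a positive finite real, got {self.sigma}")
        if not (self.lambda_ > 0 and np.isfinite(self.lambda_)):
            raise ValueError(f"lambda must be a positive finite real, got {self.lambda_}")

    def to_ev(self) -> "EVParams":
        """Log-domain image: ``mu = -ln(sigma)``, ``theta = 1/lambda``."""
        return EVParams(mu=-np.log(self.sigma), theta=1.0 / self.lambda_)


@dataclass(frozen=True)
class EVParams:
    """Gumbel location ``mu`` (log-lifetime units) and scale ``theta > 0``."""

    mu: float
    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (self.theta > 0 and np.isfinite(self.theta)):
            raise ValueError(f"theta must be a positive finite real, got {self.theta}")

    def to_iw(self) -> IWParams:
        """Original-scale image: ``sigma = e^{-mu}``, ``lambda = 1/theta``."""
        return IWParams(sigma=float(np.exp(-self.mu)), lambda_=1.0 / self.theta)


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("x must be strictly positive")
    return x


def iw_cdf(x, params: IWParams):
    """Inverse Weibull cdf ``exp[-(x*sigma)^(-lambda)]``."""
    x = _check_x(x)
    out = np.exp(-np.power(x * params.sigma, -params.lambda_))
    return out if out.ndim else float(out)


def iw_pdf(x, params: IWParams):
    """Inverse Weibull density ``lambda * sigma^-lambda * x^-(lambda+1) * exp[-(x*sigma)^-lambda]``."""
    x = _check_x(x)
    lam, sig = params.lambda_, params.sigma
    out = lam * sig ** (-lam) * np.power(x, -(lam + 1.0)) * np.exp(
        -np.power(x * sig, -lam)
    )
    return out if out.ndim else float(out)


def iw_quantile(p, params: IWParams):
    """Inverse Weibull quantile ``(1/sigma) * (-ln p)^(-1/lambda)``.

    ``p`` is clamped away from {0, 1} only by requiring it to lie strictly
    inside the open interval; out-of-range values raise.
    """
    p = np.asarray(p, dtype=float)
    if np.any(~((p > 0) & (p < 1))):
        raise ValueError("p must lie strictly inside (0, 1)")
    out = np.power(-np.log(p), -1.0 / params.lambda_) / params.sigma
    return out if out.ndim else float(out)


def ev_std_cdf(z):
    """Standard Gumbel cdf ``F(z) = exp(-e^{-z})`` with overflow guards."""
    z = np.asarray(z, dtype=float)
    out = np.where(z < -_Z_GUARD, 0.0, np.where(z > _Z_GUARD, 1.0, np.exp(-np.exp(-np.clip(z, -_Z_GUARD, _Z_GUARD)))))
    return out if out.ndim else float(out)


def ev_std_pdf(z):
    """Standard Gumbel density ``f(z) = e^{-z} exp(-e^{-z})``.

    Underflows to 0 in both tails; ``e^{-z}`` overflow for very negative z is
    avoided by noting the density is already numerically 0 there.
    """
    z = np.asarray(z, dtype=float)
    zg = np.maximum(z, -_Z_GUARD)  # below the guard the density underflows anyway
    out = np.where(z < -_Z_GUARD, 0.0, np.exp(-zg - np.exp(-zg)))
    return out if out.ndim else float(out)


def ev_std_pdf_prime(z):
    """Derivative of the standard Gumbel density: ``f'(z) = f(z)(e^{-z} - 1)``."""
    z = np.asarray(z, dtype=float)
    zg = np.maximum(z, -_Z_GUARD)
    out = ev_std_pdf(z) * (np.exp(-zg) - 1.0)
    return out if out.ndim else float(out)


def plotting_positions(scheme):
    """Plotting positions for the observed ranks of a censoring scheme.

    For each observed rank ``a_j`` returns ``p_j = a_j/(n+1)``,
    ``q_j = 1 - p_j`` and the standard Gumbel quantile
    ``xi_j = -ln(-ln p_j)``, so that ``ev_std_cdf(xi_j) = p_j`` exactly.

    Returns
    -------
    (p, q, xi) : tuple of ndarray, each of length ``s``.
    """
    a = np.asarray(scheme.ranks, dtype=float)
    p = a / (scheme.n + 1.0)
    q = 1.0 - p
    xi = -np.log(-np.log(p))
    return p, q, xi
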