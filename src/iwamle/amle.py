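"""Closed-form approximate maximum likelihood estimation (AMLE).

Under multiply type-II censoring only the order statistics at fixed ranks
``a_1 < a_2 < ... < a_s`` out of ``n`` units are observed.  On the log scale
the data follow a Gumbel law with location ``mu`` and scale ``theta``, and
the likelihood combines the left-tail mass below the first observed order
statistic, the right-tail mass above the last, the density at each observed
point, and the probability mass of each unobserved gap.

The score equations in ``mu`` and ``theta`` involve the hazard
``f/(1-F)``, the gap ratios ``f(z_j)/(F(z_j)-F(z_{j-1}))`` and the terms
``e^{-z}`` and ``e^{-z} z``, none of which admit closed-form roots.  The AMLE
replaces each such term by its first-order Taylor expansion around the
plotting-position quantiles ``xi_{a_j} = -ln(-ln(a_j/(n+1)))``.  The
linearized ``mu``-score and ``theta``-score form a 2x2 linear system whose
solution is ``mu_hat = E/D``; substituting ``mu_hat`` back into the
``theta``-score with the quadratic (tangent-line times ``z``) treatment of
``e^{-z} z`` and the hazard term yields ``s*theta^2 + B1*theta + C1 = 0``,
solved by the "+" branch of the quadratic formula.

Two coefficient variants are provided.  The shipped default,
``"derivation-consistent"``, uses the exact tangent line
``e^{-z} ~ e^{-xi}(1+xi) - e^{-xi} z`` and the algebraically consistent
assembly of the linear system; it reproduces the reference worked-example
estimates to six decimals.  A ``"paper-literal"`` variant retains the
coefficient forms exactly as typeset in the original derivation (including
an ``(1+xi^2)`` factor and a sign slip) and is kept only for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .distributions import (
    EVParams,
    IWParams,
    ev_std_cdf,
    ev_std_pdf,
    ev_std_pdf_prime,
    plotting_positions,
)

__all__ = [
    "CensoringScheme",
    "CensoredSample",
    "ExpansionCoefficients",
    "FitIntermediates",
    "FitResult",
    "FitError",
    "expansion_coefficients",
    "estimate_mu",
    "estimate_theta",
    "fit_amle",
    "censored_loglik",
    "fit_mle_numeric",
    "DERIVATION_CONSISTENT",
    "PAPER_LITERAL",
]

DERIVATION_CONSISTENT = "derivation-consistent"
PAPER_LITERAL = "paper-literal"


class FitError(RuntimeError):
    """Raised when the closed-form fit degenerates (zero determinant,
    negative discriminant or a nonpositive scale root)."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class CensoringScheme:
    """Total sample size ``n`` and the strictly increasing observed ranks."""

    n: int
    ranks: tuple

    def __init__(self, n: int, ranks: Sequence[int]):
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "ranks", tuple(int(r) for r in ranks))
        if self.n < 1:
            raise ValueError(f"n must be a positive integer, got {n}")
        if len(self.ranks) == 0:
            raise ValueError("at least one observed rank is required")
        arr = np.asarray(self.ranks)
        if arr[0] < 1 or arr[-1] > self.n:
            raise ValueError(f"ranks must lie in [1, n={self.n}], got {self.ranks}")
        if np.any(np.diff(arr) <= 0):
            raise ValueError(f"ranks must be strictly increasing, got {self.ranks}")

    @classmethod
    def complete(cls, n: int) -> "CensoringScheme":
        """The uncensored scheme with ranks ``1..n``."""
        return cls(n, range(1, n + 1))

    @property
    def s(self) -> int:
        return len(self.ranks)

    @property
    def is_complete(self) -> bool:
        return self.s == self.n


@dataclass(frozen=True, eq=False)
class CensoredSample:
    """A censoring scheme plus the observed order-statistic lifetimes."""

    scheme: CensoringScheme
    x: np.ndarray

    def __init__(self, scheme: CensoringScheme, x: Sequence[float]):
        xa = np.array(x, dtype=float)
        if xa.ndim != 1 or len(xa) != scheme.s:
            raise ValueError(
                f"expected {scheme.s} observed values for scheme {scheme.ranks}, got {len(xa)}"
            )
        if np.any(~(xa > 0)):
            raise ValueError("all observed lifetimes must be strictly positive")
        if np.any(np.diff(xa) < 0):
            raise ValueError("observed order statistics must be nondecreasing")
        xa.flags.writeable = False
        object.__setattr__(self, "scheme", scheme)
        object.__setattr__(self, "x", xa)

    @property
    def y(self) -> np.ndarray:
        """Log-lifetimes ``ln x``."""
        return np.log(self.x)

    @property
    def s(self) -> int:
        return self.scheme.s

    def restrict(self, scheme: CensoringScheme) -> "CensoredSample":
        """View a complete sample through a coarser censoring scheme.

        The receiving sample must be complete with the same ``n``.
        """
        if not self.scheme.is_complete:
            raise ValueError("restrict() requires a complete sample")
        if scheme.n != self.scheme.n:
            raise ValueError("scheme n must match the sample's n")
        idx = np.asarray(scheme.ranks) - 1
        return CensoredSample(scheme, self.x[idx])


@dataclass(frozen=True, eq=False)
class ExpansionCoefficients:
    """Taylor-linearization constants for one censoring scheme.

    All arrays indexed by observed-rank position; gap arrays (``K`` and the
    alpha/beta/gamma families) have length ``s - 1`` and correspond to the
    gaps ``j = 2..s``.  Coefficients depend only on ``(n, ranks)``, never on
    the data.
    """

    scheme: CensoringScheme
    p: np.ndarray
    q: np.ndarray
    xi: np.ndarray
    kappa1: float
    delta1: float
    kappa2: float
    delta2: float
    K: np.ndarray
    alpha1: np.ndarray
    beta1: np.ndarray
    gamma1: np.ndarray
    alpha2: np.ndarray
    beta2: np.ndarray
    gamma2: np.ndarray
    alpha3: np.ndarray
    beta3: np.ndarray
    gamma3: np.ndarray
    alpha4: np.ndarray
    beta4: np.ndarray
    gamma4: np.ndarray


@dataclass
class FitIntermediates:
    """Assembled constants of the linear system (``mu_hat``) and the
    quadratic (``theta_hat``)."""

    A_mu: float
    B_mu: float
    C_mu: float
    A_2: float
    B_2: float
    C_2: float
    D: float
    E: float
    B_1: float = field(default=np.nan)
    C_1: float = field(default=np.nan)


@dataclass(frozen=True, eq=False)
class FitResult:
    """AMLE fit: Gumbel-domain and inverse-Weibull-domain parameters,
    with the intermediates and coefficients that produced them."""

    ev: EVParams
    iw: IWParams
    intermediates: FitIntermediates
    coefficients: ExpansionCoefficients
    variant: str


def expansion_coefficients(scheme: CensoringScheme) -> ExpansionCoefficients:
    """All Taylor-linearization constants for one censoring scheme.

    The hazard ``f/(1-F)`` and its ``z``-weighted version are expanded at the
    last observed quantile (``kappa1/delta1`` and ``kappa2/delta2``); the gap
    ratios and their differences at the flanking quantiles of each gap
    (``alpha/beta/gamma`` families, with ``K_j`` the gap ratio's value at the
    expansion point).
    """
    if scheme.s < 2:
        raise ValueError("estimation requires at least two observed ranks (s >= 2)")
    p, q, xi = plotting_positions(scheme)
    f = ev_std_pdf(xi)
    fp = ev_std_pdf_prime(xi)

    fs, fps, qs, xs = f[-1], fp[-1], q[-1], xi[-1]
    kappa1 = (fs - xs * fps - fs**2 / qs * xs) / qs
    delta1 = (fps + fs**2 / qs) / qs
    kappa2 = -(xs**2 / qs) * (fps + fs**2 / qs)
    delta2 = (fs + xs * fps + fs**2 / qs * xs) / qs

    dp = p[1:] - p[:-1]
    fj, fj1 = f[1:], f[:-1]
    fpj, fpj1 = fp[1:], fp[:-1]
    xj, xj1 = xi[1:], xi[:-1]

    K = (fj * xj - fj1 * xj1) / dp
    alpha1 = ((1.0 + K) * fj - xj * fpj) / dp
    beta1 = fpj / dp - (fj / dp) ** 2
    gamma1 = fj * fj1 / dp**2
    alpha2 = ((1.0 + K) * fj1 - xj1 * fpj1) / dp
    beta2 = -gamma1
    gamma2 = fpj1 / dp + (fj1 / dp) ** 2
    alpha4 = K**2 - (xj**2 * fpj - xj1**2 * fpj1) / dp
    beta4 = ((1.0 - K) * fj + xj * fpj) / dp
    gamma4 = -((1.0 - K) * fj1 + xj1 * fpj1) / dp

    return ExpansionCoefficients(
        scheme=scheme,
        p=p,
        q=q,
        xi=xi,
        kappa1=float(kappa1),
        delta1=float(delta1),
        kappa2=float(kappa2),
        delta2=float(delta2),
        K=K,
        alpha1=alpha1,
        beta1=beta1,
        gamma1=gamma1,
        alpha2=alpha2,
        beta2=beta2,
        gamma2=gamma2,
        alpha3=alpha1 - alpha2,
        beta3=beta1 - beta2,
        gamma3=gamma1 - gamma2,
        alpha4=alpha4,
        beta4=beta4,
        gamma4=gamma4,
    )


def _ez_linear_coef(xi: np.ndarray, variant: str) -> np.ndarray:
    # constant part of the tangent line e^{-z} ~ A - e^{-xi} z:
    # derivation-consistent A = e^{-xi}(1+xi); paper-literal A = e^{-xi}(1+xi^2)
    if variant == DERIVATION_CONSISTENT:
        return np.exp(-xi) * (1.0 + xi)
    return np.exp(-xi) * (1.0 + xi**2)


def _check_variant(variant: str) -> None:
    if variant not in (DERIVATION_CONSISTENT, PAPER_LITERAL):
        raise ValueError(
            f"variant must be {DERIVATION_CONSISTENT!r} or {PAPER_LITERAL!r}, got {variant!r}"
        )


def estimate_mu(
    sample: CensoredSample,
    coeffs: ExpansionCoefficients,
    variant: str = DERIVATION_CONSISTENT,
) -> tuple[float, FitIntermediates]:
    """Closed-form ``mu_hat = E/D`` from the two linearized score equations.

    L1 (mu-score):    A_mu*theta + B_mu - C_mu*mu = 0
    L2 (theta-score): A_2*theta  + B_2 - C_2*mu  = 0
    """
    _check_variant(variant)
    if coeffs.scheme != sample.scheme:
        raise ValueError("coefficients were computed for a different censoring scheme")
    c = coeffs
    a = np.asarray(sample.scheme.ranks)
    n, s = sample.scheme.n, sample.scheme.s
    y = sample.y
    e = np.exp(-c.xi)
    A = _ez_linear_coef(c.xi, variant)
    m = (a[1:] - a[:-1] - 1).astype(float)  # gap multipliers a_j - a_{j-1} - 1
    t0 = float(a[0] - 1)
    tn = float(n - a[-1])

    A_mu = t0 * A[0] - tn * c.kappa1 + np.sum(A) - s + np.sum(m * c.alpha3)
    B_mu = (
        -t0 * e[0] * y[0]
        - tn * c.delta1 * y[-1]
        - np.sum(e * y)
        + np.sum(m * (c.beta3 * y[1:] + c.gamma3 * y[:-1]))
    )
    C_mu = -t0 * e[0] - tn * c.delta1 - np.sum(e) + np.sum(m * (c.beta3 + c.gamma3))

    A_2 = s + t0 * e[0] * c.xi[0] ** 2 - tn * c.kappa2 + np.sum(e * c.xi**2) + np.sum(
        m * c.alpha4
    )
    sum_y_sign = -1.0 if variant == DERIVATION_CONSISTENT else 1.0
    B_2 = (
        t0 * e[0] * (1.0 - c.xi[0]) * y[0]
        - tn * c.delta2 * y[-1]
        + np.sum(e * (1.0 - c.xi) * y)
        + sum_y_sign * np.sum(y)
        + np.sum(m * (c.beta4 * y[1:] + c.gamma4 * y[:-1]))
    )
    C_2 = (
        t0 * e[0] * (1.0 - c.xi[0])
        - tn * c.delta2
        + np.sum(e * (1.0 - c.xi))
        - s
        + np.sum(m * (c.beta4 + c.gamma4))
    )

    D = A_mu * C_2 - A_2 * C_mu
    E = A_mu * B_2 - A_2 * B_mu
    if D == 0.0 or not np.isfinite(D):
        raise FitError("degenerate linear system: D = A_mu*C_2 - A_2*C_mu vanishes",
                       {"D": D, "E": E})
    inter = FitIntermediates(
        A_mu=float(A_mu), B_mu=float(B_mu), C_mu=float(C_mu),
        A_2=float(A_2), B_2=float(B_2), C_2=float(C_2),
        D=float(D), E=float(E),
    )
    return float(E / D), inter


def estimate_theta(
    sample: CensoredSample,
    coeffs: ExpansionCoefficients,
    mu_hat: float,
    variant: str = DERIVATION_CONSISTENT,
) -> tuple[float, float, float]:
    """Positive root of ``s*theta^2 + B_1*theta + C_1 = 0`` given ``mu_hat``.

    Returns ``(theta_hat, B_1, C_1)``.
    """
    _check_variant(variant)
    if coeffs.scheme != sample.scheme:
        raise ValueError("coefficients were computed for a different censoring scheme")
    c = coeffs
    a = np.asarray(sample.scheme.ranks)
    n, s = sample.scheme.n, sample.scheme.s
    y = sample.y
    w = y - mu_hat
    e = np.exp(-c.xi)
    A = _ez_linear_coef(c.xi, variant)
    m = (a[1:] - a[:-1] - 1).astype(float)
    t0 = float(a[0] - 1)
    tn = float(n - a[-1])

    if variant == DERIVATION_CONSISTENT:
        # B_1 is homogeneous of degree 1 in the residuals w = y - mu_hat
        gap = np.sum(m * (c.alpha1 * w[1:] - c.alpha2 * w[:-1]))
        B_1 = t0 * A[0] * w[0] - tn * c.kappa1 * w[-1] + np.sum(A * w) - np.sum(w) + gap
    else:
        # literal typeset form: y-part and mu-bracket assembled separately,
        # gap pairing alpha1/gamma2, bracket first term e^{-xi_1} xi_1^2
        gap_y = np.sum(m * (c.alpha1 * y[1:] - c.gamma2 * y[:-1]))
        y_part = (
            t0 * A[0] * y[0] - tn * c.kappa1 * y[-1] + np.sum(A * y) - np.sum(y) + gap_y
        )
        bracket = (
            t0 * e[0] * c.xi[0] ** 2
            - tn * c.kappa1
            + np.sum(A)
            - s
            + np.sum(m * (c.alpha1 - c.gamma2))
        )
        B_1 = y_part - bracket * mu_hat

    C_1 = (
        -t0 * e[0] * w[0] ** 2
        - tn * c.delta1 * w[-1] ** 2
        - np.sum(e * w**2)
        + np.sum(
            m
            * (
                c.beta1 * w[1:] ** 2
                + 2.0 * c.gamma1 * w[1:] * w[:-1]
                - c.gamma2 * w[:-1] ** 2
            )
        )
    )

    disc = B_1**2 - 4.0 * s * C_1
    if disc < 0:
        raise FitError(
            "negative discriminant in the theta quadratic",
            {"B_1": float(B_1), "C_1": float(C_1), "discriminant": float(disc)},
        )
    theta = (-B_1 + np.sqrt(disc)) / (2.0 * s)
    if not (theta > 0):
        raise FitError(
            "nonpositive scale root",
            {"B_1": float(B_1), "C_1": float(C_1), "theta": float(theta)},
        )
    return float(theta), float(B_1), float(C_1)


def fit_amle(
    sample: CensoredSample,
    variant: str = DERIVATION_CONSISTENT,
    coeffs: Optional[ExpansionCoefficients] = None,
) -> FitResult:
    """Full closed-form AMLE pipeline.

    plotting positions -> expansion coefficients -> ``mu_hat = E/D`` ->
    ``theta_hat`` (positive quadratic root) -> back-transform
    ``sigma_hat = e^{-mu_hat}``, ``lambda_hat = 1/theta_hat``.

    Complete samples go through the same formulas: the left/right tail
    multipliers and all gap multipliers vanish.  Passing precomputed
    ``coeffs`` (which depend only on the scheme) amortizes repeated fits
    under one censoring scheme.
    """
    _check_variant(variant)
    if coeffs is None:
        coeffs = expansion_coefficients(sample.scheme)
    mu_hat, inter = estimate_mu(sample, coeffs, variant)
    theta_hat, B_1, C_1 = estimate_theta(sample, coeffs, mu_hat, variant)
    inter.B_1 = B_1
    inter.C_1 = C_1
    ev = EVParams(mu=mu_hat, theta=theta_hat)
    return FitResult(ev=ev, iw=ev.to_iw(), intermediates=inter, coefficients=coeffs,
                     variant=variant)


def censored_loglik(sample: CensoredSample, params: EVParams) -> float:
    """Exact log-likelihood of the multiply type-II censored Gumbel sample.

    Includes the left-tail term ``(a_1-1) ln F(z_{a_1})``, the right-tail
    term ``(n-a_s) ln[1-F(z_{a_s})]``, the density product and the gap terms
    ``(a_j-a_{j-1}-1) ln[F(z_{a_j})-F(z_{a_{j-1}})]``.  The multinomial
    constant is omitted (it does not depend on the parameters).  Returns
    ``-inf`` for parameter values at which any required term degenerates.
    """
    a = np.asarray(sample.scheme.ranks)
    n = sample.scheme.n
    z = (sample.y - params.mu) / params.theta
    s = sample.s
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # everything in the log domain: t = e^{-z}, ln f = -z - t, ln F = -t
        t = np.exp(-z)
        ll = -s * np.log(params.theta) + np.sum(-z - t)
        if a[0] > 1:
            ll += (a[0] - 1) * (-t[0])
        if a[-1] < n:
            # ln(1 - F) = ln(1 - e^{-t}); for tied values this is still finite
            ll += (n - a[-1]) * np.log(-np.expm1(-t[-1]))
        gaps = a[1:] - a[:-1] - 1
        if np.any(gaps > 0):
            # ln[F(z_j) - F(z_{j-1})] = -t_j + ln(1 - e^{-(t_{j-1} - t_j)})
            mask = gaps > 0
            dt = t[:-1] - t[1:]
            lng = -t[1:] + np.log(-np.expm1(-dt))
            ll += np.sum(gaps[mask] * lng[mask])
    return float(ll) if np.isfinite(ll) else float("-inf")


def fit_mle_numeric(
    sample: CensoredSample,
    init: Optional[EVParams] = None,
) -> EVParams:
    """Numerical maximizer of :func:`censored_loglik`.

    Starts from the AMLE (or from ``init``) and maximizes over
    ``(mu, ln theta)``.  Used as an internal oracle for the quality of the
    closed-form estimators; raises on non-convergence.
    """
    if init is None:
        init = fit_amle(sample).ev

    def nll(v):
        mu, logth = v
        return -censored_loglik(sample, EVParams(mu=mu, theta=float(np.exp(logth))))

    res = minimize(
        nll,
        x0=[init.mu, np.log(init.theta)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    if not res.success:
        raise FitError(f"numerical MLE did not converge: {res.message}")
    return EVParams(mu=float(res.x[0]), theta=float(np.exp(res.x[1])))
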