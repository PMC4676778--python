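"""Graphical goodness-of-fit diagnostics for the inverse Weibull fit.

Two coordinate-series diagnostics, both centred at zero when the fitted
inverse Weibull law describes the data:

* the modified normalized sample Lorenz curve (MNSLC) — the ratio of an
  empirical partial-sum Lorenz-type curve to its fitted-quantile
  counterpart, plotted as ``(1 - r_i, 1 - MNSLC_i)`` with ``r_i = a_i/n``;
* an EDF-spacing plot — the ratio ``R_i/P_i`` of cumulative fitted-cdf
  spacings to cumulative rank spacings, plotted as
  ``(a_i/(n+1), R_i/P_i - 1)``.

A lack of fit shows up as a systematic hump: for MNSLC, heavier-lower-tail
alternatives (Pareto, Weibull) rise then fall, while beta, lognormal and
normal alternatives fall then rise; for the EDF-spacing plot the directions
are reversed (normal/lognormal rise then fall, Weibull/beta fall then
rise).  :func:`classify_shape` assigns those qualitative labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amle import CensoredSample
from .distributions import IWParams, iw_cdf, iw_quantile, plotting_positions

__all__ = [
    "DiagnosticSeries",
    "mnslc",
    "nslc_complete",
    "edf_spacing",
    "classify_shape",
    "SHAPE_NEAR_ZERO",
    "SHAPE_RISE_THEN_FALL",
    "SHAPE_FALL_THEN_RISE",
    "SHAPE_OTHER",
]

SHAPE_NEAR_ZERO = "near_zero"
SHAPE_RISE_THEN_FALL = "rise_then_fall"
SHAPE_FALL_THEN_RISE = "fall_then_rise"
SHAPE_OTHER = "other"

#: default near-zero tolerance for shape classification (no reference value
#: exists; chosen for complete samples of n >= 100)
DEFAULT_EPSILON = 0.01


@dataclass(frozen=True, eq=False)
class DiagnosticSeries:
    """Plot coordinates of one diagnostic, plus its qualitative shape."""

    kind: str  # "mnslc" | "edf_spacing"
    x: np.ndarray
    y: np.ndarray
    ranks: tuple
    shape: str

    @property
    def points(self):
        """Ordered list of ``(x, y)`` pairs."""
        return list(zip(self.x.tolist(), self.y.tolist()))


def _series(kind, x, y, ranks, epsilon):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    shape = _classify(y, epsilon) if len(y) >= 4 else SHAPE_OTHER
    return DiagnosticSeries(kind=kind, x=x, y=y, ranks=tuple(ranks), shape=shape)


def mnslc(
    sample: CensoredSample,
    fit: IWParams,
    epsilon: float = DEFAULT_EPSILON,
) -> DiagnosticSeries:
    """Modified normalized sample Lorenz curve under a fitted model.

    For ``i = 1..s`` with ``r_i = a_i/n``:

        MTSL(r_i)   = sum_{j<=i}(x_{a_j} - x_{a_1}) / sum_{j<=s}(x_{a_j} - x_{a_1}) - r_i + 1
        MTSL_F(r_i) = same with x replaced by fitted quantiles F^{-1}(p_{a_j})
        MNSLC_i     = MTSL(r_i) / MTSL_F(r_i)

    and the emitted point is ``(1 - r_i, 1 - MNSLC_i)``.  The first and last
    y-values are exactly zero by construction.
    """
    if sample.s < 2:
        raise ValueError("diagnostic requires s >= 2")
    x = sample.x
    if x[-1] == x[0]:
        raise ValueError("all observed values are equal; empirical Lorenz curve degenerates")
    a = np.asarray(sample.scheme.ranks, float)
    n = sample.scheme.n
    r = a / n
    p, _, _ = plotting_positions(sample.scheme)
    xf = iw_quantile(p, fit)

    def mtsl(v):
        num = np.cumsum(v - v[0])
        return num / num[-1] - r + 1.0

    ratio = mtsl(x) / mtsl(xf)
    return _series("mnslc", 1.0 - r, 1.0 - ratio, sample.scheme.ranks, epsilon)


def nslc_complete(
    sample: CensoredSample,
    fit: IWParams,
    epsilon: float = DEFAULT_EPSILON,
) -> DiagnosticSeries:
    """Normalized sample Lorenz curve for a complete sample.

    Named convenience: coincides pointwise with :func:`mnslc` when the
    scheme is the complete one (``a_j = j``).
    """
    if not sample.scheme.is_complete:
        raise ValueError("nslc_complete requires a complete (uncensored) sample")
    return mnslc(sample, fit, epsilon)


def edf_spacing(
    sample: CensoredSample,
    fit: IWParams,
    epsilon: float = DEFAULT_EPSILON,
) -> DiagnosticSeries:
    """EDF-spacing diagnostic under a fitted model.

    With ``F_j = F(x_{a_j}; sigma_hat, lambda_hat)``:

        R_i = sum_{j<=i}(F_j - F_1) / (F_s - F_1) + 1
        P_i = sum_{j<=i}(a_j - a_1) / (a_s - a_1) + 1

    and the emitted point is ``(a_i/(n+1), R_i/P_i - 1)``.  The first
    y-value is exactly zero.  The per-term differences sit inside the sums,
    which is what makes the series vanish identically when the fitted cdf
    reproduces the plotting positions.
    """
    if sample.s < 2:
        raise ValueError("diagnostic requires s >= 2")
    a = np.asarray(sample.scheme.ranks, float)
    n = sample.scheme.n
    F = np.asarray(iw_cdf(sample.x, fit), float)
    if F[-1] <= F[0]:
        raise ValueError(
            "degenerate fitted cdf spread: F(x_max) must exceed F(x_min) under the fit"
        )
    R = np.cumsum(F - F[0]) / (F[-1] - F[0]) + 1.0
    P = np.cumsum(a - a[0]) / (a[-1] - a[0]) + 1.0
    return _series("edf_spacing", a / (n + 1.0), R / P - 1.0, sample.scheme.ranks, epsilon)


def _classify(y: np.ndarray, epsilon: float) -> str:
    if np.max(np.abs(y)) <= epsilon:
        return SHAPE_NEAR_ZERO
    k = int(np.argmax(np.abs(y)))
    interior = 0 < k < len(y) - 1
    if interior and y[k] > 0:
        return SHAPE_RISE_THEN_FALL
    if interior and y[k] < 0:
        return SHAPE_FALL_THEN_RISE
    return SHAPE_OTHER


def classify_shape(series: DiagnosticSeries, epsilon: float = DEFAULT_EPSILON) -> str:
    """Qualitative label for a diagnostic series.

    ``near_zero`` if ``max|y| <= epsilon``; otherwise ``rise_then_fall`` /
    ``fall_then_rise`` when the largest-magnitude extremum is an interior
    positive maximum / negative minimum; ``other`` when it sits at an
    endpoint.
    """
    if len(series.y) < 4:
        raise ValueError("shape classification requires at least 4 points")
    return _classify(np.asarray(series.y, float), epsilon)
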