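"""Readers and writers: censoring-scheme notation, sample CSV, fit JSON,
diagnostic-series CSV.

Ranks are 1-based throughout, matching the order-statistic convention
``x_{i:n}``.  Sample files are CSV with a ``rank,value`` header (or a bare
``value`` column plus an explicit scheme).  Fits are written as JSON with
numbers at 17 significant digits so that write -> read round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .amle import CensoredSample, CensoringScheme, FitResult
from .gof import DiagnosticSeries

__all__ = ["parse_scheme", "format_scheme", "load_sample", "write_sample",
           "write_fit", "read_fit", "write_series"]


def parse_scheme(text: str, n: int) -> CensoringScheme:
    """Parse compact rank notation like ``"1,2,5-14,18-21"`` into a scheme.

    Ranges are inclusive; ``"1-n"`` is the complete scheme.  Overlapping or
    descending tokens and ranks above ``n`` raise with the offending token
    named.
    """
    ranks: list[int] = []
    for token in str(text).split(","):
        token = token.strip()
        if not token:
            continue
        try:
            if "-" in token:
                lo_s, hi_s = token.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
                if hi < lo:
                    raise ValueError
                chunk = list(range(lo, hi + 1))
            else:
                chunk = [int(token)]
        except ValueError:
            raise ValueError(f"malformed scheme token {token!r}") from None
        if chunk[-1] > n:
            raise ValueError(f"scheme token {token!r} exceeds n = {n}")
        if ranks and chunk[0] <= ranks[-1]:
            raise ValueError(f"scheme token {token!r} overlaps or descends")
        ranks.extend(chunk)
    if not ranks:
        raise ValueError("empty censoring scheme")
    return CensoringScheme(n, ranks)


def format_scheme(scheme: CensoringScheme) -> str:
    """Inverse of :func:`parse_scheme`: compact ``"1,2,5-14,18-21"`` text."""
    out = []
    ranks = list(scheme.ranks)
    start = prev = ranks[0]
    for r in ranks[1:] + [None]:
        if r is not None and r == prev + 1:
            prev = r
            continue
        out.append(str(start) if start == prev else f"{start}-{prev}")
        if r is not None:
            start = prev = r
    return ",".join(out)


def load_sample(path, scheme: CensoringScheme | None = None, n: int | None = None) -> CensoredSample:
    """Read a censored sample from CSV.

    Accepts either a ``rank,value`` table (``n`` taken from ``scheme`` if
    given, else the largest rank), or a bare ``value`` column with an
    explicit ``scheme``.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "value" not in cols:
        raise ValueError(f"{path}: expected a 'value' column, found {cols}")
    bad = df.index[~(pd.to_numeric(df["value"], errors="coerce") > 0)]
    if len(bad):
        raise ValueError(f"{path}: nonpositive or malformed value at data row {bad[0] + 1}")
    if "rank" in cols:
        ranks = df["rank"].astype(int).to_numpy()
        order = np.argsort(ranks)
        ranks = ranks[order]
        values = df["value"].to_numpy(float)[order]
        if scheme is None:
            scheme = CensoringScheme(n if n is not None else int(ranks[-1]), ranks)
        elif tuple(ranks) != scheme.ranks:
            raise ValueError(f"{path}: file ranks {tuple(ranks)} do not match the given scheme")
        return CensoredSample(scheme, values)
    if scheme is None:
        values = df["value"].to_numpy(float)
        if n is not None and n != len(values):
            raise ValueError("a bare value column needs an explicit scheme when n != s")
        return CensoredSample(CensoringScheme.complete(len(values)), np.sort(values))
    return CensoredSample(scheme, df["value"].to_numpy(float))


def write_sample(sample: CensoredSample, path) -> None:
    """Write a censored sample as ``rank,value`` CSV."""
    pd.DataFrame({"rank": sample.scheme.ranks, "value": sample.x}).to_csv(path, index=False)


def _fingerprint(sample: CensoredSample) -> str:
    payload = json.dumps(
        {"n": sample.scheme.n, "ranks": list(sample.scheme.ranks),
         "x": [repr(v) for v in sample.x]},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def fit_to_dict(result: FitResult, sample: CensoredSample | None = None) -> dict:
    """JSON-ready dictionary of a fit (17-significant-digit floats)."""
    inter = result.intermediates
    d = {
        "sigma_hat": result.iw.sigma,
        "lambda_hat": result.iw.lambda_,
        "mu_hat": result.ev.mu,
        "theta_hat": result.ev.theta,
        "variant": result.variant,
        "scheme": {"n": result.coefficients.scheme.n,
                   "ranks": format_scheme(result.coefficients.scheme)},
        "intermediates": {k: getattr(inter, k)
                          for k in ("A_mu", "B_mu", "C_mu", "A_2", "B_2", "C_2",
                                    "D", "E", "B_1", "C_1")},
    }
    if sample is not None:
        d["input_fingerprint"] = _fingerprint(sample)
    return d


def write_fit(result: FitResult, path, sample: CensoredSample | None = None) -> None:
    """Write a fit as JSON; floats keep full precision for exact round-trip."""
    Path(path).write_text(json.dumps(fit_to_dict(result, sample), indent=2) + "\n")


def read_fit(path) -> dict:
    return json.loads(Path(path).read_text())


def write_series(series: DiagnosticSeries, path) -> None:
    """Write a diagnostic series as CSV (columns kind, i, rank, x, y)."""
    pd.DataFrame(
        {
            "kind": series.kind,
            "i": np.arange(1, len(series.x) + 1),
            "rank": series.ranks,
            "x": series.x,
            "y": series.y,
        }
    ).to_csv(path, index=False)
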