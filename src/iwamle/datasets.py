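"""Bundled worked-example datasets.

Two classical lifetime/extreme-value datasets:

* ``ball_bearings`` — millions of revolutions to failure of 23 deep-groove
  ball bearings in an endurance test (Lieblein & Zelen's data).  The inverse
  Weibull analysis works on the reciprocals; by default the reciprocals are
  computed at full floating-point precision from the revolution counts, with
  a ``rounded=True`` toggle returning the 3-decimal rounded inverse times
  often quoted alongside the data (sensitivity mode).
* ``flood_levels`` — maximum flood levels (millions of cubic feet per
  second) of the Susquehanna River at Harrisburg over 20 four-year periods,
  1890-1969 (Dumonceaux & Antle's data).

Both loaders return complete :class:`~iwamle.amle.CensoredSample` objects
sorted ascending; use :meth:`CensoredSample.restrict` with one of the scheme
presets to obtain the censored versions.
"""

from __future__ import annotations

import numpy as np

from .amle import CensoredSample, CensoringScheme

__all__ = [
    "BALL_BEARING_REVOLUTIONS",
    "BALL_BEARING_INVERSE_ROUNDED",
    "FLOOD_LEVELS",
    "ball_bearings",
    "flood_levels",
    "load_dataset",
    "scheme_preset",
    "SCHEME_PRESETS",
]

#: millions of revolutions before failure, 23 ball bearings (ascending)
BALL_BEARING_REVOLUTIONS = (
    17.88, 28.92, 33.00, 41.52, 42.12, 45.60, 48.40, 51.84, 51.96, 54.12,
    55.56, 67.80, 68.64, 68.64, 68.88, 84.12, 93.12, 98.64, 105.12, 105.84,
    127.92, 128.04, 173.40,
)

#: the same data as inverse failure times rounded to 3 decimals (ascending)
BALL_BEARING_INVERSE_ROUNDED = (
    0.006, 0.008, 0.008, 0.009, 0.010, 0.010, 0.011, 0.012, 0.015, 0.015,
    0.015, 0.015, 0.018, 0.018, 0.019, 0.019, 0.021, 0.022, 0.024, 0.024,
    0.030, 0.035, 0.056,
)

#: maximum flood levels of the Susquehanna River, 20 four-year periods
FLOOD_LEVELS = (
    0.654, 0.613, 0.315, 0.449, 0.297, 0.402, 0.379, 0.423, 0.379, 0.324,
    0.269, 0.740, 0.418, 0.412, 0.494, 0.416, 0.338, 0.392, 0.484, 0.265,
)

#: named censoring schemes used with the bundled data and in figure-style
#: simulations ("paper-figure-n30" reflects a figure-caption scheme)
SCHEME_PRESETS = {
    "ball-bearings-censored": (23, "1,2,5-14,18-21"),
    "flood-levels-censored": (20, "1-7,11-18"),
    "paper-figure-n30": (30, "1,5-13,17-25,28-30"),
}


def ball_bearings(rounded: bool = False) -> CensoredSample:
    """Complete sample of the 23 inverse failure times, ascending.

    ``rounded=False`` (default) computes reciprocals of the revolution
    counts at full precision; ``rounded=True`` returns the printed 3-decimal
    inverse times instead.
    """
    if rounded:
        x = np.asarray(BALL_BEARING_INVERSE_ROUNDED)
    else:
        x = np.sort(1.0 / np.asarray(BALL_BEARING_REVOLUTIONS))
    return CensoredSample(CensoringScheme.complete(23), x)


def flood_levels() -> CensoredSample:
    """Complete sample of the 20 flood levels, sorted ascending."""
    return CensoredSample(CensoringScheme.complete(20), np.sort(FLOOD_LEVELS))


def load_dataset(name: str, **kwargs) -> CensoredSample:
    """Load a bundled dataset by name ("ball_bearings" or "flood_levels")."""
    loaders = {"ball_bearings": ball_bearings, "flood_levels": flood_levels}
    if name not in loaders:
        raise KeyError(f"unknown dataset {name!r}; available: {sorted(loaders)}")
    return loaders[name](**kwargs)


def scheme_preset(name: str) -> CensoringScheme:
    """Named censoring-scheme preset (see :data:`SCHEME_PRESETS`)."""
    from .io import parse_scheme

    if name not in SCHEME_PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(SCHEME_PRESETS)}")
    n, text = SCHEME_PRESETS[name]
    return parse_scheme(text, n)
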