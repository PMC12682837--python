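"""Negative-exponential organ growth model.

Every root and leaf in the simulation elongates following the classic
negative-exponential law

    l(t) = l_max * (1 - exp(-r * t / l_max))

where ``r`` (cm d⁻¹) is the initial elongation rate — the derivative at
emergence — and ``l_max`` (cm) the asymptotic maximal length.  The model has
a closed-form inverse,

    age(l) = -(l_max / r) * ln(1 - l / l_max),

which is used both to date root segments (a point laid down at arc length
``l`` along an organ was created at organ age ``age(l)``) and to convert
distance-from-base hydraulic conductivity profiles to age-dependent ones.

The fitting routine estimates ``r`` only, with ``l_max`` held fixed, by
bounded one-dimensional least squares — the protocol used to extract
elongation rates from rhizotron length time series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "GrowthFit",
    "length_at_age",
    "age_at_length",
    "fit_elongation",
    "distance_profile_to_age_profile",
    "trim_declining_phase",
]

#: Upper bound on the elongation rate (cm/d) for the bounded 1-D fit.
R_MAX = 50.0


@dataclass(frozen=True)
class GrowthFit:
    """Result of a fixed-``l_max`` elongation-rate fit."""

    r_hat: float  # fitted initial elongation rate (cm/d)
    l_max_fixed: float  # the fixed maximal length (cm)
    rss: float  # residual sum of squares (cm^2)
    n_points: int


def length_at_age(t, r: float, l_max: float):
    """Organ length (cm) at age ``t`` (d) under negative-exponential growth.

    Accepts scalar or array ``t``.  Raises ``ValueError`` for negative ages
    or non-positive parameters.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("organ age must be non-negative")
    if r <= 0 or l_max <= 0:
        raise ValueError("r and l_max must be positive")
    out = l_max * (-np.expm1(-r * t / l_max))
    return float(out) if out.ndim == 0 else out


def age_at_length(l, r: float, l_max: float):
    """Inverse growth law: age (d) at which an organ reaches length ``l`` (cm).

    Undefined at or beyond the asymptote; ``l >= l_max`` raises.
    """
    l = np.asarray(l, dtype=float)
    if r <= 0 or l_max <= 0:
        raise ValueError("r and l_max must be positive")
    if np.any(l < 0):
        raise ValueError("length must be non-negative")
    if np.any(l >= l_max):
        raise ValueError("length must be below l_max; age is undefined at the asymptote")
    out = -(l_max / r) * np.log1p(-l / l_max)
    return float(out) if out.ndim == 0 else out


def fit_elongation(series: Sequence[tuple[float, float]], l_max: float) -> GrowthFit:
    """Least-squares estimate of the initial elongation rate ``r``.

    ``series`` is a sequence of (time d, cumulative length cm) pairs with
    strictly increasing times and non-decreasing lengths below ``l_max``.
    ``l_max`` is held fixed; the residual sum of squares is minimized over
    ``r`` in (0, 50] by bounded scalar minimization.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (t, length) pairs")
    t, l = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(np.diff(l) < 0):
        raise ValueError("lengths must be non-decreasing")
    if np.any(l >= l_max):
        raise ValueError("lengths must stay below the fixed l_max")
    if np.all(l == 0):
        raise ValueError("all lengths are zero; elongation rate not identifiable")

    def rss(r):
        return float(np.sum((length_at_age(t, r, l_max) - l) ** 2))

    res = minimize_scalar(rss, bounds=(1e-8, R_MAX), method="bounded",
                          options={"xatol": 1e-12})
    return GrowthFit(r_hat=float(res.x), l_max_fixed=float(l_max),
                     rss=float(res.fun), n_points=len(t))


def trim_declining_phase(series: Sequence[tuple[float, float]],
                         fraction: float = 0.2) -> np.ndarray:
    """Drop trailing points of a leaf growth series once daily elongation declines.

    Points after the finite-difference increment per day falls below
    ``fraction`` of the maximum observed increment are excluded; the fitting
    protocol uses only the phase before daily elongation starts declining.
    """
    arr = np.asarray(series, dtype=float)
    if arr.shape[0] < 3:
        return arr
    inc = np.diff(arr[:, 1]) / np.diff(arr[:, 0])
    cutoff = fraction * inc.max()
    below = np.nonzero(inc < cutoff)[0]
    if below.size == 0:
        return arr
    # keep everything up to (and including) the node before the first slow step
    return arr[: below[0] + 1]


def distance_profile_to_age_profile(profile: Sequence[tuple[float, float]],
                                    r: float, l_max: float) -> list[tuple[float, float]]:
    """Convert a distance-from-base profile to an age profile via the inverse growth law.

    Each (distance cm, value) entry becomes (age d, value); values are
    unchanged and ordering of distances maps to ordering of ages.  Entries at
    or beyond ``l_max`` are rejected with the offending distance named.
    """
    out = []
    for i, (dist, value) in enumerate(profile):
        if dist >= l_max:
            raise ValueError(
                f"profile entry {i} at distance {dist} cm is not below l_max={l_max} cm"
            )
        out.append((age_at_length(float(dist), r, l_max), value))
    return out
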