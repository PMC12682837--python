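"""Soil-phosphorus dose-response functions for maize architecture parameters.

Three responses convert plant-available soil P (mg P per 100 g soil, CAL
extraction) into treatment-specific architecture parameters:

* axial-root radius:   a_ax(P) = α_a · P + a_P0   (linear, valid on the
  observed [P_min, P_max] window; no extrapolation),
* crown-root initial elongation rate, driven by the soil-P-to-biomass ratio
  PB = P / DM_plant:  r_c(PB) = α_rc · min(PB, PB_max)  (capped linear
  through the origin),
* leaf initial elongation rate:  r_l(P) = α_rl · P + r_P0  (linear, bounded).

``apply_response`` rewrites a base ("general") parameter table so that only
these identified response parameters change with P; everything else is kept
bit-identical, mirroring the response-driven model variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .tables import ParameterTable, SOIL_P_LEVELS

__all__ = [
    "PResponseModel", "fit_axial_radius_response", "fit_leaf_elongation_response",
    "fit_capped_linear", "crown_elongation_response", "leaf_elongation_response",
    "axial_radius_response", "apply_response",
]

AXIAL_TYPES = ("primary", "seminal", "crown")


@dataclass
class PResponseModel:
    """Fitted coefficients of the three P-response functions with bounds."""

    alpha_a: float  # radius slope (cm per mg P hg soil^-1)
    a_P0: float  # radius intercept (cm)
    P_min: float  # validity bounds (mg P hg soil^-1)
    P_max: float
    alpha_rc: float  # crown elongation slope (cm d^-1 per PB unit)
    PB_max: float  # cap (mg P hg soil^-1 g biomass^-1)
    alpha_rl: float  # leaf elongation slope
    r_P0: float  # leaf elongation intercept (cm d^-1)
    P_ref: float  # reference P at which the base table is anchored
    provenance: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PResponseModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_bounds(P: float, model: PResponseModel) -> None:
    if not (model.P_min <= P <= model.P_max):
        raise ValueError(f"P={P} outside the fitted validity window "
                         f"[{model.P_min}, {model.P_max}]; no extrapolation")


def fit_axial_radius_response(P_levels: Sequence[float],
                              radii: Sequence[float]) -> tuple[float, float, dict]:
    """OLS line through (soil P, axial-root radius) observations.

    Returns (slope α_a, intercept a_P0, diagnostics).  The validity bounds
    are the observed min/max P.  All-equal P levels are rejected.
    """
    P = np.asarray(P_levels, dtype=float)
    a = np.asarray(radii, dtype=float)
    if P.size < 2 or np.all(P == P[0]):
        raise ValueError("need at least two distinct P levels")
    res = stats.linregress(P, a)
    diag = {"r_value": res.rvalue, "stderr": res.stderr,
            "P_min": float(P.min()), "P_max": float(P.max()),
            "residuals": (a - (res.slope * P + res.intercept)).tolist()}
    return float(res.slope), float(res.intercept), diag


def fit_leaf_elongation_response(P_levels: Sequence[float],
                                 rates: Sequence[float]) -> tuple[float, float, dict]:
    """OLS line through (soil P, leaf initial elongation rate)."""
    return fit_axial_radius_response(P_levels, rates)


def fit_capped_linear(PB: Sequence[float],
                      y: Sequence[float]) -> tuple[float, float, dict]:
    """Fit y = α · min(PB, PB_max) by profiling the changepoint.

    The changepoint is profiled over the observed PB values; for each
    candidate cap the through-origin slope has the closed form
    Σ x y / Σ x².  Returns (α, PB_max, diagnostics).  When every
    observation sits below the best cap the cap is unidentifiable and the
    diagnostics flag it (cap then equals the maximum observed PB).
    """
    PB = np.asarray(PB, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(PB < 0):
        raise ValueError("PB must be non-negative")
    best = None
    for cap in np.unique(PB[PB > 0]):
        x = np.minimum(PB, cap)
        alpha = float(x @ y / (x @ x))
        rss = float(np.sum((alpha * x - y) ** 2))
        if best is None or rss < best[2]:
            best = (alpha, float(cap), rss)
    if best is None:
        raise ValueError("no positive PB observations")
    alpha, cap, rss = best
    identifiable = cap < float(PB.max())
    return alpha, cap, {"rss": rss, "cap_identifiable": identifiable}


def axial_radius_response(P: float, model: PResponseModel) -> float:
    """Pooled axial-root radius (cm) at soil P level ``P``."""
    _check_bounds(P, model)
    return model.alpha_a * P + model.a_P0


def crown_elongation_response(PB: float, model: PResponseModel) -> float:
    """Crown-root initial elongation rate (cm d⁻¹) at biomass ratio ``PB``.

    Linear through the origin below the cap; constant α_rc · PB_max beyond.
    """
    if PB < 0:
        raise ValueError("PB must be non-negative")
    return model.alpha_rc * min(PB, model.PB_max)


def leaf_elongation_response(P: float, model: PResponseModel) -> float:
    """Leaf initial elongation rate (cm d⁻¹) at soil P level ``P``."""
    _check_bounds(P, model)
    return model.alpha_rl * P + model.r_P0


def fit_response_model(radius_obs: Optional[dict] = None,
                       crown_obs: Optional[dict] = None,
                       leaf_obs: Optional[dict] = None,
                       dm_plant: Optional[dict] = None) -> PResponseModel:
    """Fit all three responses from per-treatment mean observations.

    Each ``*_obs`` maps treatment label -> observed mean (radius cm, crown r
    cm/d, leaf r cm/d).  ``dm_plant`` maps treatment -> plant dry matter (g)
    used to form PB for the crown response.  Missing blocks default to the
    packaged per-treatment table means (and the synthetic stand-in dry
    matter, flagged in provenance).
    """
    from .tables import load_parameter_table  # deferred: avoids cycle at import

    provenance = []
    treatments = sorted(SOIL_P_LEVELS)
    P = np.array([SOIL_P_LEVELS[t] for t in treatments])

    if radius_obs is None or crown_obs is None or leaf_obs is None:
        tables = {t: load_parameter_table(t) for t in treatments}
    if radius_obs is None:
        # pool the three axial types per treatment
        radius_obs = {t: float(np.mean([tables[t].get(rt, "a")[0]
                                        for rt in AXIAL_TYPES]))
                      for t in treatments}
        provenance.append("axial radii from packaged tables (pooled axial types)")
    if crown_obs is None:
        crown_obs = {t: tables[t].get("crown", "r")[0] for t in treatments}
        provenance.append("crown elongation from packaged tables")
    if leaf_obs is None:
        leaf_obs = {t: tables[t].get("leaf", "r")[0] for t in treatments}
        provenance.append("leaf elongation from packaged tables")
    if dm_plant is None:
        import pandas as pd
        from .tables import data_path
        dm = pd.read_csv(data_path("dry_matter_synthetic.csv"), comment="#")
        dm_plant = dict(zip(dm["treatment"], dm["dm_plant_g"]))
        provenance.append("dry matter: synthetic stand-in values")

    alpha_a, a_P0, _ = fit_axial_radius_response(
        P, [radius_obs[t] for t in treatments])
    alpha_rl, r_P0, _ = fit_leaf_elongation_response(
        P, [leaf_obs[t] for t in treatments])
    PB = np.array([SOIL_P_LEVELS[t] / dm_plant[t] for t in treatments])
    alpha_rc, PB_max, _ = fit_capped_linear(PB, [crown_obs[t] for t in treatments])

    return PResponseModel(alpha_a=alpha_a, a_P0=a_P0,
                          P_min=float(P.min()), P_max=float(P.max()),
                          alpha_rc=alpha_rc, PB_max=PB_max,
                          alpha_rl=alpha_rl, r_P0=r_P0,
                          P_ref=float(P.mean()),
                          provenance="; ".join(provenance))


def apply_response(base: ParameterTable, P: float, dm_plant: float,
                   model: PResponseModel) -> ParameterTable:
    """Derive a P-specific parameter table from the base ("general") set.

    Only the identified response parameters change: the three axial-root
    radius means are scaled by the fitted radius line's ratio at ``P``
    versus the anchor ``P_ref`` (preserving per-type offsets), the crown
    initial elongation rate follows the capped PB response, and the leaf
    initial elongation rate follows the linear P response.  All standard
    deviations and all other parameters are preserved bit-identically.
    """
    _check_bounds(P, model)
    out = base.copy()
    out.treatment = f"{base.treatment}@P={P}"

    ratio = axial_radius_response(P, model) / axial_radius_response(model.P_ref, model)
    for rt in AXIAL_TYPES:
        mean, sd = out.root_types[rt]["a"]
        out.root_types[rt]["a"] = (mean * ratio, sd)

    _, crown_sd = out.root_types["crown"]["r"]
    out.root_types["crown"]["r"] = (
        crown_elongation_response(P / dm_plant, model), crown_sd)

    if "leaf" in out.shoot:
        _, leaf_sd = out.shoot["leaf"]["r"]
        out.shoot["leaf"]["r"] = (leaf_elongation_response(P, model), leaf_sd)

    return out
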