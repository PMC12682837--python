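"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with a
recorded truth: rhizotron-style per-root length time series following the
negative-exponential growth law plus tracing noise, RSML time series of a
simulated plant projected to the rhizotron plane, age-dependent hydraulic
conductivity profiles, and linear/capped-linear P-response datasets.  All
generators are deterministic under a fixed seed and write machine-readable
truth records next to their outputs, so recovery studies can compare
estimates against the generating parameters without any external data.

Default observation days mirror a four-week rhizotron campaign: daily
imaging for three weeks, then every second day to day 28.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .architecture import (PlantNetwork, PlantParams, network_at_time,
                           simulate_plant)
from .growth import length_at_age
from .hydraulics import HydraulicProfile
from .rsml import RsmlRoot, write_rsml

__all__ = [
    "SyntheticSpec", "default_observation_days", "gen_root_length_series",
    "gen_synthetic_rhizotron", "gen_hydraulic_profile", "gen_response_dataset",
    "network_to_rsml",
]


def default_observation_days() -> np.ndarray:
    """Imaging days: daily to day 21, then every 2 d to day 28."""
    return np.concatenate([np.arange(1.0, 22.0), np.arange(22.0, 29.0, 2.0)])


@dataclass
class SyntheticSpec:
    """Ground-truth parameters and noise model for the generators."""

    rng_seed: int = 0
    r: float = 3.0  # true initial elongation rate (cm/d)
    l_max: float = 139.0  # true maximal length (cm)
    days: np.ndarray = field(default_factory=default_observation_days)
    noise_sd_length: float = 0.5  # tracing noise on cumulative length (cm)
    noise_rel_radius: float = 0.10  # relative noise on radii
    noise_rel_response: float = 0.05  # relative noise on response data
    # capped-linear / linear response truths
    alpha_a: float = 0.006
    a_P0: float = 0.045
    alpha_rc: float = 1.5
    PB_max: float = 2.5
    alpha_rl: float = 0.5
    r_P0: float = 6.9

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("observation days must be strictly increasing")
        for name in ("noise_sd_length", "noise_rel_radius", "noise_rel_response"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def gen_root_length_series(spec: SyntheticSpec) -> tuple[np.ndarray, dict]:
    """(day, cumulative length) series from the growth law plus Gaussian noise.

    Noisy lengths are clipped to be non-decreasing (a traced root never
    shrinks).  Returns the series and a truth record.
    """
    rng = spec.rng()
    clean = length_at_age(spec.days, spec.r, spec.l_max)
    noisy = clean + rng.normal(0.0, spec.noise_sd_length, size=clean.shape) \
        if spec.noise_sd_length > 0 else clean.copy()
    noisy = np.maximum.accumulate(np.maximum(noisy, 0.0))
    noisy = np.minimum(noisy, spec.l_max * (1 - 1e-9))
    series = np.column_stack([spec.days, noisy])
    truth = {"r": spec.r, "l_max": spec.l_max,
             "noise_sd_length": spec.noise_sd_length, "rng_seed": spec.rng_seed}
    return series, truth


def network_to_rsml(net: PlantNetwork, t: float,
                    planar: bool = True) -> list[RsmlRoot]:
    """Convert the root part of a network at time ``t`` to RSML roots.

    The primary root is listed first (tracing convention).  ``planar``
    zeroes the y coordinate, mimicking flat-rhizotron traces.  Root ids are
    organ ids, stable across time points.
    """
    sub = network_at_time(net, t)
    by_organ: dict[int, list] = {}
    for s in sub.segments:
        if s.organ_type == "stem":
            continue
        by_organ.setdefault(s.organ_id, []).append(s)

    organ_order = sorted(
        by_organ,
        key=lambda oid: (0 if net.organs[oid].type == "primary" else 1,
                         net.organs[oid].t0, oid))
    roots = []
    for oid in organ_order:
        segs = sorted(by_organ[oid], key=lambda s: s.id)
        info = net.organs[oid]
        pts = [net.nodes[segs[0].prox]] + [net.nodes[s.dist] for s in segs]
        pts = np.vstack(pts)
        if planar:
            pts = pts.copy()
            pts[:, 1] = 0.0
        times = np.array([info.t0] + [s.creation_time for s in segs])
        radii = np.full(len(pts), info.radius)
        parent = info.parent_organ
        roots.append(RsmlRoot(
            id=f"organ-{oid}",
            parent_id=None if parent < 0 or net.organs[parent].type == "stem"
            else f"organ-{parent}",
            polyline=pts, radii=radii, creation_times=times,
            type_label=info.type,
            branching_order=0 if info.type in ("primary", "seminal", "crown") else 1,
        ))
    return roots


def gen_synthetic_rhizotron(spec: SyntheticSpec, params: PlantParams,
                            out_dir, days: Optional[np.ndarray] = None) -> dict:
    """Simulate one plant and write an RSML trace per imaging day.

    Root ids are consistent across days.  Returns a manifest with the file
    paths and the truth record (the realized organ parameters).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    days = spec.days if days is None else np.asarray(days, dtype=float)
    t_end = float(days.max())
    net = simulate_plant(params, t_end, rng_seed=spec.rng_seed)

    files = []
    for day in days:
        roots = network_to_rsml(net, float(day))
        path = out_dir / f"day_{day:05.1f}.rsml"
        write_rsml(roots, path)
        files.append(str(path))

    truth = {
        "rng_seed": spec.rng_seed,
        "treatment": params.treatment,
        "organs": {str(oid): {"type": o.type, "t0": o.t0, "r": o.r,
                              "l_max": o.l_max, "radius": o.radius}
                   for oid, o in net.organs.items()},
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return {"files": files, "truth": truth, "network": net}


def gen_hydraulic_profile(spec: SyntheticSpec,
                          scale: float = 1.0) -> tuple[HydraulicProfile, dict]:
    """Synthetic age-dependent hydraulic profile with known knot values.

    Per root type, k_r decreases and K_x increases piecewise-linearly with
    segment age (constant beyond the last knot); magnitudes follow the
    packaged synthetic stand-in, whose scale puts the whole-plant K_rs of a
    28-d high-P plant inside the published young-maize range
    [7.00e-5, 2.37e-2] cm² d⁻¹.  ``scale`` multiplies every knot (K_rs
    scales with it exactly, by linearity).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    profile = HydraulicProfile.default().scaled(scale)
    truth = {"scale": scale,
             "knots": {t: {"age": a.tolist(), "kr": kr.tolist(), "kx": kx.tolist()}
                       for t, (a, kr, kx) in profile.knots.items()}}
    return profile, truth


def gen_response_dataset(spec: SyntheticSpec, P_levels=None,
                         n_per_level: int = 5) -> tuple[dict, dict]:
    """Linear / capped-linear response observations with known coefficients.

    Generates per-plant axial radii (linear in P), crown elongation rates
    (capped linear in PB) and leaf elongation rates (linear in P) with
    relative Gaussian noise.  PB is formed with a dry-matter proxy
    increasing in P.  Flags the cap as unidentifiable when every PB sits
    below it.
    """
    rng = spec.rng()
    P = np.asarray(P_levels if P_levels is not None else [1.8, 3.3, 4.6, 7.7],
                   dtype=float)
    if P.size < 4:
        raise ValueError("need at least 4 P levels")
    P_rep = np.repeat(P, n_per_level)
    # fixed PB design grid; the default truth PB_max (2.5) sits on it because
    # the profiling changepoint estimator searches observed PB values, so
    # recovery is only well-posed for representable caps
    pb_levels = np.sort(np.resize([1.5, 2.0, 2.5, 3.2], P.size))
    PB = np.repeat(pb_levels, n_per_level)
    dm = P_rep / PB  # implied dry-matter covariate (g)

    def noisy(clean):
        if spec.noise_rel_response == 0:
            return clean.copy()
        return clean * (1 + rng.normal(0, spec.noise_rel_response,
                                       size=clean.shape))

    radii = noisy(spec.alpha_a * P_rep + spec.a_P0)
    r_c = noisy(spec.alpha_rc * np.minimum(PB, spec.PB_max))
    r_l = noisy(spec.alpha_rl * P_rep + spec.r_P0)

    data = {"P": P_rep, "PB": PB, "radii": radii, "r_c": r_c, "r_l": r_l}
    truth = {"alpha_a": spec.alpha_a, "a_P0": spec.a_P0,
             "alpha_rc": spec.alpha_rc, "PB_max": spec.PB_max,
             "alpha_rl": spec.alpha_rl, "r_P0": spec.r_P0,
             "cap_identifiable": bool(np.any(PB > spec.PB_max)),
             "rng_seed": spec.rng_seed}
    return data, truth
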