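"""Steady-state xylem water flow on a plant network.

The root system is a tree of cylindrical segments.  Each root segment
exchanges water radially with the soil through a radial conductance

    Kr = 2 π a dl k_r(age, type)          (cm² d⁻¹)

and conducts water axially through its xylem with conductance ``K_x(age,
type)`` (cm³ d⁻¹).  Stem segments take no radial water (k_r = 0) and conduct
axially following Hagen–Poiseuille,

    K_x,stem = π a_xyl⁴ / (8 μ),

with μ the head-based dynamic viscosity of water at 20 °C.  Potentials are
water heads (cm).  Imposing mass balance at every node yields a sparse
symmetric positive-definite linear system; its solution gives nodal xylem
potentials, per-segment radial and axial flows, the actual transpiration
``T_act`` (collar outflow), the standard uptake fraction ``SUF`` (each
segment's share of total uptake under uniform soil potential, summing to 1)
and the root-system conductance

    K_rs = T_act / (ψ_sr,eff − ψ_collar),   ψ_sr,eff = SUFᵀ ψ_sr,

which by linearity is independent of the boundary potentials chosen.

Discretization: potentials live at segment end nodes; the axial law is
discretized per segment as ``Jx = Kx (ψ_dist − ψ_prox)/dl`` and the radial
exchange uses the segment midpoint potential (mean of the end nodes), which
is second-order accurate and converges to the single-root closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .architecture import PlantNetwork, network_at_time
from .tables import data_path

__all__ = [
    "HydraulicProfile", "SegmentConductances", "HydraulicSolution",
    "segment_conductances", "solve_water_flow", "compute_suf", "compute_krs",
    "krs_time_series", "MU_HEAD_CM_D",
]

# Head-based viscosity constant for Hagen-Poiseuille in cm-day head units:
# eta = 1.002e-3 Pa s (water, 20 degC), rho*g = 9810 N m^-3.
# mu = eta/(rho*g) = 1.0214e-7 m s = 1.0214e-5 cm s / 86400 s/d.
_ETA_PA_S = 1.002e-3
_RHO_G = 9810.0
MU_HEAD_CM_D = _ETA_PA_S / _RHO_G * 100.0 / 86400.0  # ~1.182e-10 cm d

#: Stem equivalent xylem radius as a fraction of the stem radius.  Keeps the
#: stem far from limiting; K_rs sensitivity to this default is < 1 %.
A_XYL_FRACTION = 0.1

#: Default uniform soil water potential (cm head) for SUF / K_rs runs; the
#: value is irrelevant to K_rs by linearity.
DEFAULT_PSI_SOIL = -300.0
DEFAULT_PSI_COLLAR = -15000.0


class HydraulicProfile:
    """Age- and type-dependent root hydraulic properties.

    Per root type, ``k_r`` (d⁻¹) and ``K_x`` (cm³ d⁻¹) are piecewise-linear
    in segment age between knots and constant beyond the last knot.  The
    same properties are used for every soil-P treatment; only architecture
    (radii, lengths) differs between treatments.
    """

    def __init__(self, knots: dict, a_xyl_fraction: float = A_XYL_FRACTION):
        """``knots``: type -> (ages, kr values, kx values) arrays."""
        self.knots = {}
        self.a_xyl_fraction = float(a_xyl_fraction)
        for rtype, (ages, kr, kx) in knots.items():
            ages = np.asarray(ages, dtype=float)
            kr = np.asarray(kr, dtype=float)
            kx = np.asarray(kx, dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"{rtype}: profile ages must be increasing")
            if np.any(kr < 0):
                raise ValueError(f"{rtype}: k_r must be non-negative")
            if np.any(kx <= 0):
                raise ValueError(f"{rtype}: K_x must be positive")
            self.knots[rtype] = (ages, kr, kx)

    @classmethod
    def from_csv(cls, path) -> "HydraulicProfile":
        df = pd.read_csv(path, comment="#")
        knots = {}
        for rtype, grp in df.groupby("type"):
            grp = grp.sort_values("age_d")
            knots[rtype] = (grp["age_d"].to_numpy(),
                            grp["kr_per_d"].to_numpy(),
                            grp["kx_cm3_per_d"].to_numpy())
        return cls(knots)

    @classmethod
    def default(cls) -> "HydraulicProfile":
        """The packaged synthetic stand-in profile (see the CSV header)."""
        return cls.from_csv(data_path("hydraulic_profiles_synthetic.csv"))

    @classmethod
    def constant(cls, kr: float, kx: float, types=None) -> "HydraulicProfile":
        """Age-constant profile (handy for closed-form comparisons)."""
        types = types or ("primary", "seminal", "crown", "l-lateral", "s-lateral")
        return cls({t: ([0.0, 1.0], [kr, kr], [kx, kx]) for t in types})

    def scaled(self, factor: float) -> "HydraulicProfile":
        return HydraulicProfile(
            {t: (a.copy(), kr * factor, kx * factor)
             for t, (a, kr, kx) in self.knots.items()},
            self.a_xyl_fraction)

    def kr(self, rtype: str, ages) -> np.ndarray:
        ages_k, kr_k, _ = self._get(rtype)
        return np.interp(np.asarray(ages, dtype=float), ages_k, kr_k)

    def kx(self, rtype: str, ages) -> np.ndarray:
        ages_k, _, kx_k = self._get(rtype)
        return np.interp(np.asarray(ages, dtype=float), ages_k, kx_k)

    def stem_kx(self, stem_radius: float) -> float:
        """Hagen-Poiseuille axial conductance of a stem segment (cm³ d⁻¹)."""
        a_xyl = self.a_xyl_fraction * stem_radius
        return float(np.pi * a_xyl ** 4 / (8.0 * MU_HEAD_CM_D))

    def _get(self, rtype: str):
        if rtype not in self.knots:
            raise KeyError(f"no hydraulic profile for root type {rtype!r}")
        return self.knots[rtype]


@dataclass
class SegmentConductances:
    """Per-segment radial conductance Kr (cm² d⁻¹) and axial Kx (cm³ d⁻¹)."""

    Kr: np.ndarray
    Kx: np.ndarray
    time: float


def segment_conductances(net: PlantNetwork, profile: HydraulicProfile,
                         t: float) -> SegmentConductances:
    """Evaluate Kr = 2π a dl k_r(age) and Kx = K_x(age) for every segment.

    Stem segments get Kr = 0 and the Hagen-Poiseuille axial conductance.
    Segment age at query time ``t`` is ``t - creation_time`` and must be
    non-negative for every included segment.
    """
    arr = net.arrays()
    n = len(net.segments)
    ages = t - arr["creation_time"]
    if np.any(ages < -1e-9):
        raise ValueError("segments younger than the query time present; "
                         "restrict the network with network_at_time first")
    ages = np.maximum(ages, 0.0)
    Kr = np.zeros(n)
    Kx = np.zeros(n)
    for rtype in np.unique(arr["type"]):
        mask = arr["type"] == rtype
        if rtype == "stem":
            Kx[mask] = [profile.stem_kx(r) for r in arr["radius"][mask]]
        else:
            Kr[mask] = (2.0 * np.pi * arr["radius"][mask] * arr["dl"][mask]
                        * profile.kr(rtype, ages[mask]))
            Kx[mask] = profile.kx(rtype, ages[mask])
    return SegmentConductances(Kr=Kr, Kx=Kx, time=float(t))


@dataclass
class HydraulicSolution:
    """Solved water-flow state of one network at one time."""

    Jr: np.ndarray  # per-segment radial inflow (cm³/d)
    Jx: np.ndarray  # per-segment axial flow toward the collar (cm³/d)
    psi_nodes: np.ndarray  # xylem potential per global node id (NaN if unused)
    psi_collar: float
    T_act: float  # cm³/d
    psi_sr: np.ndarray  # per-segment soil potential used
    suf: Optional[np.ndarray] = None
    krs: Optional[float] = None
    psi_sr_eff: Optional[float] = None


def _soil_vector(soil: Union[float, np.ndarray], n: int) -> np.ndarray:
    psi = np.asarray(soil, dtype=float)
    if psi.ndim == 0:
        return np.full(n, float(psi))
    if psi.shape[0] != n:
        raise ValueError(f"soil potential vector length {psi.shape[0]} "
                         f"does not match segment count {n}")
    if not np.all(np.isfinite(psi)):
        raise ValueError("soil potentials must be finite")
    return psi


def solve_water_flow(net: PlantNetwork, cond: SegmentConductances,
                     soil: Union[float, np.ndarray],
                     psi_collar: float) -> HydraulicSolution:
    """Solve nodal mass balance on the network tree.

    At every junction the axial flows from the children plus the local
    radial inflow balance the axial flow toward the parent; radial exchange
    uses the segment midpoint potential.  Collar potential is a Dirichlet
    boundary.  Raises if no segment has a positive radial conductance (the
    uptake problem is then degenerate).
    """
    n = len(net.segments)
    if n == 0:
        raise ValueError("empty network")
    if not np.any(cond.Kr > 0):
        raise ValueError("all radial conductances are zero: "
                         "no water can enter the network")
    arr = net.arrays()
    psi_sr = _soil_vector(soil, n)

    prox, dist = arr["prox"], arr["dist"]
    c_ax = cond.Kx / arr["dl"]
    kq = cond.Kr / 4.0

    rows = np.concatenate([prox, dist, prox, dist, prox, dist, prox, dist])
    cols = np.concatenate([prox, dist, dist, prox, prox, dist, dist, prox])
    vals = np.concatenate([c_ax, c_ax, -c_ax, -c_ax, kq, kq, kq, kq])

    n_nodes = len(net.nodes)
    A = coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    b = np.zeros(n_nodes)
    half = cond.Kr * psi_sr / 2.0
    np.add.at(b, prox, half)
    np.add.at(b, dist, half)

    # restrict to nodes actually referenced by segments; Dirichlet at collar
    used = np.unique(np.concatenate([prox, dist]))
    collar = net.collar_node
    unknown = used[used != collar]
    idx = -np.ones(n_nodes, dtype=int)
    idx[unknown] = np.arange(len(unknown))

    A_uu = A[unknown][:, unknown]
    b_u = b[unknown] - A[unknown][:, [collar]].toarray().ravel() * psi_collar
    psi_u = spsolve(A_uu.tocsc(), b_u)

    psi = np.full(n_nodes, np.nan)
    psi[collar] = psi_collar
    psi[unknown] = psi_u

    mid = 0.5 * (psi[prox] + psi[dist])
    Jr = cond.Kr * (psi_sr - mid)
    Jx = c_ax * (psi[dist] - psi[prox])

    T_act = float(np.sum(Jr))
    return HydraulicSolution(Jr=Jr, Jx=Jx, psi_nodes=psi,
                             psi_collar=float(psi_collar), T_act=T_act,
                             psi_sr=psi_sr)


def compute_suf(net: PlantNetwork, cond: SegmentConductances) -> HydraulicSolution:
    """Standard uptake fraction: per-segment share of uptake under uniform soil.

    Solves with a uniform soil potential; ``SUF_i = Jr_i / T_act`` sums to 1
    and is non-negative.  For any soil vector, ``ψ_sr,eff = SUFᵀ ψ_sr``.
    """
    sol = solve_water_flow(net, cond, DEFAULT_PSI_SOIL, DEFAULT_PSI_COLLAR)
    if sol.T_act == 0:
        raise ValueError("zero total uptake: SUF undefined")
    sol.suf = sol.Jr / sol.T_act
    return sol


def compute_krs(net: PlantNetwork, cond: SegmentConductances,
                soil: Union[float, np.ndarray] = DEFAULT_PSI_SOIL,
                psi_collar: float = DEFAULT_PSI_COLLAR) -> HydraulicSolution:
    """Root-system conductance K_rs = T_act / (ψ_sr,eff − ψ_collar) (cm² d⁻¹).

    Invariant to the choice of ψ_collar and to adding a constant to all
    potentials (the system is linear).  The effective soil potential is the
    SUF-weighted mean of the per-segment soil potentials.
    """
    sol = solve_water_flow(net, cond, soil, psi_collar)
    psi_sr = sol.psi_sr
    if np.all(psi_sr == psi_sr[0]):
        suf_sol = sol
        if sol.T_act == 0:
            raise ValueError("no potential difference: K_rs undefined")
        suf = sol.Jr / sol.T_act
        psi_eff = float(psi_sr[0])
    else:
        suf_sol = compute_suf(net, cond)
        suf = suf_sol.suf
        psi_eff = float(suf @ psi_sr)
    denom = psi_eff - psi_collar
    if denom == 0:
        raise ValueError("effective soil potential equals collar potential; "
                         "K_rs undefined")
    sol.suf = suf
    sol.psi_sr_eff = psi_eff
    sol.krs = sol.T_act / denom
    return sol


def krs_time_series(net: PlantNetwork, profile: HydraulicProfile, times,
                    soil: float = DEFAULT_PSI_SOIL,
                    psi_collar: float = DEFAULT_PSI_COLLAR) -> list:
    """(t, K_rs) pairs: restrict the network to each time, re-age, solve."""
    out = []
    for t in times:
        sub = network_at_time(net, float(t))
        cond = segment_conductances(sub, profile, float(t))
        sol = compute_krs(sub, cond, soil, psi_collar)
        out.append((float(t), sol.krs))
    return out
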