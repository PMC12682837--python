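"""Stochastic simulation of a growing maize plant (root system + stem).

A plant is generated from a :class:`~rhizoconduct.tables.ParameterTable` as a
rooted tree of cylindrical segments.  Axial roots (primary, seminal, crown)
emerge on a schedule — the primary at sowing, seminals from ``first_B`` every
``delay_B`` days, crown-root whorls of ``n_C`` roots from ``first_SB`` every
``delay_RC`` days — and every organ elongates along the negative-exponential
growth law with its own realized initial rate ``r`` and maximal length
``l_max``.  Laterals branch beyond the basal zone ``l_b`` at inter-branch
spacing ``l_n``; the apical zone ``l_delay`` stays unbranched, so a lateral
sitting at arc length ``s`` emerges when the parent axis has grown to
``s + l_delay``.  Headings follow the insertion angle at emergence and then a
gravitropism-biased random walk.

Organ extension is resolved analytically: node creation times are computed
with the exact inverse of the growth law, so each organ's length at any
query time matches the growth curve to within one segment, with no
time-stepping error.  All stochasticity flows through one
``numpy.random.Generator``, making networks bit-reproducible per seed.

Coordinates are right-handed with z negative downward (cm); the seed sits at
``seedPos`` (default [0, 0, -3]) and the collar at the soil surface.  The
below-ground stem (mesocotyl) connects seed to collar as segments of type
``"stem"``; crown whorls attach to it at ``dz_S`` vertical spacing.  Leaves
are tracked as shoot metadata (length/area), not as hydraulic segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .growth import age_at_length, length_at_age


def _age_at_length_fast(l: float, r: float, l_max: float) -> float:
    # scalar fast path of growth.age_at_length (inputs pre-validated here)
    return -(l_max / r) * math.log1p(-l / l_max)
from .tables import ParameterTable

__all__ = [
    "RootTypeParams", "ShootParams", "PlantParams", "Segment", "OrganInfo",
    "PlantNetwork", "sample_parameters", "schedule_axial_roots",
    "simulate_plant", "network_at_time", "summarize",
    "AXIAL_TYPES", "LATERAL_TYPES", "DEFAULT_DX", "AXIAL_L_MAX",
]

AXIAL_TYPES = ("primary", "seminal", "crown")
LATERAL_TYPES = ("l-lateral", "s-lateral")

#: Maximal segment length (cm); the parameter catalogue names dx but prints
#: no value — 0.25 cm resolves radial-conductance integration without
#: excessive segment counts.
DEFAULT_DX = 0.25

#: Fixed maximal axial-root length (cm), taken from the literature.
AXIAL_L_MAX = 139.0

#: Documented default insertion angles (rad from vertical) for axial roots;
#: the printed tables carry insertion angles for laterals only.
AXIAL_INSERTION_ANGLE = {"primary": 0.0, "seminal": 1.0, "crown": 1.2}

#: Tropism defaults: number of candidate headings per step (most downward
#: kept) and angular deflection s.d. (rad per cm of growth).
TROPISM_N = {"primary": 1.5, "seminal": 1.5, "crown": 1.5,
             "l-lateral": 1.0, "s-lateral": 1.0}
TROPISM_SIGMA = 0.2

#: Negative truncated-normal draws are floored at this fraction of the mean.
TRUNCATION_FLOOR = 1e-4


@dataclass
class RootTypeParams:
    """Per-root-type parameter distributions ((mean, s.d.) pairs)."""

    a: tuple  # radius (cm)
    r: tuple  # initial elongation rate (cm/d)
    l_max: tuple  # maximal length (cm)
    theta: tuple  # insertion angle (rad)
    l_b: Optional[tuple] = None  # basal zone (cm); None -> unbranched type
    l_delay: Optional[tuple] = None  # apical unbranched zone (cm)
    l_n: Optional[tuple] = None  # inter-branch distance (cm)
    successors: dict = field(default_factory=dict)  # lateral type -> probability
    tropism_N: float = 1.0
    dx: float = DEFAULT_DX

    @property
    def branching(self) -> bool:
        return bool(self.successors) and self.l_n is not None


@dataclass
class ShootParams:
    stem_a: tuple
    stem_l_n: tuple
    stem_r: tuple
    leaf_r: tuple
    leaf_l_max: tuple
    leaf_theta: tuple
    delay_lat: float
    width_blade: float
    area_max: float
    rot_beta: float
    dz_S: float  # vertical spacing between crown whorls along the shoot (cm)


@dataclass
class PlantParams:
    """Distributional plant parameters plus the emergence schedule scalars."""

    treatment: str
    types: dict  # root type -> RootTypeParams
    shoot: ShootParams
    seed_pos: np.ndarray
    simulation_time: float
    first_B: float
    delay_B: float
    max_B: float
    first_SB: float
    delay_SB: float
    delay_RC: float
    n_C: float
    rng_seed: Optional[int] = None


def _pair(table: ParameterTable, organ: str, param: str,
          default: Optional[tuple] = None) -> Optional[tuple]:
    try:
        return table.get(organ, param)
    except KeyError:
        return default


def build_plant_params(table: ParameterTable) -> PlantParams:
    """Assemble :class:`PlantParams` from a loaded parameter table."""
    rs = table.root_system
    types = {}
    for rt in AXIAL_TYPES + LATERAL_TYPES:
        axial = rt in AXIAL_TYPES
        if axial:
            successors = {"l-lateral": rs["p_l_lateral"],
                          "s-lateral": rs["p_s_lateral"]}
            l_max = (AXIAL_L_MAX, 0.0)
            theta = (AXIAL_INSERTION_ANGLE[rt], 0.0)
        elif rt == "l-lateral":
            successors = {"s-lateral": 1.0}
            l_max = table.get(rt, "l_max")
            theta = table.get(rt, "theta")
        else:
            successors = {}
            l_max = table.get(rt, "l_max")
            theta = table.get(rt, "theta")
        types[rt] = RootTypeParams(
            a=table.get(rt, "a"),
            r=table.get(rt, "r"),
            l_max=l_max,
            theta=theta,
            l_b=_pair(table, rt, "l_b"),
            l_delay=_pair(table, rt, "l_delay"),
            l_n=_pair(table, rt, "l_n"),
            successors=successors,
            tropism_N=TROPISM_N[rt],
        )

    shoot = ShootParams(
        stem_a=table.get("stem", "a"),
        stem_l_n=table.get("stem", "l_n"),
        stem_r=table.get("stem", "r"),
        leaf_r=table.get("leaf", "r"),
        leaf_l_max=table.get("leaf", "l_max"),
        leaf_theta=table.get("leaf", "theta"),
        delay_lat=table.get("leaf", "delay_lat")[0],
        width_blade=table.get("leaf", "Width_Blade")[0],
        area_max=table.get("leaf", "Area_max")[0],
        rot_beta=table.get("leaf", "RotBeta")[0],
        dz_S=table.get("stem", "l_n")[0],
    )

    return PlantParams(
        treatment=table.treatment,
        types=types,
        shoot=shoot,
        seed_pos=np.array([rs["seedPos_x"], rs["seedPos_y"], rs["seedPos_z"]]),
        simulation_time=rs["simulationTime"],
        first_B=rs["first_B"], delay_B=rs["delay_B"], max_B=rs["max_B"],
        first_SB=rs["first_SB"], delay_SB=rs["delay_SB"],
        delay_RC=rs["delay_RC"], n_C=rs["n_C"],
    )


def sample_parameters(table: ParameterTable, rng_seed: int) -> PlantParams:
    """Bind a parameter table to an RNG seed for on-demand per-organ draws.

    Each numeric parameter is realized per organ as normal(mean, s.d.)
    truncated below at a small positive floor; identical seeds give
    identical draw sequences.
    """
    for organ, params in table.root_types.items():
        for name, (_, sd) in params.items():
            if sd < 0:
                raise ValueError(f"{organ}/{name}: negative s.d.")
    params = build_plant_params(table)
    params.rng_seed = int(rng_seed)
    return params


def realize(pair: tuple, rng: np.random.Generator) -> float:
    """Draw one truncated-normal realization of a (mean, s.d.) parameter."""
    mean, sd = pair
    value = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
    if mean > 0:
        return max(value, TRUNCATION_FLOOR * mean)
    return max(value, 0.0)


def _round_count(mean: float, rng: np.random.Generator) -> int:
    """Bernoulli rounding: realize a fractional count preserving its mean."""
    lo = math.floor(mean)
    frac = mean - lo
    return int(lo + (1 if rng.random() < frac else 0)) if frac > 0 else int(lo)


def schedule_axial_roots(params: PlantParams,
                         rng: Optional[np.random.Generator] = None) -> list:
    """Emergence schedule: list of (root type, emergence day, whorl index).

    The primary emerges at sowing; seminals from ``first_B`` spaced
    ``delay_B`` with realized count ``max_B``; crown whorls at
    ``first_SB + k*delay_RC``, each with a realized ``n_C`` roots spaced
    ``delay_SB``, while the whorl day is within the simulation time.
    Fractional counts are realized by Bernoulli rounding (mean-preserving),
    drawn from ``rng`` (deterministic floor/ceil-free means need s.d. 0).
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    schedule = [("primary", 0.0, -1)]
    n_seminal = _round_count(params.max_B, rng)
    for i in range(n_seminal):
        day = params.first_B + i * params.delay_B
        if day <= params.simulation_time:
            schedule.append(("seminal", day, -1))
    k = 0
    while True:
        whorl_day = params.first_SB + k * params.delay_RC
        if whorl_day > params.simulation_time:
            break
        n_c = _round_count(params.n_C, rng)
        for j in range(n_c):
            day = whorl_day + j * params.delay_SB
            if day <= params.simulation_time:
                schedule.append(("crown", day, k))
        k += 1
    return schedule


@dataclass
class Segment:
    """One cylindrical segment; proximal/distal are node indices."""

    id: int
    organ_id: int
    organ_type: str
    prox: int
    dist: int
    dl: float
    radius: float
    creation_time: float
    parent: int  # parent segment id, -1 at the collar


@dataclass
class OrganInfo:
    id: int
    type: str
    t0: float  # emergence day
    r: float  # realized initial elongation rate (cm/d)
    l_max: float  # realized maximal length (cm)
    radius: float
    parent_organ: int  # -1 for axial roots / stem
    whorl: int = -1


class PlantNetwork:
    """Rooted tree of cylindrical segments (roots + below-ground stem)."""

    def __init__(self, t_end: float, treatment: str = ""):
        self.t_end = float(t_end)
        self.treatment = treatment
        self.nodes: list = [np.zeros(3)]  # collar at origin (soil surface)
        self.collar_node = 0
        self.segments: list[Segment] = []
        self.organs: dict[int, OrganInfo] = {}
        self.shoot_state: dict = {}

    # -- construction ------------------------------------------------------
    def add_node(self, pos) -> int:
        self.nodes.append(np.asarray(pos, dtype=float))
        return len(self.nodes) - 1

    def add_segment(self, organ_id, organ_type, prox, dist, radius,
                    creation_time, parent) -> int:
        delta = self.nodes[dist] - self.nodes[prox]
        dl = math.sqrt(float(delta @ delta))
        sid = len(self.segments)
        self.segments.append(Segment(sid, organ_id, organ_type, prox, dist,
                                     dl, radius, creation_time, parent))
        return sid

    # -- views -------------------------------------------------------------
    def node_array(self) -> np.ndarray:
        return np.vstack(self.nodes)

    def arrays(self) -> dict:
        """Column arrays over segments (for vectorized consumers)."""
        segs = self.segments
        return {
            "prox": np.array([s.prox for s in segs], dtype=int),
            "dist": np.array([s.dist for s in segs], dtype=int),
            "dl": np.array([s.dl for s in segs]),
            "radius": np.array([s.radius for s in segs]),
            "creation_time": np.array([s.creation_time for s in segs]),
            "type": np.array([s.organ_type for s in segs], dtype=object),
            "organ": np.array([s.organ_id for s in segs], dtype=int),
        }

    def count_organs(self, organ_type: str) -> int:
        organ_ids = {s.organ_id for s in self.segments}
        return sum(1 for oid in organ_ids
                   if self.organs[oid].type == organ_type)

    def validate(self) -> None:
        """Check tree structure: connected, acyclic, rooted at the collar."""
        dist_to_seg = {}
        for s in self.segments:
            if s.dist in dist_to_seg:
                raise ValueError(f"node {s.dist} is distal to two segments")
            dist_to_seg[s.dist] = s
        for s in self.segments:
            if s.prox != self.collar_node and s.prox not in dist_to_seg:
                raise ValueError(f"segment {s.id} dangles at node {s.prox}")
            if s.creation_time < 0 or s.creation_time > self.t_end + 1e-9:
                raise ValueError(f"segment {s.id}: creation time out of range")
            if s.dl <= 0:
                raise ValueError(f"segment {s.id}: non-positive length")


def _cross(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _perpendicular_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _cross(d, helper)
    u /= math.sqrt(u @ u)
    return u, _cross(d, u)


def _rotate_from(d: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle ``theta`` from ``d``, azimuth ``phi``."""
    u, v = _perpendicular_basis(d)
    return math.cos(theta) * d + math.sin(theta) * (math.cos(phi) * u
                                                    + math.sin(phi) * v)


def _tropism_step(direction: np.ndarray, dl: float, N: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gravitropic biased random walk: keep the most downward of N candidates."""
    n_cand = int(N) + (1 if rng.random() < N - int(N) else 0)
    n_cand = max(n_cand, 1)
    best = None
    sigma = TROPISM_SIGMA * dl
    for _ in range(n_cand):
        cand = direction + sigma * rng.standard_normal(3)
        cand = cand / math.sqrt(cand @ cand)
        if best is None or cand[2] < best[2]:  # z negative downward
            best = cand
    return best


def _grow_root(net: PlantNetwork, params: PlantParams, organ_type: str,
               t0: float, base_node: int, base_segment: int,
               direction: np.ndarray, rng: np.random.Generator,
               parent_organ: int, whorl: int, t_end: float) -> None:
    tp: RootTypeParams = params.types[organ_type]
    r = realize(tp.r, rng)
    l_max = realize(tp.l_max, rng)
    radius = realize(tp.a, rng)
    age = t_end - t0
    if age <= 0:
        return
    length = length_at_age(age, r, l_max)
    dx = tp.dx
    if length < 1e-9:
        return

    oid = len(net.organs)
    net.organs[oid] = OrganInfo(oid, organ_type, t0, r, l_max, radius,
                                parent_organ, whorl)

    # branch plan: arc positions of lateral initiation sites
    branch_arcs: list[float] = []
    l_delay = 0.0
    if tp.branching:
        l_b = realize(tp.l_b, rng)
        l_delay = realize(tp.l_delay, rng) if tp.l_delay else 0.0
        s = l_b
        while s < length:
            branch_arcs.append(s)
            s += realize(tp.l_n, rng)

    n_seg = int(math.ceil(length / dx - 1e-12))
    arcs = np.minimum(np.arange(1, n_seg + 1) * dx, length)
    node_arcs = [0.0]
    node_ids = [base_node]
    axis_segs = [base_segment]
    prev_seg = base_segment
    eps = 1e-12 * l_max
    for s_dist in arcs:
        direction = _tropism_step(direction, s_dist - node_arcs[-1], tp.tropism_N, rng)
        pos = net.nodes[node_ids[-1]] + direction * (s_dist - node_arcs[-1])
        node = net.add_node(pos)
        ctime = t0 + _age_at_length_fast(min(s_dist, l_max - eps), r, l_max)
        prev_seg = net.add_segment(oid, organ_type, node_ids[-1], node, radius,
                                   min(ctime, t_end), prev_seg)
        node_ids.append(node)
        axis_segs.append(prev_seg)
        node_arcs.append(float(s_dist))

    # lateral emergence: a site at arc s produces a lateral once the axis
    # has extended past s + l_delay
    for s_b in branch_arcs:
        s_emerge = s_b + l_delay
        if s_emerge >= min(length, l_max):
            continue  # apical zone still covers this site at t_end
        t_b = t0 + _age_at_length_fast(s_emerge, r, l_max)
        succ = tp.successors
        names = list(succ)
        probs = np.array([succ[n] for n in names], dtype=float)
        child_type = names[int(rng.choice(len(names), p=probs / probs.sum()))]
        # attach at the polyline node nearest the branch arc
        idx = int(np.argmin(np.abs(np.asarray(node_arcs) - s_b)))
        idx = max(idx, 1)  # never attach upstream of the organ base
        attach_node = node_ids[idx]
        seg_of_node = axis_segs[idx]
        local_dir = net.nodes[node_ids[idx]] - net.nodes[node_ids[idx - 1]]
        local_dir = local_dir / np.linalg.norm(local_dir)
        theta = realize(params.types[child_type].theta, rng)
        child_dir = _rotate_from(local_dir, theta, rng.uniform(0, 2 * math.pi))
        _grow_root(net, params, child_type, t_b, attach_node, seg_of_node,
                   child_dir, rng, oid, -1, t_end)


def _build_stem(net: PlantNetwork, params: PlantParams,
                rng: np.random.Generator) -> tuple[int, list[int], list[int]]:
    """Below-ground stem from collar down to the seed; returns seed node and
    stem node ids/segment ids ordered collar → seed."""
    depth = abs(float(params.seed_pos[2]))
    stem_radius = realize(params.shoot.stem_a, rng)
    dx = DEFAULT_DX
    n_seg = max(1, int(math.ceil(depth / dx - 1e-12)))
    oid = len(net.organs)
    net.organs[oid] = OrganInfo(oid, "stem", 0.0, 1.0, depth, stem_radius, -1)
    node_ids = [net.collar_node]
    seg_ids = []
    prev_seg = -1
    for i in range(1, n_seg + 1):
        z = -min(i * dx, depth)
        node = net.add_node([params.seed_pos[0], params.seed_pos[1], z])
        prev_seg = net.add_segment(oid, "stem", node_ids[-1], node, stem_radius,
                                   0.0, prev_seg)
        node_ids.append(node)
        seg_ids.append(prev_seg)
    return node_ids[-1], node_ids, seg_ids


def _grow_shoot(params: PlantParams, rng: np.random.Generator,
                t_end: float) -> dict:
    """Above-ground shoot state: stem length (linear growth, no printed
    maximal stem length) and per-leaf lengths/areas; leaves carry no
    hydraulic segments."""
    sp = params.shoot
    stem_r = realize(sp.stem_r, rng)
    leaves = []
    i = 1
    while i * sp.delay_lat < t_end:
        t0 = i * sp.delay_lat
        lr = realize(sp.leaf_r, rng)
        lmax = realize(sp.leaf_l_max, rng)
        length = length_at_age(t_end - t0, lr, lmax)
        area = min(length * sp.width_blade, sp.area_max)
        leaves.append({"t0": t0, "r": lr, "l_max": lmax,
                       "length": length, "area": area})
        i += 1
    return {"stem_length": stem_r * t_end, "stem_rate": stem_r,
            "leaves": leaves}


def simulate_plant(params: PlantParams, t_end: float, dt: float = 0.5,
                   rng_seed: Optional[int] = None) -> PlantNetwork:
    """Simulate one stochastic plant up to ``t_end`` days after sowing.

    ``dt`` is validated for API compatibility but organ extension is
    resolved analytically (exact in time), so results do not depend on it.
    ``rng_seed`` overrides the seed bound by :func:`sample_parameters`.
    """
    if dt is not None and dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if t_end > params.simulation_time:
        raise ValueError("t_end exceeds the configured simulation time")
    seed = rng_seed if rng_seed is not None else params.rng_seed
    if seed is None:
        raise ValueError("no RNG seed: pass rng_seed or use sample_parameters")
    rng = np.random.default_rng(int(seed))

    net = PlantNetwork(t_end, params.treatment)
    seed_node, stem_nodes, stem_segs = _build_stem(net, params, rng)
    schedule = schedule_axial_roots(params, rng)
    seed_seg = stem_segs[-1]

    # stem node nearest each whorl's target height above the seed
    stem_z = np.array([net.nodes[n][2] for n in stem_nodes])
    seed_z = float(params.seed_pos[2])

    for organ_type, day, whorl in schedule:
        if day >= t_end:
            continue
        if organ_type == "crown":
            target_z = min(seed_z + (whorl + 1) * params.shoot.dz_S, 0.0)
            idx = int(np.argmin(np.abs(stem_z - target_z)))
            idx = max(idx, 1)
            base_node = stem_nodes[idx]
            base_seg = stem_segs[idx - 1]
        else:
            base_node = seed_node
            base_seg = seed_seg
        theta = realize(params.types[organ_type].theta, rng)
        direction = _rotate_from(np.array([0.0, 0.0, -1.0]), theta,
                                 rng.uniform(0, 2 * math.pi))
        _grow_root(net, params, organ_type, day, base_node, base_seg,
                   direction, rng, -1, whorl, t_end)

    net.shoot_state = _grow_shoot(params, rng, t_end)
    return net


def network_at_time(net: PlantNetwork, t: float) -> PlantNetwork:
    """Restriction of a simulated network to segments created by day ``t``."""
    if t < 0 or t > net.t_end + 1e-9:
        raise ValueError(f"t={t} outside simulated span [0, {net.t_end}]")
    sub = PlantNetwork(t, net.treatment)
    sub.nodes = net.nodes
    sub.collar_node = net.collar_node
    sub.segments = [s for s in net.segments if s.creation_time <= t]
    sub.organs = net.organs
    sub.shoot_state = net.shoot_state
    return sub


def summarize(net: PlantNetwork, t: Optional[float] = None) -> dict:
    """Total length, surface and volume (cm, cm², cm³) per organ type.

    Sums cylinder formulas exactly over segments present at time ``t``
    (defaults to the network's end time).
    """
    if t is None:
        t = net.t_end
    totals: dict[str, dict[str, float]] = {}
    for s in net.segments:
        if s.creation_time > t:
            continue
        d = totals.setdefault(s.organ_type,
                              {"length": 0.0, "surface": 0.0, "volume": 0.0})
        d["length"] += s.dl
        d["surface"] += 2.0 * math.pi * s.radius * s.dl
        d["volume"] += math.pi * s.radius ** 2 * s.dl
    root_types = [k for k in totals if k != "stem"]
    totals["roots-total"] = {
        key: sum(totals[rt][key] for rt in root_types)
        for key in ("length", "surface", "volume")
    }
    return totals
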