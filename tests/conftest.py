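import numpy as np
import pytest

from rhizoconduct.architecture import OrganInfo, PlantNetwork


def build_single_root(length: float, dx: float, radius: float,
                      rtype: str = "primary",
                      creation_time: float = 0.0) -> PlantNetwork:
    """Straight unbranched root hanging from the collar (no stem)."""
    n = int(round(length / dx))
    net = PlantNetwork(t_end=max(creation_time, 1.0) * 10)
    net.organs[0] = OrganInfo(0, rtype, 0.0, 1.0, length, radius, -1)
    prev, prev_seg = 0, -1
    for i in range(1, n + 1):
        node = net.add_node([0.0, 0.0, -i * dx])
        prev_seg = net.add_segment(0, rtype, prev, node, radius,
                                   creation_time, prev_seg)
        prev = node
    return net


def build_random_tree(rng: np.random.Generator, n_segments: int) -> PlantNetwork:
    """Random tree topology of root segments for solver oracle tests."""
    net = PlantNetwork(t_end=100.0)
    net.organs[0] = OrganInfo(0, "primary", 0.0, 1.0, 100.0, 0.05, -1)
    attachable = [(0, -1)]  # (node, segment id)
    for _ in range(n_segments):
        prox, parent_seg = attachable[rng.integers(len(attachable))]
        pos = net.nodes[prox] + rng.normal(0, 1, 3) * 0.3
        node = net.add_node(pos)
        radius = float(rng.uniform(0.01, 0.1))
        ctime = float(rng.uniform(0, 20))
        sid = net.add_segment(0, "primary", prox, node, radius, ctime, parent_seg)
        attachable.append((node, sid))
    return net


@pytest.fixture(scope="session")
def p3_table():
    from rhizoconduct.tables import load_parameter_table
    return load_parameter_table("P3")


@pytest.fixture(scope="session")
def p3_params(p3_table):
    from rhizoconduct.architecture import build_plant_params
    return build_plant_params(p3_table)


@pytest.fixture(scope="session")
def p3_plant(p3_params):
    from rhizoconduct.architecture import simulate_plant
    return simulate_plant(p3_params, 28.0, rng_seed=42)
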