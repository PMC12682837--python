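"""Hydraulic solver: formulas, oracle equivalence, conservation, limits."""

import math

import numpy as np
import pytest

from conftest import build_random_tree, build_single_root
from rhizoconduct.architecture import OrganInfo, PlantNetwork
from rhizoconduct.hydraulics import (HydraulicProfile, MU_HEAD_CM_D,
                                     SegmentConductances, compute_krs,
                                     compute_suf, segment_conductances,
                                     solve_water_flow)


def dense_oracle(net, cond, psi_sr, psi_collar):
    """Independent dense assembly of the nodal balance equations.

    Loop-built from the physics directly: for each segment, axial
    conductance Kx/dl couples its end nodes, and the radial exchange
    Kr (ψ_soil − midpoint) is split half to each end node.
    """
    n_nodes = len(net.nodes)
    A = np.zeros((n_nodes, n_nodes))
    b = np.zeros(n_nodes)
    for k, s in enumerate(net.segments):
        c = cond.Kx[k] / s.dl
        for i, j in ((s.prox, s.dist), (s.dist, s.prox)):
            A[i, i] += c
            A[i, j] -= c
        kr = cond.Kr[k]
        for i in (s.prox, s.dist):
            A[i, s.prox] += kr / 4.0
            A[i, s.dist] += kr / 4.0
            b[i] += kr * psi_sr / 2.0
    used = sorted({s.prox for s in net.segments}
                  | {s.dist for s in net.segments})
    unknown = [i for i in used if i != net.collar_node]
    Auu = A[np.ix_(unknown, unknown)]
    bu = b[unknown] - A[np.ix_(unknown, [net.collar_node])].ravel() * psi_collar
    psi = np.full(n_nodes, np.nan)
    psi[net.collar_node] = psi_collar
    psi[unknown] = np.linalg.solve(Auu, bu)
    return psi


def random_conductances(rng, n):
    return SegmentConductances(Kr=rng.uniform(1e-5, 1e-2, n),
                               Kx=rng.uniform(1e-3, 1.0, n), time=0.0)


class TestSegmentConductances:
    def test_radial_formula_instantiation(self):
        net = build_single_root(0.25, 0.25, radius=0.05)
        prof = HydraulicProfile.constant(1e-3, 0.1)
        cond = segment_conductances(net, prof, 5.0)
        assert cond.Kr[0] == pytest.approx(2 * np.pi * 0.05 * 0.25 * 1e-3)
        assert cond.Kx[0] == pytest.approx(0.1)

    def test_stem_has_zero_radial_conductance(self):
        net = PlantNetwork(1.0)
        net.organs[0] = OrganInfo(0, "stem", 0.0, 1.0, 3.0, 0.13, -1)
        node = net.add_node([0, 0, -0.25])
        net.add_segment(0, "stem", 0, node, 0.13, 0.0, -1)
        prof = HydraulicProfile.constant(1e-3, 0.1)
        cond = segment_conductances(net, prof, 1.0)
        assert cond.Kr[0] == 0.0
        # Hagen-Poiseuille with the documented head-based viscosity constant
        a_xyl = prof.a_xyl_fraction * 0.13
        assert cond.Kx[0] == pytest.approx(np.pi * a_xyl ** 4 / (8 * MU_HEAD_CM_D))

    def test_stem_kx_quartic_in_radius(self):
        prof = HydraulicProfile.constant(1e-3, 0.1)
        assert prof.stem_kx(0.2) / prof.stem_kx(0.1) == pytest.approx(16.0)

    def test_missing_type_named(self):
        net = build_single_root(1.0, 0.25, 0.05, rtype="crown")
        prof = HydraulicProfile.constant(1e-3, 0.1, types=("primary",))
        with pytest.raises(KeyError, match="crown"):
            segment_conductances(net, prof, 1.0)

    def test_age_interpolation_constant_beyond_last_knot(self):
        prof = HydraulicProfile({"primary": ([0.0, 10.0], [2e-4, 1e-4],
                                             [0.01, 0.1])})
        assert prof.kr("primary", 5.0) == pytest.approx(1.5e-4)
        assert prof.kr("primary", 50.0) == pytest.approx(1e-4)
        assert prof.kx("primary", 50.0) == pytest.approx(0.1)


class TestSolver:
    def test_no_gradient_no_flow(self):
        net = build_single_root(5.0, 0.25, 0.05)
        cond = segment_conductances(net, HydraulicProfile.constant(1e-4, 0.05), 1.0)
        sol = solve_water_flow(net, cond, soil=-500.0, psi_collar=-500.0)
        assert np.allclose(sol.Jr, 0.0, atol=1e-12)
        assert np.allclose(sol.Jx, 0.0, atol=1e-12)
        assert sol.T_act == pytest.approx(0.0, abs=1e-12)

    def test_sibling_symmetry(self):
        # two identical roots from the collar take up identical flows
        net = PlantNetwork(1.0)
        net.organs[0] = OrganInfo(0, "primary", 0.0, 1.0, 5.0, 0.05, -1)
        for side in (-1.0, 1.0):
            prev, prev_seg = 0, -1
            for i in range(1, 11):
                node = net.add_node([side * i * 0.05, 0, -i * 0.25])
                prev_seg = net.add_segment(0, "primary", prev, node, 0.05,
                                           0.0, prev_seg)
                prev = node
        cond = segment_conductances(net, HydraulicProfile.constant(1e-4, 0.05), 1.0)
        sol = solve_water_flow(net, cond, soil=-300.0, psi_collar=-2000.0)
        left, right = sol.Jr[:10], sol.Jr[10:]
        np.testing.assert_allclose(left, right, rtol=1e-10)

    def test_mass_conservation(self):
        rng = np.random.default_rng(2)
        net = build_random_tree(rng, 80)
        cond = random_conductances(rng, 80)
        sol = solve_water_flow(net, cond, soil=-300.0, psi_collar=-4000.0)
        # T_act equals the collar axial inflow (plus the collar's radial half)
        collar_in = 0.0
        for k, s in enumerate(net.segments):
            if s.prox == net.collar_node:
                collar_in += sol.Jx[k] + sol.Jr[k] / 2.0
        assert collar_in == pytest.approx(sol.T_act, rel=1e-10)

    @pytest.mark.parametrize("n_segments", [10, 50, 200])
    def test_dense_oracle_equivalence(self, n_segments):
        rng = np.random.default_rng(n_segments)
        net = build_random_tree(rng, n_segments)
        cond = random_conductances(rng, n_segments)
        sol = solve_water_flow(net, cond, soil=-300.0, psi_collar=-4000.0)
        psi_ref = dense_oracle(net, cond, -300.0, -4000.0)
        mask = ~np.isnan(psi_ref)
        err = np.abs(sol.psi_nodes[mask] - psi_ref[mask]) / np.abs(psi_ref[mask])
        assert err.max() <= 1e-8

    def test_all_kr_zero_rejected(self):
        net = build_single_root(1.0, 0.25, 0.05)
        cond = SegmentConductances(Kr=np.zeros(4), Kx=np.full(4, 0.1), time=0.0)
        with pytest.raises(ValueError, match="radial"):
            solve_water_flow(net, cond, -300.0, -4000.0)


class TestSUF:
    def test_single_segment_suf_is_one(self):
        net = build_single_root(0.25, 0.25, 0.05)
        cond = segment_conductances(net, HydraulicProfile.constant(1e-4, 0.05), 1.0)
        sol = compute_suf(net, cond)
        np.testing.assert_allclose(sol.suf, [1.0], atol=1e-12)

    def test_parallel_roots_split_evenly(self):
        net = PlantNetwork(1.0)
        net.organs[0] = OrganInfo(0, "primary", 0.0, 1.0, 5.0, 0.05, -1)
        for side in (-1.0, 1.0):
            prev, prev_seg = 0, -1
            for i in range(1, 9):
                node = net.add_node([side * i * 0.1, 0, -i * 0.25])
                prev_seg = net.add_segment(0, "primary", prev, node, 0.05,
                                           0.0, prev_seg)
                prev = node
        cond = segment_conductances(net, HydraulicProfile.constant(1e-4, 0.05), 1.0)
        sol = compute_suf(net, cond)
        assert sol.suf[:8].sum() == pytest.approx(0.5, abs=1e-10)
        assert sol.suf.sum() == pytest.approx(1.0, abs=1e-10)

    def test_suf_normalized_nonnegative_on_random_trees(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            net = build_random_tree(rng, 60)
            cond = random_conductances(rng, 60)
            sol = compute_suf(net, cond)
            assert sol.suf.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(sol.suf >= -1e-12)

    def test_uniform_soil_effective_potential_is_that_value(self):
        net = build_single_root(5.0, 0.25, 0.05)
        cond = segment_conductances(net, HydraulicProfile.constant(1e-4, 0.05), 1.0)
        sol = compute_krs(net, cond, soil=-123.0, psi_collar=-9000.0)
        assert sol.psi_sr_eff == pytest.approx(-123.0)


class TestKrs:
    def test_collar_potential_invariance(self):
        net = build_single_root(10.0, 0.25, 0.05)
        cond = segment_conductances(net, HydraulicProfile.constant(1e-4, 0.05), 1.0)
        k1 = compute_krs(net, cond, psi_collar=-1000.0).krs
        k2 = compute_krs(net, cond, psi_collar=-5000.0).krs
        assert k1 == pytest.approx(k2, rel=1e-10)

    def test_single_root_tanh_closed_form(self):
        a, kr, kx, length = 0.05, 1e-4, 0.05, 30.0
        net = build_single_root(length, 0.1, a)
        cond = segment_conductances(net, HydraulicProfile.constant(kr, kx), 1.0)
        sol = compute_krs(net, cond)
        kappa = math.sqrt(2 * math.pi * a * kr / kx)
        expected = math.sqrt(2 * math.pi * a * kr * kx) * math.tanh(length * kappa)
        assert sol.krs == pytest.approx(expected, rel=1e-3)

    def test_krs_monotone_in_radial_conductivity(self):
        rng = np.random.default_rng(4)
        net = build_random_tree(rng, 40)
        cond = random_conductances(rng, 40)
        base = compute_krs(net, cond).krs
        for k in (0, 17, 39):
            bumped = SegmentConductances(Kr=cond.Kr.copy(), Kx=cond.Kx.copy(),
                                         time=0.0)
            bumped.Kr[k] *= 2.0
            assert compute_krs(net, bumped).krs >= base - 1e-15

    def test_scale_equivariance(self):
        net = build_single_root(10.0, 0.25, 0.05)
        prof = HydraulicProfile.constant(1e-4, 0.05)
        k1 = compute_krs(net, segment_conductances(net, prof, 1.0)).krs
        k4 = compute_krs(net, segment_conductances(net, prof.scaled(4.0), 1.0)).krs
        assert k4 == pytest.approx(4.0 * k1, rel=1e-10)

    def test_all_radial_limit(self):
        # as K_x -> infinity, K_rs approaches the sum of radial conductances
        net = build_single_root(5.0, 0.25, 0.05)
        cond = segment_conductances(net, HydraulicProfile.constant(1e-4, 1e9), 1.0)
        sol = compute_krs(net, cond)
        assert sol.krs == pytest.approx(cond.Kr.sum(), rel=1e-5)

    def test_krs_vanishes_without_radial_uptake(self):
        net = build_single_root(5.0, 0.25, 0.05)
        cond = segment_conductances(net, HydraulicProfile.constant(1e-12, 0.05), 1.0)
        assert compute_krs(net, cond).krs == pytest.approx(0.0, abs=1e-10)


class TestTimeSeries:
    def test_single_time_matches_direct(self, p3_plant):
        from rhizoconduct.hydraulics import krs_time_series
        from rhizoconduct.architecture import network_at_time
        prof = HydraulicProfile.default()
        series = krs_time_series(p3_plant, prof, [28.0])
        sub = network_at_time(p3_plant, 28.0)
        direct = compute_krs(sub, segment_conductances(sub, prof, 28.0)).krs
        assert series[0][1] == pytest.approx(direct, rel=1e-12)

    def test_monotone_for_growing_network_age_constant_props(self, p3_plant):
        from rhizoconduct.hydraulics import krs_time_series
        prof = HydraulicProfile.constant(1e-4, 0.05)
        series = krs_time_series(p3_plant, prof, [7.0, 14.0, 21.0, 28.0])
        values = [k for _, k in series]
        assert values == sorted(values)

    def test_krs_insensitive_to_stem_xylem_radius_default(self, p3_plant):
        # the stem is never the limiting resistance: halving or doubling the
        # equivalent xylem radius fraction moves whole-plant K_rs by < 1 %
        from rhizoconduct.hydraulics import krs_time_series
        base = HydraulicProfile.default()
        k0 = krs_time_series(p3_plant, base, [28.0])[0][1]
        for fraction in (0.05, 0.2):
            alt = HydraulicProfile(base.knots, a_xyl_fraction=fraction)
            k = krs_time_series(p3_plant, alt, [28.0])[0][1]
            assert abs(k - k0) / k0 < 0.01

    def test_das_protocol_evaluation(self, p3_plant):
        # the experiment evaluates K_rs at 7, 14, 21 and 28 DAS
        from rhizoconduct.hydraulics import krs_time_series
        series = krs_time_series(p3_plant, HydraulicProfile.default(),
                                 [7.0, 14.0, 21.0, 28.0])
        assert [t for t, _ in series] == [7.0, 14.0, 21.0, 28.0]
        assert all(k > 0 for _, k in series)
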