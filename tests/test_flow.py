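import numpy as np
import pytest

from perfterra.flow import (
    BoundaryConditions,
    FluidConstants,
    MMHG_TO_DYN_CM2,
    ML_MIN_TO_CM3_S,
    build_system,
    compute_distribution,
    inlet_contribution_map,
    solve_steady_flow,
)
from perfterra.network import CenterlinePoint, Segment, VascularNetwork


def _net(points, segments, inlets):
    n = VascularNetwork(
        points={i: CenterlinePoint(i, np.array(p, float), r)
                for i, (p, r) in points.items()},
        segments={i: Segment(i, list(pids), label)
                  for i, (pids, label) in segments.items()},
        inlets=set(inlets),
    )
    n.validate()
    return n


def _dense_oracle(system):
    """Independent solve: stack the per-edge resistance law and per-node
    mass balance into one dense least-squares system over (pressures,
    edge flows) — no Laplacian elimination.  Works in mmHg relative to the
    maximum inlet pressure and mL/min, so the system is well scaled."""
    keys = system.node_keys
    idx = {k: i for i, k in enumerate(keys)}
    n, m = len(keys), len(system.edges)
    p_ref = max(system.bcs.inlet_pressure_mmhg.values())
    rows = []
    rhs = []
    for j, e in enumerate(system.edges):
        # resistance in mmHg per (mL/min)
        res = (1.0 / e.conductance) * ML_MIN_TO_CM3_S / MMHG_TO_DYN_CM2
        r = np.zeros(n + m)
        r[idx[e.u]] = 1.0
        r[idx[e.v]] = -1.0
        r[n + j] = -res
        rows.append(r)
        rhs.append(0.0)
    pinned = set(system.bcs.inlet_pressure_mmhg)
    for k in keys:
        r = np.zeros(n + m)
        if k in pinned:
            r[idx[k]] = 1.0
            rows.append(r)
            rhs.append(system.bcs.inlet_pressure_mmhg[k] - p_ref)
        else:
            for j, e in enumerate(system.edges):
                if e.v == k:
                    r[n + j] += 1.0
                if e.u == k:
                    r[n + j] -= 1.0
            rows.append(r)
            rhs.append(system.extraction.get(k, 0.0) / ML_MIN_TO_CM3_S)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return {keys[i]: sol[i] + p_ref for i in range(n)}, list(sol[n:])


def _single_segment(radius_mm=1.0, length_mm=10.0):
    return _net({0: ((0, 0, 0), radius_mm), 1: ((0, 0, length_mm), radius_mm)},
                {0: ([0, 1], "seg")}, inlets={0})


class TestPoiseuille:
    @pytest.mark.parametrize("r_mm,len_mm,q_ml_min", [
        (1.0, 10.0, 60.0),  # r=0.1 cm, L=1 cm, Q=1 cm^3/s
        (0.5, 25.0, 10.0),
        (2.0, 40.0, 300.0),
        (0.3, 5.0, 1.0),
    ])
    def test_single_segment_matches_closed_form(self, r_mm, len_mm, q_ml_min):
        net = _single_segment(r_mm, len_mm)
        bcs = BoundaryConditions({0: 93.33}, {1: q_ml_min})
        sol = solve_steady_flow(build_system(net, bcs))
        mu, r_cm, l_cm = 0.04, r_mm / 10, len_mm / 10
        q_cgs = q_ml_min / 60.0
        dp = 8 * mu * l_cm * q_cgs / (np.pi * r_cm**4) / MMHG_TO_DYN_CM2
        assert sol.node_pressure_mmhg[0] == pytest.approx(93.33, rel=1e-12)
        assert sol.node_pressure_mmhg[1] == pytest.approx(93.33 - dp, rel=1e-10)
        assert sol.segment_flow_ml_min[0] == pytest.approx(q_ml_min, rel=1e-10)

    def test_reference_pressure_drop_value(self):
        # rbar = 0.1 cm, L = 1 cm, Q = 1 cm^3/s: dp = 0.32/(pi*1e-4) dyn/cm^2
        net = _single_segment(1.0, 10.0)
        sol = solve_steady_flow(build_system(net, BoundaryConditions({0: 93.33},
                                                                     {1: 60.0})))
        dp = sol.node_pressure_mmhg[0] - sol.node_pressure_mmhg[1]
        assert dp * MMHG_TO_DYN_CM2 == pytest.approx(1018.59, rel=1e-4)
        assert dp == pytest.approx(0.764, rel=1e-3)

    def test_doubling_radius_multiplies_conductance_by_16(self):
        s1 = build_system(_single_segment(1.0), BoundaryConditions({0: 93.33}))
        s2 = build_system(_single_segment(2.0), BoundaryConditions({0: 93.33}))
        assert s2.edges[0].conductance == pytest.approx(
            16 * s1.edges[0].conductance, rel=1e-12)

    def test_midpoint_split_with_zero_sink_is_identity(self):
        net = _single_segment()
        plain = solve_steady_flow(build_system(
            net, BoundaryConditions({0: 93.33}, {1: 5.0})))
        split = solve_steady_flow(build_system(
            net, BoundaryConditions({0: 93.33}, {1: 5.0},
                                    midpoint_sink_ml_min={0: 0.0})))
        assert split.node_pressure_mmhg[1] == pytest.approx(
            plain.node_pressure_mmhg[1], rel=1e-12)
        assert split.segment_flow_ml_min[0] == pytest.approx(5.0, rel=1e-10)


class TestNetworks:
    def test_symmetric_y(self):
        net = _net(
            {0: ((0, 0, -10), 1.5), 1: ((0, 0, 0), 1.5),
             2: ((4, 0, 8), 0.8), 3: ((-4, 0, 8), 0.8)},
            {0: ([0, 1], "trunk"), 1: ([1, 2], "r"), 2: ([1, 3], "l")},
            inlets={0})
        q = 3.0
        sol = solve_steady_flow(build_system(
            net, BoundaryConditions({0: 93.33}, {2: q, 3: q})))
        assert sol.segment_flow_ml_min[0] == pytest.approx(2 * q, rel=1e-10)
        assert sol.node_pressure_mmhg[2] == pytest.approx(
            sol.node_pressure_mmhg[3], rel=1e-12)

    def _loop_net(self, loop_r=1.0):
        """Two inlets feeding a diamond loop with two outlets.

        ``loop_r`` sets the interior radius of the communicating segments;
        a tiny value drives their conductance toward zero (the mean radius
        is arclength-weighted and the interior dominates)."""
        return _net(
            {0: ((0, 0, -10), 1.5), 1: ((0, 0, 0), 1.2),
             2: ((10, 0, -10), 1.4), 3: ((10, 0, 0), 1.1),
             4: ((5, 0, 6), 1.0),
             5: ((0, 0, 10), 0.6), 6: ((10, 0, 10), 0.7),
             7: ((1, 0, 1), loop_r), 8: ((4, 0, 5), loop_r),
             9: ((9, 0, 1), loop_r), 10: ((6, 0, 5), loop_r)},
            {0: ([0, 1], "inL"), 1: ([2, 3], "inR"),
             2: ([1, 7, 8, 4], "loopL"), 3: ([3, 9, 10, 4], "loopR"),
             4: ([1, 5], "outL"), 5: ([3, 6], "outR")},
            inlets={0, 2})

    def test_loop_against_dense_oracle(self):
        net = self._loop_net()
        bcs = BoundaryConditions({0: 93.33, 2: 93.33}, {5: 4.0, 6: 1.0},
                                 midpoint_sink_ml_min={2: 0.7})
        system = build_system(net, bcs)
        sol = solve_steady_flow(system)
        p_ref, q_ref = _dense_oracle(system)
        for k in system.node_keys:
            assert sol.node_pressure_mmhg[k] == pytest.approx(p_ref[k], rel=1e-9)
        for q, qr in zip(sol.edge_flow_ml_min, q_ref):
            assert q == pytest.approx(qr, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_looped_graphs_against_oracle(self, seed):
        """Random <= 12-node looped resistor networks vs the dense solve."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 12))
        pts = {i: (tuple(rng.uniform(-20, 20, 3)), float(rng.uniform(0.5, 2.0)))
               for i in range(n)}
        # spanning tree + extra loop edges
        edges = [(i, int(rng.integers(0, i))) for i in range(1, n)]
        for _ in range(3):
            a, b = rng.integers(0, n, 2)
            if a != b and (a, b) not in edges and (b, a) not in edges:
                edges.append((int(a), int(b)))
        segs = {k: ([a, b], f"e{k}") for k, (a, b) in enumerate(edges)}
        net = _net(pts, segs, inlets={0})
        deg = net.node_degrees()
        sinks = {i: float(rng.uniform(0, 2)) for i in range(1, n) if deg[i] == 1}
        system = build_system(net, BoundaryConditions({0: 93.33}, sinks))
        sol = solve_steady_flow(system)
        p_ref, q_ref = _dense_oracle(system)
        for k in system.node_keys:
            assert sol.node_pressure_mmhg[k] == pytest.approx(p_ref[k], rel=1e-9)
        for q, qr in zip(sol.edge_flow_ml_min, q_ref):
            assert q == pytest.approx(qr, rel=1e-9, abs=1e-9)

    def test_pressure_maximum_principle(self, cow_results):
        sol = cow_results.solution
        assert max(sol.node_pressure_mmhg.values()) <= 93.33 + 1e-9

    def test_global_conservation(self, cow_results):
        sol = cow_results.solution
        bcs = cow_results.boundary_conditions
        total_out = (sum(bcs.outlet_flow_ml_min.values())
                     + sum(bcs.midpoint_sink_ml_min.values()))
        assert abs(sol.total_inflow_ml_min - total_out) <= 1e-10 * total_out
        assert sol.conservation_residual <= 1e-10

    def test_loop_to_tree_limit(self):
        """Shrinking the communicating edges reproduces the tree solution."""
        net = self._loop_net()
        bcs = BoundaryConditions({0: 93.33, 2: 93.33}, {5: 4.0, 6: 1.0})
        sol_loop = solve_steady_flow(build_system(net, bcs))
        sol_thin = solve_steady_flow(build_system(self._loop_net(loop_r=1e-3), bcs))
        # with no usable collateral, each outlet is fed by its own inlet
        assert sol_thin.inlet_inflow_ml_min[0] == pytest.approx(4.0, rel=1e-3)
        assert sol_thin.inlet_inflow_ml_min[2] == pytest.approx(1.0, rel=1e-3)
        # and the looped version shares load across the collateral
        assert sol_loop.inlet_inflow_ml_min[0] < 4.0

    def test_component_without_inlet_raises_with_labels(self):
        from perfterra.network import UnsolvableComponentError

        net = _net(
            {0: ((0, 0, 0), 1.0), 1: ((0, 0, 10), 1.0),
             2: ((20, 0, 0), 1.0), 3: ((20, 0, 10), 1.0)},
            {0: ([0, 1], "supplied"), 1: ([2, 3], "stranded")},
            inlets={0})
        with pytest.raises(UnsolvableComponentError, match="stranded"):
            build_system(net, BoundaryConditions({0: 93.33}))


class TestDistribution:
    def test_symmetric_phantom_equal_sides(self, cow_results):
        d = cow_results.distribution
        for a, b in [("LMCA", "RMCA"), ("LACA", "RACA"), ("LPCA", "RPCA")]:
            assert d.artery_ratio_pct[a] == pytest.approx(
                d.artery_ratio_pct[b], rel=1e-12)

    def test_inlet_ratios_sum_to_100(self, cow_results):
        assert sum(cow_results.distribution.inlet_ratio_pct.values()) == \
            pytest.approx(100.0, abs=1e-9)

    def test_artery_ratios_sum_to_100(self, cow_results):
        assert sum(cow_results.distribution.artery_ratio_pct.values()) == \
            pytest.approx(100.0, abs=1e-9)

    def test_hand_computed_ratios(self):
        """Tree with hand-assigned outlet demands: ratios follow arithmetic."""
        net = _net(
            {0: ((0, 0, -10), 1.5), 1: ((0, 0, 0), 1.5),
             2: ((4, 0, 8), 0.8), 3: ((-4, 0, 8), 0.8)},
            {0: ([0, 1], "BA"), 1: ([1, 2], "RPCA-P2"), 2: ([1, 3], "LPCA-P2")},
            inlets={0})
        sol = solve_steady_flow(build_system(
            net, BoundaryConditions({0: 93.33}, {2: 3.0, 3: 1.0})))
        d = compute_distribution(sol)
        assert d.artery_ratio_pct["RPCA"] == pytest.approx(75.0, rel=1e-12)
        assert d.artery_ratio_pct["LPCA"] == pytest.approx(25.0, rel=1e-12)
        assert set(d.missing_arteries) == {"LMCA", "RMCA", "LACA", "RACA"}

    def test_missing_artery_flagged(self, cow):
        from perfterra import PerfusionModel
        from perfterra.synthetic import PhantomSpec, make_phantom

        net, mesh = make_phantom(PhantomSpec(variant="fetal_rpca"))
        res = PerfusionModel(net, mesh).fit()
        # P1 is gone but P2 is still measured: nothing missing
        assert res.distribution.missing_arteries == []
        # ... and the RPCA is fed through the PCoA collateral
        assert res.distribution.artery_ratio_pct["RPCA"] > 0


class TestContributions:
    def test_tree_territory_is_single_inlet(self):
        net = _net(
            {0: ((0, 0, -10), 1.5), 1: ((0, 0, 0), 1.5),
             2: ((4, 0, 8), 0.8), 3: ((-4, 0, 8), 0.8)},
            {0: ([0, 1], "trunk"), 1: ([1, 2], "r"), 2: ([1, 3], "l")},
            inlets={0})
        sol = solve_steady_flow(build_system(
            net, BoundaryConditions({0: 93.33}, {2: 2.0, 3: 1.0})))
        contrib = inlet_contribution_map(sol)
        for node in (1, 2, 3):
            assert contrib["nodes"][node] == pytest.approx({0: 1.0})

    def test_symmetric_loop_far_side_splits_evenly(self):
        """Demand at the loop's midpoint, equal inlet pressures: 50/50."""
        net = _net(
            {0: ((-10, 0, -10), 1.2), 1: ((-10, 0, 0), 1.2),
             2: ((10, 0, -10), 1.2), 3: ((10, 0, 0), 1.2),
             4: ((0, 0, 6), 1.0)},
            {0: ([0, 1], "inL"), 1: ([2, 3], "inR"),
             2: ([1, 4], "halfL"), 3: ([3, 4], "halfR")},
            inlets={0, 2})
        sol = solve_steady_flow(build_system(
            net, BoundaryConditions({0: 93.33, 2: 93.33}, {4: 2.0})))
        mix = inlet_contribution_map(sol)["nodes"][4]
        assert mix[0] == pytest.approx(0.5, rel=1e-9)
        assert mix[2] == pytest.approx(0.5, rel=1e-9)

    def test_contralateral_supply_across_acoa(self):
        """Raising the left-side demand pulls right-inlet blood across the
        anterior communicating artery into left territory."""
        from perfterra import PerfusionModel
        from perfterra.synthetic import PhantomSpec, make_phantom

        net, mesh = make_phantom(PhantomSpec())
        res = PerfusionModel(net, mesh).fit()
        bcs = res.boundary_conditions
        scaled_out = {n: q * (1.6 if net.points[n].position[0] < 0 else 1.0)
                      for n, q in bcs.outlet_flow_ml_min.items()}
        lab = {seg.label: sid for sid, seg in res.model.network.segments.items()}
        scaled_mid = {s: q * (1.6 if (res.model.network.segments[s].label or
                                      "").startswith("L") else 1.0)
                      for s, q in bcs.midpoint_sink_ml_min.items()}
        sys2 = build_system(res.model.network, BoundaryConditions(
            bcs.inlet_pressure_mmhg, scaled_out, scaled_mid))
        sol2 = solve_steady_flow(sys2)
        # ACoA is oriented right-A1 -> left-A1: positive = rightward supply to left
        q_acoa = sol2.segment_throughflow_ml_min(lab["ACoA"])
        assert q_acoa > 1e-6
        # the left A2 outlet territory now has a right-ICA component
        contrib = inlet_contribution_map(sol2)
        la3 = lab["LACA-A3a"]
        node = res.model.network.segments[la3].point_ids[-1]
        mix = contrib["nodes"][node]
        rica_inlet = [n for n in bcs.inlet_pressure_mmhg
                      if res.model.network.points[n].position[0] > 5]
        assert sum(mix.get(n, 0.0) for n in rica_inlet) > 0
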