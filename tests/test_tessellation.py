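import numpy as np
import pytest

from perfterra import tessellation as tess
from perfterra.synthetic import PhantomSpec, box_mesh, make_phantom
from perfterra.tessellation import (
    SourcePoint,
    aggregate_segment_sinks,
    select_sources,
    tessellate,
    territory_demand,
)
from perfterra.tissue import TissueClassTable, total_demand


def _sources(positions, speeds=None):
    speeds = speeds or [1.0] * len(positions)
    return [SourcePoint(i, -1, "perforator", -1, np.asarray(p, float), c)
            for i, (p, c) in enumerate(zip(positions, speeds))]


def _brute_force_eq1(mesh, sources):
    """Exhaustive weighted-Voronoi rule over all (element, source) pairs,
    with the relative tie-gap per element for tie exclusion."""
    import math

    cen = mesh.centroids()
    winners = np.empty(mesh.n_elements, np.int64)
    gaps = np.empty(mesh.n_elements)
    for e in range(mesh.n_elements):
        costs = [math.dist(cen[e], s.position) / s.speed for s in sources]
        order = np.argsort(costs, kind="stable")
        winners[e] = order[0]
        gaps[e] = (costs[order[1]] - costs[order[0]]) / max(costs[order[0]], 1e-300)
    return winners, gaps


class TestSelectSources:
    def test_outlets_always_included(self, small_phantom):
        net, mesh = small_phantom
        src = select_sources(net, mesh, d_max=0.0)  # no perforators possible
        assert {s.kind for s in src} == {"outlet"}
        assert len(src) == len(net.outlet_nodes())

    def test_distance_threshold_boundary(self):
        mesh = box_mesh((2, 2, 2), (2.0, 2.0, 2.0))  # centroids within the box
        from perfterra.network import CenterlinePoint, Segment, VascularNetwork

        cen = mesh.centroids()
        # nearest centroid to a point far on +x axis
        near = cen[np.argmax(cen[:, 0])]
        for offset, expect in [(2.9, True), (3.1, False)]:
            p_far = near + np.array([offset, 0.0, 0.0])
            net = VascularNetwork(
                points={0: CenterlinePoint(0, p_far + [5, 0, 0], 1.0),
                        1: CenterlinePoint(1, p_far, 1.0),
                        2: CenterlinePoint(2, p_far + [2.5, 2.5, 0], 1.0)},
                segments={0: Segment(0, [0, 1, 2])},
                inlets={0},
            )
            kinds = {s.kind for s in select_sources(net, mesh, d_max=3.0)
                     if s.network_point_id == 1}
            assert ("perforator" in kinds) is expect

    def test_agrees_with_all_pairs_distances(self, small_phantom):
        """Spatial-index selection equals the O(N*M) exhaustive check."""
        net, mesh = small_phantom
        src = select_sources(net, mesh, d_max=3.0)
        selected = {s.network_point_id for s in src if s.kind == "perforator"}
        cen = mesh.centroids()
        roles = net.node_roles()
        brute = set()
        for pid, pt in net.points.items():
            if roles.get(pid) in ("outlet", "inlet"):
                continue
            d = np.linalg.norm(cen - pt.position, axis=1).min()
            if d <= 3.0:
                brute.add(pid)
        assert selected == brute

    def test_empty_mesh_errors(self, small_phantom):
        net, mesh = small_phantom
        import dataclasses

        class Empty:
            n_elements = 0

        with pytest.raises(ValueError, match="no elements"):
            select_sources(net, Empty(), 3.0)


class TestTessellate:
    def test_single_source_owns_everything(self):
        mesh = box_mesh((2, 2, 2), (10.0, 10.0, 10.0))
        a = tessellate(mesh, _sources([(0, 0, 5)]))
        assert a.n_assigned == mesh.n_elements
        assert np.all(a.element_source == 0)

    def test_mirror_symmetric_sources_split_evenly(self):
        mesh = box_mesh((4, 4, 4), (20.0, 20.0, 20.0))
        a = tessellate(mesh, _sources([(-5.0, 0.1, 10.0), (5.0, 0.1, 10.0)]))
        territory_demand(a, mesh, TissueClassTable.uniform(0.5))
        assert a.volume_ml[0] == pytest.approx(a.volume_ml[1], abs=1e-12)

    def test_matches_brute_force_eq1_on_convex_phantom(self, rng):
        """Connectivity constraint is inactive on a convex mesh: the
        assignment equals the exhaustive weighted-Voronoi rule."""
        mesh = box_mesh((8, 8, 4), (40.0, 40.0, 20.0))  # 1280 elements
        pos = rng.uniform([-18, -18, 2], [18, 18, 18], size=(5, 3))
        sources = _sources(pos)
        a = tessellate(mesh, sources)
        winners, gaps = _brute_force_eq1(mesh, sources)
        non_tie = gaps > 1e-9
        assert non_tie.sum() > 1000
        np.testing.assert_array_equal(a.element_source[non_tie], winners[non_tie])

    def test_speed_scale_invariance(self, rng):
        mesh = box_mesh((4, 4, 2), (20.0, 20.0, 10.0))
        pos = rng.uniform(-8, 8, size=(4, 3)) + [0, 0, 10]
        a1 = tessellate(mesh, _sources(pos, [1.0, 2.0, 0.5, 1.5]))
        a2 = tessellate(mesh, _sources(pos, [3.0, 6.0, 1.5, 4.5]))
        np.testing.assert_array_equal(a1.element_source, a2.element_source)

    def test_weighted_speeds_shift_boundary(self):
        mesh = box_mesh((4, 2, 2), (20.0, 10.0, 10.0))
        fast = tessellate(mesh, _sources([(-5, 0, 5), (5, 0, 5)], [3.0, 1.0]))
        even = tessellate(mesh, _sources([(-5, 0, 5), (5, 0, 5)], [1.0, 1.0]))
        assert (fast.element_source == 0).sum() > (even.element_source == 0).sum()

    def test_partition_property(self, cow_results):
        a = cow_results.assignment
        counts = np.bincount(a.element_source[a.element_source >= 0])
        assert counts.sum() + len(a.unassigned_elements) == len(a.element_source)

    def test_territories_connected(self, cow_results):
        """Each territory is one connected piece of the mesh (node-sharing
        adjacency)."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        a = cow_results.assignment
        mesh = cow_results.model.mesh
        adj = mesh.vertex_adjacency_graph().tocoo()
        same = a.element_source[adj.row] == a.element_source[adj.col]
        n = mesh.n_elements
        _, comp = connected_components(
            coo_matrix((np.ones(same.sum()), (adj.row[same], adj.col[same])),
                       shape=(n, n)), directed=False)
        for s in np.unique(a.element_source[a.element_source >= 0]):
            owned = np.nonzero(a.element_source == s)[0]
            assert len(np.unique(comp[owned])) == 1, f"territory {s} disconnected"

    def test_radius_independence(self, cow):
        """Perturbing vessel radii changes no territory."""
        from perfterra.synthetic import perturb_radii

        net, mesh = cow
        src0 = select_sources(net, mesh)
        src1 = select_sources(perturb_radii(net, relative_sd=0.3, seed=7), mesh)
        a0 = tessellate(mesh, src0)
        a1 = tessellate(mesh, src1)
        np.testing.assert_array_equal(a0.element_source, a1.element_source)

    def test_connectivity_enforced_on_split_mesh(self):
        """Two boxes joined by nothing: a source in one box cannot claim
        elements of the other even if it is the Euclidean winner there."""
        from perfterra.tissue import TissueMesh

        m1 = box_mesh((2, 2, 2), (6.0, 6.0, 6.0))
        m2 = box_mesh((2, 2, 2), (6.0, 6.0, 6.0))
        nodes = np.vstack([m1.nodes, m2.nodes + [20.0, 0, 0]])
        tets = np.vstack([m1.elements, m2.elements + len(m1.nodes)])
        mesh = TissueMesh(nodes, tets, ["other"] * len(tets))
        # source A inside box 1; source B far beyond box 2 so that A is the
        # Euclidean winner of *both* boxes
        a = tessellate(mesh, _sources([(0.0, 0.0, 3.0), (60.0, 0.0, 3.0)]))
        left = a.element_source[: m1.n_elements]
        right = a.element_source[m1.n_elements:]
        assert np.all(left == 0)
        # box 2 is the Euclidean territory of A but unreachable from A's
        # component; with no claimant inside it, it is reported unassigned
        assert np.all(right == -1)
        assert len(a.unassigned_elements) == m1.n_elements


class TestDemand:
    def test_single_white_element_demand(self):
        from perfterra.tissue import TissueMesh

        nodes = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 60]], float)
        mesh = TissueMesh(nodes, [[0, 1, 2, 3]], ["white"])  # 1 mL
        a = tessellate(mesh, _sources([(0, 0, 0)]))
        territory_demand(a, mesh, TissueClassTable())
        assert a.demand_ml_min[0] == pytest.approx(0.208)  # 1.04 * 1 * 0.2

    def test_demands_sum_to_total(self, cow_results):
        a = cow_results.assignment
        mesh = cow_results.model.mesh
        total = total_demand(mesh, TissueClassTable(),
                             np.nonzero(a.element_source >= 0)[0])
        assert np.sum(a.demand_ml_min) == pytest.approx(total, rel=1e-13)

    def test_known_partition_demands(self):
        """Hand-computed demands on a two-source mirror phantom."""
        mesh = box_mesh((2, 2, 2), (10.0, 10.0, 10.0), gray_shell_mm=100.0)
        a = tessellate(mesh, _sources([(-2.5, 0.1, 5.0), (2.5, 0.1, 5.0)]))
        territory_demand(a, mesh, TissueClassTable())
        # all gray: each half is 500 mm^3 = 0.5 mL; Q = 1.04 * 0.5 * 0.8
        assert a.demand_ml_min[0] == pytest.approx(1.04 * 0.5 * 0.8, rel=1e-12)
        assert a.demand_ml_min[1] == pytest.approx(1.04 * 0.5 * 0.8, rel=1e-12)


class TestSinks:
    def test_perforator_demands_lumped_at_segment_midpoint(self, cow):
        net, mesh = cow
        src = select_sources(net, mesh)
        a = tessellate(mesh, src)
        territory_demand(a, mesh, TissueClassTable())
        outlet_flows, midpoint_sinks = aggregate_segment_sinks(a, net)
        # conservation: outlets + sinks == sum of demands
        total = sum(outlet_flows.values()) + sum(midpoint_sinks.values())
        assert total == pytest.approx(np.sum(a.demand_ml_min), rel=1e-12)
        # each midpoint sink is the sum of its segment's perforator demands
        for sid, q in midpoint_sinks.items():
            mine = [a.demand_ml_min[s.id] for s in a.sources
                    if s.kind == "perforator" and s.segment_id == sid]
            assert q == pytest.approx(np.sum(mine), rel=1e-12)

    def test_segment_without_perforators_has_no_sink(self):
        mesh = box_mesh((2, 2, 2), (10.0, 10.0, 10.0))
        src = [SourcePoint(0, 5, "outlet", 3, np.array([0.0, 0.0, 5.0]))]
        a = tessellate(mesh, src)
        territory_demand(a, mesh, TissueClassTable.uniform(0.5))
        from perfterra.network import CenterlinePoint, Segment, VascularNetwork

        net = VascularNetwork(
            points={4: CenterlinePoint(4, np.array([0, 0, 20.0]), 1.0),
                    5: CenterlinePoint(5, np.array([0, 0, 5.0]), 1.0)},
            segments={3: Segment(3, [4, 5])}, inlets={4})
        outlet_flows, midpoint_sinks = aggregate_segment_sinks(a, net)
        assert midpoint_sinks == {}
        assert outlet_flows[5] == pytest.approx(np.sum(a.demand_ml_min))
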