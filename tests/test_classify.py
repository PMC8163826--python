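from collections import Counter

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from latticectx.classify import (
    classify_from_positions,
    classify_pair,
    classify_pairs,
    enumerate_context_sweep,
    local_symmetry,
    number_positions,
    orientation_class,
    ring_order,
    symmetry_independent_monomers,
)
from latticectx.geometry import euler_from_rotation
from latticectx.synthetic import LatticeGraph, build_polyhedron, build_tube


def rotate_graph(g, R):
    units = []
    for u in g.units:
        v = u.copy()
        v.position = R @ u.position
        v.euler = euler_from_rotation(R @ u.rotation)
        units.append(v)
    return LatticeGraph(units, list(g.edges), closed=g.closed,
                        voxel_size=g.voxel_size, spacing=g.spacing)


class TestPositionNumbering:
    def test_pentamer_partner_is_slot_one(self, t3_graph):
        found = False
        for a, b in t3_graph.edges:
            a_pent = t3_graph.units[a].is_pentamer
            b_pent = t3_graph.units[b].is_pentamer
            if a_pent == b_pent:
                continue
            hexamer_first = (b, a) if a_pent else (a, b)
            pos_h, pos_p = number_positions(t3_graph, hexamer_first)
            assert 1 in pos_h  # the hexamer's slot-1 partner is the pentamer
            found = True
            break
        assert found

    def test_shared_neighbor_identity(self, t3_graph):
        # slot 2 of A names the same unit as slot 6 of B and vice versa
        for e in t3_graph.edges:
            a, b = e
            if t3_graph.units[a].is_pentamer or \
                    t3_graph.units[b].is_pentamer:
                continue
            ra = ring_order(t3_graph, a, first=b)
            rb = ring_order(t3_graph, b, first=a)
            assert ra[1] == rb[-1]
            assert ra[-1] == rb[1]

    def test_tube_pair_has_empty_position_sets(self, tube_graph):
        interior = [e for e in tube_graph.edges
                    if len(tube_graph.neighbors(e[0])) == 6
                    and len(tube_graph.neighbors(e[1])) == 6]
        pos_a, pos_b = number_positions(tube_graph, interior[0])
        assert pos_a == frozenset() and pos_b == frozenset()


class TestGroups:
    def test_t1_all_group_one(self, t1_graph):
        assert {classify_pair(t1_graph, e).group
                for e in t1_graph.edges} == {1}

    def test_t3_hexamer_pairs_group_two_sharing_two(self, t3_graph):
        for e in t3_graph.edges:
            pc = classify_pair(t3_graph, e)
            a_pent = t3_graph.units[e[0]].is_pentamer
            b_pent = t3_graph.units[e[1]].is_pentamer
            if a_pent or b_pent:
                assert pc.group == 1
            else:
                assert pc.group == 2
                assert pc.subclass == 2  # two shared pentamer neighbors

    def test_tube_interior_group_five_three_subclasses(self, tube_graph):
        interior = [e for e in tube_graph.edges
                    if len(tube_graph.neighbors(e[0])) == 6
                    and len(tube_graph.neighbors(e[1])) == 6]
        pcs = [classify_pair(tube_graph, e) for e in interior]
        assert {pc.group for pc in pcs} == {5}
        assert {pc.orientation_class for pc in pcs} == {1, 2, 3}

    def test_swap_consistency(self, poly42_graph):
        g = poly42_graph
        for e in g.edges[::3]:
            ab = classify_pair(g, e)
            ba = classify_pair(g, (e[1], e[0]))
            assert ab.group == ba.group
            assert ab.positions_a == ba.positions_b
            assert ab.positions_b == ba.positions_a

    @pytest.mark.parametrize("seed", range(10))
    def test_total_over_random_polyhedrons(self, seed):
        g = build_polyhedron(42 + 10 * (seed % 2), 0.04 * (seed % 3), seed)
        for e in g.edges:
            pc = classify_pair(g, e)
            assert pc.group in (1, 2, 3, 4, 5, 6)

    def test_sweep_yields_exactly_six_groups(self):
        sweep = enumerate_context_sweep()
        groups = {s[2] for s in sweep}
        assert groups == {1, 2, 3, 4, 5, 6}

    def test_rule_function_examples(self):
        f = frozenset
        assert classify_from_positions(f([1]), f())[0] == 1
        assert classify_from_positions(f([2]), f([6]))[0] == 2
        assert classify_from_positions(f([3]), f([4]), 1)[0] == 3
        assert classify_from_positions(f([4]), f(), 2) == (4, 2)
        assert classify_from_positions(f(), f(), 3) == (5, 3)
        assert classify_from_positions(f([3, 5]), f())[0] == 6


class TestOrientationClass:
    def test_rigid_rotation_invariance(self, tube_graph):
        R = Rotation.from_rotvec([0.3, -0.8, 0.5]).as_matrix()
        rot = rotate_graph(tube_graph, R)
        interior = [e for e in tube_graph.edges
                    if len(tube_graph.neighbors(e[0])) == 6
                    and len(tube_graph.neighbors(e[1])) == 6]
        for e in interior[::5]:
            assert orientation_class(tube_graph, e) == \
                orientation_class(rot, e)

    def test_hexagon_edges_alternate_families(self, tube_graph):
        # the six edges around one interior hexamer cycle through the
        # three lattice edge families twice
        g = tube_graph
        center = next(i for i in range(len(g))
                      if len(g.neighbors(i)) == 6
                      and all(len(g.neighbors(j)) == 6
                              for j in g.neighbors(i)))
        ring = ring_order(g, center)
        classes = [orientation_class(g, (center, j)) for j in ring]
        assert classes[:3] == classes[3:]
        assert set(classes) == {1, 2, 3}

    def test_spherical_region_gives_none(self, t3_graph):
        assert orientation_class(t3_graph, t3_graph.edges[0]) is None


class TestLocalSymmetry:
    def test_t3_hexamers_are_c3(self, t3_graph):
        for i, u in enumerate(t3_graph.units):
            if not u.is_pentamer:
                assert local_symmetry(t3_graph, i) == "C3"

    def test_tube_hexamers_are_c2_tube(self, tube_graph):
        for i in range(len(tube_graph)):
            if len(tube_graph.neighbors(i)) == 6:
                assert local_symmetry(tube_graph, i) == "C2_tube"

    def test_single_pentamer_neighbor_breaks_symmetry(self, t3_graph):
        # demote two of a hexamer's three pentamer neighbors to hexamers:
        # one remaining pentamer -> C1
        g = LatticeGraph([u.copy() for u in t3_graph.units],
                         list(t3_graph.edges), closed=True,
                         spacing=t3_graph.spacing)
        hexamer = next(i for i, u in enumerate(g.units)
                       if not u.is_pentamer)
        pents = [j for j in g.neighbors(hexamer)
                 if g.units[j].is_pentamer]
        for j in pents[:2]:
            g.units[j].unit_type = "hexamer_C6"
        assert local_symmetry(g, hexamer) == "C1"

    def test_antipodal_pentamers_give_c2(self, t3_graph):
        g = LatticeGraph([u.copy() for u in t3_graph.units],
                         list(t3_graph.edges), closed=True,
                         spacing=t3_graph.spacing)
        hexamer = next(i for i, u in enumerate(g.units)
                       if not u.is_pentamer)
        ring = ring_order(g, hexamer)
        for j in ring:
            g.units[j].unit_type = "hexamer_C6"
        g.units[ring[0]].unit_type = "pentamer_C5"
        g.units[ring[3]].unit_type = "pentamer_C5"
        assert local_symmetry(g, hexamer) == "C2_pentamer"

    def test_independent_monomer_counts(self):
        assert symmetry_independent_monomers("hexamer_C2", "C2_tube") == 3
        assert symmetry_independent_monomers("hexamer_C6", "C3") == 2
        assert symmetry_independent_monomers("pentamer_C5", "C5") == 1
        with pytest.raises(ValueError):
            symmetry_independent_monomers("pentamer_C5", "C2")
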