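"""Force simulation, UniUni straightening, curve generation, glyph emission."""

import math

import pytest

import sbmlviz as sv
from sbmlviz.autolayout import (
    LayoutParams,
    fr_step,
    generate_curves,
    ideal_edge_length,
    place_initial,
    run_force_layout,
    straighten_uniuni,
)
from sbmlviz.netgraph import NetworkEdge, NetworkGraph, NetworkNode, add_emptyset_nodes, build_graph, create_aliases
from sbmlviz.types import Point, Role

from helpers import build_doc, fr_step_reference, two_node_graph


def small_graph(seed):
    doc = sv.generate_model(sv.SyntheticSpec(n_species=10, seed=seed))
    return create_aliases(add_emptyset_nodes(build_graph(doc)), 10)


class TestPlaceInitial:
    def test_same_seed_identical(self):
        g = small_graph(0)
        p = LayoutParams(seed=11)
        assert place_initial(g, p) == place_initial(g, p)

    def test_different_seeds_differ(self):
        g = small_graph(0)
        a = place_initial(g, LayoutParams(seed=1))
        b = place_initial(g, LayoutParams(seed=2))
        assert a != b

    def test_positions_inside_padded_canvas(self):
        g = small_graph(3)
        p = LayoutParams(seed=5, canvas_width=400, canvas_height=300, padding=25)
        pos = place_initial(g, p)
        for pt in pos.values():
            assert 25 <= pt.x <= 375
            assert 25 <= pt.y <= 275

    def test_invalid_params_rejected(self):
        with pytest.raises(sv.ParameterError):
            place_initial(small_graph(0), LayoutParams(iterations=-1))
        with pytest.raises(sv.ParameterError):
            place_initial(small_graph(0), LayoutParams(k_scale=0))


class TestFrStep:
    def test_single_isolated_node_does_not_move(self):
        g = NetworkGraph()
        g.add_node(NetworkNode("A", "species"))
        p = LayoutParams(seed=0, canvas_width=500, canvas_height=500)
        pos = {"A": Point(240.0, 260.0)}
        new = fr_step(g, pos, 50.0, p)
        assert new["A"] == Point(240.0, 260.0)

    def test_coincident_nodes_are_separated(self):
        g = two_node_graph()
        p = LayoutParams(seed=4, canvas_width=500, canvas_height=500)
        pos = {"A": Point(250.0, 250.0), "c": Point(250.0, 250.0)}
        new = fr_step(g, pos, 50.0, p)
        d = math.hypot(new["A"].x - new["c"].x, new["A"].y - new["c"].y)
        assert d > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        g = small_graph(seed)
        p = LayoutParams(seed=seed)
        pos = place_initial(g, p)
        got = fr_step(g, pos, 40.0, p)
        ref = fr_step_reference(g, pos, 40.0, p)
        for nid in g.nodes:
            assert abs(got[nid].x - ref[nid][0]) < 1e-9
            assert abs(got[nid].y - ref[nid][1]) < 1e-9


class TestRunForceLayout:
    def test_zero_iterations_equals_initial(self):
        g = small_graph(1)
        p = LayoutParams(seed=2, iterations=0)
        assert run_force_layout(g, p) == place_initial(g, p)

    def test_two_node_equilibrium_approaches_k(self):
        g = two_node_graph()
        p = LayoutParams(iterations=500, seed=8, canvas_width=2000, canvas_height=2000)
        pos = run_force_layout(g, p)
        k = ideal_edge_length(p, 2)
        d = math.hypot(pos["A"].x - pos["c"].x, pos["A"].y - pos["c"].y)
        assert abs(d - k) / k < 0.05

    def test_deterministic_across_runs(self):
        g = small_graph(5)
        p = LayoutParams(seed=13, iterations=30)
        assert run_force_layout(g, p) == run_force_layout(g, p)


class TestStraightenUniUni:
    def test_centroid_moves_to_midpoint(self):
        doc = build_doc([("R1", ["A"], ["B"], [])])
        g = build_graph(doc)
        pos = {"A": Point(0.0, 0.0), "B": Point(60.0, 80.0),
               "centroid_R1": Point(500.0, 500.0)}
        new = straighten_uniuni(g, pos)
        assert new["centroid_R1"] == Point(30.0, 40.0)
        assert new["A"] == pos["A"] and new["B"] == pos["B"]

    def test_horizontal_chain_gives_collinear_centroid(self):
        doc = build_doc([("R1", ["A"], ["B"], [])])
        g = build_graph(doc)
        pos = {"A": Point(0.0, 0.0), "B": Point(100.0, 0.0),
               "centroid_R1": Point(7.0, 93.0)}
        assert straighten_uniuni(g, pos)["centroid_R1"] == Point(50.0, 0.0)

    def test_multi_reactant_centroid_untouched(self):
        doc = build_doc([("R1", ["A", "B"], ["C"], [])])
        g = build_graph(doc)
        pos = {"A": Point(0, 0), "B": Point(10, 0), "C": Point(5, 10),
               "centroid_R1": Point(99.0, 99.0)}
        assert straighten_uniuni(g, pos)["centroid_R1"] == Point(99.0, 99.0)

    def test_modifiers_do_not_disqualify(self):
        doc = build_doc([("R1", ["A"], ["B"], ["M"])])
        g = build_graph(doc)
        pos = {"A": Point(0, 0), "B": Point(100, 0), "M": Point(50, 50),
               "centroid_R1": Point(0.0, 99.0)}
        assert straighten_uniuni(g, pos)["centroid_R1"] == Point(50.0, 0.0)


class TestGenerateCurves:
    def test_uniuni_control_points_exactly_collinear(self):
        doc = build_doc([("R1", ["A"], ["B"], [])])
        g = build_graph(doc)
        pos = {"A": Point(100.0, 137.0), "B": Point(413.0, 291.0),
               "centroid_R1": Point(0.0, 0.0)}
        pos = straighten_uniuni(g, pos)
        curves = generate_curves(g, pos, LayoutParams())
        for segs in curves.values():
            (seg,) = segs
            for bp in (seg.base_point_1, seg.base_point_2):
                cross = ((bp.x - seg.start.x) * (seg.end.y - seg.start.y)
                         - (bp.y - seg.start.y) * (seg.end.x - seg.start.x))
                assert cross == 0.0

    def test_attachment_points_distinct_on_shared_species(self):
        doc = build_doc([(f"R{i}", ["HUB"], [f"P{i}"], []) for i in range(3)])
        g = build_graph(doc)
        pos = {"HUB": Point(200.0, 200.0)}
        # all three centroids in nearly the same direction to force congestion
        for i in range(3):
            pos[f"P{i}"] = Point(400.0, 200.0 + i)
            pos[f"centroid_R{i}"] = Point(300.0, 200.0 + 0.1 * i)
        curves = generate_curves(g, pos, LayoutParams())
        starts = [tuple(curves[e.edge_id][0].start)
                  for e in g.edges if e.species_node == "HUB"]
        assert len(set(starts)) == 3
        sp = pos["HUB"]
        angles = sorted(math.degrees(math.atan2(y - sp.y, x - sp.x)) for x, y in starts)
        gaps = [angles[i + 1] - angles[i] for i in range(len(angles) - 1)]
        assert all(gap >= 15.0 - 1e-6 for gap in gaps)

    def test_substrate_product_tangents_separated_by_more_than_90_degrees(self):
        doc = build_doc([("R1", ["A", "B"], ["C"], [])])
        g = build_graph(doc)
        pos = {"A": Point(100.0, 100.0), "B": Point(100.0, 300.0),
               "C": Point(420.0, 200.0), "centroid_R1": Point(260.0, 200.0)}
        curves = generate_curves(g, pos, LayoutParams())
        tangents = {}
        for e in g.edges:
            seg = curves[e.edge_id][0]
            tangents[e.species_node] = (seg.base_point_2.x - seg.end.x,
                                        seg.base_point_2.y - seg.end.y)
        for sub in ("A", "B"):
            dot = (tangents[sub][0] * tangents["C"][0]
                   + tangents[sub][1] * tangents["C"][1])
            angle = math.degrees(math.acos(
                dot / (math.hypot(*tangents[sub]) * math.hypot(*tangents["C"]))))
            assert angle > 90.0


class TestBuildLayout:
    def test_two_species_one_reaction_completeness(self):
        doc = build_doc([("R1", ["A"], ["B"], [])])
        sv.build_layout(doc, LayoutParams(seed=1))
        layout = doc.layout
        assert len(layout.species_glyphs) == 2
        assert len(layout.text_glyphs) == 2
        assert len(layout.reaction_glyphs) == 1
        assert len(layout.reaction_glyphs[0].reference_glyphs) == 2
        assert sv.validate_layout(doc) == []

    def test_every_edge_has_a_curve_and_no_nans(self):
        doc = sv.generate_model(sv.SyntheticSpec(n_species=24, seed=9))
        sv.build_layout(doc, LayoutParams(seed=9))
        for rg in doc.layout.reaction_glyphs:
            for srg in rg.reference_glyphs:
                assert srg.curve
                for seg in srg.curve:
                    for pt in (seg.start, seg.end, seg.base_point_1, seg.base_point_2):
                        assert pt is None or pt.is_finite()

    def test_compartment_containment(self):
        doc = build_doc(
            [("R1", ["A"], ["B"], []), ("R2", ["C"], ["D"], [])],
            compartments=("cyto", "nucleus"),
            species_compartment={"C": "nucleus", "D": "nucleus"},
        )
        sv.build_layout(doc, LayoutParams(seed=2))
        comp = {g.compartment_id: g.bbox for g in doc.layout.compartment_glyphs}
        for g in doc.layout.species_glyphs:
            sp = doc.model.find_species(g.species_id)
            assert comp[sp.compartment_id].contains(g.bbox)

    def test_end_to_end_determinism(self):
        params = LayoutParams(seed=21)
        doc1 = sv.generate_model(sv.SyntheticSpec(n_species=16, seed=4))
        sv.build_layout(doc1, params)
        doc2 = sv.generate_model(sv.SyntheticSpec(n_species=16, seed=4))
        sv.build_layout(doc2, params)
        assert sv.write_document(doc1) == sv.write_document(doc2)

    def test_existing_layout_kept_unless_regeneration_requested(self):
        doc = build_doc([("R1", ["A"], ["B"], [])])
        sv.build_layout(doc, LayoutParams(seed=1))
        xml = sv.write_document(doc)
        sv.build_layout(doc, LayoutParams(seed=99, regenerate=False))
        assert sv.write_document(doc) == xml

    def test_aliases_appear_as_glyphs(self):
        doc = build_doc([(f"R{i}", ["HUB"], [f"P{i}"], []) for i in range(6)])
        sv.build_layout(doc, LayoutParams(seed=1, alias_threshold=3))
        hubs = doc.layout.species_glyphs_of("HUB")
        assert len(hubs) == 2
        assert sorted(g.alias_index for g in hubs) == [0, 1]
        assert sv.validate_layout(doc) == []
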