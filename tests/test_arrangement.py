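"""Geometric arrangement: axis alignment, circular arcs, glyph moves."""

import math

import pytest

import sbmlviz as sv
from sbmlviz.arrangement import ArcSpec
from sbmlviz.types import Point

from helpers import build_doc


def laid_out_chain(n=4, seed=1):
    """A linear chain A0 -R1-> A1 -R2-> A2 ... with a layout."""
    reactions = [(f"R{i+1}", [f"A{i}"], [f"A{i+1}"], []) for i in range(n)]
    doc = build_doc(reactions)
    sv.build_layout(doc, sv.LayoutParams(seed=seed))
    return doc


class TestAlignReaction:
    @pytest.mark.parametrize("orientation", ["horizontal", "vertical"])
    def test_collinear_through_centroid(self, orientation):
        doc = laid_out_chain()
        rg = doc.layout.find_reaction_glyph_by_reaction("R2")
        sub_gid = rg.reference_glyphs[0].species_glyph_id
        prod_gid = rg.reference_glyphs[1].species_glyph_id
        sv.align_reaction(doc, "R2", orientation)
        s = doc.layout.find_species_glyph(sub_gid).bbox.center
        p = doc.layout.find_species_glyph(prod_gid).bbox.center
        c = rg.center_bbox.center
        axis = "y" if orientation == "horizontal" else "x"
        assert getattr(s, axis) == getattr(p, axis) == getattr(c, axis)
        assert sv.validate_layout(doc) == []

    def test_chord_length_preserved(self):
        doc = laid_out_chain()
        rg = doc.layout.find_reaction_glyph_by_reaction("R1")
        s0 = doc.layout.find_species_glyph(rg.reference_glyphs[0].species_glyph_id).bbox.center
        p0 = doc.layout.find_species_glyph(rg.reference_glyphs[1].species_glyph_id).bbox.center
        before = math.hypot(p0.x - s0.x, p0.y - s0.y)
        sv.align_reaction(doc, "R1", "horizontal")
        s1 = doc.layout.find_species_glyph(rg.reference_glyphs[0].species_glyph_id).bbox.center
        p1 = doc.layout.find_species_glyph(rg.reference_glyphs[1].species_glyph_id).bbox.center
        assert math.hypot(p1.x - s1.x, p1.y - s1.y) == pytest.approx(before, abs=1e-9)

    def test_unknown_reaction_lists_available_ids(self):
        doc = laid_out_chain()
        with pytest.raises(sv.UnknownElementError, match="R1"):
            sv.align_reaction(doc, "Rx", "horizontal")

    def test_layout_absent_is_an_error(self):
        doc = build_doc([("R1", ["A"], ["B"], [])])
        with pytest.raises(sv.ParameterError):
            sv.align_reaction(doc, "R1", "horizontal")

    def test_locality_other_reactions_untouched(self):
        doc = laid_out_chain(n=5)
        far = doc.layout.find_reaction_glyph_by_reaction("R5")
        snapshot = [
            [(tuple(s.start), tuple(s.end)) for s in srg.curve]
            for srg in far.reference_glyphs
        ]
        sv.align_reaction(doc, "R1", "vertical")
        after = [
            [(tuple(s.start), tuple(s.end)) for s in srg.curve]
            for srg in far.reference_glyphs
        ]
        assert after == snapshot


class TestArrangeCircle:
    def test_four_reactions_at_cardinal_points(self):
        doc = laid_out_chain(n=4)
        arc = ArcSpec(center=Point(0.0, 0.0), radius=100.0)
        sv.arrange_reactions_circle(doc, ["R1", "R2", "R3", "R4"], arc)
        centers = [doc.layout.find_reaction_glyph_by_reaction(r).center_bbox.center
                   for r in ("R1", "R2", "R3", "R4")]
        expected = [(0, -100), (100, 0), (0, 100), (-100, 0)]  # y-down, clockwise
        for c, (ex, ey) in zip(centers, expected):
            assert c.x == pytest.approx(ex, abs=1e-6)
            assert c.y == pytest.approx(ey, abs=1e-6)

    @pytest.mark.parametrize("n", [1, 3, 4, 8])
    def test_radius_and_equal_gaps(self, n):
        doc = laid_out_chain(n=max(n, 2))
        rids = [f"R{i+1}" for i in range(n)]
        arc = ArcSpec(center=Point(400.0, 400.0), radius=150.0)
        sv.arrange_reactions_circle(doc, rids, arc)
        angles = []
        for rid in rids:
            c = doc.layout.find_reaction_glyph_by_reaction(rid).center_bbox.center
            assert math.hypot(c.x - 400, c.y - 400) == pytest.approx(150.0, abs=1e-6)
            angles.append(math.degrees(math.atan2(c.x - 400, -(c.y - 400))) % 360.0)
        if n > 1:
            gaps = [(angles[i + 1] - angles[i]) % 360.0 for i in range(n - 1)]
            for gap in gaps:
                assert gap == pytest.approx(360.0 / n, abs=1e-9)
        assert sv.validate_layout(doc) == []

    def test_consecutive_reactions_share_one_species_glyph(self):
        doc = laid_out_chain(n=3)
        arc = ArcSpec(center=Point(400.0, 400.0), radius=120.0, span=180.0)
        n_before = len(doc.layout.species_glyphs)
        sv.arrange_reactions_circle(doc, ["R1", "R2", "R3"], arc)
        # the chain already shares glyphs; nothing is merged or orphaned
        assert len(doc.layout.species_glyphs) == n_before
        assert sv.validate_layout(doc) == []
        r1 = doc.layout.find_reaction_glyph_by_reaction("R1")
        r2 = doc.layout.find_reaction_glyph_by_reaction("R2")
        assert r1.reference_glyphs[1].species_glyph_id == \
            r2.reference_glyphs[0].species_glyph_id

    def test_aliased_shared_species_are_merged_on_the_arc(self):
        # X is split into two alias glyphs; chaining R1 -> R2 through X on the
        # arc must merge them back into a single glyph without orphaning refs
        doc = build_doc([("R1", ["A"], ["X"], []), ("R2", ["X"], ["B"], [])])
        sv.build_layout(doc, sv.LayoutParams(seed=3, alias_threshold=1))
        assert len(doc.layout.species_glyphs_of("X")) == 2
        arc = ArcSpec(center=Point(400.0, 400.0), radius=120.0, span=180.0)
        sv.arrange_reactions_circle(doc, ["R1", "R2"], arc)
        assert len(doc.layout.species_glyphs_of("X")) == 1
        assert sv.validate_layout(doc) == []
        r1 = doc.layout.find_reaction_glyph_by_reaction("R1")
        r2 = doc.layout.find_reaction_glyph_by_reaction("R2")
        assert r1.reference_glyphs[1].species_glyph_id == \
            r2.reference_glyphs[0].species_glyph_id

    def test_duplicate_and_unknown_ids_rejected(self):
        doc = laid_out_chain(n=3)
        arc = ArcSpec(center=Point(0, 0), radius=50.0)
        with pytest.raises(sv.ParameterError, match="duplicate"):
            sv.arrange_reactions_circle(doc, ["R1", "R1"], arc)
        with pytest.raises(sv.UnknownElementError):
            sv.arrange_reactions_circle(doc, ["R9"], arc)

    def test_single_reaction_sits_at_start_angle(self):
        doc = laid_out_chain(n=2)
        arc = ArcSpec(center=Point(300.0, 300.0), radius=80.0, start_angle=90.0)
        sv.arrange_reactions_circle(doc, ["R1"], arc)
        c = doc.layout.find_reaction_glyph_by_reaction("R1").center_bbox.center
        assert c.x == pytest.approx(380.0, abs=1e-6)
        assert c.y == pytest.approx(300.0, abs=1e-6)


class TestMoveSpeciesGlyph:
    def test_center_round_trips(self):
        doc = laid_out_chain()
        sv.move_species_glyph(doc, "sg_A0", Point(321.0, 123.0))
        c = doc.layout.find_species_glyph("sg_A0").bbox.center
        assert (c.x, c.y) == pytest.approx((321.0, 123.0), abs=1e-9)

    def test_incident_curves_reattach_to_new_boundary(self):
        doc = laid_out_chain()
        sv.move_species_glyph(doc, "sg_A0", Point(500.0, 500.0))
        sg = doc.layout.find_species_glyph("sg_A0")
        rg = doc.layout.find_reaction_glyph_by_reaction("R1")
        srg = next(s for s in rg.reference_glyphs if s.species_glyph_id == "sg_A0")
        attach = srg.curve[0].start
        c = sg.bbox.center
        # boundary of the inscribed ellipse
        val = (((attach.x - c.x) / (sg.bbox.width / 2)) ** 2
               + ((attach.y - c.y) / (sg.bbox.height / 2)) ** 2)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_non_incident_reactions_bit_identical(self):
        doc = laid_out_chain(n=5)
        far = doc.layout.find_reaction_glyph_by_reaction("R5")
        before = [
            [(tuple(s.start), tuple(s.end),
              tuple(s.base_point_1) if s.base_point_1 else None) for s in srg.curve]
            for srg in far.reference_glyphs
        ]
        sv.move_species_glyph(doc, "sg_A0", Point(50.0, 60.0))
        after = [
            [(tuple(s.start), tuple(s.end),
              tuple(s.base_point_1) if s.base_point_1 else None) for s in srg.curve]
            for srg in far.reference_glyphs
        ]
        assert before == after

    def test_unknown_glyph_rejected(self):
        doc = laid_out_chain()
        with pytest.raises(sv.UnknownElementError):
            sv.move_species_glyph(doc, "sg_nope", Point(0, 0))
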