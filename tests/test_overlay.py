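"""Value normalization, gradient interpolation, overlays, color bar."""

import pytest
from hypothesis import given, settings, strategies as st

import sbmlviz as sv
from sbmlviz.types import GradientStop, LinearGradient, Role

from helpers import build_doc


def black_red():
    return LinearGradient("g", [GradientStop(0.0, "#000000"), GradientStop(1.0, "#FF0000")])


def overlay_ready_doc(seed=1, n=16):
    doc = sv.generate_model(sv.SyntheticSpec(n_species=n, seed=seed))
    sv.build_layout(doc, sv.LayoutParams(seed=seed))
    sv.default_render(doc)
    return doc


class TestNormalizeValues:
    def test_even_spacing(self):
        assert sv.normalize_values({"a": 2.0, "b": 4.0, "c": 6.0}) == \
            {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_single_value_maps_to_half(self):
        assert sv.normalize_values({"a": 7.0}) == {"a": 0.5}

    def test_explicit_range(self):
        assert sv.normalize_values({"a": 2.0}, (0.0, 10.0)) == {"a": 0.2}

    def test_out_of_range_clipped(self):
        out = sv.normalize_values({"a": -5.0, "b": 15.0}, (0.0, 10.0))
        assert out == {"a": 0.0, "b": 1.0}

    def test_symmetric_centers_zero(self):
        out = sv.normalize_values({"a": -4.0, "b": 0.0, "c": 2.0},
                                  normalization="symmetric")
        assert out == {"a": 0.0, "b": 0.5, "c": 0.75}

    def test_empty_map_is_an_error(self):
        with pytest.raises(sv.ParameterError):
            sv.normalize_values({})


class TestValueToColor:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.0, "#000000"), (1.0, "#FF0000"), (0.5, "#800000")],
    )
    def test_closed_forms_on_black_to_red(self, fraction, expected):
        assert sv.value_to_color(fraction, black_red()) == expected

    def test_three_stop_midpoint_is_exact_stop(self):
        grad = sv.default_gradient()
        assert sv.value_to_color(0.5, grad) == "#D9D9D9"

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_on_channel_monotone_gradient(self, f1, f2):
        lo, hi = sorted((f1, f2))
        red = lambda c: int(c[1:3], 16)  # noqa: E731
        assert red(sv.value_to_color(lo, black_red())) <= \
            red(sv.value_to_color(hi, black_red()))

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(sv.ParameterError):
            sv.value_to_color(1.5, black_red())


class TestReactionOverlay:
    def test_color_channel_boundaries(self):
        doc = overlay_ready_doc()
        rids = [r.reaction_id for r in doc.model.reactions]
        values = {rid: float(i) for i, rid in enumerate(rids)}
        spec = sv.OverlaySpec(target="reactions", channel="color", gradient=black_red())
        sv.overlay_reaction_values(doc, values, spec)
        low = doc.layout.find_reaction_glyph_by_reaction(rids[0])
        high = doc.layout.find_reaction_glyph_by_reaction(rids[-1])
        assert sv.effective_group(doc, low.glyph_id).stroke == "#000000"
        assert sv.effective_group(doc, high.glyph_id).stroke == "#FF0000"
        assert sv.validate_layout(doc) == []

    def test_width_channel_boundaries(self):
        doc = overlay_ready_doc()
        rids = [r.reaction_id for r in doc.model.reactions]
        values = {rid: float(i) for i, rid in enumerate(rids)}
        spec = sv.OverlaySpec(target="reactions", channel="width", out_range=(1.0, 10.0))
        sv.overlay_reaction_values(doc, values, spec)
        low = doc.layout.find_reaction_glyph_by_reaction(rids[0])
        high = doc.layout.find_reaction_glyph_by_reaction(rids[-1])
        assert sv.effective_group(doc, low.glyph_id).stroke_width == 1.0
        assert sv.effective_group(doc, high.glyph_id).stroke_width == 10.0

    def test_missing_policy_error_names_the_id(self):
        doc = overlay_ready_doc()
        spec = sv.OverlaySpec(target="reactions", channel="color")
        with pytest.raises(sv.UnknownElementError, match="R_missing"):
            sv.overlay_reaction_values(doc, {"R_missing": 1.0, "R1": 2.0}, spec)

    def test_missing_policy_skip_styles_the_rest(self):
        doc = overlay_ready_doc()
        spec = sv.OverlaySpec(target="reactions", channel="color",
                              gradient=black_red(), missing_policy="skip")
        sv.overlay_reaction_values(doc, {"R_missing": 9.0, "R1": 1.0, "R2": 2.0}, spec)
        assert sv.validate_layout(doc) == []
        rg = doc.layout.find_reaction_glyph_by_reaction("R2")
        assert sv.effective_group(doc, rg.glyph_id).stroke == "#FF0000"

    def test_base_template_styles_never_mutated(self):
        doc = overlay_ready_doc()
        base_style_snapshot = [(s.style_id, s.group.stroke, s.group.stroke_width)
                               for s in doc.render.styles]
        values = {r.reaction_id: float(i) for i, r in enumerate(doc.model.reactions)}
        sv.overlay_reaction_values(
            doc, values, sv.OverlaySpec(target="reactions", channel="color"))
        kept = [(s.style_id, s.group.stroke, s.group.stroke_width)
                for s in doc.render.styles[:len(base_style_snapshot)]]
        assert kept == base_style_snapshot
        # removing the overrides restores the prior rendering
        doc.render.styles = doc.render.styles[:len(base_style_snapshot)]
        doc2 = overlay_ready_doc()
        assert sv.write_document(doc) == sv.write_document(doc2)


class TestSpeciesOverlay:
    def test_fill_is_identical_across_alias_glyphs(self):
        doc = build_doc([(f"R{i}", ["HUB"], [f"P{i}"], []) for i in range(6)])
        sv.build_layout(doc, sv.LayoutParams(seed=1, alias_threshold=3))
        sv.default_render(doc)
        assert len(doc.layout.species_glyphs_of("HUB")) == 2
        spec = sv.OverlaySpec(target="species", channel="color", gradient=black_red())
        sv.overlay_species_values(doc, {"HUB": 5.0, "P0": 1.0}, spec)
        fills = {sv.effective_group(doc, g.glyph_id).fill
                 for g in doc.layout.species_glyphs_of("HUB")}
        assert len(fills) == 1

    def test_size_channel_boundary_scaling(self):
        doc = overlay_ready_doc()
        sids = [s.species_id for s in doc.model.species[:3]]
        values = {sids[0]: 0.0, sids[1]: 5.0, sids[2]: 10.0}
        spec = sv.OverlaySpec(target="species", channel="size", out_range=(0.5, 2.0))
        sv.overlay_species_values(doc, values, spec)
        low = doc.layout.species_glyphs_of(sids[0])[0]
        high = doc.layout.species_glyphs_of(sids[2])[0]
        assert low.bbox.width == pytest.approx(0.5 * 60.0)
        assert high.bbox.width == pytest.approx(2.0 * 60.0)
        assert low.bbox.height / low.bbox.width == pytest.approx(36.0 / 60.0)
        assert sv.validate_layout(doc) == []

    def test_size_overlay_reattaches_curves(self):
        doc = overlay_ready_doc()
        sid = doc.model.species[0].species_id
        spec = sv.OverlaySpec(target="species", channel="size", out_range=(2.0, 2.0))
        sv.overlay_species_values(doc, {sid: 1.0}, spec)
        g = doc.layout.species_glyphs_of(sid)[0]
        c = g.bbox.center
        for rg in doc.layout.reaction_glyphs:
            for srg in rg.reference_glyphs:
                if srg.species_glyph_id != g.glyph_id:
                    continue
                attach = (srg.curve[0].end if srg.role.is_product_like
                          else srg.curve[0].start)
                val = (((attach.x - c.x) / (g.bbox.width / 2)) ** 2
                       + ((attach.y - c.y) / (g.bbox.height / 2)) ** 2)
                assert val == pytest.approx(1.0, abs=1e-9)


class TestColorBar:
    def test_two_ticks_label_the_ends(self):
        doc = overlay_ready_doc(n=8)
        sv.add_colorbar(doc, black_red(), (0.0, 10.0),
                        sv.ColorBarSpec(tick_count=2))
        labels = [t.text for t in doc.layout.text_glyphs
                  if t.glyph_id.startswith("colorbar_tick")]
        assert labels == ["0", "10"]

    def test_three_ticks_midpoint_label(self):
        doc = overlay_ready_doc(n=8)
        sv.add_colorbar(doc, black_red(), (0.0, 10.0),
                        sv.ColorBarSpec(tick_count=3))
        labels = [t.text for t in doc.layout.text_glyphs
                  if t.glyph_id.startswith("colorbar_tick")]
        assert labels == ["0", "5", "10"]

    def test_bar_round_trips_through_sbml(self):
        doc = overlay_ready_doc(n=8)
        sv.add_colorbar(doc, black_red(), (0.0, 4.0), sv.ColorBarSpec(tick_count=4))
        xml = sv.write_document(doc)
        doc2 = sv.read_document(xml)
        assert any(g.glyph_id == "colorbar" for g in doc2.layout.additional_objects)
        assert len([t for t in doc2.layout.text_glyphs
                    if t.glyph_id.startswith("colorbar_tick")]) == 4
        assert doc2.render.find_gradient("g") is not None
        assert sv.write_document(doc2) == xml

    def test_inverted_range_rejected(self):
        doc = overlay_ready_doc(n=8)
        with pytest.raises(sv.ParameterError):
            sv.add_colorbar(doc, black_red(), (5.0, 1.0))


class TestValueFiles:
    def test_csv_with_header_and_comments(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("# flux snapshot\nid,value\nR1,2.5\nR2,-1\n")
        assert sv.read_value_map(str(p)) == {"R1": 2.5, "R2": -1.0}

    def test_tsv_autodetected(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("R1\t1.5\nR2\t2\n")
        assert sv.read_value_map(str(p)) == {"R1": 1.5, "R2": 2.0}

    def test_non_numeric_value_rejected(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("id,value\nR1,abc\n")
        with pytest.raises(sv.ParameterError):
            sv.read_value_map(str(p))
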