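"""Colors, default styles, templates, cascade, selection and batch editing."""

import json

import pytest

import sbmlviz as sv
from sbmlviz.styling import (
    HTML_COLORS,
    SBGN_CLASSES,
    StyleTemplate,
    element_kind,
    matching_style,
    sbgn_style_for_class,
)
from sbmlviz.types import (
    EllipsePrimitive,
    PolygonPrimitive,
    RectanglePrimitive,
    RenderCurvePrimitive,
    Role,
)

from helpers import build_doc


def laid_out_doc(seed=1, n=16):
    doc = sv.generate_model(sv.SyntheticSpec(n_species=n, seed=seed))
    sv.build_layout(doc, sv.LayoutParams(seed=seed))
    return doc


class TestResolveColor:
    @pytest.mark.parametrize(
        "name,expected",
        [("white", "#FFFFFF"), ("black", "#000000"), ("WhItE", "#FFFFFF"),
         ("#ff0000", "#FF0000"), ("#aabbccdd", "#AABBCCDD"), ("rebeccapurple", "#663399")],
    )
    def test_lookup_and_normalization(self, name, expected):
        assert sv.resolve_color(name) == expected

    def test_table_has_all_148_standard_names(self):
        assert len(HTML_COLORS) == 148

    def test_unknown_name_suggests_near_matches(self):
        with pytest.raises(sv.UnknownColorError) as exc:
            sv.resolve_color("whyte")
        assert "white" in exc.value.suggestions

    def test_bad_hex_rejected(self):
        with pytest.raises(sv.UnknownColorError):
            sv.resolve_color("#12345")


class TestDefaultRender:
    def test_full_coverage_and_validity(self):
        doc = laid_out_doc()
        sv.default_render(doc)
        assert sv.validate_layout(doc) == []
        for element_id in element_kind(doc):
            assert matching_style(doc, element_id) is not None

    def test_product_arcs_get_arrowheads_substrates_none(self):
        doc = laid_out_doc()
        sv.default_render(doc)
        for rg in doc.layout.reaction_glyphs:
            for srg in rg.reference_glyphs:
                group = sv.effective_group(doc, srg.glyph_id)
                if srg.role in (Role.PRODUCT, Role.SIDE_PRODUCT):
                    assert group.end_head == "arrow_filled"
                elif srg.role in (Role.SUBSTRATE, Role.SIDE_SUBSTRATE):
                    assert group.end_head is None

    def test_second_call_replaces_not_duplicates(self):
        doc = laid_out_doc()
        sv.default_render(doc)
        n = len(doc.render.styles)
        sv.default_render(doc)
        assert len(doc.render.styles) == n

    def test_requires_layout(self):
        doc = build_doc([("R1", ["A"], ["B"], [])])
        with pytest.raises(sv.ParameterError):
            sv.default_render(doc)


class TestSbgnRecipes:
    def test_every_supported_class_has_a_recipe(self):
        for cls in SBGN_CLASSES:
            recipe = sbgn_style_for_class(cls)
            assert recipe.is_arc or recipe.group.primitives

    def test_process_is_a_square(self):
        recipe = sbgn_style_for_class("process")
        assert recipe.node_size[0] == recipe.node_size[1]
        assert isinstance(recipe.group.primitives[0], RectanglePrimitive)

    def test_simple_chemical_is_an_ellipse(self):
        assert isinstance(sbgn_style_for_class("simple-chemical").group.primitives[0],
                          EllipsePrimitive)

    def test_complex_is_a_cut_corner_octagon(self):
        prim = sbgn_style_for_class("complex").group.primitives[0]
        assert isinstance(prim, PolygonPrimitive)
        assert len(prim.points) == 8

    def test_inhibition_head_is_a_bar(self):
        recipe = sbgn_style_for_class("inhibition")
        assert recipe.group.end_head == "inhibit_bar"

    def test_source_and_sink_is_slashed_circle(self):
        prims = sbgn_style_for_class("source-and-sink").group.primitives
        assert any(isinstance(p, EllipsePrimitive) for p in prims)
        assert any(isinstance(p, RenderCurvePrimitive) for p in prims)

    def test_unsupported_class_raises_capability_error(self):
        with pytest.raises(sv.CapabilityError):
            sbgn_style_for_class("annotation")


class TestTemplates:
    @pytest.mark.parametrize("name", ["default", "sbgn-pd", "escher"])
    def test_coverage_and_roundtrip(self, name):
        doc = laid_out_doc()
        sv.apply_template(doc, name)
        assert sv.validate_layout(doc) == []
        for element_id in element_kind(doc):
            assert matching_style(doc, element_id) is not None
        xml = sv.write_document(doc)
        assert sv.write_document(sv.read_document(xml)) == xml

    def test_sbgn_class_from_annotation_drives_shape(self):
        doc = build_doc([("R1", ["glc"], ["atp"], [])])
        doc.model.find_species("glc").sbgn_class = "simple-chemical"
        sv.build_layout(doc, sv.LayoutParams(seed=1))
        sv.apply_template(doc, "sbgn-pd")
        group = sv.effective_group(doc, "sg_glc")
        assert isinstance(group.primitives[0], EllipsePrimitive)
        # fallback for the unannotated one is macromolecule (rounded rect)
        group2 = sv.effective_group(doc, "sg_atp")
        assert isinstance(group2.primitives[0], RectanglePrimitive)
        assert group2.primitives[0].rx > 0

    def test_sbgn_class_from_sbo_term(self):
        doc = build_doc([("R1", ["c1"], ["p1"], [])])
        doc.model.find_species("c1").sbo_term = "SBO:0000253"
        sv.build_layout(doc, sv.LayoutParams(seed=1))
        sv.apply_template(doc, "sbgn-pd")
        prim = sv.effective_group(doc, "sg_c1").primitives[0]
        assert isinstance(prim, PolygonPrimitive) and len(prim.points) == 8

    def test_template_application_is_idempotent(self):
        doc = laid_out_doc()
        sv.apply_template(doc, "escher")
        xml = sv.write_document(doc)
        sv.apply_template(doc, "escher")
        assert sv.write_document(doc) == xml

    def test_unknown_template_lists_the_three_names(self):
        doc = laid_out_doc(n=8)
        with pytest.raises(sv.ParameterError) as exc:
            sv.apply_template(doc, "bogus")
        for name in ("default", "sbgn-pd", "escher"):
            assert name in str(exc.value)

    def test_escher_resizes_species_to_circles(self):
        doc = laid_out_doc()
        sv.apply_template(doc, "escher")
        for g in doc.layout.species_glyphs:
            if g.species_id is not None:
                assert g.bbox.width == g.bbox.height == 25.0
        arc_widths = {sv.effective_group(doc, srg.glyph_id).stroke_width
                      for rg in doc.layout.reaction_glyphs
                      for srg in rg.reference_glyphs
                      if srg.role in (Role.SUBSTRATE, Role.PRODUCT)}
        assert arc_widths == {9.0}

    def test_custom_template_from_json(self, tmp_path):
        path = tmp_path / "theme.json"
        path.write_text(json.dumps({
            "name": "night",
            "defaults": {"background_color": "midnightblue", "stroke": "white"},
            "class_styles": {
                "species": {"shape": "ellipse", "fill": "#222244", "stroke": "white"},
                "product": {"stroke": "orange", "stroke-width": 3},
            },
        }))
        template = sv.load_template(str(path))
        assert isinstance(template, StyleTemplate)
        doc = laid_out_doc(n=8)
        sv.apply_template(doc, "night")
        assert doc.render.background_color == "#191970"
        sg = doc.layout.species_glyphs[0]
        assert sv.effective_group(doc, sg.glyph_id).fill == "#222244"


class TestSelectAndBatch:
    def test_select_by_fill(self):
        doc = laid_out_doc(n=8)
        sv.default_render(doc)
        ids = [g.glyph_id for g in doc.layout.species_glyphs[:2]]
        sv.batch_set(doc, ids, "fill", "#FF0000")
        selected = sv.select_elements(doc, "fill", "#FF0000")
        assert set(ids) <= set(selected)
        third = doc.layout.species_glyphs[2].glyph_id
        assert third not in selected

    def test_batch_preserves_other_attributes(self):
        doc = laid_out_doc(n=8)
        sv.default_render(doc)
        gid = doc.layout.species_glyphs[0].glyph_id
        before = sv.effective_group(doc, gid)
        stroke_before = before.stroke
        sv.batch_set(doc, [gid], "fill", "#00FF00")
        after = sv.effective_group(doc, gid)
        assert after.fill == "#00FF00"
        assert after.stroke == stroke_before
        assert sv.validate_layout(doc) == []

    def test_empty_id_list_is_identity(self):
        doc = laid_out_doc(n=8)
        sv.default_render(doc)
        xml = sv.write_document(doc)
        sv.batch_set(doc, [], "fill", "#00FF00")
        assert sv.write_document(doc) == xml

    def test_negative_stroke_width_rejected(self):
        doc = laid_out_doc(n=8)
        sv.default_render(doc)
        gid = doc.layout.species_glyphs[0].glyph_id
        with pytest.raises(sv.ParameterError):
            sv.batch_set(doc, [gid], "stroke-width", -1)

    def test_unknown_id_and_attribute_rejected(self):
        doc = laid_out_doc(n=8)
        sv.default_render(doc)
        with pytest.raises(sv.UnknownElementError, match="sg_nope"):
            sv.batch_set(doc, ["sg_nope"], "fill", "#FFFFFF")
        with pytest.raises(sv.ParameterError):
            sv.select_elements(doc, "sparkle", 1)

    def test_cascade_id_beats_role_beats_type(self):
        doc = laid_out_doc(n=8)
        sv.default_render(doc)
        rg = doc.layout.reaction_glyphs[0]
        srg = rg.reference_glyphs[0]
        role_group = sv.effective_group(doc, srg.glyph_id)
        assert matching_style(doc, srg.glyph_id).role_list  # role beats type/default
        sv.batch_set(doc, [srg.glyph_id], "stroke", "#123456")
        assert matching_style(doc, srg.glyph_id).id_list == [srg.glyph_id]
        assert sv.effective_group(doc, srg.glyph_id).stroke == "#123456"
        assert role_group.stroke != "#123456"  # base style untouched
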