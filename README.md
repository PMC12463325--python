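# sbmlviz

Standards-based visualization of SBML biochemical models. sbmlviz generates
SBML **Layout** and **Render** package data automatically — so positions,
shapes, colors and data overlays live *inside* the SBML file next to the
model — instead of in a tool-specific sidecar format. It is aimed at systems
biologists who need reproducible, interoperable pathway figures: SBGN
Process Description diagrams, Escher-style metabolic maps, and flux or
concentration overlays.

## What it does

* **Biochemistry-aware auto-layout.** Rather than treating the network as a
  plain node–edge graph, each reaction is modeled as a hyper-edge anchored
  at a dedicated *centroid* node, so multi-reactant/multi-product reactions
  keep their semantics. The placement stage adapts the classical
  Fruchterman–Reingold simulation: pairwise repulsion `k²/d`, attraction
  `d²/k` along participation edges, with ideal edge length
  `k = k_scale · √(area / n)`, per-node displacement capped by a linearly
  cooling temperature. On top of the raw positions come the heuristics that
  make biochemical maps readable:
  * species that participate in many reactions are split into **alias**
    glyphs (balanced edge partition) to reduce crossings;
  * reactions missing a reactant or product get an emancipated **∅
    source/sink** glyph;
  * role-aware **Bézier curves**: substrate arcs enter the centroid from the
    substrate half-plane, product arcs from the opposite one, modifiers
    perpendicular to the axis, with even fanning per role and congestion-
    limited attachment points on species boundaries;
  * **UniUni** (one reactant, one product) reactions are straightened into an
    exact reactant-to-product line.
* **Styling.** 148 named HTML colors, an automatic default style set, and
  predefined templates: `default`, `sbgn-pd` (one styling recipe per SBGN
  Process Description class), and `escher` (thick colored reaction curves,
  circular metabolite nodes, bold labels). Styles cascade
  `id > role > type > default`; batch edits are pure id-selector overrides.
* **Data overlays.** Map reaction fluxes / species concentrations to gradient
  color, curve thickness or node size, with a customizable color bar — all
  persisted as ordinary Layout+Render elements.
* **Arrangement.** Align single reactions horizontally/vertically, place
  reaction sets on circular arcs (TCA-style), move glyphs with automatic
  curve re-attachment.
* **Export.** SVG (native Render→SVG mapping), PNG, JPEG, PDF.

## Worked example

```python
import sbmlviz as sv

doc = sv.generate_model(sv.SyntheticSpec(n_species=20, seed=7))
sv.build_layout(doc, sv.LayoutParams(seed=7))
sv.default_render(doc)

fluxes = {"R1": 0.4, "R2": 3.1, "R3": 9.8, "R4": 1.2, "R5": 6.0}
spec = sv.OverlaySpec(target="reactions", channel="color",
                      gradient=sv.default_gradient())
sv.overlay_reaction_values(doc, fluxes, spec)
sv.add_colorbar(doc, sv.default_gradient(),
                (min(fluxes.values()), max(fluxes.values())),
                sv.ColorBarSpec(tick_count=3))
```

Running `python examples/03_flux_overlay.py` (the script above) prints:

```
R1: flux  0.4 → curve stroke #5B7DA2
R2: flux  3.1 → curve stroke #A3B2C2
R3: flux  9.8 → curve stroke #E8262C
R4: flux  1.2 → curve stroke #708DAB
R5: flux  6.0 → curve stroke #DCB7B8
color bar ticks: ['0.4', '5.1', '9.8']  (min / mid / max of the flux range)
document still valid: True
```

Low fluxes map to the muted blue end of the gradient, the highest flux to
vivid red, and the tick labels span the observed flux range. Writing the
document (`sv.write_document(doc)`) stores the layout, the styles, the
overlay overrides and the color bar inside the SBML file; reading it back
reproduces the figure byte-for-byte.

The `examples/` directory has one short script per capability
(auto-layout, SBGN template, flux overlay, circular arrangement,
benchmarking). The same pipeline is available from the shell:

```bash
sbmlviz synth --species 20 -o toy.xml
sbmlviz layout toy.xml --seed 42 -o laid.xml
sbmlviz style laid.xml --template sbgn-pd -o styled.xml
sbmlviz export styled.xml -f svg -o figure.svg
```

## Documentation

`docs/methods.md` describes the force model and its constants, the curve
and aliasing heuristics, what the synthetic generator does and does not
emulate, numerical choices, and known limitations.
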