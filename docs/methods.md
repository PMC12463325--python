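# Methods

## Scope and data model

sbmlviz operates on a single `Document`: an SBML Level 3 model plus optional
Layout and Render sections. The in-memory types mirror the two packages
(glyphs with bounding boxes and cubic Bézier curves; color definitions,
linear gradients, line endings, and selector-based styles whose attribute
vocabulary follows SVG). Serialization targets L3V1 with Layout v1 and
Render v1 namespaces; other Level-3 package versions are read permissively
by matching the namespace path rather than the exact version string. One
layout and one local render-information block are operated on per document.

Coordinates: origin top-left, y down, units are layout points (pt), boxes
are (origin, width, height) — the shared convention of the Layout package
and SVG. Emancipated source/sink glyphs carry no model reference and are
serialized as generic graphical objects with the reserved id/metaid prefix
`emptyset_`, which makes their round-trip testable. Render primitive
coordinates are stored on the Render package's 0–100 percent-of-box scale,
and all floats are serialized via `repr`, so write→read is value-exact.

## Reaction hypergraph

`build_graph` creates one node per species, one centroid node per reaction,
and one role-labeled edge per listed participation, in model document order
(this ordering is what makes the whole pipeline deterministic). Modifier
subtype resolution: SBO:0000020 or the annotation keyword "inhibitor" →
inhibitor; SBO:0000459 / "activator" → activator; otherwise a generic
modifier. Reactions with no reactants (or no products) gain a fresh ∅ node
per deficit — never shared, since a source/sink symbol belongs to one
reaction.

**Aliasing.** A species with k incident edges, k > t (threshold t, default
10 — hub metabolites such as ATP or NADH exceed this, pathway intermediates
do not), is replaced by ⌈k/t⌉ alias nodes over which its edges are
partitioned as evenly as possible (load difference ≤ 1) in input order. The
operation conserves the participation multiset and is idempotent. ∅ nodes
are excluded. Each alias is initialized at the mean position of the
centroids in its edge partition, which is what lets aliasing actually cut
crossings rather than merely duplicating a node.

## Force model

One synchronous iteration applies, for ideal edge length
`k = k_scale·√(W·H/n)`:

* repulsion `k²/d` between every node pair (centroids participate as
  ordinary nodes with a small 10×10 pt footprint vs 60×36 pt species);
* attraction `d²/k` along every participation edge;
* a weak pull of each node toward its compartment's running centroid at 0.1
  of the edge-attraction strength — enough to keep compartments separable
  without fighting the main forces; containment is then enforced
  geometrically when compartment boxes are sized;
* displacement capped at the current temperature, positions clamped to the
  padded canvas.

Defaults: `k_scale = 1`, initial temperature `W/10`, linear cooling over 50
iterations, padding 20 pt. The canvas auto-sizes to `max(500, ⌈90·√n⌉)` pt
per side when not given. Coincident nodes are separated by a deterministic
ε-jitter (1e-4 pt, directions drawn from the seeded generator) before force
evaluation. The implementation is vectorized over the full n×n pair matrix
(no Barnes–Hut or parallelism); at 2,500 nodes one pass over 50 iterations
takes on the order of fifteen seconds on one core, which is the design
point — model sizes beyond a few thousand species are outside typical use.

The analytically known two-node equilibrium (attraction balances repulsion
at d = k) and a plain-loop reference implementation of the same force
equations serve as correctness anchors in the test suite; the vectorized
step agrees with the loop reference to ~1e-13 pt.

## Curves

Each participation edge gets one cubic Bézier from a species-boundary
attachment point to the reaction centroid.

* **Centroid tangents.** Substrate arcs enter from the half-plane facing the
  substrate mass-center, product arcs from the opposite half-plane,
  modifiers perpendicular to the substrate→product axis (alternating
  sides). Within a role class, tangents fan evenly with a per-class span
  capped at 80° (50° for modifiers), so substrate and product tangents are
  always separated by more than 90°.
* **Attachment points** sit where the direction to the centroid crosses the
  inscribed ellipse of the node box; when several reactions converge on one
  species the angles are minimally rotated apart until pairwise separation
  reaches 15° (falling back to even spacing when more than 360°/15° arcs
  compete).
* **Control points** are placed at one third of the chord from each end,
  displaced along the species-boundary normal and the assigned centroid
  tangent respectively.
* **UniUni reactions** are straightened: the centroid snaps to the
  reactant–product midpoint and the curve's control points are set *equal to
  its endpoints*. A degenerate cubic with coincident control points is
  exactly the straight segment, so the collinearity invariant holds
  exactly in floating point, with no last-ulp residue from interpolation.

Product arcs are emitted centroid→species so their arrowhead line ending
lands at the species end; all other roles run species→centroid.

## Styling

`resolve_color` covers the 148 standard HTML color names (case-insensitive,
with near-miss suggestions) and normalizes hex input to uppercase
`#RRGGBB[AA]`. The cascade is a total order — id-selector > role-selector >
type-selector > default, later styles winning within a tier — and
`batch_set` writes id-selector overrides seeded from the previous effective
style, so removing the overrides restores the prior rendering exactly.

Templates replace the render block wholesale and are idempotent:

* `default` — rounded-rectangle species, filled-triangle product arrows,
  bar inhibitors, open-circle activators, dashed generic modifiers,
  slashed-circle ∅ glyphs.
* `sbgn-pd` — one recipe per supported Process Description class
  (macromolecule, simple chemical, nucleic acid feature, complex,
  source-and-sink, process, association, dissociation, compartment, and the
  consumption/production/catalysis/inhibition/stimulation/modulation arcs).
  Class resolution: explicit annotation → SBO term → glyph-type fallback
  (species→macromolecule, reaction→process, ∅→source-and-sink). Process
  nodes are resized to 14×14 pt squares. The SBGN "annotation" glyph is not
  representable in the Render vocabulary and raises a capability error.
* `escher` — reaction curves `#334E75` at 9 pt, species as 25 pt circles,
  bold 20 pt labels, scaled filled-triangle arrowheads at curve ends. The
  concrete values are this package's own calibration of the look and are
  fully overridable. Arrowheads sit at curve ends (not mid-curve) so one
  line-ending mechanism serves every template.

Custom templates load from JSON (`{name, class_styles, defaults}`) with the
same attribute vocabulary.

## Overlays

Values are min–max normalized to [0,1] (explicit range optional,
out-of-range clipped; a degenerate range maps everything to 0.5). Signed
data can use the `symmetric` convention: range ±max|v| so zero lands at 0.5.
Gradient interpolation is per-channel linear in 8-bit RGB with round-half-up;
fractions 0 and 1 return the first/last stop exactly, and channel-monotone
stops give monotone output. The default gradient runs muted blue → light
gray → vivid red.

Color/width overlays write only id-selector overrides; size overlays scale
species boxes about their centers relative to the default 60×36 pt footprint
(aspect preserved) and re-attach incident curves. Unknown ids in a value map
follow the missing policy: `error` (named in the exception), `skip`, or
`dim`, where `dim` additionally grays out document elements absent from the
map. The color bar is an ordinary graphical object filled by a registered
linear gradient plus tick text glyphs (labels linearly interpolated over the
value range, `str.format` pattern, default `{:g}`), so it round-trips
through the SBML file like everything else.

## Arrangement

Angle convention: 0° = 12 o'clock, positive clockwise, in y-down screen
coordinates — how cyclic pathways are read. `align_reaction` makes the
first-listed substrate, the centroid and the first-listed product collinear
while preserving the chord length and which side each species was on; only
that reaction's curves are regenerated (locality is a guarantee, so curves
of other reactions sharing a moved species are deliberately left alone).
`arrange_reactions_circle` spaces centroids at span/n (full circle) or
span/(n−1) (partial arc) and places main substrates/products a half-step
before/after, merging the glyphs of exact species-id matches between
consecutive reactions so chains close cleanly; merging retargets references
first and never orphans them. Arc centers should lie inside the canvas —
coordinates are not re-shifted afterwards, to preserve locality. All
arrangement operations expand (never shrink) the layout dimensions to keep
every box enclosed.

## Export

SVG is the reference renderer: rectangle→`rect` (with corner radii),
ellipse→`ellipse`, polygon→`polygon`, curves→`path` with `C` segments,
gradients→`linearGradient` defs, line endings→`marker` defs with
`orient="auto"` when rotational mapping is on. Z-order: background,
compartments, reaction curves, species, additional objects, text. Raster
(PNG/JPEG) and PDF go through matplotlib drawing the same primitives;
there, gradients are approximated by their mean stop color and arrowheads
by polygons oriented along the end tangent — output pixel dimensions are
exactly ⌈dims × scale⌉. Fonts are generic family keywords; nothing is
embedded.

## Synthetic models and benchmark

The generator emulates benchmark-style inputs: n species in one compartment
and ⌊n/4⌋ reactions (the ratio is a parameter, 4:1 by default), each drawing
1–2 reactants and 1–2 products without replacement from the pool via the
seeded generator — a UniUni/BiBi mix representative of biochemical models.
It deliberately does *not* emulate hub-metabolite degree distributions,
multi-compartment structure, kinetics, or annotations; tests passing on
these inputs therefore demonstrate structural and numerical correctness of
the pipeline, not figure aesthetics on curated real-world maps. The
benchmark harness reports the median wall-clock layout time over repeated
runs per size; timings are descriptive and never asserted.

Sizes used by the shipped checks: the force-step cross-validation uses 100
ten-species graphs (≤ 20 nodes each); round-trip fidelity uses 50 randomized
documents spanning aliases, ∅ glyphs, all three templates, overlays and the
color bar; the end-to-end determinism check runs the full CLI pipeline twice
on the 2,000-species model at 50 iterations, with benchmark rows at
20/200/2,000 species.

## Numerical choices and degeneracies

* All randomness flows from `numpy.random.default_rng(seed)`; seeds default
  to 0, never to wall-clock time. Identical inputs give byte-identical
  output files.
* Coincident nodes: 1e-4 pt seeded jitter. Zero-length axes in curve
  generation fall back to the unit x direction.
* A single-valued or constant value map normalizes to 0.5 rather than
  erroring, so one-reaction overlays still render.
* Validation returns issues (severity, message, element id) instead of
  raising; writing refuses documents whose invariants fail, before emitting
  anything.

## Known limitations

* No overlap removal or constraint solving after manual moves; no undo.
* No grid/Barnes–Hut acceleration — layouts beyond a few thousand species
  get slow by design honesty, not accident.
* SBGN Entity Relationship / Activity Flow languages, BioTapestry-style
  gene-regulatory rendering, time-course animation and distribution-valued
  overlays are out of scope; a simulator hook (any callable returning a
  value map) is the extension point for simulation-driven overlays.
* Raster output approximates gradients and arrowhead shapes (see Export);
  the SVG output is authoritative.
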