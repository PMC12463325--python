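"""Arrange a reaction chain on a circle, the way cyclic pathways (e.g. the
TCA cycle) are conventionally drawn.

Centroids are spaced at equal angles starting from 12 o'clock, clockwise;
consecutive reactions chain through their shared species on the arc.
"""

import math

import sbmlviz as sv
from sbmlviz.types import Compartment, Model, Point, Reaction, Species, SpeciesReference


def build_cycle(metabolites):
    model = Model(model_id="cycle", compartments=[Compartment("cell")])
    model.species = [Species(m, "cell") for m in metabolites]
    n = len(metabolites)
    model.reactions = [
        Reaction(f"R{i+1}",
                 reactants=[SpeciesReference(metabolites[i])],
                 products=[SpeciesReference(metabolites[(i + 1) % n])])
        for i in range(n)
    ]
    return sv.Document(model=model)


doc = build_cycle(["ACoA", "Cit", "aKG", "SucCoA", "OAA"])
sv.build_layout(doc, sv.LayoutParams(seed=2))

rids = [r.reaction_id for r in doc.model.reactions]
arc = sv.ArcSpec(center=Point(300.0, 300.0), radius=150.0)
sv.arrange_reactions_circle(doc, rids, arc)

for rid in rids:
    c = doc.layout.find_reaction_glyph_by_reaction(rid).center_bbox.center
    r = math.hypot(c.x - 300, c.y - 300)
    angle = math.degrees(math.atan2(c.x - 300, -(c.y - 300))) % 360
    print(f"{rid}: center ({c.x:7.2f}, {c.y:7.2f})  radius {r:.6f}  angle {angle:6.1f}°")
print("equal spacing:", 360 / len(rids), "° between consecutive reactions")
print("valid:", sv.validate_layout(doc) == [])
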