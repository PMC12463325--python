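"""Synthetic SBML model generation and a layout-timing harness.

Models keep a fixed species-to-reaction ratio (default 4:1) across sizes so
the benchmark series is comparable; reactions draw 1–2 reactants and 1–2
products without replacement from the species pool, giving a UniUni/BiBi mix
representative of biochemical models.  No kinetics are attached — layout
needs topology only.
"""

from __future__ import annotations

import statistics
import time
from dataclasses import dataclass

import numpy as np

from .autolayout import LayoutParams, build_layout
from .errors import ParameterError
from .types import Compartment, Document, Model, Reaction, Species, SpeciesReference

__all__ = ["SyntheticSpec", "BenchmarkRow", "generate_model", "run_benchmark"]


@dataclass
class SyntheticSpec:
    n_species: int = 20
    ratio: int = 4  # species per reaction
    seed: int = 0

    def validate(self) -> None:
        if self.ratio < 1:
            raise ParameterError("ratio must be ≥ 1")
        if self.n_species < self.ratio:
            raise ParameterError(
                f"n_species ({self.n_species}) must be ≥ ratio ({self.ratio})")

    @property
    def n_reactions(self) -> int:
        return self.n_species // self.ratio


@dataclass
class BenchmarkRow:
    n_species: int
    n_reactions: int
    median_seconds: float
    reps: int
    iterations: int


def generate_model(spec: SyntheticSpec) -> Document:
    """One compartment, `n_species` species, floor(n/ratio) reactions with
    participants drawn without replacement by the seeded generator."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    model = Model(model_id=f"synthetic_{spec.n_species}")
    model.compartments.append(Compartment(compartment_id="cell"))
    for i in range(1, spec.n_species + 1):
        model.species.append(Species(species_id=f"S{i}", compartment_id="cell"))
    n_rxn = spec.n_reactions
    for j in range(1, n_rxn + 1):
        n_react = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(spec.n_species, size=n_react + n_prod, replace=False)
        reactants = [SpeciesReference(f"S{int(p) + 1}") for p in picks[:n_react]]
        products = [SpeciesReference(f"S{int(p) + 1}") for p in picks[n_react:]]
        model.reactions.append(
            Reaction(reaction_id=f"R{j}", reactants=reactants, products=products)
        )
    return Document(model=model)


def run_benchmark(
    sizes: list[int],
    iterations: int = 50,
    reps: int = 10,
    seed: int = 0,
    ratio: int = 4,
) -> list[BenchmarkRow]:
    """Median wall-clock build_layout time per model size over `reps` runs.

    Timings are reported, never asserted — they are hardware-dependent.
    """
    if not sizes:
        raise ParameterError("sizes list is empty")
    rows = []
    for n in sizes:
        spec = SyntheticSpec(n_species=n, ratio=ratio, seed=seed)
        times = []
        for _ in range(max(reps, 1)):
            doc = generate_model(spec)
            params = LayoutParams(iterations=iterations, seed=seed)
            t0 = time.perf_counter()
            build_layout(doc, params)
            times.append(time.perf_counter() - t0)
        rows.append(
            BenchmarkRow(
                n_species=n,
                n_reactions=spec.n_reactions,
                median_seconds=statistics.median(times),
                reps=len(times),
                iterations=iterations,
            )
        )
    return rows
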