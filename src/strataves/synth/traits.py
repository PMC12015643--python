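"""Synthetic species trait tables with the five-category, 22-axis structure.

Categories mirror the avian trait compilations the pipeline consumes: ten
proportional diet axes, seven proportional foraging-stratum axes, three
continuous beak measurements, body mass, and hand-wing index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..traitspace import TraitTable

DIET_AXES = (
    "diet_inv", "diet_vend", "diet_vect", "diet_fish", "diet_vunk",
    "diet_scav", "diet_nect", "diet_fruit", "diet_seed", "diet_plant",
)
FORAGING_AXES = (
    "for_aerial", "for_canopy", "for_mid", "for_understory", "for_ground",
    "for_wataround", "for_watbelow",
)
BEAK_AXES = ("beak_length", "beak_width", "beak_depth")


def generate_traits(n_species: int, seed: int = 0, species=None) -> TraitTable:
    """Draw a 22-axis trait table for ``n_species`` species.

    Proportional categories are sparse Dirichlet draws (each species uses a
    few diet/foraging axes heavily); beak axes are correlated lognormals
    scaling with body mass; HWI is lognormal around typical passerine values.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    if species is None:
        species = [f"sp{i:03d}" for i in range(n_species)]
    species = pd.Index(species, name="species")

    diet = rng.dirichlet(np.full(len(DIET_AXES), 0.3), size=n_species)
    forage = rng.dirichlet(np.full(len(FORAGING_AXES), 0.4), size=n_species)
    log_mass = rng.normal(np.log(30.0), 1.0, size=n_species)
    beak_base = 0.35 * log_mass[:, None] + rng.normal(0.0, 0.25, size=(n_species, 1))
    beak = np.exp(beak_base + rng.normal(0.0, 0.15, size=(n_species, 3)) + np.log([2.0, 0.8, 0.9]))
    hwi = np.exp(rng.normal(np.log(25.0), 0.35, size=n_species))

    data = pd.DataFrame(
        np.column_stack([diet, forage, beak, np.exp(log_mass), hwi]),
        index=species,
        columns=list(DIET_AXES) + list(FORAGING_AXES) + list(BEAK_AXES) + ["mass", "hwi"],
    )
    categories = {a: "diet" for a in DIET_AXES}
    categories.update({a: "foraging" for a in FORAGING_AXES})
    categories.update({a: "beak" for a in BEAK_AXES})
    categories["mass"] = "mass"
    categories["hwi"] = "hwi"
    kinds = {a: "proportional" for a in list(DIET_AXES) + list(FORAGING_AXES)}
    kinds.update({a: "continuous" for a in list(BEAK_AXES) + ["mass", "hwi"]})
    return TraitTable(data=data, categories=categories, kinds=kinds)
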