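"""Ultrametric Yule (pure-birth) phylogenies for synthetic communities."""

from __future__ import annotations

import random

import dendropy
from dendropy.simulate import treesim


def generate_tree(
    n_species: int,
    seed: int = 0,
    birth_rate: float = 1.0,
    species=None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """One ultrametric Yule tree with ``n_species`` extant tips.

    Tip labels follow the synthetic species ids (``sp000`` ...) unless an
    explicit label list is given.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if species is None:
        species = [f"sp{i:03d}" for i in range(n_species)]
    if len(species) != n_species:
        raise ValueError("species label count must match n_species")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace(list(species))
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label if n.taxon else "")
    for leaf, label in zip(leaves, species):
        taxon = tns.get_taxon(label)
        if taxon is None:
            taxon = tns.new_taxon(label)
        leaf.taxon = taxon
    tree.taxon_namespace = tns
    tree.update_taxon_namespace()
    return tree


def generate_trees(n_species: int, n_trees: int, seed: int = 0, birth_rate: float = 1.0):
    """A posterior-sample stand-in: ``n_trees`` independent Yule trees."""
    tns = dendropy.TaxonNamespace([f"sp{i:03d}" for i in range(n_species)])
    return [
        generate_tree(n_species, seed=seed + 1000 * t, birth_rate=birth_rate, taxon_namespace=tns)
        for t in range(n_trees)
    ]
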