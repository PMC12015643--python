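"""One-config generation of every synthetic input the pipeline consumes.

A scenario bundles the survey design (plots nested in sites nested in
domains), one vegetation scene per plot, distance-binned counts simulated
from a known community, a trait table, a sample of Yule trees and a range
mask, and writes them all as plain-text artifacts (XYZ clouds, tidy CSV,
Newick, JSON truth record).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..habitat import STRATA
from .community import (
    CommunityTruth,
    SurveyDesign,
    counts_to_frame,
    generate_community,
    generate_counts,
)
from .ranges import generate_ranges
from .scene import SceneSpec, generate_scene
from .traits import generate_traits
from .trees import generate_trees


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study."""

    n_plots: int = 12
    n_species: int = 8
    n_sites: int = 4
    n_domains: int = 2
    n_observers: int = 3
    n_trees: int = 10
    scene_radius: float = 15.0
    survey_radius: float = 250.0
    n_bins: int = 10
    point_density: float = 4.0
    #: demo communities run abundant (lambda ~ e^1.5 per species) so that
    #: hull-based FD metrics are defined at nearly every plot
    hyper_mu: dict = field(default_factory=lambda: {"beta0": 1.5})
    hyper_sd: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**known)


def _plot_scene_spec(cfg: ScenarioConfig, plot_index: int) -> SceneSpec:
    """Deterministic per-plot variation in structure.

    Patch counts cycle with the plot index so every metric varies across
    plots; occupancies are seeded draws.
    """
    rng = np.random.default_rng(cfg.seed + 7919 * plot_index)
    occ = {s: float(rng.uniform(0.1, 0.5)) for s in STRATA}
    patches = {s: 1 + (plot_index + i) % 3 for i, s in enumerate(STRATA)}
    return SceneSpec(
        plot_radius=cfg.scene_radius,
        strata_occupancy=occ,
        patch_count_target=patches,
        point_density=cfg.point_density,
        seed=cfg.seed + 104729 * plot_index,
    )


def generate_scenario(cfg: ScenarioConfig, outdir) -> dict:
    """Generate and write every input; returns a path map."""
    outdir = Path(outdir)
    (outdir / "scenes").mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    design = SurveyDesign.generate(
        cfg.n_plots, cfg.n_sites, cfg.n_domains, cfg.n_observers, seed=cfg.seed
    )
    truth = generate_community(
        design, cfg.n_species, hyper_mu=cfg.hyper_mu or None,
        hyper_sd=cfg.hyper_sd or None, seed=cfg.seed + 1,
    )
    from ..distance_sampling import DistanceBinning

    binning = DistanceBinning.default(cfg.survey_radius, cfg.n_bins)
    counts = generate_counts(truth, binning, seed=cfg.seed + 2)

    covs_path = outdir / "covariates.csv"
    design.covariates.to_csv(covs_path)
    paths["covariates"] = str(covs_path)

    counts_path = outdir / "counts.csv"
    counts_to_frame(counts, design.plots, truth.species).to_csv(counts_path, index=False)
    paths["counts"] = str(counts_path)

    scene_paths = {}
    for j, plot in enumerate(design.plots):
        scene = generate_scene(_plot_scene_spec(cfg, j))
        p = outdir / "scenes" / f"{plot}.xyz"
        scene.cloud.to_xyz(p)
        scene_paths[plot] = str(p)
    paths["scenes"] = scene_paths

    traits = generate_traits(cfg.n_species, seed=cfg.seed + 3)
    traits.to_csv(outdir / "traits.csv")
    paths["traits"] = str(outdir / "traits.csv")

    trees = generate_trees(cfg.n_species, cfg.n_trees, seed=cfg.seed + 4)
    trees_path = outdir / "trees.nwk"
    with open(trees_path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick"))
    paths["trees"] = str(trees_path)

    mask = generate_ranges(
        truth.species, design.covariates["domain"], seed=cfg.seed + 5
    )
    mask.member.to_csv(outdir / "ranges_member.csv")
    paths["ranges_member"] = str(outdir / "ranges_member.csv")

    truth_rec = {
        "hyper_mu": truth.hyper_mu,
        "hyper_sd": truth.hyper_sd,
        "obs_eff": truth.obs_eff.tolist(),
        "coefs": truth.coefs.to_dict(),
        "binning_edges": binning.edges.tolist(),
        "seed": cfg.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_rec, fh, indent=1, sort_keys=True)
    paths["truth"] = str(outdir / "truth.json")
    return paths
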