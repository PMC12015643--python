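"""End-to-end orchestration: synth -> habitat -> abundance -> diversity -> models.

Every stage reads and writes plain files (XYZ, CSV, Newick, JSON), so stages
are independently testable and real data can be substituted for any
synthetic input.  A run manifest records the SHA-256 of every artifact, the
seeds, versions and per-stage wall time, enabling bit-exact replay checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import consensus, loo_compare
from .distance_sampling import DistanceBinning, HierarchicalDistanceSampling, postprocess
from .fd import fd_metrics, hull_volume
from .habitat import PointCloud, StructureMetrics, compute_metrics, normalize_height, voxelize
from .mixed import BayesianMixedModel, model_specs, standardize
from .nulls import build_nulls, ses
from .phylo import faith_pd, mpd, patristic_matrix
from .synth.community import counts_from_frame
from .synth.ranges import RangeMask
from .synth.scenario import ScenarioConfig, generate_scenario
from .traitspace import TraitTable, balance_weights, gower_distance, pcoa

log = logging.getLogger("strataves.pipeline")

STAGES = ("synth", "habitat", "abundance", "diversity", "models")

#: the ten diversity responses and their model families.
RESPONSES = {
    "SpRich": "poisson",
    "FRich_SES": "gaussian",
    "FEven": "beta",
    "FDiv": "gaussian",
    "PC1": "gaussian",
    "PC2": "gaussian",
    "PC3": "gaussian",
    "PC4": "gaussian",
    "FPD_SES": "gaussian",
    "MPD_SES": "gaussian",
}


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    output_dir: str
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seed: int = 0
    mcmc_draws: int = 400
    mcmc_warmup: int = 400
    mcmc_chains: int = 2
    n_null: int = 30
    gower_iters: int = 60
    threshold: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scen = ScenarioConfig(**raw.pop("scenario", {}))
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        if "output_dir" not in raw:
            raise ValueError("config needs output_dir")
        return cls(scenario=scen, stages=stages, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_tree(paths: list[Path]) -> dict:
    return {str(p): _sha256(p) for p in sorted(paths)}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def validate(config: RunConfig) -> None:
    """Fail fast: every enabled stage's inputs must be resolvable.

    When an upstream stage is toggled off, its outputs must already exist;
    if a previous manifest is present, their hashes must match it (stale
    upstream artifacts are refused).
    """
    out = Path(config.output_dir)
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    requirements = {
        "habitat": [out / "inputs" / "covariates.csv"],
        "abundance": [out / "inputs" / "counts.csv", out / "inputs" / "covariates.csv"],
        "diversity": [out / "abundance" / "nhat.csv", out / "inputs" / "traits.csv"],
        "models": [out / "diversity.csv", out / "metrics.csv"],
    }
    manifest_path = out / "manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else None
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        produced_upstream = {
            "habitat": ["synth"], "abundance": ["synth"],
            "diversity": ["synth", "abundance"], "models": ["habitat", "diversity"],
        }.get(stage, [])
        for need in requirements.get(stage, []):
            if any(config.stages.get(u, True) for u in produced_upstream):
                continue  # a live upstream stage will produce it this run
            if not need.exists():
                raise StageError(stage, f"required input {need} missing and its stage disabled")
            if previous is not None:
                recorded = previous.get("hashes", {}).get(str(need))
                if recorded is not None and recorded != _sha256(need):
                    raise StageError(
                        stage, f"stale upstream artifact {need}: hash differs from manifest"
                    )


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the manifest."""
    validate(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "scenario_seed": config.scenario.seed,
        "stages": {},
        "hashes": {},
    }
    artifacts: list[Path] = []

    def timed(stage, fn):
        if not config.stages.get(stage, True):
            log.info("stage %s skipped", stage)
            return
        t0 = time.perf_counter()
        try:
            produced = fn()
        except StageError:
            raise
        except Exception as exc:  # halt with the stage name attached
            raise StageError(stage, str(exc)) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"seconds": round(dt, 3)}
        artifacts.extend(produced)
        log.info("stage %s done in %.2fs", stage, dt)

    timed("synth", lambda: _stage_synth(config, out))
    timed("habitat", lambda: _stage_habitat(config, out))
    timed("abundance", lambda: _stage_abundance(config, out))
    timed("diversity", lambda: _stage_diversity(config, out))
    timed("models", lambda: _stage_models(config, out))

    manifest["hashes"] = _hash_tree([p for p in artifacts if p.exists()])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# --------------------------------------------------------------------- #
def _stage_synth(config: RunConfig, out: Path) -> list[Path]:
    paths = generate_scenario(config.scenario, out / "inputs")
    flat = []
    for v in paths.values():
        if isinstance(v, dict):
            flat.extend(Path(x) for x in v.values())
        else:
            flat.append(Path(v))
    return flat


def _load_inputs(config: RunConfig, out: Path):
    covs = pd.read_csv(out / "inputs" / "covariates.csv", index_col=0)
    return covs


def _stage_habitat(config: RunConfig, out: Path) -> list[Path]:
    covs = _load_inputs(config, out)
    rows = {}
    for plot in covs.index:
        cloud = PointCloud.from_xyz(out / "inputs" / "scenes" / f"{plot}.xyz")
        norm = normalize_height(cloud)
        rows[plot] = compute_metrics(voxelize(norm)).as_series()
    metrics = pd.DataFrame(rows).T
    metrics.index.name = "plot"
    metrics.to_csv(out / "metrics.csv")
    return [out / "metrics.csv"]


def _stage_abundance(config: RunConfig, out: Path) -> list[Path]:
    covs = _load_inputs(config, out)
    counts_df = pd.read_csv(out / "inputs" / "counts.csv")
    species = sorted(counts_df["species"].unique())
    n_bins = int(counts_df["bin"].max()) + 1
    counts = counts_from_frame(counts_df, list(covs.index), species, n_bins)
    binning = DistanceBinning.default(config.scenario.survey_radius, n_bins)
    model = HierarchicalDistanceSampling(counts, covs, binning, species=species)
    res = model.fit(
        draws=config.mcmc_draws, warmup=config.mcmc_warmup,
        chains=config.mcmc_chains, seed=config.seed + 11,
    )
    adir = out / "abundance"
    adir.mkdir(exist_ok=True)
    res.nhat.to_csv(adir / "nhat.csv")
    res.summary().to_csv(adir / "hyper_summary.csv")
    with open(adir / "diagnostics.json", "w") as fh:
        json.dump(
            {"converged": res.converged, "parameters": res.diagnostics},
            fh, indent=1, sort_keys=True,
        )
    return [adir / "nhat.csv", adir / "hyper_summary.csv", adir / "diagnostics.json"]


def _load_ranges(out: Path, covs: pd.DataFrame) -> RangeMask:
    member = pd.read_csv(out / "inputs" / "ranges_member.csv", index_col=0).astype(bool)
    return RangeMask(member=member, domain_of_plot=covs["domain"])


def _stage_diversity(config: RunConfig, out: Path) -> list[Path]:
    covs = _load_inputs(config, out)
    nhat = pd.read_csv(out / "abundance" / "nhat.csv", index_col=0)
    ranges = _load_ranges(out, covs)
    abund = postprocess(nhat, ranges, config.threshold)

    traits = TraitTable.from_csv(out / "inputs" / "traits.csv")
    weights = balance_weights(traits, n_iter=config.gower_iters, seed=config.seed + 21)
    gd = gower_distance(traits, category_weights=weights)
    space = pcoa(gd)
    fdr = fd_metrics(space, abund)

    nulls = build_nulls(abund, ranges, n_null=config.n_null, seed=config.seed + 22)

    def frich_metric(members, w):
        if len(members) < 2:
            raise ValueError("FRich undefined below 2 species")
        return hull_volume(space.coords.loc[members].values)

    frich_ses = ses(frich_metric, abund, nulls)

    import dendropy

    trees = dendropy.TreeList.get(path=str(out / "inputs" / "trees.nwk"), schema="newick")
    pdms = [patristic_matrix(t) for t in trees]
    fpd_ses = ses(lambda m, w, t: faith_pd(t, m), abund, nulls, trees=list(trees))
    mpd_ses = ses(lambda m, w, d: mpd(d, m), abund, nulls, trees=pdms)

    div = fdr.table.copy()
    div["FRich_SES"] = frich_ses.table["ses"]
    div["FPD_SES"] = fpd_ses.table["ses"]
    div["MPD_SES"] = mpd_ses.table["ses"]
    div.to_csv(out / "diversity.csv")
    return [out / "diversity.csv"]


def _stage_models(config: RunConfig, out: Path) -> list[Path]:
    covs = _load_inputs(config, out)
    metrics = pd.read_csv(out / "metrics.csv", index_col=0)
    div = pd.read_csv(out / "diversity.csv", index_col=0)
    env = pd.DataFrame(
        {
            "TempRange": covs["temp_range"],
            "Elevation": covs["elevation"],
            "Latitude": covs["latitude"],
        }
    )
    design = pd.concat([env, metrics], axis=1)
    design_std, _ = standardize(design)
    data = pd.concat([design_std, div, covs[["site"]]], axis=1)

    produced = []
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    for response, family in RESPONSES.items():
        sub = data.dropna(subset=[response])
        if len(sub) < 4 or sub[response].nunique() < 2:
            log.warning("response %s: too few usable plots; skipped", response)
            continue
        fits = {}
        for k, spec in enumerate(model_specs(family)):
            model = BayesianMixedModel.from_spec(spec, sub, response)
            fits[spec.name] = model.fit(
                draws=config.mcmc_draws, warmup=config.mcmc_warmup,
                chains=config.mcmc_chains, seed=config.seed + 31 + 13 * k,
            )
        comp = loo_compare(fits)
        cons = consensus(fits, comp)
        comp.table.to_csv(mdir / f"loo_{response}.csv")
        cons.to_csv(mdir / f"consensus_{response}.csv")
        produced += [mdir / f"loo_{response}.csv", mdir / f"consensus_{response}.csv"]
    return produced
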