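"""Simulated bird communities under the hierarchical distance-sampling model.

Species-level abundance and detection coefficients are drawn from
community-level normal hyperdistributions; plot-level expected abundance
follows a log-linear Poisson model in elevation and latitude, and detection
follows a half-normal function of distance whose scale is log-linear in
cloud cover, air temperature, wind speed and observer identity — exactly the
model :class:`strataves.distance_sampling.HierarchicalDistanceSampling` fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: order of the seven hierarchical coefficients per species.
COEF_NAMES = ("beta0", "beta1_elev", "beta2_lat", "alpha0", "alpha1_cloud", "alpha2_temp", "alpha3_wind")

#: default community hypermeans/hyper-SDs.  The abundance intercept gives a
#: few individuals per plot for a typical species; the detection intercept
#: puts the half-normal scale near 110 m on a 250 m disc (log 110 ~ 4.7),
#: both with moderate among-species spread.
DEFAULT_HYPER_MU = {"beta0": 0.7, "beta1_elev": -0.3, "beta2_lat": -0.2,
                    "alpha0": 4.7, "alpha1_cloud": 0.0, "alpha2_temp": 0.1, "alpha3_wind": -0.1}
DEFAULT_HYPER_SD = {"beta0": 0.6, "beta1_elev": 0.3, "beta2_lat": 0.3,
                    "alpha0": 0.25, "alpha1_cloud": 0.1, "alpha2_temp": 0.1, "alpha3_wind": 0.1}


@dataclass
class SurveyDesign:
    """Per-plot survey and environmental covariates.

    ``covariates`` holds one row per plot: standardized cloud, airtemp, wind,
    elevation, latitude, temp_range; integer ``observer``; ``site`` and
    ``domain`` labels (sites nest within domains, plots within sites).
    """

    covariates: pd.DataFrame

    @property
    def n_plots(self) -> int:
        return len(self.covariates)

    @property
    def plots(self) -> pd.Index:
        return self.covariates.index

    @classmethod
    def generate(
        cls,
        n_plots: int,
        n_sites: int = 4,
        n_domains: int = 2,
        n_observers: int = 3,
        seed: int = 0,
    ) -> "SurveyDesign":
        if n_sites < n_domains:
            raise ValueError("need at least one site per domain")
        rng = np.random.default_rng(seed)

        def std(v):
            return (v - v.mean()) / v.std(ddof=0) if v.std(ddof=0) > 0 else v - v.mean()

        site_of_plot = rng.integers(0, n_sites, size=n_plots)
        # every domain gets at least one site
        domain_of_site = np.concatenate(
            [np.arange(n_domains), rng.integers(0, n_domains, size=n_sites - n_domains)]
        )
        df = pd.DataFrame(
            {
                "cloud": std(rng.normal(size=n_plots)),
                "airtemp": std(rng.normal(size=n_plots)),
                "wind": std(rng.normal(size=n_plots)),
                "elevation": std(rng.normal(size=n_plots)),
                "latitude": std(rng.normal(size=n_plots)),
                "temp_range": std(rng.normal(size=n_plots)),
                "observer": rng.integers(0, n_observers, size=n_plots),
                "site": [f"S{site_of_plot[j]:02d}" for j in range(n_plots)],
                "domain": [f"D{domain_of_site[site_of_plot[j]]:02d}" for j in range(n_plots)],
            },
            index=pd.Index([f"P{j:03d}" for j in range(n_plots)], name="plot"),
        )
        return cls(df)


@dataclass
class CommunityTruth:
    """Ground-truth parameters of a simulated community."""

    coefs: pd.DataFrame          # species x 7 coefficients
    obs_eff: np.ndarray          # per-observer detection effects
    hyper_mu: dict
    hyper_sd: dict
    design: SurveyDesign
    lam: pd.DataFrame = field(init=False)    # expected abundance, plot x species
    sigma: pd.DataFrame = field(init=False)  # detection scale (m), plot x species

    def __post_init__(self) -> None:
        c = self.design.covariates
        b = self.coefs
        log_lam = (
            b["beta0"].values[None, :]
            + np.outer(c["elevation"].values, b["beta1_elev"].values)
            + np.outer(c["latitude"].values, b["beta2_lat"].values)
        )
        log_sig = (
            b["alpha0"].values[None, :]
            + np.outer(c["cloud"].values, b["alpha1_cloud"].values)
            + np.outer(c["airtemp"].values, b["alpha2_temp"].values)
            + np.outer(c["wind"].values, b["alpha3_wind"].values)
            + self.obs_eff[c["observer"].values][:, None]
        )
        self.lam = pd.DataFrame(np.exp(log_lam), index=c.index, columns=b.index)
        self.sigma = pd.DataFrame(np.exp(log_sig), index=c.index, columns=b.index)

    @property
    def species(self) -> pd.Index:
        return self.coefs.index


def generate_community(
    design: SurveyDesign,
    n_species: int,
    hyper_mu: dict | None = None,
    hyper_sd: dict | None = None,
    obs_eff_sd: float = 0.1,
    seed: int = 0,
) -> CommunityTruth:
    """Draw species-level coefficients from the community hyperdistributions."""
    if n_species < 2:
        raise ValueError("a community needs at least 2 species")
    mu = dict(DEFAULT_HYPER_MU, **(hyper_mu or {}))
    sd = dict(DEFAULT_HYPER_SD, **(hyper_sd or {}))
    rng = np.random.default_rng(seed)
    species = pd.Index([f"sp{i:03d}" for i in range(n_species)], name="species")
    coefs = pd.DataFrame(
        {name: rng.normal(mu[name], sd[name], size=n_species) for name in COEF_NAMES},
        index=species,
    )
    n_obs = int(design.covariates["observer"].max()) + 1
    obs_eff = rng.normal(0.0, obs_eff_sd, size=n_obs)
    return CommunityTruth(coefs=coefs, obs_eff=obs_eff, hyper_mu=mu, hyper_sd=sd, design=design)


def generate_counts(
    truth: CommunityTruth,
    binning,
    seed: int = 0,
    return_truth_n: bool = False,
):
    """Simulate distance-binned counts for every plot x species.

    True abundance is Poisson(lambda); individuals are placed uniformly by
    area on the plot disc (radial density proportional to distance), each is
    detected with half-normal probability ``exp(-d^2 / (2 sigma^2))``, and
    survivors are tallied into the distance bins.  Returns a
    plot x species x bin integer array wrapped in a tidy DataFrame via
    :func:`counts_to_frame`, plus the latent abundance matrix on request.
    """
    edges = np.asarray(binning.edges, dtype=float)
    R = edges[-1]
    rng = np.random.default_rng(seed)
    J = truth.design.n_plots
    S = truth.species.size
    K = edges.size - 1
    counts = np.zeros((J, S, K), dtype=np.int64)
    true_n = rng.poisson(truth.lam.values)
    sig = truth.sigma.values
    for j in range(J):
        for s in range(S):
            n = true_n[j, s]
            if n == 0:
                continue
            r = R * np.sqrt(rng.random(n))
            detected = rng.random(n) < np.exp(-(r**2) / (2 * sig[j, s] ** 2))
            if detected.any():
                counts[j, s] += np.histogram(r[detected], bins=edges)[0]
    if return_truth_n:
        return counts, pd.DataFrame(true_n, index=truth.design.plots, columns=truth.species)
    return counts


def counts_to_frame(counts: np.ndarray, plots, species) -> pd.DataFrame:
    """Tidy (plot, species, bin, count) view of a counts array."""
    J, S, K = counts.shape
    rec = [
        (plots[j], species[s], k, int(counts[j, s, k]))
        for j in range(J)
        for s in range(S)
        for k in range(K)
    ]
    return pd.DataFrame(rec, columns=["plot", "species", "bin", "count"])


def counts_from_frame(df: pd.DataFrame, plots, species, n_bins: int) -> np.ndarray:
    counts = np.zeros((len(plots), len(species), n_bins), dtype=np.int64)
    pi = {p: j for j, p in enumerate(plots)}
    si = {s: i for i, s in enumerate(species)}
    for _, row in df.iterrows():
        counts[pi[row["plot"]], si[row["species"]], int(row["bin"])] = int(row["count"])
    return counts
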