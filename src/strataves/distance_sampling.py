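"""Bayesian hierarchical distance sampling with community hyperparameters.

The ecological process model is Poisson: ``N_js ~ Poisson(lambda_js)`` with
``log lambda_js = beta0_s + beta1_s * elevation_j + beta2_s * latitude_j``.
Detection declines with observer distance under a half-normal function
``g(d; sigma) = exp(-d^2 / (2 sigma^2))`` whose scale is log-linear in cloud
cover, air temperature, wind speed and observer identity.  Counts are
recorded in distance bins on a circular plot; with individuals uniform by
area, the thinning identity makes the binned counts independent Poissons
with mean ``lambda * pi_k``, which is the (default, marginalized) likelihood
the sampler uses.  Species-level coefficients are draws from community-level
normal hyperdistributions, borrowing strength for rare species.

The model/results pair follows the statsmodels convention:
``HierarchicalDistanceSampling(counts, covariates, binning).fit()`` returns a
:class:`DistanceSamplingResults` carrying posterior draws, diagnostics, a
``summary()`` table, and the detection-corrected abundance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .mcmc import adapt_log_scale, half_normal_logpdf, normal_logpdf, rhat_ess
from .synth.community import COEF_NAMES

_SQ2PI = 0.5 * np.log(2 * np.pi)


@dataclass
class DistanceBinning:
    """Distance bin edges (m) from zero to the plot radius."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 2 or self.edges[0] != 0 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must increase from 0 to the plot radius")

    @classmethod
    def default(cls, radius: float = 250.0, n_bins: int = 10) -> "DistanceBinning":
        """The survey default: 10 bins of 25 m on a 250 m disc."""
        return cls(np.linspace(0.0, radius, n_bins + 1))

    @property
    def radius(self) -> float:
        return float(self.edges[-1])

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


def detection_prob(sigma: float, a: float, b: float, dialect: str = "area") -> float:
    """Average half-normal detection probability over the bin [a, b).

    ``dialect="area"`` weights distances by the point-transect area density
    (2d on a disc), for which the integral has the closed form
    ``2 sigma^2 (exp(-a^2/2sigma^2) - exp(-b^2/2sigma^2)) / (b^2 - a^2)``;
    ``dialect="midpoint"`` evaluates g at the bin midpoint.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 <= a < b:
        raise ValueError("need 0 <= a < b")
    if dialect == "midpoint":
        m = 0.5 * (a + b)
        return float(np.exp(-(m**2) / (2 * sigma**2)))
    if dialect != "area":
        raise ValueError("dialect must be 'area' or 'midpoint'")
    # e^{-a^2/2s^2} - e^{-b^2/2s^2} written via expm1 for large-sigma stability
    diff = -np.exp(-(a**2) / (2 * sigma**2)) * np.expm1(-(b**2 - a**2) / (2 * sigma**2))
    return float(2 * sigma**2 * diff / (b**2 - a**2))


def bin_cell_probs(sigma: np.ndarray, binning: DistanceBinning, dialect: str = "area") -> np.ndarray:
    """pi_k: P(individual falls in bin k AND is detected), shape (..., K).

    For an individual uniform by area on the disc of radius R,
    ``pi_k = P(in bin k) * avg detection`` which in the area dialect is
    ``2 sigma^2 (e_a - e_b) / R^2``.
    """
    sigma = np.asarray(sigma, dtype=float)[..., None]
    edges = binning.edges
    R = binning.radius
    if dialect == "area":
        a2 = edges[:-1] ** 2
        b2 = edges[1:] ** 2
        diff = -np.exp(-a2 / (2 * sigma**2)) * np.expm1(-(b2 - a2) / (2 * sigma**2))
        return 2 * sigma[..., 0][..., None] ** 2 * diff / R**2
    mids = 0.5 * (edges[:-1] + edges[1:])
    g = np.exp(-(mids**2) / (2 * sigma**2))
    area_frac = np.diff(edges**2) / R**2
    return g * area_frac


@dataclass
class Priors:
    """Weakly informative defaults; the source analysis reports none."""

    hyper_mu_sd: float = 2.0       # Normal(0, .) on the 7 hypermeans
    hyper_sd_scale: float = 1.0    # half-Normal(0, .) on the 7 hyper-SDs
    obs_sd: float = 1.0            # Normal(0, .) on per-observer effects


def _linear_predictors(coefs: np.ndarray, obs_eff: np.ndarray, covs: pd.DataFrame):
    """(log lambda, log sigma), each (J, S)."""
    elev = covs["elevation"].values
    lat = covs["latitude"].values
    log_lam = (
        coefs[:, 0][None, :]
        + np.outer(elev, coefs[:, 1])
        + np.outer(lat, coefs[:, 2])
    )
    log_sig = (
        coefs[:, 3][None, :]
        + np.outer(covs["cloud"].values, coefs[:, 4])
        + np.outer(covs["airtemp"].values, coefs[:, 5])
        + np.outer(covs["wind"].values, coefs[:, 6])
        + obs_eff[covs["observer"].values.astype(int)][:, None]
    )
    return log_lam, log_sig


def log_likelihood(
    coefs: np.ndarray,
    obs_eff: np.ndarray,
    counts: np.ndarray,
    covariates: pd.DataFrame,
    binning: DistanceBinning,
    dialect: str = "area",
    marginalize: bool = True,
    n_max: int = 200,
    per_species: bool = False,
):
    """Joint log-likelihood of the binned counts.

    ``marginalize=True`` uses the Poisson-thinning identity (binned counts
    independent Poisson with mean ``lambda * pi_k``); ``marginalize=False``
    sums the latent abundance N explicitly up to ``n_max`` (exact for
    ``n_max`` large; the two agree, which the tests exploit).
    """
    if not np.all(np.isfinite(covariates.select_dtypes(float).values)):
        raise ValueError("covariates must be finite")
    coefs = np.asarray(coefs, dtype=float)
    log_lam, log_sig = _linear_predictors(coefs, np.asarray(obs_eff, float), covariates)
    lam = np.exp(log_lam)
    pi = bin_cell_probs(np.exp(log_sig), binning, dialect)  # (J,S,K)
    C = counts
    if marginalize:
        mean = lam[..., None] * pi
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(C > 0, C * np.log(mean), 0.0) - mean - gammaln(C + 1)
        per_s = terms.sum(axis=(0, 2))
    else:
        per_s = np.zeros(C.shape[1])
        for s in range(C.shape[1]):
            tot = 0.0
            for j in range(C.shape[0]):
                tot += _latent_logpmf(C[j, s], lam[j, s], pi[j, s], n_max)
            per_s[s] = tot
    return per_s if per_species else float(per_s.sum())


def _latent_logpmf(c: np.ndarray, lam: float, pi: np.ndarray, n_max: int) -> float:
    """Brute-force P(C) = sum_N Poisson(N; lam) Multinomial(C | N, pi)."""
    c_tot = int(c.sum())
    pi_tot = pi.sum()
    ns = np.arange(c_tot, n_max + 1)
    if lam > 0:
        log_pois = -lam + ns * np.log(lam) - gammaln(ns + 1)
    else:
        log_pois = np.where(ns == 0, 0.0, -np.inf)
    log_bins = (np.where(c > 0, c * np.log(pi), 0.0)).sum()
    if pi_tot < 1:
        log_multi = (
            gammaln(ns + 1)
            - gammaln(c + 1).sum()
            - gammaln(ns - c_tot + 1)
            + log_bins
            + (ns - c_tot) * np.log1p(-pi_tot)
        )
    else:  # perfect detection: only N == c_tot contributes
        log_multi = np.where(
            ns == c_tot, gammaln(ns + 1) - gammaln(c + 1).sum() + log_bins, -np.inf
        )
    m = log_pois + log_multi
    mx = m.max()
    return float(mx + np.log(np.exp(m - mx).sum()))


@dataclass
class AbundanceMatrix:
    """Detection-corrected, range-filtered, thresholded abundances."""

    nhat: pd.DataFrame       # plot x species
    presence: pd.DataFrame   # plot x species, bool
    threshold: float = 0.95


def postprocess(nhat: pd.DataFrame, ranges, threshold: float = 0.95) -> AbundanceMatrix:
    """Apply the range filter and the presence threshold to posterior N-hat.

    Species outside a plot's domain pool are set to zero; estimates below
    ``threshold`` (default 0.95) are treated as absences and zeroed; the
    presence flag is ``nhat >= threshold``.  Filter and threshold commute.
    """
    missing = set(nhat.columns) - set(ranges.species)
    if missing:
        raise ValueError(f"species missing from range mask: {sorted(missing)}")
    allowed = ranges.allowed(nhat.index)[nhat.columns]
    filtered = nhat.where(allowed, 0.0)
    filtered = filtered.where(filtered >= threshold, 0.0)
    return AbundanceMatrix(filtered, filtered >= threshold, threshold)


_HYPER_NAMES = [f"mu_{n}" for n in COEF_NAMES] + [f"sd_{n}" for n in COEF_NAMES]


class HierarchicalDistanceSampling:
    """Model object for the community distance-sampling fit.

    Parameters
    ----------
    counts
        Integer array (n_plots, n_species, n_bins).
    covariates
        Per-plot frame with standardized ``cloud, airtemp, wind, elevation,
        latitude`` and integer ``observer``.
    binning
        The distance bins; their last edge is the plot radius over which
        abundance is expressed.
    dialect
        "area" (default) or "midpoint" bin detection probabilities.
    """

    def __init__(
        self,
        counts: np.ndarray,
        covariates: pd.DataFrame,
        binning: DistanceBinning,
        species=None,
        dialect: str = "area",
        priors: Priors | None = None,
    ):
        counts = np.asarray(counts)
        if counts.ndim != 3:
            raise ValueError("counts must be (plots, species, bins)")
        if counts.shape[1] < 2:
            raise ValueError("community hyperparameters need >= 2 species")
        if counts.shape[0] != len(covariates):
            raise ValueError("counts and covariates disagree on plot count")
        if counts.shape[2] != binning.n_bins:
            raise ValueError("counts and binning disagree on bin count")
        self.counts = counts.astype(np.int64)
        self.covariates = covariates
        self.binning = binning
        self.dialect = dialect
        self.priors = priors or Priors()
        self.species = (
            pd.Index(species)
            if species is not None
            else pd.Index([f"sp{i:03d}" for i in range(counts.shape[1])], name="species")
        )
        self.plots = covariates.index
        self.n_observers = int(covariates["observer"].max()) + 1

    # -- the per-species marginal likelihood used by every MH block
    def _loglik_species(self, coefs, obs_eff):
        return log_likelihood(
            coefs, obs_eff, self.counts, self.covariates, self.binning,
            self.dialect, per_species=True,
        )

    def _loglik_plot(self, coefs, obs_eff):
        log_lam, log_sig = _linear_predictors(coefs, obs_eff, self.covariates)
        lam = np.exp(log_lam)
        pi = bin_cell_probs(np.exp(log_sig), self.binning, self.dialect)
        mean = lam[..., None] * pi
        C = self.counts
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(C > 0, C * np.log(mean), 0.0) - mean - gammaln(C + 1)
        return terms.sum(axis=(1, 2))

    def fit(
        self,
        draws: int = 1000,
        warmup: int = 1000,
        chains: int = 2,
        seed: int = 0,
        progress: bool = False,
    ) -> "DistanceSamplingResults":
        """Run the adaptive Metropolis-within-Gibbs sampler."""
        chain_hyper = []
        chain_nhat = []
        chain_theta = []
        for c in range(chains):
            h, nh, th = self._run_chain(draws, warmup, seed + 1000003 * c + c)
            chain_hyper.append(h)
            chain_nhat.append(nh)
            chain_theta.append(th)
        hyper = np.stack(chain_hyper)            # (chains, draws, 14)
        nhat = np.mean(chain_nhat, axis=0)       # (J, S)
        theta = np.concatenate(chain_theta)      # (chains*draws_thin, S, 7)
        diagnostics = {}
        for i, name in enumerate(_HYPER_NAMES):
            r, e = rhat_ess(hyper[:, :, i])
            diagnostics[name] = {"rhat": r, "ess": e}
        max_rhat = max(v["rhat"] for v in diagnostics.values())
        converged = bool(max_rhat < 1.05)
        if not converged:
            warnings.warn(
                f"MCMC convergence suspect: max R-hat {max_rhat:.3f}", stacklevel=2
            )
        return DistanceSamplingResults(
            model=self,
            hyper_draws=hyper,
            theta_draws=theta,
            nhat=pd.DataFrame(nhat, index=self.plots, columns=self.species),
            diagnostics=diagnostics,
            converged=converged,
        )

    def _run_chain(self, draws, warmup, seed):
        rng = np.random.default_rng(seed)
        J, S, K = self.counts.shape
        pr = self.priors
        # initialize near the data: total counts give a crude abundance scale
        tot = self.counts.sum(axis=2)
        theta = np.zeros((S, 7))
        theta[:, 0] = np.log(np.maximum(tot.mean(axis=0), 0.5))
        theta[:, 3] = np.log(self.binning.radius / 3.0)
        theta += rng.normal(0, 0.1, theta.shape)
        mu = theta.mean(axis=0)
        tau = np.maximum(theta.std(axis=0), 0.1)
        obs = np.zeros(self.n_observers)

        log_scale_theta = np.full((S, 7), np.log(0.1))
        log_scale_tau = np.full(7, np.log(0.3))
        log_scale_obs = np.log(0.05)
        acc_theta = np.zeros((S, 7))
        acc_tau = np.zeros(7)
        acc_obs = 0.0
        window = 25

        ll_s = self._loglik_species(theta, obs)
        obs_idx = self.covariates["observer"].values.astype(int)
        c_tot = tot.astype(float)

        hyper_out = np.empty((draws, 14))
        nhat_sum = np.zeros((J, S))
        thin = max(1, draws // 200)
        theta_out = []

        for it in range(warmup + draws):
            # --- species coefficients: column-wise proposals, accepted
            # per species (the likelihood factorizes over species)
            for mcol in range(7):
                prop = theta.copy()
                prop[:, mcol] = theta[:, mcol] + np.exp(log_scale_theta[:, mcol]) * rng.normal(size=S)
                ll_prop = self._loglik_species(prop, obs)
                d_lp = normal_logpdf(prop[:, mcol], mu[mcol], tau[mcol]) - normal_logpdf(
                    theta[:, mcol], mu[mcol], tau[mcol]
                )
                accept = np.log(rng.random(S)) < (ll_prop - ll_s + d_lp)
                theta[accept, mcol] = prop[accept, mcol]
                ll_s[accept] = ll_prop[accept]
                acc_theta[accept, mcol] += 1

            # --- hypermeans: conjugate normal draw
            prec = S / tau**2 + 1.0 / pr.hyper_mu_sd**2
            mean = (theta.sum(axis=0) / tau**2) / prec
            mu = mean + rng.normal(size=7) / np.sqrt(prec)

            # --- hyper-SDs: MH on log tau
            for m in range(7):
                lt_prop = np.log(tau[m]) + np.exp(log_scale_tau[m]) * rng.normal()
                t_prop = np.exp(lt_prop)
                cur = (
                    normal_logpdf(theta[:, m], mu[m], tau[m]).sum()
                    + half_normal_logpdf(tau[m], pr.hyper_sd_scale)
                    + np.log(tau[m])
                )
                new = (
                    normal_logpdf(theta[:, m], mu[m], t_prop).sum()
                    + half_normal_logpdf(t_prop, pr.hyper_sd_scale)
                    + lt_prop
                )
                if np.log(rng.random()) < new - cur:
                    tau[m] = t_prop
                    acc_tau[m] += 1

            # --- observer effects: per-observer MH (plots partition by observer)
            if self.n_observers > 1:
                prop_obs = obs + np.exp(log_scale_obs) * rng.normal(size=self.n_observers)
                llp_cur = self._loglik_plot(theta, obs)
                llp_prop = self._loglik_plot(theta, prop_obs)
                for o in range(self.n_observers):
                    sel = obs_idx == o
                    d_ll = llp_prop[sel].sum() - llp_cur[sel].sum()
                    d_lp = (
                        normal_logpdf(prop_obs[o], 0.0, pr.obs_sd)
                        - normal_logpdf(obs[o], 0.0, pr.obs_sd)
                    )
                    if np.log(rng.random()) < d_ll + d_lp:
                        obs[o] = prop_obs[o]
                        acc_obs += 1.0 / self.n_observers
                ll_s = self._loglik_species(theta, obs)

            # --- warmup adaptation
            if it < warmup and (it + 1) % window == 0:
                log_scale_theta = adapt_log_scale(log_scale_theta, acc_theta / window, it)
                log_scale_tau = adapt_log_scale(log_scale_tau, acc_tau / window, it)
                log_scale_obs = adapt_log_scale(log_scale_obs, acc_obs / window, it)
                acc_theta[:] = 0
                acc_tau[:] = 0
                acc_obs = 0.0

            if it >= warmup:
                d = it - warmup
                hyper_out[d, :7] = mu
                hyper_out[d, 7:] = tau
                log_lam, log_sig = _linear_predictors(theta, obs, self.covariates)
                lam = np.exp(log_lam)
                pi_tot = bin_cell_probs(np.exp(log_sig), self.binning, self.dialect).sum(-1)
                nhat_sum += c_tot + lam * (1.0 - pi_tot)
                if d % thin == 0:
                    theta_out.append(theta.copy())

        return hyper_out, nhat_sum / draws, np.array(theta_out)


@dataclass
class DistanceSamplingResults:
    """Posterior summaries of a hierarchical distance-sampling fit.

    ``nhat`` is the posterior-mean abundance on the plot disc per plot and
    species: the observed total plus the posterior mean of the undetected
    Poisson mass ``lambda * (1 - sum_k pi_k)``.
    """

    model: HierarchicalDistanceSampling
    hyper_draws: np.ndarray      # (chains, draws, 14): 7 hypermeans then 7 hyper-SDs
    theta_draws: np.ndarray      # thinned species-level coefficient draws
    nhat: pd.DataFrame
    diagnostics: dict
    converged: bool

    def hyper_posterior(self) -> pd.DataFrame:
        flat = self.hyper_draws.reshape(-1, len(_HYPER_NAMES))
        return pd.DataFrame(flat, columns=_HYPER_NAMES)

    def summary(self, ci: float = 0.90) -> pd.DataFrame:
        """Posterior table for the community hyperparameters."""
        post = self.hyper_posterior()
        lo = (1 - ci) / 2
        out = pd.DataFrame(
            {
                "mean": post.mean(),
                "sd": post.std(ddof=1),
                f"q{lo:.3f}": post.quantile(lo),
                f"q{1-lo:.3f}": post.quantile(1 - lo),
                "rhat": [self.diagnostics[n]["rhat"] for n in post.columns],
                "ess": [self.diagnostics[n]["ess"] for n in post.columns],
            }
        )
        out.index.name = "parameter"
        return out

    def hyper_interval(self, name: str, ci: float = 0.90) -> tuple[float, float]:
        post = self.hyper_posterior()[name]
        lo = (1 - ci) / 2
        return float(post.quantile(lo)), float(post.quantile(1 - lo))

    def postprocess(self, ranges, threshold: float = 0.95) -> AbundanceMatrix:
        """Range-filter and threshold the posterior-mean abundances."""
        return postprocess(self.nhat, ranges, threshold)
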