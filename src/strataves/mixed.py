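"""Bayesian mixed-effects models for the diversity responses.

Each diversity index is modelled as ``F(y_i) = alpha + sum_k beta_k x_ik +
u_site(i)`` with site random intercepts ``u ~ Normal(0, tau^2)``, under a
Poisson family for species richness (log link), a Beta family for
functional evenness (logit mean link with precision), and Gaussian for
everything else.  Twelve candidate models — fixed combinations of habitat
composition, habitat configuration and environmental covariates — encode
competing hypotheses and are compared by PSIS-LOO (:mod:`strataves.compare`).

Gaussian fits use conjugate Gibbs draws for the location parameters with
Metropolis steps for the scales; Poisson and Beta fits use adaptive
random-walk Metropolis throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .mcmc import adapt_log_scale, half_normal_logpdf, normal_logpdf, rhat_ess

#: the covariate vocabulary of the model table.
COVARIATES = (
    "TempRange", "Elevation", "Latitude",
    "Total_A", "Can_A", "Sub_A", "Mid_A", "Und_A",
    "Total_C", "Can_C", "Sub_C", "Mid_C", "Und_C", "Vert_V",
)

_ENV = ["TempRange", "Elevation", "Latitude"]
_COMP = ["Can_A", "Sub_A", "Mid_A", "Und_A"]
_CONF = ["Total_C", "Can_C", "Sub_C", "Mid_C", "Und_C"]

#: the 12 candidate models (name -> covariate list).
MODEL_TABLE: dict[str, list[str]] = {
    "Full": _ENV + ["Total_A"] + _COMP + _CONF + ["Vert_V"],
    "Full_minusTotVol": _ENV + _COMP + _CONF + ["Vert_V"],
    "Structure": _COMP + _CONF + ["Vert_V"],
    "Configuration": _CONF + ["Vert_V"],
    "Configuration_env": _ENV + _CONF + ["Vert_V"],
    "Composition": list(_COMP),
    "Composition_env": _ENV + _COMP,
    "Horizontal": _COMP + _CONF[1:],
    "Horizontal_env": _ENV + _COMP + _CONF[1:],
    "Amount": _ENV + ["Total_A"],
    "Vertical": _ENV + ["Total_A", "Vert_V"],
    "Climate": list(_ENV),
}


def standardize(design: pd.DataFrame):
    """Center and scale every column to mean 0, sd 1.

    Returns the standardized frame and a parameter frame (mean, sd) enabling
    exact back-transformation.  A zero-variance covariate is an error.
    """
    mu = design.mean()
    sd = design.std(ddof=0)
    zero = sd.index[sd.values == 0]
    if len(zero):
        raise ValueError(f"zero-variance covariates: {list(zero)}")
    out = (design - mu) / sd
    params = pd.DataFrame({"mean": mu, "sd": sd})
    return out, params


def unstandardize(design_std: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    return design_std * params["sd"] + params["mean"]


def correlation_report(design: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pre-flight multicollinearity screen: pairs with |r| >= threshold."""
    corr = design.corr()
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                rows.append((a, b, float(r)))
    return pd.DataFrame(rows, columns=["var1", "var2", "r"])


@dataclass
class ModelSpec:
    """One candidate model: a named covariate combination."""

    name: str
    covariates: list
    family: str = "gaussian"
    group: str = "site"

    def __post_init__(self) -> None:
        bad = set(self.covariates) - set(COVARIATES)
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")
        if self.family not in ("gaussian", "poisson", "beta"):
            raise ValueError("family must be gaussian, poisson or beta")


def model_specs(family: str = "gaussian", names=None) -> list[ModelSpec]:
    """The 12 table models as specs for one response family."""
    names = list(MODEL_TABLE) if names is None else list(names)
    return [ModelSpec(n, list(MODEL_TABLE[n]), family) for n in names]


@dataclass
class MixedPriors:
    intercept_sd: float = 5.0
    slope_sd: float = 2.0
    tau_scale: float = 2.0       # half-Normal on the random-intercept SD
    sigma_scale: float = 2.0     # half-Normal on the Gaussian residual SD
    phi_shape: float = 2.0       # Gamma on the Beta precision
    phi_rate: float = 0.1


class BayesianMixedModel:
    """Model object: response + design + family + grouping.

    Use :meth:`from_dataframe` to build from a tidy frame; ``fit`` returns a
    :class:`MixedModelResults`.
    """

    def __init__(self, endog, exog: pd.DataFrame, family: str, groups, priors=None, name=""):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.family = family
        self.name = name
        self.priors = priors or MixedPriors()
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_idx = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        n = self.endog.size
        if len(exog) != n or len(self.group_idx) != n:
            raise ValueError("response, design and groups must align")
        y = self.endog
        if family == "poisson":
            if np.any(y < 0) or np.any(y != np.round(y)):
                raise ValueError("Poisson family needs non-negative integer counts")
        elif family == "beta":
            if np.any(y < 0) or np.any(y > 1):
                raise ValueError("Beta family needs responses in [0, 1]")
            if np.any(y <= 0) or np.any(y >= 1):
                # boundary squeeze: y' = (y (n-1) + 1/2) / n
                self.endog = (y * (n - 1) + 0.5) / n
        elif family == "gaussian":
            if not np.all(np.isfinite(y)):
                raise ValueError("Gaussian family needs finite responses")
        else:
            raise ValueError(f"unknown family {family!r}")
        self.X = np.column_stack([np.ones(n), exog.values.astype(float)])
        self.coef_names = ["Intercept"] + list(exog.columns)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, covariates, family: str,
        group: str = "site", priors=None, name="",
    ) -> "BayesianMixedModel":
        missing = [c for c in [response, group, *covariates] if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        return cls(
            data[response].values, data[list(covariates)], family, data[group].values,
            priors=priors, name=name or response,
        )

    @classmethod
    def from_spec(cls, spec: ModelSpec, data: pd.DataFrame, response: str, priors=None):
        m = cls.from_dataframe(
            data, response, spec.covariates, spec.family, group=spec.group,
            priors=priors, name=spec.name,
        )
        return m

    # ------------------------------------------------------------------ #
    def _pointwise(self, eta, extra):
        """Pointwise log-likelihood given the linear predictor."""
        y = self.endog
        if self.family == "gaussian":
            sigma = extra["sigma"]
            return normal_logpdf(y, eta, sigma)
        if self.family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            return y * np.log(mu) - mu - gammaln(y + 1)
        phi = extra["phi"]
        m = expit(eta)
        a = np.clip(m * phi, 1e-8, None)
        b = np.clip((1 - m) * phi, 1e-8, None)
        return (
            gammaln(a + b) - gammaln(a) - gammaln(b)
            + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
        )

    def fit(self, draws: int = 1000, warmup: int = 1000, chains: int = 2, seed: int = 0):
        """Sample the posterior and return a results object."""
        store = [self._run_chain(draws, warmup, seed + 99991 * c + c) for c in range(chains)]
        coef = np.stack([s["coef"] for s in store])          # (chains, draws, p)
        tau = np.stack([s["tau"] for s in store])
        u = np.stack([s["u"] for s in store])
        ll = np.stack([s["loglik"] for s in store])          # (chains, draws, n)
        scales = {k: np.stack([s[k] for s in store]) for k in ("sigma", "phi") if k in store[0]}
        diagnostics = {}
        for i, nm in enumerate(self.coef_names):
            r, e = rhat_ess(coef[:, :, i])
            diagnostics[nm] = {"rhat": r, "ess": e}
        r, e = rhat_ess(tau)
        diagnostics["tau_site"] = {"rhat": r, "ess": e}
        max_rhat = max(v["rhat"] for v in diagnostics.values())
        converged = bool(max_rhat < 1.05)
        if not converged:
            warnings.warn(f"{self.name}: max R-hat {max_rhat:.3f}", stacklevel=2)
        return MixedModelResults(
            model=self, coef_draws=coef, tau_draws=tau, u_draws=u,
            scale_draws=scales, loglik=ll, diagnostics=diagnostics, converged=converged,
        )

    def _run_chain(self, draws, warmup, seed):
        rng = np.random.default_rng(seed)
        n, p = self.X.shape
        pr = self.priors
        G = self.n_groups
        gi = self.group_idx
        y = self.endog
        X = self.X
        prior_sd = np.array([pr.intercept_sd] + [pr.slope_sd] * (p - 1))

        coef = np.zeros(p)
        if self.family == "gaussian":
            coef[0] = y.mean()
        elif self.family == "poisson":
            coef[0] = np.log(max(y.mean(), 0.1))
        else:
            coef[0] = np.log(y.mean() / (1 - y.mean()))
        u = np.zeros(G)
        tau = 0.5
        sigma = max(y.std(), 0.1) if self.family == "gaussian" else None
        phi = 10.0 if self.family == "beta" else None

        ls_coef = np.full(p, np.log(0.1))
        ls_u = np.log(0.1)
        ls_scale = np.log(0.2)
        acc_coef = np.zeros(p)
        acc_u = 0.0
        acc_scale = 0.0
        window = 25

        out = {
            "coef": np.empty((draws, p)),
            "tau": np.empty(draws),
            "u": np.empty((draws, G)),
            "loglik": np.empty((draws, n)),
        }
        if sigma is not None:
            out["sigma"] = np.empty(draws)
        if phi is not None:
            out["phi"] = np.empty(draws)

        def extra():
            d = {}
            if sigma is not None:
                d["sigma"] = sigma
            if phi is not None:
                d["phi"] = phi
            return d

        for it in range(warmup + draws):
            if self.family == "gaussian":
                # conjugate joint draw of (intercept, slopes)
                resid = y - u[gi]
                prec = X.T @ X / sigma**2 + np.diag(1.0 / prior_sd**2)
                mean = np.linalg.solve(prec, X.T @ resid / sigma**2)
                L = np.linalg.cholesky(np.linalg.inv(prec))
                coef = mean + L @ rng.normal(size=p)
                # conjugate site intercepts
                res2 = y - X @ coef
                for g in range(G):
                    sel = gi == g
                    pg = sel.sum() / sigma**2 + 1.0 / tau**2
                    mg = res2[sel].sum() / sigma**2 / pg
                    u[g] = mg + rng.normal() / np.sqrt(pg)
                # residual scale: MH on log sigma
                eta = X @ coef + u[gi]
                for _ in range(1):
                    lsp = np.log(sigma) + np.exp(ls_scale) * rng.normal()
                    sp = np.exp(lsp)
                    cur = normal_logpdf(y, eta, sigma).sum() + half_normal_logpdf(sigma, pr.sigma_scale) + np.log(sigma)
                    new = normal_logpdf(y, eta, sp).sum() + half_normal_logpdf(sp, pr.sigma_scale) + lsp
                    if np.log(rng.random()) < new - cur:
                        sigma = sp
                        acc_scale += 1
            else:
                eta = X @ coef + u[gi]
                ll_cur = self._pointwise(eta, extra()).sum()
                # componentwise coefficient updates
                for k in range(p):
                    prop = coef.copy()
                    prop[k] += np.exp(ls_coef[k]) * rng.normal()
                    eta_p = X @ prop + u[gi]
                    ll_p = self._pointwise(eta_p, extra()).sum()
                    d_lp = (
                        normal_logpdf(prop[k], 0.0, prior_sd[k])
                        - normal_logpdf(coef[k], 0.0, prior_sd[k])
                    )
                    if np.log(rng.random()) < ll_p - ll_cur + d_lp:
                        coef = prop
                        ll_cur = ll_p
                        acc_coef[k] += 1
                # per-site intercept updates (sites partition the data)
                eta = X @ coef + u[gi]
                pw_cur = self._pointwise(eta, extra())
                u_prop = u + np.exp(ls_u) * rng.normal(size=G)
                pw_prop = self._pointwise(X @ coef + u_prop[gi], extra())
                for g in range(G):
                    sel = gi == g
                    d_ll = pw_prop[sel].sum() - pw_cur[sel].sum()
                    d_lp = normal_logpdf(u_prop[g], 0, tau) - normal_logpdf(u[g], 0, tau)
                    if np.log(rng.random()) < d_ll + d_lp:
                        u[g] = u_prop[g]
                        acc_u += 1.0 / G
                if phi is not None:
                    eta = X @ coef + u[gi]
                    lpp = np.log(phi) + np.exp(ls_scale) * rng.normal()
                    pp = np.exp(lpp)
                    def phi_post(ph, lph):
                        return (
                            self._pointwise(eta, {"phi": ph}).sum()
                            + (pr.phi_shape - 1) * lph - pr.phi_rate * ph + lph
                        )
                    if np.log(rng.random()) < phi_post(pp, lpp) - phi_post(phi, np.log(phi)):
                        phi = pp
                        acc_scale += 1

            # random-intercept SD: MH on log tau (conditional on u only)
            ltp = np.log(tau) + 0.3 * rng.normal()
            tp = np.exp(ltp)
            cur = normal_logpdf(u, 0, tau).sum() + half_normal_logpdf(tau, pr.tau_scale) + np.log(tau)
            new = normal_logpdf(u, 0, tp).sum() + half_normal_logpdf(tp, pr.tau_scale) + ltp
            if np.log(rng.random()) < new - cur:
                tau = tp

            if it < warmup and (it + 1) % window == 0:
                ls_coef = adapt_log_scale(ls_coef, acc_coef / window, it)
                ls_u = adapt_log_scale(ls_u, acc_u / window, it)
                ls_scale = adapt_log_scale(ls_scale, acc_scale / window, it)
                acc_coef[:] = 0
                acc_u = 0.0
                acc_scale = 0.0

            if it >= warmup:
                d = it - warmup
                out["coef"][d] = coef
                out["tau"][d] = tau
                out["u"][d] = u
                if sigma is not None:
                    out["sigma"][d] = sigma
                if phi is not None:
                    out["phi"][d] = phi
                out["loglik"][d] = self._pointwise(X @ coef + u[gi], extra())
        return out


@dataclass
class MixedModelResults:
    """Posterior draws, diagnostics and pointwise log-likelihood."""

    model: BayesianMixedModel
    coef_draws: np.ndarray       # (chains, draws, p)
    tau_draws: np.ndarray        # (chains, draws)
    u_draws: np.ndarray          # (chains, draws, G)
    scale_draws: dict
    loglik: np.ndarray           # (chains, draws, n)
    diagnostics: dict
    converged: bool

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def coef_names(self) -> list:
        return self.model.coef_names

    def coef_flat(self) -> pd.DataFrame:
        c = self.coef_draws.reshape(-1, self.coef_draws.shape[-1])
        return pd.DataFrame(c, columns=self.coef_names)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        d = self.coef_flat()[name]
        lo = (1 - level) / 2
        return float(d.quantile(lo)), float(d.quantile(1 - lo))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        post = self.coef_flat()
        lo = (1 - level) / 2
        tab = pd.DataFrame(
            {
                "mean": post.mean(),
                "sd": post.std(ddof=1),
                f"q{lo:g}": post.quantile(lo),
                f"q{1-lo:g}": post.quantile(1 - lo),
                "rhat": [self.diagnostics[n]["rhat"] for n in post.columns],
            }
        )
        tau = self.tau_draws.reshape(-1)
        tab.loc["tau_site"] = [
            tau.mean(), tau.std(ddof=1), np.quantile(tau, lo), np.quantile(tau, 1 - lo),
            self.diagnostics["tau_site"]["rhat"],
        ]
        tab.index.name = "parameter"
        return tab

    def to_inference_data(self):
        """arviz InferenceData with the log_likelihood group (for LOO)."""
        import arviz as az

        return az.from_dict(
            posterior={"coef": self.coef_draws, "tau_site": self.tau_draws},
            log_likelihood={"y": self.loglik},
            coords={"coef_dim_1": self.coef_names},
            dims=None,
        )
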