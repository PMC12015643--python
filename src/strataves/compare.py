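"""Model comparison by PSIS-LOO and covariate consensus classification.

Models are ranked by expected log pointwise predictive density (elpd)
estimated with Pareto-smoothed importance-sampling leave-one-out
cross-validation; a model is "statistically equivalent" to the best when its
elpd deficit is within three times the standard error of the pairwise
pointwise difference.  Covariate effects are then classed across the model
set: a solid star when every model containing the covariate estimates a
same-signed effect whose 95% credible interval excludes zero; an open star
when the best model and at least half of the equally-top models do; otherwise
the top set's pooled posterior decides positive / negative / null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ComparisonResult:
    """LOO table, the best model, and per-model pointwise elpd."""

    table: pd.DataFrame      # model, elpd, se, p_loo, elpd_diff, se_diff, top_set
    best: str
    loo_i: dict              # model -> pointwise elpd array

    @property
    def top_set(self) -> list:
        return list(self.table.index[self.table["top_set"]])


def _loo_one(res):
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = az.loo(res.to_inference_data(), pointwise=True)
    k = np.asarray(loo.pareto_k)
    return {
        "elpd": float(loo.elpd_loo),
        "se": float(loo.se),
        "p_loo": float(loo.p_loo),
        "loo_i": np.asarray(loo.loo_i),
        "k_warn": int((k > 0.7).sum()),
    }


def loo_compare(results: dict, se_factor: float = 3.0) -> ComparisonResult:
    """Compare fitted models on identical observations by PSIS-LOO.

    ``results`` maps model name to :class:`~strataves.mixed.MixedModelResults`.
    The top set holds every model whose elpd difference from the best is
    within ``se_factor`` times the SE of the pointwise differences (the best
    model is always a member).
    """
    if not results:
        raise ValueError("no models to compare")
    n_obs = {name: r.loglik.shape[-1] for name, r in results.items()}
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"models fitted to different observation sets: {n_obs}")
    loos = {name: _loo_one(r) for name, r in results.items()}
    best = max(loos, key=lambda nm: loos[nm]["elpd"])
    rows = {}
    for name, lo in loos.items():
        diff_i = loos[best]["loo_i"] - lo["loo_i"]
        n = diff_i.size
        se_diff = float(np.sqrt(n * np.var(diff_i, ddof=1))) if n > 1 else 0.0
        elpd_diff = float(diff_i.sum())
        rows[name] = {
            "elpd": lo["elpd"],
            "se": lo["se"],
            "p_loo": lo["p_loo"],
            "elpd_diff": elpd_diff,
            "se_diff": se_diff,
            "top_set": bool(name == best or elpd_diff <= se_factor * se_diff),
            "pareto_k_warnings": lo["k_warn"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_values("elpd", ascending=False)
    table.index.name = "model"
    return ComparisonResult(table=table, best=best, loo_i={n: loos[n]["loo_i"] for n in loos})


def _sign_ci(res, cov, level):
    lo, hi = res.ci(cov, level)
    if lo > 0:
        return 1
    if hi < 0:
        return -1
    return 0


def consensus(results: dict, comparison: ComparisonResult, level: float = 0.95) -> pd.DataFrame:
    """Classify each covariate across the model set.

    Classes: ``solid-star`` (every model containing the covariate gives a
    same-signed CI excluding zero), ``open-star`` (the best model does and at
    least 50% of the top set's containing models agree), else ``positive`` /
    ``negative`` / ``null`` from the pooled posterior draws of the top-set
    models containing the covariate.
    """
    covs: list[str] = []
    for r in results.values():
        for c in r.coef_names:
            if c != "Intercept" and c not in covs:
                covs.append(c)
    top = comparison.top_set
    best = comparison.best
    rows = {}
    for cov in covs:
        containing = {n: r for n, r in results.items() if cov in r.coef_names}
        signs = [_sign_ci(r, cov, level) for r in containing.values()]
        top_containing = {n: r for n, r in containing.items() if n in top}
        pooled = (
            np.concatenate([r.coef_flat()[cov].values for r in top_containing.values()])
            if top_containing
            else np.array([np.nan])
        )
        lo, hi = np.quantile(pooled, [(1 - level) / 2, 1 - (1 - level) / 2])
        pooled_sign = 1 if lo > 0 else (-1 if hi < 0 else 0)
        cls = None
        if signs and all(s == signs[0] and s != 0 for s in signs):
            cls = "solid-star"
        elif best in containing and _sign_ci(containing[best], cov, level) != 0:
            bs = _sign_ci(containing[best], cov, level)
            agree = [n for n, r in top_containing.items() if _sign_ci(r, cov, level) == bs]
            if top_containing and len(agree) >= 0.5 * len(top_containing):
                cls = "open-star"
        if cls is None:
            cls = {1: "positive", -1: "negative", 0: "null"}[pooled_sign]
        rows[cov] = {
            "class": cls,
            "pooled_mean": float(np.mean(pooled)),
            "pooled_lo": float(lo),
            "pooled_hi": float(hi),
            "n_models": len(containing),
            "n_top_models": len(top_containing),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "covariate"
    return out
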