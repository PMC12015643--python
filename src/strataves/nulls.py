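"""Richness-preserving, range-constrained null communities and SES.

Null assemblages randomize which species hold a plot's abundances while
keeping the plot's species richness fixed and drawing occupants only from
the species pool of the plot's ecological domain.  Standardized effect sizes
compare an observed metric to the null distribution:
``SES = (obs - mean(null)) / sd(null)``.  Tree-based metrics are evaluated
over the cross of null replicates and trees (n_null x n_trees evaluations
per plot) with the observed value averaged across trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class NullEnsemble:
    """n_null reshuffled abundance matrices plus randomization metadata."""

    weights: np.ndarray          # (n_null, n_plots, n_species)
    plots: pd.Index
    species: pd.Index
    seed: int
    method: str

    @property
    def n_null(self) -> int:
        return self.weights.shape[0]

    def replicate(self, r: int) -> pd.DataFrame:
        return pd.DataFrame(self.weights[r], index=self.plots, columns=self.species)


def build_nulls(
    abund,
    ranges,
    n_null: int = 100,
    seed: int = 0,
    method: str = "pool_resample",
) -> NullEnsemble:
    """Build the null ensemble from an abundance matrix and a range mask.

    ``method="pool_resample"`` (default): per plot and replicate, draw a
    species set of the observed richness from the plot's domain pool and
    assign the plot's abundance values to the drawn species in random order
    (abundance multiset preserved).  ``method="swap"``: checkerboard swaps of
    presences between plot pairs within each domain, which additionally
    preserves species-level occurrence frequencies.
    """
    weights_df = abund.nhat if hasattr(abund, "nhat") else abund
    W = weights_df.values.astype(float)
    plots, species = weights_df.index, weights_df.columns
    sp_pos = {s: i for i, s in enumerate(species)}
    rng = np.random.default_rng(seed)
    pools = {}
    for j, p in enumerate(plots):
        pool = [sp_pos[s] for s in ranges.pool_of_plot(p) if s in sp_pos]
        rich = int((W[j] > 0).sum())
        if rich > len(pool):
            raise ValueError(
                f"plot {p!r}: richness {rich} exceeds domain pool size {len(pool)}"
            )
        pools[p] = np.array(pool, dtype=int)

    out = np.zeros((n_null, *W.shape))
    if method == "pool_resample":
        for r in range(n_null):
            for j, p in enumerate(plots):
                vals = W[j][W[j] > 0]
                if vals.size == 0:
                    continue
                chosen = rng.choice(pools[p], size=vals.size, replace=False)
                out[r, j, chosen] = rng.permutation(vals)
    elif method == "swap":
        domains = pd.Series({p: ranges.domain_of_plot.loc[p] for p in plots})
        for r in range(n_null):
            M = W.copy()
            pres = M > 0
            for dom in domains.unique():
                rows = np.flatnonzero(domains.values == dom)
                if rows.size < 2:
                    continue
                n_swaps = 10 * pres[rows].sum()
                for _ in range(int(n_swaps)):
                    j1, j2 = rng.choice(rows, size=2, replace=False)
                    s1, s2 = rng.integers(0, M.shape[1], size=2)
                    # 2x2 checkerboard: species s1 at j1 only, s2 at j2 only
                    ok = (
                        pres[j1, s1] and not pres[j2, s1]
                        and pres[j2, s2] and not pres[j1, s2]
                        and s1 in pools[plots[j2]] and s2 in pools[plots[j1]]
                    )
                    if ok:
                        M[j2, s1], M[j1, s1] = M[j1, s1], 0.0
                        M[j1, s2], M[j2, s2] = M[j2, s2], 0.0
                        pres = M > 0
            out[r] = M
    else:
        raise ValueError("method must be 'pool_resample' or 'swap'")
    return NullEnsemble(out, plots, species, seed, method)


@dataclass
class SESResult:
    """Per-plot observed value, null mean/SD and standardized effect size."""

    table: pd.DataFrame
    n_evaluations: int = 0
    notes: dict = field(default_factory=dict)


def ses(metric_fn, abund, nulls: NullEnsemble, trees=None) -> SESResult:
    """Standardized effect sizes of a community metric against the nulls.

    ``metric_fn(members, weights)`` for abundance-space metrics, or
    ``metric_fn(members, weights, tree)`` when ``trees`` is given, returning
    one number per assemblage (may raise ValueError for degenerate input,
    recorded as missing).  With trees, each of the ``n_null`` replicates is
    evaluated on each tree (n_null x n_trees null evaluations per plot) and
    the observed value is the mean across trees.
    """
    weights_df = abund.nhat if hasattr(abund, "nhat") else abund
    rows = {}
    notes = {}
    n_eval = 0

    def evaluate(row, tree=None):
        members = list(row.index[row.values > 0])
        w = row.values[row.values > 0].astype(float)
        if tree is None:
            return metric_fn(members, w)
        return metric_fn(members, w, tree)

    for j, plot in enumerate(weights_df.index):
        obs_row = weights_df.iloc[j]
        try:
            if trees is None:
                obs = evaluate(obs_row)
            else:
                obs = float(np.mean([evaluate(obs_row, t) for t in trees]))
        except ValueError as exc:
            notes[plot] = f"observed metric undefined: {exc}"
            rows[plot] = (np.nan, np.nan, np.nan, np.nan)
            continue
        null_vals = []
        failed = False
        for r in range(nulls.n_null):
            null_row = pd.Series(nulls.weights[r, j], index=weights_df.columns)
            try:
                if trees is None:
                    null_vals.append(evaluate(null_row))
                    n_eval += 1
                else:
                    for t in trees:
                        null_vals.append(evaluate(null_row, t))
                        n_eval += 1
            except ValueError as exc:
                notes[plot] = f"null metric undefined: {exc}"
                failed = True
                break
        if failed:
            rows[plot] = (obs, np.nan, np.nan, np.nan)
            continue
        null_vals = np.asarray(null_vals, dtype=float)
        mu, sd = float(null_vals.mean()), float(null_vals.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            notes[plot] = "degenerate null distribution (zero SD)"
            rows[plot] = (obs, mu, sd, np.nan)
        else:
            rows[plot] = (obs, mu, sd, (obs - mu) / sd)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["obs", "null_mean", "null_sd", "ses"]
    )
    table.index.name = weights_df.index.name or "plot"
    return SESResult(table=table, n_evaluations=n_eval, notes=notes)
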