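"""Domain-structured species range masks.

Plots nest within ecological domains; a species may only be estimated as
present at a plot if its geographic range overlaps that plot's domain.  The
synthetic mask draws Bernoulli memberships but guarantees every species
belongs to at least one domain and every domain's species pool meets a
minimum size (so richness-preserving null draws are always feasible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RangeMask:
    """Boolean species x domain membership plus the plot -> domain map."""

    member: pd.DataFrame           # species x domain, bool
    domain_of_plot: pd.Series      # plot -> domain label

    def __post_init__(self) -> None:
        missing = set(self.domain_of_plot.unique()) - set(self.member.columns)
        if missing:
            raise ValueError(f"plots map to unknown domains: {sorted(missing)}")

    @property
    def species(self) -> pd.Index:
        return self.member.index

    def pool(self, domain: str) -> pd.Index:
        """Species whose range overlaps ``domain``."""
        return self.member.index[self.member[domain].values]

    def pool_of_plot(self, plot) -> pd.Index:
        return self.pool(self.domain_of_plot.loc[plot])

    def allowed(self, plots: pd.Index) -> pd.DataFrame:
        """Plot x species allowance matrix."""
        rows = [self.member[self.domain_of_plot.loc[p]].values for p in plots]
        return pd.DataFrame(np.array(rows), index=plots, columns=self.member.index)


def generate_ranges(
    species,
    domain_of_plot: pd.Series,
    membership_prob: float = 0.85,
    min_pool: int | None = None,
    seed: int = 0,
) -> RangeMask:
    """Draw a range mask over the given species and plot -> domain map.

    ``min_pool`` (default: 80% of the species count) is the smallest species
    pool any domain may have; shortfalls are topped up at random.
    """
    species = pd.Index(species, name="species")
    if species.size < 2:
        raise ValueError("need at least 2 species")
    domains = sorted(domain_of_plot.unique())
    if min_pool is None:
        min_pool = max(2, int(np.ceil(0.8 * species.size)))
    min_pool = min(min_pool, species.size)
    rng = np.random.default_rng(seed)
    member = rng.random((species.size, len(domains))) < membership_prob
    for i in range(species.size):           # every species lives somewhere
        if not member[i].any():
            member[i, rng.integers(len(domains))] = True
    for d in range(len(domains)):           # every domain pool large enough
        short = min_pool - int(member[:, d].sum())
        if short > 0:
            absent = np.flatnonzero(~member[:, d])
            member[rng.choice(absent, size=short, replace=False), d] = True
    return RangeMask(
        member=pd.DataFrame(member, index=species, columns=domains),
        domain_of_plot=domain_of_plot.copy(),
    )
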