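import numpy as np
import pandas as pd
import pytest

from strataves.distance_sampling import DistanceBinning
from strataves.synth import generate_traits, generate_trees
from strataves.synth.community import SurveyDesign, generate_community, generate_counts
from strataves.synth.ranges import generate_ranges
from strataves.traitspace import TraitTable


@pytest.fixture(scope="session")
def small_design():
    return SurveyDesign.generate(12, n_sites=4, n_domains=2, n_observers=3, seed=11)


@pytest.fixture(scope="session")
def small_community(small_design):
    return generate_community(small_design, 6, seed=12)


@pytest.fixture(scope="session")
def small_counts(small_community):
    binning = DistanceBinning.default(250.0, 10)
    return generate_counts(small_community, binning, seed=13), binning


@pytest.fixture(scope="session")
def traits12():
    return generate_traits(12, seed=21)


@pytest.fixture(scope="session")
def trees12():
    return generate_trees(12, 3, seed=22)


@pytest.fixture(scope="session")
def ranges12(small_design, traits12):
    # pools cover all species so small-plot null draws are always feasible
    return generate_ranges(
        traits12.species, small_design.covariates["domain"], membership_prob=1.0, seed=23
    )


def continuous_traits(values: np.ndarray, categories=None) -> TraitTable:
    """Helper: all-continuous trait table from a raw matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    cols = [f"t{k}" for k in range(p)]
    data = pd.DataFrame(values, columns=cols,
                        index=pd.Index([f"sp{i:03d}" for i in range(n)], name="species"))
    cats = categories or {c: c for c in cols}
    return TraitTable(data=data, categories=dict(cats), kinds={c: "continuous" for c in cols})
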