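"""Category-balanced Gower trait spaces.

Pairwise species dissimilarity is a range-normalized Gower distance computed
per trait axis, averaged within the five trait categories (diet, foraging,
beak, mass, HWI) and then combined across categories by weights.  The
weights can be optimized so each category contributes equally to the
combined distance (the "balanced" correction), after which the space is
ordinated by principal coordinates, its quality tracked by the RMSD between
original and embedded distances, and individual trait axes fitted back onto
the ordination as direction vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform


@dataclass
class TraitTable:
    """Species x trait-axis values with category and kind labels.

    Proportional categories (e.g. the ten diet axes) must sum to one per
    species; continuous axes must be finite.
    """

    data: pd.DataFrame
    categories: dict
    kinds: dict

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.categories)
        if missing:
            raise ValueError(f"axes without category labels: {sorted(missing)}")
        if not np.all(np.isfinite(self.data.values)):
            raise ValueError("trait values must be finite")
        for cat in self.category_names:
            axes = self.axes_of(cat)
            if all(self.kinds.get(a) == "proportional" for a in axes) and len(axes) > 1:
                sums = self.data[axes].sum(axis=1)
                if not np.allclose(sums, 1.0, atol=1e-6):
                    bad = sums.index[~np.isclose(sums, 1.0, atol=1e-6)]
                    raise ValueError(
                        f"proportional category {cat!r} does not sum to 1 for {list(bad[:5])}"
                    )

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def category_names(self) -> list:
        seen = []
        for a in self.data.columns:
            c = self.categories[a]
            if c not in seen:
                seen.append(c)
        return seen

    def axes_of(self, category: str) -> list:
        return [a for a in self.data.columns if self.categories[a] == category]

    def to_csv(self, path) -> None:
        meta = pd.DataFrame(
            {
                "category": [self.categories[a] for a in self.data.columns],
                "kind": [self.kinds.get(a, "continuous") for a in self.data.columns],
            },
            index=self.data.columns,
        )
        self.data.to_csv(str(path))
        meta.to_csv(str(path) + ".meta")

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        data = pd.read_csv(str(path), index_col=0)
        meta = pd.read_csv(str(path) + ".meta", index_col=0)
        return cls(
            data=data,
            categories=meta["category"].to_dict(),
            kinds=meta["kind"].to_dict(),
        )


@dataclass
class GowerDistance:
    """Combined dissimilarity matrix plus the pieces it was built from."""

    matrix: pd.DataFrame                 # species x species, in [0, 1]
    category_matrices: dict              # category -> condensed distance vector
    category_weights: dict
    dropped_axes: list = field(default_factory=list)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.matrix.values, checks=False)


def _axis_distance(values: np.ndarray) -> np.ndarray | None:
    """Condensed range-normalized |xi - xj| for one axis; None if zero range."""
    rng = values.max() - values.min()
    if rng == 0:
        return None
    n = values.size
    i, j = np.triu_indices(n, k=1)
    return np.abs(values[i] - values[j]) / rng


def gower_distance(
    traits: TraitTable,
    category_weights: dict | None = None,
    axis_weights: dict | None = None,
) -> GowerDistance:
    """Category-balanced Gower dissimilarity among all species.

    Axes are range-normalized and averaged (optionally weighted) within each
    category; category matrices are then combined by ``category_weights``
    (default: equal).  Zero-range axes are dropped with a warning.  The
    result lies in [0, 1], is symmetric, and has a zero diagonal.
    """
    if traits.species.size < 2:
        raise ValueError("need at least 2 species")
    cat_mats: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for cat in traits.category_names:
        parts, wts = [], []
        for a in traits.axes_of(cat):
            d = _axis_distance(traits.data[a].values.astype(float))
            if d is None:
                dropped.append(a)
                continue
            parts.append(d)
            wts.append((axis_weights or {}).get(a, 1.0))
        if parts:
            w = np.asarray(wts, dtype=float)
            cat_mats[cat] = np.average(np.stack(parts), axis=0, weights=w)
    if dropped:
        warnings.warn(f"dropped zero-range axes: {dropped}", stacklevel=2)
    if not cat_mats:
        raise ValueError("all axes have zero range")
    weights = {c: (category_weights or {}).get(c, 1.0) for c in cat_mats}
    wsum = sum(weights.values())
    combined = sum(weights[c] * m for c, m in cat_mats.items()) / wsum
    mat = pd.DataFrame(
        squareform(combined, checks=False), index=traits.species, columns=traits.species
    )
    return GowerDistance(mat, cat_mats, weights, dropped)


def category_contributions(gd: GowerDistance) -> pd.Series:
    """Pearson correlation of each category's distances with the combined."""
    comb = gd.condensed
    return pd.Series(
        {c: float(np.corrcoef(m, comb)[0, 1]) for c, m in gd.category_matrices.items()}
    )


def _contribution_sd(traits: TraitTable, weights: dict) -> float:
    gd = gower_distance(traits, category_weights=weights)
    return float(category_contributions(gd).std(ddof=0))


def balance_weights(traits: TraitTable, n_iter: int = 300, seed: int = 0) -> dict:
    """Search category weights equalizing category contributions.

    Seeded random-restart search with local refinement over the weight
    simplex, ``n_iter`` objective evaluations; the objective is the standard
    deviation of the per-category correlations between each category's
    distance matrix and the combined matrix.  Returns the best weights found
    (scaled to mean 1).
    """
    cats = gower_distance(traits).category_matrices.keys()
    cats = list(cats)
    if len(cats) < 2:
        return {c: 1.0 for c in cats}
    rng = np.random.default_rng(seed)
    best_w = np.full(len(cats), 1.0 / len(cats))
    best = _contribution_sd(traits, dict(zip(cats, best_w)))
    for it in range(n_iter):
        if it % 3 == 0:
            cand = rng.dirichlet(np.ones(len(cats)))
        else:  # local refinement around the incumbent
            cand = best_w * np.exp(rng.normal(0.0, 0.3, len(cats)))
            cand /= cand.sum()
        val = _contribution_sd(traits, dict(zip(cats, cand)))
        if val < best:
            best, best_w = val, cand
    scale = len(cats) / best_w.sum()
    return {c: float(w * scale) for c, w in zip(cats, best_w)}


@dataclass
class FunctionalSpace:
    """PCoA embedding of a Gower distance matrix.

    ``coords`` holds the retained axes (PC1..) ordered by decreasing
    eigenvalue; ``rmsd`` maps candidate dimensionality m to the root mean
    squared deviation between original distances and m-axis Euclidean
    distances; ``negative_fraction`` records the variance lost by dropping
    negative eigenvalues.
    """

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    rmsd: pd.Series
    negative_fraction: float
    n_axes: int

    @property
    def species(self) -> pd.Index:
        return self.coords.index


def pcoa(dist: GowerDistance, n_axes: int = 4, rmsd_max_axes: int = 10) -> FunctionalSpace:
    """Classical scaling (double-centering + eigendecomposition).

    Negative eigenvalues are dropped; the fraction of absolute eigenvalue
    mass they carry is recorded rather than corrected.  RMSD is computed for
    m = 1..min(rmsd_max_axes, #positive axes).
    """
    D = dist.matrix.values
    n = D.shape[0]
    if np.allclose(D[np.triu_indices(n, 1)], D[0, 1] if n > 1 else 0.0, atol=1e-15) and n > 2:
        warnings.warn("all pairwise distances equal; ordination is degenerate", stacklevel=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    neg_mass = float(np.abs(vals[~pos]).sum())
    total_mass = float(np.abs(vals).sum())
    negative_fraction = neg_mass / total_mass if total_mass > 0 else 0.0
    vals_p, vecs_p = vals[pos], vecs[:, pos]
    coords_full = vecs_p * np.sqrt(vals_p)

    iu = np.triu_indices(n, 1)
    d_obs = D[iu]
    rmsd = {}
    for m in range(1, min(rmsd_max_axes, coords_full.shape[1]) + 1):
        sub = coords_full[:, :m]
        d_m = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))[iu]
        rmsd[m] = float(np.sqrt(np.mean((d_obs - d_m) ** 2)))

    k = min(n_axes, coords_full.shape[1])
    coords = pd.DataFrame(
        coords_full[:, :k],
        index=dist.matrix.index,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return FunctionalSpace(coords, vals_p, pd.Series(rmsd), negative_fraction, k)


def fit_trait_vectors(space: FunctionalSpace, traits: TraitTable) -> pd.DataFrame:
    """Fit each trait axis as a direction vector in the retained PC space.

    Ordinary least squares of the centered trait on the PC coordinates; the
    returned frame holds unit direction cosines per PC plus the fit R^2
    (the ordination-vector fit used for trait interpretation).  Constant
    traits are skipped with a warning.
    """
    common = space.species.intersection(traits.species)
    if common.empty:
        raise ValueError("no shared species between space and traits")
    X = space.coords.loc[common].values
    rows = {}
    for a in traits.data.columns:
        y = traits.data.loc[common, a].values.astype(float)
        if np.ptp(y) == 0:
            warnings.warn(f"trait {a!r} is constant; skipped", stacklevel=2)
            continue
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(X, yc, rcond=None)
        fitted = X @ coef
        ss_res = float(((yc - fitted) ** 2).sum())
        ss_tot = float((yc**2).sum())
        r2 = 1.0 - ss_res / ss_tot
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        rows[a] = list(direction) + [r2]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(space.coords.columns) + ["r2"]
    )
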