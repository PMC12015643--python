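"""Gower distances, weight balancing, PCoA and trait-vector fitting."""

import numpy as np
import pandas as pd
import pytest

from strataves.traitspace import (
    balance_weights,
    category_contributions,
    fit_trait_vectors,
    gower_distance,
    pcoa,
)

from conftest import continuous_traits


class TestGower:
    def test_identical_species_zero_distance(self):
        t = continuous_traits([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        gd = gower_distance(t)
        assert gd.matrix.iloc[0, 1] == 0.0

    def test_opposite_extremes_distance_one(self):
        t = continuous_traits([[0.0, 10.0], [1.0, 20.0]])
        gd = gower_distance(t)
        assert gd.matrix.iloc[0, 1] == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_three_species(self):
        # two axes in one category, equal weights: mean of range-normalized diffs
        t = continuous_traits([[0.0, 0.0], [1.0, 4.0], [2.0, 2.0]],
                              categories={"t0": "c", "t1": "c"})
        gd = gower_distance(t)
        d01 = 0.5 * (1 / 2 + 4 / 4)
        d02 = 0.5 * (2 / 2 + 2 / 4)
        d12 = 0.5 * (1 / 2 + 2 / 4)
        assert gd.matrix.iloc[0, 1] == pytest.approx(d01, abs=1e-12)
        assert gd.matrix.iloc[0, 2] == pytest.approx(d02, abs=1e-12)
        assert gd.matrix.iloc[1, 2] == pytest.approx(d12, abs=1e-12)

    def test_bounds_symmetry_diagonal(self, traits12):
        gd = gower_distance(traits12)
        M = gd.matrix.values
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0)
        assert M.min() >= 0 and M.max() <= 1

    def test_zero_range_axis_dropped_with_warning(self):
        t = continuous_traits([[1.0, 5.0], [2.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-range"):
            gd = gower_distance(t)
        assert gd.dropped_axes == ["t1"]


class TestBalanceWeights:
    def test_reduces_contribution_spread(self, traits12):
        w = balance_weights(traits12, n_iter=120, seed=1)
        sd_eq = category_contributions(gower_distance(traits12)).std(ddof=0)
        sd_bal = category_contributions(
            gower_distance(traits12, category_weights=w)
        ).std(ddof=0)
        assert sd_bal <= sd_eq

    def test_beats_random_weight_vectors(self, traits12):
        w = balance_weights(traits12, n_iter=300, seed=2)
        best = category_contributions(
            gower_distance(traits12, category_weights=w)
        ).std(ddof=0)
        rng = np.random.default_rng(99)
        cats = list(w)
        wins = 0
        n_draw = 300
        for _ in range(n_draw):
            cand = dict(zip(cats, rng.dirichlet(np.ones(len(cats)))))
            sd = category_contributions(
                gower_distance(traits12, category_weights=cand)
            ).std(ddof=0)
            wins += best <= sd
        assert wins / n_draw >= 0.99

    def test_symmetric_categories_near_equal_weights(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(15, 2))
        # two categories with byte-identical distance structure
        t = continuous_traits(np.column_stack([vals[:, 0], vals[:, 0]]),
                              categories={"t0": "a", "t1": "b"})
        w = balance_weights(t, n_iter=100, seed=4)
        assert w["a"] / w["b"] == pytest.approx(1.0, abs=0.7)

    def test_deterministic_given_seed(self, traits12):
        assert balance_weights(traits12, 60, seed=5) == balance_weights(traits12, 60, seed=5)

    def test_single_category_identity(self):
        t = continuous_traits([[0.0], [1.0], [2.0]], categories={"t0": "only"})
        assert balance_weights(t, 10, seed=0) == {"only": 1.0}


class TestPCoA:
    @staticmethod
    def _euclidean_gd(points):
        from scipy.spatial.distance import pdist, squareform

        pts = np.asarray(points, float)
        labels = [f"sp{i}" for i in range(len(pts))]
        M = pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)
        from strataves.traitspace import GowerDistance

        return GowerDistance(M, {}, {})

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        space = pcoa(self._euclidean_gd(pts), n_axes=2)
        from scipy.spatial.distance import pdist

        got = pdist(space.coords.values)
        want = pdist(pts)
        assert np.allclose(got, want, atol=1e-8)
        assert space.rmsd[2] == pytest.approx(0.0, abs=1e-8)

    def test_right_triangle_side_lengths(self):
        gd = self._euclidean_gd([[0, 0], [3, 0], [0, 4]])
        space = pcoa(gd, n_axes=2)
        from scipy.spatial.distance import pdist

        sides = sorted(pdist(space.coords.values))
        assert sides == pytest.approx([3.0, 4.0, 5.0], abs=1e-9)

    def test_rmsd_non_increasing(self, traits12):
        space = pcoa(gower_distance(traits12))
        vals = space.rmsd.values
        assert np.all(np.diff(vals) <= 1e-12)

    def test_matches_scikit_bio(self, traits12):
        skbio = pytest.importorskip("skbio")
        gd = gower_distance(traits12)
        space = pcoa(gd, n_axes=4)
        dm = skbio.DistanceMatrix(gd.matrix.values, ids=list(gd.matrix.index))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio.stats.ordination.pcoa(dm)
        ref_eigs = np.sort(ref.eigvals.values[ref.eigvals.values > 1e-10])[::-1]
        got_eigs = np.sort(space.eigenvalues)[::-1][: len(ref_eigs)]
        assert np.allclose(got_eigs, ref_eigs[: len(got_eigs)], rtol=1e-6)
        # embedded distances agree axis count for axis count
        from scipy.spatial.distance import pdist

        ref_coords = ref.samples.values[:, :4]
        assert np.allclose(
            pdist(space.coords.values), pdist(ref_coords), rtol=1e-6, atol=1e-8
        )


class TestTraitVectors:
    def test_trait_equal_to_pc1_loads_on_pc1(self, traits12):
        space = pcoa(gower_distance(traits12))
        fake = continuous_traits(space.coords[["PC1"]].values, categories={"t0": "x"})
        fake.data.index = space.species
        loadings = fit_trait_vectors(space, fake)
        assert abs(loadings.loc["t0", "PC1"]) == pytest.approx(1.0, abs=1e-8)
        assert loadings.loc["t0", "r2"] == pytest.approx(1.0, abs=1e-8)

    def test_noise_trait_low_r2(self, traits12):
        space = pcoa(gower_distance(traits12))
        rng = np.random.default_rng(11)
        r2s = []
        for rep in range(30):
            noise = continuous_traits(rng.normal(size=(space.species.size, 1)),
                                      categories={"t0": "x"})
            noise.data.index = space.species
            r2s.append(fit_trait_vectors(space, noise).loc["t0", "r2"])
        assert np.mean(r2s) < 0.5

    def test_matches_normal_equations(self, traits12):
        space = pcoa(gower_distance(traits12))
        y = traits12.data["mass"].values.astype(float)
        X = space.coords.values
        yc = y - y.mean()
        beta = np.linalg.solve(X.T @ X, X.T @ yc)
        r2 = 1 - ((yc - X @ beta) ** 2).sum() / (yc**2).sum()
        loadings = fit_trait_vectors(space, traits12)
        assert loadings.loc["mass", "r2"] == pytest.approx(r2, rel=1e-10)
        got_dir = loadings.loc["mass", space.coords.columns].values.astype(float)
        assert np.allclose(got_dir, beta / np.linalg.norm(beta), atol=1e-10)

    def test_constant_trait_skipped(self, traits12):
        space = pcoa(gower_distance(traits12))
        const = continuous_traits(np.ones((space.species.size, 1)), categories={"t0": "x"})
        const.data.index = space.species
        with pytest.warns(UserWarning, match="constant"):
            out = fit_trait_vectors(space, const)
        assert out.empty
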