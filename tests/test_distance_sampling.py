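"""Distance-sampling model: detection math, likelihood identity, fit, postprocess."""

import numpy as np
import pandas as pd
import pytest
import scipy.integrate as si

from strataves.distance_sampling import (
    DistanceBinning,
    HierarchicalDistanceSampling,
    bin_cell_probs,
    detection_prob,
    log_likelihood,
    postprocess,
)
from strataves.synth.community import SurveyDesign, generate_community, generate_counts
from strataves.synth.ranges import RangeMask


class TestDetectionProb:
    def test_limits_and_closed_form(self):
        assert detection_prob(1e9, 0, 25) == pytest.approx(1.0, abs=1e-6)
        # point evaluation at d = sigma: exp(-1/2)
        assert detection_prob(50.0, 49.999, 50.001, dialect="midpoint") == pytest.approx(
            np.exp(-0.5), rel=1e-6
        )

    def test_matches_quadrature(self):
        for sigma in (20.0, 50.0, 120.0):
            for a, b in ((0, 25), (50, 75), (200, 250)):
                num = si.quad(
                    lambda r: np.exp(-(r**2) / (2 * sigma**2)) * 2 * r, a, b
                )[0] / (b**2 - a**2)
                assert detection_prob(sigma, a, b) == pytest.approx(num, abs=1e-8)

    def test_monotone_in_sigma_and_distance(self):
        sigmas = [10, 30, 60, 120]
        vals = [detection_prob(s, 25, 50) for s in sigmas]
        assert all(v1 < v2 for v1, v2 in zip(vals, vals[1:]))
        edges = np.linspace(0, 250, 11)
        binvals = [detection_prob(50.0, a, b) for a, b in zip(edges[:-1], edges[1:])]
        assert all(v1 > v2 for v1, v2 in zip(binvals, binvals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detection_prob(0.0, 0, 25)
        with pytest.raises(ValueError):
            detection_prob(50.0, 30, 25)

    def test_cell_probs_sum_below_one(self):
        pi = bin_cell_probs(np.array([30.0, 300.0]), DistanceBinning.default())
        assert pi.shape == (2, 10)
        assert np.all(pi.sum(axis=-1) <= 1.0 + 1e-12)


class TestLikelihood:
    def test_marginal_equals_latent_brute_force(self, small_community, small_counts):
        counts, binning = small_counts
        truth = small_community
        ll_m = log_likelihood(truth.coefs.values, truth.obs_eff, counts,
                              truth.design.covariates, binning)
        ll_l = log_likelihood(truth.coefs.values, truth.obs_eff, counts,
                              truth.design.covariates, binning,
                              marginalize=False, n_max=250)
        assert ll_m == pytest.approx(ll_l, abs=1e-8)

    def test_single_cell_poisson_pmf_by_hand(self):
        design = SurveyDesign.generate(1, seed=0)
        covs = design.covariates.copy()
        covs[["cloud", "airtemp", "wind", "elevation", "latitude"]] = 0.0
        binning = DistanceBinning(np.array([0.0, 250.0]))
        lam, sigma, c = 3.0, 80.0, 2
        coefs = np.array([[np.log(lam), 0, 0, np.log(sigma), 0, 0, 0],
                          [np.log(lam), 0, 0, np.log(sigma), 0, 0, 0]])
        counts = np.array([[[c], [0]]])
        pi = 2 * sigma**2 * (1 - np.exp(-(250.0**2) / (2 * sigma**2))) / 250.0**2
        mu = lam * pi
        import math

        by_hand = (c * np.log(mu) - mu - np.log(math.factorial(c))) + (-mu)
        got = log_likelihood(coefs, np.zeros(1), counts, covs, binning)
        assert got == pytest.approx(by_hand, rel=1e-12)

    def test_zero_counts_loglik_tends_to_zero(self):
        design = SurveyDesign.generate(2, seed=0)
        binning = DistanceBinning.default(250.0, 5)
        counts = np.zeros((2, 2, 5), dtype=int)
        vals = []
        for log_lam in (-2.0, -6.0, -12.0):
            coefs = np.tile([log_lam, 0, 0, np.log(80.0), 0, 0, 0], (2, 1))
            vals.append(log_likelihood(coefs, np.zeros(3), counts,
                                       design.covariates, binning))
        assert vals[0] < vals[1] < vals[2] < 0
        assert vals[2] == pytest.approx(0.0, abs=1e-4)

    def test_dialects_differ_but_agree_for_narrow_bins(self):
        sigma = 60.0
        wide = DistanceBinning(np.array([0.0, 125.0, 250.0]))
        narrow = DistanceBinning(np.linspace(0, 250, 201))
        pa = bin_cell_probs(np.array(sigma), wide)[0].sum()
        pm = bin_cell_probs(np.array(sigma), wide, dialect="midpoint")[0].sum()
        assert pa != pytest.approx(pm, rel=1e-3)
        pa_n = bin_cell_probs(np.array(sigma), narrow)[0].sum()
        pm_n = bin_cell_probs(np.array(sigma), narrow, dialect="midpoint")[0].sum()
        assert pa_n == pytest.approx(pm_n, rel=1e-4)


@pytest.fixture(scope="module")
def fitted(small_counts, small_community):
    counts, binning = small_counts
    model = HierarchicalDistanceSampling(
        counts, small_community.design.covariates, binning,
        species=list(small_community.species),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(draws=300, warmup=300, chains=2, seed=17)


class TestFit:
    def test_nhat_at_least_observed(self, fitted, small_counts):
        counts, _ = small_counts
        assert np.all(fitted.nhat.values >= counts.sum(axis=2) - 1e-9)

    def test_summary_structure(self, fitted):
        s = fitted.summary()
        assert len(s) == 14
        assert {"mean", "sd", "rhat", "ess"} <= set(s.columns)
        assert np.all(s["ess"] > 0)

    def test_needs_two_species(self, small_community, small_counts):
        counts, binning = small_counts
        with pytest.raises(ValueError, match="2 species"):
            HierarchicalDistanceSampling(
                counts[:, :1], small_community.design.covariates, binning
            )


class TestPostprocess:
    @staticmethod
    def _mask(plots, species, forbid=()):
        member = pd.DataFrame(True, index=pd.Index(species, name="species"),
                              columns=["D0"])
        for s in forbid:
            member.loc[s, "D0"] = False
        return RangeMask(member=member,
                         domain_of_plot=pd.Series("D0", index=plots))

    def test_threshold_is_inclusive_at_0_95(self):
        nhat = pd.DataFrame({"a": [0.94, 0.95], "b": [3.2, 0.0]},
                            index=["P0", "P1"])
        out = postprocess(nhat, self._mask(nhat.index, nhat.columns))
        assert out.nhat.loc["P0", "a"] == 0.0 and not out.presence.loc["P0", "a"]
        assert out.nhat.loc["P1", "a"] == 0.95 and out.presence.loc["P1", "a"]

    def test_out_of_range_zeroed(self):
        nhat = pd.DataFrame({"a": [3.2], "b": [2.0]}, index=["P0"])
        out = postprocess(nhat, self._mask(nhat.index, nhat.columns, forbid=["a"]))
        assert out.nhat.loc["P0", "a"] == 0.0
        assert out.nhat.loc["P0", "b"] == 2.0

    def test_missing_species_error_lists_ids(self):
        nhat = pd.DataFrame({"a": [1.0], "zz": [1.0]}, index=["P0"])
        with pytest.raises(ValueError, match="zz"):
            postprocess(nhat, self._mask(nhat.index, ["a"]))

    def test_idempotent_and_filter_threshold_commute(self):
        rng = np.random.default_rng(8)
        nhat = pd.DataFrame(rng.uniform(0, 3, (4, 5)),
                            index=[f"P{i}" for i in range(4)],
                            columns=[f"s{i}" for i in range(5)])
        mask = self._mask(nhat.index, nhat.columns, forbid=["s1"])
        once = postprocess(nhat, mask)
        twice = postprocess(once.nhat, mask)
        assert once.nhat.equals(twice.nhat)
        # threshold first, then filter: same result
        thresholded = nhat.where(nhat >= 0.95, 0.0)
        other = postprocess(thresholded, mask)
        assert once.nhat.equals(other.nhat)
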