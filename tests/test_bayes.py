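import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from wgctraj.bayes import (
    EVParams,
    PriorSpec,
    confusion_metrics,
    fit_ev_likelihood,
    posterior,
    prior_probability,
    train_predict,
    vertexwise_maps,
)
from wgctraj.core_io import SubjectMatrix, VertexMap


class TestEvLikelihood:
    def test_density_at_mode_is_inverse_e_over_sigma(self):
        for sigma in (0.5, 1.0, 2.0):
            p = EVParams(mu=0.3, sigma=sigma, orientation="plus", fit_quality=1.0)
            assert p.pdf(0.3) == pytest.approx(math.exp(-1.0) / sigma, rel=1e-12)

    def test_mle_recovers_parameters_at_large_n(self):
        rng = np.random.default_rng(0)
        mus, sigmas = [], []
        for rep in range(10):
            draws = stats.gumbel_l.rvs(loc=0.3, scale=0.8, size=10_000, random_state=rng)
            fit = fit_ev_likelihood(draws)
            assert fit.orientation == "plus"
            mus.append(fit.mu)
            sigmas.append(fit.sigma)
        assert abs(np.mean(mus) - 0.3) < 0.03
        assert abs(np.mean(sigmas) - 0.8) < 0.03

    def test_mle_bias_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        errs = []
        for n in (100, 1000, 10_000):
            mu_err = np.mean(
                [
                    abs(
                        fit_ev_likelihood(
                            stats.gumbel_l.rvs(0.0, 1.0, size=n, random_state=rng)
                        ).mu
                    )
                    for _ in range(8)
                ]
            )
            errs.append(mu_err)
        assert errs[2] < errs[0]

    def test_minus_orientation_detected_for_right_skew(self):
        rng = np.random.default_rng(2)
        draws = stats.gumbel_r.rvs(loc=-0.2, scale=0.5, size=5000, random_state=rng)
        fit = fit_ev_likelihood(draws)
        assert fit.orientation == "minus"
        assert fit.mu == pytest.approx(0.2, abs=0.05)

    def test_density_integrates_to_one(self):
        fit = EVParams(mu=0.4, sigma=0.7, orientation="minus", fit_quality=1.0)
        # the exponential (slow) tail of the minus orientation is on the right
        total, _ = quad(fit.pdf, -12 * 0.7 - 0.4, 40 * 0.7 - 0.4, limit=400)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_ev_likelihood(np.full(50, 1.3))

    def test_tiny_sample_is_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_ev_likelihood(np.arange(5.0))


class TestPrior:
    def spec(self, bsr=-1.0, bsr_max=2.0):
        return PriorSpec(bsr=bsr, bsr_max=bsr_max, domain=(-5.0, 5.0))

    def test_midpoint_is_half_for_both_classes(self):
        s = self.spec()
        assert prior_probability(0.0, s, "TD") == pytest.approx(0.5)
        assert prior_probability(0.0, s, "ASD") == pytest.approx(0.5)

    def test_td_prior_increases_with_x_when_bsr_negative(self):
        s = self.spec(bsr=-1.5)
        x = np.linspace(-4, 4, 50)
        p = prior_probability(x, s, "TD")
        assert np.all(np.diff(p) > 0)

    def test_asd_prior_increases_with_x_when_bsr_positive(self):
        s = self.spec(bsr=1.5)
        p = prior_probability(np.linspace(-4, 4, 50), s, "ASD")
        assert np.all(np.diff(p) > 0)

    def test_direct_evaluation_at_unit_input(self):
        s = PriorSpec(bsr=2.0, bsr_max=2.0, domain=(-5.0, 5.0))
        assert prior_probability(1.0, s, "ASD") == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0))
        )
        assert prior_probability(1.0, s, "ASD") == pytest.approx(0.7310585786300049)

    def test_complementarity_over_domain(self):
        s = self.spec(bsr=0.7)
        x = np.linspace(-5, 5, 101)
        total = prior_probability(x, s, "TD") + prior_probability(x, s, "ASD")
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_non_positive_bsr_max_rejected(self):
        with pytest.raises(ValueError, match="bsr_max"):
            PriorSpec(bsr=0.0, bsr_max=0.0, domain=(-1.0, 1.0))


class TestPosterior:
    def ev(self, mu, sigma=1.0, orientation="plus"):
        return EVParams(mu=mu, sigma=sigma, orientation=orientation, fit_quality=1.0)

    def test_identical_likelihoods_flat_prior_give_half(self):
        p_asd, p_td = posterior(0.3, self.ev(0.0), self.ev(0.0), None)
        assert p_asd == pytest.approx(0.5, abs=1e-12)
        assert p_td == pytest.approx(0.5, abs=1e-12)

    def test_flat_prior_posterior_ratio_equals_likelihood_ratio(self):
        a, t = self.ev(-1.0), self.ev(1.0)
        x = 0.4
        p_asd, p_td = posterior(x, a, t, None)
        assert p_asd / p_td == pytest.approx(a.pdf(x) / t.pdf(x), rel=1e-10)

    def test_hand_built_scalar_oracle(self):
        """Explicit scalar evaluation of the likelihood-times-prior chain."""
        a = self.ev(-1.0)
        t = self.ev(1.0)
        spec = PriorSpec(bsr=-2.0, bsr_max=2.0, domain=(-3.0, 3.0))
        x = -1.0
        def gumbel(x, mu, sigma=1.0):
            z = (x - mu) / sigma
            return math.exp(z - math.exp(z)) / sigma
        prior_asd = 1.0 / (1.0 + math.exp(-1.0 * x * (-2.0) / 2.0))
        prior_td = 1.0 / (1.0 + math.exp(+1.0 * x * (-2.0) / 2.0))
        num_a = gumbel(x, -1.0) * prior_asd
        num_t = gumbel(x, 1.0) * prior_td
        p_asd, p_td = posterior(x, a, t, spec)
        assert p_asd == pytest.approx(num_a / (num_a + num_t), rel=1e-10)
        assert p_asd + p_td == pytest.approx(1.0, abs=1e-12)

    def test_normalisation_on_many_random_inputs(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-50, 50, 100_000)
        spec = PriorSpec(bsr=-1.0, bsr_max=1.5, domain=(-4.0, 4.0))
        p_asd, p_td = posterior(x, self.ev(-0.5, 0.7), self.ev(0.5, 1.3, "minus"), spec)
        np.testing.assert_allclose(p_asd + p_td, 1.0, atol=1e-12)

    def test_monotone_evidence_with_negative_bsr(self):
        spec = PriorSpec(bsr=-2.0, bsr_max=2.0, domain=(-4.0, 4.0))
        ev = self.ev(0.0)
        x = np.linspace(-4, 4, 41)
        p_asd, _ = posterior(x, ev, ev, spec)
        assert np.all(np.diff(p_asd) <= 1e-12)


class TestConfusionMetrics:
    def test_published_longitudinal_counts(self):
        true = ["ASD"] * 12 + ["TD"] * 9
        pred = ["ASD"] * 10 + ["TD"] * 2 + ["TD"] * 6 + ["ASD"] * 3
        sens, spec, acc = confusion_metrics(true, pred)
        assert sens == pytest.approx(10 / 12)
        assert spec == pytest.approx(6 / 9)
        assert acc == pytest.approx(16 / 21)

    def test_perfect_and_inverted_predictions(self):
        true = ["ASD", "TD", "ASD", "TD"]
        assert confusion_metrics(true, true) == (1.0, 1.0, 1.0)
        flipped = ["TD", "ASD", "TD", "ASD"]
        assert confusion_metrics(true, flipped) == (0.0, 0.0, 0.0)

    def test_absent_class_reported_missing(self):
        sens, spec, acc = confusion_metrics(["ASD", "ASD"], ["ASD", "TD"])
        assert spec is None
        assert sens == pytest.approx(0.5)
        assert acc == pytest.approx(0.5)


def _split_study(study):
    return (
        study.crsc_angles,
        study.crsc_cohort,
        study.lngt_angles,
        study.lngt_cohort,
        VertexMap(study.pls_crsc.bsr[:, 0]),
    )


class TestTrainPredict:
    def test_whole_cortex_prediction_beats_chance(self, small_study):
        res = small_study.prediction
        assert res.accuracy > 0.6
        np.testing.assert_allclose(
            res.posterior_asd.clip(0, 1), res.posterior_asd, atol=0
        )

    def test_region_of_identical_vertices_matches_single_vertex(self, small_study):
        crsc, ccoh, lngt, lcoh, bsr = _split_study(small_study)
        v = 3
        dup = SubjectMatrix(crsc.row_ids, np.tile(crsc.values[:, [v]], (1, 4)), kind="zscored_angle")
        dup_l = SubjectMatrix(lngt.row_ids, np.tile(lngt.values[:, [v]], (1, 4)), kind="zscored_angle")
        bsr_dup = VertexMap(np.full(4, bsr.values[v]))
        multi = train_predict(dup, ccoh, dup_l, lcoh, bsr_dup)
        single = train_predict(dup, ccoh, dup_l, lcoh, bsr_dup, region=[0])
        np.testing.assert_allclose(multi.posterior_asd, single.posterior_asd, atol=1e-10)

    def test_empty_region_is_error(self, small_study):
        with pytest.raises(ValueError, match="empty region"):
            train_predict(*_split_study(small_study), region=[])

    def test_unstandardised_input_rejected(self, small_study):
        crsc, ccoh, lngt, lcoh, bsr = _split_study(small_study)
        raw = SubjectMatrix(crsc.row_ids, crsc.values, kind="angle")
        with pytest.raises(ValueError, match="standardised"):
            train_predict(raw, ccoh, lngt, lcoh, bsr)


class TestVertexwiseMaps:
    def test_maps_and_mutual_mask(self, small_study):
        crsc, ccoh, lngt, lcoh, bsr = _split_study(small_study)
        sub = np.arange(12)
        crsc_s = SubjectMatrix(crsc.row_ids, crsc.values[:, sub], kind="zscored_angle")
        lngt_s = SubjectMatrix(lngt.row_ids, lngt.values[:, sub], kind="zscored_angle")
        bsr_s = VertexMap(bsr.values[sub])
        sens, spec, mask = vertexwise_maps(crsc_s, ccoh, lngt_s, lcoh, bsr_s)
        ok = np.isfinite(sens.values) & np.isfinite(spec.values)
        assert ok.any()
        np.testing.assert_array_equal(
            mask, (sens.values > 0.5) & (spec.values > 0.5)
        )
        # planted-effect vertices should usually discriminate above chance
        assert (sens.values[ok] + spec.values[ok]).mean() > 1.0
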