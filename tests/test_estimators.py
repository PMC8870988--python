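"""The three fitting methods: MH on exceedances, BMH, and IPBMH."""

import math

import numpy as np
import pytest

import conftest as oracles
from gpdbayes import (
    EmptyTailError,
    ExceedanceSample,
    GPDParams,
    InformativePrior,
    InvalidParameterError,
    MHConfig,
    PriorSpec,
    StableSpec,
    build_informative_prior,
    default_prior,
    family_relation,
    fit_baseline_scale,
    fit_bmh,
    fit_ipbmh,
    fit_mh_for_family,
    fit_mh_heavy,
    fit_mh_light,
    gpd_sample,
    map_to_gpd,
    stable_sample,
)
from gpdbayes.estimators import (
    heavy_log_posterior,
    informative_log_posterior,
    light_log_posterior,
)

FAST = MHConfig(n_keep=1000, burn_in=500, thinning=2, seed=0)
MED = MHConfig(n_keep=2000, burn_in=1000, thinning=5, seed=0)


class TestRatioStructure:
    """exp(delta log-posterior) must reproduce the closed-form conditional ratios."""

    def setup_method(self):
        self.rng = np.random.default_rng(2024)
        self.x_heavy = gpd_sample(50, GPDParams(1.0, 2.0), seed=1)
        self.x_light = gpd_sample(50, GPDParams(-0.3, 1.0), seed=2)

    def test_light_tail_ratios(self):
        a0, b0, a1, b1 = 2.0, 1.5, 3.0, 0.5
        lp = light_log_posterior(
            self.x_light, PriorSpec("gamma", a0, b0), PriorSpec("gamma", a1, b1)
        )
        xmax = self.x_light.max()
        for _ in range(100):
            k, k_new = self.rng.uniform(0.05, 3.0, size=2)
            d, d_new = xmax + self.rng.uniform(0.05, 5.0, size=2)
            assert lp((k_new, d)) - lp((k, d)) == pytest.approx(
                oracles.printed_log_rk(k_new, k, d, self.x_light, a0, b0), abs=1e-10
            )
            assert lp((k, d_new)) - lp((k, d)) == pytest.approx(
                oracles.printed_log_rdelta(d_new, d, k, self.x_light, a1, b1), abs=1e-10
            )

    def test_heavy_tail_ratios(self):
        a0, b0, a1, b1 = 1.0, 0.01, 2.0, 1.0
        lp = heavy_log_posterior(
            self.x_heavy, PriorSpec("pareto1", a0, b0), PriorSpec("inverse_gamma", a1, b1)
        )
        for _ in range(100):
            xi, xi_new = self.rng.uniform(0.1, 3.0, size=2)
            s, s_new = self.rng.uniform(0.5, 5.0, size=2)
            assert lp((xi_new, s)) - lp((xi, s)) == pytest.approx(
                oracles.printed_log_rxi(xi_new, xi, s, self.x_heavy, a0), abs=1e-10
            )
            assert lp((xi, s_new)) - lp((xi, s)) == pytest.approx(
                oracles.printed_log_rsigma(s_new, s, xi, self.x_heavy, a1, b1), abs=1e-10
            )

    def test_informative_prior_ratios(self):
        prior = InformativePrior(
            xi_mean=1.0, xi_sd=0.065, sigma_mean=3.18, sigma_sd=0.24, p=0.9, family="cauchy"
        )
        lp = informative_log_posterior(self.x_heavy, prior)
        for _ in range(100):
            xi, xi_new = self.rng.uniform(0.1, 3.0, size=2)
            s, s_new = self.rng.uniform(0.5, 5.0, size=2)
            assert lp((xi_new, s)) - lp((xi, s)) == pytest.approx(
                oracles.printed_log_rxi_ip(xi_new, xi, s, self.x_heavy, 1.0, 0.065), abs=1e-10
            )
            assert lp((xi, s_new)) - lp((xi, s)) == pytest.approx(
                oracles.printed_log_rsigma_ip(s_new, s, xi, self.x_heavy, 3.18, 0.24), abs=1e-10
            )


class TestSupportConstraints:
    def test_light_delta_below_max_rejected_with_certainty(self):
        x = np.array([0.5, 1.0, 2.0])
        lp = light_log_posterior(x, default_prior("k"), default_prior("delta"))
        assert lp((0.5, 1.9)) == -math.inf  # delta <= max(x)
        assert lp((0.5, 2.0)) == -math.inf
        assert lp((0.5, 2.1)) > -math.inf

    def test_heavy_xi_below_prior_bound_rejected(self):
        x = np.array([0.5, 1.0])
        lp = heavy_log_posterior(x, PriorSpec("pareto1", 1.0, 0.1), default_prior("sigma"))
        assert lp((0.1, 1.0)) == -math.inf
        assert lp((0.05, 1.0)) == -math.inf
        assert lp((0.2, 1.0)) > -math.inf

    def test_informative_support_enforced_via_likelihood(self):
        prior = InformativePrior(
            xi_mean=-0.151, xi_sd=0.03, sigma_mean=0.534, sigma_sd=0.02, p=0.9
        )
        x = np.array([0.5, 1.0])
        lp = informative_log_posterior(x, prior)
        assert lp((-0.6, 0.534)) == -math.inf  # upper endpoint 0.89 < max(x)
        assert lp((-0.3, 0.534)) > -math.inf  # endpoint 1.78 > max(x)
        assert lp((0.1, -1.0)) == -math.inf


class TestRecovery:
    def test_heavy_tail_recovery(self, heavy_tail_sample):
        fit = fit_mh_heavy(heavy_tail_sample, config=MED.replace(seed=21))
        assert fit.xi == pytest.approx(1.0, abs=0.1)
        assert fit.sigma == pytest.approx(3.1831, rel=0.1)

    def test_light_tail_recovery(self, light_tail_sample):
        fit = fit_mh_light(light_tail_sample, config=MED.replace(seed=22))
        assert fit.xi == pytest.approx(-0.151, abs=0.05)
        assert fit.sigma == pytest.approx(0.534, abs=0.08)
        # native chain is (k, delta); reported (xi, sigma) are the transforms
        assert fit.posterior.param_names == ("k", "delta")

    def test_empty_tail_rejected(self):
        empty = ExceedanceSample(u=1.0, p=0.9, values=np.array([]), n_source=10)
        with pytest.raises(EmptyTailError):
            fit_mh_heavy(empty, config=FAST)

    @pytest.mark.parametrize("fitter", ["light", "heavy", "ipbmh"])
    def test_bias_shrinks_with_sample_size(self, fitter):
        """Averaged over seeded replicates, |posterior mean - truth| falls from m=100 to m=2000."""
        if fitter == "light":
            truth = GPDParams(-0.151, 0.534)
        elif fitter == "heavy":
            truth = GPDParams(1.0, 1 / (math.pi * 0.1))
        else:
            # truth offset from the prior centre: more data must overcome
            # the informative prior's shrinkage toward (1, 3.18)
            truth = GPDParams(1.2, 4.0)
        prior = build_informative_prior("cauchy", 0.9, 1.0)
        errs = {}
        for m in (100, 2000):
            acc = []
            for rep in range(10):
                tail = oracles.make_tail(truth.xi, truth.sigma, m=m, seed=1000 * m + rep)
                cfg = FAST.replace(seed=rep)
                if fitter == "light":
                    fit = fit_mh_light(tail, config=cfg)
                elif fitter == "heavy":
                    fit = fit_mh_heavy(tail, config=cfg)
                else:
                    fit = fit_ipbmh(tail, prior, config=cfg)
                acc.append(abs(fit.xi - truth.xi))
            errs[m] = np.mean(acc)
        assert errs[2000] < errs[100]


class TestBaselineScale:
    def test_levy_conjugate_posterior_mean(self):
        data = stable_sample(512, StableSpec.from_family("levy"), seed=31)
        prior = PriorSpec("gamma", 0.01, 0.01)
        res = fit_baseline_scale(data, "levy", prior=prior, config=MED.replace(seed=32))
        shape = prior.hyper_a + 0.5 * data.size
        rate = prior.hyper_b + 0.5 * (1.0 / data).sum()
        closed_form = shape / rate
        draws = res.chain.draws[:, 0]
        mcse = draws.std() / math.sqrt(draws.size / 10)  # conservative ESS deflation
        assert abs(res.point_estimate[0] - closed_form) < 3 * mcse

    def test_normal_conjugate_posterior_on_a_squared(self):
        data = stable_sample(512, StableSpec.from_family("normal", a=2.0), seed=33)
        prior = PriorSpec("inverse_gamma", 0.01, 0.01)
        res = fit_baseline_scale(data, "normal", prior=prior, config=MED.replace(seed=34))
        # chain is on a; compare the a^2 draws with the inverse-gamma posterior mean
        a_sq = res.chain.draws[:, 0] ** 2
        shape = prior.hyper_a + 0.5 * data.size
        rate = prior.hyper_b + 0.5 * (data**2).sum()
        closed_form = rate / (shape - 1)
        mcse = a_sq.std() / math.sqrt(a_sq.size / 10)
        assert abs(a_sq.mean() - closed_form) < 3 * mcse
        assert res.chain.param_names == ("a",)

    def test_cauchy_scale_recovery(self):
        # average over replicate data sets: one Cauchy sample of 512 can
        # easily sit a full posterior-sd (~0.13) away from the truth
        means = []
        for rep in range(5):
            data = stable_sample(512, StableSpec.from_family("cauchy", a=2.0), seed=35 + rep)
            res = fit_baseline_scale(data, "cauchy", config=MED.replace(seed=135 + rep))
            means.append(res.point_estimate[0])
        assert np.mean(means) == pytest.approx(2.0, abs=0.15)

    def test_levy_rejects_non_positive_data(self):
        with pytest.raises(Exception, match="positive"):
            fit_baseline_scale(np.array([-1.0, 2.0]), "levy", config=FAST)


class TestBMH:
    def test_levy_shape_is_exactly_two(self):
        data = stable_sample(64, StableSpec.from_family("levy", a=0.5), seed=41)
        fit = fit_bmh(data, "levy", 0.9, config=FAST.replace(seed=42))
        assert fit.xi == 2.0  # data-independent by the family relation

    def test_cauchy_scale_composition(self):
        # a_hat = 1.5 at p = 0.9 must map to sigma = 1.5 / (pi * 0.1)
        gpd = map_to_gpd(family_relation("cauchy", 0.9), 1.5)
        assert gpd.sigma == pytest.approx(4.7746, abs=1e-4)

    def test_normal_recovery_at_unit_scale(self):
        data = stable_sample(512, StableSpec.from_family("normal"), seed=43)
        fit = fit_bmh(data, "normal", 0.9, config=MED.replace(seed=44))
        assert fit.xi == pytest.approx(-0.151, abs=1e-12)
        assert fit.sigma == pytest.approx(0.534, rel=0.1)

    def test_sigma_interval_contains_point(self):
        data = stable_sample(128, StableSpec.from_family("cauchy"), seed=45)
        fit = fit_bmh(data, "cauchy", 0.9, config=FAST.replace(seed=46))
        lo, hi = fit.sigma_interval
        assert lo <= fit.sigma <= hi


class TestInformativePriors:
    def test_b2_evaluations(self):
        # direct evaluation of b2 = exp(c1 p^2 + c2 p + c3) per family
        prior = build_informative_prior("normal", 0.9, 1.0)
        assert prior.sigma_sd == pytest.approx(
            math.exp(-46.24 * 0.81 + 83.55 * 0.9 - 41.58), rel=1e-12
        )
        assert prior.sigma_sd == pytest.approx(0.0215, abs=5e-4)
        levy = build_informative_prior("levy", 0.9, 1.0)
        assert levy.sigma_sd == pytest.approx(math.exp(2.552), abs=0.2)

    def test_b1_constants(self):
        assert build_informative_prior("cauchy", 0.9, 1.0).xi_sd == 0.065
        assert build_informative_prior("levy", 0.9, 1.0).xi_sd == 0.1
        assert build_informative_prior("normal", 0.9, 1.0).xi_sd == 0.03

    def test_prior_means_from_relation(self):
        prior = build_informative_prior("cauchy", 0.9, 2.0)
        assert prior.xi_mean == 1.0
        assert prior.sigma_mean == pytest.approx(2.0 / (math.pi * 0.1), rel=1e-12)

    def test_degenerate_prior_pins_posterior(self, heavy_tail_sample):
        prior = InformativePrior(
            xi_mean=1.0, xi_sd=1e-6, sigma_mean=3.1831, sigma_sd=1e-6, p=0.9, family="cauchy"
        )
        fit = fit_ipbmh(heavy_tail_sample, prior, config=FAST.replace(seed=51))
        assert fit.xi == pytest.approx(1.0, abs=1e-3)
        assert fit.sigma == pytest.approx(3.1831, abs=1e-3)

    def test_diffuse_prior_matches_classical_mh(self, heavy_tail_sample):
        base = build_informative_prior("cauchy", 0.9, 1.0)
        diffuse = InformativePrior(
            xi_mean=base.xi_mean,
            xi_sd=base.xi_sd * 1e4,
            sigma_mean=base.sigma_mean,
            sigma_sd=base.sigma_sd * 1e4,
            p=0.9,
            family="cauchy",
        )
        ip = fit_ipbmh(
            heavy_tail_sample,
            diffuse,
            config=MED.replace(seed=52, proposal_sds=(0.1, 0.3)),
        )
        mh = fit_mh_heavy(heavy_tail_sample, config=MED.replace(seed=53))
        assert ip.xi == pytest.approx(mh.xi, abs=0.1)
        assert ip.sigma == pytest.approx(mh.sigma, rel=0.1)

    def test_posterior_mean_shrinks_between_prior_and_mh(self):
        # informative prior centred away from the data truth: the posterior
        # mean must land between the prior mean and the classical MH estimate
        tail = oracles.make_tail(1.3, 4.0, m=200, seed=54)
        prior = InformativePrior(
            xi_mean=1.0, xi_sd=0.065, sigma_mean=3.1831, sigma_sd=0.3, p=0.9, family="cauchy"
        )
        ip = fit_ipbmh(tail, prior, config=MED.replace(seed=55))
        mh = fit_mh_heavy(tail, config=MED.replace(seed=56))
        lo, hi = sorted((prior.xi_mean, mh.xi))
        assert lo - 0.02 <= ip.xi <= hi + 0.02

    def test_invalid_widths(self):
        with pytest.raises(InvalidParameterError):
            InformativePrior(xi_mean=1.0, xi_sd=0.0, sigma_mean=1.0, sigma_sd=1.0, p=0.9)


class TestDispatcher:
    def test_family_routes(self, heavy_tail_sample, light_tail_sample):
        heavy = fit_mh_for_family(heavy_tail_sample, "cauchy", config=FAST.replace(seed=61))
        assert heavy.method == "mh_heavy"
        light = fit_mh_for_family(light_tail_sample, "normal", config=FAST.replace(seed=62))
        assert light.method == "mh_light"
        gamma = fit_mh_for_family(heavy_tail_sample, "gamma", config=FAST.replace(seed=63))
        assert gamma.method == "mh_heavy"

    def test_report_round_trip(self, heavy_tail_sample):
        fit = fit_mh_heavy(heavy_tail_sample, config=FAST.replace(seed=64))
        report = fit.to_report()
        assert report["method"] == "mh_heavy"
        assert report["m"] == heavy_tail_sample.m
        assert len(report["acceptance_rates"]) == 2
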