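"""Mixture distributions, hierarchical location model, likelihood and prior."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import norm

from hbtrends.groups import CHILDREN, NON_PREGNANT, PREGNANT
from hbtrends.model import (
    HYPER_NAMES,
    FamilyParameters,
    MixtureDistribution,
    ModelConfig,
    combined_women_pdf,
    individual_loglik,
    location_mean,
    loglik_observation,
    logposterior,
    logprior,
    mixture_cdf,
    mixture_pdf,
    rw2_logpdf,
    summary_loglik_rows,
    total_loglik,
)
from hbtrends.survey_io import HbObservation
from tests.conftest import TINY_MODEL_CFG


def make_params(data, a0=120.0, b0=0.0, delta_val=10.0, tau=12.0, hyper=1.0) -> FamilyParameters:
    """Zeroed parameters with a near-degenerate (near-normal) mixture."""
    is_women = data.family == "women"
    return FamilyParameters(
        a0=a0,
        b0=b0,
        ar=np.zeros(data.R),
        br=np.zeros(data.R),
        ac=np.zeros(data.C),
        bc=np.zeros(data.C),
        u0=np.zeros(data.T),
        ur=np.zeros((data.R, data.T)),
        uc=np.zeros((data.C, data.T)),
        beta=np.zeros(data.P),
        e=np.zeros(data.n_ind_surveys),
        offsets_raw=np.linspace(-2e-6, 2e-6, 5),
        weights=np.full(5, 0.2),
        taus=np.full(5, tau),
        hypers={n: hyper for n in HYPER_NAMES},
        delta=np.full(data.C, delta_val) if is_women else None,
        mu_delta_region=np.full(data.R, delta_val) if is_women else None,
        mu_delta0=delta_val if is_women else None,
    )


SYM = dict(
    offsets=np.array([-4.0, -2.0, 0.0, 2.0, 4.0]),
    weights=np.array([0.1, 0.2, 0.4, 0.2, 0.1]),
    taus=np.full(5, 10.0),
)
SKEW = MixtureDistribution.from_raw(
    118.0, [-30.0, -12.0, 0.0, 8.0, 14.0], [0.06, 0.16, 0.42, 0.26, 0.10], [16, 13, 11, 10, 10]
)


class TestMixtureDistribution:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureDistribution(100.0, SYM["offsets"], SYM["weights"] * 2, SYM["taus"])
        with pytest.raises(ValueError, match="increasing"):
            MixtureDistribution(100.0, SYM["offsets"][::-1], SYM["weights"], SYM["taus"])
        with pytest.raises(ValueError, match="> 0"):
            MixtureDistribution(100.0, SYM["offsets"], SYM["weights"], -SYM["taus"])
        with pytest.raises(ValueError, match="mean identity"):
            MixtureDistribution(100.0, SYM["offsets"] + 1.0, SYM["weights"], SYM["taus"])

    def test_from_raw_pins_mean(self):
        assert abs(SKEW.weights @ SKEW.offsets) < 1e-12
        assert SKEW.mean == 118.0

    def test_degenerate_single_component_is_normal(self):
        d = MixtureDistribution(110.0, np.array([0.0, 1.0, 2.0, 3.0, 4.0]) * 1.0 - 0.0, np.array([1.0, 0.0, 0.0, 0.0, 0.0]), np.full(5, 9.0))
        h = np.linspace(60, 160, 11)
        np.testing.assert_allclose(mixture_pdf(d, h), norm.pdf(h, 110.0, 9.0), atol=1e-12)
        np.testing.assert_allclose(mixture_cdf(d, h), norm.cdf(h, 110.0, 9.0), atol=1e-12)

    def test_pdf_integrates_to_one(self):
        h = np.arange(0.0, 250.0, 0.01)
        assert np.trapezoid(mixture_pdf(SKEW, h), h) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_mixture_symmetry_and_median(self):
        d = MixtureDistribution(120.0, **SYM)
        x = np.linspace(0.1, 50.0, 40)
        np.testing.assert_allclose(mixture_pdf(d, 120.0 + x), mixture_pdf(d, 120.0 - x), atol=1e-14)
        assert mixture_cdf(d, 120.0) == pytest.approx(0.5, abs=1e-14)

    def test_cdf_limits_and_monotonicity(self):
        assert mixture_cdf(SKEW, 1e4) == pytest.approx(1.0)
        assert mixture_cdf(SKEW, 0.0) == pytest.approx(0.0, abs=1e-8)
        cuts = np.linspace(40, 200, 300)
        assert np.all(np.diff(mixture_cdf(SKEW, cuts)) > 0)

    def test_cdf_decreasing_in_location(self):
        lo = MixtureDistribution.from_raw(110.0, SKEW.offsets, SKEW.weights, SKEW.taus)
        hi = MixtureDistribution.from_raw(120.0, SKEW.offsets, SKEW.weights, SKEW.taus)
        assert mixture_cdf(hi, 110.0) < mixture_cdf(lo, 110.0)

    def test_monte_carlo_cdf_oracle(self):
        rng = np.random.default_rng(17)
        frac = float(np.mean(SKEW.rvs(10**6, rng) < 110.0))
        assert mixture_cdf(SKEW, 110.0) == pytest.approx(frac, abs=0.002)


class TestCombinedWomen:
    d_np = MixtureDistribution.from_raw(125.0, SKEW.offsets, SKEW.weights, SKEW.taus)
    d_p = MixtureDistribution.from_raw(114.0, SKEW.offsets, SKEW.weights, SKEW.taus)

    def test_boundaries(self):
        h = np.linspace(60, 180, 25)
        np.testing.assert_allclose(combined_women_pdf(0.0, self.d_np, self.d_p, h), mixture_pdf(self.d_np, h))
        np.testing.assert_allclose(combined_women_pdf(1.0, self.d_np, self.d_p, h), mixture_pdf(self.d_p, h))

    def test_mean_is_linear_in_fraction(self):
        p = 0.3
        h = np.arange(0.0, 260.0, 0.02)
        dens = combined_women_pdf(p, self.d_np, self.d_p, h)
        mean = np.trapezoid(h * dens, h)
        assert mean == pytest.approx((1 - p) * 125.0 + p * 114.0, abs=1e-6)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            combined_women_pdf(1.5, self.d_np, self.d_p, 120.0)


class TestLocationMean:
    def test_collapsed_model_is_global_line(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        p = make_params(data, a0=111.0, b0=0.2)
        for year in (1998.0, 2001.5, 2006.0):
            assert location_mean(p, data, data.countries[0], year, CHILDREN) == pytest.approx(
                111.0 + 0.2 * (year - 2000.0)
            )

    def test_pregnant_is_shifted_by_delta(self, tiny_prepared):
        data = tiny_prepared.families["women"]
        p = make_params(data, a0=125.0, delta_val=9.5)
        th_np = location_mean(p, data, data.countries[1], 2003.0, NON_PREGNANT)
        th_p = location_mean(p, data, data.countries[1], 2003.0, PREGNANT)
        assert th_np - th_p == pytest.approx(9.5)

    def test_reference_year_removes_slope(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        p1 = make_params(data, a0=110.0, b0=0.0)
        p2 = make_params(data, a0=110.0, b0=0.7)
        c = data.countries[0]
        assert location_mean(p1, data, c, 2000.0, CHILDREN) == location_mean(p2, data, c, 2000.0, CHILDREN)

    def test_unknown_country_is_error(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        with pytest.raises(KeyError):
            location_mean(make_params(data), data, "ZZZ", 2000.0, CHILDREN)


def _summary_obs(data, **kw):
    base = dict(
        source_id="t",
        country=data.countries[0],
        year=2002.0,
        group=CHILDREN if data.family == "children" else NON_PREGNANT,
        coverage="national",
        data_form="summary",
        n=400,
        mean_hb=112.0,
        sd_hb=12.0,
    )
    base.update(kw)
    return HbObservation(**base)


class TestLoglik:
    def test_collapses_to_textbook_normal(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        p = make_params(data, a0=110.0, hyper=1e-9)
        obs = _summary_obs(data)
        ll = loglik_observation(p, data, obs)
        th = location_mean(p, data, obs.country, obs.year, CHILDREN)
        expect = norm.logpdf(112.0, th, 12.0 / math.sqrt(400))
        assert ll == pytest.approx(expect, abs=1e-6)

    def test_subnational_flattens_the_likelihood(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        p = make_params(data, a0=110.0, hyper=3.0)
        h = 0.01
        grads = {}
        for cov, nreg in (("national", None), ("subnational", 3)):
            lls = [
                loglik_observation(p, data, _summary_obs(data, coverage=cov, n_regions_covered=nreg, mean_hb=m))
                for m in (118.0 - h, 118.0 + h)
            ]
            grads[cov] = abs(lls[1] - lls[0]) / (2 * h)
        assert grads["subnational"] < grads["national"]

    def test_single_obs_path_matches_vectorised_rows(self, tiny_prepared):
        data = tiny_prepared.families["women"]
        p = make_params(data)
        if data.n_summary == 0:
            pytest.skip("no summary rows in fixture")
        i = 0
        group = [NON_PREGNANT, PREGNANT, "women_combined"][data.s_gcode[i]]
        obs = HbObservation(
            source_id="row0",
            country=data.countries[data.s_country[i]],
            year=float(data.s_year[i]),
            group=group,
            coverage="subnational" if data.s_sub[i] else "national",
            n_regions_covered=3 if data.s_sub[i] else None,
            data_form="summary",
            n=int(data.s_n[i]),
            mean_hb=None if np.isnan(data.s_mean[i]) else float(data.s_mean[i]),
            sd_hb=float(data.s_sd[i]),
            prev_anaemia=None if np.isnan(data.s_prev[i]) else float(data.s_prev[i]),
            prev_severe=None if np.isnan(data.s_prevsev[i]) else float(data.s_prevsev[i]),
            age_range_matches=not data.s_agemis[i],
            pregnant_fraction=float(data.s_pregfrac[i]) if data.s_gcode[i] == 2 else None,
        )
        rows = summary_loglik_rows(p, data, prevalence_mode="always")
        assert loglik_observation(p, data, obs) == pytest.approx(rows[i], abs=1e-9)

    def test_observation_without_content_is_error(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        obs = _summary_obs(data, mean_hb=None, prev_anaemia=None, prev_severe=None)
        with pytest.raises(ValueError, match="neither mean nor prevalence"):
            loglik_observation(make_params(data), data, obs)

    def test_total_is_sum_of_parts(self, tiny_prepared):
        data = tiny_prepared.families["women"]
        p = make_params(data)
        cfg = TINY_MODEL_CFG
        total = total_loglik(p, data, cfg)
        parts = float(np.sum(summary_loglik_rows(p, data, cfg.prevalence_mode))) + individual_loglik(p, data)
        assert total == pytest.approx(parts, rel=1e-12)


class TestPrior:
    def test_shrinkage_monotonic_in_country_deviation(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        cfg = TINY_MODEL_CFG
        p1 = make_params(data)
        p2 = make_params(data)
        p1.ac[0] = 1.0
        p2.ac[0] = 2.0
        assert logprior(p2, data, cfg) < logprior(p1, data, cfg)

    def test_rw2_linear_sequence_is_maximal(self):
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        best = rw2_logpdf(base, 0.5)
        for i in (1, 2, 3):
            for eps in (-0.2, -0.05, 0.05, 0.2):
                u = base.copy()
                u[i] += eps
                assert rw2_logpdf(u, 0.5) < best

    def test_outside_support_is_minus_inf(self, tiny_prepared):
        data = tiny_prepared.families["women"]
        cfg = TINY_MODEL_CFG
        p = make_params(data)
        p.hypers["sigma_ns"] = -1.0
        assert logprior(p, data, cfg) == -math.inf
        p = make_params(data)
        p.delta[0] = -0.5
        assert logprior(p, data, cfg) == -math.inf
        p = make_params(data)
        p.offsets_raw = p.offsets_raw[::-1].copy()
        assert logprior(p, data, cfg) == -math.inf

    def test_logposterior_identity(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        cfg = TINY_MODEL_CFG
        p = make_params(data)
        assert logposterior(p, data, cfg) == pytest.approx(
            logprior(p, data, cfg) + total_loglik(p, data, cfg), rel=1e-12
        )
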