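"""Posterior summaries: centiles, prevalence, aggregation, trends, iron share."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from hbtrends.groups import CHILDREN, NON_PREGNANT, PREGNANT
from hbtrends.inference import FamilyPosterior, PosteriorDraws
from hbtrends.model import HYPER_NAMES, MixtureDistribution, mixture_cdf
from hbtrends.summaries import (
    GLOBE,
    change_per_decade,
    counts,
    estimates_table,
    halving_probability,
    iron_amenable_share,
    per_draw_distribution,
    posterior_probability_increase,
    prevalence,
    scope_metric_draws,
    summarize,
    theta_draws,
)


def constant_posterior(data, a0: float, b0: float = 0.0, S: int = 64, tau: float = 12.0) -> PosteriorDraws:
    """A posterior whose every draw is the same near-normal model."""
    full = lambda shape, v: np.full((1, S) + shape, v, dtype=float)
    R, C, T, P = data.R, data.C, data.T, data.P
    draws = {
        "a0": full((), a0),
        "b0": full((), b0),
        "ar": full((R,), 0.0),
        "br": full((R,), 0.0),
        "ac": full((C,), 0.0),
        "bc": full((C,), 0.0),
        "u0": full((T,), 0.0),
        "ur": full((R, T), 0.0),
        "uc": full((C, T), 0.0),
        "beta": full((P,), 0.0),
        "e": np.zeros((1, S, data.n_ind_surveys)),
        "offsets_raw": np.tile(np.linspace(-2e-6, 2e-6, 5), (1, S, 1)),
        "weights": full((5,), 0.2),
        "taus": full((5,), tau),
        "hypers": full((len(HYPER_NAMES),), 1.0),
    }
    if data.family == "women":
        draws["delta"] = full((C,), 10.0)
        draws["mu_delta_region"] = full((R,), 10.0)
        draws["mu_delta0"] = full((), 10.0)
    fp = FamilyPosterior(data=data, draws=draws, target=S)
    return PosteriorDraws(families={data.family: fp}, meta={})


class TestSummarize:
    def test_order_statistics_oracle(self):
        cell = summarize(np.arange(1.0, 1001.0))
        assert cell.lo == pytest.approx(25.975)
        assert cell.hi == pytest.approx(975.025)
        assert 25 <= cell.lo <= 26 and 975 <= cell.hi <= 976

    def test_constant_draws_collapse(self):
        cell = summarize(np.full(100, 7.5))
        assert cell.lo == cell.point == cell.hi == 7.5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=500)
        a, b = summarize(v), summarize(rng.permutation(v))
        assert (a.lo, a.hi) == (b.lo, b.hi)  # quantiles sort, hence exact
        assert a.point == pytest.approx(b.point, rel=1e-12)

    def test_empty_draws_error_and_small_draws_warn(self):
        with pytest.raises(ValueError):
            summarize(np.array([]))
        with pytest.warns(UserWarning, match="40 draws"):
            summarize(np.arange(10.0))


class TestPerDrawDistribution:
    def test_length_is_S_and_mean_identity(self, tiny_fit):
        d0 = tiny_fit["children"].data
        mixtures = per_draw_distribution(tiny_fit, d0.countries[0], 2002, CHILDREN)
        assert len(mixtures) == tiny_fit.S
        th = theta_draws(tiny_fit, CHILDREN)[:, 0, 2002 - int(d0.years[0])]
        for s in (0, 17, 119):
            assert mixtures[s].mean == pytest.approx(th[s])

    def test_unknown_year_is_error(self, tiny_fit):
        d0 = tiny_fit["children"].data
        with pytest.raises(KeyError):
            per_draw_distribution(tiny_fit, d0.countries[0], 1950, CHILDREN)


class TestPrevalence:
    def test_extreme_cutoff_saturates(self, tiny_fit):
        d0 = tiny_fit["children"].data
        cell = prevalence(tiny_fit, d0.countries[0], 2002, CHILDREN, cutoff=250.0)
        assert cell.point == pytest.approx(1.0, abs=1e-9)

    def test_severe_nested_in_total_per_draw(self, tiny_fit, tiny_prepared):
        rm = tiny_prepared.region_map
        for g in (CHILDREN, PREGNANT, NON_PREGNANT):
            tot = scope_metric_draws(tiny_fit, GLOBE, GLOBE, 2002, g, "prev_total", rm)
            sev = scope_metric_draws(tiny_fit, GLOBE, GLOBE, 2002, g, "prev_severe", rm)
            assert np.all(sev <= tot)

    def test_monotone_in_cutoff(self, tiny_fit):
        d0 = tiny_fit["children"].data
        pts = [
            prevalence(tiny_fit, d0.countries[0], 2002, CHILDREN, cutoff=c).point
            for c in (70.0, 90.0, 110.0, 130.0, 150.0)
        ]
        assert all(a < b for a, b in zip(pts, pts[1:]))

    def test_matches_monte_carlo_fraction(self, tiny_fit):
        d0 = tiny_fit["children"].data
        d = per_draw_distribution(tiny_fit, d0.countries[0], 2002, CHILDREN)[0]
        rng = np.random.default_rng(9)
        frac = float(np.mean(d.rvs(10**6, rng) < 110.0))
        assert mixture_cdf(d, 110.0) == pytest.approx(frac, abs=0.002)


class TestAggregation:
    def test_two_equal_population_countries_average(self, tiny_prepared, tiny_fit):
        import pandas as pd

        from hbtrends.survey_io import RegionMap

        d0 = tiny_fit["children"].data
        c1, c2 = d0.countries[0], d0.countries[1]
        pop = pd.DataFrame(
            [
                {"country": c, "year": 2002, "group": CHILDREN, "population": 1e6}
                for c in d0.countries
            ]
        )
        rm = RegionMap(region_of=dict(tiny_prepared.region_map.region_of), population=pop)
        region = rm.region_of[c1]
        members = [c for c in d0.countries if rm.region_of[c] == region]
        agg = scope_metric_draws(tiny_fit, "region", region, 2002, CHILDREN, "prev_total", rm)
        per_country = [
            scope_metric_draws(tiny_fit, "country", c, 2002, CHILDREN, "prev_total", rm)
            for c in members
        ]
        np.testing.assert_allclose(agg, np.mean(per_country, axis=0), rtol=1e-14)

    def test_global_conservation_per_draw(self, tiny_fit, tiny_prepared):
        rm = tiny_prepared.region_map
        d0 = tiny_fit["children"].data
        glob = scope_metric_draws(tiny_fit, GLOBE, GLOBE, 2002, CHILDREN, "prev_total", rm)
        pops = np.array([rm.population_of(c, 2002, CHILDREN) for c in d0.countries])
        per_c = np.stack(
            [scope_metric_draws(tiny_fit, "country", c, 2002, CHILDREN, "prev_total", rm) for c in d0.countries],
            axis=1,
        )
        np.testing.assert_allclose(glob, per_c @ pops / pops.sum(), rtol=1e-12)

    def test_missing_population_names_country(self, tiny_fit, tiny_prepared):
        import pandas as pd

        from hbtrends.survey_io import RegionMap

        d0 = tiny_fit["children"].data
        pop = tiny_prepared.region_map.population
        dropped = d0.countries[0]
        rm = RegionMap(
            region_of={c: r for c, r in tiny_prepared.region_map.region_of.items() if c != dropped} | {dropped: "R1"},
            population=pop[pop.country != dropped],
        )
        with pytest.raises(KeyError, match=dropped):
            scope_metric_draws(tiny_fit, GLOBE, GLOBE, 2002, CHILDREN, "prev_total", rm)


class TestCounts:
    def test_count_is_prevalence_times_population(self, tiny_fit, tiny_prepared):
        rm = tiny_prepared.region_map
        d0 = tiny_fit["children"].data
        c = d0.countries[0]
        prev = scope_metric_draws(tiny_fit, "country", c, 2002, CHILDREN, "prev_total", rm)
        cnt = scope_metric_draws(tiny_fit, "country", c, 2002, CHILDREN, "count_total", rm)
        np.testing.assert_allclose(cnt, prev * rm.population_of(c, 2002, CHILDREN), rtol=1e-14)

    def test_severe_counts_nested(self, tiny_fit, tiny_prepared):
        rm = tiny_prepared.region_map
        tot = counts(tiny_fit, GLOBE, GLOBE, 2002, CHILDREN, rm, severe=False)
        sev = counts(tiny_fit, GLOBE, GLOBE, 2002, CHILDREN, rm, severe=True)
        assert sev.point <= tot.point and sev.hi <= tot.hi

    def test_region_counts_sum_to_globe(self, tiny_fit, tiny_prepared):
        rm = tiny_prepared.region_map
        glob = scope_metric_draws(tiny_fit, GLOBE, GLOBE, 2002, CHILDREN, "count_total", rm)
        regs = sum(
            scope_metric_draws(tiny_fit, "region", r, 2002, CHILDREN, "count_total", rm)
            for r in rm.regions
        )
        np.testing.assert_allclose(glob, regs, rtol=1e-6)


class TestTrends:
    def test_mean_change_closed_form(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        pdd = constant_posterior(data, a0=100.0, b0=1.0)  # +1 g/L per year
        cell = change_per_decade(pdd, "country", data.countries[0], CHILDREN, "mean_hb", y1=1998, y2=2006)
        assert cell.point == pytest.approx(10.0, abs=1e-9)
        assert cell.lo == pytest.approx(cell.hi)

    def test_no_change_is_zero(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        pdd = constant_posterior(data, a0=100.0, b0=0.0)
        for metric in ("mean_hb", "prev_total"):
            cell = change_per_decade(pdd, "country", data.countries[0], CHILDREN, metric, y1=1998, y2=2006)
            assert cell.point == pytest.approx(0.0, abs=1e-9)

    def test_prevalence_halving_geometric_closed_form(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        # craft a trend whose prevalence halves from 0.30 to 0.15 over 8 years
        f = lambda th, p: norm.cdf(110.0, th, 12.0) - p
        th1 = brentq(lambda t: f(t, 0.30), 80.0, 150.0)
        th2 = brentq(lambda t: f(t, 0.15), 80.0, 150.0)
        b0 = (th2 - th1) / 8.0
        a0 = th1 + 2.0 * b0  # so that theta(1998) = th1 with t_ref = 2000
        pdd = constant_posterior(data, a0=a0, b0=b0)
        cell = change_per_decade(pdd, "country", data.countries[0], CHILDREN, "prev_total", y1=1998, y2=2006)
        assert cell.point == pytest.approx(0.5 ** (10.0 / 8.0) - 1.0, abs=1e-4)
        arith = change_per_decade(
            pdd, "country", data.countries[0], CHILDREN, "prev_total", y1=1998, y2=2006, convention="arithmetic"
        )
        assert arith.point == pytest.approx(-0.5 * 10.0 / 8.0, abs=1e-4)

    def test_probability_all_increasing(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        pdd = constant_posterior(data, a0=100.0, b0=0.5)
        p = posterior_probability_increase(pdd, "country", data.countries[0], CHILDREN, "mean_hb", 1998, 2006)
        assert p == 1.0

    def test_probability_ties_count_half(self, tiny_fit):
        d0 = tiny_fit["children"].data
        c = d0.countries[0]
        assert posterior_probability_increase(tiny_fit, "country", c, CHILDREN, "mean_hb", 2002, 2002) == 0.5

    def test_probability_complementarity(self, tiny_fit):
        d0 = tiny_fit["children"].data
        c = d0.countries[0]
        p12 = posterior_probability_increase(tiny_fit, "country", c, CHILDREN, "mean_hb", 1999, 2005)
        p21 = posterior_probability_increase(tiny_fit, "country", c, CHILDREN, "mean_hb", 2005, 1999)
        assert p12 + p21 == pytest.approx(1.0)


class TestIronShare:
    NEAR_NORMAL = MixtureDistribution.from_raw(
        110.0, np.linspace(-2e-6, 2e-6, 5), np.full(5, 0.2), np.full(5, 12.0)
    )

    def test_normal_closed_form(self):
        share = iron_amenable_share(self.NEAR_NORMAL, shift=8.0, cutoff=110.0)
        expect = (0.5 - norm.cdf(-8.0 / 12.0)) / 0.5
        assert share == pytest.approx(expect, abs=1e-6)
        assert share == pytest.approx(0.495, abs=1e-3)

    def test_limits(self):
        assert iron_amenable_share(self.NEAR_NORMAL, shift=1e6, cutoff=110.0) == pytest.approx(1.0)
        assert iron_amenable_share(self.NEAR_NORMAL, shift=1e-9, cutoff=110.0) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_shift(self):
        shares = [iron_amenable_share(self.NEAR_NORMAL, s, 110.0) for s in (1.0, 4.0, 8.0, 16.0, 32.0)]
        assert all(a < b for a, b in zip(shares, shares[1:]))

    def test_zero_baseline_prevalence_is_error(self):
        with pytest.raises(ValueError, match="zero baseline"):
            iron_amenable_share(self.NEAR_NORMAL, shift=8.0, cutoff=-500.0)


class TestHalving:
    def test_zero_trend_never_halves(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        pdd = constant_posterior(data, a0=105.0, b0=0.0)
        assert halving_probability(pdd, "country", data.countries[0], CHILDREN, base_year=2006) == 0.0

    def test_strong_improvement_always_halves(self, tiny_prepared):
        data = tiny_prepared.families["children"]
        pdd = constant_posterior(data, a0=105.0, b0=2.0)
        assert halving_probability(pdd, "country", data.countries[0], CHILDREN, base_year=2006) == 1.0


class TestEstimatesTable:
    def test_row_count_closed_form_and_uniqueness(self, tiny_fit, tiny_prepared):
        rm = tiny_prepared.region_map
        tbl = estimates_table(tiny_fit, rm, years=[1999, 2005])
        d0 = tiny_fit["children"].data
        n_scopes = len(d0.countries) + len(rm.regions) + 1
        assert len(tbl) == n_scopes * 2 * 3 * 5
        assert not tbl.duplicated(["scope", "scope_id", "year", "group", "metric"]).any()
        assert (tbl.lo <= tbl.point + 1e-12).all() and (tbl.point <= tbl.hi + 1e-12).all()
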