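"""MCMC fitting: retained-draw contract, determinism, diagnostics, checks."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from hbtrends.inference import (
    FamilyPosterior,
    FitConfig,
    PosteriorDraws,
    diagnostics,
    fit,
    load_draws,
    posterior_predictive_check,
    save_draws,
)
from hbtrends.model import prepare_family_data
from hbtrends.pipeline import prepare_from_csv
from hbtrends.synthetic import (
    SurveyDesign,
    WorldConfig,
    generate_surveys,
    generate_true_world,
    write_surveys,
    write_world,
)
from tests.conftest import TINY_MODEL_CFG


class TestRetainedDraws:
    def test_default_fit_config_targets_2500(self):
        assert FitConfig().target_retained == 2500

    def test_pooled_count_exact_regardless_of_chains(self, tiny_fit):
        assert tiny_fit.S == 120
        for fp in tiny_fit.families.values():
            assert fp.pooled("a0").shape[0] == 120

    def test_odd_chain_split_still_exact(self, tiny_prepared):
        pdd = fit(
            {"children": tiny_prepared.families["children"]},
            TINY_MODEL_CFG,
            FitConfig(chains=3, warmup=10, target_retained=50, seed=2),
        )
        assert pdd["children"].pooled("a0").shape[0] == 50

    def test_same_seed_identical_draws(self, tiny_prepared):
        fc = FitConfig(chains=1, warmup=25, target_retained=30, seed=12)
        data = {"children": tiny_prepared.families["children"]}
        a = fit(data, TINY_MODEL_CFG, fc)
        b = fit(data, TINY_MODEL_CFG, fc)
        for name in a["children"].draws:
            np.testing.assert_array_equal(a["children"].draws[name], b["children"].draws[name])


class TestPosteriorSanity:
    def test_single_country_posterior_tracks_survey_mean(self, tmp_path):
        cfg = WorldConfig(n_regions=1, countries_per_region=1, year_start=1998, year_end=2006, seed=11)
        design = SurveyDesign(
            surveys_per_country_per_decade=3.0,
            frac_summary_only=0.0,
            frac_subnational=0.0,
            frac_unadjusted_altitude=0.0,
            frac_age_mismatch=0.0,
            n_per_survey=(800, 1200),
        )
        world = generate_true_world(cfg)
        individuals, observations = generate_surveys(world, design, seed=4)
        write_world(world, tmp_path)
        write_surveys(individuals, observations, tmp_path)
        prep = prepare_from_csv(tmp_path, TINY_MODEL_CFG)
        data = prep.families["children"]
        assert data.n_cells >= 1
        pdd = fit({"children": data}, TINY_MODEL_CFG, FitConfig(chains=2, warmup=120, target_retained=200, seed=6))
        from hbtrends.summaries import theta_draws

        th = theta_draws(pdd, "children")  # (S, 1, T)
        for j in range(data.n_cells):
            sample_mean = float(data.rec_hb[data.rec_cell == j].mean())
            cell_draws = th[:, 0, data.cell_tidx[j]]
            post_mean, post_sd = cell_draws.mean(), cell_draws.std()
            assert abs(post_mean - sample_mean) < 2.0 * post_sd + 2.0

    def test_no_data_posterior_matches_prior(self, tiny_prepared, tiny_world):
        from hbtrends.survey_io import read_region_map

        region_map = tiny_prepared.region_map
        covs = tiny_world.covariates
        data = prepare_family_data([], [], covs, region_map, "children", TINY_MODEL_CFG)
        pdd = fit({"children": data}, TINY_MODEL_CFG, FitConfig(chains=2, warmup=150, target_retained=400, seed=8))
        # with no data the sigma_ns posterior is its half-normal prior
        from hbtrends.model import HYPER_NAMES

        i = HYPER_NAMES.index("sigma_ns")
        draws = pdd["children"].pooled("hypers")[:, i]
        scale = TINY_MODEL_CFG.sigma_ns_scale
        prior_mean = scale * math.sqrt(2.0 / math.pi)
        prior_sd = scale * math.sqrt(1.0 - 2.0 / math.pi)
        assert abs(draws.mean() - prior_mean) < 0.25 * prior_mean
        assert abs(draws.std() - prior_sd) < 0.25 * prior_sd


def _fake_posterior(data, arr):
    return PosteriorDraws(families={"children": FamilyPosterior(data=data, draws={"x": arr}, target=arr.shape[0] * arr.shape[1])}, meta={})


class TestDiagnostics:
    def test_iid_chains_pass(self, tiny_prepared):
        rng = np.random.default_rng(0)
        pdd = _fake_posterior(tiny_prepared.families["children"], rng.standard_normal((2, 600)))
        rep = diagnostics(pdd)
        assert len(rep) == 1
        assert rep.rhat.iloc[0] == pytest.approx(1.0, abs=0.02)
        assert rep.attrs["pass"]

    def test_disjoint_chains_fail(self, tiny_prepared):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((2, 600))
        arr[1] += 10.0
        rep = diagnostics(_fake_posterior(tiny_prepared.families["children"], arr))
        assert rep.rhat.iloc[0] > 1.5
        assert not rep.attrs["pass"]

    def test_single_chain_warns_and_omits_rhat(self, tiny_prepared):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="single chain"):
            rep = diagnostics(_fake_posterior(tiny_prepared.families["children"], rng.standard_normal((1, 600))))
        assert np.isnan(rep.rhat.iloc[0])

    def test_row_count_is_number_of_scalars(self, tiny_fit):
        rep = diagnostics(tiny_fit)
        expected = sum(
            int(np.prod(a.shape[2:])) if a.ndim > 2 else 1
            for fp in tiny_fit.families.values()
            for a in fp.draws.values()
        )
        assert len(rep) == expected


class TestPosteriorPredictive:
    def test_one_row_per_mean_reporting_summary(self, tiny_fit):
        rep = posterior_predictive_check(tiny_fit, seed=1)
        expected = sum(
            int(np.sum(~np.isnan(fp.data.s_mean))) for fp in tiny_fit.families.values()
        )
        assert len(rep) == expected

    def test_indicator_consistent_and_coverage_reasonable(self, tiny_fit):
        rep = posterior_predictive_check(tiny_fit, seed=1)
        for _, r in rep.iterrows():
            assert r.inside == (r.pred_lo <= r.observed <= r.pred_hi)
        # data were simulated from the model family itself
        assert rep.attrs["coverage"] >= 0.7


class TestPersistence:
    def test_round_trip_identical(self, tiny_fit, tmp_path):
        save_draws(tiny_fit, tmp_path)
        back = load_draws(tmp_path, {f: fp.data for f, fp in tiny_fit.families.items()})
        assert back.S == tiny_fit.S
        for fam, fp in tiny_fit.families.items():
            for name, arr in fp.draws.items():
                np.testing.assert_array_equal(back[fam].draws[name], arr)
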