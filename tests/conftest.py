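"""Shared fixtures: a small synthetic world, its CSVs, and a quick fit."""

from __future__ import annotations

import pytest

from hbtrends.inference import FitConfig, fit
from hbtrends.model import ModelConfig
from hbtrends.pipeline import prepare_from_csv
from hbtrends.synthetic import (
    SurveyDesign,
    WorldConfig,
    generate_surveys,
    generate_true_world,
    write_surveys,
    write_world,
)

TINY_WORLD_CFG = WorldConfig(
    n_regions=2, countries_per_region=2, year_start=1998, year_end=2006, seed=42
)
TINY_DESIGN = SurveyDesign(surveys_per_country_per_decade=4.0, n_per_survey=(150, 400))
TINY_MODEL_CFG = ModelConfig(year_start=1998, year_end=2006)


@pytest.fixture(scope="session")
def tiny_world():
    return generate_true_world(TINY_WORLD_CFG)


@pytest.fixture(scope="session")
def tiny_data_dir(tmp_path_factory, tiny_world):
    d = tmp_path_factory.mktemp("tinydata")
    individuals, observations = generate_surveys(tiny_world, TINY_DESIGN, seed=7)
    write_world(tiny_world, d)
    write_surveys(individuals, observations, d)
    return d


@pytest.fixture(scope="session")
def tiny_prepared(tiny_data_dir):
    return prepare_from_csv(tiny_data_dir, TINY_MODEL_CFG)


@pytest.fixture(scope="session")
def tiny_fit(tiny_prepared):
    return fit(
        tiny_prepared.families,
        TINY_MODEL_CFG,
        FitConfig(chains=2, warmup=80, target_retained=120, seed=3),
    )
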