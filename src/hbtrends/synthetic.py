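"""Synthetic world and survey generator with known ground truth.

The generator mirrors the data-generating assumptions of the hierarchical
model: country locations follow a global linear trend plus region and
country deviations in intercept and slope, a smooth nonlinear component
(second-order random walk, detrended so it carries curvature only), and
covariate effects; pregnant women's locations sit a country-specific
8-15 g/L below non-pregnant women's.  Population haemoglobin distributions
are mildly left-skewed five-component normal mixtures whose analytic mean
equals the location by construction.

Surveys are then drawn with the heterogeneity of real compilations:
individual-level and summary-only sources, national and subnational
coverage, pooled pregnant/non-pregnant ("combined-women") reporting,
sources left unadjusted for altitude, non-sampling noise beyond sampling
error, and sources whose age range does not match the target groups.
Everything is deterministic given the configured seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adjustments import AltitudeDistribution, cdc_altitude_shift, mean_shift_for_distribution, write_altitude_bands
from .groups import (
    CHILDREN,
    DEFAULT_CUTOFFS,
    ESTIMATE_GROUPS,
    FAMILY_CHILDREN,
    FAMILY_OF,
    FAMILY_WOMEN,
    NON_PREGNANT,
    PREGNANCY_WEEKS_THRESHOLD,
    PREGNANT,
    WOMEN_COMBINED,
    CutoffSet,
)
from .model import MixtureDistribution, mixture_cdf
from .survey_io import (
    COVARIATE_COLUMNS,
    CountryYearCovariate,
    HbObservation,
    IndividualRecord,
    write_individuals,
    write_observations,
)

#: fraction of biologically pregnant women past the 8-week operational
#: threshold when gestational age is uniform on [0, 42] weeks
OPERATIONAL_PREGNANT_SHARE = (42.0 - PREGNANCY_WEEKS_THRESHOLD) / 42.0


@dataclass(frozen=True)
class MixtureShape:
    """Raw (un-centred) component offsets, weights and sds of a family."""

    raw_offsets: tuple[float, ...] = (-30.0, -12.0, 0.0, 8.0, 14.0)
    weights: tuple[float, ...] = (0.06, 0.16, 0.42, 0.26, 0.10)
    taus: tuple[float, ...] = (16.0, 13.0, 11.0, 10.0, 10.0)

    def mixture(self, theta: float) -> MixtureDistribution:
        return MixtureDistribution.from_raw(theta, self.raw_offsets, self.weights, self.taus)


@dataclass(frozen=True)
class WorldConfig:
    """Ground-truth configuration of the synthetic world."""

    n_regions: int = 2
    countries_per_region: int = 5
    year_start: int = 1990
    year_end: int = 2012
    seed: int = 2013

    # global lines (g/L at the 2000 reference; slopes per decade)
    global_intercept: Mapping[str, float] = field(
        default_factory=lambda: {FAMILY_CHILDREN: 110.0, FAMILY_WOMEN: 125.0}
    )
    global_slope_per_decade: Mapping[str, float] = field(
        default_factory=lambda: {FAMILY_CHILDREN: 1.5, FAMILY_WOMEN: 0.8}
    )
    region_intercept_sd: float = 5.0
    country_intercept_sd: float = 4.0
    region_slope_sd_per_decade: float = 1.0
    country_slope_sd_per_decade: float = 0.8
    # RW2 innovation sds (g/L); the simulated walks are detrended so these
    # control curvature, not level or slope.  The global value keeps the
    # world-mean trajectory smooth and near-monotone (peak-to-peak curvature
    # well under 1 g/L), matching the reported global series; countries and
    # regions fluctuate more (curvature around 1 g/L).
    nonlinear_sd_global: float = 0.04
    nonlinear_sd_region: float = 0.08
    nonlinear_sd_country: float = 0.08
    pregnancy_offset_range: tuple[float, float] = (8.0, 15.0)
    pregnant_share_range: tuple[float, float] = (0.04, 0.08)

    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            FAMILY_CHILDREN: {
                "maternal_education": 0.4,
                "urban_prop": 2.0,
                "abs_latitude": 0.05,
                "hb_disorder_prev": -30.0,
                "mean_waz": 2.0,
            },
            FAMILY_WOMEN: {
                "maternal_education": 0.4,
                "urban_prop": 2.0,
                "abs_latitude": 0.05,
                "hb_disorder_prev": -30.0,
                "mean_bmi": 0.3,
            },
        }
    )
    mixture_shape: Mapping[str, MixtureShape] = field(
        default_factory=lambda: {FAMILY_CHILDREN: MixtureShape(), FAMILY_WOMEN: MixtureShape()}
    )
    #: shape of the pregnant mixture; defaults to the non-pregnant one
    #: (switchable for robustness experiments)
    pregnant_shape: MixtureShape | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ValueError("need at least one region and one country per region")
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("year span must cover at least 3 years")
        lo, hi = self.pregnancy_offset_range
        if not (0 < lo <= hi):
            raise ValueError("pregnancy offsets must be positive")


@dataclass(frozen=True)
class SurveyDesign:
    """Heterogeneity of the simulated survey compilation."""

    surveys_per_country_per_decade: float = 1.8
    #: probability that a survey measures each group, mirroring real
    #: compilations where most sources cover both children and women
    p_measure_children: float = 0.9
    p_measure_women: float = 0.85
    frac_summary_only: float = 0.4
    frac_combined_women: float = 0.25
    frac_subnational: float = 0.15
    frac_unadjusted_altitude: float = 0.15
    frac_age_mismatch: float = 0.1
    n_per_survey: tuple[int, int] = (300, 1200)
    nonsampling_sd: float = 2.5  # g/L
    subnational_extra_sd: float = 2.0
    age_extra_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("frac_summary_only", "frac_combined_women", "frac_subnational", "frac_unadjusted_altitude", "frac_age_mismatch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_survey[0] < 2 or self.n_per_survey[1] < self.n_per_survey[0]:
            raise ValueError("invalid n_per_survey range")


@dataclass
class TrueWorld:
    """Ground truth: locations, offsets, covariates, and side tables."""

    config: WorldConfig
    years: np.ndarray
    regions: list[str]
    countries: list[str]
    region_of: dict[str, str]
    theta: dict[str, np.ndarray]  # family -> (C, T) non-pregnant / children locations
    delta: np.ndarray  # (C,) pregnancy offsets, > 0
    covariates: list[CountryYearCovariate]
    population: pd.DataFrame
    altitude: dict[str, AltitudeDistribution]
    pregnant_share: dict[str, float]  # biologically pregnant share of women

    def theta_at(self, family: str, ci: int, year: float) -> float:
        """True location at a decimal year (linear interpolation on the grid)."""
        return float(np.interp(year, self.years.astype(float), self.theta[family][ci]))

    def mixture_for(self, country: str, year: float, group: str) -> MixtureDistribution:
        ci = self.countries.index(country)
        fam = FAMILY_OF[group]
        th = self.theta_at(fam, ci, year)
        if group == PREGNANT:
            th -= float(self.delta[ci])
            shape = self.config.pregnant_shape or self.config.mixture_shape[fam]
        else:
            shape = self.config.mixture_shape[fam]
        return shape.mixture(th)


def _rw2(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Detrended second-order random walk (curvature only)."""
    if sd == 0.0 or n < 3:
        return np.zeros(n)
    u = np.zeros(n)
    for t in range(2, n):
        u[t] = 2 * u[t - 1] - u[t - 2] + rng.normal(0.0, sd)
    t = np.arange(n, dtype=float)
    A = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(A, u, rcond=None)
    return u - A @ coef


def generate_true_world(cfg: WorldConfig) -> TrueWorld:
    """Draw one synthetic world; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    R, K = cfg.n_regions, cfg.countries_per_region
    C = R * K
    regions = [f"R{i + 1}" for i in range(R)]
    # ISO3-like synthetic codes: AAA, AAB, ...
    countries = ["".join(chr(ord("A") + d) for d in (i // 676, (i // 26) % 26, i % 26)) for i in range(C)]
    region_of = {c: regions[i // K] for i, c in enumerate(countries)}
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    T = len(years)
    tc = years.astype(float) - 2000.0

    # covariates
    covs: list[CountryYearCovariate] = []
    cov_grid: dict[str, np.ndarray] = {}
    base = {
        "maternal_education": rng.uniform(2.0, 10.0, C),
        "urban_prop": rng.uniform(0.2, 0.8, C),
        "abs_latitude": rng.uniform(0.0, 50.0, C),
        "hb_disorder_prev": rng.uniform(0.0, 0.08, C),
        "mean_bmi": rng.uniform(21.0, 27.0, C),
        "mean_waz": rng.uniform(-1.5, 0.5, C),
    }
    drift = {
        "maternal_education": 0.05,
        "urban_prop": 0.004,
        "abs_latitude": 0.0,
        "hb_disorder_prev": 0.0,
        "mean_bmi": 0.03,
        "mean_waz": 0.01,
    }
    for nm in base:
        g = base[nm][:, None] + drift[nm] * (tc[None, :] + 10.0)
        if nm == "urban_prop":
            g = np.clip(g, 0.0, 1.0)
        cov_grid[nm] = g
    for ci, c in enumerate(countries):
        for ti, y in enumerate(years):
            covs.append(
                CountryYearCovariate(
                    country=c,
                    year=int(y),
                    **{nm: float(cov_grid[nm][ci, ti]) for nm in base},
                )
            )

    theta: dict[str, np.ndarray] = {}
    for fam in (FAMILY_CHILDREN, FAMILY_WOMEN):
        a_r = rng.normal(0.0, cfg.region_intercept_sd, R)
        b_r = rng.normal(0.0, cfg.region_slope_sd_per_decade / 10.0, R)
        a_c = rng.normal(0.0, cfg.country_intercept_sd, C)
        b_c = rng.normal(0.0, cfg.country_slope_sd_per_decade / 10.0, C)
        u0 = _rw2(rng, T, cfg.nonlinear_sd_global)
        ur = np.stack([_rw2(rng, T, cfg.nonlinear_sd_region) for _ in range(R)])
        uc = np.stack([_rw2(rng, T, cfg.nonlinear_sd_country) for _ in range(C)])
        ridx = np.array([regions.index(region_of[c]) for c in countries])
        th = (
            cfg.global_intercept[fam]
            + a_r[ridx][:, None]
            + a_c[:, None]
            + (cfg.global_slope_per_decade[fam] / 10.0 + b_r[ridx][:, None] + b_c[:, None]) * tc[None, :]
            + u0[None, :]
            + ur[ridx]
            + uc
        )
        for nm, eff in cfg.covariate_effects[fam].items():
            th = th + eff * cov_grid[nm]
        theta[fam] = th

    delta = rng.uniform(*cfg.pregnancy_offset_range, C)
    pregnant_share = {c: float(rng.uniform(*cfg.pregnant_share_range)) for c in countries}

    # populations (persons), mild exponential growth
    rows = []
    child_pop0 = rng.uniform(0.5e6, 5e6, C)
    women_pop0 = child_pop0 * rng.uniform(3.0, 5.0, C)
    for ci, c in enumerate(countries):
        for ti, y in enumerate(years):
            grow = 1.01 ** (ti)
            wp = women_pop0[ci] * grow
            preg = wp * pregnant_share[c] * OPERATIONAL_PREGNANT_SHARE
            rows.append({"country": c, "year": int(y), "group": CHILDREN, "population": child_pop0[ci] * grow})
            rows.append({"country": c, "year": int(y), "group": PREGNANT, "population": preg})
            rows.append({"country": c, "year": int(y), "group": NON_PREGNANT, "population": wp - preg})
    population = pd.DataFrame(rows)

    # altitude: one high-altitude country per region, the rest lowland
    altitude: dict[str, AltitudeDistribution] = {}
    for i, c in enumerate(countries):
        if i % K == K - 1:  # last country of each region is mountainous
            altitude[c] = AltitudeDistribution(c, ((200.0, 0.6), (1800.0, 0.25), (2600.0, 0.15)))
        else:
            altitude[c] = AltitudeDistribution(c, ((200.0, 1.0),))

    return TrueWorld(
        config=cfg,
        years=years,
        regions=regions,
        countries=countries,
        region_of=region_of,
        theta=theta,
        delta=delta,
        covariates=covs,
        population=population,
        altitude=altitude,
        pregnant_share=pregnant_share,
    )


def world_truth_table(world: TrueWorld, cutoffs: CutoffSet = DEFAULT_CUTOFFS) -> pd.DataFrame:
    """True mean and anaemia prevalences per country-year-group."""
    rows = []
    for c in world.countries:
        for y in world.years:
            for g in ESTIMATE_GROUPS:
                d = world.mixture_for(c, float(y), g)
                rows.append(
                    {
                        "country": c,
                        "year": int(y),
                        "group": g,
                        "true_mean": d.mean,
                        "true_prev": mixture_cdf(d, cutoffs.total[g]),
                        "true_severe_prev": mixture_cdf(d, cutoffs.severe[g]),
                    }
                )
    return pd.DataFrame(rows)


def _survey_altitudes(rng, alt: AltitudeDistribution, n: int) -> np.ndarray:
    mids = np.array([m for m, _ in alt.bands])
    shares = np.array([s for _, s in alt.bands])
    return mids[rng.choice(len(mids), size=n, p=shares / shares.sum())]


def _summarize(hb: np.ndarray, cut_t: np.ndarray | float, cut_s: np.ndarray | float):
    return (
        float(hb.mean()),
        float(hb.std(ddof=1)),
        float(np.mean(hb < cut_t)),
        float(np.mean(hb < cut_s)),
    )


def generate_surveys(
    world: TrueWorld,
    design: SurveyDesign = SurveyDesign(),
    seed: int = 0,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> tuple[list[IndividualRecord], list[HbObservation]]:
    """Simulate a survey compilation from the true world.

    Returns ``(individuals, observations)``; every survey, including
    individual-level ones, has a metadata row among the observations
    (individual-level rows leave summary statistics blank).
    """
    rng = np.random.default_rng(seed)
    cfg = world.config
    n_years = len(world.years)
    individuals: list[IndividualRecord] = []
    observations: list[HbObservation] = []

    # survey effort concentrates in populous countries (sqrt-damped), so the
    # compilation covers most of the population, as real compilations do
    mid = int(world.years[len(world.years) // 2])
    pop = world.population
    totals = np.array(
        [
            pop[(pop["country"] == c) & (pop["year"] == mid)]["population"].sum()
            for c in world.countries
        ]
    )
    weight = np.sqrt(totals)
    weight = weight / weight.mean()
    total_rate = design.surveys_per_country_per_decade * n_years / 10.0

    for ci, country in enumerate(world.countries):
        n_surv = rng.poisson(total_rate * weight[ci])
        for k in range(n_surv):
            sid = f"SVY-{country}-{k:03d}"
            year = round(float(rng.uniform(world.years[0], world.years[-1])), 1)
            summary_only = rng.random() < design.frac_summary_only
            subnational = rng.random() < design.frac_subnational
            agemis = rng.random() < design.frac_age_mismatch
            unadj_alt = rng.random() < design.frac_unadjusted_altitude
            n_regions_covered = int(rng.choice([2, 3, 4, 5], p=[0.25, 0.35, 0.25, 0.15])) if subnational else None
            coverage = "subnational" if subnational else "national"
            alt = world.altitude[country]
            measured = [
                fam
                for fam, pmeas in ((FAMILY_CHILDREN, design.p_measure_children), (FAMILY_WOMEN, design.p_measure_women))
                if rng.random() < pmeas
            ]

            common = dict(
                country=country,
                year=year,
                coverage=coverage,
                n_regions_covered=n_regions_covered,
                smoking_adjusted=bool(rng.random() < 0.5),
                age_range_matches=not agemis,
            )

            for fam in measured:
                shape = cfg.mixture_shape[fam]
                p_shape = cfg.pregnant_shape or shape
                n = int(rng.integers(design.n_per_survey[0], design.n_per_survey[1] + 1))
                var = design.nonsampling_sd**2
                if subnational:
                    var += design.subnational_extra_sd**2
                if agemis:
                    var += design.age_extra_sd**2
                offset = rng.normal(0.0, np.sqrt(var))
                th = world.theta_at(fam, ci, year) + offset

                if fam == FAMILY_CHILDREN:
                    hb = shape.mixture(th).rvs(n, rng)
                    weeks = np.full(n, np.nan)
                    groups = np.full(n, CHILDREN, dtype=object)
                    cut_t = np.full(n, cutoffs.total[CHILDREN])
                    cut_s = np.full(n, cutoffs.severe[CHILDREN])
                else:
                    biologically_pregnant = rng.random(n) < world.pregnant_share[country]
                    weeks = np.where(biologically_pregnant, rng.uniform(0.0, 42.0, n), np.nan)
                    op_pregnant = biologically_pregnant & (weeks > PREGNANCY_WEEKS_THRESHOLD)
                    hb = np.empty(n)
                    n_p = int(op_pregnant.sum())
                    hb[~op_pregnant] = shape.mixture(th).rvs(n - n_p, rng)
                    hb[op_pregnant] = p_shape.mixture(th - float(world.delta[ci])).rvs(n_p, rng)
                    groups = np.where(op_pregnant, PREGNANT, NON_PREGNANT).astype(object)
                    cut_t = np.where(op_pregnant, cutoffs.total[PREGNANT], cutoffs.total[NON_PREGNANT])
                    cut_s = np.where(op_pregnant, cutoffs.severe[PREGNANT], cutoffs.severe[NON_PREGNANT])

                if unadj_alt:
                    alts = _survey_altitudes(rng, alt, n)
                    hb_meas = hb + cdc_altitude_shift(alts)
                else:
                    alts = None
                    hb_meas = hb

                if summary_only:
                    if fam == FAMILY_WOMEN and rng.random() < design.frac_combined_women:
                        m, s, pt, ps = _summarize(hb_meas, cut_t, cut_s)
                        op_share = float(np.mean(groups == PREGNANT))
                        observations.append(
                            HbObservation(
                                source_id=sid,
                                group=WOMEN_COMBINED,
                                data_form="summary",
                                n=n,
                                mean_hb=m,
                                sd_hb=s,
                                prev_anaemia=pt,
                                prev_severe=ps,
                                altitude_adjusted=not unadj_alt,
                                pregnant_fraction=op_share,
                                **common,
                            )
                        )
                    else:
                        emit = [(CHILDREN, np.ones(n, bool))] if fam == FAMILY_CHILDREN else [
                            (NON_PREGNANT, groups == NON_PREGNANT),
                            (PREGNANT, groups == PREGNANT),
                        ]
                        for g, mask in emit:
                            if mask.sum() < 10 and g == PREGNANT:
                                continue  # too few pregnant women measured to report
                            m, s, pt, ps = _summarize(hb_meas[mask], cutoffs.total[g], cutoffs.severe[g])
                            observations.append(
                                HbObservation(
                                    source_id=sid,
                                    group=g,
                                    data_form="summary",
                                    n=int(mask.sum()),
                                    mean_hb=m,
                                    sd_hb=s,
                                    prev_anaemia=pt,
                                    prev_severe=ps,
                                    altitude_adjusted=not unadj_alt,
                                    **common,
                                )
                            )
                else:
                    grp_meta = CHILDREN if fam == FAMILY_CHILDREN else NON_PREGNANT
                    observations.append(
                        HbObservation(
                            source_id=sid,
                            group=grp_meta,
                            data_form="individual",
                            n=n,
                            altitude_adjusted=not unadj_alt,
                            **common,
                        )
                    )
                    for i in range(n):
                        individuals.append(
                            IndividualRecord(
                                source_id=sid,
                                country=country,
                                year=year,
                                group=str(groups[i]),
                                hb=float(hb_meas[i]),
                                altitude_m=None if alts is None else float(alts[i]),
                                gestational_weeks=None if np.isnan(weeks[i]) else float(weeks[i]),
                                age=float(rng.uniform(6, 59)) if fam == FAMILY_CHILDREN else float(rng.uniform(15, 49)),
                                altitude_adjusted=not unadj_alt,
                            )
                        )
    return individuals, observations


def write_world(world: TrueWorld, out_dir, cutoffs: CutoffSet = DEFAULT_CUTOFFS) -> dict[str, Path]:
    """Write the world's side tables and truth table as CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cov = pd.DataFrame([dataclasses.asdict(c) for c in world.covariates], columns=COVARIATE_COLUMNS)
    paths["covariates"] = out / "covariates.csv"
    cov.to_csv(paths["covariates"], index=False)
    paths["regions"] = out / "regions.csv"
    pd.DataFrame(
        {"country": world.countries, "region": [world.region_of[c] for c in world.countries]}
    ).to_csv(paths["regions"], index=False)
    paths["population"] = out / "population.csv"
    world.population.to_csv(paths["population"], index=False)
    paths["altitude_bands"] = out / "altitude_bands.csv"
    write_altitude_bands(list(world.altitude.values()), paths["altitude_bands"])
    paths["truth"] = out / "truth.csv"
    world_truth_table(world, cutoffs).to_csv(paths["truth"], index=False)
    return paths


def write_surveys(individuals, observations, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"observations": out / "observations.csv", "individuals": out / "individuals.csv"}
    write_observations(observations, paths["observations"])
    write_individuals(individuals, paths["individuals"])
    return paths
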