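"""Bayesian hierarchical normal-mixture model for haemoglobin distributions.

The population haemoglobin distribution of a country-year-group is a
five-component normal mixture whose location (analytic mean) follows a
hierarchical regression:

    theta[c, t] = (a0 + a_r + a_c) + (b0 + b_r + b_c) (t - t_ref)
                  + u0(t) + u_r(t) + u_c(t) + x[c, t]' beta

with global/regional/national intercepts and linear slopes, smooth
nonlinear trends u(.) modelled as second-order random walks at each level,
and country-year covariates.  Pregnant women's location is the non-pregnant
location minus a nonnegative country-level pregnancy offset delta_c, itself
shrunk toward a region mean.  The mixture shape (ordered component offsets
o_k with sum_k w_k o_k = 0, weights w_k, component sds tau_k) is shared
across countries within a family, so the analytic mean of every mixture
equals its location theta exactly.

Children and women are fitted as separate model families; within the
women's family the pregnant and non-pregnant mixtures share shape and
differ by location only.

Observation likelihoods:

* individual records: sum of log mixture densities at the record's cell;
* summary means:  Normal(mean_hb; theta, sd^2/n + sigma_ns^2
  [+ sigma_sub^2 if subnational] [+ sigma_age^2 if age range mismatched]);
* summary prevalences: Normal(prev; F(cutoff), p(1-p)/n + f(cutoff)^2 *
  design variance) — a first-order propagation of the same design variance;
* combined-women sources: pregnancy-fraction mixtures of the two women's
  distributions, for both densities and cdfs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import log_ndtr  # noqa: F401  (handy for tail-safe work)
from scipy.stats import norm

from .groups import (
    CHILDREN,
    DEFAULT_CUTOFFS,
    FAMILY_CHILDREN,
    FAMILY_OF,
    FAMILY_WOMEN,
    NON_PREGNANT,
    PREGNANT,
    WOMEN_COMBINED,
    CutoffSet,
)
from .survey_io import (
    FAMILY_COVARIATES,
    CountryYearCovariate,
    HbObservation,
    IndividualRecord,
    RegionMap,
    classify_pregnancy,
    flag_out_of_range,
)

_LOG_2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x, mu, sd):
    z = (np.asarray(x, float) - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


# --------------------------------------------------------------------------
# mixture distribution
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureDistribution:
    """A K-component normal mixture with analytic mean pinned to ``theta``.

    Component offsets are strictly increasing (label-switching guard) and
    satisfy sum_k w_k o_k = 0, so the mean of the mixture is exactly the
    location parameter.
    """

    theta: float
    offsets: np.ndarray
    weights: np.ndarray
    taus: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.offsets, float)
        w = np.asarray(self.weights, float)
        t = np.asarray(self.taus, float)
        if not (o.shape == w.shape == t.shape) or o.ndim != 1:
            raise ValueError("offsets, weights, taus must be 1-d and equally sized")
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("weights must be nonnegative and sum to 1")
        w = w / w.sum()  # renormalise to machine precision
        if np.any(np.diff(o) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(t <= 0):
            raise ValueError("component sds must be > 0")
        if abs(float(w @ o)) > 1e-8:
            raise ValueError("sum_k w_k o_k must be 0 (mean identity)")
        object.__setattr__(self, "offsets", o)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "taus", t)

    @classmethod
    def from_raw(cls, theta, raw_offsets, weights, taus) -> "MixtureDistribution":
        """Build a valid mixture by recentring raw offsets to zero mean."""
        w = np.asarray(weights, float)
        w = w / w.sum()
        o = np.asarray(raw_offsets, float)
        return cls(theta=float(theta), offsets=o - float(w @ o), weights=w, taus=np.asarray(taus, float))

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def mean(self) -> float:
        return self.theta

    @property
    def variance(self) -> float:
        w, o, t = self.weights, self.offsets, self.taus
        return float(w @ (t**2 + o**2))

    def pdf(self, h):
        return mixture_pdf(self, h)

    def cdf(self, h):
        return mixture_cdf(self, h)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.choice(self.k, size=size, p=self.weights)
        return self.theta + self.offsets[z] + rng.standard_normal(size) * self.taus[z]


def mixture_pdf(d: MixtureDistribution, h):
    """Density of the mixture at haemoglobin ``h`` (g/L), vectorised."""
    h = np.asarray(h, float)
    out = np.zeros_like(h, dtype=float)
    for w, o, t in zip(d.weights, d.offsets, d.taus):
        out = out + w * norm.pdf(h, d.theta + o, t)
    return float(out) if out.ndim == 0 else out


def mixture_cdf(d: MixtureDistribution, cutoff):
    """P(Hb < cutoff) under the mixture, vectorised over cutoffs."""
    c = np.asarray(cutoff, float)
    out = np.zeros_like(c, dtype=float)
    for w, o, t in zip(d.weights, d.offsets, d.taus):
        out = out + w * norm.cdf(c, d.theta + o, t)
    return float(out) if out.ndim == 0 else out


def combined_women_pdf(pregnant_fraction: float, d_np: MixtureDistribution, d_p: MixtureDistribution, h):
    """Density for pooled pregnant + non-pregnant women."""
    if not 0.0 <= pregnant_fraction <= 1.0:
        raise ValueError("pregnant_fraction must be in [0, 1]")
    return (1.0 - pregnant_fraction) * mixture_pdf(d_np, h) + pregnant_fraction * mixture_pdf(d_p, h)


def combined_women_cdf(pregnant_fraction: float, d_np: MixtureDistribution, d_p: MixtureDistribution, c):
    if not 0.0 <= pregnant_fraction <= 1.0:
        raise ValueError("pregnant_fraction must be in [0, 1]")
    return (1.0 - pregnant_fraction) * mixture_cdf(d_np, c) + pregnant_fraction * mixture_cdf(d_p, c)


def rw2_logpdf(u: np.ndarray, sd: float) -> float:
    """Second-order random-walk smoothness prior: Normal second differences.

    Improper in the intercept and slope directions; identification is added
    separately via soft sum-to-zero and zero-mean-slope constraints.
    """
    u = np.asarray(u, float)
    if sd <= 0:
        return -math.inf
    d2 = u[2:] - 2.0 * u[1:-1] + u[:-2]
    return float(np.sum(_norm_logpdf(d2, 0.0, sd)))


# --------------------------------------------------------------------------
# configuration and parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Hyperprior scales and structural switches for one model family."""

    year_start: int = 1990
    year_end: int = 2012
    t_ref: float = 2000.0
    n_components: int = 5
    #: how reported prevalences enter the likelihood.  A survey's mean and
    #: prevalence are computed from the same sample, so treating both as
    #: independent data double-counts the draw; by default prevalences are
    #: used only for sources that report no mean.
    prevalence_mode: str = "when_mean_absent"  # | "always" | "never"

    a0_scale: float = 50.0
    # slope and smoothness scales are kept at epidemiologically plausible
    # magnitudes: observed national haemoglobin trends rarely exceed a few
    # g/L per decade
    b0_scale: float = 0.3  # g/L per year
    region_intercept_scale: float = 10.0
    region_slope_scale: float = 0.15
    country_intercept_scale: float = 10.0
    country_slope_scale: float = 0.1
    rw2_scale_global: float = 0.2
    rw2_scale_region: float = 0.1
    rw2_scale_country: float = 0.1
    sigma_ns_scale: float = 5.0
    sigma_sub_scale: float = 5.0
    sigma_age_scale: float = 5.0
    # per standardised covariate unit; effects beyond ~2 g/L per sd of a
    # national covariate are not epidemiologically plausible
    beta_scale: float = 2.0

    delta_mu0_loc: float = 11.0
    delta_mu0_scale: float = 5.0
    delta_region_scale: float = 3.0
    sigma_delta_scale: float = 3.0

    dirichlet_alpha: float = 2.0
    offset_prior_scale: float = 20.0
    tau_prior_scale: float = 15.0

    rw2_constraint_sd: float = 1e-3  # soft identification of RW2 level/slope
    summary_sd_impute: float = 12.0  # g/L, when a summary source omits sd
    prev_floor: float = 1e-4  # floor on p(1-p) in the prevalence variance


HYPER_NAMES = (
    "sd_ar",
    "sd_br",
    "sd_ac",
    "sd_bc",
    "sd_u0",
    "sd_ur",
    "sd_uc",
    "sigma_ns",
    "sigma_sub",
    "sigma_age",
    "sigma_delta",
)


@dataclass
class FamilyParameters:
    """All latent quantities of one model family (children or women)."""

    a0: float
    b0: float
    ar: np.ndarray  # (R,)
    br: np.ndarray
    ac: np.ndarray  # (C,)
    bc: np.ndarray
    u0: np.ndarray  # (T,)
    ur: np.ndarray  # (R, T)
    uc: np.ndarray  # (C, T)
    beta: np.ndarray  # (P,)
    e: np.ndarray  # survey effects for individual-level surveys (S_ind,)
    offsets_raw: np.ndarray  # (K,) strictly increasing
    weights: np.ndarray  # (K,) simplex
    taus: np.ndarray  # (K,) > 0
    hypers: dict[str, float]
    delta: np.ndarray | None = None  # (C,), women only, >= 0
    mu_delta_region: np.ndarray | None = None  # (R,)
    mu_delta0: float | None = None

    @property
    def offsets(self) -> np.ndarray:
        """Recentred component offsets (mean identity sum_k w_k o_k = 0)."""
        return self.offsets_raw - float(self.weights @ self.offsets_raw)

    def mixture(self, theta: float) -> MixtureDistribution:
        return MixtureDistribution(
            theta=float(theta), offsets=self.offsets, weights=self.weights, taus=self.taus
        )

    def copy(self) -> "FamilyParameters":
        return FamilyParameters(
            a0=self.a0,
            b0=self.b0,
            ar=self.ar.copy(),
            br=self.br.copy(),
            ac=self.ac.copy(),
            bc=self.bc.copy(),
            u0=self.u0.copy(),
            ur=self.ur.copy(),
            uc=self.uc.copy(),
            beta=self.beta.copy(),
            e=self.e.copy(),
            offsets_raw=self.offsets_raw.copy(),
            weights=self.weights.copy(),
            taus=self.taus.copy(),
            hypers=dict(self.hypers),
            delta=None if self.delta is None else self.delta.copy(),
            mu_delta_region=None if self.mu_delta_region is None else self.mu_delta_region.copy(),
            mu_delta0=self.mu_delta0,
        )


# --------------------------------------------------------------------------
# prepared dataset
# --------------------------------------------------------------------------

# group codes within a family
G_MAIN = 0  # children, or non-pregnant women
G_PREGNANT = 1
G_COMBINED = 2


@dataclass
class FamilyModelData:
    """Survey data and design structures for one family, ready to fit."""

    family: str
    countries: list[str]
    regions: list[str]
    region_idx: np.ndarray  # (C,) region index per country
    years: np.ndarray  # (T,) integer year grid
    t_ref: float
    covariate_names: list[str]
    X: np.ndarray  # (C, T, P) standardised covariates
    X_mean: np.ndarray
    X_sd: np.ndarray
    cutoffs: CutoffSet

    # summary observations (one row per summary cell)
    s_country: np.ndarray
    s_tidx: np.ndarray
    s_year: np.ndarray
    s_gcode: np.ndarray
    s_n: np.ndarray
    s_mean: np.ndarray  # nan when absent
    s_sd: np.ndarray  # imputed where the source omitted it
    s_prev: np.ndarray  # nan when absent
    s_prevsev: np.ndarray
    s_sub: np.ndarray  # bool
    s_agemis: np.ndarray  # bool
    s_pregfrac: np.ndarray  # pregnant fraction, 0 for non-combined rows

    # individual-level data, grouped into (survey x group) cells
    cell_country: np.ndarray
    cell_tidx: np.ndarray
    cell_year: np.ndarray
    cell_gcode: np.ndarray  # G_MAIN or G_PREGNANT
    cell_survey: np.ndarray  # index into survey-effect vector
    rec_hb: np.ndarray  # (N,)
    rec_cell: np.ndarray  # (N,) cell index per record
    isurv_sub: np.ndarray  # per individual-level survey
    isurv_agemis: np.ndarray
    isurv_source: list[str]

    n_out_of_range: int = 0

    @property
    def C(self) -> int:
        return len(self.countries)

    @property
    def R(self) -> int:
        return len(self.regions)

    @property
    def T(self) -> int:
        return len(self.years)

    @property
    def P(self) -> int:
        return len(self.covariate_names)

    @property
    def n_summary(self) -> int:
        return len(self.s_country)

    @property
    def n_cells(self) -> int:
        return len(self.cell_country)

    @property
    def n_ind_surveys(self) -> int:
        return len(self.isurv_sub)

    def total_cutoff(self, gcode: int) -> float:
        g = CHILDREN if self.family == FAMILY_CHILDREN else (PREGNANT if gcode == G_PREGNANT else NON_PREGNANT)
        return self.cutoffs.total[g]

    def severe_cutoff(self, gcode: int) -> float:
        g = CHILDREN if self.family == FAMILY_CHILDREN else (PREGNANT if gcode == G_PREGNANT else NON_PREGNANT)
        return self.cutoffs.severe[g]


def prepare_family_data(
    observations: Sequence[HbObservation],
    individuals: Sequence[IndividualRecord],
    covariates: Sequence[CountryYearCovariate],
    region_map: RegionMap,
    family: str,
    config: ModelConfig = ModelConfig(),
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
    pregnancy_rates: Mapping[str, float] | None = None,
) -> FamilyModelData:
    """Assemble the per-family dataset consumed by the sampler.

    ``observations`` must already have passed inclusion rules and the
    altitude/smoking policies.  Individual women's records are classified by
    the operational pregnancy rule here; out-of-plausible-range records are
    flagged and excluded from the likelihood with a logged count.
    ``pregnancy_rates`` supplies a country-level pregnant fraction for
    combined-women sources that did not record one.
    """
    fam_groups = {g for g, f in FAMILY_OF.items() if f == family}
    obs = [o for o in observations if o.group in fam_groups]
    recs = [r for r in individuals if r.group in fam_groups]

    countries = region_map.countries()
    country_idx = {c: i for i, c in enumerate(countries)}
    regions = region_map.regions
    region_idx = np.array([regions.index(region_map.region_of[c]) for c in countries])
    years = np.arange(config.year_start, config.year_end + 1)
    tidx_of = lambda y: int(np.clip(round(y) - config.year_start, 0, len(years) - 1))

    # covariate grid, standardised
    names = FAMILY_COVARIATES[family]
    cov_lookup = {(cv.country, cv.year): cv for cv in covariates}
    X = np.empty((len(countries), len(years), len(names)))
    for ci, c in enumerate(countries):
        for ti, y in enumerate(years):
            cv = cov_lookup.get((c, int(y)))
            if cv is None:
                raise ValueError(f"missing covariates for ({c}, {y})")
            X[ci, ti] = [getattr(cv, nm) for nm in names]
    X_mean = X.reshape(-1, len(names)).mean(axis=0)
    X_sd = X.reshape(-1, len(names)).std(axis=0)
    X_sd[X_sd == 0] = 1.0
    Xs = (X - X_mean) / X_sd

    def gcode_of(group: str) -> int:
        if family == FAMILY_CHILDREN:
            return G_MAIN
        return {NON_PREGNANT: G_MAIN, PREGNANT: G_PREGNANT, WOMEN_COMBINED: G_COMBINED}[group]

    # ---- summary rows
    srows = [o for o in obs if o.data_form == "summary"]
    s_country = np.array([country_idx[o.country] for o in srows], dtype=int)
    s_tidx = np.array([tidx_of(o.year) for o in srows], dtype=int)
    s_year = np.array([o.year for o in srows], dtype=float)
    s_gcode = np.array([gcode_of(o.group) for o in srows], dtype=int)
    s_n = np.array([o.n for o in srows], dtype=float)
    s_mean = np.array([np.nan if o.mean_hb is None else o.mean_hb for o in srows])
    s_sd = np.array(
        [config.summary_sd_impute if o.sd_hb is None else o.sd_hb for o in srows], dtype=float
    )
    s_prev = np.array([np.nan if o.prev_anaemia is None else o.prev_anaemia for o in srows])
    s_prevsev = np.array([np.nan if o.prev_severe is None else o.prev_severe for o in srows])
    s_sub = np.array([o.coverage == "subnational" for o in srows], dtype=bool)
    s_agemis = np.array([not o.age_range_matches for o in srows], dtype=bool)
    pf = []
    for o in srows:
        if gcode_of(o.group) == G_COMBINED:
            if o.pregnant_fraction is not None:
                pf.append(o.pregnant_fraction)
            elif pregnancy_rates and o.country in pregnancy_rates:
                pf.append(pregnancy_rates[o.country])
            else:
                raise ValueError(
                    f"combined-women source {o.source_id} lacks pregnant_fraction and no "
                    "country pregnancy rate was supplied"
                )
        else:
            pf.append(0.0)
    s_pregfrac = np.array(pf, dtype=float)

    # ---- individual records, classified and grouped into cells
    ind_meta = {o.source_id: o for o in obs if o.data_form == "individual"}
    recs = [r for r in recs if r.source_id in ind_meta]
    recs, flagged = flag_out_of_range(recs)
    cells: dict[tuple[str, int], int] = {}
    cell_country, cell_tidx, cell_year, cell_gcode, cell_survey = [], [], [], [], []
    surveys: dict[str, int] = {}
    isurv_sub, isurv_agemis, isurv_source = [], [], []
    rec_hb, rec_cell = [], []
    for r in recs:
        meta = ind_meta[r.source_id]
        if family == FAMILY_WOMEN:
            g = G_PREGNANT if classify_pregnancy(r) == PREGNANT else G_MAIN
        else:
            g = G_MAIN
        if r.source_id not in surveys:
            surveys[r.source_id] = len(surveys)
            isurv_sub.append(meta.coverage == "subnational")
            isurv_agemis.append(not meta.age_range_matches)
            isurv_source.append(r.source_id)
        key = (r.source_id, g)
        if key not in cells:
            cells[key] = len(cell_country)
            cell_country.append(country_idx[r.country or meta.country])
            cell_tidx.append(tidx_of(r.year if r.year is not None else meta.year))
            cell_year.append(float(r.year if r.year is not None else meta.year))
            cell_gcode.append(g)
            cell_survey.append(surveys[r.source_id])
        rec_hb.append(r.hb)
        rec_cell.append(cells[key])

    return FamilyModelData(
        family=family,
        countries=countries,
        regions=regions,
        region_idx=region_idx,
        years=years,
        t_ref=config.t_ref,
        covariate_names=names,
        X=Xs,
        X_mean=X_mean,
        X_sd=X_sd,
        cutoffs=cutoffs,
        s_country=s_country,
        s_tidx=s_tidx,
        s_year=s_year,
        s_gcode=s_gcode,
        s_n=s_n,
        s_mean=s_mean,
        s_sd=s_sd,
        s_prev=s_prev,
        s_prevsev=s_prevsev,
        s_sub=s_sub,
        s_agemis=s_agemis,
        s_pregfrac=s_pregfrac,
        cell_country=np.array(cell_country, dtype=int),
        cell_tidx=np.array(cell_tidx, dtype=int),
        cell_year=np.array(cell_year, dtype=float),
        cell_gcode=np.array(cell_gcode, dtype=int),
        cell_survey=np.array(cell_survey, dtype=int),
        rec_hb=np.array(rec_hb, dtype=float),
        rec_cell=np.array(rec_cell, dtype=int),
        isurv_sub=np.array(isurv_sub, dtype=bool),
        isurv_agemis=np.array(isurv_agemis, dtype=bool),
        isurv_source=isurv_source,
        n_out_of_range=len(flagged),
    )


# --------------------------------------------------------------------------
# location model
# --------------------------------------------------------------------------


def theta_grid(params: FamilyParameters, data: FamilyModelData) -> np.ndarray:
    """Non-pregnant / children location theta[c, t] on the integer year grid."""
    t_c = data.years.astype(float) - data.t_ref  # (T,)
    r = data.region_idx
    a = params.a0 + params.ar[r][:, None] + params.ac[:, None]  # (C, 1)
    b = params.b0 + params.br[r][:, None] + params.bc[:, None]
    u = params.u0[None, :] + params.ur[r, :] + params.uc
    return a + b * t_c[None, :] + u + data.X @ params.beta


def location_mean(
    params: FamilyParameters,
    data: FamilyModelData,
    country: str,
    year: float,
    group: str,
) -> float:
    """Location theta (g/L) for a country-year-group.

    The linear trend uses the exact (possibly decimal) year; the nonlinear
    random-walk component and the covariates are read at the nearest grid
    year.  The pregnant group's location is the non-pregnant one minus the
    country's pregnancy offset.
    """
    if country not in data.countries:
        raise KeyError(f"unknown country {country!r}")
    ci = data.countries.index(country)
    ri = int(data.region_idx[ci])
    ti = int(np.clip(round(year) - int(data.years[0]), 0, data.T - 1))
    th = (
        params.a0
        + params.ar[ri]
        + params.ac[ci]
        + (params.b0 + params.br[ri] + params.bc[ci]) * (year - data.t_ref)
        + params.u0[ti]
        + params.ur[ri, ti]
        + params.uc[ci, ti]
        + float(data.X[ci, ti] @ params.beta)
    )
    if group == PREGNANT:
        if params.delta is None:
            raise ValueError("model family has no pregnancy offsets")
        th -= params.delta[ci]
    elif group not in (CHILDREN, NON_PREGNANT):
        raise ValueError(f"location_mean is defined per estimate group, got {group!r}")
    return float(th)


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------


def _design_var(params: FamilyParameters, sub, agemis):
    h = params.hypers
    return (
        h["sigma_ns"] ** 2
        + np.where(sub, h["sigma_sub"] ** 2, 0.0)
        + np.where(agemis, h["sigma_age"] ** 2, 0.0)
    )


def summary_loglik_rows(
    params: FamilyParameters,
    data: FamilyModelData,
    prevalence_mode: str = "always",
    prev_floor: float = 1e-4,
    include_mean: bool = True,
) -> np.ndarray:
    """Per-row log-likelihood of every summary observation."""
    if data.n_summary == 0:
        return np.zeros(0)
    th = theta_grid(params, data)  # (C, T)
    t_exact = data.s_year - data.t_ref
    t_grid = data.years[data.s_tidx].astype(float) - data.t_ref
    r = data.region_idx[data.s_country]
    slope = params.b0 + params.br[r] + params.bc[data.s_country]
    th_np = th[data.s_country, data.s_tidx] + slope * (t_exact - t_grid)
    if params.delta is not None:
        d = params.delta[data.s_country]
        th_p = th_np - d
    else:
        th_p = th_np  # unused for children
    pf = data.s_pregfrac
    mean_model = np.where(
        data.s_gcode == G_PREGNANT,
        th_p,
        np.where(data.s_gcode == G_COMBINED, (1 - pf) * th_np + pf * th_p, th_np),
    )
    dvar = _design_var(params, data.s_sub, data.s_agemis)
    var_mean = data.s_sd**2 / data.s_n + dvar
    out = np.zeros(data.n_summary)
    if include_mean:
        has_mean = ~np.isnan(data.s_mean)
        out[has_mean] = _norm_logpdf(
            data.s_mean[has_mean], mean_model[has_mean], np.sqrt(var_mean[has_mean])
        )

    if prevalence_mode != "never":
        stats = prevalence_model_stats(params, data, th_np, th_p, mode=prevalence_mode)
        for which, (idx, p_model, f_model) in stats.items():
            pobs_all = data.s_prev if which == "total" else data.s_prevsev
            pv = np.clip(p_model * (1 - p_model), prev_floor, None)
            var_p = pv / data.s_n[idx] + f_model**2 * dvar[idx]
            out[idx] += _norm_logpdf(pobs_all[idx], p_model, np.sqrt(var_p))
    return out


def _summary_locations(params: FamilyParameters, data: FamilyModelData):
    """Model locations (non-pregnant and pregnant) at every summary row."""
    th = theta_grid(params, data)
    t_exact = data.s_year - data.t_ref
    t_grid = data.years[data.s_tidx].astype(float) - data.t_ref
    r = data.region_idx[data.s_country]
    slope = params.b0 + params.br[r] + params.bc[data.s_country]
    th_np = th[data.s_country, data.s_tidx] + slope * (t_exact - t_grid)
    th_p = th_np - params.delta[data.s_country] if params.delta is not None else th_np
    return th_np, th_p


def _mix_F_f(params: FamilyParameters, theta_arr: np.ndarray, cut: float):
    """Mixture cdf and density at a scalar cutoff, low-overhead."""
    from scipy.special import ndtr

    F = np.zeros_like(theta_arr)
    f = np.zeros_like(theta_arr)
    o, w, tau = params.offsets, params.weights, params.taus
    for wk, ok, tk in zip(w, o, tau):
        z = (cut - theta_arr - ok) / tk
        F += wk * ndtr(z)
        f += (wk / (tk * math.sqrt(2.0 * math.pi))) * np.exp(-0.5 * z * z)
    return F, f


def prevalence_model_stats(
    params: FamilyParameters,
    data: FamilyModelData,
    th_np: np.ndarray | None = None,
    th_p: np.ndarray | None = None,
    mode: str = "always",
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Model prevalence and density-at-cutoff for every reporting row.

    Returns ``{"total"|"severe": (row_idx, p_model, f_model)}``; the design
    variance enters the likelihood separately, so these stats can be reused
    across variance-component updates.
    """
    if th_np is None:
        th_np, th_p = _summary_locations(params, data)
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if mode not in ("always", "when_mean_absent", "never"):
        raise ValueError(f"unknown prevalence mode {mode!r}")
    for which, pobs_all in (("total", data.s_prev), ("severe", data.s_prevsev)):
        has = ~np.isnan(pobs_all)
        if mode == "when_mean_absent":
            has &= np.isnan(data.s_mean)
        if not has.any():
            continue
        idx = np.where(has)[0]
        gc = data.s_gcode[idx]
        cut_np = data.total_cutoff(G_MAIN) if which == "total" else data.severe_cutoff(G_MAIN)
        cut_p = data.total_cutoff(G_PREGNANT) if which == "total" else data.severe_cutoff(G_PREGNANT)
        p_model = np.empty(len(idx))
        f_model = np.empty(len(idx))
        m_main = gc == G_MAIN
        if m_main.any():
            F, f = _mix_F_f(params, th_np[idx[m_main]], cut_np)
            p_model[m_main], f_model[m_main] = F, f
        m_p = gc == G_PREGNANT
        if m_p.any():
            F, f = _mix_F_f(params, th_p[idx[m_p]], cut_p)
            p_model[m_p], f_model[m_p] = F, f
        m_c = gc == G_COMBINED
        if m_c.any():
            pfx = data.s_pregfrac[idx[m_c]]
            F1, f1 = _mix_F_f(params, th_np[idx[m_c]], cut_np)
            F2, f2 = _mix_F_f(params, th_p[idx[m_c]], cut_p)
            p_model[m_c] = (1 - pfx) * F1 + pfx * F2
            f_model[m_c] = (1 - pfx) * f1 + pfx * f2
        out[which] = (idx, p_model, f_model)
    return out


def prevalence_loglik_from_stats(
    data: FamilyModelData,
    stats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    dvar: np.ndarray,
    prev_floor: float = 1e-4,
) -> float:
    """Prevalence log-likelihood given precomputed model stats."""
    ll = 0.0
    for which, (idx, p_model, f_model) in stats.items():
        pobs = (data.s_prev if which == "total" else data.s_prevsev)[idx]
        pv = np.clip(p_model * (1 - p_model), prev_floor, None)
        var_p = pv / data.s_n[idx] + f_model**2 * dvar[idx]
        ll += float(np.sum(_norm_logpdf(pobs, p_model, np.sqrt(var_p))))
    return ll


def individual_loglik(params: FamilyParameters, data: FamilyModelData) -> float:
    """Log-likelihood of all individual records, conditional on survey effects."""
    if len(data.rec_hb) == 0:
        return 0.0
    th = theta_grid(params, data)
    base = th[data.cell_country, data.cell_tidx] + params.e[data.cell_survey]
    if params.delta is not None:
        base = base - np.where(data.cell_gcode == G_PREGNANT, params.delta[data.cell_country], 0.0)
    mu = base[data.rec_cell]
    o, w, tau = params.offsets, params.weights, params.taus
    dens = np.zeros_like(mu)
    resid = data.rec_hb - mu
    for wk, ok, tk in zip(w, o, tau):
        dens += wk * norm.pdf(resid, ok, tk)
    return float(np.sum(np.log(np.clip(dens, 1e-300, None))))


def loglik_observation(
    params: FamilyParameters,
    data: FamilyModelData,
    obs: HbObservation | Sequence[IndividualRecord],
    survey_effect: float = 0.0,
    prevalence_mode: str = "always",
) -> float:
    """Log-likelihood contribution of one observation.

    ``obs`` is either a summary :class:`HbObservation` or a sequence of
    individual records from one source.  For individual records the
    contribution is conditional on the source's non-sampling effect
    (``survey_effect``, default 0).
    """
    if isinstance(obs, HbObservation):
        if obs.data_form != "summary":
            raise ValueError("pass the individual records themselves for individual sources")
        if obs.mean_hb is None and obs.prev_anaemia is None and obs.prev_severe is None:
            raise ValueError(f"observation {obs.source_id} has neither mean nor prevalence")
        sub = prepare_like_row(params, data, obs)
        return float(summary_loglik_rows(params, sub, prevalence_mode=prevalence_mode)[0])
    recs = list(obs)
    if not recs:
        raise ValueError("empty record set")
    ll = 0.0
    for r in recs:
        g = r.group
        if data.family == FAMILY_WOMEN and g in (PREGNANT, NON_PREGNANT, WOMEN_COMBINED):
            g = classify_pregnancy(r)
        th = location_mean(params, data, r.country, r.year, CHILDREN if data.family == FAMILY_CHILDREN else g)
        d = params.mixture(th + survey_effect)
        ll += math.log(max(mixture_pdf(d, r.hb), 1e-300))
    return ll


def prepare_like_row(params, data: FamilyModelData, obs: HbObservation) -> FamilyModelData:
    """A one-row view of ``data`` holding a single summary observation."""
    gcode = (
        G_MAIN
        if data.family == FAMILY_CHILDREN
        else {NON_PREGNANT: G_MAIN, PREGNANT: G_PREGNANT, WOMEN_COMBINED: G_COMBINED}[obs.group]
    )
    ci = data.countries.index(obs.country)
    ti = int(np.clip(round(obs.year) - int(data.years[0]), 0, data.T - 1))
    pregfrac = obs.pregnant_fraction if obs.pregnant_fraction is not None else 0.0
    return replace(
        data,
        s_country=np.array([ci]),
        s_tidx=np.array([ti]),
        s_year=np.array([obs.year]),
        s_gcode=np.array([gcode]),
        s_n=np.array([float(obs.n)]),
        s_mean=np.array([np.nan if obs.mean_hb is None else obs.mean_hb]),
        s_sd=np.array([obs.sd_hb if obs.sd_hb else 12.0]),
        s_prev=np.array([np.nan if obs.prev_anaemia is None else obs.prev_anaemia]),
        s_prevsev=np.array([np.nan if obs.prev_severe is None else obs.prev_severe]),
        s_sub=np.array([obs.coverage == "subnational"]),
        s_agemis=np.array([not obs.age_range_matches]),
        s_pregfrac=np.array([pregfrac]),
    )


def total_loglik(params: FamilyParameters, data: FamilyModelData, config: ModelConfig) -> float:
    return float(
        np.sum(summary_loglik_rows(params, data, config.prevalence_mode, config.prev_floor))
    ) + individual_loglik(params, data)


# --------------------------------------------------------------------------
# prior
# --------------------------------------------------------------------------


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return float(_norm_logpdf(x, 0.0, scale)) + math.log(2.0)


def logprior(params: FamilyParameters, data: FamilyModelData, config: ModelConfig, a0_loc: float | None = None) -> float:
    """Log prior density of a full parameter set (−inf outside support)."""
    h = params.hypers
    for nm in HYPER_NAMES:
        if h[nm] <= 0:
            return -math.inf
    lp = 0.0
    loc0 = config.t_ref * 0 + (a0_loc if a0_loc is not None else 120.0)
    lp += float(_norm_logpdf(params.a0, loc0, config.a0_scale))
    lp += float(_norm_logpdf(params.b0, 0.0, config.b0_scale))
    lp += float(np.sum(_norm_logpdf(params.ar, 0.0, h["sd_ar"])))
    lp += float(np.sum(_norm_logpdf(params.br, 0.0, h["sd_br"])))
    lp += float(np.sum(_norm_logpdf(params.ac, 0.0, h["sd_ac"])))
    lp += float(np.sum(_norm_logpdf(params.bc, 0.0, h["sd_bc"])))
    lp += float(np.sum(_norm_logpdf(params.beta, 0.0, config.beta_scale)))

    tgrid = np.arange(data.T, dtype=float)
    tc = tgrid - tgrid.mean()
    tc_norm = tc / math.sqrt(float(tc @ tc))
    eps = config.rw2_constraint_sd

    def u_prior(u: np.ndarray, sd: float) -> float:
        v = rw2_logpdf(u, sd)
        v += float(_norm_logpdf(u.mean(), 0.0, eps))
        v += float(_norm_logpdf(float(tc_norm @ u), 0.0, eps))
        return v

    lp += u_prior(params.u0, h["sd_u0"])
    for i in range(data.R):
        lp += u_prior(params.ur[i], h["sd_ur"])
    for i in range(data.C):
        lp += u_prior(params.uc[i], h["sd_uc"])

    # hyperpriors
    lp += _half_normal_logpdf(h["sd_ar"], config.region_intercept_scale)
    lp += _half_normal_logpdf(h["sd_br"], config.region_slope_scale)
    lp += _half_normal_logpdf(h["sd_ac"], config.country_intercept_scale)
    lp += _half_normal_logpdf(h["sd_bc"], config.country_slope_scale)
    lp += _half_normal_logpdf(h["sd_u0"], config.rw2_scale_global)
    lp += _half_normal_logpdf(h["sd_ur"], config.rw2_scale_region)
    lp += _half_normal_logpdf(h["sd_uc"], config.rw2_scale_country)
    lp += _half_normal_logpdf(h["sigma_ns"], config.sigma_ns_scale)
    lp += _half_normal_logpdf(h["sigma_sub"], config.sigma_sub_scale)
    lp += _half_normal_logpdf(h["sigma_age"], config.sigma_age_scale)
    lp += _half_normal_logpdf(h["sigma_delta"], config.sigma_delta_scale)

    # survey effects: non-sampling variance (plus extras) as prior variance
    if params.e.size:
        evar = _design_var(params, data.isurv_sub, data.isurv_agemis)
        lp += float(np.sum(_norm_logpdf(params.e, 0.0, np.sqrt(evar))))

    # pregnancy offsets (women only): truncated-normal shrinkage to region means
    if params.delta is not None:
        if np.any(params.delta < 0):
            return -math.inf
        mu_r = params.mu_delta_region[data.region_idx]
        sd_d = h["sigma_delta"]
        lp += float(
            np.sum(
                _norm_logpdf(params.delta, mu_r, sd_d)
                - np.log(np.clip(norm.cdf(mu_r / sd_d), 1e-300, None))
            )
        )
        lp += float(
            np.sum(_norm_logpdf(params.mu_delta_region, params.mu_delta0, config.delta_region_scale))
        )
        lp += float(_norm_logpdf(params.mu_delta0, config.delta_mu0_loc, config.delta_mu0_scale))

    # mixture shape
    w = params.weights
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
        return -math.inf
    if np.any(np.diff(params.offsets_raw) <= 0):
        return -math.inf
    lp += float(np.sum((config.dirichlet_alpha - 1.0) * np.log(w)))
    lp += float(np.sum(_norm_logpdf(params.offsets_raw, 0.0, config.offset_prior_scale)))
    for t in params.taus:
        lp += _half_normal_logpdf(float(t), config.tau_prior_scale)
    return lp


def logposterior(
    params: FamilyParameters, data: FamilyModelData, config: ModelConfig, a0_loc: float | None = None
) -> float:
    """logprior + total log-likelihood (the identity the sampler targets)."""
    lp = logprior(params, data, config, a0_loc=a0_loc)
    if not math.isfinite(lp):
        return lp
    return lp + total_loglik(params, data, config)
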