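"""Posterior summaries: distributions, prevalences, counts, and trends.

Every reported quantity is computed per posterior draw and then summarised:
the point estimate is the posterior mean and the 95% credibility interval
is the 2.5th-97.5th centiles of the draws (linear interpolation between
order statistics, numpy's default quantile rule, applied everywhere).
Regional and global quantities are population-weighted averages of the
constituent countries within each draw, so conservation holds draw by draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .groups import (
    CHILDREN,
    DEFAULT_CUTOFFS,
    ESTIMATE_GROUPS,
    FAMILY_OF,
    NON_PREGNANT,
    PREGNANT,
    CutoffSet,
)
from .inference import FamilyPosterior, PosteriorDraws
from .model import MixtureDistribution, mixture_cdf
from .survey_io import RegionMap

GLOBE = "globe"

METRICS = ("mean_hb", "prev_total", "prev_severe", "count_total", "count_severe")


@dataclass(frozen=True)
class EstimateCell:
    """A summarised posterior quantity with its 95% credibility interval."""

    scope: str  # country | region | globe
    scope_id: str
    year: object
    group: str
    metric: str
    point: float
    lo: float
    hi: float
    S: int


@dataclass(frozen=True)
class IronShift:
    """Mean haemoglobin gains from iron supplementation trials (g/L)."""

    shifts: Mapping[str, float] = field(
        default_factory=lambda: {PREGNANT: 10.17, NON_PREGNANT: 8.64, CHILDREN: 8.0}
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.shifts.values()):
            raise ValueError("iron shifts must be positive")


DEFAULT_IRON_SHIFTS = IronShift()


def summarize(values: np.ndarray, cell_kw: dict | None = None) -> EstimateCell:
    """Posterior mean and central 95% interval of per-draw values."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty draw set")
    if v.size < 40:
        warnings.warn("fewer than 40 draws: centiles are unstable", stacklevel=2)
    kw = dict(scope="", scope_id="", year=None, group="", metric="")
    kw.update(cell_kw or {})
    return EstimateCell(
        point=float(v.mean()),
        lo=float(np.quantile(v, 0.025)),
        hi=float(np.quantile(v, 0.975)),
        S=int(v.size),
        **kw,
    )


# --------------------------------------------------------------------------
# per-draw building blocks
# --------------------------------------------------------------------------


def theta_draws(pd_draws: PosteriorDraws, group: str) -> np.ndarray:
    """Location draws (S, C, T) for an estimate group on the year grid."""
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    tc = d.years.astype(float) - d.t_ref
    r = d.region_idx
    a0, b0 = fp.pooled("a0"), fp.pooled("b0")
    ar, br = fp.pooled("ar"), fp.pooled("br")
    ac, bc = fp.pooled("ac"), fp.pooled("bc")
    u0, ur, uc = fp.pooled("u0"), fp.pooled("ur"), fp.pooled("uc")
    beta = fp.pooled("beta")
    th = (
        (a0[:, None] + ar[:, r] + ac)[:, :, None]
        + (b0[:, None] + br[:, r] + bc)[:, :, None] * tc[None, None, :]
        + u0[:, None, :]
        + ur[:, r, :]
        + uc
        + np.einsum("ctp,sp->sct", d.X, beta)
    )
    if group == PREGNANT:
        th = th - fp.pooled("delta")[:, :, None]
    return th


def shape_draws(fp: FamilyPosterior):
    """Recentred offsets, weights and component sds per pooled draw (S, K)."""
    raw = fp.pooled("offsets_raw")
    w = fp.pooled("weights")
    o = raw - np.sum(w * raw, axis=1, keepdims=True)
    return o, w, fp.pooled("taus")


def mixture_cdf_draws(fp: FamilyPosterior, th: np.ndarray, cutoff: float) -> np.ndarray:
    """F(cutoff) per draw for location array ``th`` of shape (S, ...)."""
    o, w, tau = shape_draws(fp)
    extra = (1,) * (th.ndim - 1)
    out = np.zeros_like(th)
    for k in range(o.shape[1]):
        ok = o[:, k].reshape(-1, *extra)
        wk = w[:, k].reshape(-1, *extra)
        tk = tau[:, k].reshape(-1, *extra)
        out += wk * norm.cdf((cutoff - th - ok) / tk)
    return out


def per_draw_distribution(
    pd_draws: PosteriorDraws, country: str, year: int, group: str
) -> list[MixtureDistribution]:
    """One mixture per retained draw for a country-year-group (length S)."""
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    if country not in d.countries:
        raise KeyError(f"unknown country {country!r}")
    if int(year) not in d.years:
        raise KeyError(f"year {year} outside the fitted grid")
    ci = d.countries.index(country)
    ti = int(year) - int(d.years[0])
    th = theta_draws(pd_draws, group)[:, ci, ti]
    o, w, tau = shape_draws(fp)
    return [
        MixtureDistribution(theta=float(th[s]), offsets=o[s], weights=w[s], taus=tau[s])
        for s in range(fp.S)
    ]


def _pop_vector(region_map: RegionMap, countries: Sequence[str], year: int, group: str) -> np.ndarray:
    df = region_map.population
    sel = df[(df["year"] == int(year)) & (df["group"] == group)]
    lut = dict(zip(sel["country"], sel["population"]))
    missing = [c for c in countries if c not in lut]
    if missing:
        raise KeyError(f"missing population for {missing} in {year}/{group}")
    return np.array([lut[c] for c in countries], dtype=float)


def _country_metric_draws(
    pd_draws: PosteriorDraws,
    group: str,
    year: int,
    metric: str,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Per-draw country values (S, C) for mean or prevalence metrics."""
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    ti = int(year) - int(d.years[0])
    if not 0 <= ti < d.T:
        raise KeyError(f"year {year} outside the fitted grid")
    th = theta_draws(pd_draws, group)[:, :, ti]
    if metric == "mean_hb":
        return th
    if metric in ("prev_total", "count_total"):
        return mixture_cdf_draws(fp, th, cutoffs.total[group])
    if metric in ("prev_severe", "count_severe"):
        return mixture_cdf_draws(fp, th, cutoffs.severe[group])
    raise ValueError(f"unknown metric {metric!r}")


def scope_metric_draws(
    pd_draws: PosteriorDraws,
    scope: str,
    scope_id: str,
    year: int,
    group: str,
    metric: str,
    region_map: RegionMap | None = None,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Per-draw values of any metric at country, region, or global scope.

    Regional/global prevalences and means are population-weighted averages
    of the member countries per draw; counts are prevalence x population
    summed over member countries.
    """
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    base_metric = metric
    is_count = metric.startswith("count")
    vals = _country_metric_draws(pd_draws, group, year, base_metric, cutoffs)  # (S, C)
    if scope == "country":
        ci = d.countries.index(scope_id)
        if is_count:
            if region_map is None:
                raise ValueError("counts need a region map with populations")
            pop = _pop_vector(region_map, [scope_id], year, group)[0]
            return vals[:, ci] * pop
        return vals[:, ci]
    if region_map is None:
        raise ValueError("regional/global scopes need a region map with populations")
    if scope == "region":
        members = [c for c in d.countries if region_map.region_of[c] == scope_id]
        if not members:
            raise KeyError(f"unknown region {scope_id!r}")
    elif scope == GLOBE:
        members = list(d.countries)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    idx = [d.countries.index(c) for c in members]
    pop = _pop_vector(region_map, members, year, group)
    sub = vals[:, idx]
    if is_count:
        return sub @ pop
    return (sub @ pop) / pop.sum()


# --------------------------------------------------------------------------
# reported quantities
# --------------------------------------------------------------------------


def prevalence(
    pd_draws: PosteriorDraws,
    country: str,
    year: int,
    group: str,
    cutoff: float | None = None,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> EstimateCell:
    """Country anaemia prevalence at a cutoff (default: the group's total)."""
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    ci = d.countries.index(country)
    ti = int(year) - int(d.years[0])
    cut = cutoffs.total[group] if cutoff is None else float(cutoff)
    if cut <= 0:
        raise ValueError("cutoff must be positive")
    th = theta_draws(pd_draws, group)[:, ci, ti]
    draws = mixture_cdf_draws(fp, th, cut)
    return summarize(
        draws,
        dict(scope="country", scope_id=country, year=int(year), group=group, metric="prev"),
    )


def aggregate(
    pd_draws: PosteriorDraws,
    scope: str,
    year: int,
    group: str,
    region_map: RegionMap,
    metric: str = "prev_total",
    scope_id: str | None = None,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Per-draw population-weighted regional or global values."""
    return scope_metric_draws(
        pd_draws, scope, scope_id or scope, year, group, metric, region_map, cutoffs
    )


def counts(
    pd_draws: PosteriorDraws,
    scope: str,
    scope_id: str,
    year: int,
    group: str,
    region_map: RegionMap,
    severe: bool = False,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> EstimateCell:
    """Number of people with (severe) anaemia in a scope-year-group."""
    metric = "count_severe" if severe else "count_total"
    draws = scope_metric_draws(pd_draws, scope, scope_id, year, group, metric, region_map, cutoffs)
    return summarize(
        draws, dict(scope=scope, scope_id=scope_id, year=int(year), group=group, metric=metric)
    )


def change_per_decade(
    pd_draws: PosteriorDraws,
    scope: str,
    scope_id: str,
    group: str,
    metric: str,
    region_map: RegionMap | None = None,
    y1: int = 1995,
    y2: int = 2011,
    convention: str = "geometric",
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> EstimateCell:
    """Change per decade between two years, per draw then summarised.

    Mean haemoglobin changes are absolute (g/L per decade).  Prevalence
    changes are proportional per decade; the default geometric convention is
    ((p2/p1)^(10/(y2-y1)) - 1), with an arithmetic alternative
    ((p2-p1)/p1 * 10/(y2-y1)) behind the ``convention`` flag.  Draws with
    zero baseline prevalence are excluded with a logged count.
    """
    if y2 <= y1:
        raise ValueError("y2 must exceed y1")
    v1 = scope_metric_draws(pd_draws, scope, scope_id, y1, group, metric, region_map, cutoffs)
    v2 = scope_metric_draws(pd_draws, scope, scope_id, y2, group, metric, region_map, cutoffs)
    span = 10.0 / (y2 - y1)
    if metric == "mean_hb":
        ch = (v2 - v1) * span
    else:
        ok = v1 > 0
        if not ok.all():
            warnings.warn(f"{int((~ok).sum())} draw(s) with zero baseline prevalence excluded", stacklevel=2)
        v1, v2 = v1[ok], v2[ok]
        if convention == "geometric":
            ch = np.power(v2 / v1, span) - 1.0
        elif convention == "arithmetic":
            ch = (v2 - v1) / v1 * span
        else:
            raise ValueError(f"unknown convention {convention!r}")
    return summarize(
        ch,
        dict(scope=scope, scope_id=scope_id, year=f"{y1}-{y2}", group=group, metric=f"{metric}_change_per_decade"),
    )


def posterior_probability_increase(
    pd_draws: PosteriorDraws,
    scope: str,
    scope_id: str,
    group: str,
    metric: str,
    y1: int,
    y2: int,
    region_map: RegionMap | None = None,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> float:
    """Posterior probability that the metric increased between y1 and y2.

    0.50 means an increase is statistically indistinguishable from a
    decrease; ties count one half.
    """
    v1 = scope_metric_draws(pd_draws, scope, scope_id, y1, group, metric, region_map, cutoffs)
    v2 = scope_metric_draws(pd_draws, scope, scope_id, y2, group, metric, region_map, cutoffs)
    return float(np.mean(v2 > v1) + 0.5 * np.mean(v2 == v1))


def iron_amenable_share(d: MixtureDistribution, shift: float, cutoff: float) -> float:
    """Share of anaemia removed when anaemic individuals gain ``shift`` g/L.

    share = (F(cutoff) - F(cutoff - shift)) / F(cutoff).  Shifting only the
    sub-cutoff portion and shifting the whole distribution give the same
    post-shift prevalence F(cutoff - shift), so the two readings of
    "applying the supplementation shift" coincide for this statistic.
    """
    if shift <= 0:
        raise ValueError("shift must be positive")
    base = mixture_cdf(d, cutoff)
    if base <= 0:
        raise ValueError("zero baseline prevalence: share undefined")
    return float((base - mixture_cdf(d, cutoff - shift)) / base)


def iron_amenable_share_draws(
    pd_draws: PosteriorDraws,
    scope: str,
    scope_id: str,
    year: int,
    group: str,
    region_map: RegionMap | None = None,
    shifts: IronShift = DEFAULT_IRON_SHIFTS,
    severe: bool = False,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Per-draw iron-amenable share at any scope (population-weighted)."""
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    ti = int(year) - int(d.years[0])
    cut = (cutoffs.severe if severe else cutoffs.total)[group]
    shift = shifts.shifts[group]
    th = theta_draws(pd_draws, group)[:, :, ti]
    base = mixture_cdf_draws(fp, th, cut)
    shifted = mixture_cdf_draws(fp, th, cut - shift)
    if scope == "country":
        ci = d.countries.index(scope_id)
        b, s = base[:, ci], shifted[:, ci]
    else:
        if region_map is None:
            raise ValueError("regional/global scopes need a region map")
        members = list(d.countries) if scope == GLOBE else [
            c for c in d.countries if region_map.region_of[c] == scope_id
        ]
        idx = [d.countries.index(c) for c in members]
        pop = _pop_vector(region_map, members, year, group)
        b = base[:, idx] @ pop
        s = shifted[:, idx] @ pop
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(b > 0, (b - s) / b, np.nan)


def theta_draws_extrapolated(pd_draws: PosteriorDraws, group: str, year: float) -> np.ndarray:
    """Locations (S, C) beyond the fitted grid: the linear trend continues,
    the random-walk components and covariates are held at their last values."""
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    r = d.region_idx
    a0, b0 = fp.pooled("a0"), fp.pooled("b0")
    ar, br = fp.pooled("ar"), fp.pooled("br")
    ac, bc = fp.pooled("ac"), fp.pooled("bc")
    th = (
        a0[:, None]
        + ar[:, r]
        + ac
        + (b0[:, None] + br[:, r] + bc) * (year - d.t_ref)
        + fp.pooled("u0")[:, [-1]]
        + fp.pooled("ur")[:, r, -1]
        + fp.pooled("uc")[:, :, -1]
        + np.einsum("cp,sp->sc", d.X[:, -1, :], fp.pooled("beta"))
    )
    if group == PREGNANT:
        th = th - fp.pooled("delta")
    return th


def halving_probability(
    pd_draws: PosteriorDraws,
    scope: str,
    scope_id: str,
    group: str,
    region_map: RegionMap | None = None,
    base_year: int = 2011,
    target_year: int = 2025,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> float:
    """Probability of halving anaemia prevalence by ``target_year``.

    Each draw's location is extrapolated by continuing its linear trend and
    freezing the nonlinear component at its final value; the draw counts as
    a success when the extrapolated prevalence is at most half the
    ``base_year`` prevalence.
    """
    fp = pd_draws[FAMILY_OF[group]]
    d = fp.data
    cut = cutoffs.total[group]
    ti = int(base_year) - int(d.years[0])
    th_base = theta_draws(pd_draws, group)[:, :, ti]
    th_target = theta_draws_extrapolated(pd_draws, group, float(target_year))
    p_base = mixture_cdf_draws(fp, th_base, cut)
    p_target = mixture_cdf_draws(fp, th_target, cut)
    if scope == "country":
        ci = d.countries.index(scope_id)
        pb, pt = p_base[:, ci], p_target[:, ci]
    else:
        if region_map is None:
            raise ValueError("regional/global scopes need a region map")
        members = list(d.countries) if scope == GLOBE else [
            c for c in d.countries if region_map.region_of[c] == scope_id
        ]
        idx = [d.countries.index(c) for c in members]
        popb = _pop_vector(region_map, members, base_year, group)
        popt_year = min(int(target_year), int(d.years[-1]) + 0)
        # population weights for the target year fall back to the base year
        try:
            popt = _pop_vector(region_map, members, target_year, group)
        except KeyError:
            popt = popb
        pb = (p_base[:, idx] @ popb) / popb.sum()
        pt = (p_target[:, idx] @ popt) / popt.sum()
    return float(np.mean(pt <= 0.5 * pb))


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------


def estimates_table(
    pd_draws: PosteriorDraws,
    region_map: RegionMap,
    years: Sequence[int],
    groups: Sequence[str] = ESTIMATE_GROUPS,
    metrics: Sequence[str] = METRICS,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """One row per (scope, scope_id, year, group, metric)."""
    d0 = next(iter(pd_draws.families.values())).data
    scopes = [("country", c) for c in d0.countries]
    scopes += [("region", r) for r in region_map.regions]
    scopes += [(GLOBE, GLOBE)]
    rows = []
    for scope, sid in scopes:
        for y in years:
            for g in groups:
                for m in metrics:
                    draws = scope_metric_draws(pd_draws, scope, sid, y, g, m, region_map, cutoffs)
                    cell = summarize(
                        draws, dict(scope=scope, scope_id=sid, year=int(y), group=g, metric=m)
                    )
                    rows.append(cell.__dict__)
    return pd.DataFrame(rows)


def trends_table(
    pd_draws: PosteriorDraws,
    region_map: RegionMap,
    groups: Sequence[str] = ESTIMATE_GROUPS,
    y1: int = 1995,
    y2: int = 2011,
    convention: str = "geometric",
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Change per decade and posterior trend probability per scope-group."""
    d0 = next(iter(pd_draws.families.values())).data
    scopes = [("region", r) for r in region_map.regions] + [(GLOBE, GLOBE)]
    rows = []
    for scope, sid in scopes:
        for g in groups:
            for m in ("mean_hb", "prev_total"):
                cell = change_per_decade(
                    pd_draws, scope, sid, g, m, region_map, y1, y2, convention, cutoffs
                )
                prob = posterior_probability_increase(
                    pd_draws, scope, sid, g, m, y1, y2, region_map, cutoffs
                )
                row = cell.__dict__ | {"prob_increase": prob, "convention": convention if m != "mean_hb" else "absolute"}
                rows.append(row)
    return pd.DataFrame(rows)
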