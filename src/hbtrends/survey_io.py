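"""Reading, validation, and filtering of survey observations and side tables.

CSV schemas (documented in ``schemas/``):

* ``observations.csv`` — one row per source x country-year x group cell, in
  either summary form (mean/sd/prevalences) or individual form (records live
  in ``individuals.csv``, linked by ``source_id``).
* ``individuals.csv`` — one haemoglobin measurement per row.
* ``covariates.csv`` — country-year covariates used by the model.
* ``regions.csv`` — country-to-region map.
* ``population.csv`` — persons per country-year-group (for aggregation).

Rows failing validation are rejected with row-level messages; nothing is
silently coerced or dropped.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .groups import (
    CHILDREN,
    DEFAULT_CUTOFFS,
    GROUPS,
    NON_PREGNANT,
    PREGNANCY_WEEKS_THRESHOLD,
    PREGNANT,
    WOMEN_COMBINED,
    CutoffSet,
)

SCHEMA_VERSION = "1"

OBSERVATION_COLUMNS = [
    "source_id",
    "country",
    "year",
    "group",
    "coverage",
    "n_regions_covered",
    "data_form",
    "n",
    "mean_hb",
    "sd_hb",
    "prev_anaemia",
    "prev_severe",
    "altitude_adjusted",
    "smoking_adjusted",
    "age_range_matches",
    "pregnant_fraction",
]

INDIVIDUAL_COLUMNS = [
    "source_id",
    "country",
    "year",
    "group",
    "hb",
    "altitude_m",
    "gestational_weeks",
    "age",
    "cluster_id",
]

COVARIATE_COLUMNS = [
    "country",
    "year",
    "maternal_education",
    "urban_prop",
    "abs_latitude",
    "hb_disorder_prev",
    "mean_bmi",
    "mean_waz",
]

#: covariates entering each model family
FAMILY_COVARIATES = {
    "children": ["maternal_education", "urban_prop", "abs_latitude", "hb_disorder_prev", "mean_waz"],
    "women": ["maternal_education", "urban_prop", "abs_latitude", "hb_disorder_prev", "mean_bmi"],
}


@dataclass(frozen=True)
class HbObservation:
    """One survey datum for a country-year-group cell."""

    source_id: str
    country: str
    year: float
    group: str
    coverage: str  # national | subnational
    data_form: str  # individual | summary
    n: int
    n_regions_covered: int | None = None
    mean_hb: float | None = None
    sd_hb: float | None = None
    prev_anaemia: float | None = None
    prev_severe: float | None = None
    altitude_adjusted: bool = False
    smoking_adjusted: bool = False
    age_range_matches: bool = True
    pregnant_fraction: float | None = None
    notes: tuple[str, ...] = ()

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        errs: list[str] = []
        if self.group not in GROUPS:
            errs.append(f"unknown group {self.group!r}")
        if self.coverage not in ("national", "subnational"):
            errs.append(f"unknown coverage {self.coverage!r}")
        if self.data_form not in ("individual", "summary"):
            errs.append(f"unknown data_form {self.data_form!r}")
        if self.n < 1:
            errs.append(f"n must be >= 1, got {self.n}")
        if self.mean_hb is not None and not (40.0 < self.mean_hb < 190.0):
            errs.append(f"mean_hb {self.mean_hb} outside (40, 190) g/L")
        if self.sd_hb is not None and not self.sd_hb > 0:
            errs.append(f"sd_hb must be > 0, got {self.sd_hb}")
        for name in ("prev_anaemia", "prev_severe", "pregnant_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                errs.append(f"{name} {v} outside [0, 1]")
        if self.coverage == "subnational" and self.n_regions_covered is None:
            errs.append("subnational coverage requires n_regions_covered")
        return errs


@dataclass(frozen=True)
class IndividualRecord:
    """One haemoglobin measurement from an individual-level source."""

    source_id: str
    hb: float
    group: str
    country: str | None = None
    year: float | None = None
    altitude_m: float | None = None
    gestational_weeks: float | None = None
    age: float | None = None
    cluster_id: str | None = None
    altitude_adjusted: bool = False
    hb_raw: float | None = None  # pre-adjustment value, kept for audit
    flags: tuple[str, ...] = ()

    def validate(self) -> list[str]:
        errs: list[str] = []
        if self.group not in GROUPS:
            errs.append(f"unknown group {self.group!r}")
        if self.gestational_weeks is not None and not (0.0 <= self.gestational_weeks <= 44.0):
            errs.append(f"gestational_weeks {self.gestational_weeks} outside [0, 44]")
        if not math.isfinite(self.hb):
            errs.append("hb not finite")
        return errs


@dataclass(frozen=True)
class CountryYearCovariate:
    country: str
    year: int
    maternal_education: float
    urban_prop: float
    abs_latitude: float
    hb_disorder_prev: float
    mean_bmi: float
    mean_waz: float


@dataclass
class RegionMap:
    """Country-to-region map plus populations per country-year-group."""

    region_of: dict[str, str]
    population: pd.DataFrame  # columns: country, year, group, population

    def __post_init__(self) -> None:
        if (self.population["population"] <= 0).any():
            raise ValueError("populations must be > 0")
        unknown = set(self.population["country"]) - set(self.region_of)
        if unknown:
            raise ValueError(f"countries without region: {sorted(unknown)}")

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.region_of.values()))

    def countries(self, region: str | None = None) -> list[str]:
        if region is None:
            return sorted(self.region_of)
        return sorted(c for c, r in self.region_of.items() if r == region)

    def population_of(self, country: str, year: int, group: str) -> float:
        df = self.population
        m = (df["country"] == country) & (df["year"] == year) & (df["group"] == group)
        if not m.any():
            raise KeyError(f"no population for ({country}, {year}, {group})")
        return float(df.loc[m, "population"].iloc[0])


@dataclass
class ReadReport:
    """Validated records plus row-level rejections from one CSV read."""

    records: list
    rejections: list[tuple[int, str, str]] = field(default_factory=list)  # row, source_id, msg


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(f)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValueError(f"unparseable boolean {v!r}")


def _check_header(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)


def read_observations(path, schema_version: str = SCHEMA_VERSION) -> ReadReport:
    """Read and validate ``observations.csv``.

    Returns a :class:`ReadReport`; rows violating invariants land in
    ``rejections`` as ``(row_index, source_id, message)``.
    """
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path, dtype={"source_id": str, "country": str})
    _check_header(df, OBSERVATION_COLUMNS, path)
    report = ReadReport(records=[])
    for i, row in df.iterrows():
        sid = str(row["source_id"])
        try:
            obs = HbObservation(
                source_id=sid,
                country=str(row["country"]),
                year=float(row["year"]),
                group=str(row["group"]),
                coverage=str(row["coverage"]),
                n_regions_covered=_opt_int(row["n_regions_covered"]),
                data_form=str(row["data_form"]),
                n=int(row["n"]),
                mean_hb=_opt_float(row["mean_hb"]),
                sd_hb=_opt_float(row["sd_hb"]),
                prev_anaemia=_opt_float(row["prev_anaemia"]),
                prev_severe=_opt_float(row["prev_severe"]),
                altitude_adjusted=_as_bool(row["altitude_adjusted"]),
                smoking_adjusted=_as_bool(row["smoking_adjusted"]),
                age_range_matches=_as_bool(row["age_range_matches"]),
                pregnant_fraction=_opt_float(row["pregnant_fraction"]),
            )
        except (ValueError, TypeError) as exc:
            report.rejections.append((int(i), sid, f"unparseable row: {exc}"))
            continue
        errs = obs.validate()
        if errs:
            report.rejections.append((int(i), sid, "; ".join(errs)))
        else:
            report.records.append(obs)
    return report


def write_observations(obs: Iterable[HbObservation], path) -> None:
    rows = []
    for o in obs:
        d = dataclasses.asdict(o)
        d.pop("notes")
        rows.append(d)
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    df.to_csv(path, index=False)


def read_individuals(path, schema_version: str = SCHEMA_VERSION) -> ReadReport:
    """Read and validate ``individuals.csv``."""
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path, dtype={"source_id": str, "country": str, "cluster_id": str})
    _check_header(df, INDIVIDUAL_COLUMNS, path)
    report = ReadReport(records=[])
    for i, row in df.iterrows():
        sid = str(row["source_id"])
        try:
            rec = IndividualRecord(
                source_id=sid,
                country=str(row["country"]),
                year=float(row["year"]),
                group=str(row["group"]),
                hb=float(row["hb"]),
                altitude_m=_opt_float(row["altitude_m"]),
                gestational_weeks=_opt_float(row["gestational_weeks"]),
                age=_opt_float(row["age"]),
                cluster_id=None if pd.isna(row["cluster_id"]) else str(row["cluster_id"]),
            )
        except (ValueError, TypeError) as exc:
            report.rejections.append((int(i), sid, f"unparseable row: {exc}"))
            continue
        errs = rec.validate()
        if errs:
            report.rejections.append((int(i), sid, "; ".join(errs)))
        else:
            report.records.append(rec)
    return report


def write_individuals(recs: Iterable[IndividualRecord], path) -> None:
    rows = []
    for r in recs:
        rows.append({c: getattr(r, c) for c in INDIVIDUAL_COLUMNS})
    pd.DataFrame(rows, columns=INDIVIDUAL_COLUMNS).to_csv(path, index=False)


def read_covariates(path) -> list[CountryYearCovariate]:
    df = pd.read_csv(path, dtype={"country": str})
    _check_header(df, COVARIATE_COLUMNS, path)
    out = [
        CountryYearCovariate(
            country=str(r["country"]),
            year=int(r["year"]),
            maternal_education=float(r["maternal_education"]),
            urban_prop=float(r["urban_prop"]),
            abs_latitude=float(r["abs_latitude"]),
            hb_disorder_prev=float(r["hb_disorder_prev"]),
            mean_bmi=float(r["mean_bmi"]),
            mean_waz=float(r["mean_waz"]),
        )
        for _, r in df.iterrows()
    ]
    # haemoglobinopathy prevalence must be constant over time within country
    g = df.groupby("country")["hb_disorder_prev"].nunique()
    bad = g[g > 1]
    if len(bad):
        raise ValueError(f"hb_disorder_prev varies over time for {list(bad.index)}")
    return out


def read_region_map(regions_path, population_path) -> RegionMap:
    rdf = pd.read_csv(regions_path, dtype={"country": str, "region": str})
    _check_header(rdf, ["country", "region"], regions_path)
    if rdf["country"].duplicated().any():
        dup = rdf.loc[rdf["country"].duplicated(), "country"].tolist()
        raise ValueError(f"country mapped to more than one region: {dup}")
    pdf = pd.read_csv(population_path, dtype={"country": str, "group": str})
    _check_header(pdf, ["country", "year", "group", "population"], population_path)
    return RegionMap(region_of=dict(zip(rdf["country"], rdf["region"])), population=pdf)


# reason codes for exclusions
SUBNATIONAL_LT_3 = "subnational_lt_3_regions"


@dataclass
class InclusionResult:
    included: list[HbObservation]
    excluded: list[tuple[HbObservation, str]]


def apply_inclusion_rules(obs: Sequence[HbObservation]) -> InclusionResult:
    """Keep sources representative at national level or covering >= 3 regions.

    National sources are always included; subnational sources qualify only
    when they covered at least three regions within the country.  The result
    partitions the input: nothing is lost or duplicated, and the operation is
    idempotent on its ``included`` output.
    """
    res = InclusionResult(included=[], excluded=[])
    for o in obs:
        if o.coverage == "national":
            res.included.append(o)
        elif (o.n_regions_covered or 0) >= 3:
            res.included.append(o)
        else:
            res.excluded.append((o, SUBNATIONAL_LT_3))
    return res


def classify_pregnancy(rec: IndividualRecord) -> str:
    """Classify a woman's record by the operational pregnancy definition.

    Pregnant iff gestational age is recorded and strictly exceeds 8 weeks
    (reporting of pregnancy status in household surveys only becomes
    consistent around weeks 6-10, which is also when the haemoglobin decline
    is steepest); anything else counts as non-pregnant.
    """
    if rec.group == CHILDREN:
        raise ValueError("classify_pregnancy applies to women's records only")
    if rec.gestational_weeks is not None and rec.gestational_weeks > PREGNANCY_WEEKS_THRESHOLD:
        return PREGNANT
    return NON_PREGNANT


def summarize_individuals(
    recs: Sequence[IndividualRecord],
    country: str,
    year: float,
    group: str,
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
    source_id: str | None = None,
    coverage: str = "national",
) -> HbObservation:
    """Collapse one country-year-group cell of records to a summary row.

    Uses the unbiased (n-1) standard deviation; prevalences are computed
    against the group's total and severe cutoffs.  A zero-variance cell is
    flagged degenerate rather than rejected.
    """
    if len(recs) < 2:
        raise ValueError("need >= 2 records per cell (sd undefined otherwise)")
    hb = np.array([r.hb for r in recs], dtype=float)
    sd = float(np.std(hb, ddof=1))
    notes: tuple[str, ...] = ()
    if sd == 0.0:
        notes = ("degenerate_zero_variance",)
    cut_t = cutoffs.total[group if group != WOMEN_COMBINED else NON_PREGNANT]
    cut_s = cutoffs.severe[group if group != WOMEN_COMBINED else NON_PREGNANT]
    return HbObservation(
        source_id=source_id or recs[0].source_id,
        country=country,
        year=year,
        group=group,
        coverage=coverage,
        data_form="summary",
        n=len(recs),
        mean_hb=float(np.mean(hb)),
        sd_hb=sd if sd > 0 else None,
        prev_anaemia=float(np.mean(hb < cut_t)),
        prev_severe=float(np.mean(hb < cut_s)),
        notes=notes,
    )


def flag_out_of_range(recs: Sequence[IndividualRecord], lo: float = 25.0, hi: float = 220.0):
    """Split records into (in-range, flagged) by biological plausibility."""
    ok: list[IndividualRecord] = []
    flagged: list[IndividualRecord] = []
    for r in recs:
        if lo <= r.hb <= hi:
            ok.append(r)
        else:
            flagged.append(replace(r, flags=r.flags + ("hb_out_of_range",)))
    return ok, flagged
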