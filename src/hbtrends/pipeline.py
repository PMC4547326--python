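"""End-to-end plumbing: CSV directory -> validated, adjusted, prepared data."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from .adjustments import (
    DEFAULT_POLICY,
    AdjustmentPolicy,
    adjust_individual,
    adjust_summary,
    read_altitude_bands,
    smoking_policy,
)
from .groups import DEFAULT_CUTOFFS, FAMILIES, CutoffSet
from .model import FamilyModelData, ModelConfig, prepare_family_data
from .survey_io import (
    InclusionResult,
    RegionMap,
    apply_inclusion_rules,
    read_covariates,
    read_individuals,
    read_observations,
    read_region_map,
)

log = logging.getLogger("hbtrends")


@dataclass
class PreparedData:
    families: dict[str, FamilyModelData]
    region_map: RegionMap
    inclusion: InclusionResult
    n_rejected_rows: int


def prepare_from_csv(
    data_dir,
    model_cfg: ModelConfig = ModelConfig(),
    cutoffs: CutoffSet = DEFAULT_CUTOFFS,
    policy: AdjustmentPolicy = DEFAULT_POLICY,
    strict: bool = False,
) -> PreparedData:
    """Read a data directory and produce per-family model-ready datasets.

    Applies, in order: row validation, the inclusion rules (national, or
    subnational covering >= 3 regions), the smoking policy, and altitude
    adjustment (individual records via their altitude of residence; summary
    sources via the country's altitude distribution when the country is
    high-altitude).
    """
    d = Path(data_dir)
    obs_rep = read_observations(d / "observations.csv")
    ind_rep = read_individuals(d / "individuals.csv") if (d / "individuals.csv").exists() else None
    n_rejected = len(obs_rep.rejections) + (len(ind_rep.rejections) if ind_rep else 0)
    if n_rejected:
        for row, sid, msg in (obs_rep.rejections + (ind_rep.rejections if ind_rep else []))[:20]:
            log.warning("rejected row %s (source %s): %s", row, sid, msg)
        if strict:
            raise ValueError(f"{n_rejected} rows failed validation")
    covs = read_covariates(d / "covariates.csv")
    region_map = read_region_map(d / "regions.csv", d / "population.csv")
    alt = read_altitude_bands(d / "altitude_bands.csv") if (d / "altitude_bands.csv").exists() else {}

    inclusion = apply_inclusion_rules(obs_rep.records)
    for o, reason in inclusion.excluded:
        log.info("excluded %s: %s", o.source_id, reason)

    observations = []
    for o in inclusion.included:
        o = smoking_policy(o)
        if o.data_form == "summary" and not o.altitude_adjusted:
            dist = alt.get(o.country)
            if dist is not None:
                o = adjust_summary(o, dist, policy)
            else:
                o = replace(o, notes=o.notes + ("no_altitude_distribution",))
        observations.append(o)

    individuals = []
    if ind_rep:
        adjusted_sources = {o.source_id: o.altitude_adjusted for o in obs_rep.records}
        for r in ind_rep.records:
            if not adjusted_sources.get(r.source_id, True):
                r = adjust_individual(r, policy)
            individuals.append(r)

    families = {
        fam: prepare_family_data(
            observations, individuals, covs, region_map, fam, model_cfg, cutoffs
        )
        for fam in FAMILIES
    }
    for fam, fd in families.items():
        if fd.n_out_of_range:
            log.warning("%s: %d records outside plausible range excluded", fam, fd.n_out_of_range)
    return PreparedData(
        families=families,
        region_map=region_map,
        inclusion=inclusion,
        n_rejected_rows=n_rejected,
    )
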