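"""Altitude adjustment of haemoglobin (CDC formula) and the smoking policy.

Physiological haemoglobin needs rise with altitude, so measurements from
people living above 1000 m are shifted downwards to their sea-level
equivalent before anaemia is assessed.  The shift follows the CDC
polynomial in altitude expressed in thousands of feet,

    shift(A) = max(0, -0.32 A + 0.22 A**2)   [g/L],  A = metres * 0.0032808,

applied only at or above 1000 m (the polynomial itself turns positive near
443 m, but the adjustment rule starts at 1000 m).  At 1500 m the shift is
about 3.8 g/L and at 2200 m about 9.2 g/L.

Summary-level sources can only be adjusted through the country's population
distribution over altitude bands, and only countries where more than 5% of
people live at 1500 m or higher are adjusted at all.  Data not adjusted for
smoking are used as-is: the smoking effect (~0.3 g/L) is an order of
magnitude below the altitude effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .survey_io import HbObservation, IndividualRecord

#: metres -> thousands of feet
_M_TO_KFT = 0.0032808
#: CDC polynomial coefficients (g/L per kft, per kft^2)
_CDC_LINEAR = -0.32
_CDC_QUAD = 0.22


@dataclass(frozen=True)
class AltitudeDistribution:
    """Population shares by altitude band (band midpoints in metres)."""

    country: str
    bands: tuple[tuple[float, float], ...]  # (midpoint_m, share)

    def __post_init__(self) -> None:
        shares = [s for _, s in self.bands]
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError("altitude band shares must sum to 1")
        if any(m < 0 for m, _ in self.bands):
            raise ValueError("band midpoints must be >= 0")

    def share_at_or_above(self, metres: float) -> float:
        return sum(s for m, s in self.bands if m >= metres)


@dataclass(frozen=True)
class AdjustmentPolicy:
    """Thresholds governing when and where the altitude adjustment applies."""

    high_altitude_country_threshold: float = 0.05  # population share
    high_altitude_m: float = 1500.0
    apply_above_m: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.high_altitude_country_threshold, self.high_altitude_m, self.apply_above_m) <= 0:
            raise ValueError("policy thresholds must be positive")


DEFAULT_POLICY = AdjustmentPolicy()


def cdc_altitude_shift(altitude_m, policy: AdjustmentPolicy = DEFAULT_POLICY):
    """Downward haemoglobin shift (g/L) for residence at ``altitude_m``.

    Vectorised over altitude.  Zero below ``policy.apply_above_m``; the
    negative low-altitude branch of the polynomial is clamped to zero.
    """
    alt = np.asarray(altitude_m, dtype=float)
    if np.any(alt < 0):
        raise ValueError("altitude must be >= 0")
    a = alt * _M_TO_KFT
    raw = _CDC_LINEAR * a + _CDC_QUAD * a * a
    shift = np.where(alt >= policy.apply_above_m, np.maximum(raw, 0.0), 0.0)
    return float(shift) if np.isscalar(altitude_m) or shift.ndim == 0 else shift


def adjust_individual(
    rec: IndividualRecord, policy: AdjustmentPolicy = DEFAULT_POLICY
) -> IndividualRecord:
    """Altitude-adjust one individual record, keeping the raw value for audit.

    Records without altitude of residence pass through unchanged with an
    ``unadjusted_no_altitude`` flag.
    """
    if rec.altitude_adjusted:
        raise ValueError(f"record from {rec.source_id} is already altitude-adjusted")
    if rec.altitude_m is None:
        return replace(rec, flags=rec.flags + ("unadjusted_no_altitude",))
    shift = cdc_altitude_shift(rec.altitude_m, policy)
    return replace(rec, hb=rec.hb - shift, hb_raw=rec.hb, altitude_adjusted=True)


def mean_shift_for_distribution(
    alt: AltitudeDistribution, policy: AdjustmentPolicy = DEFAULT_POLICY
) -> float:
    """Population-weighted mean shift over a country's altitude bands."""
    return float(sum(share * cdc_altitude_shift(m, policy) for m, share in alt.bands))


def adjust_summary(
    obs: HbObservation,
    alt: AltitudeDistribution | None,
    policy: AdjustmentPolicy = DEFAULT_POLICY,
) -> HbObservation:
    """Altitude-adjust a summary observation via the country's altitude mix.

    Only countries where more than ``high_altitude_country_threshold`` of the
    population lives at ``high_altitude_m`` or above are adjusted; elsewhere
    the observation is returned unchanged with a ``low_altitude_country``
    note.  Prevalences cannot be shifted exactly from a summary, so they are
    recomputed from a normal approximation with the shifted mean and the
    reported sd (noted on the observation).
    """
    if obs.data_form != "summary":
        raise ValueError("adjust_summary applies to summary observations")
    if obs.altitude_adjusted:
        raise ValueError(f"observation {obs.source_id} is already altitude-adjusted")
    if alt is None or alt.share_at_or_above(policy.high_altitude_m) <= policy.high_altitude_country_threshold:
        if alt is None:
            raise ValueError(f"no altitude distribution for country {obs.country}")
        return replace(obs, notes=obs.notes + ("low_altitude_country",))
    shift = mean_shift_for_distribution(alt, policy)
    new = replace(
        obs,
        mean_hb=None if obs.mean_hb is None else obs.mean_hb - shift,
        altitude_adjusted=True,
        notes=obs.notes + (f"altitude_summary_shift={shift:.4f}",),
    )
    if obs.prev_anaemia is not None and obs.mean_hb is not None and obs.sd_hb:
        # normal approximation: re-read the prevalence off a shifted normal
        from .groups import DEFAULT_CUTOFFS, NON_PREGNANT, WOMEN_COMBINED

        g = obs.group if obs.group != WOMEN_COMBINED else NON_PREGNANT
        new = replace(
            new,
            prev_anaemia=float(norm.cdf(DEFAULT_CUTOFFS.total[g], new.mean_hb, obs.sd_hb)),
            prev_severe=None
            if obs.prev_severe is None
            else float(norm.cdf(DEFAULT_CUTOFFS.severe[g], new.mean_hb, obs.sd_hb)),
            notes=new.notes + ("prevalence_normal_approx",),
        )
    return new


def smoking_policy(obs: HbObservation) -> HbObservation:
    """Record the smoking-adjustment status without changing any value.

    Data already adjusted for smoking are used as such; unadjusted data get
    no post-adjustment (the smoking effect is small relative to altitude).
    Idempotent.
    """
    tag = "smoking_pre_adjusted" if obs.smoking_adjusted else "smoking_not_adjusted"
    if tag in obs.notes:
        return obs
    return replace(obs, notes=obs.notes + (tag,))


def read_altitude_bands(path) -> dict[str, AltitudeDistribution]:
    """Read ``altitude_bands.csv`` (country, band_midpoint_m, population_share)."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"country": str})
    out: dict[str, AltitudeDistribution] = {}
    for country, grp in df.groupby("country"):
        out[str(country)] = AltitudeDistribution(
            country=str(country),
            bands=tuple(zip(grp["band_midpoint_m"].astype(float), grp["population_share"].astype(float))),
        )
    return out


def write_altitude_bands(dists: Sequence[AltitudeDistribution], path) -> None:
    import pandas as pd

    rows = [
        {"country": d.country, "band_midpoint_m": m, "population_share": s}
        for d in dists
        for m, s in d.bands
    ]
    pd.DataFrame(rows, columns=["country", "band_midpoint_m", "population_share"]).to_csv(
        path, index=False
    )
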