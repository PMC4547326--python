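"""Population groups, model families, and anaemia cutoffs.

Estimates are made for three population groups: children aged 6-59 months,
pregnant women, and non-pregnant women aged 15-49 years.  Surveys sometimes
report pregnant and non-pregnant women pooled ("women_combined"); such
sources are modelled as a pregnancy-fraction mixture of the two women's
distributions, never as a group of their own in the estimates.

Children and women are modelled separately (two model "families"); within
the women's family the pregnant distribution is the non-pregnant one shifted
down by a country-level pregnancy offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

CHILDREN = "children"
PREGNANT = "pregnant"
NON_PREGNANT = "non_pregnant"
WOMEN_COMBINED = "women_combined"

#: groups accepted in input data
GROUPS = (CHILDREN, PREGNANT, NON_PREGNANT, WOMEN_COMBINED)
#: groups for which estimates are produced
ESTIMATE_GROUPS = (CHILDREN, PREGNANT, NON_PREGNANT)

FAMILY_CHILDREN = "children"
FAMILY_WOMEN = "women"
FAMILIES = (FAMILY_CHILDREN, FAMILY_WOMEN)

FAMILY_OF = {
    CHILDREN: FAMILY_CHILDREN,
    PREGNANT: FAMILY_WOMEN,
    NON_PREGNANT: FAMILY_WOMEN,
    WOMEN_COMBINED: FAMILY_WOMEN,
}

#: operational definition of pregnancy: strictly more than this many
#: completed gestational weeks
PREGNANCY_WEEKS_THRESHOLD = 8.0

#: biological plausibility window for a single haemoglobin measurement (g/L);
#: records outside are flagged and excluded from the likelihood, never
#: silently dropped
HB_PLAUSIBLE_LO = 25.0
HB_PLAUSIBLE_HI = 220.0


@dataclass(frozen=True)
class CutoffSet:
    """WHO haemoglobin cutoffs (g/L) defining total and severe anaemia."""

    total: Mapping[str, float] = field(
        default_factory=lambda: {CHILDREN: 110.0, PREGNANT: 110.0, NON_PREGNANT: 120.0}
    )
    severe: Mapping[str, float] = field(
        default_factory=lambda: {CHILDREN: 70.0, PREGNANT: 70.0, NON_PREGNANT: 80.0}
    )

    def __post_init__(self) -> None:
        for g in ESTIMATE_GROUPS:
            if not self.severe[g] < self.total[g]:
                raise ValueError(f"severe cutoff must be below total cutoff for {g}")


DEFAULT_CUTOFFS = CutoffSet()
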