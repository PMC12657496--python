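"""Feature schema for the 33 sociodemographic profile variables.

The clustering stage operates on 33 categorical/ordinal variables
partitioned into three domains: 8 parental characteristics, 11 family and
sustenance-related indicators, and 14 child and school-related factors.
Nine of the 33 are the discriminative features on which the latent
environmental subgroups differ (peer involvement, parent employment,
income, school engagement, marital status, social role engagement,
likeness to parent behaviour); the remainder are named filler variables
drawn from subgroup-independent base rates.

Each feature carries an ordered category list and a base-rate vector;
ordinal features are integer-coded by category order, nominal features by
position in the category list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

PARENTAL = "parental"
FAMILY = "family_sustenance"
CHILD = "child_school"


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    domain: str           # parental | family_sustenance | child_school
    kind: str             # "ordinal" | "nominal"
    categories: Tuple[str, ...]
    base_rates: Tuple[float, ...]

    def __post_init__(self):
        if len(self.categories) != len(self.base_rates):
            raise ValueError(f"{self.name}: categories/base_rates length mismatch")
        if abs(sum(self.base_rates) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: base rates must sum to 1")

    @property
    def codes(self) -> Dict[str, int]:
        return {c: i for i, c in enumerate(self.categories)}


_AGREE4 = ("Definitely Not True", "Mostly Not True", "Mostly True", "Definitely True")
_ENGAGE4 = ("Not True", "Somewhat True", "Mostly True", "Definitely True")
_PEERS5 = ("Almost None", "A Few", "Half of the Peers", "Most", "All")
_HARDSHIP3 = ("Never", "Sometimes", "Often")

EMPLOYMENT_CATEGORIES = ("Working Now", "Not Working: Other", "Stay-at-Home Parent")
MARITAL_CATEGORIES = ("Married", "Divorced/Separated/Widowed", "Never Married")
INCOME_CATEGORIES = (
    "<$5K", "$5K-$12K", "$12K-$16K", "$16K-$25K", "$25K-$35K",
    "$35K-$50K", "$50K-$75K", "$75K-$100K", "$100K-$200K", ">$200K",
)


def _norm(v) -> Tuple[float, ...]:
    a = np.asarray(v, dtype=float)
    return tuple(a / a.sum())


# ---------------------------------------------------------------------------
# The 33 features: 8 parental, 11 family/sustenance, 14 child/school.
# Base rates are realistic marginals for a large US community sample of
# 9-10 year-olds (income/employment/marital rates follow the cohort the
# generator emulates; binary hardship items are rare events).
# ---------------------------------------------------------------------------

FEATURES: Tuple[FeatureSpec, ...] = (
    # -- parental (8) -------------------------------------------------------
    FeatureSpec("parent_employment", PARENTAL, "nominal", EMPLOYMENT_CATEGORIES,
                _norm([0.73, 0.10, 0.17])),
    FeatureSpec("marital_status", PARENTAL, "nominal", MARITAL_CATEGORIES,
                _norm([0.715, 0.13, 0.155])),
    FeatureSpec("parent_age_band", PARENTAL, "ordinal",
                ("20-25", "26-30", "31-35", "36-40", "41-45", "46-50", ">50"),
                _norm([0.003, 0.06, 0.17, 0.29, 0.27, 0.15, 0.05])),
    FeatureSpec("parent_education", PARENTAL, "ordinal",
                ("< High School", "High School", "Some College", "Bachelor", "Postgraduate"),
                _norm([0.05, 0.15, 0.30, 0.30, 0.20])),
    FeatureSpec("parent_relationship", PARENTAL, "nominal",
                ("Biological Parent", "Other Blood Relative", "Adoptive/Foster/Other"),
                _norm([0.88, 0.07, 0.05])),
    FeatureSpec("parental_monitoring", PARENTAL, "ordinal", _ENGAGE4,
                _norm([0.05, 0.20, 0.40, 0.35])),
    FeatureSpec("parental_acceptance", PARENTAL, "ordinal", _ENGAGE4,
                _norm([0.05, 0.25, 0.40, 0.30])),
    FeatureSpec("parental_warmth", PARENTAL, "ordinal", _ENGAGE4,
                _norm([0.04, 0.16, 0.40, 0.40])),
    # -- family & sustenance (11) -------------------------------------------
    FeatureSpec("family_income", FAMILY, "ordinal", INCOME_CATEGORIES,
                _norm([0.017, 0.025, 0.015, 0.040, 0.059, 0.105, 0.151, 0.175,
                       0.302, 0.111])),
    FeatureSpec("food_insecurity", FAMILY, "ordinal", _HARDSHIP3,
                _norm([0.82, 0.13, 0.05])),
    FeatureSpec("service_interruptions", FAMILY, "ordinal", _HARDSHIP3,
                _norm([0.85, 0.10, 0.05])),
    FeatureSpec("rent_difficulty", FAMILY, "ordinal", _HARDSHIP3,
                _norm([0.80, 0.14, 0.06])),
    FeatureSpec("housing_instability", FAMILY, "ordinal", _HARDSHIP3,
                _norm([0.85, 0.10, 0.05])),
    FeatureSpec("utility_difficulty", FAMILY, "ordinal", _HARDSHIP3,
                _norm([0.80, 0.14, 0.06])),
    FeatureSpec("unmet_healthcare_need", FAMILY, "ordinal", _HARDSHIP3,
                _norm([0.82, 0.12, 0.06])),
    FeatureSpec("unmet_dental_need", FAMILY, "ordinal", _HARDSHIP3,
                _norm([0.78, 0.15, 0.07])),
    FeatureSpec("parent_psychiatric_history", FAMILY, "nominal", ("No", "Yes"),
                (0.72, 0.28)),
    FeatureSpec("financial_adversity_count", FAMILY, "ordinal",
                ("0", "1", "2", "3", "4+"),
                _norm([0.70, 0.15, 0.08, 0.04, 0.03])),
    FeatureSpec("household_size", FAMILY, "ordinal",
                ("2", "3", "4", "5", "6", "7+"),
                _norm([0.06, 0.18, 0.38, 0.24, 0.09, 0.05])),
    # -- child & school (14) ------------------------------------------------
    FeatureSpec("prosocial_peer_involvement", CHILD, "ordinal", _PEERS5,
                _norm([0.08, 0.22, 0.34, 0.24, 0.12])),
    FeatureSpec("rule_breaking_peer_involvement", CHILD, "ordinal", _PEERS5,
                _norm([0.62, 0.25, 0.08, 0.04, 0.01])),
    FeatureSpec("school_disengagement", CHILD, "ordinal", _AGREE4,
                _norm([0.45, 0.30, 0.15, 0.10])),
    FeatureSpec("school_involvement", CHILD, "ordinal", _AGREE4,
                _norm([0.08, 0.17, 0.42, 0.33])),
    FeatureSpec("social_role_engagement", CHILD, "ordinal", _ENGAGE4,
                _norm([0.22, 0.34, 0.28, 0.16])),
    FeatureSpec("parent_likeness", CHILD, "ordinal",
                ("Not Like Him/Her", "Somewhat Like Him/Her", "A Lot Like Him/Her"),
                _norm([0.25, 0.50, 0.25])),
    FeatureSpec("academic_grades", CHILD, "ordinal",
                ("Mostly D/F", "Mostly C", "Mostly B", "Mostly A"),
                _norm([0.05, 0.17, 0.38, 0.40])),
    FeatureSpec("school_environment", CHILD, "ordinal", _AGREE4,
                _norm([0.06, 0.14, 0.45, 0.35])),
    FeatureSpec("peer_victimization", CHILD, "ordinal",
                ("Never", "Rarely", "Sometimes", "Often"),
                _norm([0.55, 0.25, 0.15, 0.05])),
    FeatureSpec("extracurricular_activities", CHILD, "ordinal",
                ("None", "One", "Two", "Three+"),
                _norm([0.20, 0.35, 0.28, 0.17])),
    FeatureSpec("neighborhood_safety", CHILD, "ordinal", _AGREE4,
                _norm([0.05, 0.12, 0.38, 0.45])),
    FeatureSpec("child_substance_curiosity", CHILD, "ordinal",
                ("Not At All", "A Little", "Somewhat", "Very"),
                _norm([0.75, 0.15, 0.07, 0.03])),
    FeatureSpec("sleep_duration", CHILD, "ordinal",
                ("<7h", "7-8h", "8-9h", "9-11h", ">11h"),
                _norm([0.04, 0.14, 0.30, 0.46, 0.06])),
    FeatureSpec("screen_time", CHILD, "ordinal",
                ("<1h", "1-2h", "2-4h", "4-6h", ">6h"),
                _norm([0.15, 0.30, 0.32, 0.15, 0.08])),
)

FEATURE_NAMES: Tuple[str, ...] = tuple(f.name for f in FEATURES)
FEATURES_BY_NAME: Dict[str, FeatureSpec] = {f.name: f for f in FEATURES}

#: the nine features on which the default latent profiles differ
DISCRIMINATIVE_FEATURES: Tuple[str, ...] = (
    "prosocial_peer_involvement",
    "parent_employment",
    "family_income",
    "school_disengagement",
    "school_involvement",
    "marital_status",
    "social_role_engagement",
    "rule_breaking_peer_involvement",
    "parent_likeness",
)


def domain_counts() -> Dict[str, int]:
    counts: Dict[str, int] = {PARENTAL: 0, FAMILY: 0, CHILD: 0}
    for f in FEATURES:
        counts[f.domain] += 1
    return counts


def validate_schema(features: Sequence[FeatureSpec] = FEATURES) -> None:
    """Assert the 8/11/14 domain partition and name uniqueness."""
    names = [f.name for f in features]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in schema")
    counts = {PARENTAL: 0, FAMILY: 0, CHILD: 0}
    for f in features:
        counts[f.domain] += 1
    if (counts[PARENTAL], counts[FAMILY], counts[CHILD]) != (8, 11, 14):
        raise ValueError(f"domain partition must be 8/11/14, got {counts}")
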