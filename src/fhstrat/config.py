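"""Generator configuration: latent subgroup profiles and cohort parameters.

The default configuration encodes the study conditions the package
emulates: five latent environmental profiles over the 33 sociodemographic
features (defined by modal levels of the nine discriminative features),
mixing weights proportional to the reported subgroup sizes
(744/300/267/201/443), ~25% of participants in two-child families across
21 sites, and outcome distributions whose subgroup shifts follow the
reported group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

from fhstrat import schema as _schema

#: outcome columns produced by the generator, by domain
CBCL_OUTCOMES = ("cbcl_internalizing", "cbcl_externalizing", "cbcl_total")
UPPS_OUTCOMES = (
    "upps_negative_urgency",
    "upps_positive_urgency",
    "upps_lack_premeditation",
    "upps_lack_perseverance",
    "upps_sensation_seeking",
)

#: population (family-history-negative) outcome means and SDs
DEFAULT_OUTCOME_MEANS: Dict[str, float] = {
    "cbcl_internalizing": 47.46,
    "cbcl_externalizing": 44.06,
    "cbcl_total": 44.22,
    "upps_negative_urgency": 8.34,
    "upps_positive_urgency": 7.68,
    "upps_lack_premeditation": 7.66,
    "upps_lack_perseverance": 6.90,
    "upps_sensation_seeking": 9.87,
}
DEFAULT_OUTCOME_SDS: Dict[str, float] = {
    "cbcl_internalizing": 10.06,
    "cbcl_externalizing": 9.44,
    "cbcl_total": 10.42,
    "upps_negative_urgency": 2.54,
    "upps_positive_urgency": 2.81,
    "upps_lack_premeditation": 2.22,
    "upps_lack_perseverance": 2.16,
    "upps_sensation_seeking": 2.62,
}

#: additive mean shifts per latent subgroup (subgroup mean minus population mean)
DEFAULT_OUTCOME_EFFECTS: Dict[str, Dict[str, float]] = {
    "cbcl_internalizing": {"SG1": 1.11, "SG2": 3.17, "SG3": 3.38, "SG4": 3.57, "SG5": 2.51},
    "cbcl_externalizing": {"SG1": 1.22, "SG2": 3.28, "SG3": 4.91, "SG4": 3.81, "SG5": 3.16},
    "cbcl_total":         {"SG1": 1.23, "SG2": 3.56, "SG3": 4.84, "SG4": 5.02, "SG5": 3.56},
    "upps_negative_urgency":   {"SG1": -0.13, "SG2": 0.18, "SG3": 0.21, "SG4": 0.43, "SG5": 0.62},
    "upps_positive_urgency":   {"SG1": 0.00, "SG2": 0.07, "SG3": 0.80, "SG4": 0.49, "SG5": 0.57},
    "upps_lack_premeditation": {"SG1": -0.19, "SG2": -0.09, "SG3": -0.18, "SG4": 0.18, "SG5": 1.15},
    "upps_lack_perseverance":  {"SG1": -0.35, "SG2": -0.10, "SG3": -0.04, "SG4": 0.66, "SG5": 1.02},
    "upps_sensation_seeking":  {"SG1": 0.22, "SG2": -0.17, "SG3": -0.29, "SG4": -0.59, "SG5": 0.05},
}


@dataclass(frozen=True)
class SubgroupProfile:
    """A latent environmental profile: modal levels of the discriminative features."""

    name: str
    modal_levels: Mapping[str, str]
    weight: float

    def __post_init__(self):
        if not 0 < self.weight <= 1:
            raise ValueError(f"{self.name}: weight must be in (0, 1]")
        for feat, level in self.modal_levels.items():
            spec = _schema.FEATURES_BY_NAME.get(feat)
            if spec is None:
                raise ValueError(f"{self.name}: unknown feature {feat!r}")
            if level not in spec.categories:
                raise ValueError(
                    f"{self.name}: {level!r} is not a category of {feat!r}"
                )


def default_profiles() -> Tuple[SubgroupProfile, ...]:
    """The five default profiles; weights follow the 744/300/267/201/443 split."""
    total = 744 + 300 + 267 + 201 + 443
    common12 = {
        "prosocial_peer_involvement": "Half of the Peers",
        "family_income": "$100K-$200K",
        "school_disengagement": "Definitely Not True",
        "school_involvement": "Mostly True",
        "marital_status": "Married",
        "social_role_engagement": "Somewhat True",
        "rule_breaking_peer_involvement": "Almost None",
        "parent_likeness": "Somewhat Like Him/Her",
    }
    return (
        SubgroupProfile("SG1", {**common12, "parent_employment": "Working Now"},
                        744 / total),
        SubgroupProfile("SG2", {**common12, "parent_employment": "Stay-at-Home Parent"},
                        300 / total),
        SubgroupProfile("SG3", {
            "prosocial_peer_involvement": "A Few",
            "parent_employment": "Working Now",
            "family_income": "$12K-$16K",
            "school_disengagement": "Mostly True",
            "school_involvement": "Mostly True",
            "marital_status": "Never Married",
            "social_role_engagement": "Not True",
            "rule_breaking_peer_involvement": "Almost None",
            "parent_likeness": "Not Like Him/Her",
        }, 267 / total),
        SubgroupProfile("SG4", {
            "prosocial_peer_involvement": "Almost None",
            "parent_employment": "Working Now",
            "family_income": "$50K-$75K",
            "school_disengagement": "Mostly Not True",
            "school_involvement": "Mostly Not True",
            "marital_status": "Married",
            "social_role_engagement": "Not True",
            "rule_breaking_peer_involvement": "Almost None",
            "parent_likeness": "Not Like Him/Her",
        }, 201 / total),
        SubgroupProfile("SG5", {
            "prosocial_peer_involvement": "A Few",
            "parent_employment": "Working Now",
            "family_income": "$100K-$200K",
            "school_disengagement": "Definitely True",
            "school_involvement": "Mostly Not True",
            "marital_status": "Married",
            "social_role_engagement": "Not True",
            "rule_breaking_peer_involvement": "Almost None",
            "parent_likeness": "Not Like Him/Her",
        }, 443 / total),
    )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``profile_separation`` tilts each discriminative feature's category
    weights toward the subgroup's modal level on the log scale
    (weights ∝ base_rate · exp(separation · 1[modal])); 0 removes all
    subgroup signal, the default of 5.0 yields strongly expressed
    profiles.
    """

    n_participants: int = 6324
    n_sites: int = 21
    sibling_fraction: float = 0.2511
    subgroup_profiles: Tuple[SubgroupProfile, ...] = field(default_factory=default_profiles)
    profile_separation: float = 5.0
    fhsu_positive_fraction: float = 0.309
    outcome_means: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MEANS))
    outcome_sds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_SDS))
    outcome_effects: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_EFFECTS.items()})
    site_sd: float = 1.0
    family_sd: float = 2.0
    mid_hit_prob: float = 0.6
    mid_n_runs: int = 2
    fhd_target_positive: float = 0.56
    fhd_target_negative: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < len(self.subgroup_profiles):
            raise ValueError("n_participants must be at least the number of subgroups")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        weights = sum(p.weight for p in self.subgroup_profiles)
        if abs(weights - 1.0) > 1e-9:
            raise ValueError(f"subgroup mixing weights must sum to 1, got {weights}")
        for name, val in [("sibling_fraction", self.sibling_fraction),
                          ("fhsu_positive_fraction", self.fhsu_positive_fraction),
                          ("mid_hit_prob", self.mid_hit_prob)]:
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, val in [("profile_separation", self.profile_separation),
                          ("site_sd", self.site_sd), ("family_sd", self.family_sd)]:
            if val < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def subgroup_names(self) -> Tuple[str, ...]:
        return tuple(p.name for p in self.subgroup_profiles)
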