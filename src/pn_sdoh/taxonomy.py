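"""SDoH code taxonomy for two patient-navigation study sites.

Site A is a Chinatown-style tracking log with a flat codebook of 22
substantive social-determinant categories plus the wildcard ``none`` (no
barrier recorded in an encounter) and the write-in ``other``.  Site B is a
DuPage-style log whose codes are two-level ``generic:specific`` pairs; an
alias map sends every site-B code to a site-A category, falling back from
the specific code to its generic parent, and finally to ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Wildcard emitted when an encounter records no barrier.
NONE_CODE = "none"
#: Write-in catch-all for codes with no codebook correspondence.
OTHER_CODE = "other"
#: The dominant category in navigation logs for limited-English populations.
LANGUAGE_CODE = "language_interpreter"

#: The 22 substantive site-A SDoH categories (navigator barrier codebook).
SITE_A_CODES: tuple[str, ...] = (
    "attitudes_toward_providers",
    "case_management",
    "childcare_issues",
    "citizenship",
    "communication_with_medical_personnel",
    "distance_from_facility",
    "employment",
    "family_community_issues",
    "fear",
    "financial_problems",
    "housing",
    "insurance_uninsured_underinsured",
    "language_interpreter",
    "literacy",
    "medical_mental_comorbidity",
    "out_of_town_country",
    "patient_disability",
    "perceptions_beliefs_about_treatment",
    "social_practical_support",
    "system_problems_scheduling",
    "transportation",
    "work_schedule_conflicts",
)

#: Site-B (generic -> site-A) correspondences.  Generic codes are the coarse
#: DuPage-style groupings; each maps to the closest site-A category.
SITE_B_GENERIC_MAP: dict[str, str] = {
    "language": "language_interpreter",
    "transport": "transportation",
    "finance": "financial_problems",
    "insurance": "insurance_uninsured_underinsured",
    "family": "family_community_issues",
    "support": "social_practical_support",
    "housing": "housing",
    "fear": "fear",
    "beliefs": "perceptions_beliefs_about_treatment",
    "scheduling": "system_problems_scheduling",
    "employment": "employment",
    "casemgmt": "case_management",
    "none": NONE_CODE,
}

#: Specific site-B codes (``generic:specific``) with a *direct* site-A match,
#: overriding the generic fallback.
SITE_B_SPECIFIC_MAP: dict[str, str] = {
    "transport:distance": "distance_from_facility",
    "finance:work_hours": "work_schedule_conflicts",
    "family:childcare": "childcare_issues",
    "support:disability": "patient_disability",
    "language:literacy": "literacy",
    "casemgmt:comm_provider": "communication_with_medical_personnel",
}

#: Specific site-B codes that exist in the site-B codebook but have no direct
#: site-A correspondence (they resolve through their generic parent).
SITE_B_SPECIFIC_ONLY: tuple[str, ...] = (
    "language:interpreter_needed",
    "transport:no_car",
    "finance:copay",
    "insurance:lapsed",
    "family:elder_care",
    "support:no_near_family",
    "housing:eviction",
    "fear:diagnosis",
    "beliefs:screening",
    "scheduling:clinic_hours",
    "employment:shift_work",
    "casemgmt:referral",
)


@dataclass(frozen=True)
class SDoHTaxonomy:
    """Ordered SDoH codebook for one harmonization run.

    ``codes`` are the substantive site-A categories; ``none`` and ``other``
    are carried separately.  ``alias_map`` must be total on site-B codes at
    the generic level (every generic has an entry; specifics fall back).
    """

    codes: tuple[str, ...] = SITE_A_CODES
    alias_map: dict[str, str] = field(
        default_factory=lambda: {**SITE_B_GENERIC_MAP, **SITE_B_SPECIFIC_MAP}
    )

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("taxonomy codes must be unique")
        for reserved in (NONE_CODE, OTHER_CODE):
            if reserved in self.codes:
                raise ValueError(f"reserved code {reserved!r} in substantive codes")

    @property
    def all_codes(self) -> tuple[str, ...]:
        """Substantive codes plus the ``none`` and ``other`` wildcards."""
        return self.codes + (NONE_CODE, OTHER_CODE)

    def is_valid(self, code: str) -> bool:
        return code in self.codes or code in (NONE_CODE, OTHER_CODE)

    def site_b_codes(self) -> tuple[str, ...]:
        """Every code the site-B generator may emit."""
        generics = tuple(g for g in SITE_B_GENERIC_MAP if g != "none")
        return generics + tuple(SITE_B_SPECIFIC_MAP) + SITE_B_SPECIFIC_ONLY + (NONE_CODE,)


def default_taxonomy() -> SDoHTaxonomy:
    return SDoHTaxonomy()


def taxonomy_from_yaml(path) -> SDoHTaxonomy:
    """Load a user-edited codebook: ``codes`` list and ``alias_map`` mapping.

    Either key may be omitted to keep the shipped default.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    if "codes" in data:
        kwargs["codes"] = tuple(data["codes"])
    if "alias_map" in data:
        kwargs["alias_map"] = dict(data["alias_map"])
    return SDoHTaxonomy(**kwargs)
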