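"""The 22-label annotation scheme for depression signals in short texts.

The scheme combines 9 depressive-symptom parent categories (DSM-5 major
depressive disorder criteria), 12 psychosocial-stressor parent categories
(DSM-IV Axis IV, plus two context categories, *weather* and *media*, that
recur in social-media data), and a *no evidence of clinical depression*
label that is mutually exclusive with all others.

Category order is fixed: symptoms first, then stressors, then no-evidence.
That order indexes every correlation matrix and heatmap axis produced
downstream, so it is part of the public contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Group(str, Enum):
    """Which block of the scheme a label belongs to."""

    SYMPTOM = "symptom"
    STRESSOR = "stressor"
    NO_EVIDENCE = "no_evidence"


#: Canonical snake_case identifiers, in scheme order.
SYMPTOMS: tuple[str, ...] = (
    "depressed_mood",
    "anhedonia",
    "weight_change",
    "disturbed_sleep",
    "psychomotor_agitation",
    "fatigue",
    "worthlessness",
    "diminished_concentration",
    "suicidal_ideation",
)

STRESSORS: tuple[str, ...] = (
    "life_course",
    "primary_support",
    "social_environment",
    "educational_problems",
    "occupational_problems",
    "housing_problems",
    "economic_problems",
    "health_care_access",
    "legal_system",
    "other_psychosocial",
    "weather",
    "media",
)

NO_EVIDENCE: str = "no_evidence"

#: Mapping from canonical identifiers to the printed category names.
DISPLAY_NAMES: dict[str, str] = {
    "depressed_mood": "Depressed mood",
    "anhedonia": "Anhedonia",
    "weight_change": "Weight change or change in appetite",
    "disturbed_sleep": "Disturbed sleep",
    "psychomotor_agitation": "Psychomotor agitation or retardation",
    "fatigue": "Fatigue or loss of energy",
    "worthlessness": "Feelings of worthlessness or excessive inappropriate guilt",
    "diminished_concentration": "Diminished ability to think or concentrate, indecisiveness",
    "suicidal_ideation": "Recurrent thoughts of death, suicidal ideation",
    "life_course": "Problems with expected life course with respect to self",
    "primary_support": "Problems with primary support group",
    "social_environment": "Problems related to the social environment",
    "educational_problems": "Educational problems",
    "occupational_problems": "Occupational problems",
    "housing_problems": "Housing problems",
    "economic_problems": "Economic problems",
    "health_care_access": "Problems with access to health care",
    "legal_system": "Problems related to the legal system and crime",
    "other_psychosocial": "Other psychosocial and environmental problems",
    "weather": "Weather",
    "media": "Media",
    "no_evidence": "No evidence of clinical depression",
}


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered, closed label space with group tags.

    Invariants (enforced at construction): exactly 9 symptom labels,
    12 stressor labels and 1 no-evidence label; labels unique.
    """

    symptoms: tuple[str, ...] = SYMPTOMS
    stressors: tuple[str, ...] = STRESSORS
    no_evidence: str = NO_EVIDENCE
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.symptoms) != 9:
            raise ValueError(f"scheme requires 9 symptom labels, got {len(self.symptoms)}")
        if len(self.stressors) != 12:
            raise ValueError(f"scheme requires 12 stressor labels, got {len(self.stressors)}")
        cats = self.categories
        if len(set(cats)) != len(cats):
            raise ValueError("scheme labels must be unique")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(cats)})

    @property
    def categories(self) -> tuple[str, ...]:
        """All 22 labels in canonical order."""
        return self.symptoms + self.stressors + (self.no_evidence,)

    @property
    def evidence_categories(self) -> tuple[str, ...]:
        """The 21 symptom/stressor labels (no-evidence excluded)."""
        return self.symptoms + self.stressors

    def group(self, category: str) -> Group:
        if category in self.symptoms:
            return Group.SYMPTOM
        if category in self.stressors:
            return Group.STRESSOR
        if category == self.no_evidence:
            return Group.NO_EVIDENCE
        raise KeyError(f"unknown category: {category!r}")

    def index(self, category: str) -> int:
        """Position of a label in scheme order (heatmap axis index)."""
        try:
            return self._index[category]
        except KeyError:
            raise KeyError(f"unknown category: {category!r}") from None

    def __contains__(self, category: object) -> bool:
        return category in self._index

    def display_name(self, category: str) -> str:
        if category not in self:
            raise KeyError(f"unknown category: {category!r}")
        return DISPLAY_NAMES.get(category, category)


#: The default scheme instance used throughout the package.
DEFAULT_SCHEME = CategoryScheme()
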