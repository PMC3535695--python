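"""Genetic-lesion-status label hierarchy.

Every gene-symbol mention in a trial document receives one leaf category.
Four of the leaves describe the status of a genetic lesion (detected, not
detected, mentioned without result, gene entity only); the remaining two
capture the common non-gene senses of a symbol (part of a drug/therapy name,
or an ordinary English word as in "criteria are met"). The leaves coarsen
into three top-level classes used by stage 1 of the cascade classifier.

An optional seventh leaf, "detected or not detected" (eligibility satisfied
as long as the genetic status was measured at all), can be enabled for
corpora annotated with the extended guideline.
"""

from __future__ import annotations

import enum


class StatusCategory(enum.Enum):
    """Leaf category assigned to a single gene-symbol mention."""

    GENETIC_LESION_DETECTED = "Genetic lesion detected"
    GENETIC_LESION_NOT_DETECTED = "Genetic lesion not detected"
    GENETIC_LESION_MENTIONED = "Genetic lesion mentioned"
    GENE_ONLY = "Gene only"
    DRUG = "Drug"
    OTHERS = "Others"
    GENETIC_LESION_DETECTED_OR_NOT = "Genetic lesion detected or not detected"

    @property
    def ordinal(self) -> int:
        return CATEGORY_ORDER.index(self)

    def __lt__(self, other: "StatusCategory") -> bool:
        return self.ordinal < other.ordinal


class Stage1Label(enum.Enum):
    """Coarse class predicted by stage 1 of the cascade."""

    GENE_RELATED = "Gene-related"
    DRUG = "Drug"
    OTHERS = "Others"


#: Canonical ordinal order; also the deterministic tie-break order.
CATEGORY_ORDER: tuple[StatusCategory, ...] = (
    StatusCategory.GENETIC_LESION_DETECTED,
    StatusCategory.GENETIC_LESION_NOT_DETECTED,
    StatusCategory.GENETIC_LESION_MENTIONED,
    StatusCategory.GENE_ONLY,
    StatusCategory.DRUG,
    StatusCategory.OTHERS,
    StatusCategory.GENETIC_LESION_DETECTED_OR_NOT,
)

#: The default six-category label set.
DEFAULT_CATEGORIES: tuple[StatusCategory, ...] = CATEGORY_ORDER[:6]

#: The extended seven-category set (adds "detected or not detected").
EXTENDED_CATEGORIES: tuple[StatusCategory, ...] = CATEGORY_ORDER

#: Leaves that coarsen to GENE_RELATED.
GENE_RELATED_CATEGORIES: frozenset[StatusCategory] = frozenset(
    {
        StatusCategory.GENETIC_LESION_DETECTED,
        StatusCategory.GENETIC_LESION_NOT_DETECTED,
        StatusCategory.GENETIC_LESION_MENTIONED,
        StatusCategory.GENE_ONLY,
        StatusCategory.GENETIC_LESION_DETECTED_OR_NOT,
    }
)


def enabled_categories(include_detected_or_not: bool = False) -> tuple[StatusCategory, ...]:
    """Return the configured leaf label set."""
    return EXTENDED_CATEGORIES if include_detected_or_not else DEFAULT_CATEGORIES


def coarsen_label(category: StatusCategory) -> Stage1Label:
    """Map a leaf category to its stage-1 coarse class.

    The lesion-status leaves (detected / not detected / mentioned / gene only,
    plus the optional "detected or not detected") all merge into GENE_RELATED;
    DRUG and OTHERS map to themselves.
    """
    if category in GENE_RELATED_CATEGORIES:
        return Stage1Label.GENE_RELATED
    if category is StatusCategory.DRUG:
        return Stage1Label.DRUG
    return Stage1Label.OTHERS


def category_from_name(name: str, categories: tuple[StatusCategory, ...]) -> StatusCategory:
    """Resolve a label string (enum name or display value) to a category.

    Raises ``ValueError`` listing the valid labels when the string does not
    name a category in the enabled set.
    """
    for cat in categories:
        if name == cat.name or name == cat.value:
            return cat
    valid = ", ".join(c.name for c in categories)
    raise ValueError(f"unknown label {name!r}; valid labels: {valid}")
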