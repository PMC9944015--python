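"""Classification of exposures into age group, FOV category, operation mode
and clinical indication.

Age groups follow the pediatric dosimetry convention 4–6 y, 7–11 y, 12–14 y and
≥15 y; conversion factors for a 15-year-old are taken as a good estimate for
adults, so the last group is open-ended.  Ages below 4 are rejected because no
conversion factor covers them.

FOV categories are driven by the area product diameter × height (cm²):
small < 40, 40 ≤ medium ≤ 100, large > 100.  The 40 cm² boundary belongs to
the medium group (an 8 × 5 cm volume is a medium FOV).
"""

from __future__ import annotations

import enum

from .model import DeviceProfile, DoseAuditError


class AgeGroup(enum.Enum):
    Y4_6 = "4-6y"
    Y7_11 = "7-11y"
    Y12_14 = "12-14y"
    Y15_PLUS = ">=15y"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Integer ages spanned by each group. The open-ended adult group is
#: represented by age 15 alone: adult conversion factors are the 15-y ones.
AGE_GROUP_AGES: dict[AgeGroup, tuple[int, ...]] = {
    AgeGroup.Y4_6: (4, 5, 6),
    AgeGroup.Y7_11: (7, 8, 9, 10, 11),
    AgeGroup.Y12_14: (12, 13, 14),
    AgeGroup.Y15_PLUS: (15,),
}

AGE_GROUPS: tuple[AgeGroup, ...] = tuple(AgeGroup)


class AgeBelowRangeError(DoseAuditError):
    """Patient younger than the youngest covered age group."""


def assign_age_group(age: int) -> AgeGroup:
    """Bucket an integer age (floor of chronological age) into its group.

    Raises :class:`AgeBelowRangeError` for ages below 4, for which no
    effective-dose conversion factor exists.
    """
    if age < 0:
        raise DoseAuditError(f"age must be non-negative, got {age}")
    if age < 4:
        raise AgeBelowRangeError(
            f"age {age} is below the youngest covered age group (4-6 y); "
            "no conversion factor exists for this age"
        )
    if age <= 6:
        return AgeGroup.Y4_6
    if age <= 11:
        return AgeGroup.Y7_11
    if age <= 14:
        return AgeGroup.Y12_14
    return AgeGroup.Y15_PLUS


class FovCategory(enum.Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_fov(diameter_cm: float, height_cm: float) -> FovCategory:
    """Classify a FOV by its area product diameter × height in cm²."""
    if diameter_cm <= 0 or height_cm <= 0:
        raise DoseAuditError(
            f"FOV dimensions must be positive, got {diameter_cm} x {height_cm}"
        )
    area = diameter_cm * height_cm
    if area < 40:
        return FovCategory.SMALL
    if area <= 100:
        return FovCategory.MEDIUM
    return FovCategory.LARGE


class OperationMode(enum.Enum):
    STANDARD = "standard"
    HR = "HR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Device-native labels, lowercased and trimmed, to the normalized vocabulary.
# High-fidelity and high-resolution modes play the same dose/image-quality role
# and are pooled as HR; standard and regular-scan are pooled as standard.
_MODE_SYNONYMS: dict[str, OperationMode] = {
    "standard": OperationMode.STANDARD,
    "regular scan": OperationMode.STANDARD,
    "high-fidelity": OperationMode.HR,
    "high fidelity": OperationMode.HR,
    "high-resolution": OperationMode.HR,
    "high resolution": OperationMode.HR,
    "hr": OperationMode.HR,
}


def normalize_mode(raw_label: str, device: DeviceProfile) -> OperationMode:
    """Map a device-native mode label to {standard, HR}.

    The label must appear in the device's protocol catalog; matching is
    case-insensitive after trimming.
    """
    wanted = raw_label.strip().lower()
    known = device.mode_labels()
    if wanted not in {m.strip().lower() for m in known}:
        raise DoseAuditError(
            f"unknown operation mode {raw_label!r} for device {device.device_id!r}; "
            f"known labels: {known}"
        )
    try:
        return _MODE_SYNONYMS[wanted]
    except KeyError:
        raise DoseAuditError(
            f"mode label {raw_label!r} has no normalized equivalent "
            f"(known synonyms: {sorted(_MODE_SYNONYMS)})"
        ) from None


#: The seven clinical-indication categories of the audit.
INDICATIONS: tuple[str, ...] = (
    "endodontics",
    "orthodontic planning",
    "pedodontics",
    "implant placement",
    "surgical planning and follow-up",
    "second opinion radiodiagnosis",
    "medically compromised patient care",
)


class IndicationMapping:
    """Referral department → clinical indication lookup.

    The mapping is user-editable; values are validated against the
    seven-category vocabulary.  In strict mode (default) an unmapped
    department raises; in lenient mode it routes to ``fallback``.
    """

    def __init__(
        self,
        table: dict[str, str],
        strict: bool = True,
        fallback: str | None = None,
    ):
        self.table = {k.strip().lower(): v for k, v in table.items()}
        for dept, ind in self.table.items():
            if ind not in INDICATIONS:
                raise DoseAuditError(
                    f"department {dept!r} maps to unknown indication {ind!r}; "
                    f"allowed: {list(INDICATIONS)}"
                )
        if not strict:
            if fallback is None or fallback not in INDICATIONS:
                raise DoseAuditError(
                    "lenient indication mapping requires a fallback from the "
                    f"seven-category vocabulary, got {fallback!r}"
                )
        self.strict = strict
        self.fallback = fallback

    def __contains__(self, department: str) -> bool:
        return department.strip().lower() in self.table


def map_indication(referral_department: str, mapping: IndicationMapping) -> str:
    """Resolve a referral department to one of the seven clinical indications."""
    key = referral_department.strip().lower()
    if key in mapping.table:
        return mapping.table[key]
    if mapping.strict:
        raise DoseAuditError(
            f"referral department {referral_department!r} is not in the "
            "indication mapping (strict mode)"
        )
    assert mapping.fallback is not None
    return mapping.fallback
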