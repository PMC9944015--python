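"""Per-exam effective dose and cohort collective dose.

E = CF_E × DAP_corrected, with E in µSv, CF_E in µSv/(dGy·cm²) and the
corrected DAP in dGy·cm².  All arithmetic is carried at full precision;
rounding to 3 significant figures happens only at report boundaries.
The collective dose is the sum of individual effective doses in man-sievert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .classify import (
    AgeGroup,
    FovCategory,
    IndicationMapping,
    OperationMode,
    assign_age_group,
    classify_fov,
    map_indication,
    normalize_mode,
)
from .conversion import CFPerDAPTable
from .model import DoseAuditError, ExposureRecord, Registry
from .qc import apply_correction


@dataclass(frozen=True)
class DoseResult:
    """An exposure record with its classifications and effective dose."""

    record: ExposureRecord
    corrected_dap_dgycm2: float
    age_group: AgeGroup
    fov_category: FovCategory
    mode: OperationMode
    indication: str
    effective_dose_usv: float


@dataclass(frozen=True)
class RejectedRecord:
    """A record the dose engine could not process, with the reason."""

    record: ExposureRecord
    reason: str


def effective_dose(corrected_dap_dgycm2: float, cf_usv_per_dapcm2: float) -> float:
    """Effective dose in µSv: CF_E × corrected DAP, full precision."""
    if corrected_dap_dgycm2 < 0:
        raise DoseAuditError(f"corrected DAP must be non-negative, got {corrected_dap_dgycm2}")
    if cf_usv_per_dapcm2 <= 0:
        raise DoseAuditError(f"conversion factor must be positive, got {cf_usv_per_dapcm2}")
    return corrected_dap_dgycm2 * cf_usv_per_dapcm2


def compute_doses(
    records: Sequence[ExposureRecord],
    registry: Registry,
    cf_table: CFPerDAPTable,
    indication_mapping: IndicationMapping,
    correction_factors: Mapping[str, float] | None = None,
) -> tuple[list[DoseResult], list[RejectedRecord]]:
    """Classify every record and compute its effective dose.

    The DAP correction factor comes from ``correction_factors`` when given,
    otherwise from the device profile.  Records that fail age-group
    assignment (age < 4) are routed to the rejects list, never silently
    dropped.  Missing CF coverage for a (device, age group) is an error:
    it indicates a misconfigured CF table rather than an odd patient.
    """
    results: list[DoseResult] = []
    rejects: list[RejectedRecord] = []
    for rec in records:
        try:
            device = registry[rec.device_id]
        except KeyError:
            raise DoseAuditError(
                f"exam {rec.exam_id!r}: unknown device {rec.device_id!r}; "
                f"known: {sorted(registry)}"
            ) from None
        try:
            age_group = assign_age_group(rec.patient_age)
        except DoseAuditError as exc:
            rejects.append(RejectedRecord(record=rec, reason=str(exc)))
            continue
        k = (correction_factors or {}).get(rec.device_id, device.dap_correction_factor)
        corrected = apply_correction(rec.recorded_dap_dgycm2, k)
        cf = cf_table.lookup(rec.device_id, age_group)
        results.append(
            DoseResult(
                record=rec,
                corrected_dap_dgycm2=corrected,
                age_group=age_group,
                fov_category=classify_fov(rec.fov_diameter_cm, rec.fov_height_cm),
                mode=normalize_mode(rec.operation_mode_raw, device),
                indication=map_indication(rec.referral_department, indication_mapping),
                effective_dose_usv=effective_dose(corrected, cf),
            )
        )
    return results, rejects


def collective_dose(doses: Sequence[DoseResult]) -> float:
    """Collective effective dose in manSv: Σ E_i × 10⁻⁶."""
    return sum(d.effective_dose_usv for d in doses) * 1e-6
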