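"""Effective-dose conversion factors and their derivation.

Two CF dialects exist:

* per-mAs (``µSv/mAs``): Monte-Carlo-derived factors discriminated by device,
  scanned-region clinical indication and integer patient age (5–15 y), the
  form in which pediatric CBCT dosimetry literature publishes them;
* per-DAP (``µSv/(dGy·cm²)``): one factor per device and age group, the form
  a DICOM-header-driven dose monitor can actually apply, since the clinical
  indication is not available in the header.

This module converts the first form into the second.  For every FOV a device
offers, the per-mAs factors of all clinical indications linked to that FOV
and all integer ages inside an age group are averaged without weighting.  The
per-FOV averaged factor then yields one effective dose per exam
(CF(FOV) × mAs), which divided by the corrected DAP gives a per-exam
µSv/(dGy·cm²) ratio; the per-DAP CF of the (device, age group) cell is the
unweighted mean of those ratios — over the protocol catalog for a fixed-
exposure device, over real patient exams for a TCM device.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .classify import AGE_GROUP_AGES, AGE_GROUPS, AgeGroup
from .model import DeviceProfile, DoseAuditError, ExposureRecord
from .qc import apply_correction


@dataclass(frozen=True)
class CFPerMAsEntry:
    """One µSv/mAs conversion factor for (device, scanned region, age)."""

    device_id: str
    indication_region: str
    age_years: int
    cf_usv_per_mas: float

    def __post_init__(self) -> None:
        if self.cf_usv_per_mas <= 0:
            raise DoseAuditError("cf_usv_per_mas must be positive")
        if not 5 <= self.age_years <= 15:
            raise DoseAuditError(
                f"per-mAs CFs cover ages 5-15 y, got {self.age_years}"
            )


@dataclass(frozen=True)
class CFPerDAPEntry:
    """One µSv/(dGy·cm²) conversion factor for (device, age group)."""

    device_id: str
    age_group: AgeGroup
    cf_usv_per_dapcm2: float

    def __post_init__(self) -> None:
        if self.cf_usv_per_dapcm2 <= 0:
            raise DoseAuditError("cf_usv_per_dapcm2 must be positive")


class CFPerMAsTable:
    """Indication- and age-specific per-mAs conversion factors."""

    dialect = "per_mas"

    def __init__(self, entries: Sequence[CFPerMAsEntry]):
        seen: set[tuple[str, str, int]] = set()
        for e in entries:
            key = (e.device_id, e.indication_region, e.age_years)
            if key in seen:
                raise DoseAuditError(f"duplicate per-mAs CF entry for {key}")
            seen.add(key)
        self.entries: tuple[CFPerMAsEntry, ...] = tuple(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def for_device(self, device_id: str) -> list[CFPerMAsEntry]:
        return [e for e in self.entries if e.device_id == device_id]


class CFPerDAPTable:
    """Age-group-averaged per-DAP conversion factors, one per (device, group).

    Every device present must cover all four age groups.
    """

    dialect = "per_dap"

    def __init__(self, entries: Sequence[CFPerDAPEntry]):
        table: dict[tuple[str, AgeGroup], float] = {}
        for e in entries:
            key = (e.device_id, e.age_group)
            if key in table:
                raise DoseAuditError(f"duplicate per-DAP CF entry for {key}")
            table[key] = e.cf_usv_per_dapcm2
        for device_id in {e.device_id for e in entries}:
            missing = [g.value for g in AGE_GROUPS if (device_id, g) not in table]
            if missing:
                raise DoseAuditError(
                    f"per-DAP CF table for device {device_id!r} lacks age group(s): {missing}"
                )
        self._table = table
        self.entries = tuple(entries)

    def devices(self) -> list[str]:
        return sorted({d for d, _ in self._table})

    def lookup(self, device_id: str, age_group: AgeGroup) -> float:
        try:
            return self._table[(device_id, age_group)]
        except KeyError:
            raise DoseAuditError(
                f"no per-DAP CF for device {device_id!r}, age group {age_group.value!r}; "
                f"covered devices: {self.devices()}"
            ) from None


@dataclass(frozen=True)
class IndicationFovLink:
    """Which FOVs of a device serve a scanned-region clinical indication."""

    device_id: str
    indication_region: str
    fovs: tuple[tuple[float, float], ...]


def _fov_key(diameter_cm: float, height_cm: float) -> tuple[float, float]:
    return (round(float(diameter_cm), 3), round(float(height_cm), 3))


def average_cf_per_fov(
    cf_mas: CFPerMAsTable,
    links: Sequence[IndicationFovLink],
    device_id: str,
    fov: tuple[float, float],
    age_group: AgeGroup,
) -> float:
    """Average µSv/mAs factor for one FOV and age group.

    Unweighted arithmetic mean over all clinical indications linked to the FOV
    and all integer ages inside the group that the table covers.  (The adult
    group uses the 15-y factors: head circumference no longer grows
    significantly after that age.)
    """
    key = _fov_key(*fov)
    regions = {
        link.indication_region
        for link in links
        if link.device_id == device_id and any(_fov_key(*f) == key for f in link.fovs)
    }
    ages = AGE_GROUP_AGES[age_group]
    values = [
        e.cf_usv_per_mas
        for e in cf_mas.for_device(device_id)
        if e.indication_region in regions and e.age_years in ages
    ]
    if not values:
        raise DoseAuditError(
            f"no per-mAs CF entries linked to FOV {fov} for device {device_id!r}, "
            f"age group {age_group.value!r}"
        )
    return sum(values) / len(values)


def per_fov_cf_table(
    cf_mas: CFPerMAsTable,
    links: Sequence[IndicationFovLink],
    device: DeviceProfile,
    age_group: AgeGroup,
) -> dict[tuple[float, float], float]:
    """Averaged µSv/mAs factor for every distinct FOV in the device catalog."""
    out: dict[tuple[float, float], float] = {}
    for p in device.protocols:
        key = _fov_key(p.fov_diameter_cm, p.fov_height_cm)
        if key not in out:
            out[key] = average_cf_per_fov(cf_mas, links, device.device_id, key, age_group)
    return out


def derive_cf_per_dap(
    per_fov_cf: Mapping[tuple[float, float], float],
    device: DeviceProfile,
    age_group: AgeGroup,
    exposure_samples: Sequence[ExposureRecord] | None = None,
) -> CFPerDAPEntry:
    """Collapse per-FOV µSv/mAs factors into one µSv/(dGy·cm²) factor.

    Non-TCM device: each protocol contributes one ratio
    CF(FOV) × mAs / (k × nominal recorded DAP); the entry is their mean.
    TCM device: exposure parameters are patient-dependent, so per-exam ratios
    over ``exposure_samples`` (exams of patients in the age group) are
    averaged instead.
    """
    k = device.dap_correction_factor
    ratios: list[float] = []
    if device.tcm:
        if not exposure_samples:
            raise DoseAuditError(
                f"TCM device {device.device_id!r} needs patient exposure samples "
                f"for age group {age_group.value!r}"
            )
        for rec in exposure_samples:
            corrected = apply_correction(rec.recorded_dap_dgycm2, k)
            if corrected == 0:
                raise DoseAuditError(
                    f"exam {rec.exam_id!r}: corrected DAP is zero, ratio undefined"
                )
            cf = _lookup_fov_cf(per_fov_cf, rec.fov_diameter_cm, rec.fov_height_cm)
            ratios.append(cf * rec.total_exposure_mas / corrected)
    else:
        for p in device.protocols:
            corrected = apply_correction(p.nominal_recorded_dap_dgycm2, k)
            if corrected == 0:
                raise DoseAuditError(
                    f"protocol {p.mode_raw} {p.fov_label}: corrected DAP is zero"
                )
            cf = _lookup_fov_cf(per_fov_cf, p.fov_diameter_cm, p.fov_height_cm)
            ratios.append(cf * p.fixed_mas / corrected)
        if not ratios:
            raise DoseAuditError(f"device {device.device_id!r} has an empty protocol catalog")
    return CFPerDAPEntry(
        device_id=device.device_id,
        age_group=age_group,
        cf_usv_per_dapcm2=sum(ratios) / len(ratios),
    )


def _lookup_fov_cf(
    per_fov_cf: Mapping[tuple[float, float], float], diameter: float, height: float
) -> float:
    key = _fov_key(diameter, height)
    try:
        return per_fov_cf[key]
    except KeyError:
        raise DoseAuditError(
            f"no averaged per-mAs CF for FOV {key}; covered: {sorted(per_fov_cf)}"
        ) from None


@dataclass(frozen=True)
class CFValidationStats:
    """Agreement between per-DAP and original per-mAs dose estimates."""

    device_id: str
    age_group: AgeGroup
    mean_relative_deviation: float
    fraction_within_20pct: float
    n: int


#: "Within 20%" is inclusive: a deviation of exactly 0.20 counts as within.
WITHIN_BAND = 0.20


def validate_cf(
    corrected_daps: Sequence[float],
    e_mas_doses: Sequence[float],
    cf_dap: CFPerDAPEntry,
) -> CFValidationStats:
    """Per-exam relative error of the averaged per-DAP CF.

    For each exam, E_dap = CF × corrected DAP is compared with the dose E_mas
    from the original indication- and age-specific per-mAs factors:
    deviation = |E_dap − E_mas| / E_mas.
    """
    if len(corrected_daps) != len(e_mas_doses):
        raise DoseAuditError("corrected_daps and e_mas_doses must align")
    if not corrected_daps:
        raise DoseAuditError("validation needs at least one exam")
    deviations = []
    for dap, e_mas in zip(corrected_daps, e_mas_doses):
        if e_mas == 0:
            raise DoseAuditError("per-mAs reference dose is zero, relative error undefined")
        e_dap = cf_dap.cf_usv_per_dapcm2 * dap
        deviations.append(abs(e_dap - e_mas) / e_mas)
    n = len(deviations)
    return CFValidationStats(
        device_id=cf_dap.device_id,
        age_group=cf_dap.age_group,
        mean_relative_deviation=sum(deviations) / n,
        fraction_within_20pct=sum(d <= WITHIN_BAND for d in deviations) / n,
        n=n,
    )


def cf_table_from_mapping(values: Mapping[str, Mapping[str, float]]) -> CFPerDAPTable:
    """Build a per-DAP table from {device_id: {age group value: cf}}."""
    entries = [
        CFPerDAPEntry(device_id=d, age_group=AgeGroup(g), cf_usv_per_dapcm2=v)
        for d, groups in values.items()
        for g, v in groups.items()
    ]
    return CFPerDAPTable(entries)


def iter_age_groups() -> Iterable[AgeGroup]:
    return iter(AGE_GROUPS)
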