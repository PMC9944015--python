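"""Shared data model for CBCT exposure auditing.

The pipeline's unit of work is one CBCT acquisition (:class:`ExposureRecord`)
read from a flat DICOM-header-style exposure log.  Scanners are described by a
:class:`DeviceProfile` carrying the clinical protocol catalog, whether the unit
applies tube current modulation (TCM), and the QC-derived dose-area-product
(DAP) correction factor.  All DAPs are in dGy·cm², tube loading in mAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence


class DoseAuditError(ValueError):
    """Base class for validation failures in the audit pipeline."""


class SchemaError(DoseAuditError):
    """A file is missing a mandatory column or declares an unknown layout."""


class RowError(DoseAuditError):
    """A single row of an input file failed validation (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class UnknownDeviceError(DoseAuditError):
    """A record references a device_id absent from the registry."""


@dataclass(frozen=True)
class ExposureRecord:
    """One CBCT acquisition as extracted from the image DICOM header.

    ``fov_diameter_cm`` × ``fov_height_cm`` define the cylindrical scan volume;
    their product (cm²) drives the small/medium/large FOV classification.
    ``recorded_dap_dgycm2`` is the device-displayed DAP before QC correction.
    """

    exam_id: str
    device_id: str
    acquired_on: date
    patient_age: int
    referral_department: str
    operation_mode_raw: str
    fov_diameter_cm: float
    fov_height_cm: float
    tube_voltage_kv: float
    total_exposure_mas: float
    recorded_dap_dgycm2: float

    def __post_init__(self) -> None:
        if self.fov_diameter_cm <= 0 or self.fov_height_cm <= 0:
            raise DoseAuditError(
                f"exam {self.exam_id!r}: FOV dimensions must be positive, got "
                f"{self.fov_diameter_cm} x {self.fov_height_cm}"
            )
        if self.tube_voltage_kv <= 0:
            raise DoseAuditError(f"exam {self.exam_id!r}: tube voltage must be positive")
        if self.total_exposure_mas <= 0:
            raise DoseAuditError(f"exam {self.exam_id!r}: total exposure (mAs) must be positive")
        if self.recorded_dap_dgycm2 < 0:
            raise DoseAuditError(f"exam {self.exam_id!r}: recorded DAP must be non-negative")
        if self.patient_age < 0:
            raise DoseAuditError(f"exam {self.exam_id!r}: patient age must be non-negative")

    @property
    def fov_area_cm2(self) -> float:
        return self.fov_diameter_cm * self.fov_height_cm

    @property
    def fov_label(self) -> str:
        def fmt(x: float) -> str:
            return f"{int(x)}" if float(x).is_integer() else f"{x}"

        return f"{fmt(self.fov_diameter_cm)}x{fmt(self.fov_height_cm)}"


@dataclass(frozen=True)
class Protocol:
    """One selectable acquisition setting of a scanner.

    For a non-TCM device ``total_exposure_mas`` is a single fixed value and
    ``nominal_recorded_dap_dgycm2`` the fixed displayed DAP.  For a TCM device
    the mAs is a (min, max) range and the nominal DAP is a cohort mean.
    """

    mode_raw: str
    fov_diameter_cm: float
    fov_height_cm: float
    tube_voltage_kv: float
    total_exposure_mas: float | tuple[float, float]
    nominal_recorded_dap_dgycm2: float

    @property
    def fov_area_cm2(self) -> float:
        return self.fov_diameter_cm * self.fov_height_cm

    @property
    def fov_label(self) -> str:
        def fmt(x: float) -> str:
            return f"{int(x)}" if float(x).is_integer() else f"{x}"

        return f"{fmt(self.fov_diameter_cm)}x{fmt(self.fov_height_cm)}"

    @property
    def mas_is_range(self) -> bool:
        return isinstance(self.total_exposure_mas, tuple)

    @property
    def fixed_mas(self) -> float:
        if self.mas_is_range:
            raise DoseAuditError(
                f"protocol {self.mode_raw} {self.fov_label}: mAs is a TCM range, not fixed"
            )
        return float(self.total_exposure_mas)  # type: ignore[arg-type]


@dataclass(frozen=True)
class DeviceProfile:
    """Scanner identity, TCM flag, protocol catalog and DAP correction factor."""

    device_id: str
    display_name: str
    tcm: bool
    dap_correction_factor: float
    protocols: tuple[Protocol, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 < self.dap_correction_factor <= 2:
            raise DoseAuditError(
                f"device {self.device_id!r}: DAP correction factor must lie in (0, 2], "
                f"got {self.dap_correction_factor}"
            )
        if not self.tcm:
            for p in self.protocols:
                if p.mas_is_range:
                    raise DoseAuditError(
                        f"device {self.device_id!r} has no TCM: protocol "
                        f"{p.mode_raw} {p.fov_label} must carry a fixed mAs"
                    )

    def mode_labels(self) -> list[str]:
        seen: list[str] = []
        for p in self.protocols:
            if p.mode_raw not in seen:
                seen.append(p.mode_raw)
        return seen

    def protocol(self, mode_raw: str, fov_label: str) -> Protocol:
        for p in self.protocols:
            if p.mode_raw.strip().lower() == mode_raw.strip().lower() and p.fov_label == fov_label:
                return p
        raise DoseAuditError(
            f"device {self.device_id!r}: no protocol ({mode_raw!r}, {fov_label!r}); "
            f"known: {[(p.mode_raw, p.fov_label) for p in self.protocols]}"
        )


Registry = dict[str, DeviceProfile]


def build_registry(profiles: Sequence[DeviceProfile]) -> Registry:
    """Index device profiles by id; rejects duplicate device_ids."""
    registry: Registry = {}
    for p in profiles:
        if p.device_id in registry:
            raise DoseAuditError(f"duplicate device_id {p.device_id!r} in registry")
        registry[p.device_id] = p
    return registry


@dataclass(frozen=True)
class QCMeasurement:
    """One (measured, recorded) DAP pair from an annual QC campaign."""

    device_id: str
    fov_label: str
    measured_dap_dgycm2: float
    recorded_dap_dgycm2: float

    def __post_init__(self) -> None:
        if self.measured_dap_dgycm2 <= 0 or self.recorded_dap_dgycm2 <= 0:
            raise DoseAuditError(
                f"QC measurement ({self.device_id}, {self.fov_label}): "
                "both DAP values must be strictly positive"
            )
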