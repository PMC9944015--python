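"""Reading and writing exposure logs, registries, QC files and CF tables.

All tabular inputs are UTF-8 delimited text with a dot decimal separator and
ISO-8601 dates: a flat, PHI-free stand-in for DICOM-header extracts.  The
device registry is a YAML document versioned with ``schema_version``.
"""

from __future__ import annotations

import logging
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .classify import INDICATIONS, AgeGroup, IndicationMapping
from .conversion import (
    CFPerDAPEntry,
    CFPerDAPTable,
    CFPerMAsEntry,
    CFPerMAsTable,
)
from .model import (
    DeviceProfile,
    DoseAuditError,
    ExposureRecord,
    Protocol,
    QCMeasurement,
    Registry,
    RowError,
    SchemaError,
    UnknownDeviceError,
    build_registry,
)

logger = logging.getLogger(__name__)

#: Exposure-log column order; exactly the ExposureRecord fields.
EXPOSURE_COLUMNS = (
    "exam_id",
    "device_id",
    "acquired_on",
    "patient_age",
    "referral_department",
    "operation_mode_raw",
    "fov_diameter_cm",
    "fov_height_cm",
    "tube_voltage_kv",
    "total_exposure_mas",
    "recorded_dap_dgycm2",
)

QC_COLUMNS = ("device_id", "fov_label", "measured_dap_dgycm2", "recorded_dap_dgycm2")

REGISTRY_SCHEMA_VERSION = 1


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing mandatory column(s): {missing}")


def read_exposure_log(path: str | Path, registry: Registry) -> list[ExposureRecord]:
    """Read and validate an exposure log CSV against a device registry.

    Duplicate exam_ids are removed keeping the first occurrence; the number
    removed is logged.  Row-level failures carry the 1-based file line number
    (header is line 1).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, EXPOSURE_COLUMNS, f"exposure log {path}")
    records: list[ExposureRecord] = []
    seen: set[str] = set()
    n_duplicates = 0
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header occupies line 1
        exam_id = row["exam_id"].strip()
        if exam_id in seen:
            n_duplicates += 1
            continue
        device_id = row["device_id"].strip()
        if device_id not in registry:
            raise UnknownDeviceError(
                f"line {line}: unknown device_id {device_id!r}; known ids: {sorted(registry)}"
            )
        try:
            record = ExposureRecord(
                exam_id=exam_id,
                device_id=device_id,
                acquired_on=date.fromisoformat(row["acquired_on"].strip()),
                patient_age=int(row["patient_age"]),
                referral_department=row["referral_department"].strip(),
                operation_mode_raw=row["operation_mode_raw"].strip(),
                fov_diameter_cm=float(row["fov_diameter_cm"]),
                fov_height_cm=float(row["fov_height_cm"]),
                tube_voltage_kv=float(row["tube_voltage_kv"]),
                total_exposure_mas=float(row["total_exposure_mas"]),
                recorded_dap_dgycm2=float(row["recorded_dap_dgycm2"]),
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, DoseAuditError):
                raise RowError(str(exc), line=line) from exc
            raise RowError(f"unparseable cell ({exc})", line=line) from exc
        seen.add(exam_id)
        records.append(record)
    if n_duplicates:
        logger.info("removed %d duplicate exam_id(s) from %s", n_duplicates, path)
    return records


def write_exposure_log(records: Sequence[ExposureRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical column order."""
    frame = pd.DataFrame(
        [
            {
                "exam_id": r.exam_id,
                "device_id": r.device_id,
                "acquired_on": r.acquired_on.isoformat(),
                "patient_age": r.patient_age,
                "referral_department": r.referral_department,
                "operation_mode_raw": r.operation_mode_raw,
                "fov_diameter_cm": repr(r.fov_diameter_cm),
                "fov_height_cm": repr(r.fov_height_cm),
                "tube_voltage_kv": repr(r.tube_voltage_kv),
                "total_exposure_mas": repr(r.total_exposure_mas),
                "recorded_dap_dgycm2": repr(r.recorded_dap_dgycm2),
            }
            for r in records
        ],
        columns=list(EXPOSURE_COLUMNS),
    )
    frame.to_csv(path, index=False)


def read_qc_measurements(path: str | Path) -> list[QCMeasurement]:
    """Read a QC file of (measured, recorded) DAP pairs."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, QC_COLUMNS, f"QC file {path}")
    out = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        try:
            out.append(
                QCMeasurement(
                    device_id=row["device_id"].strip(),
                    fov_label=row["fov_label"].strip(),
                    measured_dap_dgycm2=float(row["measured_dap_dgycm2"]),
                    recorded_dap_dgycm2=float(row["recorded_dap_dgycm2"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise RowError(f"invalid QC measurement ({exc})", line=line) from exc
    return out


_PER_DAP_COLUMNS = {"device", "age_group", "cf_usv_per_dapcm2"}
_PER_MAS_COLUMNS = {"device", "indication", "age_years", "cf_usv_per_mas"}


def read_cf_table(path: str | Path) -> CFPerDAPTable | CFPerMAsTable:
    """Read a conversion-factor table, inferring its dialect from the columns.

    ``per_dap`` files carry (device, age_group, cf_usv_per_dapcm2) and must
    cover all four age groups for every device present; ``per_mas`` files
    carry (device, indication, age_years, cf_usv_per_mas).  A file matching
    both or neither schema is rejected.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = set(frame.columns)
    is_dap = _PER_DAP_COLUMNS <= cols
    is_mas = _PER_MAS_COLUMNS <= cols
    if is_dap and is_mas:
        raise SchemaError(f"CF table {path} mixes the per_dap and per_mas dialects")
    if not (is_dap or is_mas):
        raise SchemaError(
            f"CF table {path} matches neither dialect; per_dap needs "
            f"{sorted(_PER_DAP_COLUMNS)}, per_mas needs {sorted(_PER_MAS_COLUMNS)}"
        )
    if is_dap:
        entries_dap = []
        for idx, row in frame.iterrows():
            try:
                entries_dap.append(
                    CFPerDAPEntry(
                        device_id=row["device"].strip(),
                        age_group=AgeGroup(row["age_group"].strip()),
                        cf_usv_per_dapcm2=float(row["cf_usv_per_dapcm2"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise RowError(f"invalid per-DAP CF entry ({exc})", line=int(idx) + 2) from exc
        return CFPerDAPTable(entries_dap)
    entries_mas = []
    for idx, row in frame.iterrows():
        try:
            entries_mas.append(
                CFPerMAsEntry(
                    device_id=row["device"].strip(),
                    indication_region=row["indication"].strip(),
                    age_years=int(row["age_years"]),
                    cf_usv_per_mas=float(row["cf_usv_per_mas"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise RowError(f"invalid per-mAs CF entry ({exc})", line=int(idx) + 2) from exc
    return CFPerMAsTable(entries_mas)


def write_cf_table(table: CFPerDAPTable | CFPerMAsTable, path: str | Path) -> None:
    if isinstance(table, CFPerDAPTable):
        frame = pd.DataFrame(
            [
                {
                    "device": e.device_id,
                    "age_group": e.age_group.value,
                    "cf_usv_per_dapcm2": repr(e.cf_usv_per_dapcm2),
                }
                for e in table.entries
            ]
        )
    else:
        frame = pd.DataFrame(
            [
                {
                    "device": e.device_id,
                    "indication": e.indication_region,
                    "age_years": e.age_years,
                    "cf_usv_per_mas": repr(e.cf_usv_per_mas),
                }
                for e in table.entries
            ]
        )
    frame.to_csv(path, index=False)


def read_indication_fov_links(path: str | Path) -> list["IndicationFovLink"]:
    """Read the (device, indication region, FOV) link table.

    One row per (device, indication, fov); the ``fov`` column uses the
    ``DxH`` label form (e.g. ``10x10``).  Rows sharing (device, indication)
    accumulate into one link.
    """
    from .conversion import IndicationFovLink

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, ("device", "indication", "fov"), f"link table {path}")
    acc: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for idx, row in frame.iterrows():
        try:
            d, h = (float(x) for x in row["fov"].strip().lower().split("x"))
        except ValueError as exc:
            raise RowError(f"invalid fov label {row['fov']!r}", line=int(idx) + 2) from exc
        acc.setdefault((row["device"].strip(), row["indication"].strip()), []).append((d, h))
    return [
        IndicationFovLink(device_id=dev, indication_region=ind, fovs=tuple(fovs))
        for (dev, ind), fovs in acc.items()
    ]


def write_indication_fov_links(links, path: str | Path) -> None:
    rows = [
        {
            "device": link.device_id,
            "indication": link.indication_region,
            "fov": f"{d:g}x{h:g}",
        }
        for link in links
        for d, h in link.fovs
    ]
    pd.DataFrame(rows, columns=["device", "indication", "fov"]).to_csv(path, index=False)


def read_device_registry(path: str | Path) -> Registry:
    """Read the device registry from a versioned YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return registry_from_dict(doc, source=str(path))


def registry_from_dict(doc: dict, source: str = "<dict>") -> Registry:
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise SchemaError(f"device registry {source} lacks a schema_version field")
    if int(doc["schema_version"]) != REGISTRY_SCHEMA_VERSION:
        raise SchemaError(
            f"device registry {source}: unsupported schema_version "
            f"{doc['schema_version']} (expected {REGISTRY_SCHEMA_VERSION})"
        )
    profiles = []
    for dev in doc.get("devices", []):
        protocols = []
        for p in dev.get("protocols", []):
            mas = p["total_exposure_mas"]
            if isinstance(mas, (list, tuple)):
                mas = (float(mas[0]), float(mas[1]))
            else:
                mas = float(mas)
            d, h = (float(x) for x in str(p["fov"]).lower().split("x"))
            protocols.append(
                Protocol(
                    mode_raw=str(p["mode"]),
                    fov_diameter_cm=d,
                    fov_height_cm=h,
                    tube_voltage_kv=float(p["tube_voltage_kv"]),
                    total_exposure_mas=mas,
                    nominal_recorded_dap_dgycm2=float(p["nominal_recorded_dap_dgycm2"]),
                )
            )
        profiles.append(
            DeviceProfile(
                device_id=str(dev["device_id"]),
                display_name=str(dev.get("display_name", dev["device_id"])),
                tcm=bool(dev["tcm"]),
                dap_correction_factor=float(dev["dap_correction_factor"]),
                protocols=tuple(protocols),
            )
        )
    return build_registry(profiles)


def read_indication_mapping(
    path: str | Path, strict: bool = True, fallback: str | None = None
) -> IndicationMapping:
    """Read the two-column (department, indication) mapping CSV."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, ("department", "indication"), f"indication mapping {path}")
    table = {}
    for idx, row in frame.iterrows():
        ind = row["indication"].strip()
        if ind not in INDICATIONS:
            raise RowError(
                f"indication {ind!r} is outside the seven-category vocabulary",
                line=int(idx) + 2,
            )
        table[row["department"].strip()] = ind
    return IndicationMapping(table, strict=strict, fallback=fallback)
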