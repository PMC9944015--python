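"""Stratified summaries, frequency tables and headline ratios.

Produces the audit's reporting surfaces: the per-(device, age group, FOV
category, mode) dose table with 95% confidence intervals, frequency tables of
imaging requests by clinical indication, and the headline request/dose ratios.

Confidence intervals use the normal approximation mean ± 1.96 × SD/√n with the
sample (n−1) standard deviation, and are omitted for singleton strata.  The
choice is isolated in :func:`_ci95` so a t-based variant is a one-line swap.
Display rounding is 3 significant figures for doses and DAPs, 1 decimal for
percentages and ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classify import AGE_GROUPS, AgeGroup, FovCategory, OperationMode
from .conversion import CFPerDAPTable
from .dose import DoseResult, collective_dose
from .model import DeviceProfile, DoseAuditError
from .qc import apply_correction

Z95 = 1.96

#: Default stratification of the dose summary table.
DEFAULT_GROUPING = ("device_id", "age_group", "fov_category", "mode")


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention for doses)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


@dataclass(frozen=True)
class StratumSummary:
    """Counts, mean DAP/dose and 95% CIs for one stratum.

    ``freq_pct`` is the stratum share of its device's examinations; the CIs
    are ``None`` for singleton strata.
    """

    device_id: str
    age_group: AgeGroup | None
    fov_category: FovCategory | None
    mode: OperationMode | None
    n: int
    freq_pct: float | None
    mean_dap_dgycm2: float
    ci95_dap: tuple[float, float] | None
    mean_dose_usv: float
    ci95_dose: tuple[float, float] | None


def doses_to_frame(doses: Sequence[DoseResult]) -> pd.DataFrame:
    """Flatten dose results into a DataFrame for aggregation and CSV export."""
    rows = []
    for d in doses:
        r = d.record
        rows.append(
            {
                "exam_id": r.exam_id,
                "device_id": r.device_id,
                "acquired_on": r.acquired_on,
                "patient_age": r.patient_age,
                "referral_department": r.referral_department,
                "operation_mode_raw": r.operation_mode_raw,
                "fov_diameter_cm": r.fov_diameter_cm,
                "fov_height_cm": r.fov_height_cm,
                "tube_voltage_kv": r.tube_voltage_kv,
                "total_exposure_mas": r.total_exposure_mas,
                "recorded_dap_dgycm2": r.recorded_dap_dgycm2,
                "corrected_dap_dgycm2": d.corrected_dap_dgycm2,
                "age_group": d.age_group.value,
                "fov_category": d.fov_category.value,
                "mode": d.mode.value,
                "indication": d.indication,
                "effective_dose_usv": d.effective_dose_usv,
            }
        )
    return pd.DataFrame(rows)


def _ci95(values: pd.Series) -> tuple[float, float] | None:
    n = len(values)
    if n < 2:
        return None
    mean = values.mean()
    half = Z95 * values.std(ddof=1) / math.sqrt(n)
    return (mean - half, mean + half)


def summarize_strata(
    doses: Sequence[DoseResult],
    grouping: Sequence[str] = DEFAULT_GROUPING,
) -> list[StratumSummary]:
    """Per-stratum n, mean corrected DAP and dose, 95% CIs and frequency.

    ``grouping`` picks the stratification axes from
    {device_id, age_group, fov_category, mode, indication}; frequency
    percentages are relative to the device total.
    """
    if not doses:
        raise DoseAuditError("cannot summarize zero dose results")
    frame = doses_to_frame(doses)
    allowed = {"device_id", "age_group", "fov_category", "mode", "indication"}
    unknown = [g for g in grouping if g not in allowed]
    if unknown:
        raise DoseAuditError(f"unknown grouping field(s) {unknown}; allowed: {sorted(allowed)}")
    device_totals = frame.groupby("device_id").size()
    out: list[StratumSummary] = []
    for key, sub in frame.groupby(list(grouping), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        fields = dict(zip(grouping, key))
        device_id = fields.get("device_id", "")
        out.append(
            StratumSummary(
                device_id=device_id,
                age_group=AgeGroup(fields["age_group"]) if "age_group" in fields else None,
                fov_category=(
                    FovCategory(fields["fov_category"]) if "fov_category" in fields else None
                ),
                mode=OperationMode(fields["mode"]) if "mode" in fields else None,
                n=len(sub),
                freq_pct=(
                    100.0 * len(sub) / device_totals[device_id]
                    if device_id in device_totals.index
                    else None
                ),
                mean_dap_dgycm2=sub["corrected_dap_dgycm2"].mean(),
                ci95_dap=_ci95(sub["corrected_dap_dgycm2"]),
                mean_dose_usv=sub["effective_dose_usv"].mean(),
                ci95_dose=_ci95(sub["effective_dose_usv"]),
            )
        )
    return out


def protocol_dose_table(
    device: DeviceProfile,
    cf_table: CFPerDAPTable,
    correction_factor: float | None = None,
) -> list[StratumSummary]:
    """Protocol-level dose summary for a fixed-exposure (non-TCM) device.

    With no patient log, exposure is fixed per protocol, so the mean corrected
    DAP of each (FOV category, mode) cell is the unweighted mean over the
    protocols in that cell, and the mean dose is CF(age group) × mean DAP for
    each of the four age groups.  ``n`` counts protocols, not patients, and
    no CI or frequency applies.
    """
    from .classify import classify_fov, normalize_mode

    if device.tcm:
        raise DoseAuditError(
            f"device {device.device_id!r} applies TCM: protocol-level dose summaries "
            "need patient exposure data, use summarize_strata on a computed log"
        )
    k = correction_factor if correction_factor is not None else device.dap_correction_factor
    cells: dict[tuple[FovCategory, OperationMode], list[float]] = {}
    for p in device.protocols:
        cat = classify_fov(p.fov_diameter_cm, p.fov_height_cm)
        mode = normalize_mode(p.mode_raw, device)
        cells.setdefault((cat, mode), []).append(
            apply_correction(p.nominal_recorded_dap_dgycm2, k)
        )
    out: list[StratumSummary] = []
    for age_group in AGE_GROUPS:
        cf = cf_table.lookup(device.device_id, age_group)
        for (cat, mode), daps in sorted(cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
            mean_dap = sum(daps) / len(daps)
            out.append(
                StratumSummary(
                    device_id=device.device_id,
                    age_group=age_group,
                    fov_category=cat,
                    mode=mode,
                    n=len(daps),
                    freq_pct=None,
                    mean_dap_dgycm2=mean_dap,
                    ci95_dap=None,
                    mean_dose_usv=mean_dap * cf,
                    ci95_dose=None,
                )
            )
    return out


def find_stratum(
    strata: Sequence[StratumSummary],
    device_id: str | None = None,
    age_group: AgeGroup | None = None,
    fov_category: FovCategory | None = None,
    mode: OperationMode | None = None,
) -> StratumSummary:
    """Locate a unique stratum by its coordinates."""
    hits = [
        s
        for s in strata
        if (device_id is None or s.device_id == device_id)
        and (age_group is None or s.age_group == age_group)
        and (fov_category is None or s.fov_category == fov_category)
        and (mode is None or s.mode == mode)
    ]
    if len(hits) != 1:
        raise DoseAuditError(
            f"expected exactly one stratum for ({device_id}, {age_group}, "
            f"{fov_category}, {mode}), found {len(hits)}"
        )
    return hits[0]


def frequency_tables(doses: Sequence[DoseResult]) -> dict[str, pd.DataFrame]:
    """Request-frequency percentages by clinical indication.

    Returns crosstabs indication × {age group, FOV category, mode} with cell
    percentages relative to the combined grand total, plus
    ``indication_by_age_group_pct`` with columns normalized per age group
    (the per-age-group indication shares) and the marginal ``mode_pct`` /
    ``fov_category_pct`` shares.
    """
    if not doses:
        raise DoseAuditError("cannot tabulate zero dose results")
    frame = doses_to_frame(doses)
    total = len(frame)
    out: dict[str, pd.DataFrame] = {}
    for axis in ("age_group", "fov_category", "mode"):
        counts = pd.crosstab(frame["indication"], frame[axis])
        out[f"indication_by_{axis}"] = 100.0 * counts / total
    per_age = pd.crosstab(frame["indication"], frame["age_group"])
    out["indication_by_age_group_pct"] = 100.0 * per_age / per_age.sum(axis=0)
    out["mode_pct"] = (100.0 * frame["mode"].value_counts() / total).to_frame("freq_pct")
    out["fov_category_pct"] = (
        100.0 * frame["fov_category"].value_counts() / total
    ).to_frame("freq_pct")
    return out


def standard_hr_request_ratio(mode_freq_pct: Mapping[str, float]) -> float:
    """How many standard-mode requests per HR request, 1-decimal display."""
    std = mode_freq_pct[OperationMode.STANDARD.value]
    hr = mode_freq_pct[OperationMode.HR.value]
    if hr == 0:
        raise DoseAuditError("no HR requests: ratio undefined")
    return round(std / hr, 1)


def medium_large_request_ratio(fov_freq_pct: Mapping[str, float]) -> float:
    med = fov_freq_pct[FovCategory.MEDIUM.value]
    large = fov_freq_pct[FovCategory.LARGE.value]
    if large == 0:
        raise DoseAuditError("no large-FOV requests: ratio undefined")
    return round(med / large, 1)


def hr_standard_dose_ratio(
    strata: Sequence[StratumSummary],
    device_id: str,
    fov_category: FovCategory,
) -> float:
    """HR:standard mean-dose ratio for one device and FOV category.

    Averages the per-age-group ratios over age groups where both modes exist,
    rounded to 1 decimal.  (With age-group-independent protocols the per-age
    ratios coincide: the conversion factor cancels.)
    """
    ratios = []
    for ag in AGE_GROUPS:
        try:
            hr = find_stratum(strata, device_id, ag, fov_category, OperationMode.HR)
            std = find_stratum(strata, device_id, ag, fov_category, OperationMode.STANDARD)
        except DoseAuditError:
            continue
        if std.mean_dose_usv > 0:
            ratios.append(hr.mean_dose_usv / std.mean_dose_usv)
    if not ratios:
        raise DoseAuditError(
            f"no age group has both HR and standard strata for "
            f"({device_id}, {fov_category.value})"
        )
    return round(sum(ratios) / len(ratios), 1)


def headline_ratios(
    strata: Sequence[StratumSummary],
    mode_freq_pct: Mapping[str, float] | None = None,
    fov_freq_pct: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """The audit's headline ratios; missing strata are warned about and omitted.

    Emits the standard:HR request ratio and medium:large FOV request ratio
    (when the frequency shares are given), the per-device HR:standard dose
    ratio for every FOV category where both modes exist, and the cross-device
    standard-mode dose ratio over matching (age group, FOV category) strata.
    """
    out: dict[str, float] = {}
    if mode_freq_pct is not None:
        out["standard_hr_request_ratio"] = standard_hr_request_ratio(mode_freq_pct)
    if fov_freq_pct is not None:
        out["medium_large_request_ratio"] = medium_large_request_ratio(fov_freq_pct)
    devices = sorted({s.device_id for s in strata})
    for device_id in devices:
        for cat in FovCategory:
            try:
                out[f"hr_standard_dose_ratio:{device_id}:{cat.value}"] = hr_standard_dose_ratio(
                    strata, device_id, cat
                )
            except DoseAuditError:
                continue
    if len(devices) == 2:
        a, b = devices
        ratios = []
        for ag in AGE_GROUPS:
            for cat in FovCategory:
                try:
                    sa = find_stratum(strata, a, ag, cat, OperationMode.STANDARD)
                    sb = find_stratum(strata, b, ag, cat, OperationMode.STANDARD)
                except DoseAuditError:
                    continue
                if sb.mean_dose_usv > 0:
                    ratios.append(sa.mean_dose_usv / sb.mean_dose_usv)
        if ratios:
            out[f"standard_dose_ratio:{a}:{b}"] = round(sum(ratios) / len(ratios), 1)
        else:
            warnings.warn("no matching standard-mode strata across devices; ratio omitted")
    return out


def reconstruct_collective_dose_usv(strata: Sequence[StratumSummary]) -> float:
    """Σ over strata of n × mean dose, in µSv.

    For disjoint strata covering a cohort this reconstructs the cohort's
    collective dose × 10⁶ exactly.
    """
    return sum(s.n * s.mean_dose_usv for s in strata)


def strata_to_frame(strata: Sequence[StratumSummary]) -> pd.DataFrame:
    """Dose-summary table as a DataFrame with display-rounded companion columns."""
    rows = []
    for s in strata:
        rows.append(
            {
                "device_id": s.device_id,
                "age_group": s.age_group.value if s.age_group else None,
                "fov_category": s.fov_category.value if s.fov_category else None,
                "mode": s.mode.value if s.mode else None,
                "n": s.n,
                "freq_pct": round(s.freq_pct, 1) if s.freq_pct is not None else None,
                "mean_dap_dgycm2": s.mean_dap_dgycm2,
                "mean_dap_display": round_sig(s.mean_dap_dgycm2),
                "ci95_dap_lo": s.ci95_dap[0] if s.ci95_dap else None,
                "ci95_dap_hi": s.ci95_dap[1] if s.ci95_dap else None,
                "mean_dose_usv": s.mean_dose_usv,
                "mean_dose_display": round_sig(s.mean_dose_usv),
                "ci95_dose_lo": s.ci95_dose[0] if s.ci95_dose else None,
                "ci95_dose_hi": s.ci95_dose[1] if s.ci95_dose else None,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "StratumSummary",
    "summarize_strata",
    "protocol_dose_table",
    "find_stratum",
    "frequency_tables",
    "headline_ratios",
    "standard_hr_request_ratio",
    "medium_large_request_ratio",
    "hr_standard_dose_ratio",
    "reconstruct_collective_dose_usv",
    "doses_to_frame",
    "strata_to_frame",
    "round_sig",
    "collective_dose",
]
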