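"""Synthetic exposure logs, QC campaigns and per-mAs CF tables.

Patient-level CBCT exposure data are protected and never published, so every
pipeline stage is exercised on synthetic cohorts with the statistical
structure the analysis assumes:

* a fixed-exposure (non-TCM) scanner emits exactly its protocol's mAs and
  nominal recorded DAP for every exam;
* a TCM scanner draws the recorded DAP of each exam from a log-normal
  distribution per stratum — positive and right-skewed, as expected under
  patient-size-driven tube-current modulation — and an mAs uniform within
  the protocol's modulation range.

All randomness flows through a single :class:`numpy.random.Generator` built
from one integer seed; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .classify import AGE_GROUP_AGES, AGE_GROUPS, AgeGroup, INDICATIONS
from .conversion import CFPerMAsEntry, CFPerMAsTable, CFPerDAPTable, IndicationFovLink
from .model import DeviceProfile, DoseAuditError, ExposureRecord, QCMeasurement
from .qc import apply_correction

#: Canonical referral department emitting each clinical indication.
DEPARTMENT_FOR_INDICATION: dict[str, str] = {
    "endodontics": "endodontics clinic",
    "orthodontic planning": "orthodontics clinic",
    "pedodontics": "pedodontics clinic",
    "implant placement": "implantology clinic",
    "surgical planning and follow-up": "maxillofacial surgery",
    "second opinion radiodiagnosis": "oral radiology",
    "medically compromised patient care": "special dental care",
}

_PROB_TOL = 1e-6


@dataclass(frozen=True)
class DapModel:
    """Log-normal recorded-DAP model with a target mean and coefficient of variation."""

    mean: float
    cv: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise DoseAuditError(f"DAP model mean must be positive, got {self.mean}")
        if self.cv < 0:
            raise DoseAuditError(f"DAP model CV must be non-negative, got {self.cv}")

    def draw(self, rng: np.random.Generator, size: int | None = None):
        if self.cv == 0:
            return self.mean if size is None else np.full(size, self.mean)
        sigma2 = math.log1p(self.cv**2)
        mu = math.log(self.mean) - sigma2 / 2
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _check_probs(probs: Sequence[float], what: str) -> None:
    if any(p < 0 for p in probs):
        raise DoseAuditError(f"{what}: negative probability")
    if abs(sum(probs) - 1.0) > _PROB_TOL:
        raise DoseAuditError(f"{what}: probabilities sum to {sum(probs)}, not 1")


@dataclass(frozen=True)
class CohortSpec:
    """Statistical recipe for one device's synthetic exposure log.

    ``fov_mode_mix`` assigns (FOV label, raw mode) probabilities per
    (age group, indication); the indication slot ``"*"`` is the age-group-wide
    fallback.  ``tcm_dap_model`` maps (age group or None, FOV label, raw mode)
    to a :class:`DapModel`; the ``None`` age slot is the FOV-wide fallback.
    Non-TCM devices ignore ``tcm_dap_model`` entirely.
    """

    device_id: str
    n_exams: int
    age_mix: Mapping[AgeGroup, float]
    indication_mix: Mapping[AgeGroup, Mapping[str, float]]
    fov_mode_mix: Mapping[tuple[AgeGroup, str], Sequence[tuple[tuple[str, str], float]]]
    tcm_dap_model: Mapping[tuple[AgeGroup | None, str, str], DapModel] = field(
        default_factory=dict
    )
    year: int = 2019

    def __post_init__(self) -> None:
        if self.n_exams < 0:
            raise DoseAuditError("n_exams must be non-negative")
        _check_probs([self.age_mix.get(g, 0.0) for g in AGE_GROUPS], "age mix")
        for g, mix in self.indication_mix.items():
            unknown = set(mix) - set(INDICATIONS)
            if unknown:
                raise DoseAuditError(f"indication mix for {g.value}: unknown {sorted(unknown)}")
            _check_probs(list(mix.values()), f"indication mix for {g.value}")
        for key, pairs in self.fov_mode_mix.items():
            _check_probs([p for _, p in pairs], f"FOV/mode mix for {key}")

    def fov_mode_pairs(
        self, age_group: AgeGroup, indication: str
    ) -> Sequence[tuple[tuple[str, str], float]]:
        for key in ((age_group, indication), (age_group, "*")):
            if key in self.fov_mode_mix:
                return self.fov_mode_mix[key]
        raise DoseAuditError(
            f"no FOV/mode assignment for age group {age_group.value!r}, "
            f"indication {indication!r} (and no '*' fallback)"
        )

    def dap_model(self, age_group: AgeGroup, fov_label: str, mode_raw: str) -> DapModel:
        for key in ((age_group, fov_label, mode_raw), (None, fov_label, mode_raw)):
            if key in self.tcm_dap_model:
                return self.tcm_dap_model[key]
        raise DoseAuditError(
            f"no TCM DAP model for ({age_group.value}, {fov_label}, {mode_raw})"
        )


def _normalized(weights: dict) -> dict:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def synthesize_cohort(
    spec: CohortSpec,
    device: DeviceProfile,
    seed: int | np.random.Generator,
) -> list[ExposureRecord]:
    """Draw a reproducible exposure log for one device.

    Non-TCM exams carry exactly the protocol's fixed mAs and nominal recorded
    DAP; TCM exams draw the DAP from the stratum's log-normal model and an
    mAs uniform within the protocol's modulation range.
    """
    if spec.device_id != device.device_id:
        raise DoseAuditError(
            f"spec is for {spec.device_id!r} but device is {device.device_id!r}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = list(AGE_GROUPS)
    group_p = np.array([spec.age_mix.get(g, 0.0) for g in groups])
    records: list[ExposureRecord] = []
    start = date(spec.year, 1, 1)
    for i in range(spec.n_exams):
        group = groups[rng.choice(len(groups), p=group_p)]
        ages = AGE_GROUP_AGES[group]
        if group is AgeGroup.Y15_PLUS:
            age = int(rng.integers(15, 80))
        else:
            age = int(rng.choice(ages))
        mix = spec.indication_mix[group]
        inds = list(mix)
        indication = inds[rng.choice(len(inds), p=np.array([mix[k] for k in inds]))]
        pairs = spec.fov_mode_pairs(group, indication)
        (fov_label, mode_raw) = pairs[rng.choice(len(pairs), p=np.array([p for _, p in pairs]))][0]
        protocol = device.protocol(mode_raw, fov_label)
        if device.tcm:
            model = spec.dap_model(group, fov_label, mode_raw)
            dap = float(model.draw(rng))
            lo, hi = protocol.total_exposure_mas  # type: ignore[misc]
            mas = float(rng.uniform(lo, hi))
        else:
            dap = protocol.nominal_recorded_dap_dgycm2
            mas = protocol.fixed_mas
        records.append(
            ExposureRecord(
                exam_id=f"{device.device_id}-{i:05d}",
                device_id=device.device_id,
                acquired_on=start + timedelta(days=int(rng.integers(0, 365))),
                patient_age=age,
                referral_department=DEPARTMENT_FOR_INDICATION[indication],
                operation_mode_raw=protocol.mode_raw,
                fov_diameter_cm=protocol.fov_diameter_cm,
                fov_height_cm=protocol.fov_height_cm,
                tube_voltage_kv=protocol.tube_voltage_kv,
                total_exposure_mas=mas,
                recorded_dap_dgycm2=dap,
            )
        )
    return records


def synthesize_qc(
    device: DeviceProfile,
    true_factor: float,
    noise_cv: float,
    n: int,
    seed: int | np.random.Generator,
) -> list[QCMeasurement]:
    """Emulate QC campaigns: measured = recorded × factor × multiplicative noise.

    Recorded DAPs cycle through a small, medium and large standard-mode
    protocol of the device, mirroring the annual three-FOV campaign.  The
    mean measured/recorded ratio recovers ``true_factor`` within about
    3 × CV/√n.
    """
    if true_factor <= 0:
        raise DoseAuditError("true_factor must be positive")
    if noise_cv < 0:
        raise DoseAuditError("noise_cv must be non-negative")
    if n < 1:
        raise DoseAuditError("need at least one QC measurement")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    standard = sorted(
        (p for p in device.protocols if p.mode_raw.strip().lower() in ("standard", "regular scan")),
        key=lambda p: p.fov_area_cm2,
    )
    if not standard:
        raise DoseAuditError(f"device {device.device_id!r} has no standard-mode protocols")
    picks = [standard[0], standard[len(standard) // 2], standard[-1]]
    noise = DapModel(mean=1.0, cv=noise_cv)
    out = []
    for i in range(n):
        p = picks[i % len(picks)]
        recorded = p.nominal_recorded_dap_dgycm2
        out.append(
            QCMeasurement(
                device_id=device.device_id,
                fov_label=p.fov_label,
                measured_dap_dgycm2=recorded * true_factor * float(noise.draw(rng)),
                recorded_dap_dgycm2=recorded,
            )
        )
    return out


def synthesize_cf_per_mas(
    device: DeviceProfile,
    target: CFPerDAPTable,
    spread: float = 0.1,
) -> tuple[CFPerMAsTable, list[IndicationFovLink]]:
    """Synthetic scanned-region per-mAs CF table consistent with a per-DAP target.

    Each FOV of the catalog gets its own synthetic indication region linked
    1:1, and per-age factors spread symmetrically (mean-preserving, relative
    half-width ``spread``) around the closed-form value
    CF_dap × corrected DAP / mAs, so averaging over the ages of a group and
    deriving a per-DAP factor reproduces ``target`` exactly on a
    fixed-exposure device.  Ages span the 5–15 y range of published
    Monte-Carlo factors.
    """
    if device.tcm:
        raise DoseAuditError("closed-form synthesis is defined for fixed-exposure devices")
    entries: list[CFPerMAsEntry] = []
    links: list[IndicationFovLink] = []
    by_fov: dict[str, list] = {}
    for p in device.protocols:
        by_fov.setdefault(p.fov_label, []).append(p)
    for fov_label, protocols in by_fov.items():
        p0 = protocols[0]
        region = f"region_{fov_label}"
        links.append(
            IndicationFovLink(
                device_id=device.device_id,
                indication_region=region,
                fovs=((p0.fov_diameter_cm, p0.fov_height_cm),),
            )
        )
        # an FOV shared by several modes sees different mAs-per-DAP ratios;
        # normalizing by their mean keeps the catalog-wide derivation exact
        mean_mas_per_dap = sum(
            p.fixed_mas / apply_correction(p.nominal_recorded_dap_dgycm2, device.dap_correction_factor)
            for p in protocols
        ) / len(protocols)
        for group in AGE_GROUPS:
            ages = [a for a in AGE_GROUP_AGES[group] if 5 <= a <= 15]
            base = target.lookup(device.device_id, group) / mean_mas_per_dap
            k = len(ages)
            for j, age in enumerate(ages):
                offset = 0.0 if k == 1 else spread * (2 * j - (k - 1)) / (k - 1)
                entries.append(
                    CFPerMAsEntry(
                        device_id=device.device_id,
                        indication_region=region,
                        age_years=age,
                        cf_usv_per_mas=base * (1 + offset),
                    )
                )
    return CFPerMAsTable(entries), links


# --------------------------------------------------------------------------
# Default cohort specifications: the study conditions of the audited center.
# --------------------------------------------------------------------------

#: Default coefficient of variation of the TCM recorded DAP within a stratum,
#: calibrated so synthetic stratum CI widths are of the order of the audit's.
DEFAULT_TCM_DAP_CV = 0.25

#: Concrete FOV drawn for each (category, normalized mode) on the TCM device:
#: the modal FOV of each category in the audited workload.
_NEWTOM_FOV_FOR = {
    ("small", "standard"): ("5x5", "Regular scan"),
    ("small", "HR"): ("5x5", "High-Resolution"),
    ("medium", "standard"): ("10x10", "Regular scan"),
    ("medium", "HR"): ("10x10", "High-Resolution"),
    ("large", "standard"): ("24x19", "Regular scan"),
}

_AGE_GROUP_BY_VALUE = {g.value: g for g in AGE_GROUPS}

#: Indication shares per age group: children skew to pedodontics/orthodontics,
#: adults to surgical planning and implants, approximating the audited center.
_DEFAULT_INDICATION_MIX: dict[AgeGroup, dict[str, float]] = {
    AgeGroup.Y4_6: {
        "surgical planning and follow-up": 0.45,
        "pedodontics": 0.30,
        "orthodontic planning": 0.10,
        "second opinion radiodiagnosis": 0.10,
        "endodontics": 0.02,
        "implant placement": 0.01,
        "medically compromised patient care": 0.02,
    },
    AgeGroup.Y7_11: {
        "surgical planning and follow-up": 0.45,
        "pedodontics": 0.30,
        "orthodontic planning": 0.10,
        "second opinion radiodiagnosis": 0.10,
        "endodontics": 0.02,
        "implant placement": 0.01,
        "medically compromised patient care": 0.02,
    },
    AgeGroup.Y12_14: {
        "surgical planning and follow-up": 0.40,
        "pedodontics": 0.25,
        "orthodontic planning": 0.15,
        "second opinion radiodiagnosis": 0.12,
        "endodontics": 0.04,
        "implant placement": 0.02,
        "medically compromised patient care": 0.02,
    },
    AgeGroup.Y15_PLUS: {
        "surgical planning and follow-up": 0.66,
        "implant placement": 0.09,
        "second opinion radiodiagnosis": 0.09,
        "pedodontics": 0.10,
        "endodontics": 0.03,
        "orthodontic planning": 0.01,
        "medically compromised patient care": 0.02,
    },
}


def default_newtom_spec(
    n_exams: int | None = None, dap_cv: float = DEFAULT_TCM_DAP_CV
) -> CohortSpec:
    """Default TCM-device cohort: the audited Newtom workload shape.

    Age-group and (FOV category, mode) shares and per-stratum target mean
    DAPs come from the published stratum summary (4967 exams); the
    within-stratum dispersion is the calibrated log-normal CV.
    """
    from .defaults import NEWTOM, newtom_reported_strata

    ref = newtom_reported_strata()
    total = int(ref["n"].sum())
    age_mix = {
        _AGE_GROUP_BY_VALUE[g]: n / total for g, n in ref.groupby("age_group")["n"].sum().items()
    }
    fov_mode_mix: dict[tuple[AgeGroup, str], tuple] = {}
    dap_model: dict[tuple[AgeGroup | None, str, str], DapModel] = {}
    for g_value, sub in ref.groupby("age_group"):
        group = _AGE_GROUP_BY_VALUE[g_value]
        weights = {}
        for _, row in sub.iterrows():
            fov_label, mode_raw = _NEWTOM_FOV_FOR[(row["fov_category"], row["mode"])]
            weights[(fov_label, mode_raw)] = row["n"]
            dap_model[(group, fov_label, mode_raw)] = DapModel(
                mean=float(row["mean_corrected_dap_dgycm2"]), cv=dap_cv
            )
        fov_mode_mix[(group, "*")] = tuple(_normalized(weights).items())
    return CohortSpec(
        device_id=NEWTOM,
        n_exams=total if n_exams is None else n_exams,
        age_mix=age_mix,
        indication_mix=_DEFAULT_INDICATION_MIX,
        fov_mode_mix=fov_mode_mix,
        tcm_dap_model=dap_model,
    )


#: Fixed-exposure device workload: mostly adult standard-mode exams; the HR
#: (High-Fidelity) protocols exist only for large FOVs and serve second-opinion
#: reads, so they are a small share.  Weights are normalized at build time.
_ACCUITOMO_FOV_MODE_WEIGHTS = {
    ("4x4", "Standard"): 4,
    ("6x6", "Standard"): 6,
    ("10x5", "Standard"): 19,
    ("8x8", "Standard"): 38,
    ("10x10", "Standard"): 48,
    ("14x10", "Standard"): 35,
    ("17x12", "Standard"): 38,
    ("14x10", "High-Fidelity"): 4,
    ("17x12", "High-Fidelity"): 4,
}


def default_accuitomo_spec(n_exams: int | None = None) -> CohortSpec:
    """Default fixed-exposure-device cohort (196 exams, standard:HR ≈ 188:8)."""
    from .defaults import ACCUITOMO, COHORT_SIZES, newtom_reported_strata

    ref = newtom_reported_strata()
    total = int(ref["n"].sum())
    age_mix = {
        _AGE_GROUP_BY_VALUE[g]: n / total for g, n in ref.groupby("age_group")["n"].sum().items()
    }
    pairs = tuple(_normalized(dict(_ACCUITOMO_FOV_MODE_WEIGHTS)).items())
    return CohortSpec(
        device_id=ACCUITOMO,
        n_exams=COHORT_SIZES[ACCUITOMO] if n_exams is None else n_exams,
        age_mix=age_mix,
        indication_mix=_DEFAULT_INDICATION_MIX,
        fov_mode_mix={(g, "*"): pairs for g in AGE_GROUPS},
    )
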