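"""QC-based DAP correction.

Device-displayed DAP values on dental CBCT systems are frequently inaccurate;
annual quality-control campaigns measure the true DAP with a calibrated meter
for a small, medium and large FOV.  The per-device correction factor k is the
arithmetic mean of the measured/recorded ratios over all pooled QC pairs, and
every recorded DAP is multiplied by k before any dose arithmetic.  Corrections
are carried at full precision; rounding is a reporting concern only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import DoseAuditError, QCMeasurement

#: Ratios deviating from the mean by more than this fraction are flagged.
DEVIATION_FLAG_THRESHOLD = 0.05


@dataclass(frozen=True)
class CorrectionFactorResult:
    """Outcome of deriving a DAP correction factor for one device.

    ``factor`` (symbol k, dimensionless) is the mean measured/recorded ratio;
    ``max_relative_deviation`` is max |ratio − k| / k over the QC pairs.
    The deviation flag is a warning, not a hard failure.
    """

    device_id: str
    factor: float
    per_measurement_ratios: tuple[float, ...]
    max_relative_deviation: float
    deviation_flagged: bool


def derive_correction_factor(measurements: Sequence[QCMeasurement]) -> CorrectionFactorResult:
    """Derive k as the mean of measured/recorded DAP ratios for one device.

    All measurement pairs are pooled across campaigns and FOVs with equal
    weight.  Raises on an empty list, on a non-positive recorded DAP, or if
    the pairs span multiple devices.
    """
    if not measurements:
        raise DoseAuditError("cannot derive a correction factor from zero QC measurements")
    device_ids = {m.device_id for m in measurements}
    if len(device_ids) != 1:
        raise DoseAuditError(
            f"QC measurements span multiple devices: {sorted(device_ids)}"
        )
    for m in measurements:
        if m.recorded_dap_dgycm2 <= 0:
            raise DoseAuditError(
                f"QC measurement ({m.device_id}, {m.fov_label}): recorded DAP must be > 0"
            )
    ratios = tuple(m.measured_dap_dgycm2 / m.recorded_dap_dgycm2 for m in measurements)
    factor = sum(ratios) / len(ratios)
    max_dev = max(abs(r - factor) for r in ratios) / factor
    return CorrectionFactorResult(
        device_id=device_ids.pop(),
        factor=factor,
        per_measurement_ratios=ratios,
        max_relative_deviation=max_dev,
        deviation_flagged=max_dev > DEVIATION_FLAG_THRESHOLD,
    )


def apply_correction(recorded_dap_dgycm2: float, factor: float) -> float:
    """Corrected DAP = recorded DAP × k, at full precision (dGy·cm²)."""
    if recorded_dap_dgycm2 < 0:
        raise DoseAuditError(f"recorded DAP must be non-negative, got {recorded_dap_dgycm2}")
    if factor <= 0:
        raise DoseAuditError(f"correction factor must be positive, got {factor}")
    return recorded_dap_dgycm2 * factor
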