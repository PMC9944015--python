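"""Effective-dose engine: per-exam dose, rejects routing, collective dose."""

import pytest

from cbctdose import (
    DoseAuditError,
    collective_dose,
    compute_doses,
    effective_dose,
    round_sig,
)
from cbctdose.classify import AgeGroup, FovCategory, OperationMode

from conftest import make_record


class TestEffectiveDose:
    def test_worked_small_fov_group_mean(self):
        """Corrected small-FOV group mean DAP × adult CF gives the floor dose."""
        mean_corrected = (4.02 * 0.76 + 8.23 * 0.76) / 2
        assert mean_corrected == pytest.approx(4.655)
        assert round_sig(effective_dose(mean_corrected, 7.55)) == 35.1

    def test_worked_tcm_cell(self):
        assert round_sig(effective_dose(6.09, 19.2)) == 117

    def test_zero_dap_gives_zero_dose(self):
        assert effective_dose(0.0, 19.2) == 0.0

    def test_negative_dap_rejected(self):
        with pytest.raises(DoseAuditError):
            effective_dose(-1.0, 19.2)

    def test_dose_scales_linearly_with_correction_factor(self):
        assert effective_dose(10.0 * 0.76, 7.55) == pytest.approx(
            0.76 * effective_dose(10.0, 7.55)
        )


class TestComputeDoses:
    def test_empty_input(self, registry, cf_table, indication_mapping):
        results, rejects = compute_doses([], registry, cf_table, indication_mapping)
        assert results == [] and rejects == []

    def test_closed_form_per_record(self, registry, cf_table, indication_mapping):
        records = [
            make_record(exam_id="a"),  # Standard 4x4, recorded 4.02
            make_record(exam_id="b", fov_diameter_cm=17.0, fov_height_cm=12.0,
                        recorded_dap_dgycm2=25.6),
        ]
        results, rejects = compute_doses(records, registry, cf_table, indication_mapping)
        assert not rejects
        by_id = {r.record.exam_id: r for r in results}
        assert by_id["a"].effective_dose_usv == pytest.approx(4.02 * 0.76 * 7.55)
        assert by_id["b"].effective_dose_usv == pytest.approx(25.6 * 0.76 * 7.55)
        assert by_id["a"].fov_category is FovCategory.SMALL
        assert by_id["b"].fov_category is FovCategory.LARGE
        assert by_id["a"].mode is OperationMode.STANDARD
        assert by_id["a"].age_group is AgeGroup.Y15_PLUS
        assert by_id["a"].indication == "surgical planning and follow-up"

    def test_underage_record_routed_to_rejects(self, registry, cf_table, indication_mapping):
        records = [make_record(exam_id="ok"), make_record(exam_id="young", patient_age=3)]
        results, rejects = compute_doses(records, registry, cf_table, indication_mapping)
        assert len(results) == 1 and len(rejects) == 1
        assert rejects[0].record.exam_id == "young"
        assert "4-6" in rejects[0].reason

    def test_missing_cf_coverage_is_an_error(self, registry, indication_mapping):
        from cbctdose.conversion import CFPerDAPEntry, CFPerDAPTable

        other_device_only = CFPerDAPTable(
            [CFPerDAPEntry("newtom_vgi_evo", g, v) for g, v in
             zip(AgeGroup, (19.2, 12.9, 9.15, 7.96))]
        )
        with pytest.raises(DoseAuditError, match="accuitomo170"):
            compute_doses([make_record()], registry, other_device_only, indication_mapping)

    def test_identical_protocol_and_age_group_get_identical_doses(
        self, registry, cf_table, indication_mapping
    ):
        records = [
            make_record(exam_id=f"r{i}", patient_age=age) for i, age in enumerate((20, 40, 75))
        ]
        results, _ = compute_doses(records, registry, cf_table, indication_mapping)
        doses = {r.effective_dose_usv for r in results}
        assert len(doses) == 1


class TestCollectiveDose:
    def test_empty(self):
        assert collective_dose([]) == 0.0

    def test_hand_sum(self, registry, cf_table, indication_mapping):
        records = [
            make_record(exam_id="a", recorded_dap_dgycm2=50 / (0.76 * 7.55)),
            make_record(exam_id="b", recorded_dap_dgycm2=100 / (0.76 * 7.55)),
        ]
        results, _ = compute_doses(records, registry, cf_table, indication_mapping)
        assert collective_dose(results) == pytest.approx(1.5e-4)

    def test_additivity_over_concatenation(self, registry, cf_table, indication_mapping):
        part1 = [make_record(exam_id=f"a{i}", recorded_dap_dgycm2=i + 1.0) for i in range(3)]
        part2 = [make_record(exam_id=f"b{i}", recorded_dap_dgycm2=2 * i + 0.5) for i in range(4)]
        d1, _ = compute_doses(part1, registry, cf_table, indication_mapping)
        d2, _ = compute_doses(part2, registry, cf_table, indication_mapping)
        dall, _ = compute_doses(part1 + part2, registry, cf_table, indication_mapping)
        assert collective_dose(dall) == pytest.approx(collective_dose(d1) + collective_dose(d2))
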