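"""Per-mAs → per-DAP conversion-factor derivation and validation."""

import pytest

from cbctdose import (
    AgeGroup,
    CFPerMAsTable,
    DeviceProfile,
    DoseAuditError,
    IndicationFovLink,
    Protocol,
    average_cf_per_fov,
    derive_cf_per_dap,
    per_fov_cf_table,
    validate_cf,
)
from cbctdose.conversion import CFPerDAPEntry, CFPerMAsEntry

from conftest import make_record


def entry(ind, age, cf, device="d"):
    return CFPerMAsEntry(device, ind, age, cf)


def link(ind, *fovs, device="d"):
    return IndicationFovLink(device, ind, tuple(fovs))


def single_protocol_device(mas=87.5, dap=4.02, k=0.76, fov=(4.0, 4.0)):
    return DeviceProfile(
        device_id="d",
        display_name="d",
        tcm=False,
        dap_correction_factor=k,
        protocols=(
            Protocol("Standard", fov[0], fov[1], 90.0, mas, dap),
        ),
    )


class TestAverageCfPerFov:
    def test_single_entry_unchanged(self):
        table = CFPerMAsTable([entry("single tooth", 5, 0.42)])
        links = [link("single tooth", (4, 4))]
        assert average_cf_per_fov(table, links, "d", (4, 4), AgeGroup.Y4_6) == 0.42

    def test_two_indications_average(self):
        table = CFPerMAsTable(
            [entry("single tooth", 5, 0.4), entry("upper jaw", 5, 0.6)]
        )
        links = [link("single tooth", (4, 4)), link("upper jaw", (4, 4))]
        assert average_cf_per_fov(table, links, "d", (4, 4), AgeGroup.Y4_6) == pytest.approx(0.5)

    def test_three_ages_average_within_group(self):
        table = CFPerMAsTable(
            [entry("jaw", 7, 0.3), entry("jaw", 8, 0.3), entry("jaw", 9, 0.6)]
        )
        links = [link("jaw", (6, 6))]
        assert average_cf_per_fov(table, links, "d", (6, 6), AgeGroup.Y7_11) == pytest.approx(0.4)

    def test_unlinked_fov_rejected(self):
        table = CFPerMAsTable([entry("jaw", 7, 0.3)])
        with pytest.raises(DoseAuditError, match="no per-mAs CF entries"):
            average_cf_per_fov(table, [link("jaw", (6, 6))], "d", (10, 10), AgeGroup.Y7_11)


class TestDeriveCfPerDap:
    def test_single_protocol_closed_form(self):
        """One FOV, one indication: CF_dap = cf_mas × mAs / corrected DAP."""
        device = single_protocol_device()
        per_fov = {(4.0, 4.0): 0.4}
        result = derive_cf_per_dap(per_fov, device, AgeGroup.Y4_6)
        assert result.cf_usv_per_dapcm2 == pytest.approx(0.4 * 87.5 / 3.0552)
        assert result.cf_usv_per_dapcm2 == pytest.approx(11.46, abs=5e-3)

    def test_common_scaling_leaves_ratio_invariant(self):
        base = single_protocol_device()
        scaled = single_protocol_device(mas=87.5 * 3, dap=4.02 * 3)
        per_fov = {(4.0, 4.0): 0.4}
        assert derive_cf_per_dap(per_fov, base, AgeGroup.Y4_6).cf_usv_per_dapcm2 == pytest.approx(
            derive_cf_per_dap(per_fov, scaled, AgeGroup.Y4_6).cf_usv_per_dapcm2
        )

    def test_tcm_device_requires_samples(self, newtom):
        with pytest.raises(DoseAuditError, match="patient exposure samples"):
            derive_cf_per_dap({}, newtom, AgeGroup.Y15_PLUS, exposure_samples=[])

    def test_tcm_per_exam_mean_and_permutation_invariance(self, newtom):
        recs = [
            make_record(exam_id=f"n{i}", device_id="newtom_vgi_evo",
                        operation_mode_raw="Regular scan",
                        fov_diameter_cm=10.0, fov_height_cm=10.0,
                        tube_voltage_kv=110.0, total_exposure_mas=mas,
                        recorded_dap_dgycm2=dap)
            for i, (mas, dap) in enumerate([(20.0, 3.0), (30.0, 4.0), (25.0, 3.5)])
        ]
        per_fov = {(10.0, 10.0): 0.9}
        expected = (0.9 * 20 / 3 + 0.9 * 30 / 4 + 0.9 * 25 / 3.5) / 3
        forward = derive_cf_per_dap(per_fov, newtom, AgeGroup.Y15_PLUS, recs)
        backward = derive_cf_per_dap(per_fov, newtom, AgeGroup.Y15_PLUS, recs[::-1])
        assert forward.cf_usv_per_dapcm2 == pytest.approx(expected)
        assert backward.cf_usv_per_dapcm2 == pytest.approx(forward.cf_usv_per_dapcm2)

    def test_synthetic_per_mas_table_round_trips_to_target(self, accuitomo, cf_table):
        """Full derivation chain reproduces the shipped per-DAP factors exactly."""
        from cbctdose import synthesize_cf_per_mas

        cf_mas, links = synthesize_cf_per_mas(accuitomo, cf_table, spread=0.1)
        for group in AgeGroup:
            per_fov = per_fov_cf_table(cf_mas, links, accuitomo, group)
            derived = derive_cf_per_dap(per_fov, accuitomo, group)
            assert derived.cf_usv_per_dapcm2 == pytest.approx(
                cf_table.lookup("accuitomo170", group), rel=1e-12
            )


class TestValidateCf:
    def test_identical_doses_zero_deviation(self):
        cf = CFPerDAPEntry("d", AgeGroup.Y4_6, 10.0)
        stats = validate_cf([1.0, 2.0], [10.0, 20.0], cf)
        assert stats.mean_relative_deviation == 0.0
        assert stats.fraction_within_20pct == 1.0

    def test_known_deviation_set(self):
        cf = CFPerDAPEntry("d", AgeGroup.Y4_6, 1.0)
        # E_dap = corrected DAP; e_mas chosen so deviations are .1,.1,.3,.5
        daps = [1.1, 1.1, 1.3, 1.5]
        e_mas = [1.0, 1.0, 1.0, 1.0]
        stats = validate_cf(daps, e_mas, cf)
        assert stats.mean_relative_deviation == pytest.approx(0.25)
        assert stats.fraction_within_20pct == pytest.approx(0.5)
        assert stats.n == 4

    def test_within_20pct_is_inclusive(self):
        cf = CFPerDAPEntry("d", AgeGroup.Y4_6, 1.0)
        assert validate_cf([1.19], [1.0], cf).fraction_within_20pct == 1.0
        assert validate_cf([1.20], [1.0], cf).fraction_within_20pct == 1.0
        assert validate_cf([1.21], [1.0], cf).fraction_within_20pct == 0.0

    def test_zero_reference_dose_rejected(self):
        cf = CFPerDAPEntry("d", AgeGroup.Y4_6, 1.0)
        with pytest.raises(DoseAuditError, match="zero"):
            validate_cf([1.0], [0.0], cf)


def test_per_mas_age_range_enforced():
    with pytest.raises(DoseAuditError, match="5-15"):
        CFPerMAsEntry("d", "jaw", 4, 0.4)
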