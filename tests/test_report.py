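"""Stratified summaries, frequency tables and headline ratios."""

import math

import pytest

from cbctdose import (
    DoseAuditError,
    compute_doses,
    collective_dose,
    find_stratum,
    frequency_tables,
    headline_ratios,
    hr_standard_dose_ratio,
    protocol_dose_table,
    reconstruct_collective_dose_usv,
    round_sig,
    summarize_strata,
)
from cbctdose.classify import AgeGroup, FovCategory, OperationMode
from cbctdose.report import standard_hr_request_ratio

from conftest import make_record


def doses_from_daps(registry, cf_table, indication_mapping, daps, **overrides):
    # recorded DAP chosen so corrected DAP × CF equals the requested dose value
    k, cf = 0.76, 7.55
    records = [
        make_record(exam_id=f"r{i}", recorded_dap_dgycm2=v / (k * cf), **overrides)
        for i, v in enumerate(daps)
    ]
    results, _ = compute_doses(records, registry, cf_table, indication_mapping)
    return results


class TestSummarizeStrata:
    def test_identical_values_zero_width_ci(self, registry, cf_table, indication_mapping):
        doses = doses_from_daps(registry, cf_table, indication_mapping, [50.0, 50.0, 50.0])
        (stratum,) = summarize_strata(doses)
        lo, hi = stratum.ci95_dose
        assert lo == pytest.approx(hi) == pytest.approx(50.0)

    def test_singleton_stratum_has_no_ci(self, registry, cf_table, indication_mapping):
        doses = doses_from_daps(registry, cf_table, indication_mapping, [50.0])
        (stratum,) = summarize_strata(doses)
        assert stratum.ci95_dose is None and stratum.ci95_dap is None
        assert stratum.n == 1

    def test_hand_computed_normal_ci(self, registry, cf_table, indication_mapping):
        doses = doses_from_daps(registry, cf_table, indication_mapping, [10.0, 20.0, 30.0])
        (stratum,) = summarize_strata(doses)
        assert stratum.mean_dose_usv == pytest.approx(20.0)
        lo, hi = stratum.ci95_dose
        assert lo == pytest.approx(20 - 1.96 * 10 / math.sqrt(3), abs=1e-6)
        assert hi == pytest.approx(20 + 1.96 * 10 / math.sqrt(3), abs=1e-6)
        assert round_sig(lo) == 8.68 and round_sig(hi) == 31.3

    def test_ci_width_shrinks_as_inverse_sqrt_n(self, registry, cf_table, indication_mapping):
        import statistics

        base = [10.0, 20.0, 30.0]
        d1 = doses_from_daps(registry, cf_table, indication_mapping, base * 3)
        d2 = doses_from_daps(registry, cf_table, indication_mapping, base * 12)
        (s1,) = summarize_strata(d1)
        (s2,) = summarize_strata(d2)
        w1 = s1.ci95_dose[1] - s1.ci95_dose[0]
        w2 = s2.ci95_dose[1] - s2.ci95_dose[0]
        # width ∝ SD/√n; the sample (n−1) SDs of the two replications differ
        sd1 = statistics.stdev([d.effective_dose_usv for d in d1])
        sd2 = statistics.stdev([d.effective_dose_usv for d in d2])
        assert w1 / w2 == pytest.approx((sd1 / sd2) * math.sqrt(36 / 9), rel=1e-9)

    def test_freq_pct_sums_to_100_per_device(self, registry, cf_table, indication_mapping):
        doses = []
        for fov, n in (((4.0, 4.0), 3), ((17.0, 12.0), 7)):
            doses += doses_from_daps(
                registry, cf_table, indication_mapping, [30.0] * n,
                fov_diameter_cm=fov[0], fov_height_cm=fov[1],
            )
        strata = summarize_strata(doses)
        assert sum(s.freq_pct for s in strata) == pytest.approx(100.0, abs=0.2)

    def test_unknown_grouping_field_rejected(self, registry, cf_table, indication_mapping):
        doses = doses_from_daps(registry, cf_table, indication_mapping, [50.0])
        with pytest.raises(DoseAuditError, match="unknown grouping"):
            summarize_strata(doses, grouping=("shoe_size",))

    def test_reconstruction_identity(self, registry, cf_table, indication_mapping):
        doses = []
        for fov, vals in (((4.0, 4.0), [20.0, 40.0]), ((17.0, 12.0), [100.0, 150.0, 170.0])):
            doses += doses_from_daps(
                registry, cf_table, indication_mapping, vals,
                fov_diameter_cm=fov[0], fov_height_cm=fov[1],
            )
        strata = summarize_strata(doses)
        assert reconstruct_collective_dose_usv(strata) == pytest.approx(
            collective_dose(doses) * 1e6, rel=1e-12
        )


class TestProtocolDoseTable:
    """Protocol-level summary of the fixed-exposure device."""

    @pytest.mark.parametrize(
        "age_group, fov, mode, dap_display, dose_display",
        [
            (AgeGroup.Y15_PLUS, FovCategory.SMALL, OperationMode.STANDARD, 4.66, 35.1),
            (AgeGroup.Y15_PLUS, FovCategory.MEDIUM, OperationMode.STANDARD, 10.5, 79.0),
            (AgeGroup.Y15_PLUS, FovCategory.LARGE, OperationMode.STANDARD, 18.0, 136),
            (AgeGroup.Y15_PLUS, FovCategory.LARGE, OperationMode.HR, 31.6, 238),
            (AgeGroup.Y4_6, FovCategory.SMALL, OperationMode.STANDARD, 4.66, 77.7),
            (AgeGroup.Y4_6, FovCategory.MEDIUM, OperationMode.STANDARD, 10.5, 175),
            (AgeGroup.Y4_6, FovCategory.LARGE, OperationMode.STANDARD, 18.0, 300),
            (AgeGroup.Y4_6, FovCategory.LARGE, OperationMode.HR, 31.6, 527),
            (AgeGroup.Y7_11, FovCategory.LARGE, OperationMode.HR, 31.6, 369),
            (AgeGroup.Y12_14, FovCategory.LARGE, OperationMode.HR, 31.6, 271),
        ],
    )
    def test_cell_values(self, accuitomo, cf_table, age_group, fov, mode, dap_display, dose_display):
        table = protocol_dose_table(accuitomo, cf_table)
        cell = find_stratum(table, "accuitomo170", age_group, fov, mode)
        assert round_sig(cell.mean_dap_dgycm2) == dap_display
        assert round_sig(cell.mean_dose_usv) == dose_display

    def test_unrounded_chain(self, accuitomo, cf_table):
        """Large-FOV mean DAP is carried as 17.974, not the displayed 18.0."""
        table = protocol_dose_table(accuitomo, cf_table)
        cell = find_stratum(
            table, "accuitomo170", AgeGroup.Y4_6, FovCategory.LARGE, OperationMode.STANDARD
        )
        assert cell.mean_dap_dgycm2 == pytest.approx((21.7 * 0.76 + 25.6 * 0.76) / 2, abs=1e-12)

    def test_tcm_device_rejected(self, newtom, cf_table):
        with pytest.raises(DoseAuditError, match="TCM"):
            protocol_dose_table(newtom, cf_table)


class TestFrequencyAndRatios:
    def test_single_record_single_full_cell(self, registry, cf_table, indication_mapping):
        doses = doses_from_daps(registry, cf_table, indication_mapping, [50.0])
        tables = frequency_tables(doses)
        frame = tables["indication_by_mode"]
        assert frame.to_numpy().sum() == pytest.approx(100.0)
        assert frame.loc["surgical planning and follow-up", "standard"] == pytest.approx(100.0)

    def test_mode_shares_and_request_ratio(self, registry, cf_table, indication_mapping):
        doses = doses_from_daps(registry, cf_table, indication_mapping, [30.0] * 7)
        doses += doses_from_daps(
            registry, cf_table, indication_mapping, [90.0] * 3,
            operation_mode_raw="High-Fidelity",
            fov_diameter_cm=14.0, fov_height_cm=10.0, total_exposure_mas=154.0,
        )
        tables = frequency_tables(doses)
        shares = tables["mode_pct"]["freq_pct"]
        assert shares["standard"] == pytest.approx(70.0)
        assert shares["HR"] == pytest.approx(30.0)
        assert standard_hr_request_ratio(shares.to_dict()) == 2.3

    def test_cell_percentages_sum_to_100(self, registry, cf_table, indication_mapping):
        doses = doses_from_daps(registry, cf_table, indication_mapping, [30.0] * 5)
        for name in ("indication_by_age_group", "indication_by_fov_category", "indication_by_mode"):
            assert frequency_tables(doses)[name].to_numpy().sum() == pytest.approx(100.0)

    def test_reported_request_ratio_rounds_to_3_7(self):
        assert standard_hr_request_ratio({"standard": 78.6, "HR": 21.4}) == 3.7

    def test_hr_standard_dose_ratio_identity(self, accuitomo, cf_table):
        table = protocol_dose_table(accuitomo, cf_table)
        assert hr_standard_dose_ratio(table, "accuitomo170", FovCategory.LARGE) == 1.8
        with pytest.raises(DoseAuditError):
            hr_standard_dose_ratio(table, "accuitomo170", FovCategory.SMALL)

    def test_headline_ratios_bundle(self, accuitomo, cf_table):
        table = protocol_dose_table(accuitomo, cf_table)
        ratios = headline_ratios(
            table,
            mode_freq_pct={"standard": 78.6, "HR": 21.4},
            fov_freq_pct={"small": 2.5, "medium": 69.4, "large": 28.1},
        )
        assert ratios["standard_hr_request_ratio"] == 3.7
        assert ratios["medium_large_request_ratio"] == 2.5
        assert ratios["hr_standard_dose_ratio:accuitomo170:large"] == 1.8
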