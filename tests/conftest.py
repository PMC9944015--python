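from datetime import date

import pytest

from cbctdose import ExposureRecord
from cbctdose.defaults import (
    default_cf_table,
    default_device_registry,
    default_indication_mapping,
)


@pytest.fixture(scope="session")
def registry():
    return default_device_registry()


@pytest.fixture(scope="session")
def cf_table():
    return default_cf_table()


@pytest.fixture(scope="session")
def indication_mapping():
    return default_indication_mapping()


@pytest.fixture(scope="session")
def accuitomo(registry):
    return registry["accuitomo170"]


@pytest.fixture(scope="session")
def newtom(registry):
    return registry["newtom_vgi_evo"]


def make_record(**overrides) -> ExposureRecord:
    """A valid fixed-exposure-device record with overridable fields."""
    base = dict(
        exam_id="ex-001",
        device_id="accuitomo170",
        acquired_on=date(2019, 6, 1),
        patient_age=30,
        referral_department="maxillofacial surgery",
        operation_mode_raw="Standard",
        fov_diameter_cm=4.0,
        fov_height_cm=4.0,
        tube_voltage_kv=90.0,
        total_exposure_mas=87.5,
        recorded_dap_dgycm2=4.02,
    )
    base.update(overrides)
    return ExposureRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
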