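"""Packaged defaults: the audited center's device registry, the implemented
per-DAP conversion-factor table, the published Newtom stratum summary used
as reference input, and the default department→indication mapping.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import IndicationMapping
from .conversion import CFPerDAPTable
from .io import read_cf_table, read_device_registry, read_indication_mapping
from .model import Registry

ACCUITOMO = "accuitomo170"
NEWTOM = "newtom_vgi_evo"

#: Audited cohort sizes (number of examinations per device over one year).
COHORT_SIZES = {ACCUITOMO: 196, NEWTOM: 4967}

#: Combined-device operation-mode request shares (%), from the audit report.
REPORTED_MODE_FREQ_PCT = {"standard": 78.6, "HR": 21.4}

#: Combined-device FOV-category request shares (%), from the audit report.
REPORTED_FOV_FREQ_PCT = {"small": 2.5, "medium": 69.4, "large": 28.1}

#: TCM per-age-group sample sizes used when deriving the Newtom per-DAP CFs.
TCM_CF_SAMPLE_SIZES = (28, 143, 306, 334)


def _data_path(name: str):
    return resources.files("cbctdose.data").joinpath(name)


def default_device_registry() -> Registry:
    """The two-scanner registry with protocol catalogs and QC factors."""
    with resources.as_file(_data_path("devices.yaml")) as p:
        return read_device_registry(p)


def default_cf_table() -> CFPerDAPTable:
    """The implemented per-DAP conversion factors (µSv/(dGy·cm²)) per age group."""
    with resources.as_file(_data_path("cf_per_dap.csv")) as p:
        table = read_cf_table(p)
    assert isinstance(table, CFPerDAPTable)
    return table


def default_indication_mapping(strict: bool = True, fallback: str | None = None) -> IndicationMapping:
    """Editable default referral-department → clinical-indication mapping."""
    with resources.as_file(_data_path("indication_map.csv")) as p:
        return read_indication_mapping(p, strict=strict, fallback=fallback)


def newtom_reported_strata() -> pd.DataFrame:
    """Published per-stratum (n, mean corrected DAP) table for the TCM device.

    Patient-level TCM exposure data were never published; this per-stratum
    summary is the reference input for worked dose cells, age-group
    frequencies and the collective-dose reconstruction, and supplies the
    target means of the default synthetic cohort.
    """
    with resources.as_file(_data_path("newtom_strata_reported.csv")) as p:
        return pd.read_csv(p)
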