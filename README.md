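# cbctdose

Effective-dose auditing for dental cone-beam CT (CBCT) exposure logs.

Hospitals that monitor patient radiation dose collect, for every CBCT
acquisition, the exposure data written into the image DICOM header: scanner,
operation mode, tube parameters, field of view (FOV), recorded dose-area
product (DAP), patient age and referral department. `cbctdose` turns such
logs into a stratified effective-dose report for medical physicists and
radiology quality officers:

1. **QC-based DAP correction** — displayed DAP values are frequently
   inaccurate; a correction factor *k* is derived as the mean of the
   measured/recorded ratios from annual quality-control campaigns, and
   DAP<sub>corrected</sub> = *k* × DAP<sub>recorded</sub>.
2. **Conversion-factor derivation** — published Monte-Carlo conversion
   factors (µSv/mAs, per scanned region and integer age 5–15 y) are averaged
   per FOV and age group and collapsed into one DAP-based factor
   CF<sub>E</sub> in µSv/(dGy·cm²) per device and age group, the only form a
   DICOM-header-driven monitor can apply. For a scanner with tube current
   modulation (TCM) the collapse averages per-exam ratios over patient data;
   for a fixed-exposure scanner the protocol catalog suffices.
3. **Effective dose** — per exam, *E* = CF<sub>E</sub> × DAP<sub>corrected</sub>
   (µSv); per cohort, the collective dose Σ*E* in man-sievert.
4. **Reporting** — per-(device, age group, FOV category, operation mode)
   means with normal-approximation 95% CIs, request-frequency tables by
   clinical indication, and headline request/dose ratios.

Classifications: age groups 4–6 / 7–11 / 12–14 / ≥15 y (adults use the 15-y
factors); FOV categories by area diameter × height — small < 40 cm²,
40 ≤ medium ≤ 100 cm², large > 100 cm²; device-native modes pooled into
standard vs high-resolution (HR).

The package ships the protocol catalogs, QC factors and conversion-factor
table of a two-scanner audit (a fixed-exposure unit, *k* = 0.76, and a TCM
unit with accurate DAP display), plus a synthetic-cohort generator that
emulates the audited one-year workload, so the whole pipeline runs without
any patient data.

## Worked example

```python
from cbctdose import (
    collective_dose, compute_doses, default_cf_table, default_device_registry,
    default_indication_mapping, summarize_strata, synthesize_cohort,
)
from cbctdose.simulate import default_newtom_spec

registry = default_device_registry()
records = synthesize_cohort(default_newtom_spec(), registry["newtom_vgi_evo"], seed=1)
doses, rejects = compute_doses(records, registry, default_cf_table(),
                               default_indication_mapping())
print(len(doses), "exams,", f"{collective_dose(doses):.3f} manSv")
```

prints

```
4967 exams, 0.221 manSv
```

— a synthetic year of the TCM scanner: 4967 acquisitions whose summed
effective dose is ≈ 0.22 manSv, dominated by the adult medium-FOV
standard-mode stratum. The `examples/` directory holds one narrative script
per capability (QC correction, protocol dose table, cohort pipeline, CF
derivation, frequency report); each prints its numbers with a note on what
they mean. For the fixed-exposure scanner,
`protocol_dose_table` reproduces the full dose table from the catalog alone:
standard-mode doses run 35.1 µSv (adult, small FOV) to 300 µSv (4–6 y, large
FOV) and HR doses 238–527 µSv.

A thin CLI mirrors the library: `cbctdose synthesize | derive-cf-correction |
derive-cf | compute-dose | report` (see `cbctdose --help`).

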