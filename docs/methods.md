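# Methods

## Dose model

Per-exam effective dose is a two-factor chain:

    DAP_corrected = k · DAP_recorded
    E             = CF_E(device, age group) · DAP_corrected

with DAP in dGy·cm², E in µSv and CF_E in µSv/(dGy·cm²). Units are fixed;
there is no unit autodetection. The collective dose of a cohort is
Σ E_i · 10⁻⁶ manSv. Every intermediate is carried at full double precision;
rounding (3 significant figures for doses and DAPs, 1 decimal for
percentages and ratios) happens only in display columns and `round_sig`.
This matters: the large-FOV standard cell of the fixed-exposure scanner is
the mean of 21.7·0.76 = 16.492 and 25.6·0.76 = 19.456, i.e. 17.974 — feeding
the rounded 18.0 into the dose product would miss the printed dose values.

### QC correction factor

k is the unweighted arithmetic mean of measured/recorded DAP ratios, pooling
all campaigns and FOV sizes per measurement (campaigns are not reweighted;
with three FOVs per annual campaign this equals campaign-weighting only when
campaigns are complete). Ratios deviating from k by more than 5% set a
warning flag but never fail: the deviation is descriptive. A device whose
display is accurate gets k = 1 and the correction is the identity.

### Conversion-factor collapse

Published per-mAs factors are specific to scanned-region indication and
integer age (5–15 y; adults reuse the 15-y factors, since head circumference
is essentially constant from that age). The collapse to per-DAP factors:

1. per FOV and age group, average cf(µSv/mAs) over all linked indications
   and all covered integer ages in the group, unweighted — ages are **not**
   weighted by patient frequency, as no weighting is defensible without the
   underlying patient mix;
2. per exam (TCM device) or per protocol (fixed-exposure device), form
   ratio = cf(FOV)·mAs / DAP_corrected;
3. the per-DAP factor of the (device, age group) cell is the unweighted mean
   of these ratios. TCM exam ratios are pooled unweighted rather than
   averaged per FOV first; the two differ only under unbalanced FOV use and
   the pooled mean matches the per-exam definition of the validation error.

Validation compares E_dap = CF·DAP_corrected against the per-mAs dose per
exam; "within 20%" is inclusive (deviation ≤ 0.20). Validation statistics
are reported, never thresholded: large deviations for individual exams are
expected wherever one averaged factor stands in for indication-specific ones.

The package cannot ship the licensed per-mAs source tables; it ships the
derived per-DAP table as its default and a generator
(`synthesize_cf_per_mas`) producing *synthetic* per-mAs tables that are
mean-consistent with a per-DAP target (symmetric spread across ages; FOVs
shared by several modes are normalized by the mean mAs-per-DAP of their
protocols so the catalog-wide derivation round-trips exactly). These
synthetic tables exercise the derivation code path; they are not the
published factors.

### Classification

* Age groups 4–6, 7–11, 12–14, ≥15 y. Ages below 4 are rejected (no CF
  covers them) and routed to a rejects report, never dropped silently;
  the behaviour is strict by design.
* FOV category by area product: small strictly < 40 cm², 40–100 cm²
  inclusive medium, > 100 cm² large. The 40 cm² boundary is assigned to
  medium, matching the audited grouping of the 8×5 volume.
* Operation modes are normalized case-insensitively: standard/regular-scan →
  standard; high-fidelity/high-resolution → HR.
* Clinical indication is a pure function of referral department through an
  editable two-column mapping validated against the seven-category
  vocabulary; unmapped departments either raise (strict, default) or fall
  back to a configured category.

### Confidence intervals

Stratum CIs are mean ± 1.96·SD/√n with the sample (n−1) SD — the normal
approximation, isolated in one helper so a t-based variant is a one-line
swap. CIs are omitted for singleton strata. Frequency percentages are
relative to the device total in the dose summary and to the combined grand
total in the indication tables; the per-age-group indication table is
normalized within each age group.

## Synthetic cohorts

The generator emulates the audited center's one-year workload and is the
test bed for every stage:

* **Fixed-exposure scanner** (196 exams): records carry exactly the
  protocol's fixed mAs and nominal recorded DAP. The audited per-stratum
  breakdown for this device was not published; the default mix (standard:HR
  ≈ 188:8, HR on large FOVs only, age mix mirroring the TCM cohort) is this
  package's choice of a plausible workload.
* **TCM scanner** (4967 exams): age-group shares and per-stratum target mean
  DAPs come from the shipped published stratum summary
  (`newtom_strata_reported.csv`); the recorded DAP is log-normal per stratum
  — positive and right-skewed, as expected under patient-size-driven tube
  current modulation — with CV 0.25, calibrated so synthetic CI widths are
  of the order of the published ones; mAs is uniform within the protocol's
  modulation range. Each (category, mode) draws the modal concrete FOV of
  the audited workload (5×5, 10×10, 24×19).
* Indication mixes per age group approximate the audited distribution
  (surgery-dominant, children skewed to pedodontics/orthodontics); FOV/mode
  assignment tables are keyed per (age group, indication) with an
  age-group-wide `*` fallback, because the audited FOV/mode mix is strongly
  age-dependent.
* One `numpy.random.Generator` seeded from a single integer drives all
  draws; no global state.

What the generator does **not** emulate: correlation between patient size
and DAP beyond the age-group level, seasonal workload structure, real
department names, or intra-protocol kV/mAs variation on the fixed-exposure
device. Passing tests therefore demonstrate the pipeline's arithmetic and
statistical behaviour under the assumed structure, not clinic-level realism
of any individual stratum's dispersion.

QC campaigns are emulated as measured = recorded · k · noise with mean-one
log-normal noise; the mean ratio recovers k within ≈ 3·CV/√n.

## Problem sizes and numerical choices

Tests and the acceptance script run the full default cohorts (196 + 4967
exams) — seconds of work — plus small hand-checkable fixtures. Degenerate
inputs are errors, not silent defaults: empty QC lists, zero reference
doses, unlinked FOVs, missing CF coverage and unknown devices all raise
typed exceptions naming the offending entity. Duplicate exams are removed by
exam_id keeping the first occurrence (the only stable key a header extract
offers), and deduplication is idempotent. Dates are ISO-8601 only.

## Known limitations

* The per-DAP factors are averages over indications; individual-exam errors
  above 20% are possible and are only reported, not corrected.
* Ages < 4 y are outside the CF domain and rejected rather than
  extrapolated.
* DAP-meter calibration uncertainty and beam-energy dependence of the
  correction factor are out of scope, as are organ doses and risk
  projection.
* The published per-stratum table pins only stratum means; within-stratum
  dispersion of the synthetic TCM cohort is calibrated, not measured.
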