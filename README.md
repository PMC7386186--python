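# tbi-autoplan

An open toolkit for automating the manual treatment-planning workflow of
extended-SSD **total body irradiation (TBI)** — the whole-body photon
conditioning treatment delivered, for example, before allogeneic stem-cell
transplant. When no CT is acquired, clinics compute monitor units (MU) with a
"hand calculation" from commissioned look-up tables, then retype the results
into the treatment-planning system and the patient worksheet. Those manual
bridging steps — transcription, data entry, table look-up — are the dominant
error source in incident-learning records for this technique. This package
removes them: one validated data path from the prescription to the plan, the
worksheet, and an automated pre-treatment check battery, plus an analytics
module for the incident-learning-system (ILS) reports that motivate the
design.

It is intended for medical physicists and research software engineers studying
planning automation and safety analytics. **It is not a clinical product:**
the planning-system interface is a mock data model and the "dose engine" is an
explicit placeholder.

## The calculation

Dose is calibrated at 100 cm with a 10 × 10 cm field; treatment uses a
40 × 40 cm field at 500 cm SSD. With patient separation *s* (cm), the
prescription point is the midplane (depth *d = s/2*), and

```
dose_per_mu = ISF · Sc · Sp · TMR(d) · SF · 0.99        [cGy/MU]
ISF         = (100 / (500 + s/2))²
MU          = round_half_up(dose_per_field / dose_per_mu)
```

where Sc and Sp are the collimator and phantom scatter factors, TMR the
tissue-maximum ratio interpolated at midplane depth, SF the beam-spoiler
factor, and 0.99 the dose-to-water → dose-to-muscle conversion. The machine
dose rate is set to the **largest** deliverable rate *R* (MU/min) with
*R · dose_per_mu ≤ max_dose_rate* (typically 10 cGy/min at the prescription
point). Beam energy is chosen from the patient separation via a half-open
interval look-up table.

Modules:

| module | contents |
| --- | --- |
| `beam_data` | table containers, validation, checksummed YAML+CSV I/O, linear interpolation (no extrapolation), energy selection, seeded fixture generator |
| `mu_calc` | prescription model, protocol registry and validation, the six-factor MU / dose-rate engine |
| `plan_builder` | date-based plan naming, phantom/reference-points/fields construction, normalization-and-weight MU inversion, JSON and minimal DICOM-RT export |
| `safety_report` | patient worksheet (markdown/PDF), parse-back, and a check battery with an independent MU recomputation |
| `ils_analysis` | incident-report CSV I/O, quarterly series, half-up proportions, overrepresentation factor, pre/post-intervention summaries, Poisson report generator |
| `cli` | `tbi-autoplan plan / check / ils / fixtures` |

## Worked example

```
tbi-autoplan fixtures --seed 1 --out demo
tbi-autoplan plan --rx demo/prescription.yaml --beamdata demo/beamdata.yaml \
    --out demo/out --date 2019-07-15
```

The demo prescription is a standard adult course: 150 cGy per field, 6
fractions, 36 cm separation, 10 cGy/min limit, AP/PA fields. The audit log
prints:

```
load: beam data fixture-seed1-e2 [beam_data=cf7bfa053d10]
validate: 0 prescription finding(s) [beam_data=cf7bfa053d10]
calc: 7779 MU/field at 500.0 MU/min (9.64 cGy/min) [beam_data=cf7bfa053d10]
build: plan TBI_07-2019 with 2 field(s) [beam_data=cf7bfa053d10]
worksheet: rendered and parsed back [beam_data=cf7bfa053d10]
checks: 0 finding(s), 0 blocking [beam_data=cf7bfa053d10]
export: plan.json and plan.dcm written [beam_data=cf7bfa053d10]
```

Reading the numbers: the 36 cm separation selects the 10X beam and an 18 cm
midplane depth; the factor product gives 0.019282 cGy/MU, so 150 cGy per field
needs 7779 MU, and the fastest deliverable rate under the 10 cGy/min limit is
500 MU/min (9.64 cGy/min achieved). The worksheet (`demo/out/worksheet.md`)
lists every factor — ISF 0.037268, Sc 1.015637, Sp 1.014198, TMR 0.532046,
spoiler 0.9536, muscle 0.99 — serialized directly from the calculation record,
never retyped. Every artifact carries the beam-data version and checksum.
With `--strict` (the default), any blocking finding from the check battery
makes the run exit nonzero and refuses to export the plan — a forcing
function, not a reminder.

The check battery covers the recorded manual-error taxonomy: identifier
mismatches, mislabelled fields, a missing worksheet, wrong-protocol
parameters, wrong gantry/field size, mistranscribed separation, wrong MU
(checked against an independently coded recomputation), non-deliverable or
limit-violating dose rates, and wrong energy for the separation.

ILS analytics on the bundled example audit:

```
tbi-autoplan ils --reports demo/incidents.csv --intervention 2019-03-31 --out demo/ils
```

writes a pre/post summary (35 TBI reports over 25 pre-automation quarters,
mean 1.4 per quarter) and the quarterly histogram.

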