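# Methods

## Scope and model

The package automates the hand-calculation planning chain for extended-SSD
total body irradiation. The physics content is deliberately that of the
clinical hand calculation, nothing more: dose per MU at the patient midplane
is a product of six factors (inverse-square, collimator scatter Sc, phantom
scatter Sp, tissue-maximum ratio at midplane depth, beam-spoiler factor, and
the 0.99 water-to-muscle conversion), each drawn from commissioned 1-D
look-up tables. There is no volumetric dose calculation anywhere in the
package; the "dose state" used during plan construction is an explicit mock
whose only purpose is to exercise the normalization/weight inversion that a
scripted planning system performs.

Assumptions baked into the engine:

- **Prescription point = midplane.** Depth is `separation / 2`, distance is
  `treatment_ssd + separation / 2`. This matches the midplane dose-uniformity
  goal of the technique.
- **ISF references the 100 cm calibration distance**,
  `(cal_distance / (treatment_ssd + separation/2))²`. The calibration depth
  convention is not modelled; geometry is configurable
  (`MachineGeometry`).
- **TMR is 1-D in depth** at a protocol-level effective field size. The
  technique fixes a 40 × 40 collimator at 500 cm, so a per-protocol table is
  adequate; 2-D (depth × field size) grids are out of scope.
- **Sc and Sp are looked up at the collimator setting (40 cm side) by
  default.** Whether a clinic uses the collimator-projected or
  patient-limited equivalent square at extended distance varies; both knobs
  are exposed (`CalcOptions.sc_equivalent_square`, `sp_equivalent_square`)
  and neither convention is asserted as correct.
- **Opposed fields are equally weighted**: every field of the arrangement
  carries the same MU.

## Numerical choices

- **Interpolation is piecewise linear** with hard `OutOfRangeError` outside
  the knots. Silent extrapolation is exactly the hidden-error class the
  check battery exists to catch, so it is forbidden rather than warned about.
  Interpolation is exact at knots and bounded by bracketing values
  (property-tested).
- **MU rounding is half-up to an integer** (`decimal`-based, not banker's
  rounding), matching deliverable MU and spreadsheet behaviour. The rounding
  contract — `MU × dose_per_mu` within half an MU's dose of the prescribed
  dose per field — is asserted in tests.
- **Dose-rate selection** takes the *largest* ladder member satisfying
  `rate × dose_per_mu ≤ limit`, with a 1e-9 relative tolerance on the
  inequality so a rate landing exactly on the limit is accepted despite
  floating-point representation. Maximal-feasible minimizes beam-on time
  without violating the protocol limit; if even the slowest rate violates it,
  the calculation fails loudly (`NoFeasibleRateError`).
- **MU sanity cap** (default 30 000 MU, ≈10× a typical adult extended-SSD
  field) makes the engine refuse absurd outputs instead of emitting them —
  a forcing function ahead of any downstream check.
- **MU-setting inversion**: with per-field base MU `b_i` from the placeholder
  dose state, targets `t_i`, ratios `r_i = t_i/b_i` and `m = max r_i`, the
  package sets `weight_i = r_i/m` (the largest weight is exactly 1.0 by
  construction, avoiding a one-ulp bound violation) and
  `normalization = 100/m`. The forward model
  `delivered_i = b_i · w_i · 100/normalization` then reproduces every target
  exactly after integer rounding; weights are bounded in [1e-3, 1] and
  normalization in [0.1, 1000] %, outside which the target is declared
  unattainable.
- **Energy selection intervals are half-open** `[sep_min, sep_max)`:
  deterministic tie-break at boundaries, and the table must partition the
  covered range (validated at load).
- **Checksums**: SHA-256 over the canonical JSON of the full dataset; the
  master file's stored checksum is verified on load and echoed into every
  calculation record, worksheet and audit-log line, so a silently edited
  table or a version skew between worksheet and plan is detectable.

## Independence of the check battery

`safety_report.independent_dose_per_mu` / `independent_mu` re-derive the
calculation from raw table knots in pure Python — separate bracketing code,
no numpy, no calls into `beam_data` or `mu_calc`. A checker that shares code
with the engine it audits cannot catch that engine's bugs; the duplication is
the point. The battery's other checks (identifiers, field labels, protocol
bounds, dose-rate feasibility, energy-vs-separation, geometry presets,
worksheet attachment and echo) each mechanize one root error from the
incident taxonomy that motivated the package; the test suite carries one
fixture per taxonomy row (13 in all) plus the clean-path soundness check
(zero blocking findings on an untouched auto-built plan).

## Synthetic beam data

`beam_data.generate_fixture` emulates commissioned large-field photon data:
TMR decays exponentially beyond build-up with per-energy effective
attenuation (≈0.049/cm at 6 MV down to ≈0.039/cm at 18 MV, ±3 % seeded
jitter), Sc/Sp rise gently with equivalent-square side around unity, the
spoiler factor is a per-energy scalar in (0.9, 1.1], and dose rates form the
usual 100–600 MU/min ladder. Separations of 10–60 cm are partitioned evenly
among the energies. What it does **not** emulate: build-up-region TMR
structure, off-axis profiles, field-size-dependent TMR, machine output drift,
or any measured machine's actual values — so passing tests demonstrate the
*algebra and plumbing* are right, not that any specific machine's
commissioning is reproduced. Generation is bit-reproducible per seed.

Default study conditions used by tests and the acceptance script: a standard
adult course (150 cGy/field, 6 fractions, 36 cm separation, 10 cGy/min limit,
AP/PA), seeded fixtures with 2–3 energies, 25–100 engine-equivalence cases,
1000 dose-rate cases, 200 inversion trials. These sizes are the package's own
choice of a convincing-but-quick property sweep.

## Protocol registry and plan construction

The protocol registry (dose-per-field range, separation range, dose-rate
ceiling, age class) ships with representative defaults: 10 cGy/min ceilings
for the standard adult and pediatric protocols — the usual instantaneous
limit at the prescription point — and 15 cGy/min for a high-rate single-dose
regimen, reflecting that some protocols allow up to 15 cGy/min. The numeric
bounds are package defaults for validation demonstrations, not published
clinical constraints; clinics supply their own registry.

Plan naming is `TBI_MM-YYYY` with the smallest free `-k` suffix on collision.
Reference-point limits default to session = daily = dose_per_field × fields
per fraction and total = daily × fractions, since only "derived from the
prescription" is specified by practice. Course name equals the plan base
name. Gantry presets (AP/PA and RLat/LLat both → 270°/90°) and the isocenter
convention are configuration, validated but not asserted as universal. Dates
are injected parameters — no wall-clock reads inside logic — so runs are
reproducible byte-for-byte given (inputs, date).

DICOM-RT export is intentionally minimal (beams with name/gantry/energy/dose
rate in one control point; per-beam meterset in the fraction group) with
content-derived UIDs so export is deterministic; JSON is the lossless format.

## ILS analytics

Proportions are percentages rounded half-up to one decimal, the
overrepresentation factor is a half-up one-decimal ratio of two shares, and
quarterly series are zero-filled calendar quarters. The pre-automation window
is 2013 Q1–2019 Q1 inclusive (25 quarters), with the intervention quarter
assigned to the *pre* period. The bundled example audit fixes the totals and
marginals (9108 patients / 411 TBI; 1566 reports / 470 planning-related / 24
TBI-planning; 35 TBI reports split 17/11/7 by classification and 11/12/12 by
category); the per-quarter spread of the 35 reports is not part of the
published tallies, so the example dataset distributes them deterministically
— the mean (1.4/quarter) is fixed by the totals, the per-quarter standard
deviation is not, and no SD value is asserted anywhere. The synthetic report
generator is a seeded per-quarter Poisson process with the audit's empirical
category mix; a parameter-recovery test (500 replicates at rate 1.4) checks
the series machinery. Two post-automation quarters are too few for causal
claims, so the module stops at descriptive pre/post summaries.

## Known limitations

- No real dose computation, couch/collimator kinematics, imaging fields, or
  record-and-verify transactions; compensator and lung-block design, TLD
  boost calculations and in-vivo dosimetry are out of scope.
- The worksheet's PDF rendering (matplotlib) is a functional document, not a
  clinic-layout replica; markdown is the parse-backable format of record.
- Schema validation is explicit field checking with named-field errors rather
  than a declarative schema language.
- Prescription validation is bound checking against a registry; it cannot
  catch a wrong-but-in-range order.
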