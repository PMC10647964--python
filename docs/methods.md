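# Methods

`artflag` implements a dosimetrically triggered decision-support workflow for
adaptive radiotherapy (ART) of head-and-neck (H&N) cancer: at every delivered
fraction the end-of-treatment dose is estimated, dose-volume histogram (DVH)
metrics are extracted for targets and organs at risk (OARs), and rule-based
action levels (green / orange / red) are emitted per region of interest (ROI)
per fraction. This note records the model, its assumptions, the parameters
that matter, and the design choices made where the design was genuinely open.

## End-of-course dose estimation

At fraction `n` of an `N`-fraction course, with `d_i` the dose delivered at
fraction `i` (already expressed on the planning grid), the final dose is
estimated by assuming the remaining fractions deliver the average of those
delivered so far:

    D̂(n) = Σ_{i≤n} d_i + (N − n) · (1/n) Σ_{i≤n} d_i = (N/n) · Σ_{i≤n} d_i

Properties relied on downstream (all tested): the estimate is linear in the
fractions, exactly equals the accumulated dose at `n = N`, and recovers the
planned dose at every `n` under perfect delivery (`d_i = D*/N`).

The estimate is voxelwise; DVH metrics are then extracted from the estimated
grid. A *metrics-only* mode applies the same formula to per-fraction metric
values from CSV tables. This is an approximation — quantile metrics (D95,
D99, D2, D5) are nonlinear in dose, so extrapolating the metric is not
identical to extrapolating the dose and re-extracting — but the two coincide
whenever per-fraction dose distributions are proportional, and the mode is
the practical entry point when only DVH tables are exported by the treatment
platform. Fraction lists must be a contiguous prefix `1..n`; missed or
partial fractions are not modelled.

Upstream steps (daily image registration, dose recomputation, deformable
contour propagation, dose warping) are out of scope: the input contract is a
per-fraction dose on a common grid, or per-fraction metric tables.

## DVH conventions

* `D_p` is the greatest dose received by at least `p`% of the ROI volume
  ("minimum dose of the hottest p%"), linearly interpolated between
  cumulative-histogram bin edges. The interpolation convention matters only
  at the sub-bin scale; with the default bin width of **0.01 Gy** (well below
  the 0.1 Gy flag dead band) binning can never change a flag decision.
  A sort-all-voxels oracle agrees within one bin width (tested).
* `V_d` is the percent volume receiving ≥ `d` Gy, interpolated on the same
  curve; mean dose is the plain voxel average (the DVH integral converges to
  it as the bin width shrinks — tested at 0.1 vs 0.01 Gy).
* Masks are binary; partial-volume (fractional voxel) DVHs of clinical
  treatment-planning systems are **not** modelled. At the coarse lattices
  used here this mainly affects small structures; it is a known deviation
  from commercial DVH engines.
* Margin expansion (`CTV + m` mm) is computed on the voxel lattice: a voxel
  joins the expanded set iff its centre lies within `m` mm (Euclidean,
  anisotropic spacing honoured, ties included) of an input voxel centre,
  via an exact Euclidean distance transform. Results are nested in `m` and
  `m = 0` is the identity.

## Flagging protocols

Both protocols compare an estimated metric `m` against its planned value
`m*` and clinical threshold `t`, fraction by fraction, with no history. The
criteria table (configurable as YAML, shipped as the default) is:

| j | ROI — metric | threshold t |
|---|--------------|-------------|
| 1 | PTV — D99 | 90% of prescription |
| 2 | PTV — D95 | 95% of prescription |
| 3 | Spinal cord — D2 | 48 Gy |
| 4 | Brainstem — D2 | 60 Gy |
| 5 | Parotid ipsi. — Dmean | 30 Gy |
| 6 | Parotid contra. — Dmean | 26 Gy |
| 7 | Larynx — D5 | 45 Gy |
| 8 | Oral cavity — Dmean | 30 Gy |
| 9 | Mandible — D2 | 70 Gy |
| 10 | Superior constrictors — Dmean | 45 Gy |

Target rows apply to each target category (`PTV_T`, `PTV_NL`, `PTV_NR`)
separately, resolved against that target's own prescription.

**Initial protocol** (per metric; tolerance levels 1/2/3 = 10%/5%/2.5%).
With the adverse difference δ (= `m − m*` for OARs, `m* − m` for targets):

* planned value satisfies `t`: orange iff `δ > tol·t`; red iff `δ > tol·m*`
  **and** the estimate itself violates `t`; red takes precedence.
* planned value already violates `t` (knowingly accepted at planning):
  orange impossible; red iff `δ > tol·m*`. This avoids futile flags and is
  marked `planned_violation` in the audit trace.

**Upgraded protocol** (organ-architecture aware; OAR tolerance fixed 20%):

* *Targets* combine both coverage metrics, `m1 = D99`, `m2 = D95`:
  red iff `m1 < m1*` ∧ `m2 < m2*` ∧ `m1 < t1` ∧ `m2 < t2`; orange iff
  exactly one metric fails (below plan and its threshold) while the other
  still meets its threshold. Orange and red are mutually exclusive by
  construction (tested exhaustively on a value lattice).
* *Serial OARs* (near-maximum metrics D2/D5): orange iff
  `m − m* > tol·t` ∧ `m < t`; red iff `m > m*` ∧ `m > t`.
* *Parallel OARs* (mean-dose metrics): orange iff `m − m* > tol·t` ∧
  `m > t`; red never.

Numerical choices, where the rules leave room:

* **All inequalities are strict.** Equality with a threshold or a tolerance
  margin does not fire a condition; at `m* = t` the planned value counts as
  violating (the constraints are strict, e.g. cord `D2 < 48 Gy`).
* **Dead band.** Differences below 0.1 Gy are ignored in *every*
  difference-based condition (`m` vs `m*`, including the plain `m < m*`
  clauses of the upgraded protocol), but never in the absolute `m` vs `t`
  comparisons. Consequence (tested as a property): any perturbation of a
  metric by < 0.1 Gy from its plan leaves the decision green.
* **Per-ROI reduction (initial protocol).** A target ROI has two criteria
  (D99, D95); the per-ROI colour is the worst of the two, with the
  per-metric trace retained. This keeps the decision unit uniform —
  one colour per (patient, fraction, ROI) — across both variants.
* **Default organ classes** (never spelled out by rule tables, configurable):
  serial = spinal cord, brainstem, mandible, larynx (all carry near-max
  metrics); parallel = parotids, oral cavity, superior constrictors (mean
  dose); anything named `PTV*`/`CTV*` is a target. Larynx D5 is serial by
  default; reclassify via config if local practice differs.
* **Planned violations under the upgraded protocol** are handled by applying
  the clauses literally (a further decrease beyond the dead band can still
  satisfy a red clause) and marking the trace `planned_violation`.
* ROIs with missing metrics or no applicable criteria are skipped with a
  logged warning, never an error.

An independent straight-line transcription of both rule tables (separate
code path, no shared helpers) agrees with the engine on 10⁵ randomised
metric tuples; tolerance monotonicity (the 2.5% flag set ⊇ 5% ⊇ 10%) is
likewise tested on random tuples.

## Benchmarking

The comparison unit is one (patient, fraction, ROI). For a positive class —
`red`, `orange`, or `any` (colour-agnostic, any non-green) — decisions and
reference labels are tallied into TP/FP/FN/TN; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), reported rounded to two decimals. With per-colour
positives a red decision against an orange label counts FP for red *and* FN
for orange, which is why per-colour sensitivities understate the
colour-agnostic agreement. Undefined rates (zero denominator) are reported
as undefined, never as 0. Each matrix partitions the unit total (conserved;
tested).

Cohort summaries: percent of patients with ≥ 1 flag of a colour per
treatment week (5 fractions) and at their last fraction, and the PTV-vs-OAR
share of flags. For courses of 31–35 fractions the trailing partial week is
folded into week 6 when ≤ 2 fractions remain, and forms its own week 7
otherwise — a reporting choice for mixed-length cohorts.

## Synthetic cohort generator

No clinical dataset ships with the package; the generator emulates the
structure the protocols assume, and its defaults *are* the study conditions
of the tests:

* 38 patients; 30–35 fractions; prescriptions 52.5–70 Gy (primary target
  drawn near the top of the range, nodal targets 52.5–60 Gy); `PTV_T`
  always present, each nodal target with probability 0.8; all eight OARs —
  ~10 ROIs per patient.
* Planned metrics satisfy the criteria table by default: target D95* drawn
  at 96–99% of prescription, D99* 1–4 prescription-percent below it
  (floored above the 90% threshold); OAR planned values at 55–95% of their
  limits. An optional `planned_violation_rate` places an OAR plan 2–10%
  above its limit to exercise the protocols' special case.
* Per-fraction delivered metrics are plan/N plus (a) Gaussian noise of
  sd 0.03 Gy per fraction (~1.5% of a 2 Gy fraction metric — day-to-day
  registration/contouring variability) and (b), in drift-affected
  patient-ROI pairs, a linear adverse ramp of 0.02 Gy/fraction
  (0.015 for parallel OARs) from an onset drawn in the first half of the
  course — coverage drifts down for targets, dose up for OARs (weight loss,
  tumour shrinkage, cavity-filling phenomenology). The affected-patient
  probability is 0.15 per ROI, calibrated once so that roughly 10–45% of
  patients flag per week under the upgraded protocol, with orange flags
  front-loaded and red flags accumulating late — the qualitative pattern of
  clinical flag-rate reports. These defaults are plausible, not fitted to
  any clinical distribution (none is published).
* Ground-truth labels are generated by running the reference (upgraded)
  protocol and perturbing a configurable fraction of units by exactly one
  colour step (green↔orange, orange↔red), emulating imperfect physician
  agreement. Zero noise recovers sensitivity = specificity = 1 exactly — a
  pipeline self-consistency check, not a statement about clinical accuracy.
* All randomness flows from one cohort seed through per-patient derived
  streams; a cohort is bit-for-bit reproducible.
* *Grid mode* builds small lattices (default 32³ voxels at 3 mm) with a
  spherical CTV, a conformal planned dose (prescription plateau over
  CTV + planning margin, linear fall-off over 12 mm) and a delivered course
  whose dose profile translates progressively (0.3–0.8 mm/fraction) — a
  deterministic anatomical-drift surrogate for margin-variant coverage
  experiments on CTV + 0/2/4 mm.

**What passing tests do and do not show.** The generator reproduces the
*mechanisms* the protocols respond to (gradual adverse drift, noisy daily
metrics, planned violations, margin-dependent coverage loss), not the
anatomy or dosimetry of real H&N courses: no deformation fields, no
correlated multi-ROI changes, no realistic DVH shapes. Green suites
demonstrate that the rules, the estimator and the statistics behave as
specified — not that the protocol's clinical sensitivity on real patients
equals any particular value.

**Week-1 amplification.** The (N/n) factor multiplies week-1 per-fraction
variability by ≈ N to N/5, so early estimates systematically overstate
deviations relative to the completed course whenever day-to-day variability
or early transients are present; a *steadily increasing* ramp alone, by
contrast, yields early estimates `s·N·(n+1)/2` that grow with `n` and
understate the final deviation. The directional test therefore measures the
amplification on the generator's full model (drift + noise), where the
cohort-median week-1 |deviation| is ~3× the final one.

## Problem sizes in tests and the acceptance script

The acceptance script runs a full 38-patient metric-mode cohort (~13,000
decision units, ~16,000 metric series entries), a second 38-patient cohort
for the amplification ratio, and one 15-fraction 32³ grid course for the
margin experiment — a few seconds end to end. Unit suites use 8-patient
cohorts, ≤ 10³-voxel grids for brute-force oracles, and 10⁵ random tuples
for the rule-engine oracle. These sizes were chosen as the smallest that
exercise every property at cohort scale.

## Known limitations

* Binary masks (no partial-volume DVH); coarse lattices in grid mode.
* Metrics-only extrapolation is exact only for proportional per-fraction
  distributions (documented approximation).
* DICOM support is a thin optional RTDOSE reader; RTSTRUCT contour
  rasterisation is not provided — masks are expected from upstream tooling
  or the synthetic module.
* OAR rules are taken as specified; in the clinical experience they derive
  from, OAR flags were rare, so their parameters rest on few samples.
* History-aware or week-dependent criteria and alternative extrapolation
  strategies (project last fraction; assume planned remainder) are not
  implemented.
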