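# Methods

## Dose-volume histograms and metrics

A `StructureDVH` is either a differential histogram (strictly increasing
bin edges in Gy(RBE), non-negative per-bin volume fractions summing to
≤ 1) or a cumulative curve (fraction of the structure receiving at least
each dose).  The cumulative form is canonical internally; differential
input is converted on load by reverse partial summation, which is exactly
invertible (round-trip error < 1e-12).  A structure partially outside the
dose grid has a cumulative curve starting below 1; metrics then refer to
the covered fraction and a warning is logged.

Dx% follows the dominant treatment-planning convention: the minimum dose
received by the hottest x% of the volume, linearly interpolated between
cumulative points, with flat segments resolved to the highest qualifying
dose (a 1e-9 tolerance on the volume fraction keeps binning round-off from
hiding a flat segment).  The source analyses do not state their
interpolation convention; this choice is documented rather than inferred.
Mean dose uses differential bin midpoints; integral dose is mean body dose
times body volume; CI = V(≥ 0.95 · prescription)/V(PTV);
HI = (D2% − D98%)/D50%.  Against direct voxel computation on ≤ 1000-voxel
fixtures binned at 0.1 Gy, all Dx% agree within one bin width and
D<sub>avg</sub> within half a bin width (tested).

## NTCP models

gEUD(a) = (Σ vᵢ dᵢᵃ)^{1/a} over differential fractions; a = 1 is exactly
the mean dose; a = 0 is rejected (the log form is not used); for a < 0,
bins below 1e-6 Gy count as unirradiated and are excluded from the power
mean with a warning (all-zero dose is undefined).

Three functional forms cover the registry's model families:

* LKB probit: NTCP = Φ((S − TD50)/(m · TD50));
* multivariable logistic: NTCP = 1/(1 + e^{−(β₀ + Σ βᵢxᵢ)}), with terms
  drawn from dose summaries of the model's organ and/or named patient
  covariates (e.g. a chemotherapy indicator);
* log-logistic: NTCP = 1/(1 + (D50/S)^{4γ₅₀}).

All three are intrinsically bounded in [0, 1]; no clipping is applied.  S
is the model's configured dose summary (mean dose, gEUD(a), or D1% as
near-maximum dose).  No fractionation (EQD2) conversion is applied: the
DVHs are consumed as given.  A model whose organ or covariate is missing
is *not evaluable*; it is excluded pairwise from ΔNTCP, CTS and MBS with a
logged warning, never imputed as zero.  Covariate-bearing models use
patient-specific covariate values whenever present.

The registry is a YAML file, one block per model: organ, endpoint, form,
dose summary, parameters, evidence level, CTS weight, MBS membership and
thresholds, citation key.  The shipped default reproduces the published
16-model panel structurally — weights summing to unity (the 11 models with
weight ≤ 0.07 carry exactly ¼ of the total), 7 MBS members with standard
and young thresholds — while its dose-response *parameter values* are
representative defaults chosen for plausible complication probabilities at
typical head-and-neck OAR dose levels; they are transcription placeholders
for the cited publications, and every test constructs its own synthetic
parameter sets where parameter values matter.

## Scoring and selection

CTS = Σ wᵢΔᵢ over all 16 models, in percentage points, sign-preserving.
MBS applies a strict inequality for the single-endpoint rule ("larger
than" the threshold) and ≥ for the composite rule (Σ over the 7 MBS
models ≥ 35 points, constructed as 7 × 5); the boundary conventions differ
deliberately and boundary cases are tested.  Negative deltas enter the
composite sum as-is by default; a clamp-at-zero option exists and every
report records which convention ran.  The young threshold set applies the
per-endpoint young values with the composite bar unchanged at 35 (no young
composite is defined); threshold mode is selected per run, applying one
set to the whole cohort, with a per-patient age switch (< 40 years)
available for in-silico studies.  Because young thresholds are
componentwise ≤ standard ones, standard-eligibility implies
young-eligibility (tested as an invariant).  Cohort eligibility uses
inclusion–exclusion over the single/composite rules and surfaces all four
counts (single-only, composite-only, both, union).

## Cohort statistics

The Wilcoxon signed-rank test is implemented directly so its small-sample
branch is auditable: zero differences are dropped; |differences| are
mid-ranked under ties; for n ≤ 12 the exact null distribution of the
positive-rank sum is built by convolution over all 2ⁿ sign assignments
(half-integer midranks are doubled to make the lattice integral); the
two-sided p is min(1, 2·min(P(W ≤ w), P(W ≥ w))).  For n > 12 a normal
approximation uses the tie-corrected variance Var(W⁺) = Σ rᵢ²/4, a 0.5
continuity correction, and one symmetric Edgeworth term from
κ₄ = −Σ rᵢ⁴/8, which keeps it within ~0.005 of the exact branch at the
crossover (tested within 0.01 for n = 10–12).  Degenerate all-zero input
returns p = 1 with a flag.

Per-endpoint ΔNTCP tests are two-sided at α = 0.05 with **no**
multiple-testing correction across the 16 endpoints, and the report says
so.  The CTS comparison between eligible and non-eligible patients is a
two-*independent*-group problem, so the default test is the rank-sum
(Mann–Whitney) variant via scipy; a paired signed-rank variant is exposed
for equal-sized groups and the method used is recorded in the result.

Stratified passing-rate tables (all patients; T1–T2 vs T3–T4; N0, N1,
N2–N3) are computed from integer counts and rendered to one decimal,
rounding half away from zero; empty strata are marked `n=0`.  The
all-patients column is by construction the size-weighted average of the
stratum columns.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised.  Covariates are drawn from the cohort mix: T stage
40/14/30/16 %, N stage 16/28/30/26 %, treatment 8/54/38 %
(RT alone / RT-CHT / iCHT+RT-CHT), ages ~N(51, 11) truncated to 24–72,
overall stage derived from T/N by the standard grouping.  Prescriptions
are 69.96 Gy(RBE) in 33 fractions to the PTV-HD with a second level of
56.1 (24 % of patients) or 59.4 (20 %), or three levels
69.96/59.4/56.1 (56 %).

Each structure's photon cumulative DVH comes from a two-parameter logistic
family V(d) = σ((D50ₛ − d)/kₛ), truncated and renormalized on [0, dmax]
(dmax = D50ₛ + 10kₛ, capped at 80 Gy), chosen because the study reports
metric-level behaviour, not DVH shapes, and this family is analytically
invertible for mean/gEUD targets.  Patient-level variation enters through
Gaussian jitter on D50ₛ and kₛ and through a T-stage-dependent upward dose
shift for OARs near the target (brain, optic pathways, cochlea, superior
PCM, brainstem), the mechanism by which locally advanced tumours raise
nearby OAR doses.

The proton plan maps photon dose levels d through
h(d) = f·d + (1 − f)·d³/d<sub>ref</sub>² for near-target structures
(sparing factor f in (0, 1], near-maximum doses pinned at
d = d<sub>ref</sub>, emulating sparing concentrated in the low-to-middle
dose range) and through h(d) = f·d for structures a few centimetres from
the target (spinal cord, brain, glottic larynx, esophagus, thyroid, body),
whose near-maximum doses also fall.  h is strictly increasing and ≤ d, so
the proton mean dose never exceeds the photon mean when f < 1 (a
construction guarantee, tested).  Targets draw from the same family just
above the prescription dose for both modalities, so target coverage is
equivalent by construction; the nominal curve's V95 is validated against
the ≥ 0.95 coverage goal analytically before any sampling.

One global seed drives everything; each patient uses the substream
`default_rng([seed, patient_index])`, so extending a cohort preserves
earlier patients.

Default sparing-factor means were fixed once by inverting the generator
(`plant_effect`, bisection on a 4000-patient probe with common random
numbers) so that the default cohort reproduces the endpoint-level
conditions the analysis is designed around: expected MBS pass fractions of
24 % (xerostomia), 8 % (brain necrosis), 6 % (mucositis and trismus) and
2 % (dysphagia), zero passes on the optic endpoints (optic maximum doses
kept below the tolerance region), and mean ΔNTCP levels of ≈ 8.6 points
(tinnitus) and ≈ 9.3 (hypothyroidism).  With these defaults a 50-patient
cohort typically yields 30–50 % standard-mode eligibility and 70–85 %
young-mode eligibility, a higher eligible share among T3–T4 patients, an
integral-dose reduction of ≈ 45 %, and significantly higher CTS in the
eligible group.

What the generator does **not** emulate: real 3-D dose anatomy,
inter-structure dose correlations beyond the shared T-stage shift,
planner-specific trade-offs, or DVH shapes of clinical plans.  Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline* under known ground truth, not agreement with any clinical
cohort.

`plant_effect` itself is validated by parameter recovery: planting a 24 %
xerostomia pass fraction and regenerating 50-patient cohorts puts the
observed pass count inside the exact central 95 % binomial interval around
0.24 in ≥ 90 % of 200 seeded replicates (the count is Poisson-binomial
with patient-varying pass probabilities, so its dispersion is at most
binomial).

## Numerical choices and degenerate inputs

* Volume-fraction queries use a 1e-9 tolerance; dose grids are strictly
  increasing; cumulative curves non-increasing within 1e-12.
* Registry weight sums are validated to 1e-9 at load time (a startup
  error, never a scoring-time one).
* A patient with any not-evaluable MBS delta receives an explicit
  not-evaluable verdict, not "ineligible".
* All-zero paired differences give a flagged degenerate test result with
  p = 1.
* Reported percentages round half away from zero to one decimal.

## Problem sizes

The shipped test-suite and acceptance runs use 50-patient cohorts on
0.1 Gy dose grids (the cohort size of the motivating study), a
4000-patient probe for generator inversion, and 200 replicates for the
recovery experiment; a full 50-patient pipeline run takes about a second
on one core.

## Known limitations

Plan optimization, DICOM-RT parsing, variable-RBE weighting, EQD2
conversion, confidence intervals on NTCP differences, and refitting of the
published NTCP models are out of scope.  The default registry's parameter
values are representative, not transcribed from the cited publications,
and must be replaced before any clinical interpretation.
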