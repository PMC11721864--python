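# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Study design being emulated

The unit of analysis is one observer's correction of one AI-generated organ
contour on one scan. The default design is fully crossed: every one of 20
patients is scanned once on each of two CBCT systems (high-performance,
conventional), five pelvic organs (prostate, seminal vesicles, bladder,
rectum, bowel) are autosegmented per scan, and each of 3 observers corrects
every contour — 40 scan units, 600 delineations, and 120 metric observations
per organ. Agreement between the AI contour and the fully corrected contour
is the performance signal: DSC and HD95 per delineation.

## Contour metrics

* **DSC** = 2|A∩B| / (|A|+|B|) by voxel count; spacing-invariant.
* **HD95**: boundary voxels are foreground voxels with at least one
  face-adjacent (6-connected) background or grid-edge neighbour. Directed
  Euclidean distances between voxel centres (spacing-scaled) are computed
  from every boundary voxel of A to the nearest boundary voxel of B and vice
  versa; the metric is the linear-interpolation 95th percentile of the
  *pooled* directed set, which makes it symmetric by construction. The
  alternative convention (max of per-direction 95th percentiles) was
  rejected for symmetry and testability; this is a fixed convention, not an
  inference about any particular prior implementation.
* Distances are centre-to-centre, not sub-voxel surface distances; at 2 mm
  spacing this carries a small positive bias that is irrelevant for
  arm comparisons because it is common to both arms.
* Exact Euclidean distance transforms (`scipy.ndimage.distance_transform_edt`)
  make both directions exact; the test suite checks equality (1e-9) with an
  all-pairs brute-force oracle on random ≤32³ mask pairs.
* `restrict_to_region` implements the clinical rule that bladder/rectum/bowel
  edits are confined to a band (2 cm in the emulated workflow) around the
  prostate + seminal vesicles. Headline metrics are computed on the *full*
  corrected contours; the restriction exists for workflow emulation only.

## Synthetic cohort generator

The generator's purpose is to give every downstream statistic a known ground
truth. Geometry:

* **Truth**: per-organ superellipsoids (|x/a|ⁿ+|y/b|ⁿ+|z/c|ⁿ ≤ 1) with
  per-patient size jitter (±8%) and centre jitter (±4 mm). Organ masks are
  stored on minimal bounding sub-grids of the 96³ study grid (the mask
  carries its origin), purely for efficiency; all three masks of a record
  share one sub-grid so every metric precondition holds.
* **AI contour**: the truth warped by a smooth random displacement field
  (white noise on a coarse grid, Gaussian-filtered at a 12 mm correlation
  length, linearly upsampled, rescaled to a target RMS magnitude). The
  magnitude is read off a per-organ calibration curve (magnitude → expected
  DSC, built once under a fixed internal seed) so the induced DSC
  approximately follows the crossed linear model below.
* **Corrected contour**: the truth perturbed by a smaller observer-specific
  field — equivalently, the AI contour fully pulled back to truth and then
  observer-perturbed. The per-record total magnitude realises the
  model target; the AI share is 90% of the scan's smallest target magnitude
  and observer shares combine in quadrature.
* **Targets**: y_ijk = β₀ + β₁·x_k + u_i + v_j + ε_ijk on the DSC scale,
  x = 0 for high-performance and 1 for conventional (so a negative β₁ on DSC
  means the conventional arm is worse). One scalar magnitude cannot hit a
  DSC and an HD95 target simultaneously, so HD95 is *induced* by the same
  deformation; the β₀/β₁ HD95 config fields drive the direct (geometry-free)
  metric-table simulator used by the statistical unit tests.
* **Outlier scenario**: the flagged patient's conventional-arm bladder AI
  contour is replaced by a 0.4-scale superellipsoid displaced 100 mm along
  the longest crop axis, guaranteeing DSC < 0.2 and HD95 > 60 mm against the
  corrected contour while leaving the high-performance arm untouched.
* **Secondary endpoints**: correction times are lognormal — a per-patient
  factor calibrated so the arm-level five-organ totals match the configured
  means/SDs (defaults 663 [197] s vs 672 [190] s), times a per-record
  lognormal; confidence scores are categorical over 1–5 with per-organ,
  per-arm distributions concentrated around the configured means (defaults:
  high-performance arm 4.3–4.9, conventional 3.5–4.5).
* **Determinism**: every random stream derives from `SeedSequence` children
  of the config seed; identical config ⇒ bit-identical masks and metadata.

What the generator does **not** emulate: image intensities or CBCT physics,
segmentation networks (AI contours are simulated deformations, never
predictions), organ-shape realism beyond smooth blobs, spatial correlation
between organs, or observer-specific systematic styles (observer effects are
exchangeable random intercepts). Passing tests therefore demonstrate the
*statistical machinery* is correct under the declared model, not that any
particular imaging system behaves this way.

## Crossed random-intercepts model

For one organ and one metric, y = β₀ + β₁·x + u_patient + v_observer + ε
with independent Gaussian intercepts (crossed factors). Estimation is REML:
the criterion is profiled over the two variance ratios γ_p = σ²_p/σ²_e,
γ_o = σ²_o/σ²_e and minimised on the log scale by bounded L-BFGS-B from
several deterministic starts; all boundary sub-models (either or both
components removed) are evaluated explicitly, which is how negative moment
estimates are truncated at zero *with refit*. Under balance the ANOVA
expected-mean-squares estimators are the exact stationary point, and the
moment point is included in the candidate set so the balanced fit reproduces
the closed forms to machine precision. Reported β̂ is GLS at the optimum;
`se_beta1` is the model-based (GLS) standard error.

**Inference on β₁.** Two routes, chosen automatically:

* *Balanced complete tables*: the exact paired-contrast t test on the
  per-(patient, observer) arm differences d = y_hp − y_conv (the intercepts
  cancel, the d's are i.i.d. under the model, and β̂₁ = mean(d) under
  balance). This test has exact size at every sample size.
* *Unbalanced tables*: t = β̂₁/se with Satterthwaite degrees of freedom
  2·Var(β̂₁)²/(g′I⁻¹g), where I is the expected REML information in the
  variance components and g the gradient of Var(β̂₁); validated against
  lmerTest on a frozen reference table (df 92.19 vs 92.27, p to 1e-6).

A design note: small-sample df corrections of the Kenward–Roger type
reproduce the classical exact F/t tests where those exist. For this balanced
crossed design the Satterthwaite/KR route lands on the residual-stratum test
(97 df at the default design), which is *a* valid exact test but a different
statistic from the paired contrast (59 df). The package deliberately adopts
the paired contrast as its balanced-case inference: it is exact, simpler to
audit, and immune to the residual-stratum pooling assumption. The
Satterthwaite route remains available via `inference="satterthwaite"`.

Degenerate inputs: zero residual variance yields a flagged result with
p = 1 if β̂₁ = 0 and p = 0 otherwise; fewer than two levels of any random
factor is an error, never a silent answer.

## Interobserver variability (ICC)

Per imaging system, organ and metric, the two-way crossed decomposition
y_ij = μ + p_i + o_j + e_ij is estimated by the balanced ANOVA closed form
(REML fallback when cells are missing), components truncated at zero, and

ICC = σ²_observer / (σ²_systematic + σ²_patient + σ²_observer),

where the "systematic" term is identified with the residual component — a
constant systematic offset has zero variance, so the denominator's
systematic share can only be the non-patient, non-observer variation. An
ICC near 0 means observers are consistent; note this inverts the usual
reliability reading of an ICC. Zero total variance reports ICC = 0 with a
degeneracy flag.

**Uncertainty**: stratified cluster bootstrap — within each imaging-system
stratum, patients are resampled with replacement carrying their complete
observer set (observers are a fixed crossed factor of 3 and are never
resampled); the ICC is recomputed per replicate (B = 10 000 by default) and
a 95% percentile interval is read off. Percentile (not BCa) was chosen as
the simplest interval consistent with the procedure; its finite-sample
behaviour is quantified below. Arms are compared with a Welch two-sample t
test *on the two replicate vectors*, and the Δ 95% CI is the percentile
interval of paired-index differences (conventional − high-performance).

**Known limitations, quantified by simulation** (all numbers reproducible
from the test suite's frozen seeds):

* With 3 observers the observer mean square has 2 df at any number of
  patients, so the ICC point estimate is a ratio with an irreducibly noisy
  numerator. The resulting concavity bias is negligible at small true
  ratios (+0.01 at 0, −0.01 at 0.10, default design) but reaches ≈ −0.04 at
  a true ratio of 0.22 — and does not shrink with more patients.
* For the same reason, patient-only resampling cannot restore the
  observer-sampling variability: in ≈17% of default-design datasets the
  realised observer mean square is near zero, the replicate distribution
  collapses near 0, and the 95% percentile interval misses upward. Measured
  coverage of a true ratio 0.10 is ≈ 0.82, not the nominal 0.95.
* The Welch test on replicate vectors is anti-conservative by construction:
  its standard error shrinks like 1/√B while the arm ICCs differ at
  sampling-noise scale, so under identical generating distributions it
  rejects ≈ 90% of the time (B = 200). It is reported because it is the
  emulated study procedure; it should be read as a descriptive contrast of
  bootstrap distributions, not a calibrated test of the underlying ICC
  difference.

## Workflow statistics

* **Correction time**: per delineation times are summed over the five organs
  per (patient, arm, observer), averaged over observers, and the resulting
  per-patient arm pairs (20 at the default design) enter a classical paired
  t test.
* **Confidence**: per organ, scores are averaged over observers to patient
  level and compared by a Wilcoxon signed-rank test. Zeros are dropped
  before ranking (the original rule, chosen over Pratt's for exact
  enumerability); for n ≤ 25 retained pairs the exact two-sided p is
  computed by dynamic programming over tie-adjusted midranks (equivalent to
  enumerating all 2ⁿ sign patterns); above that, a normal approximation
  with tie correction.
* **Multiplicity**: a single Bonferroni family of 26 tests (10 performance,
  10 ICC, 1 time, 5 confidence); per-test level α/26 = 0.0019. The report
  carries both raw and Bonferroni-flagged significance so the family is
  auditable.

## Pipeline and reproducibility

`run_pipeline` executes simulate → metrics → analyze → report, writing the
metric and metadata CSVs, the four result tables, the multiplicity audit and
a human-readable report; every file carries a provenance header (package
version, SHA-256 config hash, seed). SDs use the n−1 denominator; times are
computed in seconds and displayed as m:ss. Identical config + seed produce
byte-identical outputs; any stage failure removes partial outputs and names
the stage. Every table is recomputable from the emitted metric CSV alone.

## Problem sizes used in the tests

The test suite runs the full default-design cohort once (shared fixture,
outlier scenario enabled); balanced-exactness checks use 20 tables at a
10-patient × 8-observer design, where truncation is a priori negligible, so
the interior REML/ANOVA identity — not boundary refitting — is what is
tested; null calibration uses 1000 simulated default-design tables;
ICC recovery 200 tables per ratio at the default design and at 5000
patients; bootstrap coverage 300 datasets at B = 500; the geometry ↔
statistics ordering sweep uses 1-organ cohorts with 5 observers and 3 seeds
per level, since 2-df observer estimates cannot be ordered reliably.
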