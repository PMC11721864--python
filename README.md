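# autosegeval

Evaluation framework for AI-based organ autosegmentation compared across two
cone-beam CT (CBCT) imaging systems, as used in CBCT-guided online adaptive
radiotherapy of the male pelvis. It is written for medical-physics and
biostatistics teams who need to quantify, on multi-reader multi-case data,
whether a higher-performance imaging system actually changes
autosegmentation quality, interobserver consistency, correction time or
delineation confidence — and who want every stage of that analysis testable
without any patient data.

The package provides, as a library plus a thin CLI:

* **Synthetic cohort generator** — a full crossed study design (by default
  20 patients × 2 imaging systems × 5 pelvic organs × 3 observers = 600
  delineations on a 96³ voxel grid at 2 mm): superellipsoid ground-truth
  organs, AI contours produced by smooth random displacement fields whose
  magnitude is calibrated so the induced metrics follow a configurable
  linear model, observer-corrected contours, lognormal correction times and
  categorical 1–5 confidence scores, a heavy-patient outlier scenario and a
  field-of-view exclusion flag.
* **Contour metrics** — Dice similarity coefficient (DSC) and the 95th
  percentile Hausdorff distance (HD95) on anisotropic voxel grids, plus the
  clinical 2 cm correction-region restriction. Both metrics are verified
  against brute-force oracles.
* **Crossed random-intercepts model** — for each organ and metric,

  `y = β₀ + β₁·x + u_patient + v_observer + ε`,

  with `x = 1` for the high-performance arm, fitted by REML (profiled
  criterion, bounded quasi-Newton, explicit boundary sub-models for
  truncation at zero). Inference on β₁ uses the exact paired-contrast t test
  on balanced tables and a Satterthwaite-df t test (validated against
  lmerTest) otherwise.
* **Interobserver variability** — the variance-ratio ICC
  `σ²_observer / (σ²_systematic + σ²_patient + σ²_observer)` (near 0 =
  consistent observers), stratified patient-cluster bootstrap confidence
  intervals (default B = 10 000) and a Welch comparison between arms.
* **Workflow statistics** — paired t test on per-patient observer-averaged
  correction-time totals, exact signed-rank tests on per-organ confidence
  scores, and Bonferroni control of the 26-test family (α/26 ≈ 0.0019).

## Worked example

```python
from autosegeval import (CohortConfig, fit_crossed_model, generate_cohort,
                         metrics_for_cohort)

cfg = CohortConfig(n_patients=6, outlier_patient=0, seed=42)
records = generate_cohort(cfg)          # 180 delineation records
metrics = metrics_for_cohort(records)   # one (DSC, HD95) row per record
fit = fit_crossed_model(metrics, response="dsc", organ="bladder")
print(f"beta1 = {fit.beta1:+.3f}, p = {fit.p_value:.3f}")
```

prints

```
beta1 = +0.196, p = 0.033
```

i.e. the bladder DSC is 0.196 higher on the high-performance arm — here
dominated by the simulated heavy-patient outlier, whose conventional-arm
bladder contour collapses (DSC < 0.2, HD95 > 60 mm) while the
high-performance arm is unaffected. Without the outlier flag the estimate
returns to the configured arm effect of a few DSC percent. The examples/
directory walks through each capability (cohort generation, metrics, model,
ICC bootstrap, full pipeline) as short narrative scripts, and

```bash
autosegeval all --seed 1 --out study_out
```

runs the complete simulate → metrics → analyze → report pipeline, writing
every table as CSV plus a human-readable `report.txt`.

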