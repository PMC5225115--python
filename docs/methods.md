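# Methods

## The washout estimator

The estimator assumes that after the arterial phase (first ~2 min) the
tracer deposit in tissue is complete: from the uptake peak onward, regional
activity is governed by washout alone, and differences in washout rate
between a target region and a reference region free of specific binding
carry the binding information. Writing m(t) for the target curve, m_ND(t)
for the reference curve and m(0), m_ND(0) for their peak-phase maxima, the
non-displaceable binding potential is

    BP_ND = [ m(0) · ∫ (ln m_ND(t) − ln m_ND(0)) dt ]
          / [ m_ND(0) · ∫ (ln m(t) − ln m(0)) dt ]  −  1 .

Each integral runs over that curve's *own* washout phase — from its peak
frame's mid-time to the last frame mid-time ≤ T — because target and
reference may peak at different frames. The numerator is the accumulated
log-signal of the reference (what remains versus what was deposited),
scaled by the target's initial deposit; the denominator is the symmetric
quantity for the target. The deposit scaling corrects for flow-dependent
delivery, the log-integrals for the exponential character of washout. Both
the numerator and denominator are negative for decaying curves, so
BP_ND ≥ −1 by construction, and a non-decaying target (denominator ≥ 0)
is rejected as an error rather than reported.

Two exactness properties anchor the implementation and its tests:

* **Identity**: target ≡ reference gives BP_ND = 0 exactly (the ratio is
  evaluated as a quotient of identical floating-point products).
* **Log-linearity**: for curves that decay mono-exponentially in frame
  mid-time from their peak, the integrand is linear in t, the trapezoidal
  rule is exact, and BP_ND = (m(0)·k_ND)/(m_ND(0)·k) − 1 to machine
  precision, independent of T when the peaks align.

## Phases, peaks and companion measures

* Peak search window: mid-times in [2, 10] min. The peak is the literal
  frame maximum; ties break toward the earliest frame. A smoothed or
  fitted peak would be less noise-sensitive but would break the exactness
  properties above; the literal maximum is the simpler, testable choice.
* R1 (relative uptake) = target peak / reference peak. Dimensionless
  relative delivery; it cancels global tracer dose but also genuine
  subject-level flow.
* sCBF = peak value / time-to-peak, in kBq/mL/min as computed. A
  site-specific scale factor (default 1.0 = uncalibrated) can be derived
  with `calibrate_scale_factor`, which maps the cohort mean onto a
  user-supplied mean CBF (e.g. from an [15O]water study); no calibration
  constant is invented by the package.
* SUVR: trapezoidal integrals over frames with mid-times in [40, 60] min,
  target over reference. The late window is assumed near secular
  equilibrium; at 6-min frames the trapezoid's curvature error is bounded
  by h²k²/12 (< 1% for washout rates ≤ 0.05/min).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| peak window | [2, 10] | min | flow-limited uptake phase |
| T (washout upper limit) | 60 | min | washout analysed over 2–60 min |
| SUVR window | [40, 60] | min | late steady-state window |
| reference region | CERB | — | cerebellum grey matter, no specific binding |
| clamp floor ε | 0.01 × peak | — | only *nonpositive* washout samples are clamped before the log; positive samples are never altered |
| sentinel threshold | 25% clamped frames | — | voxels noisier than this get NaN and a QC count |
| scale factor | 1.0 | — | uncalibrated sCBF unless user calibrates |

Degenerate inputs are errors, not silent values: no frame in the peak
window, all-nonpositive peak-phase signal, non-decaying washout,
nonpositive reference peak, SUVR window not covered. In voxelwise maps the
same conditions produce NaN sentinels (never zero — zero is a legal
BP_ND) counted per failure mode in the QC report.

The default frame schedule is 4×30 s + 9×1 min + 3×3 min + 10×6 min +
2×10 min (28 frames). Its total is 100 min although the acquisition it
models is described as 90 min; the schedule ships as printed and the
discrepancy is documented rather than resolved — only frames up to T
enter any estimate.

## The simulator

Synthetic data are generated from a one-tissue reference-tissue model:

* arterial input: gamma-variate shape t^α·e^(−βt) with (α, β) =
  (1.5, 3.0/min) — peaks at 0.5 min, cleared to ≪5% of maximum by 10 min,
  matching the rapid circulatory clearance the washout method assumes;
* reference tissue: one-compartment uptake of the input with washout rate
  k2_ref = 0.03/min. This is an *effective* 2–60 min clearance rate chosen
  so that (a) the reference peaks inside the 2–10 min window on the
  default schedule and (b) late-window SUVR magnitudes fall in the
  plausible 1–2.5 range;
* target tissue: C(t) = R1·C_ref(t) + R1·(k2_ref − k2a)·[C_ref ⊗ e^(−k2a·t)]
  with k2a = R1·k2_ref/(1 + BP_ND) — the analytic solution of the
  one-tissue reference-tissue model, in which the relative delivery R1
  cancels between deposit and clearance so that binding, not flow, sets
  the late washout. At BP_ND = 0, R1 = 1 the target collapses onto the
  reference exactly;
* convolution on a 0.01-min grid (FFT-based, checked against direct
  summation to <0.1%), then averaged over each frame's duration to mimic
  the time-integrating nature of PET frames;
* noise: multiplicative Gaussian per frame. By default the CV scales with
  the inverse square root of expected frame counts (activity × duration ×
  carbon-11 decay, t½ = 20.385 min), normalised so `noise_cv` (default
  0.10) is the CV of the best-counted frame; late frames are then several
  times noisier, as in real scans. A constant-CV mode
  (`count_scaled=False`) isolates estimator behaviour from the noise
  profile.

With these defaults the washout estimator recovers BP_ND ∈ [0.5, 2] within
about 9% (noiseless) — the estimator is an approximation to the full
compartment kinetics, so exact equality is not expected — and group means
of 20 noisy subjects at constant 5% frame CV are biased by under 7%.

### Cohort presets

Presets (in `presets.yaml`) define per-region distributions of (BP_ND, R1)
for AD-, DLB-, FTLD-, MCI-like groups and healthy controls at the study
group sizes (16/8/5/5/29). Regional draws share a subject-level factor
(correlation 0.7): amyloid burden and global perfusion are traits of a
subject, not of a region. The healthy-control binding background
(0.12 ± 0.30, clipped at 0) gives a realistic amyloid-positive tail among
elderly controls; flow SDs of 0.15 reflect between-subject CBF
variability. All magnitudes are simulator presets chosen for physiological
plausibility, not measured values.

What the simulator does **not** emulate: scanner resolution and
partial-volume effects, scatter/randoms, white-matter spillover into
cortex, motion, attenuation artefacts, multi-exponential plasma tails, or
anatomically shaped regions (phantoms use cuboid blocks). Passing tests
therefore show correctness of the estimators under the stated kinetic
model and noise, not robustness to those real-data effects.

## Regional statistics and ROC analysis

Regional values for cohort statistics are taken from the voxelwise
parametric maps (region means over non-sentinel voxels): because every
voxel is quantified against the mean reference curve, reference-region
voxels scatter around their null values (BP_ND 0, R1 1, SUVR 1) instead of
sitting identically on them, as in real parametric images — and the
reference region can participate in group statistics as a built-in null.

* Deviation profiles: z = (value − mean_HC)/SD_HC per region × measure,
  sample SD with n−1. Healthy controls standardise to mean 0, SD 1 by
  construction.
* Group comparison: two-sided Student t-test, equal-variance by default
  (Welch behind a flag); the significance panel reports 1/p with the
  reference region flagged. No multiple-testing correction by default.
* ROC: empirical curve; AUC by trapezoid (equal to the Mann-Whitney
  statistic with ties counting ½); cutoff at the point closest to
  (FPR 0, TPR 1), ties broken toward higher specificity, reported as the
  midpoint between the straddling observations. Binding measures
  discriminate high-is-disease, flow measures low-is-disease
  (configurable). AUC standard errors use Hanley–McNeil; pairwise AUC
  comparisons use DeLong's structural-components test (paired or
  unpaired).

Because single-cohort AUC differences between measures are dominated by
cohort sampling noise, the pattern checks (and the acceptance script)
average AUCs over six simulated study replicates. At the preset
conditions, the replicate-averaged AD-like cortical AUCs order
BP_ND > SUVR > sCBF — the washout measure is flow-corrected while SUVR
inherits variance from between-subject flow and from late-frame noise —
and the FTLD-like preset is flow-led (frontal sCBF AUC well above the
frontal BP_ND AUC, which stays near chance).

## Problem sizes

Tests and the acceptance script use: 225-point closed-form grids; cohorts
at the study sizes (16 or 5 patients vs 29 controls) with six replicates
for AUC averages; 50 replicates × 20 subjects for noise bias; 12×12×4
phantom grids for voxelwise null checks and a 16×16×16×28 phantom pipeline
(3 + 3 subjects) for the determinism check. These sizes keep the full
suite in the tens of seconds while leaving the statistical margins
comfortable.

## Known limitations

* The washout estimator carries a systematic, BP-dependent approximation
  error of up to ~10% against full compartment kinetics; it is not a
  substitute for SRTM fitting when absolute accuracy matters.
* m(0) as the literal frame maximum is noise-inflated (expected maximum of
  several noisy frames); at high noise this biases BP_ND downward through
  the denominator integral.
* sCBF inherits the temporal quantisation of time-to-peak (frame
  mid-times), which adds discrete jitter at modest noise.
* The site-specific sCBF calibration is only as good as the supplied
  target mean; without it the flow index is in arbitrary units and only
  comparable within a protocol.
* Left/right hemispheres are treated as one region unless the supplied
  mask distinguishes them.
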