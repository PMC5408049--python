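# Methods

This note records the modelling choices behind `ctmpi`, their defaults and
units, what the synthetic data do and do not emulate, and the numerical
conventions a maintainer needs.

## Forward model (phantom)

**AIF.** The arterial input is a gamma-variate bolus on a constant
baseline, parameterised by peak enhancement `amplitude` (default 300 HU —
typical descending-aorta enhancement for a 50 ml bolus at 6 ml/s and
100 kVp), arrival `onset_s` (8 s after contrast start), shape `alpha` (3)
and timescale `beta` (1.5 s), putting the peak at onset + α·β = 12.5 s.
The gamma variate is the standard first-pass bolus model: smooth, strictly
positive after onset, and cheap to fit. Its running integral has a closed
form in the regularised incomplete gamma function, which the whole package
uses instead of numerical quadrature.

**Tissue.** Each voxel's enhancement is the AIF above baseline convolved
with a flow-scaled plug-flow (box) impulse residue: contrast entering a
tissue element stays exactly `transit_time_s` (default 8 s) and then
leaves. The box residue makes the convolution analytic
(I(t) − I(t − T)) and makes the maximal-slope relation exact: as long as
the transit time exceeds the bolus rise time, the maximal model-curve
slope equals flow × AIF maximum, so the readout MBF = max slope / max AIF
recovers the generating flow identically. This is deliberate: the phantom
uses the same model family the estimator assumes, so estimator failures
measure estimation error, not model mismatch.

**Units bridge.** MBF in ml/100 ml/min equals flow per tissue volume in
1/s times 6000 (60 s/min × 100). The constant is `MBF_UNITS_PER_S`.

**Geometry and acquisition.** Short-axis annulus (defaults: endocardial
radius 8 mm, epicardial 14 mm) on a 160 × 160 grid of 0.35 mm pixels —
the clinical map pixel size at a desk-scale matrix; 512 × 512 works but
is pointless for tests. Two slices form the two shuttle stacks; each
stack is sampled once per two RR intervals (heart rate default 83 bpm,
the mean hyperaemic rate of the emulated protocol), the caudal grid
offset by one RR interval, first sample 5 s after contrast start,
12 time points per stack by default (range restricted to the 9–14
observed per patient). Sector wedges partition the annulus; each carries
a subepicardial flow, a transmural endo/epi ratio and a reference FFR.

**Transmural profile shape.** Two generators are provided. The default
`"step"` assigns ratio × flow to the inner half-wall and full flow to the
outer half; the endo-half/epi-half mean ratio (the phantom's true TPR)
then equals the requested ratio exactly, which makes TPR recovery
unambiguous to interpret. `"linear"` ramps the flow from ratio × flow at
the endocardial border to full flow at the epicardial border; its
half-means ratio is (3r + 1)/(r + 3), and it exists to test gradient
recovery along the profile. Both are non-decreasing with depth for
ratios < 1.

**Noise.** Additive i.i.d. Gaussian attenuation noise, default σ = 10 HU
(dynamic-perfusion noise level at 100 kVp with an iodine-robust kernel).
No beam hardening, no motion, no partial volume at the aorta — the aorta
is a homogeneous disk. A single integer seed drives the one RNG;
generation is bit-reproducible.

## Estimation

**AIF extraction.** Region-mean attenuation per time point, separately
for the cranial and caudal stacks, merged and time-sorted (double
sampling doubles the effective sampling rate of the input function).
Gamma-variate least squares (`scipy.optimize.curve_fit`, bounded,
deterministic initialisation from the samples). A region whose 10–90
percentile range is below 30 HU carries no bolus and is rejected
(`NoBolusError`); optimiser failure falls back to raw-sample maximum and
finite-difference slope, flagged `fit_converged = False`.

**Hybrid model fit.** Tissue model: baseline + flow × (fitted-AIF ⊛ box
residue, delayed). The fit is an exhaustive grid over transit time
(1–30 s, 1 s steps) and delay (0–10 s, 0.5 s steps) with the exact linear
least-squares solve for baseline and flow at each node (flow clamped to
[0, 0.1 /s] ≙ 600 ml/100 ml/min), refined by bounded nonlinear least
squares. No unseeded randomness anywhere; identical inputs give identical
fits.

**Maps and the SNR hierarchy.** For per-voxel maps the kinetic shape
parameters (transit, delay) are estimated once per stack from the
mask-mean curve and held fixed; each voxel then gets the exact linear
solve for flow and baseline only. Letting every voxel choose its own
(transit, delay) node makes the model chase noise and biases flow upward
by tens of percent at σ = 10 HU; with the hierarchy the sector-mean bias
is a fraction of a percent. The fully free per-voxel variant remains
available (`per_voxel_kinetics=True`) for exploratory use. Voxels with
non-finite estimates are dropped from the output mask. Slice resampling
to the clinical 3 mm / 1.5 mm stack is a property of the map metadata;
single- and two-slice phantoms are emitted unresampled.

**ROI measurement.** Freehand polygon ROIs are rasterised with
`skimage.draw.polygon`; the 50 mm² minimum is enforced as pixel count ×
pixel area (409 pixels at 0.35 mm), and ROIs must lie inside the map mask.

## Transmural perfusion ratio

Perpendicular sampling uses the local radial direction from the annulus
centre (exact for the circular phantom; a general centreline-normal
scheme would replace `WallBand` for non-circular masks). One line per
degree across the sector by default; bilinear interpolation at 0.4-mm
depth steps (sub-pixel sampling is required since pixels are 0.35 mm);
lines are averaged per depth into the profile. Values outside the mask
are nearest-neighbour filled before interpolation so border samples are
not contaminated by background.

Automatic endo/epi selection averages the profile over the [10 %, 35 %]
and [65 %, 90 %] fractional wall-depth bands, excluding the outermost
samples — manual picking is irreproducible, and the bands respect the
required distance from the lumen and epicardial borders where
displacement artifacts concentrate. Manual mode interpolates the profile
at two user-supplied depths. TPR is exactly endo / epi. Threshold
comparisons are inclusive: MBF ≤ 76 ml/100 ml/min and TPR ≤ 0.82 are
positive for ischaemia; FFR ≤ 0.80 defines the reference.

## Statistics

- **Cluster-adjusted CIs.** Territories cluster within patients. The
  proportion variance uses the cluster ratio-estimator form
  Σᵢ(xᵢ − p·nᵢ)² / N², which reduces *exactly* to the binomial Wald
  variance when every cluster has one territory and inflates under
  positive within-cluster correlation. No small-sample cluster factor is
  applied, so the singleton-cluster identity is exact.
- **AUC** by the Mann–Whitney construction with tie weight ½; the
  orientation convention is lower-score-indicates-disease.
- **DeLong** variance and correlated-AUC test from placement values;
  identical classifiers short-circuit to p = 1.
- **Youden** threshold scans the observed values with inclusive
  comparison; ties break toward higher sensitivity, then the lower
  threshold; perfectly separating classes return the midpoint of the
  separating gap.
- **ICC** is two-way, absolute-agreement, single-measure (ICC(A,1));
  a consistency variant is provided for comparison. **Kappa** is plain
  Cohen. **t-test** is pooled-variance by default with a Welch flag.
  **Effective dose** is DLP × 0.014 mSv/(mGy·cm).
- Display percentages round half away from zero; full precision is kept
  internally.
- The intermediate-flow sub-analysis filter (50–100 ml/100 ml/min) is
  inclusive on both bounds.

## Pipeline

`run_experiment` treats each seed as one synthetic patient (own noise
realisation, optional global flow jitter), measures one territory per
sector (mid-wall sector ROI for MBF, auto-mode TPR), classifies at the
published thresholds and writes territory CSV, metrics JSON (sorted keys,
byte-identical across reruns of the same config), a text report and a
SHA-256 manifest. Stage failures raise stage-tagged errors and preserve
partial outputs; turning the quantification stage off reuses existing
maps. `recovery_study` grids transmural ratio × noise × seed × global
flow scale and reports bias and RMSE for MBF and TPR; the scaling arm is
the operational test of TPR's scale invariance.

## What passing tests do and do not show

The phantom shares the estimator's model family, its aorta is noise-free
in shape, and there is no motion, beam hardening or partial volume.
Recovery results therefore bound estimation error under ideal physics,
not clinical accuracy. Stochastic guarantees are checked at desk scale
(e.g. the σ = 10 HU bias test uses 10 seeded phantoms, the recovery grids
a handful of cells) — sizes chosen so the whole suite runs in well under
a minute on one core while keeping Monte-Carlo error far below the
asserted tolerances. The published patient-level results (AUC 0.78 vs
0.65, mean ischaemic MBF 71.3) depend on unavailable clinical data and
are mirrored only qualitatively by the synthetic cohort generator used in
the DeLong power test.
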