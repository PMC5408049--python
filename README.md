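# ctmpi

Dynamic CT myocardial perfusion analysis in Python: a testable pipeline
from synthetic dynamic short-axis perfusion data through absolute
myocardial blood flow (MBF) quantification and the transmural perfusion
ratio (TPR) to a full diagnostic-statistics battery against an invasive
fractional flow reserve (FFR) reference.

## Who this is for

Researchers developing or validating quantitative perfusion indices from
dynamic contrast-enhanced CT. Patient CT-MPI data and invasive FFR
measurements are not publicly shareable, so every stage here is exercised
against a digital perfusion phantom with known ground truth: a short-axis
left-ventricular annulus at 0.35 × 0.35 mm pixels, imaged in shuttle mode
(two interleaved stacks of 9–14 time points at alternating table
positions), with a descending-aorta region carrying the arterial input
function (AIF) and sector-shaped perfusion defects with transmural flow
gradients.

## The model

Tissue enhancement follows a flow-scaled impulse-residue convolution of
the AIF. The AIF is a gamma-variate bolus; the residue is plug-flow
(a box of length equal to the transit time *T*):

    C(t) = C0 + F ∫ A(t − τ) R(τ) dτ,   R(τ) = 1 for 0 ≤ τ < T

with *F* the perfusion per unit tissue volume (1/s). The estimator fits
this hybrid deconvolution model (fitted AIF ⊛ box residue, plus baseline)
to each voxel's time–attenuation curve and reads MBF out as the
**maximal slope of the fitted model curve divided by the AIF maximum**:

    MBF = max_t dC/dt ÷ max(A) × 6000   [ml/100 ml/min]

(6000 converts 1/s to ml per 100 ml per minute). The TPR is measured from
the MBF map by sampling lines perpendicular to the myocardial surface at
0.4-mm depth intervals, averaging them into a transmural MBF profile, and
dividing the subendocardial by the subepicardial MBF read from depth bands
that avoid the artifact-prone lumen and epicardial borders. Territories
with MBF ≤ 76 ml/100 ml/min or TPR ≤ 0.82 are called positive for
ischaemia and compared against the FFR ≤ 0.80 reference with contingency
metrics (cluster-adjusted for territories nested in patients), ROC/AUC,
the DeLong test for correlated AUCs, Youden thresholds, Pearson r, ICC,
Cohen's kappa and the combined MBF × TPR index.

## Worked example

`examples/03_transmural_tpr.py` generates a phantom whose single sector has
subepicardial flow 91 ml/100 ml/min and a true endo/epi ratio of 0.64
(10 HU attenuation noise), quantifies the MBF map and measures TPR:

```
profile: 16 depth samples at 0.4 mm steps, averaged over 360 lines
auto selection: endo 58.5 at 1.4 mm, epi 89.8 at 4.6 mm -> TPR 0.65 (generated ratio 0.64)
worked example: TPR = 58/91 = 0.64 -> positive for ischaemia at the 0.82 threshold
```

The automatic measurement recovers the generated transmural ratio to
within 0.01 at this noise level, and the manual worked example — 58 over
91 ml/100 ml/min — gives TPR 0.64, below the 0.82 operating point and
hence positive for ischaemia. The other examples cover phantom generation,
MBF quantification (sector means within ~2 % of truth at 10 HU noise),
the diagnostic battery on a 94-territory synthetic cohort, and a
bias/RMSE recovery study whose global-flow-scaling arm shows the point of
a relative index: scaling all true flows by 0.7 moves absolute MBF
estimates by 30 % while TPR error is unchanged.

## Layout

- `src/ctmpi/phantom.py` — synthetic dynamic perfusion series + ground truth
- `src/ctmpi/kinetics.py` — gamma-variate AIF and box-residue tissue model
- `src/ctmpi/mbf.py` — AIF extraction, hybrid model fit, MBF maps, ROIs
- `src/ctmpi/transmural.py` — transmural profiles, TPR, territory calls
- `src/ctmpi/diagstats.py` — contingency/ROC/DeLong/Youden/ICC/kappa/dose
- `src/ctmpi/pipeline.py` — end-to-end runs, recovery studies, manifests
- `src/ctmpi/io.py` — NIfTI + JSON sidecar containers, CSV tables
- `examples/` — one narrative script per capability
- `docs/methods.md` — modelling assumptions, defaults and limitations
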