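# Methods

`rildseg` implements an automated five-class tissue classification
pipeline for radiation-induced lung damage (RILD) on thoracic CT, built
to be exercisable end to end on synthetic data. This note records the
model, its assumptions, the parameters that matter, and the design
choices made where the problem is genuinely open.

## Tissue classification model

Lung parenchyma is labelled voxel-wise with five morphological classes
of incrementally increasing density:

1. normal / emphysematous lung,
2. ground-glass-opacity-like change,
3. ground-glass opacity with overlaid reticulation,
4. mostly solid tissue just below dense opacity,
5. homogeneous dense tissue (consolidation, collapse, effusion, tumour).

Everything outside a given binary lung mask carries the sentinel label 0
and is excluded from training, inference and every evaluation sum. Lung
masks are assumed supplied (manually drawn in clinical practice);
automatic lung segmentation is out of scope.

## Segmentation method

The segmenter is an ensemble of 2D UNets operating on axial slices.

**Architecture.** Four reduction stages: encoder channel widths f, 2f,
4f, 8f with a 16f bottleneck; two 3×3 convolutions + instance
normalisation + ReLU per resolution level; 2×2 max-pooling down;
nearest-neighbour upsampling followed by a 3×3 convolution and skip
concatenation up; a 1×1 five-channel head read through softmax. The
convolution-block layout, optimiser (Adam, lr 1e-3 default, 3e-3 in the
desk-scale experiment) and batch size are conventional choices and are
all config-overridable.

**Losses.** Members differ by training loss — frequency-weighted cross
entropy (WCE), multiclass soft Dice (ε = 1 on numerator and
denominator), and Lovász-softmax (Jaccard-extension surrogate, averaged
over classes present in the batch) — and by base filter count. WCE
weights are inverse class frequencies w_c ∝ 1/π_c normalised to mean 1
and capped (default 100) for absent classes; no weighting formula is
canonical for this task, so the inverse-frequency form is declared as
this package's choice. All losses are computed over lung voxels only.

**Ensembling.** Member outputs are fused by summing pre-softmax logit
scores channel-wise and applying argmax once, so each member's
confidence enters the decision (unlike label voting). Presets:
stage one = {WCE·32, LV·32, LV·64}; stage two = {WCE, DC, LV} × {32, 64}.
No postprocessing is applied beyond re-imposing the lung mask.

**Preprocessing.** Anatomy outside the lung is replaced with air
(−1000 HU) before windowing; the fixed window [−1000, 100] HU maps
intensities to [0, 1]. Both values are declared choices: the masked fill
must be physically uninformative and the window must be robust to the
protocol variability (contrast, kernels, slice thickness 0.7–5 mm) that
the pipeline is designed around. Each volume receives one crop geometry:
the pooled axial bounding box of the lung mask placed symmetrically in
the fixed network input — (288, 384) for clinical-resolution scans,
rows = anterior–posterior — at native resolution when it fits, otherwise
shrunk by a single aspect-preserving isotropic factor s = min(H/h, W/w),
the minimal downscaling that fits. Labels are resampled
nearest-neighbour, images bilinearly. The inverse mapping is
source-driven: every lung voxel reads exactly one prediction pixel, so
map-back is exact at s = 1 and total at s < 1.

**Slice filtering.** Training slices are kept only if at least τ = 1%
of their lung area carries pathology (classes 2–5); the tie at exactly
1% is retained. The denominator is the slice's lung area, not the whole
slice. The filter applies to training-set construction only — inference
and evaluation always cover every lung-containing slice, since test
volumes must be fully labelled.

**Splits.** All splits are patient-level: every time point of a patient
shares a fold, preventing longitudinal information leakage. K-fold
(default K = 5) assignment is a seeded permutation dealt round-robin, so
fold sizes differ by at most one.

## Evaluation

The headline metric is the pooled ("global") Dice score per class:
DSC_c = 2·TP_c / (2·TP_c + FP_c + FN_c) with counts pooled over all
lung voxels of all scans in a set before the ratio. Pooling prevents
scans carrying a handful of voxels of a rare class from contributing
extreme per-scan scores with full weight. A class absent from both
prediction and truth across a whole set is *undefined* and reported as
missing — never as 0 or 1. Confusion matrices share the same pooled
counts; cross-validation summaries report mean, sd and the normal
approximation CI mean ± 1.96·sd/√K over folds, excluding (with a
warning) folds where a class is undefined.

Annotation-refinement tooling covers the bookkeeping side of two-stage
ground-truth generation: voxel-wise disagreement maps (fraction and
|Δclass| histogram), per-subset manual-vs-automatic choice fractions,
and the aggregation of ordinal 1/2/3 qualitative ratings (per-class
percentages plus a column-wise mean row). The human judgements
themselves are inputs, never computed.

## Synthetic phantom cohorts

Real RILD cohorts are not redistributable, so the generator emulates the
statistical structure the pipeline assumes: two ellipsoidal lungs in a
denser body; five HU distributions with strictly increasing means
(defaults −800, −550, −450, −200, +40 HU, spreads 50–70 HU, correlated
noise of length 1.5 voxels; class 3 carries an added zero-mean
high-frequency line texture as a reticulation analogue); lesions painted
as concentric severity shells of a smooth lateralised weight field — a
radiation-field analogue placed preferentially in one lung — whose total
volume grows linearly across the five follow-up time points (multipliers
0.25→1.75, mean 1); severe class imbalance (default targets 93.7 / 3.5 /
0.3 / 0.5 / 2.0% of lung volume, matching the regime such cohorts show);
and per-volume spacing drawn from 0.57–1.40 mm axial and 0.7–5 mm slice
thickness. The per-class HU statistics are artifact parameters — no
public per-class HU measurements exist for this task — chosen so classes
are separable in mean but overlap voxel-wise.

The phantom deliberately omits: airway/vessel/diaphragm anatomy, dose
distributions, motion and reconstruction artefacts, and inter-timepoint
anatomical change beyond lesion growth. Passing tests on phantoms
therefore demonstrate that the pipeline's mechanics (filtering,
geometry, losses, fusion, metrics, protocol) are correct and that the
ensemble can learn density-defined classes; they do not demonstrate
clinical-grade accuracy on real RILD, where class boundaries are
ambiguous and artefacts dominate the failure modes.

## Reference experiment and problem sizes

The frozen desk-scale experiment (`rildseg.experiments`) uses 8 patients
× 5 time points on 48×64×96 grids — 6 patients for training, 2 held out —
a (64, 96) network input, base filters 4 and 8, and 200 Adam steps
(batch 2, lr 3e-3) per member. The (64, 96) input is the package's
reference sizing for these phantom grids: their lung bounding boxes fit
it at native resolution, so no slice is downscaled and the crop-and-fit
logic is exercised exactly as at clinical sizes. One integer seed
determines cohort, initialisations and shuffling end to end.

## Numerical choices

* Probabilities are clamped at 1e-12 before logs; losses never return
  non-finite values on the simplex.
* Soft-Dice ε = 1 on numerator and denominator (prevents 0/0 for absent
  classes).
* Max-pool gradient routes to a single argmax element per window (first
  occurrence on ties).
* Training is float32; gradient verification runs in float64.
* Grid alignment tolerance for spacing metadata: 1e-3 mm; loaders
  reject, never repair, mismatches.
* Equal-error ties in the Lovász sort are broken by stable argsort, so
  results are order-deterministic.

The networks and losses run on a purpose-built reverse-mode autodiff
tensor engine (`rildseg._tensor`) whose convolutions are im2col + BLAS
matrix products; analytic gradients are validated against central finite
differences in the test suite.

## Known limitations

* Phantom realism as described above; no artefact or dose modelling.
* 2D slice-wise segmentation only; no 3D context beyond the optional
  adjacent-slice input channels (off in all presets).
* CPU-scale training: the reference experiment recovers the dominant
  class (1) and the high-contrast consolidation class (5) reliably; the
  thin-shell intermediate classes are harder, and class 3 — the
  thinnest, lowest-volume shell — can be missed entirely at this scale.
  The difficulty ordering mirrors what full-scale clinical work reports.
* The CI formula is a normal approximation over K = 5 folds; with so few
  folds it is descriptive, not inferential.
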