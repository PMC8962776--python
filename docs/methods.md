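# Methods

## Problem and model

Age-related macular degeneration (AMD) is graded on color fundus
photographs (CFPs) with a 12-step ordinal severity scale; severities
10–12 denote advanced (late) AMD, which is irreversible.  Visits sit on
a 6-month grid (index 0–26).  For a chosen gap `T` (in 6-month units),
every available visit pair `(x_t, x_{t+T})` of an eye receives a
3-class label

* `y = 0` — neither visit advanced,
* `y = 1` — not advanced now, advanced at the future visit,
* `y = 2` — both visits advanced,

with `(advanced, not advanced)` impossible by irreversibility (the
package raises on such input).  A CNN classifier predicts `y` from the
*first* image alone, so one forward pass simultaneously grades the
current visit (`y = 2` ⇔ advanced now) and forecasts the future one
(`y ∈ {1, 2}` ⇔ advanced at `t + T`).  Pair populations are heavily
dominated by `y = 0`, so training uses

* normalized inverse-frequency class weights
  `w_k = (1/h_k) / Σ_j (1/h_j)` from the training-histogram `h` inside a
  weighted cross-entropy `−mean(w_y · log p_y)` (we average per batch —
  the population objective is a sum, and the per-batch mean is its
  standard stochastic estimator with learning-rate invariance), and
* per-eye down-sampling: all pairs with `y ≠ 0` are kept, and zero-label
  pairs are reduced to `min(m, max(1, n))` randomly chosen ones, where
  `n` and `m` count the eye's nonzero and zero pairs.

A conditional GAN forecasts the future image itself: a U-Net generator
`G` maps `x_t` to a candidate `x_{t+T}`, and a patch discriminator `D`
scores overlapping patches of the 6-channel `(x_t, candidate)`
concatenation, enforcing that the forecast keeps the eye's fixed
anatomy (optic disc, vessel arcades) while lesions may progress.  The
objective is the conditional minimax game plus an L1 reconstruction
term weighted by `λ_r` (default 100).  The generator is trained with
the non-saturating surrogate (`maximize log D(x, G(x))`) because direct
minimization of `log(1 − D)` stalls early; the printed-form
log-likelihood terms are still what `gan_losses` reports.  Dropout in
the innermost decoder blocks — not an input noise vector — is the
source of generation stochasticity; the `stochastic` flag keeps it
active at generation time (pix2pix-style) and defaults to off so
forecasts are reproducible.

## Networks

No deep-learning framework ships in this package's dependency set; the
networks run on a compact NumPy layer stack (`fundusprog.nn`) with
explicit backprop — strided and transposed convolutions, instance
normalization, dropout, dense layers, Adam.  Every layer is verified
against central finite differences in the test suite, and backward
passes return input gradients, which the generator update and the
saliency maps rely on.

* **Classifier** — a width-scalable residual CNN: three stride-2
  convolution stages with normalization-free residual blocks, global
  average pooling, and an affine head.  `width_scale=1` corresponds to
  a 64-channel trunk; the desk-scale default in the workflows is 0.25.
  With `age_fusion` the age scalar (divided by 100) is concatenated to
  the pooled feature vector before the head.  A `pretrained` flag
  exists for parity with full-scale runs but raises here: no weights
  are bundled.
* **Generator** — a symmetric U-Net (default depth 8 at 256 px; the
  desk-scale study uses depth 6 at 64 px), LeakyReLU(0.2) encoder,
  ReLU decoder with skip concatenations, tanh output in [-1, 1].
* **Discriminator** — the classic 70×70-patch critic: kernel-4
  convolutions with channels (64, 128, 256, 512) and strides
  (2, 2, 2, 1) plus a 1-channel scoring convolution.
  `receptive_field` computes the patch size by the standard recursion
  (`rf += (k−1)·jump; jump *= s`), and is checked against a
  gradient-support oracle.  With zero padding a 70×70 input collapses
  to exactly one score; training uses padding 1 so that 64-px images
  keep a multi-patch score grid.

## Training protocol

Classifier: Adam (lr 1e-3 at desk scale, β = (0.9, 0.999)), batch 32,
default 20 epochs; the model is evaluated on the validation split every
50 optimizer steps (25 at desk scale) and the checkpoint with the
lowest validation weighted cross-entropy is kept.  Across a
hyperparameter sweep, `sweep_select` picks the checkpoint with the
highest validation Hand–Till AUC, ties broken by lower loss, then
earlier iteration.  GAN: Adam (lr 2e-4, β = (0.5, 0.999)), batch size
fixed at 1 so generated samples never share normalization statistics,
200 epochs with the learning rate constant for the first 100 and then
decayed linearly to exactly 0; both the final and the
best-validation-L1 generator states are retained.

## Evaluation

* `confusion_matrix`/`accuracy` on the 3-class problem; binarization of
  the current-visit grading collapses labels {0, 1} into "not
  advanced" (TP = c[2,2], FN = c[2,0]+c[2,1], TN = Σ c[0:2,0:2],
  FP = c[0,2]+c[1,2]).
* Hand–Till multiclass AUC: the mean over unordered class pairs of
  `(A(i|j) + A(j|i))/2`, each term a rank-based one-vs-one probability
  with ties counted ½; class pairs with an absent class are skipped
  (with a warning) and the normalization adjusted.  Verified against
  exhaustive pair enumeration and scikit-learn's one-vs-one AUC.
* Percentile bootstrap (default B = 2000, 95%) resampling at the pair
  level; failing resamples are redrawn and counted.
* Sequential pipelines: `gan3c` (classify the generated future image,
  decode its *current* status), `ganB` (binary grader on the generated
  image), and the classifier-only baselines `first3c` (decode the
  *future* bit from the real first image) and `second3c` (grade the
  real second image).  Ground truth is the second visit's advanced
  status.  If generator and classifier resolutions differ, the
  generated image is resized before classification.
* Saliency: plain input-gradient maps — channel-maximum absolute
  gradient of the target-class score, normalized to [0, 1].  The
  method name is deliberately the simplest one matching "highlight the
  influential regions"; nothing fancier is claimed.

## Synthetic cohort

Real longitudinal AMD imaging cohorts are controlled-access, so the
`phantom` module generates schematic stand-ins that preserve what the
method actually relies on:

* per-eye fixed anatomy — optic disc position (nasal side per eye),
  six quadratic-Bezier vessel arcades, base pigmentation — a pure
  function of a geometry seed, bit-identical across the eye's visits;
* severity follows a monotone random walk: per 6-month step an
  increment of 1–`max_step` levels with probability `step_up_prob`,
  absorbing at 12;
* lesions driven by severity: a per-eye list of candidate drusen
  (macular annulus placement) is revealed and enlarged monotonically
  with severity, so drusen area is non-decreasing by construction;
  severities ≥ 10 add a large late-AMD feature (pale atrophic patch or
  dark neovascular blot, chosen per eye);
* heterogeneous visit schedules: a 6-month grid (default every other
  index, 0–26) with independent visit drop-out (default 0.15).

Defaults (`step_up_prob = 0.08`, `max_step = 2`, onset-severity mass
concentrated at low severities with ≈ 8.8% advanced at baseline) were
calibrated once, by simulation, so that gap-4 pair labels land near the
published cohort imbalance (≈ 84% / 3% / 13%); the generator realizes
≈ 81% / 2.5% / 16% and the calibration was not revisited afterwards.
What the phantoms deliberately do not model: photorealistic texture,
illumination/camera artifacts, inter-visit misregistration, grading
noise, and correlation between a subject's two eyes (each progresses
independently).  Consequently, passing the synthetic end-to-end checks
shows the pipeline is wired correctly and can learn severity-driven
image structure — it does not certify clinical-grade performance on
real fundus photographs.

## Desk-scale study sizes

The end-to-end benchmark (`fundusprog.workflow.run_synthetic_study`)
uses 300 subjects at 64 px, gap T = 4: roughly 1,500 balanced pairs,
a width-0.25 classifier trained 10 epochs (validation every 25 steps),
and a depth-6/12-channel GAN trained 5 epochs on 250 pairs with the
learning rate held constant (decay would zero the final epoch of such a
short run).  These sizes keep the whole study at a few minutes on one
CPU core while leaving all acceptance margins wide.

## Numerical and design notes

* Probabilities are clamped at 1e-7 inside every log.
* Preprocessing: center square crop (fundus images are
  macula-centered) then bilinear resize; pixel intensities scaled to
  [0, 1]; the GAN maps to [-1, 1] internally.  No flips, mirrors or
  rotations, ever — they would scramble the anatomy the discriminator
  conditions on.  The full-scale protocol's crop "around the macula"
  is realized as the centered square, the simplest crop consistent
  with macula-centered imaging.
* Split sizes: train = ⌈0.9·N⌉, val = ⌈0.05·N⌉, test = remainder —
  reproducing the reference cohort's 4,166/232/230 at N = 4,628.
* The down-sampling procedure is applied per *eye* (the more specific
  reading of the protocol; the alternative per-subject reading would
  pool both eyes' pairs before sampling).
* A class absent from the training histogram is an error rather than
  an infinite weight; callers may merge classes or resample.
* Non-monotone severity in a manifest warns by default and raises in
  strict mode; silent repair would hide grading errors.
* Bootstrap intervals are percentile-type, resampled at the pair
  level.
* Classifier inputs default to 224 px and the generator to 256 px at
  full scale; sequential evaluation resizes generated images to the
  classifier's resolution.

## Known limitations

Single-CPU NumPy training limits practical problem sizes; the phantom
cohort omits the real-data nuisances listed above; multi-step
forecasts compound one-gap models and inherit their drift; and only the
printed-table arithmetic of the reference cohort is reproduced here —
no claim is made about re-training on the controlled-access data.
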