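# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `strokehier`, and what the synthetic study conditions do and
do not establish about real data.

## Synthetic cohort

The cohort generator draws a binary LVO label at prevalence 130/300 = 43.3%
and then samples every Level-1/Level-2 variable from class-conditional
distributions. Continuous variables are normal with the published per-class
means; their SDs are back-solved from the 95% confidence intervals of the
mean at the observed-case counts (SD = half-width × √n / 1.96), since only
means and CIs are reported. Categorical variables follow the per-class level
counts; where a printed percentage disagrees with its count (the non-LVO
female row), the count wins.

Linked blocks are sampled jointly so records are internally coherent:

- **GCS** — eye/verbal/motor subscales are rounded, range-clipped normals
  (eye 1–4, verbal 1–5, motor 1–6); the total is their sum, so it always lies
  in 3–15 and equals the subscales when all are observed. Totals and
  subscales are masked at their own missingness rates (totals are missing
  less often than subscales, as in registry data where a total is charted
  without its breakdown). Rounding and clipping shift the realised means by
  a few hundredths of a point; this is accepted rather than corrected.
- **Limb weakness** — presence is drawn first; laterality is then
  left-only / right-only / both with probabilities chosen so the left and
  right marginals match (the printed counts imply 3 and 7 bilateral cases in
  the two classes).
- **Facial weakness** and **smoking** — an "ascertained" indicator is drawn
  first; when false, all variables of the block are missing together (the
  shared Unknown mass in the source tables). Current and ex-smoker are a
  partition of ever-smokers, which the printed counts support exactly.
- **Blood pressures** are jointly observed or jointly missing.
- Registry comorbidity flags (atrial fibrillation, atherosclerosis,
  cardioembolism, valvular disease) have levels {yes, not-recorded}: absence
  of a diagnosis code is *not* a verified "no", so the generator emits
  missing, which downstream modelling recodes as the `Unknown` category.

Missing cells are NaN in memory and empty cells in CSV; the literal string
`Unknown` is introduced by the modelling layer (`encode_unknown`), not the
generator, so the same cohort file serves both the raw and the imputed path.

Randomness: one integer seed per study, split into named substreams
(`cohort`, `phantom-<i>`, `deep-features`, `patch-selection`) via
`np.random.default_rng([seed, crc32(name)])`, so partial re-runs reproduce
individual pieces bit-for-bit.

## Phantoms

A phantom volume is an elliptical "brain" (≈30 HU, Gaussian texture noise
SD 2) inside a 150 HU skull ring on a 512×512 grid, 10 slices of 5 mm. The
hyperdense-sign lesion is a disc of radius 2–6 px at 45–75 HU — inside the
(20, 80] attenuation window so it survives pre-processing — placed on one
candidate slice within a disc of radius 20 px around one hemisphere ROI-box
centre (the proximal Sylvian zone is described anatomically, not by
coordinates, so a fixed disc at the box centre is used; the radius keeps the
lesion inside the tiny profile's 64×64 centre crop). Distractor dots at
90–200 HU mimic calcifications and vanish under the window. Sign presence is
drawn from P(sign | LVO) = 68/130 and P(sign | no LVO) = 6/170.

Under these conditionals P(LVO | sign) = 68/74 ≈ 91.9%. The source material
prints 97.1% beside the same counts; 68/74 is what the counts give, and the
generator follows the counts.

The phantoms deliberately omit CT physics (beam hardening, noise spectra,
partial-volume effects), anatomical texture, and posterior-circulation
anatomy. Passing tests therefore demonstrate that the pipeline's geometry,
bookkeeping and learning dynamics are correct — not that the segmenter would
reach the same Dice on clinical scans.

## Pre-processing

Brain extraction keeps, per slice, the largest connected component of voxels
between the air threshold (10) and the skull threshold (100), closed with a
radius-2 disc. Registration estimates a single in-plane rotation+translation
for the whole volume: the brain-mask centroid fixes the translation, and the
rotation maximises the Pearson correlation between the mean brain-masked slab
and its mirror across the mid-row axis, by grid search over ±15° in 0.5°
steps with a 0.1° local refinement; if symmetry would not improve, the
identity is used and a warning issued. Windowing zeroes voxels outside
[20, 80] after a 3×3 median filter (out-of-window values are zeroed, not
clipped, to suppress skull/CSF rather than saturate them). Cropping takes
0-based half-open boxes rows 128:256 and 256:384 × cols 212:340 on slices
4–9 (1-based, six slices), giving 12 patches; the stated "4th–10th" range
conflicts with "six slices" and "12 scans", and six slices is the reading
consistent with both other statements.

## Segmentation network

No deep-learning framework is used: the encoder–decoder is implemented in
numpy (im2col convolutions, manual backpropagation, Adam), float32 by
default, and is verified against central finite differences in the test
suite. Architecture: one 3×3 conv + ReLU per encoder scale with channel
doubling from `base_channels`, 2×2 max pooling, a two-conv bottleneck with
`base × 2^depth` channels (1024 at the full profile), nearest-neighbour
upsampling with one conv, concatenation with the matching encoder skip, a
merge conv, and a 1×1 sigmoid head. Logits are clipped to ±25 so float32
sigmoids never saturate to an exact 0/1 (which would zero gradients
irrecoverably).

Training uses the soft-count Tversky loss with α = 0.3, β = 0.7 (false
negatives penalised harder — the recommended regime for small lesions),
smoothing 1e-6, and hard-negative mining that keeps every lesion-positive
patch plus the `ratio × n_pos` highest-loss negatives (ratio 3; a batch with
no positives keeps its single hardest negative). Batches are stratified so
each contains positives whenever any exist. The smoothing constant must stay
small: a large constant flattens the positive-patch loss while retaining a
constant false-positive push on empty patches, which drives the whole output
to zero.

The loss landscape has two degenerate attractors observed empirically at
desk scale — all-zero output (saturated sigmoid, dead gradient) and
indiscriminate over-prediction — and which basin a run lands in depends on
both the weight init and the learning rate. Three stabilisers address this:
(i) global gradient-norm clipping at 5 (typical norms are ~1–3; the spikes
that destroy an already-converged net exceed 1000); (ii) model selection by
best epoch-wise hard Dice on the *positive* training patches rather than by
the mined loss — the mined loss actively favours the collapsed state,
because with small smoothing an all-zero output scores empty patches as
perfect; and (iii) quality-gated restarts: an attempt whose best
training-positive Dice stays below 0.65 (healthy runs reach 0.8–0.9) is
retried from a fresh init substream with the learning rate cycled through
{1, 0.5, 2, 0.25}× the configured rate, up to six restarts, returning the
best attempt overall. All-zero collapse is probed a few epochs in so failed
attempts abort cheaply. The whole procedure is a deterministic function of
the seed.

Study-scale training settings (Adam 1e-5, β₁ = 0.9, 200 epochs, batch 16)
are the configuration defaults; the desk-scale runs used across the analysis
scripts, tests and acceptance report use the tiny profile (64×64 centre
crop, depth 4, base 8, bottleneck 128), learning rate 1e-3 and 30 epochs on
60 phantom patches — sizes chosen so a full run of the suite remains a
minutes-scale, single-CPU affair. "Momentum 0.9" for Adam is read as the
first-moment decay β₁.

Feature extraction: predicted masks are binarised at 0.5; per patient, the
candidate slice with the largest predicted area is selected (the third slice
of the range when no lesion is predicted anywhere; ties go to the earliest
slice); both hemisphere patches of that slice pass through the
global-max-pool head and the per-channel maximum of the two is the feature
vector. Taking the max across hemispheres makes the vector invariant to
lesion side, preserving the strongest evidence from either hemisphere; the
alternative (a single composite image) is not well defined for a
patch-input network.

## Feature screening and level assembly

Each deep channel is tested with a pooled-variance two-sample t-test between
LVO classes; the 10 smallest p-values win, ties broken by channel index, and
zero-variance channels receive p = 1. Screening is fit on training patients
only and the frozen indices applied to test patients — the conservative
reading where the source is silent, chosen to avoid selection leakage.
Level-1/2/3 tables nest by construction with deterministic column order.

At cohort scale the Level-3 block is produced by `simulate_deep_features`:
a sign indicator drawn from the class-conditional sign probabilities plus
Gaussian channels, 8 of 64 shifted by 1.5 SD when the sign is present. This
emulates what the trained extractor contributes — imaging channels
informative about LVO only through the sign — at a cost that permits
multi-seed experiments; the image path itself (phantom → pre-processing →
trained network → 1024 features → screen) is exercised at small n in the
tests and the acceptance report. The effect size and channel counts were
fixed a priori as a plausible mid-strength imaging signal.

## Learners and missing data

KNN-median imputation: distances are Euclidean over jointly observed
continuous features standardised by training mean/SD, rescaled by
√(p/p_observed); a missing cell takes the median of its column among the
k = 5 nearest training rows that observed it, falling back (with a warning)
to the training-column median when none did. k is unstated in the source;
5 is the conventional default. One-hot encoding freezes category levels at
fit time.

Stepwise logistic regression alternates backward elimination (Wald
p > 0.10) and forward inclusion (p < 0.05), banning a just-removed term from
re-entering within the same sweep to prevent cycling; perfect separation or
non-convergence falls back to an L2-penalised fit with a warning. Random
forest: 500 trees, √p features per split, probability = mean per-tree class
frequency. SVM: RBF kernel, C and γ from a small cross-validated grid,
sigmoid (Platt-type) probability calibration, and the feature set restricted
to the boosting model's positive-total-gain features — the SVM refuses to
fit without an externally supplied list. XGBoost: 300 rounds, depth 4,
learning rate 0.1, fit on the raw table (missing values routed by learned
default directions); fixed rounds were preferred over early stopping on a
further validation split, which at n_train = 200 destabilised the
cross-validated cutoff more than it helped. None of the tree/kernel
hyperparameters are stated in the source; all are exposed in configuration.

Importance reports scale total gain so the top feature is exactly 1.0, sort
descending, and omit entries below 0.01.

## Evaluation

γ = sensitivity + specificity − 1 exactly. Cutoff selection pools
out-of-fold scores from stratified 10-fold CV (models refit per fold with
the family's full missing-data policy), scans the unique observed scores as
candidate thresholds, and returns the smallest threshold attaining the
maximal empirical γ; a score equal to the cutoff counts as positive. Pooling
was chosen over per-fold cutoff averaging because a single operating point
per model is reported. AUC is the trapezoidal/concordance value.

The univariate engine routes 2×2 tables to Pearson chi-square with Yates
correction (Fisher's exact when any expected cell is below 5), and
three-level tables — Unknown counted as a real level — to the plain Pearson
chi-square with df = 2, whose tail is the closed form exp(−χ²/2). This
routing reproduces the source's atrial-fibrillation, smoking and facial
weakness p-values exactly. The source's own test choice is not fully
consistent across rows (its limb-weakness p matches Fisher's exact on a
table with expected counts ≈ 20, while its cardioembolism p matches Yates);
rows that no single routing reproduces are reported by the engine under its
stated rule and not asserted against.

Printed-performance identities: the integer confusion matrix on the
100-patient test group is recovered from a printed (recall, specificity,
accuracy) triple by exhaustive search over positive-count and cell values,
requiring uniqueness at the printed rounding; F1 and γ then follow from the
matrix.

## Orchestration and leakage control

The train/test split (200/100) is stratified by label. Every training-time
decision — screening indices, Unknown encodings, imputer state, stepwise
selection, the SVM's feature hand-off, the cutoff — is a function of the
training split only; the audit in the test suite permutes test labels and
verifies that no trained artifact or test score changes.

## Known limitations

- Phantom realism is intentionally minimal (see above); Dice values are not
  transferable to clinical CT.
- The numpy network is single-threaded and desk-scale; the full 128×128
  depth-5 profile is exercised for shape/feature contracts and short fits,
  not to convergence.
- The cohort generator models class-conditional independence except in the
  explicitly linked blocks; real comorbidity correlations (e.g. hypertension
  with age) are not reproduced.
- Registration is strictly 2-D rigid with one transform per volume; strong
  per-slice motion would defeat it.
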