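# Methods

`ngtlife` implements the statistical and machine-learning lifecycle of a
nasogastric-tube (NGT) position classifier for frontal chest radiographs:
cohort curation, a multi-resolution CNN ensemble, latent-space attribution,
a concept-drift monitor, and the evaluation/agreement suite. Real NGT
archives cannot be redistributed, so every component is exercised on a
synthetic cohort generator that reproduces the *statistical shape* of such
an archive at desk scale. This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic results
demonstrate.

## The synthetic cohort generator

`synth.generate_manifest` draws records with three tube-position classes —
`satisfactory`, `malpositioned`, `bronchial` — at prior
(4100, 2500, 481)/7081 by default, the class mix of the archive this
package models. Patients carry 1–3 records; sex is drawn at a 1.4:1
male:female ratio and patient age from N(66.5, 16²) years truncated at 16,
matching the demographic profile of adult inpatient chest radiography.
Dates are ISO-8601; age is always derived (study date − birth date), never
stored.

Images (`synth.render_image`) are crude but geometrically faithful
radiograph stand-ins on a 16-bit gray scale: a fixed thorax background
(body ellipse, dark lung fields, bright mediastinum) with a bright tube
polyline entering at the top edge. The tip lands in a class-specific
region — a lower "stomach" box (satisfactory), a mid "esophagus" band
(malpositioned), or a lateral branch beyond the carina (bronchial) — and
carries a brighter radiopaque marker blob, as real NGT tips do; the marker
makes the tip the distinctive local cue, so saliency maps of a correct
classifier concentrate there rather than along the shared tube path. The
geometry is deliberately fixed by module constants; only intensity and
noise are configurable, so the class signal stays learnable by a small CNN
in minutes.

Acquisition metadata leaves a pixel-level trace, as it does in real
archives: each manufacturer adds a uniform intensity offset (0/120/240
gray-levels by default), departments add 60 per level, and age adds
3 gray-levels per year from a 65-year reference. These values are a
modeling choice — the pixel-level differences between real radiography
systems are not characterized anywhere we could borrow from — and they are
set small relative to the tube signal (≈20 000 gray-levels) so that the
class label, not acquisition metadata, dominates any learned embedding.
That calibration reproduces the qualitative attribution pattern of
deployed classifiers: label R² first by a wide margin, metadata tags a
small cumulative fraction.

Label–metadata confounding is induced by sampling each record's
manufacturer from its class-linked level with probability
`w = sqrt(label_tag_r2)` and uniformly otherwise (default target R² 0.07,
weak confounding). The square-root rule is an approximate one-parameter
calibration: for balanced levels the regression R² of a deterministic link
diluted by a (1−w) uniform mixture scales as ≈ w².

Drift injection (`apply_drift`) supports: `mean_shift` (adds k per-dimension
SDs to embeddings), `age_band` (filters a cohort or tagged embedding set to
an age window, erroring when empty), and `manufacturer_swap` /
`department_swap`. The swaps source *every* candidate record from one
single level (default: the rarest). An earlier design that relabeled each
record to the next level was discarded: it preserves the pooled level mix
exactly, and a distributional monitor cannot — and should not — react to a
relabeling that changes no marginal distribution.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` spawn keys, with per-record render streams keyed
by record index, so a single image can be regenerated without replaying the
cohort.

## Curation

Quality control retains records with width ≥ 1024 **and** height ≥ 1024
pixels, a body part containing "chest" (case-insensitive), AP or PA view,
and age ≥ 16 years at the study date; each exclusion is logged once with its
first failing rule, and malformed or absent fields exclude with
`missing_field` rather than crashing. The age boundary uses true calendar
arithmetic (birth date + 16 years, Feb-29 births falling back to Feb-28):
a patient is retained from their 16th birthday exactly, regardless of how
many leap days the interval contains.

Report retention is a case-insensitive regex over the raw text for any of
`nasogastric, tube, placement, insertion, bronchus` — substring matching
with no stemming, so behavior is transparent and auditable.

Consensus labels are majority votes of exactly three raters; a three-way
tie returns *no consensus* and the record is excluded from downstream
agreement metrics. Resolving ties silently (e.g. "first rater wins") would
bias κ, so they are surfaced instead.

The 90/5/5 split is patient-grouped and stratified on (label, sex, view).
Exact grouped stratification is infeasible in general, so patients —
shuffled by seed, filed under their modal stratum — are greedily assigned
to the split with the largest remaining record deficit for that stratum.
Realized fractions outside the tolerance (±2 percentage points by default)
warn and flag the result rather than raising: a best-effort split is more
useful than an exception, and the flag keeps it honest. Patient
disjointness and full partition are asserted on every run.

## Classifier and training recipe

The backbone is a small conv–GAP–dense network written directly in numpy:
repeated [3×3 same-padding convolution → ReLU → 2×2 max pool] blocks
(widths (8, 16, 32) by default), global average pooling — whose output is
the image's latent embedding — then a ReLU dense layer (width tunable in
[32, 512]), dropout (rate in [0, 0.2]) and a softmax head. The backward
pass is explicit and verified against finite differences to ~1e-10, which
is also what makes Grad-CAM gradients available without a framework.

The *recipe* is the contract: inputs are resized by bilinear interpolation
ignoring aspect ratio; training uses Adam at 1e-3 on categorical
cross-entropy in batches of 32; each training batch is augmented with
brightness scaling (±10 %), rotation (±5°) and horizontal flips (p=0.5) —
magnitudes are our choice, kept modest because geometry carries the class —
and validation/test passes are augmentation-free. Training stops when the
validation loss has not improved for `patience` (default 10) consecutive
epochs or at `max_epochs`, and the weights of the best validation epoch are
restored. Hyperband tuning implements the standard bracket bookkeeping
(s_max = ⌊log_η R⌋; successive halving keeps the best third per round) with
every trial retrained from scratch at its round's epoch budget and logged.

The ensemble averages constituent probabilities arithmetically. Default
input sides are (48, 64), a desk-scale stand-in for a production
low/high-resolution pair; sides are fully configurable. The combined latent
space of an ensemble is the column-concatenation of the constituents' GAP
vectors.

Grad-CAM weights each final-conv channel by the spatial mean of
∂(class logit)/∂(activation), rectifies the weighted sum, and bilinearly
upsamples to the query image's resolution. With GAP immediately after the
final convolution the channel weights are spatially uniform, so the map
coincides with the classical class-activation map — a well-known and, here,
desirable identity. The saliency reported for an ensemble is the mean of
the constituents' maps after upsampling to the query image, which both
matches the deployed predictor and averages away single-constituent
artifacts.

Desk-scale problem sizes used by the test suite and the acceptance script:
1500 training / 75 validation / 300 test images at 64 px, two constituents
at sides (48, 64), ≤ 8 epochs. Under those conditions the ensemble reaches
one-vs-rest AUC ≥ 0.90 for every class with a wide margin, and saliency
concentrates within 15 px of the planted tube tip on ≥ 80 % of correct test
classifications.

## Parametric 2-D reduction

Two backends share one fit/transform interface. The `linear` backend
projects onto the top-2 principal directions (SVD, signs fixed by the
largest-magnitude loading) and exists so that attribution and drift can be
tested against closed-form oracles. The `triplet` backend is the fidelity
path: anchors are paired with one of their k = 15 exact nearest neighbors
(positive) and a random non-neighbor (negative) and a small numpy MLP
(d → 32 → 2) is trained with a squared-distance margin loss. Two numerical
choices matter:

* inputs are centered and scaled by a single global factor — per-feature
  standardization would flatten exactly the high-variance directions that
  carry cluster structure;
* the output layer is warm-started by least-squares regression of the
  random ReLU features onto the top-2 principal coordinates, so triplet
  refinement starts from a globally sensible layout. Margin triplets with
  local positives are good at *preserving* structure but poor at
  *discovering* it from a random collapse.

The triplet backend is seed-deterministic but, like any neural reducer, not
canonical; exact out-of-sample consistency is asserted only for the linear
backend.

## Attribution

For each metadata tag the two embedding coordinates are regressed on the
encoded tag by least squares and the pooled
R² = 1 − RSS/TSS is reported (RSS, TSS summed over both coordinates).
Numeric tags are one standardized column; age enters as the exact day count
between study and birth dates. Categorical tags use reference-level
indicators with missing values as their own level; this makes single-tag R²
identical to the pooled η² of a group-means analysis, which the tests
exploit as an oracle. Joint ("cumulative") R² regresses on concatenated
encodings via `lstsq` (pseudoinverse), so rank-deficient encodings are
safe, and is monotone in the tag set by construction. Constant tags return
R² = 0 with a warning, never NaN. R² is computed on the 2-D reduced
coordinates by default (the raw latent space can be passed instead — every
function takes an arbitrary n×2 or n×d coordinate matrix). No significance
tests are attached to R²; at the cohort sizes involved the estimates'
sampling error is not the limiting uncertainty.

## Drift monitor

The detector is a classifier two-sample test: a random forest (500 trees by
default) learns to discriminate reference coordinates (label 0) from a
candidate batch (label 1); each point's out-of-bag (OOB) probability of
being "candidate" is collected; and the two groups' OOB probability
distributions are compared with a two-sample Kolmogorov–Smirnov test. Under
no drift the forest cannot separate the groups and P is large; under drift
the distributions diverge and P collapses. `monitor` repeats this over
`n_batches` = 50 random batches of `batch_size` = 100 and flags drift when
the median P falls below α = 0.01; the per-batch P values give the box-plot
summaries a deployment dashboard would track, and the last batch's
per-point OOB probabilities serve as image-level outlier scores.

KS P values use exact enumeration when n·m ≤ 10 000 with no cross-sample
ties, and the asymptotic Kolmogorov distribution otherwise. The exact path
is verified against a full enumeration oracle (the disjoint 4+4 example has
P = 2/70) and the null level is verified by Monte-Carlo.

Two numerical caveats discovered during development are part of the
method's honest contract:

* **Exact duplicates are uninformative and must be removed.** If a
  candidate row is byte-identical to a reference row, each point's OOB
  trees contain its oppositely-labeled twin at the same coordinates, and
  the test rejects with certainty even for identical samples. Matched
  duplicate pairs are therefore dropped one-for-one before training; a
  fully duplicated batch reports D = 0, P = 1 (no evidence of drift). This
  also makes "monitor the reference against itself" a clean negative
  control.
* **Per-batch P values are anticonservative at loose thresholds.** Because
  the forest is trained on the very group labels being tested, OOB scores
  covary with chance spatial imbalance between the groups; at α = 0.05 the
  per-batch type-I rate is ≈ 0.13–0.16 rather than 0.05, across tree
  depths, leaf sizes and sample sizes, and a permutation of the computed
  OOB values does not repair it (the dependence is in training, not in the
  comparison). At the monitor's operating threshold α = 0.01 the rate is
  ≈ 0.04–0.06, and the *median*-P drift flag is robustly calibrated: the
  null median P sits near 0.3–0.5. Users should treat the per-batch P as a
  ranking/monitoring score and the flag as the decision output; a fully
  calibrated per-batch P would require refitting the forest under label
  permutations, which is out of proportion for a monitoring loop.

## Evaluation and agreement statistics

Per-class metrics are one-vs-rest binomial proportions with exact
Clopper–Pearson intervals (lower = Beta⁻¹(α/2; x, n−x+1), upper =
Beta⁻¹(1−α/2; x+1, n−x); closed at x = 0 and x = n). The exact method is
standard for sensitivity, specificity and accuracy; it is applied to PPV as
well for consistency and the method name is recorded in every output row.
Every percentage in an output table carries its (x, n) pair; reported
percentages round half-up.

AUC uses the rank (Mann–Whitney) definition with tied pairs counted half,
verified property-wise against a brute-force pairwise oracle; CIs are
seeded percentile bootstraps over case resampling (2000 resamples by
default; single-class resamples are redrawn). Cohen κ is computed from the
cross-table with its p_o and p_e components exposed; the degenerate
pe = 1 case (both raters constant and identical) is defined as κ = 1.
Reader-study comparisons use a paired two-tailed t test on per-reader κ
(df = n−1), with a two-sample variant behind a flag; a zero-variance
non-zero difference is reported as degenerate (t = ±∞, P = 0) with a
warning rather than NaN. Calibration curves use ten equal-width bins and
report the count-weighted expected calibration error, skipping and listing
empty bins. The feed/do-not-feed score of a probability triplet is the
satisfactory-class probability — the only monotone one-number reduction —
with the decision threshold exposed (default 0.5).

The synthetic reader study models shared item difficulty: 30 % of images
are "deceptive" and unaided readers independently err on them with
probability 0.78 (3 % elsewhere), which makes errors correlate across
readers — inter-reader κ exceeds reader-vs-consensus κ, as in real reader
studies. In the aided phase a single model answer per image (correct with
probability 0.85 on deceptive items) is shown to all readers, who follow it
with probability 0.85; both agreements rise, and the paired t test comes
out positive. These parameters were chosen once to land the unaided
reader-vs-consensus κ near 0.5 and are not otherwise meaningful.

## What the synthetic results do and do not show

Passing tests demonstrate that the machinery is correct and that the
pipeline reproduces the *qualitative* phenomena of the modeled study: a
learnable class signal, label-dominant latent attribution with weak
metadata tags, detectable injected drift with monotone power, and
agreement gains from decision support. They do not demonstrate clinical
performance: the images are schematic, the class geometry is perfectly
separable by construction (hence near-ceiling AUCs rather than the 0.77–0.98
of a real archive), pixel-level manufacturer effects are invented uniform
offsets, and the reader model is a two-parameter caricature of human
behavior. Manufacturer-swap drift at the default (small) offsets is at the
edge of detectability in the 2-D reduced space at desk scale; a raw-space
monitor or larger offsets make it visible, and the planted mean-shift
scenarios are the calibrated drift benchmark.

## Known limitations

* The classifier is a small CNN trained from scratch; no pretraining phase
  is included, and GPU-scale resolutions (764/1024) are configurable but
  untested at desk scale.
* The drift detector's per-batch P values are anticonservative at loose
  thresholds (see above); the median-P flag is the calibrated output.
* The triplet reducer optimizes local neighborhood preservation around a
  PCA warm start; it is not a faithful reimplementation of any specific
  published reducer.
* DICOM output is minimal (six tags plus pixel data) and intended for
  format-compatibility testing only.
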