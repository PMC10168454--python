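# Methods

## The detection model

A *shortcut detective* for an acquisition-dependent attribute A is a
binary classifier trained on a dataset constructed so that A is the
only signal separating the classes: a pool of finding-free images is
split 50/50 uniformly at random, one half is perturbed with A and
labeled 1, the other is left untouched and labeled 0. Under this
construction the joint distribution of (image, label) differs between
classes only through the perturbation, so any above-chance classifier
has learned A. Detection on a curated dataset is then a two-sample
test read out as the Mann–Whitney AUC of the detective's scores against
the dataset's own labels: AUC ≈ 0.5 means the attribute is balanced
across classes, a material deviation in either direction means the
attribute co-varies with the label.

### Perturbation operators

Both operators are global, monotone-in-character transforms of the kind
scanner hardware and vendor post-processing produce:

* **Contrast (ADA-C)** — gamma mapping `v ↦ round(255·(v/255)^γ)`.
  Monotone in v (pixel rank order preserved), endpoints 0 and 255 fixed.
  Direction *increase* uses γ = 1 + s > 1, *decrease* γ = 1/(1 + s).
* **Sharpness (ADA-S)** — unsharp mask `I + a·(I − G_σ(I))` with
  Gaussian blur G_σ (reflect padding), σ = 1.5 px by default.
  Direction *increase* uses a = +s (amplifies the detail band, never
  decreases pixel variance up to clamping), *decrease* a = −s (softens;
  a = −1 reaches the pure blur and is the admissible lower bound).

The strength s is drawn per image, uniform in `[strength_low,
strength_high]`, keyed by hashing (spec seed, image id) — so results
are independent of dataset order and a detective must learn the
attribute rather than a single fixed lookup table, mirroring the
scanner-to-scanner variation seen in practice. Defaults (chosen to be
visually subtle at 64–224 px yet reliably learnable, all configurable):
contrast s ∈ [0.15, 0.5] (γ ∈ [1.15, 1.5] or reciprocal); sharpness
a ∈ [0.5, 1.5] increasing, a ∈ [−0.7, −0.3] decreasing.

### The detective ensemble

A detective is an ensemble of K members (default 5; desk scale 3)
differing by their stratified train/validation splits; the ensemble
score is the arithmetic mean of member probabilities — chosen over
rank-merging for simplicity and because the AUC readout only needs a
rank-stable combiner.

The shipped `small-cnn` architecture is a compact convolutional network
sized for CPUs: three 3×3 convolution blocks (8→16→32 channels, ReLU,
2×2 average pooling) whose filter banks are drawn once from the seed
and kept fixed, followed by global mean and standard-deviation pooling
per channel (plus the raw image's mean/std), and a logistic read-out
head trained with minibatch Adam (lr 1e-3, batch 32, binary
cross-entropy). Freezing the convolutions at seeded random values is
the classic random-feature construction: only the head is fitted, so
training is deterministic and takes seconds, while the filter bank
still spans the band-pass statistics that a gamma or unsharp transform
shifts. Each member keeps the epoch checkpoint with the best validation
AUC. The registry also declares the ImageNet-scale architectures
commonly used for this task (VGG-16, DenseNet-121, EfficientNet, Swin
Transformer, ConvNeXt); constructing them requires a deep-learning
backend and GPU-scale training, which is outside this package's scope,
so their constructors raise with an explanatory error.

Seed handling: one master seed fans out to every consumer (split seeds,
head-init seeds, shuffle seeds, per-image strengths) through a BLAKE2b
hash of (seed, tag), keeping all derived seeds below 2^31. Training is
bit-reproducible given identical inputs and seed.

### Certification

The two-exam protocol runs against a dataset believed shortcut-free:

* Exam 1: AUC on the dataset as-is must satisfy |AUC − 0.5| ≤ δ_chance;
* Exam 2a: AUC with the detective's own recipe injected into the
  positive class must reach ≥ 1 − δ_perfect;
* Exam 2b: injected into the negative class instead, ≤ δ_perfect.

Defaults δ_chance = 0.10, δ_perfect = 0.05. Deployment flags a
shortcut when |AUC − 0.5| ≥ 0.10 **and** the 95% CI excludes 0.5; the
deviation is two-sided because an AUC of a and of 1 − a describe the
same separation with opposite label assignment. These are the unique
simple thresholds consistent with published audit practice, where
detectives scoring up to 0.56 on the certification exam are accepted,
a dataset at 0.56 (CI excluding 0.5) is not flagged, and datasets at
0.84 and 0.37 are flagged on either side of 0.5.

### AUC and confidence intervals

The AUC is the Mann–Whitney statistic with half-credit ties, computed
from average ranks; it equals the trapezoidal area under the empirical
ROC curve (both identities are enforced in the test suite against a
pairwise-enumeration oracle and scikit-learn, to 1e-12). CIs are
stratified percentile bootstrap: positives and negatives resampled
separately (class counts preserved, so no replicate degenerates), 2000
replicates, quantiles at (1±level)/2. Stratification follows the
default of the pROC reference implementation. Intervals are reported
at full precision and rounded to two decimals only for presentation;
percentile intervals of heavily tied or perfectly separated samples may
collapse (e.g. [1, 1]) — that is the correct degenerate behavior, and
the percentile interval is not guaranteed to bracket the point estimate
in pathological tie structures.

## The phantom generator

Synthetic phantoms emulate the *statistics* that matter to the
framework, not anatomy: a bright torso ellipse (soft tissue ≈ 170), a
brighter mediastinal band (≈ 215), two darker lung-field ellipses
(soft tissue − 80), sinusoidal rib bands (amplitude 22) inside the
lungs, Gaussian system blur (σ = 1 px), additive Gaussian sensor noise
(σ = 6), and a per-image exposure jitter (σ = 5) plus geometric jitter
of ellipse centers and axes — all in 8-bit units on a 64×64 (default)
or larger grid, fully determined by one seed. Because every image is
drawn from the same family, a randomly labeled phantom cohort is
exchangeable: the ideal shortcut-free certification bed.

What the phantoms do **not** model: real anatomy and pathology, patient
positioning, scatter/grid artifacts, vendor-specific nonlinear
post-processing, and detector-dependent noise correlations. Passing
desk-scale certification therefore demonstrates the *mechanics* of the
framework — the forging, training, exam logic and decision rule — not
that any particular real dataset is clean; auditing real data requires
pointing the same pipeline at real finding-free pools and cohorts via
the PNG/DICOM loaders.

## Problem sizes

Desk-scale defaults used by the pipeline helper, tests and the
acceptance script: a 1200-image phantom pool at 64×64, K = 3 members,
5 epochs, a 300+300 shortcut-free exam cohort, 2000 bootstrap
replicates. At these sizes one full certify run takes a few seconds on
a single CPU, and the exam outcomes are stable across seeds (exam 2a
≥ 0.97, exam 2b ≤ 0.03 in our runs; exam 1 within [0.44, 0.56]). The
full-scale analog of the construction — tens of thousands of 224×224
radiographs and ImageNet-scale ensembles — uses the same code paths
with larger `PhantomParams.side`, pool sizes and a heavyweight
architecture.

## Numerical and interface choices

* Rounding is half-away-from-zero everywhere an intensity is
  quantized, stated once in `imagekit` and reused, so cross-language
  ports agree bit-for-bit.
* Resizing is bilinear followed by rounding and clamping; resizing to
  the current size is the exact identity.
* DICOM conversion uses the dataset's WindowCenter/WindowWidth (first
  value if multi-valued); when absent, the full dynamic range of the
  rescaled pixel data (level = midrange, width = max − min).
  MONOCHROME1 frames are inverted before windowing to preserve the
  bright-equals-dense convention. DICOM is input-only.
* Datasets persist as PNG directories with a `path,label,patient_id`
  CSV manifest; the perturbation recipe travels alongside as a JSON
  sidecar for provenance and is echoed into certification reports.
* Train/validation splitting honors patient grouping when patient ids
  are present (no patient straddles a split; tried over seeded shuffles
  and raising when the label distribution over patients makes the
  both-labels contract unsatisfiable); the detective trainset split
  itself ignores patients, since the pool construction is random by
  design.
* Odd pools drop one image (logged) rather than erroring.
* Ensemble checkpoints are one `.ckpt` (NumPy archive) per member plus
  an `ensemble.json` sidecar carrying the architecture, image side,
  attribute kind, config, training-data fingerprint and per-member
  checksums; loading verifies the checksums.

## Known limitations

* The random-feature small-cnn is strong for global attribute shifts
  but is not a general-purpose image classifier; subtler, spatially
  localized shortcuts would need a trainable-backbone architecture.
* Only contrast and sharpness perturbations ship; noise-texture,
  geometric or marker-based (extrinsic) shortcuts are out of scope.
* Certification is only as good as the shortcut-free exam dataset; the
  package can verify exchangeability for its own phantoms but must
  trust the curation of a user-supplied exam set.
* No mitigation: the package detects shortcuts, it does not harmonize
  them away.
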