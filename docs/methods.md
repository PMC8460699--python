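# Methods

## Problem setting

One patient contributes one whole-slide image (WSI) and matched omics
profiles. Supervision exists only at the slide level (mutation present /
absent, pathway active / inactive), while the signal lives in a subset of
tiles — the classic multiple-instance learning (MIL) setting. The package
predicts binary genomic labels from bags of tile features and reports
which tiles the classifier attended to.

## Image preprocessing

Slides are cut into non-overlapping square tiles (default 512 × 512 px at
the working magnification; partial edge tiles are dropped, ordering is
row-major). A tile is background iff its mean pixel value over all pixels
and channels is **strictly** greater than 220; a mean of exactly 220 is
tissue. Tumor-tile selection then runs 2-means on box-downsampled
(128 × 128, area interpolation → 49 152-vector) pixel vectors of the
non-background tiles, with 10 restarts and a fixed seed. The cluster whose
centroid has the lower mean luminance is labeled tumor: tissue of interest
is darker than stroma; when that heuristic is wrong for a slide, the
refinement hook (`apply_refinement`, a TSV of `force_tumor` /
`force_exclude` overrides per grid position) plays the role a reviewing
pathologist plays in practice. Degenerate clustering (all tiles identical)
labels everything tumor with a warning instead of failing, which keeps
tiny slides usable.

Background filtering runs *before* clustering. The alternative order
(cluster everything) is defensible; filter-first is adopted because
background tiles carry no tumor information and would only dilute the
centroids.

Color normalization is a per-channel affine map using slide-level
statistics: `out = (in − μ_src)/σ_src · σ_tgt + μ_tgt`, clipped to
[0, 255], with one (μ_src, σ_src) per slide computed over its tumor tiles.
It operates in RGB; this mean/std contract is the implementable reading of
slide-level color standardization, and stain-deconvolution methods
(Macenko, Vahadane) are deliberately out of scope.

## Feature extraction

`FeatureExtractor` is a frozen contract: tile → fixed-length vector,
deterministic in evaluation mode, parameters never updated. Tiles are
prepared by bilinear resize to 224 × 224, scaling to [0, 1], and
per-channel standardization (defaults: the ImageNet channel statistics —
configuration data, not code). The in-repo default extractor is a seeded
Gaussian random projection of box-downsampled pixels with the standard
2048-dimensional output width; a 64-D variant backs fast tests. A
pretrained convolutional backbone (e.g. the convolutional part of a
ResNet-101) satisfies the same contract and can be plugged in where its
weights are available; nothing in the pipeline depends on which extractor
fills the slot, and a contract test asserts exactly that.

Bags are cached on disk (one HDF5 matrix per patient plus a TSV manifest
with shapes and SHA-256 checksums); training consumes only cached bags,
and reads verify integrity.

## Labels from omics

* Gene selection: point-mutation tasks keep genes altered in **at least**
  3% of patients; CNA tasks keep genes altered in **strictly more than**
  5% (the same floors gate transfer fine-tuning eligibility).
* CNA binarization is configurable because discrete call conventions vary:
  `nonzero` (any GISTIC-style call ≠ 0, the default) or `level2`
  (|call| ≥ 2, deep deletion / high amplification).
* Pathway activity for patient *s* and pathway *i*:
  `v = (1/N_gene) Σ_n w_n u_n` over member genes, `w = +1` for oncogenes,
  `−1` for tumor suppressors, `u` the expression or CNA level. The score
  is a weighted **mean**, not a bare sum, so pathways of different sizes
  are comparable. Label `l = 1` iff `v > 0`; `v = 0` is inactive. Member
  genes missing from the table (or NaN for a patient) are dropped from
  that mean with the denominator adjusted and a warning — silent zero
  imputation would bias `v` toward inactive. Pathway membership ships as a
  user-editable TSV (pathway, gene, role), not hard-coded biology.

## The attention-MIL head

Architecture (input `x`: N × D): fc1 D→512, relu, fc2 512→128, relu, one
self-attention layer, residual with trainable scale γ (initialized to 1),
mean pooling, fc_out 128→2, softmax. The attention computes
`f(h) = W_f h`, `g(h) = W_g h` (width `d_attn`, default 16 = 128/8, the
usual key-width convention), scores `s_{j,i} = f(h_i)ᵀ g(h_j)`, and
normalizes with a softmax **over the input index i** for each output j.
Two conventions in the attention literature differ on this axis; the
chosen one is the only one under which the tile weight
`β_i = 1 + γ Σ_j α_{j,i}` (attention *received* by tile i, column sums of
the row-stochastic α) varies across tiles — under the other axis every
β_i collapses to the constant 1 + γ and weight maps become meaningless.
With row-stochastic α, Σ_i β_i = N(1 + γ) identically, which tests assert
on every forward pass.

The relu between the fully connected layers, the He/√fan-in
initialization, and the 2-logit softmax head are ordinary choices made
where the architecture leaves them open; the positive-class probability
is the score used for AUC.

Training: cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), 30
epochs, learning rate 1e-4 for all parameters except γ at 1e-3. Bags have
variable N, so they are processed one at a time with gradients averaged
over an effective batch of 8 — exact loss, no padding or masking. The
best epoch by validation AUC is returned. No class re-weighting or
oversampling: imbalance is reported, not corrected. The head is
implemented in NumPy with analytic gradients (verified against central
finite differences in the test suite); at bag sizes of tens of tiles a
full training run is seconds on one CPU, so no GPU framework is needed.

## Evaluation and transfer

Patient splits use largest-remainder apportionment: floor each n·r_k,
then assign the remaining patients to the partitions with the largest
fractional parts (ties to earlier partitions). This convention uniquely
reproduces 659 → 461/99/99 under 70/15/15 and 350 → 70/280, 316 → 63/253
under 20/80. Membership is a seeded permutation; splits are at patient
level (one slide per patient), so no cross-slide leakage logic is needed.

AUC is the Mann–Whitney statistic with midrank ties, computed via
scikit-learn and property-tested against exhaustive positive–negative
pair counting. The 95% CI is the percentile interval over 1000 bootstrap
resamples of patients; a resample containing a single class is redrawn
(not skipped) so exactly 1000 replicates enter the percentiles.

Fine-tuning freezes fc1/fc2 bit-exactly (asserted via checksum) and
updates only W_f, W_g, γ, and fc_out; tasks whose label prevalence in the
new cohort does not exceed the 3%/5% floors are refused.

## Synthetic generators

The generators plant a known truth at every level so each stage has an
oracle:

* **Slides**: background tiles uniform in [230, 255] per channel, tissue
  textured in [80, 200] — strictly separated around the 220 threshold so
  the background rule is deterministic in tests. Signal tiles get a
  distinct darker tint (2-means separability *and* the lower-luminance
  tumor mapping) on top of the plain-tissue texture. Masks are recorded
  at tile resolution; signal ⊆ tissue by construction.
* **Bags**: instances standard normal; flagged instances shifted by the
  effect size along a fixed unit direction drawn once per set (pass
  `direction` explicitly to share or rotate it across sets — the train /
  validation / test splits of one experiment must come from a single
  generated set, otherwise the planted direction differs between them and
  the task is unlearnable by construction). Defaults, fixed once: bag
  sizes uniform on 10–40, signal fraction 0.3 in positive bags (at least
  one flagged instance), dim 32, half the bags positive. A bag is
  positive iff it contains a flagged instance.
* **Omics**: Bernoulli mutation calls at the planted prevalences
  (chosen in tests around the 3%/5% selection floors); per patient and
  pathway a planted activity sign; member-gene expression
  `w · sign · 1.0 + N(0, 0.3)` so the weighted mean recovers the sign
  with near certainty for ≥ 2 members; member-gene CNA calls are the
  correlated values discretized to {−2…2}; non-member CNA is sparse
  noise at the gene's prevalence.

What the generators do **not** emulate: H&E stain physics and texture,
pyramidal WSI containers, tile-count scales of real slides (hundreds of
thousands), label noise, batch effects between cohorts, and biological
correlation structure between genes beyond the planted pathway signs.
Passing the synthetic experiments therefore demonstrates that the
machinery is correct — the filters filter, the attention localizes, the
transfer protocol freezes what it must — not that any particular AUC is
attainable on real cohorts.

## Experiment sizes

The recovery experiment trains on 200 bags with 100 validation and 100
held-out bags at effect size 4 (the regime where instance-level signal is
unambiguous); the null experiment repeats it at effect size 0 over five
seeds; the transfer experiment trains on one domain, rotates the signal
direction to an orthogonal one, fine-tunes on 60 target bags, and
compares target-domain AUC against the unadapted model over five seeds.
These sizes train in seconds each while leaving the binomial noise on an
AUC over 100 bags (≈ ±0.05) small relative to the effects measured.

## Known limitations

* The default random-projection extractor is linear; it preserves the
  planted linear signal of the synthetic bags but has none of the texture
  sensitivity of a pretrained convolutional backbone. Real-cohort
  performance depends on plugging such a backbone into the contract.
* The lower-luminance tumor heuristic is a convention, not pathology;
  the refinement hook exists precisely because it can be wrong.
* k-means on raw downsampled pixels separates color-distinct regions
  only; morphologically defined tumor boundaries need the manual pass.
* The percentile bootstrap is the only uncertainty estimate; no analytic
  (DeLong) CI, no cross-validation, no calibration analysis.
* γ is unconstrained; β_i > 0 (needed for log weight maps) holds while
  γ > −1, which training never violated in practice but is not enforced.
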