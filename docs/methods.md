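# Methods

This note documents the models and procedures behind `genimg`, the
assumptions they make, the defaults and why they were chosen, and what the
synthetic benchmark does and does not demonstrate.

## The pipeline

The question the package addresses: can a case/control phenotype be
predicted from a genotype *sequence* after re-presenting it as a 2-D
image, using an off-the-shelf image-classification CNN, and how does that
compare with the natural 1-D convolutional treatment of the same sequence?

The pipeline is: simulate (or load) a cohort of diploid genotypes coded as
minor-allele dosage 0/1/2 with binary labels → stratified 80/20 train/test
split → per-SNP allelic Fisher-exact association scan **on the training
split only** → keep SNPs with p ≤ a threshold (operating points
{1.0, 5.05915e-10, 5.05915e-30, 5.05915e-50}) → encode the surviving
ordered SNP sequence as square images (2-D models) or keep it as a
sequence (1-D model) → train the fixed CNN and report train / validation /
test accuracy, averaged over repeated iterations.

## Synthetic cohort

### Genotypes: founder-mosaic model

A panel of `n_founders` haplotypes is drawn with per-SNP minor-allele
frequencies uniform on `freq_range`. Within each founder, alleles come
from thresholding a latent AR(1) Gaussian process (parameter
`founder_ld`), so each allele is marginally Bernoulli(f_j), founders are
i.i.d., and nearby SNPs within a founder are correlated. Each sample
haplotype then copies a founder SNP-by-SNP, switching to a uniformly
chosen founder with probability `switch_rate` per SNP; a genotype is the
sum of two independent haplotypes.

Population LD is the product of two decays — founder-column correlation
(≈ `founder_ld`^d) and mosaic persistence (≈ (1−`switch_rate`)^d) — giving
block-like local LD (adjacent r² ≈ 0.7–0.9 with the defaults, negligible
beyond a few hundred SNPs) while leaving Hardy–Weinberg proportions and
per-SNP frequencies intact. Setting `founder_ld=0, switch_rate=0.5` with
many founders yields fully independent SNPs — the regime used for null
calibration tests, where the Kolmogorov–Smirnov uniformity check is valid
(under LD the per-SNP p-values are still marginally uniform but not
independent, which invalidates the KS sampling distribution, not the
test's calibration).

### Phenotype: liability threshold model

`n_causal` SNPs are sampled without replacement; effects β ~ N(0,1) act on
standardized dosages; the genetic score is rescaled to variance h², noise
N(0, 1−h²) is added, and the standardized liability is cut at 0: strictly
positive → case, ties → control. The case fraction is emergent (≈ 0.5,
not forced). Within an iterated experiment the causal set and β are held
fixed while the noise, the split and the weight initialization re-derive
from `base_seed + iteration`, so labels and the surviving SNP count vary
across iterations the way re-runs of the full pipeline would.

### Default calibration

The defaults (`n_causal=8`, `heritability=0.85`, `founder_ld=0.99`,
`switch_rate=0.01`, `n_founders=20`, `freq_range=(0.05, 0.5)`) were fixed
once, by calibration against the operating regime the method is designed
for, and are not tuned per experiment:

* Full-information Bayes accuracy of the liability model is
  0.5 + arcsin(√h²)/π; h²=0.85 gives 0.874. With 8 χ²₁-distributed effect
  shares, the SNPs surviving the strictest operating point retain ≈ 0.83
  of the liability variance at n=10,000, putting the **after-selection**
  Bayes accuracy at ≈ 0.85 — the regime in which strict-threshold CNNs
  reach test accuracies in the low 0.80s. Fewer, larger effects are needed
  because χ²₁ effect mass below a fixed χ² cut is lost at selection; a
  40-SNP architecture at h²=0.7 caps full-information accuracy at 0.815
  and loses ~40% of its signal at the strict thresholds, leaving the
  strict-threshold cells far below the intended regime.
* The LD decay (≈ 0.97 per SNP step) reproduces realistic
  threshold-survivor tiers at n=10,000: a few hundred SNPs at the
  5.05915e-30 cut and ≈ 150 at the 5.05915e-50 cut, each causal SNP
  dragging a block of high-r² neighbors past the cut.

## Association scan

The per-SNP test is the allelic (2n-allele) Fisher exact test: the 2×2
table counts minor/major alleles in cases vs controls (minor count =
dosage sum). The two-sided p-value sums hypergeometric point
probabilities ≤ that of the observed table, within relative tolerance
1e−7 to absorb floating error — the standard two-sided rule. Degenerate
margins return p = 1. The scan is vectorized over the hypergeometric
support (log-pmf via `gammaln`, chunked); tests verify it against exact
integer-arithmetic enumeration for every table with total ≤ 40 and
against `scipy.stats.fisher_exact` on random tables. Raw p-values are
thresholded inclusively (p ≤ t); no multiple-testing correction is
applied, matching standard GWAS-preselection practice with fixed
operating points. Selection learned on the training split is applied
unchanged to the test split.

## Image encodings

SNP order is sequence order everywhere. Sequences wrap row-major
(left→right, top→bottom) into M×M single-channel images; trailing SNPs
beyond the square capacity are discarded (the prefix is kept):

* **E1** (additive): pixel = dosage ∈ {0,1,2}; M = ⌊√N⌋; invertible.
* **E2** (heterozygosity indicator): pixel = 1 iff dosage = 1; lossy
  (dosages 0 and 2 collapse), so no decoder exists and asking for one is
  an error. Its information loss grows with minor-allele frequency —
  at f=0.1 the indicator retains ~78% of the dosage's variance-explained,
  at f=0.4 only ~8% — which is why E2 accuracies trail E1.
* **E3** (byte packing): E2 bits in groups of 8, most significant bit
  first, one 0–255 pixel per group; M = ⌊√(N/8)⌋; invertible on the
  packed bits. MSB-first is a fixed convention (the packing order is
  otherwise arbitrary); it matches `numpy.packbits`.

Network inputs are the raw class values divided by the scheme maximum
(2, 1, 255), bounding them in [0,1]. PNG export instead uses a display
mapping (E1 {0,1,2}→{0,127,254}, E2 {0,1}→{0,255}, E3 identity) so the
images are visible; `read_png` inverts it exactly. Image similarity is
provided as pixelwise MSE/RMSE.

## Classifiers

Both models share one declarative stack:

    conv(32 filters, kernel 3, valid, stride 1, ReLU)
    maxpool(2, stride 2)
    conv(64 filters, kernel 3, valid, stride 1, ReLU)
    maxpool(2, stride 2)
    flatten
    dense(10, ReLU)
    dropout(0.3)
    dense(2)
    softmax

The 2-D model uses 3×3 kernels / 2×2 pools on an M×M×1 image; the 1-D
model is the height-1 special case (kernels 1×3, pools 1×2) on the full
selected sequence, so the two differ only in dimensionality and the 1-D
net on length N has exactly the parameter count of a 2-D net on a 1×N
image. The smallest buildable image is M=10 (at M∈{8,9} the second pool
has zero extent); experiment cells whose selected SNP count falls below
10² are recorded as failures rather than silently reshaped. A
global-average-pooling variant of the reshape stage exists but is off by
default; the flatten stack is canonical.

Training protocol (identical for every cell): batch 100, Adam
(lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), binary cross-entropy on the 2-way
softmax (identical to categorical cross-entropy for one-hot 2-class
labels), ReLU activations, dropout 0.3 after dense(10), a stratified
validation split taking the last-listed 30% of each class, a fixed epoch
count with no early stopping, and final-epoch accuracies reported
(training accuracy is the running mean over the epoch's batches,
framework-style). "Validation size 0.3" is read as the fraction 0.30; a
0.3% reading would leave a few dozen validation samples, incompatible
with stable validation accuracies.

The engine is pure NumPy (im2col convolution through BLAS matmul,
first-match max-pool routing, inverted dropout, float32 throughout),
driven entirely by `numpy.random.Generator` seeds: a fixed seed
reproduces training exactly. Gradients are verified in tests against
finite-difference directional derivatives, and the closed-form
`output_shapes` oracle is verified against the live layer stack.

## Experiments and visualization

`run_iterations` executes the grid (threshold × encoding × model) over
`n_iterations` iterations (default 5), re-deriving split/noise/init seeds
per iteration, and reports per-cell means plus per-iteration raw rows and
recorded failures. The GWAS scan only ever sees the training split, and
reported accuracies are per-sample means, invariant to test-set row order.

Classification-region maps are plain gradient saliency: |∂(predicted-class
logit)/∂pixel|, min–max normalized, with a guard mapping constant-output
models to all-zero maps. Occlusion or smoothed variants were deliberately
not added; vanilla gradients are deterministic and dependency-free. The
filter gallery renders each first-layer 3×3 kernel min→0, max→255.

The cross-model similarity trace freezes a trained 1-D model, trains the
2-D model, and records at each epoch the cosine between the flattened
dense(10)→dense(2) weight matrices (biases excluded — the only
shape-identical block in both models). A caveat found empirically and
worth stating: because the hidden-unit correspondence between two
independently initialized networks is arbitrary, the *sign and direction*
of this trace are seed-dependent (the trace drifts smoothly but in a
random direction), so a monotone increase is a per-run observation, not a
stable property of the protocol.

## Benchmark scales and what they show

The default cohort is 10,000 samples × 12,000 SNPs. The bundled
acceptance script (`scripts/acceptance.py`) keeps the 10,000 samples —
the fixed 5.05915e-X operating points correspond to allelic χ² cuts of
roughly 137 and 232, calibrated to ~16,000 training alleles, and empty
out on smaller cohorts — but runs a 1,000-SNP window with 20 epochs and
5 iterations so the whole experiment fits in minutes of CPU. At this
scale the strict-threshold cells behave like their full-scale
counterparts (selection-concentrated signal, E1 > E2, 1-D ≈ 2-D).

One full-scale phenomenon deliberately does **not** survive down-scaling:
with *no* SNP preselection the full 12,000-SNP image (M=109) leaves the
CNN on a chance-level optimization plateau for several epochs (escaping
it is slow and seed-dependent), whereas the ~1,000-SNP image (M=31) is
learned readily. The no-selection cell therefore reports a well-above-
chance accuracy at desk scale; treating no-selection performance as
"chance level" is only valid in the large-image, fixed-epoch-budget
regime.

What passing the synthetic tests does not show about real data: the
generator has no population structure, covariates, missingness, sex
chromosomes, genotyping error or long-range LD; effect sizes are Gaussian
on standardized dosages; and the liability cut is exactly at 0. Results
quantify the behavior of the *method* under a controlled, parameter-
recoverable cohort, not expected clinical performance.

## Numerical and degenerate-input choices

* Liability ties at exactly 0 are controls (deterministic split).
* Monomorphic causal SNPs contribute zero genetic score (std guard).
* Fisher p-values are clipped into (0, 1]; zero margins give 1.0.
* `square_dim` errors when not even one pixel can be filled; selection
  errors when no SNP survives a threshold; both surface as recorded cell
  failures inside experiments.
* Max-pool gradient routes to the first position attaining the maximum
  (deterministic under ties).
* All seeds derive from small-integer `SeedSequence` keys; no global RNG
  state is touched.
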