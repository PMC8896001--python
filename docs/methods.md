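# Methods

## The model

`snpae` performs nonlinear dimensionality reduction and genetic
clustering of diploid biallelic SNP genotypes with a one-dimensional
convolutional autoencoder. The input to the network is, per sample, a
sequence of markers with three channels: the genotype dosage normalized
to [0, 1] (0 → 0.0, 1 → 0.5, 2 → 1.0, missing → −1.0), a binary
missingness mask (1 = observed), and a trainable marker-specific
variable (set A below).

The encoder alternates stride-1 "same" convolutions with max-pooling;
each convolution is followed by an elu activation and batch
normalization. A fully-connected funnel then maps the flattened
convolutional output to a d-dimensional latent representation. The
decoder mirrors this: a fully-connected expansion, then convolutions
interleaved with nearest-neighbour upsampling, ending in a kernel-size-1
linear convolution (no batch normalization) that emits one scalar per
marker. Residual connections add a source layer's output to a
destination layer's output; a kernel-size-1 projection reconciles
differing channel counts, and differing spatial lengths are rejected at
build time. Inputs whose marker count is not a multiple of the total
pooling factor are zero-padded on the right and the output is cropped
back.

Because convolution is translation-invariant while genotype data gives
every position a fixed meaning, two trainable per-marker variable sets
restore positional information: set A enters as input channel 3 and is
concatenated (as an extra channel) at a configurable decoder
convolution; set B is concatenated just before the final kernel-size-1
convolution.

### Output head and loss

The decoder's scalar output o_raw is squashed with a sigmoid and
interpreted as the allele frequency o at the site for that sample. The
genotype probabilities follow from Hardy–Weinberg equilibrium:

    [f(0), f(1), f(2)] = [(1−o)², 2(1−o)o, o²]

The training loss is the weighted categorical cross-entropy between
one-hot target genotypes y and these probabilities, plus an L2 penalty
on the latent coordinates e:

    loss = mean_{i,j} [ w_ij · (−Σ_g y_g log f(g)) ] + α · mean_i Σ_k e_ik²

Logs are clamped at 1e−15 to avoid −inf at sigmoid saturation. Both
terms are means (over sample × marker entries and over samples) so the
meaning of α is independent of problem size. Optional class balancing
reweights the three genotype classes by the effective-number-of-samples
scheme w_g = (1−β)/(1−β^{n_g}), rescaled to a count-weighted mean of 1;
it is off by default (β only applies when enabled).

### Denoising augmentation

Per training batch a masking fraction f is drawn uniformly from a
configured range (default [0.0, 0.9]) and ⌊f·batch·markers⌋ entries are
set to missing (−1.0 genotype, mask 0). With probability 0.2 (one draw
per batch; a per-entry variant is a config switch) all missing entries
additionally receive random genotype values from {0.0, 0.5, 1.0} while
their mask stays 0. The loss is always computed against the true
genotypes at all sites, which makes the objective denoising: the model
must reconstruct masked genotypes from context. Validation loss is
computed without augmentation in inference mode, for stability of the
early-stopping signal.

### Optimization

Adam (published default moments) with learning rate
lr·decay_rate^(step/decay_steps), defaults lr = 1e−2, decay 0.96 per
100 steps, batch size 32. Training stops when the validation loss has
not improved for `patience` epochs (default 300) or at `max_epochs`;
the parameters returned are those of the best validation epoch.
Dropout (DropConnect on fully-connected weights, default rate 0.01)
skips the layers adjacent to the latent representation; Gaussian noise
(default std 0.2) is added to the latent representation during training
only. All randomness is seeded; identical seed and data give an
identical loss trajectory.

### Latent normalization

The latent layer is batch-normalized per unit by default
(`normalize_latent`, an affine batch normalization on the linear latent
output, before the additive noise). This design choice came out of a
failure mode observed during development: with an unnormalized latent
layer, embedding quality was unstable — on some data realizations the
k-NN F1 of the embedding peaked mid-training and then degraded while
the validation loss continued to improve, because nothing anchors the
latent scale against the additive Gaussian noise and the L2 penalty;
the reconstruction pathway can drift toward the marker-specific
variables while the latent clusters blur. Normalizing the latent to
per-unit batch mean 0 / variance 1 fixes the signal-to-noise ratio of
the embedding, after which structure recovery on the synthetic task is
stable at F1 ≈ 1.0 across seeds for the full training run. The flag can
be disabled to recover the plain linear latent.

### Clustering mode

For genetic clustering the latent layer has k units and a softmax, so
the encoding is itself a proportional assignment over k clusters (a
Q-matrix row). The loss is unchanged; the L2 penalty then acts on the
bounded post-softmax vector and is correspondingly mild. Gaussian
latent noise is applied before the softmax.

The same latent batch normalization is essential here: without it the
plain softmax encoding collapsed reliably to a single vertex (every
sample assigned wholly to one cluster, dead softmax gradients) across a
wide range of learning rates, penalties and noise levels. Normalizing
the pre-softmax logits bounds their scale, makes global single-vertex
collapse impossible in training mode, and on the synthetic recovery
task moves permutation-matched assignment accuracy from chance (1/k)
to ~1.0.

### Architecture defaults

The architecture is fully configuration-driven. The shipped default —
conv(8 kernels, size 5) → pool(5) → conv(8, 5) → pool(2) → FC(75) →
FC(d) and the mirrored decoder, with an identity/projected residual
skip across each convolution — is this implementation's compact choice,
sized for data sets of a few thousand markers. It is not a transcription
of any published layer table, and the exact residual endpoints and
marker-variable injection points are likewise configuration entries
(defaults: set A at the input of the last regular decoder convolution,
set B at the final convolution's input). Fully-connected layers use elu
except the latent layer and the outermost decoder expansion, which are
linear. Batch normalization at inference uses exponentially averaged
running statistics (momentum 0.99).

## Preprocessing

The filter chain mirrors standard practice before PCA-type structure
analysis, in order: (1) drop excluded chromosomes and non-informative
sites (all non-missing calls identical); (2) minor-allele-frequency
threshold, computed over non-missing calls, boundary kept (MAF exactly
at the threshold survives); (3) greedy left-to-right LD pruning within
a genetic-distance window (default 1.0 cM, allelic R² > 0.2 drops the
downstream SNP of the pair); (4) imputation of remaining missing calls
with the per-site modal genotype, ties to the smaller dosage. When no
genetic map is available, 1 cM ≡ 1 Mb is assumed with a warning.

Dosage counts copies of the A1 allele (.bim column 5, plink's
minor-allele convention); EIGENSTRAT genetic distances are read as
Morgans and stored as cM. This orientation choice flips the site
frequency spectrum's axis, and all "derived allele" frequencies are
orientation-relative.

## Evaluation

Embedding quality is scored by k-NN classification: each sample's label
is predicted as the modal label among its k nearest Euclidean
neighbours, the sample itself excluded (including it would trivially
inflate every score). Label ties break by smaller summed neighbour
distance, then lexicographically; equidistant neighbours resolve by
stable index order. The score is the class-size-weighted mean of
per-class F1, computed over the full sample set at both population and
superpopulation level (the labels are never seen by the model). The
PCA baseline normalizes each marker by the SMARTPCA estimator
p̂ = (1+Σg)/(2+2n), i.e. (g−μ)/√(p̂(1−p̂)), and uses a deterministic
sign convention (largest-magnitude loading positive).

## Output-genotype analyses

Hard-called output genotypes are the argmax of the Hardy–Weinberg
triple (exact boundary ties resolve to the heterozygote; they occur
only at o = 1/3 and o = 2/3). Sites at which the output carries only
one allele are excluded from both matrices so the same site set is
compared. R² is the Rogers–Huff composite measure: squared Pearson
correlation of unphased dosage columns over samples non-missing at both
sites; constant columns are skipped. LD decay is summarized as the mean
r² in 25 equal-width bp-distance bins over [0, max distance]; empty
bins report count 0 and undefined mean. The joint site-frequency
spectrum is a 100×100 histogram of (true, output) per-site allele
frequencies on [0, 1]². An optional accessibility mask is consumed as
BED intervals (0-based half-open; a site passes if position−1 falls
inside an interval), and the analysis can be restricted to one
population and a bp interval.

## Synthetic data

The generator provides the statistical structure the analyses need
without external downloads. Population structure follows the
Balding–Nichols model: ancestral frequencies Uniform(0.1, 0.9),
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) so F is the
expected fixation index, genotypes Binomial(2, p_k). Admixed
individuals draw Dirichlet(α) proportions and each allele copy picks
its source population independently (the PSD model — no ancestry
tracts). LD is emulated separately by a Markov copying chain along
haplotypes (copy the left neighbour with probability ρ, else redraw),
giving haplotypic correlation ≈ ρ^lag and hence E[r²] ≈ ρ^(2·lag).

What this does not emulate: realistic allele-frequency spectra (no
rare-variant excess), recombination maps, coalescent genealogies,
selection, or linked admixture tracts. Tests passing on this substrate
show that the implementation recovers planted structure under its own
model assumptions; they do not certify performance on real cohorts.

## Problem sizes and test design

The parameter-recovery checks train on three populations at F = 0.2
with 50 samples each and 1,000 markers — small enough to train the
numpy implementation in minutes on one CPU, while keeping the
population-recovery task honest (F = 0.2 is continental-scale
differentiation). Dimensionality-reduction recovery is declared when a
3-NN classifier on the 2-D embedding reaches weighted F1 ≥ 0.95 for a
majority of three training seeds; clustering when permutation-matched
hard-assignment accuracy reaches 0.90. LD checks use 500 samples × 400
markers of Markov haplotypes at ρ = 0.9 (decay) and ρ = 0 (null level
1/(n−1); once a decay profile reaches this floor, its fluctuation scale
is the floor itself, which is the tolerance used for monotonicity).

## Numerical notes

All network arithmetic is float64 via a small in-package reverse-mode
automatic-differentiation core (`snpae._autograd`) — the project runs
on plain numpy and has no deep-learning framework dependency. The
sigmoid output is clipped to [1e−12, 1−1e−12] so the Hardy–Weinberg
probabilities stay strictly inside (0, 1) at saturation; softmax uses
max-subtraction and is overflow-safe for arbitrary logit magnitudes;
batch normalization uses ε = 1e−5. Checkpoints are self-describing npz
archives (parameters + running statistics + config + seed).

## Known limitations

- Phased haplotypes, multiallelic sites and dosage-probability formats
  are out of scope; VCF reading accepts biallelic SNPs only.
- The LD-pruning scan is the greedy left-to-right rule stated above; it
  is not guaranteed to match plink's windowed algorithm marker for
  marker.
- Continuous admixture-proportion recovery (fuzzy Q rows for admixed
  individuals) is noticeably harder than hard-assignment recovery and
  is not covered by the shipped acceptance checks; the clustering model
  is validated on unadmixed populations.
- At the shipped training scales the output genotypes track per-site
  allele frequencies only coarsely: the joint SFS concentrates near the
  diagonal only loosely (hard-calling compresses frequencies toward
  intermediate values). Tight diagonal concentration in a 100-bin SFS
  requires training budgets well beyond the minutes-scale runs the
  tests and examples use.
- Training cost grows linearly with markers × samples; the numpy
  implementation targets method-development scale (10³–10⁴ markers),
  not biobank scale.
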