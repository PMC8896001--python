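# snpae — convolutional autoencoder for SNP genotype data

`snpae` is a toolkit for nonlinear dimensionality reduction and genetic
clustering of diploid biallelic genotype matrices (samples × markers,
dosages 0/1/2). It targets population-genetic exploratory analysis:
embedding worldwide-diversity panels into a few dimensions that
preserve both local and global population structure, admixture-style
proportional cluster assignment, and checks of what structure the model
preserves (site frequency spectra, decay of linkage disequilibrium with
distance).

## The model

The core is a 1-D convolutional autoencoder over the marker sequence.
The encoder stacks stride-1 convolutions (elu + batch normalization)
and max-pooling, then fully-connected layers down to a d-dimensional
latent representation; the decoder mirrors it with nearest-neighbour
upsampling and residual skip connections. Two trainable marker-specific
variable sets re-inject positional information that convolution
discards. Per sample and site the decoder emits one scalar; after a
sigmoid it is read as an allele frequency o and expanded into genotype
probabilities by Hardy–Weinberg equilibrium,

    [f(0), f(1), f(2)] = [(1−o)², 2(1−o)o, o²],

and the network minimizes the categorical cross-entropy between these
and one-hot true genotypes plus an L2 penalty α·Σe² on the latent
coordinates, with Adam, exponential learning-rate decay and early
stopping on validation loss. Training is a denoising scheme: a random
fraction of input genotypes per batch is masked (and sometimes
scrambled) while the loss always targets the true genotypes, which also
makes the model robust to genuinely missing data. For genetic
clustering the latent layer becomes k softmax units, so the encoding
itself is a Q-matrix row (proportional assignment over k clusters).

Everything runs on plain numpy — the network, including its
backpropagation, is implemented in-package with no deep-learning
framework dependency. See `docs/methods.md` for the full model
description and design decisions.

## Worked example

```bash
python examples/01_dimensionality_reduction.py
```

simulates three Balding–Nichols populations (FST 0.2, 50 samples each,
1,000 markers), trains a 2-D model and evaluates the embedding:

```
simulated 150 samples x 1000 markers, FST 0.2
trained 200 epochs; validation loss 1.424 -> 0.759
3-NN population F1 on the 2-D embedding: 1.000
(values near 1.0 mean the latent space cleanly separates the populations)
```

The F1 score is the class-size-weighted mean of per-class F1 of a
k-nearest-neighbour classifier run on the embedding (self excluded):
1.0 means every sample's nearest neighbours are its own population, so
the latent space has fully recovered the planted structure.

The other examples cover clustering (`02`, prints the Q matrix and its
permutation-matched accuracy against the simulated populations),
preprocessing + the SMARTPCA-normalized PCA baseline (`03`), and
output-genotype analysis (`04`, SFS diagonal mass and LD-decay
profiles of reconstructed genotypes).

## Command line

The same workflows are scriptable via the `snpae` command:

```bash
snpae simulate --n-populations 3 --fst 0.2 --out sim/
snpae preprocess --data sim/fixture --maf 0.01 --out prep
snpae train --data prep --latent-dim 2 --seed 1 --out run/
snpae project --data prep --checkpoint run/checkpoint.npz --out emb.tsv
snpae evaluate --embedding emb.tsv --ks 3,20 --out f1.tsv
snpae cluster --data prep --k 5 --seed 1 --out crun/
snpae analyze --data prep --checkpoint run/checkpoint.npz --out analysis/
```

`evaluate` accepts any embedding TSV (`sample_id`, `population`,
`dim_1..dim_d`), so embeddings produced by other methods (PCA, t-SNE,
UMAP, other autoencoders) can be scored with the identical protocol.
Supported genotype formats: PLINK 1 binary (.bed/.bim/.fam, SNP-major),
EIGENSTRAT (.geno/.snp/.ind) and VCF (biallelic SNPs, read-only).
Dosages count the A1 (.bim column 5) allele.

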