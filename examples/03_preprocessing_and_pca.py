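"""The standard preprocessing chain plus the PCA baseline.

Simulates genotypes with missing calls, applies the filter chain
(non-informative sites -> MAF threshold -> LD pruning -> modal
imputation), and projects the result with SMARTPCA-normalized PCA for
comparison with the autoencoder embedding.
"""

import numpy as np

from snpae import (
    SimulationSpec,
    filter_informative,
    impute_most_frequent,
    knn_predict,
    ld_prune,
    maf_filter,
    pca_baseline,
    simulate_populations,
    weighted_f1,
)

data, _ = simulate_populations(
    SimulationSpec(n_populations=3, samples_per_population=40, n_markers=800,
                   fst=0.1, missing_rate=0.05, seed=4)
)
print(f"input: {data.n_markers} markers, "
      f"{(data.genotypes == -1).mean():.1%} missing calls")

g = filter_informative(data)
print(f"after informativeness filter: {g.n_markers} markers")
g = maf_filter(g, 0.01)
print(f"after MAF >= 1% filter:       {g.n_markers} markers")
g = ld_prune(g, window_cm=1.0, r2_max=0.2)
print(f"after LD pruning (r2 > 0.2):  {g.n_markers} markers")
g = impute_most_frequent(g)
print(f"after modal imputation: {np.sum(g.genotypes == -1)} missing calls remain")

emb = pca_baseline(g, d=2)
pred = knn_predict(emb, g.population_labels, k=3)
print(f"3-NN population F1 of the 2-D PCA baseline: "
      f"{weighted_f1(g.population_labels, pred):.3f}")
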