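import numpy as np
import pandas as pd
import pytest

from snpae.genotype_io import MISSING, MARKER_COLUMNS, GenotypeMatrix


def make_marker_info(n_markers, chrom="1", spacing_bp=1000, with_cm=True):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n_markers,
            "marker_id": [f"snp{j}" for j in range(n_markers)],
            "pos_cm": (np.arange(1, n_markers + 1) * spacing_bp * 1e-6)
            if with_cm
            else np.full(n_markers, np.nan),
            "pos_bp": np.arange(1, n_markers + 1, dtype=np.int64) * spacing_bp,
            "allele1": ["A"] * n_markers,
            "allele2": ["G"] * n_markers,
        },
        columns=MARKER_COLUMNS,
    )


def make_matrix(genotypes, populations=None, **marker_kwargs):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    return GenotypeMatrix(
        genotypes,
        [f"s{i}" for i in range(n)],
        populations or ["P1"] * n,
        make_marker_info(m, **marker_kwargs),
    )


def random_matrix(rng, n=8, m=15, missing_rate=0.1, populations=None):
    gt = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        gt[rng.random(size=gt.shape) < missing_rate] = MISSING
    return make_matrix(gt, populations=populations)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def three_pop_data():
    """Small well-differentiated three-population data set."""
    from snpae.synthetic_data import SimulationSpec, simulate_populations

    return simulate_populations(
        SimulationSpec(
            n_populations=3, samples_per_population=20, n_markers=300, fst=0.3, seed=7
        )
    )
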