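"""Synthetic genotype data with known structure.

Population structure follows the Balding–Nichols model: per marker an
ancestral frequency p ~ Uniform(0.1, 0.9) is drawn, and each population
k receives a frequency p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so F is the
expected fixation index between populations.  Unadmixed individuals
draw genotypes Binomial(2, p_k); admixed individuals draw ancestry
proportions q ~ Dirichlet(alpha) and each of their two allele copies
independently picks a source population with probability q_k (the PSD
model — per-allele ancestry, no tract structure).

Linkage disequilibrium is emulated separately by a Markov copying chain
along haplotypes: each allele copies its left neighbour with
probability rho, otherwise it is drawn fresh, giving haplotypic
correlation that decays geometrically (≈ rho^lag), hence r² ≈ rho^(2·lag).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .genotype_io import MISSING, MARKER_COLUMNS, GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "simulate_populations",
    "simulate_ld_haplotypes",
    "inject_missing",
    "write_fixture",
]


@dataclass
class SimulationSpec:
    """Parameters of a structured-population simulation."""

    n_populations: int = 3
    samples_per_population: int = 50
    n_markers: int = 1000
    fst: float = 0.2
    admixture_alpha: float | None = None
    missing_rate: float = 0.0
    marker_spacing_bp: int = 1000
    seed: int = 0

    def validate(self):
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_populations < 1 or self.samples_per_population < 1 or self.n_markers < 1:
            raise ValueError("population, sample and marker counts must be >= 1")
        return self


def _marker_frame(n_markers: int, spacing: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["1"] * n_markers,
            "marker_id": [f"snp{j}" for j in range(n_markers)],
            "pos_cm": np.arange(1, n_markers + 1) * spacing * 1e-6,
            "pos_bp": np.arange(1, n_markers + 1, dtype=np.int64) * spacing,
            "allele1": ["A"] * n_markers,
            "allele2": ["G"] * n_markers,
        },
        columns=MARKER_COLUMNS,
    )


def simulate_populations(spec: SimulationSpec):
    """Balding–Nichols genotypes; returns (GenotypeMatrix, true Q matrix).

    Q rows are one-hot for unadmixed individuals, Dirichlet draws when
    ``admixture_alpha`` is set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K, npp, m, F = (
        spec.n_populations,
        spec.samples_per_population,
        spec.n_markers,
        spec.fst,
    )
    n = K * npp

    p_anc = rng.uniform(0.1, 0.9, size=m)
    if F == 0.0:
        p_pop = np.tile(p_anc, (K, 1))
    else:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_pop = rng.beta(a, b, size=(K, m))

    pop_of = np.repeat(np.arange(K), npp)
    if spec.admixture_alpha is None:
        q_true = np.eye(K)[pop_of]
        geno = rng.binomial(2, p_pop[pop_of, :]).astype(np.int8)
    else:
        q_true = rng.dirichlet(np.full(K, spec.admixture_alpha), size=n)
        # each of the two allele copies picks its source population from q
        geno = np.zeros((n, m), dtype=np.int8)
        for copy in range(2):
            anc = np.array([rng.choice(K, size=m, p=q_true[i]) for i in range(n)])
            geno += rng.binomial(1, p_pop[anc, np.arange(m)[None, :]]).astype(np.int8)

    g = GenotypeMatrix(
        geno,
        [f"ind{i}" for i in range(n)],
        [f"POP{k}" for k in pop_of],
        _marker_frame(m, spec.marker_spacing_bp),
    )
    if spec.missing_rate > 0.0:
        g = inject_missing(g, spec.missing_rate, seed=int(rng.integers(2**31)))
    return g, q_true


def simulate_ld_haplotypes(
    n_samples: int,
    n_markers: int,
    rho: float,
    allele_freq: float = 0.5,
    seed: int = 0,
    marker_spacing_bp: int = 1000,
) -> GenotypeMatrix:
    """Markov copying chain along haplotypes; genotype = two haplotypes.

    Adjacent-site haplotypic correlation is ≈ rho and decays as rho^lag.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    H = 2 * n_samples
    hap = np.empty((H, n_markers), dtype=np.int8)
    hap[:, 0] = rng.random(H) < allele_freq
    fresh = rng.random((H, n_markers)) < allele_freq
    copy = rng.random((H, n_markers)) < rho
    for j in range(1, n_markers):
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    geno = (hap[0::2] + hap[1::2]).astype(np.int8)
    return GenotypeMatrix(
        geno,
        [f"ind{i}" for i in range(n_samples)],
        ["POP0"] * n_samples,
        _marker_frame(n_markers, marker_spacing_bp),
    )


def inject_missing(g: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set floor(rate * n * m) uniformly chosen entries to MISSING."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n, m = g.genotypes.shape
    k = int(np.floor(rate * n * m))
    gt = g.genotypes.copy()
    if k > 0:
        flat = rng.choice(n * m, size=k, replace=False)
        gt[np.unravel_index(flat, (n, m))] = MISSING
    return GenotypeMatrix(gt, g.sample_ids, g.population_labels, g.marker_info)


def write_fixture(g: GenotypeMatrix, q_true: np.ndarray, spec: SimulationSpec, out_dir):
    """Write PLINK + EIGENSTRAT fixtures and a truth sidecar (JSON/TSV)."""
    from .genotype_io import write_eigenstrat, write_plink

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_plink(g, out / "fixture")
    write_eigenstrat(g, out / "fixture")
    np.savetxt(out / "true_q.tsv", q_true, delimiter="\t", fmt="%.6f")
    (out / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
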