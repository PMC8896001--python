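"""Genetic clustering with a softmax encoding.

Changing the latent layer to k units with a softmax turns the
autoencoder's encoding into a proportional assignment over k genetic
clusters — a Q-matrix in the admixture-analysis sense.  Training uses
the same reconstruction loss; the L2 penalty then acts on the (bounded)
post-softmax simplex vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, normalize_batch
from .model_core import ArchitectureConfig, Autoencoder, build_autoencoder, encode

__all__ = ["QMatrix", "build_clustering_model", "assign_clusters", "write_q", "read_q", "plot_q"]


@dataclass
class QMatrix:
    """Samples × k proportional cluster assignments (rows on the simplex)."""

    proportions: np.ndarray
    sample_ids: list
    population_labels: list

    @property
    def k(self) -> int:
        return self.proportions.shape[1]


def build_clustering_model(config: ArchitectureConfig, k: int, n_markers: int, seed: int = 0) -> Autoencoder:
    """Same architecture as the autoencoder, latent width k + softmax."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cfg = ArchitectureConfig.from_dict({**config.to_dict(), "latent_dim": k, "softmax_latent": True})
    return build_autoencoder(cfg, n_markers, seed=seed)


def assign_clusters(model: Autoencoder, g: GenotypeMatrix, batch_size: int = 128) -> QMatrix:
    """Inference-mode encoding (no noise or dropout) for every sample."""
    chunks = []
    for start in range(0, g.n_samples, batch_size):
        idx = np.arange(start, min(start + batch_size, g.n_samples))
        chunks.append(encode(model, normalize_batch(g, idx), training=False).coords)
    q = np.vstack(chunks)
    return QMatrix(proportions=q, sample_ids=g.sample_ids, population_labels=g.population_labels)


def write_q(q: QMatrix, path):
    """Write the .Q convention: whitespace-delimited k columns per sample.

    A companion <path>.samples file stores sample ids and labels.
    """
    path = Path(path)
    np.savetxt(path, q.proportions, fmt="%.6f", delimiter=" ")
    with open(str(path) + ".samples", "w") as fh:
        for sid, pop in zip(q.sample_ids, q.population_labels):
            fh.write(f"{sid}\t{pop}\n")


def read_q(path) -> QMatrix:
    """Read a .Q-style whitespace matrix (companion samples file optional)."""
    path = Path(path)
    props = np.atleast_2d(np.loadtxt(path))
    samples_path = Path(str(path) + ".samples")
    if samples_path.exists():
        rows = [ln.split("\t") for ln in samples_path.read_text().splitlines() if ln]
        sample_ids = [r[0] for r in rows]
        labels = [r[1] if len(r) > 1 else "UNKNOWN" for r in rows]
    else:
        sample_ids = [f"sample{i}" for i in range(props.shape[0])]
        labels = ["UNKNOWN"] * props.shape[0]
    return QMatrix(proportions=props, sample_ids=sample_ids, population_labels=labels)


def plot_q(q: QMatrix, path, superpop_map=None):
    """Stacked-bar plot ordered by population (then superpopulation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(q.population_labels)
    if superpop_map is not None:
        order = np.lexsort((labels, np.array([superpop_map[l] for l in labels])))
    else:
        order = np.argsort(labels, kind="stable")
    props = q.proportions[order]
    fig, ax = plt.subplots(figsize=(max(6, q.proportions.shape[0] / 20), 3))
    bottom = np.zeros(props.shape[0])
    x = np.arange(props.shape[0])
    for comp in range(q.k):
        ax.bar(x, props[:, comp], bottom=bottom, width=1.0)
        bottom += props[:, comp]
    ax.set_xlim(-0.5, props.shape[0] - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry proportion")
    # population boundaries
    ordered = labels[order]
    ticks = [i for i in range(1, len(ordered)) if ordered[i] != ordered[i - 1]]
    for t in ticks:
        ax.axvline(t - 0.5, color="black", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
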