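"""Embedding quality via k-nearest-neighbour classification F1.

A sample's population (or superpopulation) is predicted as the modal
label among its k nearest neighbours in the embedding, excluding the
sample itself; the score is the class-size-weighted mean of per-class
F1.  A PCA baseline with SMARTPCA-style per-SNP normalization is
included for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score

from .genotype_io import MISSING, DegenerateDataError, GenotypeMatrix, SuperpopulationMap
from .model_core import LatentEmbedding

__all__ = [
    "EvaluationResult",
    "knn_predict",
    "weighted_f1",
    "evaluate_embedding",
    "pca_baseline",
]


@dataclass
class EvaluationResult:
    k: int
    level: str  # "population" | "superpopulation"
    f1: float
    per_class_f1: dict
    n_samples: int
    d: int


def knn_predict(embedding, labels, k: int):
    """Majority vote among the k nearest neighbours (self excluded).

    Ties between labels are broken by the smaller summed distance of the
    tied labels' neighbours, then lexicographically.  Neighbour ties at
    equal distance resolve by stable index order.
    """
    coords = embedding.coords if isinstance(embedding, LatentEmbedding) else np.asarray(embedding, float)
    labels = np.asarray(labels)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples (k={k}, n={n})")
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)  # self-exclusion
    predictions = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        nn = np.argsort(dist[i], kind="stable")[:k]
        votes = {}
        for j in nn:
            lab = labels[j]
            cnt, dsum = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, dsum + dist[i, j])
        # most votes, then smaller summed distance, then lexicographic
        predictions[i] = min(votes, key=lambda lab: (-votes[lab][0], votes[lab][1], str(lab)))
    return predictions


def weighted_f1(true_labels, predicted_labels) -> float:
    """Class-size-weighted mean of per-class F1 (harmonic mean of P and R).

    Classes with precision + recall = 0 contribute 0.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size == 0:
        raise ValueError("empty label vectors")
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    return float(
        f1_score(true_labels, predicted_labels, average="weighted", zero_division=0)
    )


def per_class_f1(true_labels, predicted_labels) -> dict:
    classes = np.unique(np.asarray(true_labels))
    scores = f1_score(
        true_labels, predicted_labels, labels=classes, average=None, zero_division=0
    )
    return {str(c): float(s) for c, s in zip(classes, scores)}


def evaluate_embedding(
    embedding,
    labels,
    superpop_map: SuperpopulationMap | None = None,
    ks=(3, 20),
) -> list:
    """One EvaluationResult per (k, level) pair over the full sample set."""
    coords = embedding.coords if isinstance(embedding, LatentEmbedding) else np.asarray(embedding, float)
    labels = np.asarray(labels)
    levels = {"population": labels}
    if superpop_map is not None:
        unmapped = sorted({l for l in labels if l not in superpop_map.mapping})
        if unmapped:
            raise ValueError(f"populations missing from superpopulation map: {unmapped}")
        levels["superpopulation"] = np.array([superpop_map[l] for l in labels])
    results = []
    for k in ks:
        for level, labs in levels.items():
            pred = knn_predict(coords, labs, k)
            results.append(
                EvaluationResult(
                    k=int(k),
                    level=level,
                    f1=weighted_f1(labs, pred),
                    per_class_f1=per_class_f1(labs, pred),
                    n_samples=coords.shape[0],
                    d=coords.shape[1],
                )
            )
    return results


def pca_baseline(g: GenotypeMatrix, d: int) -> LatentEmbedding:
    """PCA with SMARTPCA normalization.

    Per marker j the allele frequency is estimated with a pseudo-count,
    p_j = (1 + sum_i g_ij) / (2 + 2n), and genotypes are normalized as
    (g_ij - mean_j) / sqrt(p_j (1 - p_j)) before the eigendecomposition.
    Component signs follow the deterministic largest-magnitude-loading-
    positive convention.
    """
    gt = g.genotypes
    if np.any(gt == MISSING):
        raise ValueError("pca_baseline requires imputed (non-missing) genotypes")
    gt = gt.astype(float)
    n = gt.shape[0]
    mono = np.all(gt == gt[0], axis=0)
    if mono.any():
        raise DegenerateDataError(
            "monomorphic markers present; apply a MAF filter before PCA"
        )
    p_hat = (1.0 + gt.sum(axis=0)) / (2.0 + 2.0 * n)
    normalized = (gt - gt.mean(axis=0)) / np.sqrt(p_hat * (1.0 - p_hat))
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(normalized)
    return LatentEmbedding(coords=scores)
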