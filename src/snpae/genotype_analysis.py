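"""Comparing model-output genotypes to the truth.

Two complementary views: the joint site-frequency spectrum (how well
per-site allele frequencies are reproduced) and the decay of linkage
disequilibrium with distance (whether spatial structure along the
chromosome survives the round trip through the bottleneck).

R² here is the Rogers–Huff composite measure: the squared Pearson
correlation of unphased dosage vectors over samples non-missing at both
sites.  Allele-frequency orientation follows the counted (A1) allele
throughout, so "derived" is orientation-relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import (
    MISSING,
    DegenerateDataError,
    GenotypeMatrix,
    allele_frequencies,
    normalize_batch,
)
from .model_core import Autoencoder, hwe_frequencies

__all__ = [
    "LDDecayProfile",
    "SFSComparison",
    "reconstruct_genotypes",
    "exclude_fixed_sites",
    "pairwise_r2",
    "ld_decay",
    "sfs_compare",
    "read_bed_intervals",
]


@dataclass
class LDDecayProfile:
    """Mean r² per inter-site distance bin (bp)."""

    bin_edges: np.ndarray  # length n_bins + 1
    mean_r2: np.ndarray  # NaN for empty bins
    pair_counts: np.ndarray


@dataclass
class SFSComparison:
    """Joint histogram of (true, output) per-site allele frequencies."""

    joint_hist: np.ndarray  # (n_bins, n_bins) counts
    bin_edges: np.ndarray  # shared axis on [0, 1]


def reconstruct_genotypes(model: Autoencoder, g: GenotypeMatrix, batch_size: int = 128) -> GenotypeMatrix:
    """Hard-call output genotypes: argmax of the Hardy–Weinberg triple.

    The exact argmax ties (o = 1/3 or 2/3 boundaries) resolve to the
    heterozygote.  Metadata is copied from the input.
    """
    out = np.empty_like(g.genotypes)
    for start in range(0, g.n_samples, batch_size):
        idx = np.arange(start, min(start + batch_size, g.n_samples))
        _, o_raw = model.forward_t(normalize_batch(g, idx).values, training=False)
        probs = hwe_frequencies(o_raw.data).genotype_probs
        # bias the heterozygote by epsilon so boundary ties resolve to 1
        tie_break = np.array([0.0, 1e-12, 0.0])
        out[idx] = (probs + tie_break).argmax(axis=-1).astype(np.int8)
    return GenotypeMatrix(out, g.sample_ids, g.population_labels, g.marker_info)


def exclude_fixed_sites(true_g: GenotypeMatrix, out_g: GenotypeMatrix) -> np.ndarray:
    """Indices of sites polymorphic in the OUTPUT genotypes.

    Sites where the output carries only one allele (frequency 0 or 1)
    have undefined R² and are dropped from both matrices downstream so
    the same site set is compared.
    """
    if true_g.n_markers != out_g.n_markers:
        raise ValueError("matrices must share their marker set")
    p = allele_frequencies(out_g.genotypes)
    keep = np.flatnonzero((p > 0.0) & (p < 1.0))
    if keep.size == 0:
        raise DegenerateDataError("every output site is fixed; nothing to analyse")
    return keep


def read_bed_intervals(path) -> list:
    """BED intervals (0-based half-open) as a list of (start, end)."""
    intervals = []
    for ln in open(path):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split()
        intervals.append((int(parts[1]), int(parts[2])))
    return sorted(intervals)


def _in_intervals(pos_bp: np.ndarray, intervals) -> np.ndarray:
    """True where the 0-based coordinate (pos_bp - 1) falls in an interval."""
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    zero_based = pos_bp - 1
    idx = np.searchsorted(starts, zero_based, side="right") - 1
    ok = idx >= 0
    ok[ok] &= zero_based[ok] < ends[idx[ok]]
    return ok


def pairwise_r2(
    g: GenotypeMatrix,
    interval=None,
    maf_threshold: float = 0.0,
    mask_intervals=None,
):
    """All-pairs (distance bp, r²) after positional/MAF/mask filtering.

    Restricted to a single chromosome.  Pairs where either dosage
    column is constant over the jointly non-missing samples are skipped.
    """
    chroms = g.marker_info["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("pairwise_r2 expects markers from a single chromosome")
    pos = g.marker_info["pos_bp"].to_numpy()
    keep = np.ones(g.n_markers, dtype=bool)
    if interval is not None:
        lo, hi = interval
        keep &= (pos >= lo) & (pos <= hi)
    if maf_threshold > 0.0:
        p = allele_frequencies(g.genotypes)
        keep &= np.minimum(p, 1.0 - p) >= maf_threshold
    if mask_intervals is not None:
        keep &= _in_intervals(pos, mask_intervals)
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise DegenerateDataError("fewer than 2 sites survive the filters")

    gt = g.genotypes[:, idx].astype(float)
    pos = pos[idx]
    missing = g.genotypes[:, idx] == MISSING
    pairs = []
    if not missing.any():
        # vectorized path: full-sample Pearson correlation matrix
        centered = gt - gt.mean(axis=0)
        sd = centered.std(axis=0)
        ok = sd > 0
        c = centered[:, ok] / sd[ok]
        r = (c.T @ c) / gt.shape[0]
        pos_ok = pos[ok]
        iu, ju = np.triu_indices(ok.sum(), k=1)
        dist = np.abs(pos_ok[ju] - pos_ok[iu]).astype(float)
        pairs = list(zip(dist, (r[iu, ju] ** 2).astype(float)))
    else:
        gt_m = np.ma.masked_array(gt, mask=missing)
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                both = ~missing[:, a] & ~missing[:, b]
                if both.sum() < 2:
                    continue
                x, y = gt[both, a], gt[both, b]
                sx, sy = x.std(), y.std()
                if sx == 0.0 or sy == 0.0:
                    continue
                r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
                pairs.append((float(abs(pos[b] - pos[a])), float(r * r)))
    if not pairs:
        raise DegenerateDataError(
            "no pair of sites with variable dosages; R² is undefined everywhere"
        )
    return pairs


def ld_decay(pairs, n_bins: int = 25) -> LDDecayProfile:
    """Equal-width distance bins on [0, max distance]; per-bin mean r².

    Empty bins report count 0 and NaN mean.
    """
    if not len(pairs):
        raise ValueError("ld_decay requires at least one (distance, r2) pair")
    dist = np.array([d for d, _ in pairs], dtype=float)
    r2 = np.array([r for _, r in pairs], dtype=float)
    edges = np.linspace(0.0, dist.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayProfile(bin_edges=edges, mean_r2=means, pair_counts=counts)


def sfs_compare(true_g: GenotypeMatrix, out_g: GenotypeMatrix, n_bins: int = 100) -> SFSComparison:
    """Joint 2-D histogram of per-site allele frequencies (truth vs output)."""
    if true_g.n_markers != out_g.n_markers:
        raise ValueError("matrices must share their marker set")
    f_true = allele_frequencies(true_g.genotypes)
    f_out = allele_frequencies(out_g.genotypes)
    hist, edges, _ = np.histogram2d(f_true, f_out, bins=n_bins, range=[[0, 1], [0, 1]])
    return SFSComparison(joint_hist=hist, bin_edges=edges)


def write_ld_profile(profile: LDDecayProfile, path):
    """TSV: bin_low, bin_high, mean_r2, n_pairs."""
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tmean_r2\tn_pairs\n")
        for lo, hi, m, c in zip(
            profile.bin_edges[:-1], profile.bin_edges[1:], profile.mean_r2, profile.pair_counts
        ):
            mtxt = "NA" if np.isnan(m) else f"{m:.6f}"
            fh.write(f"{lo:.1f}\t{hi:.1f}\t{mtxt}\t{int(c)}\n")


def plot_analysis(sfs: SFSComparison, true_profile: LDDecayProfile, out_profile: LDDecayProfile, path):
    """Two panels: SFS heat map and the two LD-decay curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    with np.errstate(divide="ignore"):
        img = np.log10(sfs.joint_hist.T + 1)
    ax1.imshow(img, origin="lower", extent=[0, 1, 0, 1], aspect="auto")
    ax1.set_xlabel("true allele frequency")
    ax1.set_ylabel("output allele frequency")
    for profile, label in ((true_profile, "true"), (out_profile, "output")):
        mid = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
        ok = profile.pair_counts > 0
        ax2.plot(mid[ok], profile.mean_r2[ok], marker="o", ms=3, label=label)
    ax2.set_xlabel("distance (bp)")
    ax2.set_ylabel("mean $R^2$")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
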