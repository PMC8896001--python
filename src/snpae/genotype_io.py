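"""Genotype containers, file formats and preprocessing.

The central container is :class:`GenotypeMatrix`: a samples × markers
matrix of diploid dosages (0/1/2, ``MISSING`` = -1) plus sample and
marker metadata.  Readers/writers cover PLINK 1 binary (.bed/.bim/.fam,
SNP-major), EIGENSTRAT (.geno/.snp/.ind) and VCF (biallelic SNPs,
read-only).

Allele orientation: dosage counts copies of the A1 allele as listed in
.bim column 5 (plink's minor-allele convention).  This choice flips the
orientation of downstream site-frequency spectra, so it is stated here
once and relied on everywhere else.

Preprocessing follows the standard chain applied to SNP data before
structure analysis: drop non-informative (monomorphic) sites and
excluded chromosomes, enforce a minor-allele-frequency threshold, prune
linked sites in centimorgan windows, and impute remaining missing calls
with the per-site modal genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

MARKER_COLUMNS = ["chrom", "marker_id", "pos_cm", "pos_bp", "allele1", "allele2"]


class GenotypeFormatError(ValueError):
    """A genotype file violates its format contract."""


class DegenerateDataError(ValueError):
    """An operation produced or received an unusably empty data set."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with metadata.

    genotypes: int8 array (n_samples, n_markers), values in {0, 1, 2, MISSING}.
    marker_info: DataFrame with columns chrom, marker_id, pos_cm, pos_bp,
        allele1, allele2 (pos_cm may be NaN when no genetic map is available).
    """

    genotypes: np.ndarray
    sample_ids: list
    population_labels: list
    marker_info: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or min(self.genotypes.shape) < 1:
            raise ValueError("genotypes must be a non-empty 2-D matrix")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, 2, MISSING}")
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if len(self.population_labels) != self.genotypes.shape[0]:
            raise ValueError("population_labels length mismatch")
        if len(self.marker_info) != self.genotypes.shape[1]:
            raise ValueError("marker_info length mismatch")
        self.sample_ids = list(self.sample_ids)
        self.population_labels = list(self.population_labels)
        self.marker_info = self.marker_info.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.genotypes[:, index],
            self.sample_ids,
            self.population_labels,
            self.marker_info.iloc[index],
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.genotypes[index],
            [self.sample_ids[i] for i in index],
            [self.population_labels[i] for i in index],
            self.marker_info,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.sample_ids == other.sample_ids
            and self.population_labels == other.population_labels
            and _frames_equal(self.marker_info, other.marker_info)
        )


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for c in a.columns:
        av, bv = a[c].to_numpy(), b[c].to_numpy()
        if np.issubdtype(av.dtype, np.number) and np.issubdtype(bv.dtype, np.number):
            if not np.allclose(av.astype(float), bv.astype(float), equal_nan=True):
                return False
        elif not np.array_equal(av, bv):
            return False
    return True


@dataclass
class NormalizedBatch:
    """Model-ready tensor: (batch, n_markers, 3).

    Channel 0: genotype mapped 0→0.0, 1→0.5, 2→1.0, missing → -1.0.
    Channel 1: missingness mask (1 = observed).
    Channel 2: marker-specific variable broadcast across the batch.
    """

    values: np.ndarray
    sample_indices: np.ndarray


@dataclass
class TargetTensor:
    """One-hot targets (batch, n_markers, 3) plus per-genotype loss weights."""

    probs: np.ndarray
    weight_mask: np.ndarray


@dataclass
class SuperpopulationMap:
    mapping: dict = field(default_factory=dict)

    @classmethod
    def read(cls, path) -> "SuperpopulationMap":
        """Two-column TSV (population, superpopulation), no header."""
        mapping = {}
        for ln in Path(path).read_text().splitlines():
            if not ln.strip():
                continue
            parts = ln.split("\t") if "\t" in ln else ln.split()
            if len(parts) < 2:
                raise GenotypeFormatError(f"malformed superpopulation map line: {ln!r}")
            mapping[parts[0]] = parts[1]
        return cls(mapping)

    def write(self, path):
        with open(path, "w") as fh:
            for pop, sup in self.mapping.items():
                fh.write(f"{pop}\t{sup}\n")

    def __getitem__(self, pop):
        return self.mapping[pop]


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

_PLINK_MAGIC = bytes([0x6C, 0x1B])
# 2-bit code -> dosage of A1: 00 hom A1/A1, 01 missing, 10 het, 11 hom A2/A2
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_BYTE_TABLE = np.zeros((256, 4), dtype=np.int8)
for _byte in range(256):
    for _i in range(4):
        _BYTE_TABLE[_byte, _i] = _CODE_TO_DOSAGE[(_byte >> (2 * _i)) & 0b11]


def read_plink(path_prefix) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triple (SNP-major .bed only).

    The .fam family-ID column is used as the population label.
    """
    prefix = Path(path_prefix)
    paths = {ext: Path(str(prefix) + f".{ext}") for ext in ("bed", "bim", "fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None, dtype=str)
    sample_ids = fam[1].tolist()
    populations = fam[0].tolist()
    n = len(sample_ids)

    bim = pd.read_csv(paths["bim"], sep=r"\s+", header=None, dtype=str)
    marker_info = pd.DataFrame(
        {
            "chrom": bim[0].astype(str),
            "marker_id": bim[1].astype(str),
            "pos_cm": pd.to_numeric(bim[2]),
            "pos_bp": pd.to_numeric(bim[3]).astype(np.int64),
            "allele1": bim[4].astype(str),
            "allele2": bim[5].astype(str),
        }
    )
    m = len(marker_info)

    raw = paths["bed"].read_bytes()
    if len(raw) < 3 or raw[:2] != _PLINK_MAGIC:
        raise GenotypeFormatError(f"{paths['bed']}: not a PLINK .bed file (bad magic)")
    if raw[2] != 0x01:
        raise GenotypeFormatError(
            f"{paths['bed']}: sample-major .bed files are not supported"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise GenotypeFormatError(
            f"{paths['bed']}: expected {expected} bytes for {n} samples × {m} markers, "
            f"found {len(raw)}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    decoded = _BYTE_TABLE[body].reshape(m, bytes_per_snp * 4)[:, :n]
    return GenotypeMatrix(decoded.T.copy(), sample_ids, populations, marker_info)


def write_plink(g: GenotypeMatrix, path_prefix):
    """Write a GenotypeMatrix as .bed/.bim/.fam (SNP-major)."""
    prefix = Path(path_prefix)
    n, m = g.n_samples, g.n_markers
    with open(Path(str(prefix) + ".fam"), "w") as fh:
        for sid, pop in zip(g.sample_ids, g.population_labels):
            fh.write(f"{pop} {sid} 0 0 0 -9\n")
    with open(Path(str(prefix) + ".bim"), "w") as fh:
        for row in g.marker_info.itertuples(index=False):
            cm = 0.0 if pd.isna(row.pos_cm) else row.pos_cm
            fh.write(
                f"{row.chrom} {row.marker_id} {cm:g} {row.pos_bp} "
                f"{row.allele1} {row.allele2}\n"
            )
    bytes_per_snp = (n + 3) // 4
    body = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0b01  # pad positions encode as missing; ignored on read
    gt = g.genotypes.T  # (m, n)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][gt == dosage] = code
    for i in range(4):
        body |= (codes[:, i::4] & 0b11).astype(np.uint8) << (2 * i)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC + b"\x01")
        fh.write(body.tobytes())


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def read_eigenstrat(path_prefix) -> GenotypeMatrix:
    """Read EIGENSTRAT .geno/.snp/.ind.

    .geno has one line per SNP, one digit per sample (9 = missing).  The
    .snp genetic-distance column is in Morgans and converted to cM.
    """
    prefix = Path(path_prefix)
    paths = {ext: Path(str(prefix) + f".{ext}") for ext in ("geno", "snp", "ind")}
    for p in paths.values():
        if not p.exists():
            raise FileNotFoundError(f"missing EIGENSTRAT file: {p}")

    ind = pd.read_csv(paths["ind"], sep=r"\s+", header=None, dtype=str)
    sample_ids = ind[0].tolist()
    populations = ind[2].tolist()
    n = len(sample_ids)

    snp = pd.read_csv(paths["snp"], sep=r"\s+", header=None, dtype=str)
    marker_info = pd.DataFrame(
        {
            "chrom": snp[1].astype(str),
            "marker_id": snp[0].astype(str),
            "pos_cm": pd.to_numeric(snp[2]) * 100.0,  # Morgans -> cM
            "pos_bp": pd.to_numeric(snp[3]).astype(np.int64),
            "allele1": snp[4].astype(str),
            "allele2": snp[5].astype(str),
        }
    )

    rows = []
    for lineno, ln in enumerate(paths["geno"].read_text().splitlines(), 1):
        ln = ln.strip()
        if not ln:
            continue
        if len(ln) != n:
            raise GenotypeFormatError(
                f"{paths['geno']} line {lineno}: {len(ln)} genotypes for {n} samples"
            )
        if not ln.isdigit():
            raise GenotypeFormatError(
                f"{paths['geno']} line {lineno}: non-digit genotype character"
            )
        row = np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0")
        if np.any((row > 2) & (row != 9)):
            raise GenotypeFormatError(
                f"{paths['geno']} line {lineno}: genotype digit outside {{0,1,2,9}}"
            )
        rows.append(row)
    if len(rows) != len(marker_info):
        raise GenotypeFormatError(
            f"{paths['geno']}: {len(rows)} SNP lines but .snp lists {len(marker_info)}"
        )
    geno = np.array(rows, dtype=np.int8).T  # samples × markers
    geno[geno == 9] = MISSING
    return GenotypeMatrix(geno, sample_ids, populations, marker_info)


def write_eigenstrat(g: GenotypeMatrix, path_prefix):
    prefix = Path(path_prefix)
    with open(Path(str(prefix) + ".ind"), "w") as fh:
        for sid, pop in zip(g.sample_ids, g.population_labels):
            fh.write(f"{sid} U {pop}\n")
    with open(Path(str(prefix) + ".snp"), "w") as fh:
        for row in g.marker_info.itertuples(index=False):
            morgans = 0.0 if pd.isna(row.pos_cm) else row.pos_cm / 100.0
            fh.write(
                f"{row.marker_id} {row.chrom} {morgans:.6f} {row.pos_bp} "
                f"{row.allele1} {row.allele2}\n"
            )
    gt = g.genotypes.T.astype(np.int16).copy()
    gt[gt == MISSING] = 9
    with open(Path(str(prefix) + ".geno"), "w") as fh:
        for row in gt:
            fh.write("".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# VCF (read only)
# ---------------------------------------------------------------------------

def read_vcf(path, populations=None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; dosage counts ALT allele copies.

    populations: optional dict sample_id -> population label (default
    "UNKNOWN" for all samples).  Any allele index outside {0, 1} raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, records = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeFormatError(
                f"{path}: non-biallelic record at {var.CHROM}:{var.POS}"
            )
        gts = np.asarray(var.genotype.array())  # (n, 3): a0, a1, phased
        alleles = gts[:, :2]
        if np.any(alleles > 1):
            raise GenotypeFormatError(
                f"{path}: allele index > 1 at {var.CHROM}:{var.POS}"
            )
        dosage = np.where(
            (alleles < 0).any(axis=1), MISSING, alleles.clip(min=0).sum(axis=1)
        ).astype(np.int8)
        rows.append(dosage)
        records.append(
            (str(var.CHROM), var.ID or f"{var.CHROM}:{var.POS}", np.nan,
             int(var.POS), str(var.ALT[0]), str(var.REF))
        )
    if not rows:
        raise DegenerateDataError(f"{path}: no variant records")
    marker_info = pd.DataFrame(records, columns=MARKER_COLUMNS)
    pops = [populations.get(s, "UNKNOWN") if populations else "UNKNOWN"
            for s in sample_ids]
    return GenotypeMatrix(np.array(rows, dtype=np.int8).T, sample_ids, pops, marker_info)


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the counted allele over non-missing calls.

    Markers with no non-missing calls get frequency 0.
    """
    obs = genotypes != MISSING
    n_obs = obs.sum(axis=0)
    total = np.where(obs, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, total / np.maximum(2 * n_obs, 1), 0.0)
    return p


def filter_informative(g: GenotypeMatrix, exclude_chromosomes=frozenset()) -> GenotypeMatrix:
    """Drop markers on excluded chromosomes and monomorphic sites.

    A site is monomorphic when all non-missing calls are identical
    (all-missing sites count as monomorphic).
    """
    exclude = {str(c) for c in exclude_chromosomes}
    chrom_ok = ~g.marker_info["chrom"].astype(str).isin(exclude).to_numpy()
    gt = np.ma.masked_equal(g.genotypes, MISSING)
    polymorphic = (gt.max(axis=0) != gt.min(axis=0)).filled(False)
    keep = np.flatnonzero(chrom_ok & polymorphic)
    if keep.size == 0:
        raise DegenerateDataError("no markers remain after informativeness filtering")
    return g.subset_markers(keep)


def maf_filter(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep markers with minor-allele frequency >= threshold.

    MAF is min(p, 1-p) with p computed over non-missing calls; sites
    with no non-missing calls are removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    p = allele_frequencies(g.genotypes)
    maf = np.minimum(p, 1.0 - p)
    n_obs = (g.genotypes != MISSING).sum(axis=0)
    keep = np.flatnonzero((maf >= threshold) & (n_obs > 0))
    if keep.size == 0:
        raise DegenerateDataError("no markers remain after MAF filtering")
    return g.subset_markers(keep)


def _genetic_positions_cm(g: GenotypeMatrix) -> np.ndarray:
    """cM positions; falls back to 1 cM ≡ 1 Mb where the map is absent.

    The map counts as absent when every genetic position is NaN or zero
    (the .bim convention for "no map").  Individually missing values are
    filled from the bp fallback.
    """
    cm = g.marker_info["pos_cm"].to_numpy(dtype=float)
    fallback = g.marker_info["pos_bp"].to_numpy(dtype=float) * 1e-6
    finite = np.isfinite(cm)
    if not finite.any() or np.nanmax(np.abs(np.where(finite, cm, 0.0))) == 0.0:
        warnings.warn(
            "no genetic map available; approximating 1 cM = 1 Mb from bp positions",
            stacklevel=3,
        )
        return fallback
    return np.where(finite, cm, fallback)


def _pairwise_dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over samples
    non-missing at both sites; 0.0 if either is constant there."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(g: GenotypeMatrix, window_cm: float = 1.0, r2_max: float = 0.2) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within centimorgan windows.

    Scanning each chromosome by position, a marker is dropped when its
    allelic R² with any previously retained marker within ``window_cm``
    exceeds ``r2_max`` (the downstream member of the pair is removed).
    """
    cm = _genetic_positions_cm(g)
    chroms = g.marker_info["chrom"].to_numpy()
    keep = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(cm[idx], kind="stable")]
        kept_on_chrom = []
        for j in idx:
            ok = True
            for i in reversed(kept_on_chrom):
                if cm[j] - cm[i] > window_cm:
                    break
                if _pairwise_dosage_r2(g.genotypes[:, i], g.genotypes[:, j]) > r2_max:
                    ok = False
                    break
            if ok:
                kept_on_chrom.append(j)
        keep.extend(kept_on_chrom)
    if not keep:
        warnings.warn("LD pruning removed every marker", stacklevel=2)
    keep = np.sort(np.array(keep, dtype=int))
    return g.subset_markers(keep)


def impute_most_frequent(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-marker modal genotype.

    Ties are broken by the smaller genotype value.  All-missing markers
    raise: filter them out first.
    """
    gt = g.genotypes.copy()
    counts = np.stack([(gt == v).sum(axis=0) for v in (0, 1, 2)])  # (3, m)
    if np.any(counts.sum(axis=0) == 0):
        raise DegenerateDataError(
            "marker(s) with all calls missing; apply filter_informative/maf_filter first"
        )
    modes = counts.argmax(axis=0).astype(np.int8)  # argmax takes smallest on ties
    miss = gt == MISSING
    gt[miss] = np.broadcast_to(modes, gt.shape)[miss]
    return GenotypeMatrix(gt, g.sample_ids, g.population_labels, g.marker_info)


# ---------------------------------------------------------------------------
# model input/target encoding
# ---------------------------------------------------------------------------

_NORM = np.array([0.0, 0.5, 1.0])


def normalize_batch(g: GenotypeMatrix, sample_indices, marker_variable=None) -> NormalizedBatch:
    """Encode genotypes for the network: (batch, n_markers, 3).

    Genotypes map 0→0.0, 1→0.5, 2→1.0 and missing → -1.0 in channel 0;
    channel 1 is the missingness mask; channel 2 broadcasts
    ``marker_variable`` (zeros when not given).
    """
    sample_indices = np.asarray(sample_indices, dtype=int)
    gt = g.genotypes[sample_indices]
    miss = gt == MISSING
    ch0 = np.where(miss, -1.0, _NORM[np.clip(gt, 0, 2)])
    ch1 = (~miss).astype(float)
    if marker_variable is None:
        marker_variable = np.zeros(g.n_markers)
    ch2 = np.broadcast_to(np.asarray(marker_variable, dtype=float), gt.shape)
    values = np.stack([ch0, ch1, ch2], axis=-1)
    return NormalizedBatch(values=values, sample_indices=sample_indices)


def one_hot_targets(g: GenotypeMatrix, sample_indices, class_weights=(1.0, 1.0, 1.0)) -> TargetTensor:
    """One-hot (batch, n_markers, 3) targets with per-genotype loss weights.

    Requires fully imputed genotypes for the selected samples.
    """
    sample_indices = np.asarray(sample_indices, dtype=int)
    gt = g.genotypes[sample_indices]
    if np.any(gt == MISSING):
        raise ValueError("one_hot_targets requires imputed (non-missing) genotypes")
    probs = np.eye(3)[gt]
    weights = np.asarray(class_weights, dtype=float)[gt]
    return TargetTensor(probs=probs, weight_mask=weights)


def denormalize(channel0: np.ndarray) -> np.ndarray:
    """Inverse of the channel-0 genotype mapping (missing stays MISSING)."""
    out = np.full(channel0.shape, MISSING, dtype=np.int8)
    for dosage, v in enumerate(_NORM):
        out[np.isclose(channel0, v)] = dosage
    return out


def stratified_split(g: GenotypeMatrix, train_fraction: float = 0.8, seed: int = 0):
    """Population-stratified train/validation index split.

    Per population the training share is round(train_fraction × n_pop),
    clamped to [1, n_pop]; single-sample populations go to training with
    a warning.  If rounding empties the validation set entirely, falls
    back to a global unstratified split at the same fraction.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(g.population_labels)
    train, valid = [], []
    for pop in pd.unique(labels):
        idx = np.flatnonzero(labels == pop)
        if idx.size == 1:
            warnings.warn(f"population {pop!r} has a single sample; assigned to training")
            train.extend(idx)
            continue
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        valid.extend(perm[n_train:])
    if not valid:
        warnings.warn(
            "stratified split produced an empty validation set; "
            "falling back to a global split"
        )
        n = g.n_samples
        n_train = min(max(int(round(train_fraction * n)), 1), n - 1)
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(valid, dtype=int))
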