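import warnings

import numpy as np
import pytest

from snpae.genotype_io import (
    MISSING,
    DegenerateDataError,
    GenotypeFormatError,
    GenotypeMatrix,
    SuperpopulationMap,
    denormalize,
    filter_informative,
    impute_most_frequent,
    ld_prune,
    maf_filter,
    normalize_batch,
    one_hot_targets,
    read_eigenstrat,
    read_plink,
    read_vcf,
    stratified_split,
    write_eigenstrat,
    write_plink,
)

from conftest import make_matrix, random_matrix


# ---------------------------------------------------------------------------
# PLINK
# ---------------------------------------------------------------------------

class TestPlink:
    def test_round_trip_identity(self, rng, tmp_path):
        g = random_matrix(rng, n=5, m=10)
        write_plink(g, tmp_path / "x")
        assert read_plink(tmp_path / "x") == g

    def test_hand_packed_bed(self, tmp_path):
        # 2 samples, 3 markers, genotypes [[0,1,2],[MISSING,2,0]].
        # SNP-major 2-bit codes (counting A1 copies): 0->11, 1->10, 2->00, miss->01;
        # low bits = first sample.
        (tmp_path / "h.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0x07, 0x02, 0x0C]))
        (tmp_path / "h.fam").write_text("F1 s0 0 0 0 -9\nF2 s1 0 0 0 -9\n")
        (tmp_path / "h.bim").write_text(
            "1 a 0 100 A G\n1 b 0 200 A G\n1 c 0 300 A G\n"
        )
        g = read_plink(tmp_path / "h")
        assert np.array_equal(g.genotypes, [[0, 1, 2], [MISSING, 2, 0]])
        assert g.population_labels == ["F1", "F2"]

    def test_sample_major_rejected(self, rng, tmp_path):
        g = random_matrix(rng, n=4, m=4)
        write_plink(g, tmp_path / "x")
        raw = bytearray((tmp_path / "x.bed").read_bytes())
        raw[2] = 0x00
        (tmp_path / "x.bed").write_bytes(bytes(raw))
        with pytest.raises(GenotypeFormatError, match="sample-major"):
            read_plink(tmp_path / "x")

    def test_truncated_bed(self, rng, tmp_path):
        g = random_matrix(rng, n=4, m=4)
        write_plink(g, tmp_path / "x")
        raw = (tmp_path / "x.bed").read_bytes()
        (tmp_path / "x.bed").write_bytes(raw[:-1])
        with pytest.raises(GenotypeFormatError, match="bytes"):
            read_plink(tmp_path / "x")

    def test_missing_file_named(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nothere"):
            read_plink(tmp_path / "nothere")

    def test_bad_magic(self, rng, tmp_path):
        g = random_matrix(rng, n=4, m=4)
        write_plink(g, tmp_path / "x")
        raw = (tmp_path / "x.bed").read_bytes()
        (tmp_path / "x.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(GenotypeFormatError, match="magic"):
            read_plink(tmp_path / "x")


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

class TestEigenstrat:
    def test_hand_fixture(self, tmp_path):
        # one .geno line per SNP, one digit per sample (9 = missing)
        (tmp_path / "e.geno").write_text("092\n122\n200\n201\n")
        (tmp_path / "e.snp").write_text(
            "".join(f"snp{j} 1 0.0{j} {100*(j+1)} A G\n" for j in range(4))
        )
        (tmp_path / "e.ind").write_text("s0 U P1\ns1 U P1\ns2 U P2\n")
        g = read_eigenstrat(tmp_path / "e")
        assert np.array_equal(
            g.genotypes, [[0, 1, 2, 2], [MISSING, 2, 0, 0], [2, 2, 0, 1]]
        )
        assert g.population_labels == ["P1", "P1", "P2"]
        # genetic distance column is Morgans; stored in cM
        assert g.marker_info["pos_cm"].iloc[1] == pytest.approx(1.0)

    def test_round_trip_identity(self, rng, tmp_path):
        g = random_matrix(rng, n=6, m=9)
        write_eigenstrat(g, tmp_path / "e")
        g2 = read_eigenstrat(tmp_path / "e")
        assert np.array_equal(g2.genotypes, g.genotypes)
        assert g2.sample_ids == g.sample_ids
        assert g2.population_labels == g.population_labels

    def test_width_mismatch(self, tmp_path):
        (tmp_path / "e.geno").write_text("012\n201\n")
        (tmp_path / "e.snp").write_text("a 1 0 100 A G\nb 1 0 200 A G\n")
        (tmp_path / "e.ind").write_text("s0 U P1\ns1 U P1\n")
        with pytest.raises(GenotypeFormatError, match="genotypes for 2 samples"):
            read_eigenstrat(tmp_path / "e")

    def test_non_digit(self, tmp_path):
        (tmp_path / "e.geno").write_text("0x\n21\n")
        (tmp_path / "e.snp").write_text("a 1 0 100 A G\nb 1 0 200 A G\n")
        (tmp_path / "e.ind").write_text("s0 U P1\ns1 U P1\n")
        with pytest.raises(GenotypeFormatError, match="non-digit"):
            read_eigenstrat(tmp_path / "e")


def test_vcf_read(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1/1\t./.\n"
    )
    g = read_vcf(vcf)
    assert np.array_equal(g.genotypes, [[0, 2], [1, MISSING]])
    assert g.sample_ids == ["s0", "s1"]


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestFilters:
    def test_monomorphic_removed(self):
        g = make_matrix([[0, 0, 1], [0, 1, 2], [0, 2, 0]])
        out = filter_informative(g)
        assert out.n_markers == 2
        assert list(out.marker_info["marker_id"]) == ["snp1", "snp2"]

    def test_chromosome_exclusion(self):
        g = make_matrix([[0, 1], [1, 0], [2, 1]])
        g.marker_info.loc[1, "chrom"] = "X"
        out = filter_informative(g, exclude_chromosomes={"X"})
        assert list(out.marker_info["chrom"]) == ["1"]

    def test_all_nonmissing_equal_removed(self):
        # [0, 0, MISSING]: every non-missing call identical -> noninformative
        g = make_matrix([[0, 0], [0, 1], [MISSING, 2]])
        out = filter_informative(g)
        assert out.n_markers == 1

    def test_everything_removed_raises(self):
        g = make_matrix([[0], [0], [0]])
        with pytest.raises(DegenerateDataError):
            filter_informative(g)

    def test_maf_boundary_kept(self):
        # p = 1/8 >= 0.01 -> kept; spec: boundary sites are kept
        g = make_matrix([[0], [0], [0], [1]])
        assert maf_filter(g, 0.01).n_markers == 1
        assert maf_filter(g, 1 / 8).n_markers == 1
        with pytest.raises(DegenerateDataError):
            maf_filter(g, 0.2)

    def test_maf_zero_threshold_keeps_everything(self, rng):
        g = random_matrix(rng, n=10, m=20)
        assert maf_filter(g, 0.0).n_markers == 20

    def test_maf_idempotent(self, rng):
        g = random_matrix(rng, n=20, m=40)
        once = maf_filter(g, 0.1)
        assert maf_filter(once, 0.1) == once

    def test_ld_prune_removes_duplicate_within_window(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        g = make_matrix(np.stack([col, col], axis=1))
        g.marker_info["pos_cm"] = [0.0, 0.5]
        out = ld_prune(g, window_cm=1.0, r2_max=0.2)
        assert out.n_markers == 1
        assert list(out.marker_info["marker_id"]) == ["snp0"]  # downstream removed

    def test_ld_prune_keeps_outside_window(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        g = make_matrix(np.stack([col, col], axis=1))
        g.marker_info["pos_cm"] = [0.0, 5.0]
        assert ld_prune(g, window_cm=1.0, r2_max=0.2).n_markers == 2

    @staticmethod
    def _greedy_oracle(g, window_cm, r2_max):
        """Exhaustive-pair reimplementation of the greedy rule."""
        cm = g.marker_info["pos_cm"].to_numpy(float)
        kept = []
        for j in range(g.n_markers):
            ok = True
            for i in kept:
                if abs(cm[j] - cm[i]) <= window_cm:
                    a = g.genotypes[:, i].astype(float)
                    b = g.genotypes[:, j].astype(float)
                    m = (g.genotypes[:, i] != MISSING) & (g.genotypes[:, j] != MISSING)
                    a, b = a[m], b[m]
                    if a.std() > 0 and b.std() > 0:
                        r = np.corrcoef(a, b)[0, 1]
                        if r * r > r2_max:
                            ok = False
                            break
            if ok:
                kept.append(j)
        return kept

    def test_ld_prune_matches_bruteforce_oracle(self, rng):
        for trial in range(5):
            gt = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
            # make some columns correlated
            gt[:, 3] = gt[:, 0]
            gt[:, 4] = np.clip(gt[:, 1] + (rng.random(30) < 0.1), 0, 2)
            g = make_matrix(gt)
            g.marker_info["pos_cm"] = np.sort(rng.uniform(0, 2.0, 6))
            out = ld_prune(g, window_cm=1.0, r2_max=0.2)
            expected = self._greedy_oracle(g, 1.0, 0.2)
            assert list(out.marker_info["marker_id"]) == [f"snp{j}" for j in expected]

    def test_ld_prune_idempotent(self, rng):
        g = random_matrix(rng, n=25, m=12, missing_rate=0.05)
        g.marker_info["pos_cm"] = np.linspace(0, 1.5, 12)
        once = ld_prune(g, 1.0, 0.2)
        assert ld_prune(once, 1.0, 0.2) == once


class TestImputation:
    def test_mode_imputation(self):
        g = make_matrix(np.array([[0], [0], [2], [MISSING]]))
        out = impute_most_frequent(g)
        assert np.array_equal(out.genotypes[:, 0], [0, 0, 2, 0])

    def test_tie_breaks_to_smaller_genotype(self):
        g = make_matrix(np.array([[0], [2], [MISSING]]))
        assert impute_most_frequent(g).genotypes[2, 0] == 0

    def test_no_missing_unchanged(self, rng):
        g = random_matrix(rng, missing_rate=0.0)
        assert impute_most_frequent(g) == g

    def test_all_missing_marker_raises(self):
        g = make_matrix(np.array([[MISSING, 0], [MISSING, 1]]))
        with pytest.raises(DegenerateDataError, match="filter"):
            impute_most_frequent(g)

    def test_frequency_shift_bounded(self, rng):
        # mode substitution moves p by at most n_missing / n_samples
        g = random_matrix(rng, n=50, m=30, missing_rate=0.2)
        obs = g.genotypes != MISSING
        p_pre = np.where(obs, g.genotypes, 0).sum(0) / (2 * obs.sum(0))
        out = impute_most_frequent(g)
        p_post = out.genotypes.sum(0) / (2 * out.n_samples)
        bound = (~obs).sum(0) / g.n_samples
        assert np.all(np.abs(p_post - p_pre) <= bound + 1e-12)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

class TestEncoding:
    def test_normalize_mapping(self):
        g = make_matrix(np.array([[0, 1, 2, MISSING]]))
        batch = normalize_batch(g, [0])
        assert np.array_equal(batch.values[0, :, 0], [0.0, 0.5, 1.0, -1.0])
        assert np.array_equal(batch.values[0, :, 1], [1, 1, 1, 0])

    def test_mask_all_ones_when_complete(self, rng):
        g = random_matrix(rng, missing_rate=0.0)
        batch = normalize_batch(g, np.arange(g.n_samples))
        assert np.all(batch.values[:, :, 1] == 1)

    def test_normalize_inverse_recovers_genotypes(self, rng):
        g = random_matrix(rng, n=10, m=20, missing_rate=0.2)
        batch = normalize_batch(g, np.arange(10))
        rec = denormalize(batch.values[:, :, 0])
        obs = batch.values[:, :, 1] == 1
        assert np.array_equal(rec[obs], g.genotypes[obs])
        assert np.all(rec[~obs] == MISSING)

    def test_marker_variable_broadcast(self):
        g = make_matrix(np.array([[0, 1], [2, 0]]))
        mv = np.array([0.3, -0.7])
        batch = normalize_batch(g, [0, 1], marker_variable=mv)
        assert np.allclose(batch.values[:, :, 2], np.tile(mv, (2, 1)))

    def test_one_hot_targets(self):
        g = make_matrix(np.array([[0, 1, 2]]))
        t = one_hot_targets(g, [0], class_weights=[0.5, 3.0, 0.5])
        assert np.array_equal(t.probs[0], np.eye(3))
        assert np.array_equal(t.weight_mask[0], [0.5, 3.0, 0.5])
        assert np.all(t.probs.sum(axis=-1) == 1)

    def test_one_hot_rejects_missing(self):
        g = make_matrix(np.array([[0, MISSING]]))
        with pytest.raises(ValueError, match="imputed"):
            one_hot_targets(g, [0])


class TestStratifiedSplit:
    def test_per_population_counts(self):
        g = make_matrix(
            np.zeros((10, 3), dtype=np.int8) + np.arange(3, dtype=np.int8),
            populations=["A"] * 5 + ["B"] * 5,
        )
        train, valid = stratified_split(g, 0.8, seed=0)
        labels = np.array(g.population_labels)
        for pop in ("A", "B"):
            assert (labels[train] == pop).sum() == 4
            assert (labels[valid] == pop).sum() == 1
        assert sorted(list(train) + list(valid)) == list(range(10))

    def test_deterministic(self, rng):
        g = random_matrix(rng, n=20, m=5, populations=["A"] * 12 + ["B"] * 8)
        s1 = stratified_split(g, 0.7, seed=3)
        s2 = stratified_split(g, 0.7, seed=3)
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])

    def test_degenerate_global_fallback(self):
        # 2 pops of 2 at fraction 0.9: per-pop round gives 2 train, 0 valid
        g = make_matrix(
            np.array([[0, 1]] * 4, dtype=np.int8), populations=["A", "A", "B", "B"]
        )
        with pytest.warns(UserWarning, match="global"):
            train, valid = stratified_split(g, 0.9, seed=0)
        assert len(valid) >= 1
        assert len(train) + len(valid) == 4

    def test_singleton_population_goes_to_training(self):
        g = make_matrix(
            np.array([[0, 1]] * 5, dtype=np.int8),
            populations=["A", "A", "A", "A", "B"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train, valid = stratified_split(g, 0.8, seed=0)
        b_idx = 4
        assert b_idx in train


def test_superpopulation_map_round_trip(tmp_path):
    m = SuperpopulationMap({"Yoruba": "Africa", "Han": "EastAsia"})
    m.write(tmp_path / "map.tsv")
    m2 = SuperpopulationMap.read(tmp_path / "map.tsv")
    assert m2.mapping == m.mapping
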