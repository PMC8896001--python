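import numpy as np
import pytest

from snpae.genotype_io import MISSING, DegenerateDataError, allele_frequencies
from snpae.genotype_analysis import (
    _in_intervals,
    exclude_fixed_sites,
    ld_decay,
    pairwise_r2,
    read_bed_intervals,
    reconstruct_genotypes,
    sfs_compare,
)
from snpae.model_core import hwe_frequencies, build_autoencoder
from snpae.synthetic_data import simulate_ld_haplotypes

from conftest import make_matrix, random_matrix
from test_model_core import small_config


class TestHardCalls:
    def test_hwe_argmax_rule(self):
        # o = 0.9 -> [0.01, 0.18, 0.81] -> genotype 2
        # o = 0.5 -> [0.25, 0.50, 0.25] -> genotype 1
        # o = 0.2 -> [0.64, 0.32, 0.04] -> genotype 0
        for o, expected in [(0.9, 2), (0.5, 1), (0.2, 0)]:
            o_raw = np.log(o / (1 - o))
            probs = hwe_frequencies(np.array([o_raw])).genotype_probs[0]
            assert probs.argmax() == expected

    def test_boundary_tie_resolves_to_heterozygote(self):
        # at o = 1/3 exactly, f(0) = f(1) = 4/9; the hard call must be het
        probs = hwe_frequencies(np.array([np.log(0.5)])).genotype_probs[0]
        assert probs[0] == pytest.approx(probs[1], abs=1e-12)
        tie_break = np.array([0.0, 1e-12, 0.0])
        assert (probs + tie_break).argmax() == 1

    def test_reconstruct_genotypes_shape_and_metadata(self, rng):
        g = random_matrix(rng, n=5, m=17, missing_rate=0.0)
        model = build_autoencoder(small_config(), 17, seed=0)
        out = reconstruct_genotypes(model, g)
        assert out.genotypes.shape == g.genotypes.shape
        assert set(np.unique(out.genotypes)) <= {0, 1, 2}
        assert out.sample_ids == g.sample_ids
        assert out.marker_info.equals(g.marker_info)


class TestExcludeFixed:
    def test_fixed_output_column_excluded(self):
        true_g = make_matrix([[0, 1], [1, 1], [2, 0]])
        out_g = make_matrix([[0, 1], [0, 1], [0, 0]])
        keep = exclude_fixed_sites(true_g, out_g)
        assert list(keep) == [1]

    def test_het_column_carries_both_alleles(self):
        # a column of all heterozygotes has both alleles present -> retained
        out_g = make_matrix([[1, 0], [1, 0], [1, 0]])
        keep = exclude_fixed_sites(out_g, out_g)
        assert 0 in keep

    def test_matches_allele_presence_oracle(self, rng):
        true_g = random_matrix(rng, n=12, m=30, missing_rate=0.0)
        out_g = random_matrix(np.random.default_rng(7), n=12, m=30, missing_rate=0.0)
        keep = set(exclude_fixed_sites(true_g, out_g))
        for j in range(30):
            p = out_g.genotypes[:, j].sum() / (2 * 12)
            assert (j in keep) == (0.0 < p < 1.0)

    def test_all_fixed_raises(self):
        g = make_matrix([[0, 2], [0, 2]])
        with pytest.raises(DegenerateDataError):
            exclude_fixed_sites(g, g)


class TestPairwiseR2:
    def test_duplicated_column_r2_one(self):
        col = np.array([0, 1, 2, 0, 2, 1])
        g = make_matrix(np.stack([col, col], axis=1))
        pairs = pairwise_r2(g)
        assert len(pairs) == 1
        assert pairs[0][1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_columns(self):
        gt = np.array([[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 1, 2], [2, 1, 0]])
        g = make_matrix(gt)  # positions 1000, 2000, 3000 bp

        def r2_hand(a, b):
            return np.corrcoef(a, b)[0, 1] ** 2

        vals = pairwise_r2(g)
        assert len(vals) == 3
        # pairs (0,1) and (1,2) at 1000 bp, (0,2) at 2000 bp
        assert sorted(v[0] for v in vals) == [1000.0, 1000.0, 2000.0]
        [r2_02] = [r for d, r in vals if d == 2000.0]
        assert r2_02 == pytest.approx(r2_hand(gt[:, 0], gt[:, 2]), abs=1e-12)
        assert sorted(r for d, r in vals if d == 1000.0) == pytest.approx(
            sorted([r2_hand(gt[:, 0], gt[:, 1]), r2_hand(gt[:, 1], gt[:, 2])]),
            abs=1e-12,
        )

    def test_relabeling_invariance(self, rng):
        g = random_matrix(rng, n=20, m=6, missing_rate=0.0)
        from snpae.genotype_io import filter_informative, GenotypeMatrix

        g = filter_informative(g)
        flipped = GenotypeMatrix(
            2 - g.genotypes, g.sample_ids, g.population_labels, g.marker_info
        )
        r1 = sorted(pairwise_r2(g))
        r2 = sorted(pairwise_r2(flipped))
        for (d1, a), (d2, b) in zip(r1, r2):
            assert d1 == d2 and a == pytest.approx(b, abs=1e-12)

    def test_missing_data_path_matches_complete_subset(self):
        gt = np.array(
            [[0, 0], [1, 1], [2, 2], [0, 1], [2, 1], [MISSING, 0]], dtype=np.int8
        )
        g = make_matrix(gt)
        pairs = pairwise_r2(g)
        sub = gt[:5].astype(float)
        expected = np.corrcoef(sub[:, 0], sub[:, 1])[0, 1] ** 2
        assert pairs[0][1] == pytest.approx(expected, abs=1e-12)

    def test_interval_and_maf_filters(self):
        gt = np.array([[0, 0, 0], [1, 1, 0], [2, 2, 0], [0, 1, 1]], dtype=np.int8)
        g = make_matrix(gt)  # positions 1000, 2000, 3000
        pairs = pairwise_r2(g, interval=(1000, 2000))
        assert len(pairs) == 1
        with pytest.raises(DegenerateDataError):
            pairwise_r2(g, interval=(2500, 3500))  # only 1 site survives

    def test_null_level_scale(self, rng):
        # independent columns: E[r^2] ~ 1/(n-1)
        n = 300
        gt = (rng.random((n, 30)) < 0.4).astype(np.int8) + (
            rng.random((n, 30)) < 0.4
        ).astype(np.int8)
        g = make_matrix(gt)
        vals = [r for _, r in pairwise_r2(g)]
        assert np.mean(vals) < 3.0 / (n - 1)


class TestLDDecay:
    def test_single_distance_single_bin(self):
        prof = ld_decay([(500.0, 0.2), (500.0, 0.4)], n_bins=25)
        occupied = prof.pair_counts > 0
        assert occupied.sum() == 1
        assert prof.mean_r2[occupied][0] == pytest.approx(0.3)

    def test_constant_r2_constant_profile(self):
        pairs = [(d, 0.5) for d in np.linspace(100, 9000, 40)]
        prof = ld_decay(pairs, n_bins=25)
        assert np.all(prof.mean_r2[prof.pair_counts > 0] == pytest.approx(0.5))

    def test_pair_count_conservation(self, rng):
        pairs = [(float(d), float(r)) for d, r in
                 zip(rng.uniform(0, 1e5, 500), rng.random(500))]
        prof = ld_decay(pairs, n_bins=25)
        assert prof.pair_counts.sum() == 500
        assert len(prof.bin_edges) == 26
        assert np.all(np.diff(prof.bin_edges) > 0)

    def test_markov_haplotypes_decay(self):
        g = simulate_ld_haplotypes(n_samples=300, n_markers=120, rho=0.9, seed=5)
        prof = ld_decay(pairwise_r2(g), n_bins=25)
        occ = np.flatnonzero(prof.pair_counts > 0)[:6]
        means = prof.mean_r2[occ]
        # strong geometric decay over the first occupied bins
        assert means[0] > 0.3
        assert np.all(np.diff(means) < 0.05)
        assert means[-1] < means[0] / 2


class TestSFS:
    def test_identity_mass_on_diagonal(self, rng):
        g = random_matrix(rng, n=10, m=40, missing_rate=0.0)
        comp = sfs_compare(g, g)
        assert comp.joint_hist.sum() == 40
        off_diag = comp.joint_hist - np.diag(np.diag(comp.joint_hist))
        assert off_diag.sum() == 0

    def test_allele_flip_antidiagonal(self, rng):
        from snpae.genotype_io import GenotypeMatrix

        # n = 7: frequencies are multiples of 1/14, which fall inside bins
        # except p = 0.5 (a shared bin edge, excluded below)
        g = random_matrix(rng, n=7, m=40, missing_rate=0.0)
        flipped = GenotypeMatrix(
            2 - g.genotypes, g.sample_ids, g.population_labels, g.marker_info
        )
        comp = sfs_compare(g, flipped)
        anti = np.fliplr(comp.joint_hist)
        # frequencies p and 1-p land in mirrored bins (up to the shared bin
        # boundary at p = 0.5)
        f = allele_frequencies(g.genotypes)
        interior = ~np.isclose(f, 0.5)
        assert np.trace(anti) >= interior.sum()

    def test_truth_marginal_matches_independent_histogram(self, rng):
        g1 = random_matrix(rng, n=10, m=60, missing_rate=0.0)
        g2 = random_matrix(np.random.default_rng(1), n=10, m=60, missing_rate=0.0)
        comp = sfs_compare(g1, g2)
        marginal = comp.joint_hist.sum(axis=1)
        f = allele_frequencies(g1.genotypes)
        expected, _ = np.histogram(f, bins=100, range=(0, 1))
        assert np.array_equal(marginal, expected)


class TestMask:
    def test_bed_half_open_membership(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t10\t20\nchr1\t30\t31\n")
        intervals = read_bed_intervals(bed)
        # 1-based positions 11..20 pass (0-based 10..19); 21 does not; 31 passes
        pos = np.array([10, 11, 20, 21, 31, 32])
        got = _in_intervals(pos, intervals)
        assert list(got) == [False, True, True, False, True, False]
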