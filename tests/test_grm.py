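import numpy as np
import pytest

from equigen.grm import (GrmMatrix, RegionSpec, build_partitioned_grms,
                         compute_grm, read_grm_gcta, read_grm_tsv,
                         write_grm_gcta, write_grm_tsv)
from conftest import make_matrix


class TestComputeGrm:
    def test_hand_evaluated_entries(self):
        # one variant at p = 0.5: z = (x - 1)/sqrt(0.5)
        G = make_matrix(np.array([[2], [0]], dtype=np.int8))
        A = compute_grm(G).values
        assert A[0, 1] == pytest.approx(-2.0)
        assert A[0, 0] == pytest.approx(2.0)
        assert A[1, 1] == pytest.approx(2.0)

    def test_all_heterozygous_degenerate(self):
        # identical genotypes everywhere: centred codes vanish, so every
        # entry equals the (zero) diagonal value
        G = make_matrix(np.ones((4, 3), dtype=np.int8))
        A = compute_grm(G).values
        assert np.allclose(A, A[0, 0])

    def test_monomorphic_subset_rejected(self):
        G = make_matrix(np.array([[0, 1], [0, 1], [0, 2]], dtype=np.int8))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(G, [0])

    def test_empty_subset_rejected(self):
        G = make_matrix(np.array([[0, 1], [1, 2]], dtype=np.int8))
        with pytest.raises(ValueError, match="empty"):
            compute_grm(G, [])

    def test_missing_genotypes_mean_imputed(self):
        from equigen.core_io import MISSING
        codes = np.array([[0], [1], [2], [MISSING]], dtype=np.int8)
        A = compute_grm(make_matrix(codes))
        assert np.isfinite(A.values).all()
        # the mean-imputed individual is exactly average: zero relationship
        assert A.values[3, 3] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_near_one_on_simulated_data(self, small_sim):
        _, G, _, _ = small_sim
        from equigen.core_io import filter_variants
        A = compute_grm(filter_variants(G, min_maf=0.01))
        assert 0.8 <= float(np.diag(A.values).mean()) <= 1.2

    def test_partition_consistency(self, small_sim):
        # GRM over a union of disjoint subsets is the count-weighted
        # average of the subset GRMs
        _, G, _, _ = small_sim
        from equigen.core_io import filter_variants
        Gf = filter_variants(G, min_maf=0.05)
        idx = np.arange(200)
        a, b = idx[:80], idx[80:]
        Ka = compute_grm(Gf, a)
        Kb = compute_grm(Gf, b)
        Kab = compute_grm(Gf, idx)
        merged = (Ka.n_variants_used * Ka.values
                  + Kb.n_variants_used * Kb.values) / Kab.n_variants_used
        assert np.allclose(Kab.values, merged, atol=1e-10)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        G = make_matrix(codes)
        A = compute_grm(G)
        perm = rng.permutation(12)
        Gp = G.subset_samples([G.samples[i] for i in perm])
        Ap = compute_grm(Gp)
        assert np.allclose(Ap.values, A.values[np.ix_(perm, perm)],
                           atol=1e-12)


class TestPartitionedGrms:
    def _geno(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(20, 9)).astype(np.int8)
        G = make_matrix(codes)
        from dataclasses import replace
        meta = [("1", 10_000_000), ("1", 50_000_000), ("1", 90_000_000),
                ("3", 103_000_000), ("3", 106_000_000), ("3", 107_373_887),
                ("3", 110_000_000), ("3", 112_000_000), ("3", 118_000_000)]
        G.variants = [replace(v, chrom=c, pos=p)
                      for v, (c, p) in zip(G.variants, meta)]
        return G

    def test_loco_counts(self):
        G = self._geno()
        grms = build_partitioned_grms(G, scheme="loco")
        assert [g.label for g in grms] == ["loco1", "loco3"]
        assert grms[0].n_variants_used == 6
        assert grms[1].n_variants_used == 3

    def test_window_grm_respects_boundaries(self):
        # 6-Mb window around 107.4 Mb: 103 and 112 Mb stay outside
        G = self._geno()
        reg = RegionSpec.around("qtl", "3", 107_400_000,
                                3_000_000, 7_000_000)
        grms = build_partitioned_grms(G, [reg], scheme="qtl_plus_rest")
        window = grms[0]
        assert window.label == "qtl_window"
        assert window.n_variants_used == 3  # 106, 107.37, 110 Mb

    def test_exclusion_buffer_leaves_variant_in_no_grm(self):
        # 103 Mb lies inside the 14-Mb exclusion but outside the window:
        # it must appear in neither GRM of the pair
        G = self._geno()
        reg = RegionSpec.around("qtl", "3", 107_400_000,
                                3_000_000, 7_000_000)
        window, rest = build_partitioned_grms(G, [reg],
                                              scheme="qtl_plus_rest")
        assert window.n_variants_used + rest.n_variants_used == 4
        assert rest.n_variants_used == 1  # only 118 Mb survives the buffer

    def test_per_chromosome(self):
        grms = build_partitioned_grms(self._geno(), scheme="per_chromosome")
        assert [g.label for g in grms] == ["chr1", "chr3"]

    def test_overlapping_windows_rejected(self):
        G = self._geno()
        regs = [RegionSpec("a", "3", (106_000_000, 110_000_000),
                           (105_000_000, 111_000_000)),
                RegionSpec("b", "3", (109_000_000, 112_000_000),
                           (109_000_000, 112_000_000))]
        with pytest.raises(ValueError, match="overlapping"):
            build_partitioned_grms(G, regs, scheme="qtl_plus_rest")

    def test_empty_window_rejected(self):
        G = self._geno()
        reg = RegionSpec.around("qtl", "3", 90_000_000, 1_000_000, 1_000_000)
        with pytest.raises(ValueError, match="no variants"):
            build_partitioned_grms(G, [reg], scheme="qtl_plus_rest")


class TestRegionSpec:
    def test_exclusion_must_contain_window(self):
        with pytest.raises(ValueError, match="contain"):
            RegionSpec("x", "1", (100, 200), (150, 300))

    def test_around_constructor_matches_qtl_design(self):
        reg = RegionSpec.around("eca3", "3", 107_400_000,
                                3_000_000, 7_000_000)
        assert reg.window == (104_400_000, 110_400_000)
        assert reg.exclusion == (100_400_000, 114_400_000)


class TestPersistence:
    def _grm(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((6, 30))
        return GrmMatrix("test", [f"s{i}" for i in range(6)],
                         Z @ Z.T / 30, 30)

    def test_tsv_round_trip(self, tmp_path):
        g = self._grm()
        write_grm_tsv(g, tmp_path / "g.tsv")
        back = read_grm_tsv(tmp_path / "g.tsv")
        assert back.samples == g.samples
        assert np.allclose(back.values, g.values, atol=1e-9)
        assert back.n_variants_used == 30

    def test_gcta_binary_round_trip(self, tmp_path):
        g = self._grm()
        write_grm_gcta(g, tmp_path / "g")
        back = read_grm_gcta(tmp_path / "g", label="test")
        assert back.samples == g.samples
        assert np.allclose(back.values, g.values, atol=1e-6)  # float32
        assert back.n_variants_used == 30
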