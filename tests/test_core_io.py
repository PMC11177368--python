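import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from equigen.core_io import (MISSING, GenotypeMatrix, ModelSpec,
                             PhenotypeTable, VariantInfo, compute_maf,
                             filter_variants, read_genotypes, write_genotypes)
from conftest import make_matrix


def write_vcf_text(path, body, samples=("s0", "s1", "s2")):
    header = ("##fileformat=VCFv4.2\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(samples) + "\n")
    path.write_text(header + body)


class TestReadVcf:
    def test_alt_minor_gt_mapping(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        G = read_genotypes(p, "vcf")
        assert list(G.codes[:, 0]) == [0, 1, 2]
        assert G.variants[0].minor_is_alt

    def test_ref_minor_is_repolarised(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/1\t1/1\n")
        G = read_genotypes(p, "vcf")
        # ALT frequency 5/6: the REF allele is the minor one
        assert not G.variants[0].minor_is_alt
        assert list(G.codes[:, 0]) == [0, 1, 0]
        assert G.variants[0].maf == pytest.approx(1 / 6)

    def test_missing_call(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\n")
        G = read_genotypes(p, "vcf")
        assert G.codes[0, 0] == MISSING

    def test_multiallelic_rejected_with_coordinates(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "1\t123\trs1\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        with pytest.raises(ValueError, match="1:123"):
            read_genotypes(p, "vcf")

    def test_unsorted_input_rejected(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "1\t200\trs1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
                          "1\t100\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        with pytest.raises(ValueError, match="unsorted"):
            read_genotypes(p, "vcf")


class TestRoundTrip:
    def _example(self):
        # no column at exactly MAF 0.5: there the minor label is a tie and
        # allele-based formats cannot preserve the orientation
        codes = np.array([[0, 2, 1], [1, MISSING, 0], [2, 0, 0], [0, 0, 0]],
                         dtype=np.int8)
        return make_matrix(codes)

    @pytest.mark.parametrize("fmt,suffix", [("vcf", "g.vcf"),
                                            ("plink_text", "g")])
    def test_identity(self, tmp_path, fmt, suffix):
        G = self._example()
        path = tmp_path / suffix
        write_genotypes(G, path, fmt)
        back = read_genotypes(path, fmt)
        assert back.samples == G.samples
        assert np.array_equal(back.codes, G.codes)
        assert [v.pos for v in back.variants] == [v.pos for v in G.variants]
        assert [v.maf for v in back.variants] == pytest.approx(
            [v.maf for v in G.variants])

    def test_minor_orientation_preserved(self, tmp_path):
        G = self._example()
        write_genotypes(G, tmp_path / "g.vcf", "vcf")
        back = read_genotypes(tmp_path / "g.vcf", "vcf")
        assert [v.minor_allele for v in back.variants] == \
               [v.minor_allele for v in G.variants]

    def test_empty_sample_list_errors(self, tmp_path):
        G = GenotypeMatrix([], [], np.zeros((0, 0), dtype=np.int8))
        for fmt in ("vcf", "plink_text"):
            with pytest.raises(ValueError):
                write_genotypes(G, tmp_path / "e", fmt)

    def test_vcf_shape(self, tmp_path):
        G = make_matrix(np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8))
        write_genotypes(G, tmp_path / "g.vcf", "vcf")
        body = [ln for ln in (tmp_path / "g.vcf").read_text().splitlines()
                if not ln.startswith("#")]
        assert len(body) == 2
        assert all(len(ln.split("\t")) == 9 + 3 for ln in body)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.sampled_from([0, 1, 2, MISSING]),
                             min_size=3, max_size=3),
                    min_size=2, max_size=8))
    def test_roundtrip_property(self, rows):
        import tempfile
        from pathlib import Path

        codes = np.array(rows, dtype=np.int8)
        if (codes == MISSING).all(axis=0).any():
            return  # orientation of an all-missing variant is undefined
        obs = np.ma.masked_equal(codes, MISSING)
        if (obs.mean(axis=0) / 2.0 > 0.5).any():
            return  # counted allele must be the minor one by convention
        G = make_matrix(codes)
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "g.vcf"
            write_genotypes(G, path, "vcf")
            back = read_genotypes(path, "vcf")
        assert np.array_equal(back.codes, G.codes)


class TestMaf:
    @pytest.mark.parametrize("codes,expected", [
        ([[0], [1], [2]], 0.5),
        ([[2], [2], [2]], 0.0),
        ([[2], [2], [1], [2]], 0.125),
    ])
    def test_examples(self, codes, expected):
        G = make_matrix(np.array(codes, dtype=np.int8))
        assert compute_maf(G)[0] == pytest.approx(expected)

    def test_all_missing_errors(self):
        G = make_matrix(np.full((3, 1), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="v0"):
            compute_maf(G)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=2, max_size=20))
    def test_always_at_most_half(self, col):
        G = make_matrix(np.array(col, dtype=np.int8)[:, None])
        m = compute_maf(G)[0]
        # invariant under relabelling which allele is counted
        G2 = make_matrix(2 - np.array(col, dtype=np.int8)[:, None])
        assert 0.0 <= m <= 0.5
        assert compute_maf(G2)[0] == pytest.approx(m)


class TestFilterVariants:
    def _geno(self):
        codes = np.array([[0, 0, 1, 2], [0, 1, 1, 0], [0, 2, 0, 1]],
                         dtype=np.int8)
        G = make_matrix(codes, chrom="3")
        from dataclasses import replace
        positions = [100_000_000, 101_000_000, 107_373_887, 112_000_000]
        G.variants = [replace(v, pos=p) for v, p in zip(G.variants, positions)]
        return G

    def test_monomorphic_removed_by_maf(self):
        G = self._geno()
        out = filter_variants(G, min_maf=0.01)
        assert "v0" not in out.variant_ids  # the all-zero column

    def test_keep_region_qtl_window(self):
        # the 6-Mb window around the ECA3 top SNP keeps 107,373,887
        out = filter_variants(self._geno(),
                              keep_region=("3", 104_400_000, 110_400_000))
        assert [v.pos for v in out.variants] == [107_373_887]

    def test_drop_region_exclusion_buffer(self):
        # the 14-Mb buffer (100.4-114.4 Mb) removes a variant at 101 Mb
        out = filter_variants(self._geno(),
                              drop_region=("3", 100_400_000, 114_400_000))
        assert [v.pos for v in out.variants] == [100_000_000]

    def test_noop_filter_is_identity(self):
        G = self._geno()
        out = filter_variants(G, min_maf=0.0)
        assert out.variant_ids == G.variant_ids
        assert np.array_equal(out.codes, G.codes)

    def test_empty_result_allowed(self):
        out = filter_variants(self._geno(), keep_region=("9", 1, 2))
        assert out.n_variants == 0


class TestModelSpec:
    def _pheno(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        n = 30
        return PhenotypeTable(pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "height": rng.normal(167, 3, n),
            "age_days": rng.uniform(800, 3600, n),
            "sex": rng.choice(["mare", "stallion"], n),
            "judge": rng.choice(["J1", "J2", "J3"], n),
        }))

    def test_design_full_rank_with_reference_dropping(self):
        spec = ModelSpec("height", covariates=["age_days"],
                         factors=["sex", "judge"])
        y, X, ids, names = spec.build_design(self._pheno())
        assert X.shape[0] == len(y) == len(ids)
        assert np.linalg.matrix_rank(X) == X.shape[1]
        assert names[0] == "intercept"
        # one level dropped per factor
        assert sum(n.startswith("judge[") for n in names) == 2

    def test_missing_trait_column_errors(self):
        with pytest.raises(ValueError, match="nope"):
            ModelSpec("nope").build_design(self._pheno())

    def test_snp_covariate(self):
        G = make_matrix(np.tile([0, 1, 2], 10)[:, None],
                        samples=[f"s{i}" for i in range(30)])
        spec = ModelSpec("height", covariates=["snp:v0"])
        y, X, ids, names = spec.build_design(self._pheno(), G)
        assert "snp:v0" in names
        assert set(np.unique(X[:, names.index("snp:v0")])) <= {0.0, 1.0, 2.0}

    def test_ordinal_validation(self):
        import pandas as pd
        t = PhenotypeTable(pd.DataFrame({
            "sample": ["a", "b"], "score": [-3, 4]}))
        with pytest.raises(ValueError):
            t.check_ordinal("score")
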