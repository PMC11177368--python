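import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from equigen.core_io import MISSING
from equigen.gwas import GwasResult
from equigen.roh import (RohParams, RohSegment, detect_roh, roh_scan_window,
                         shared_roh)
from conftest import make_matrix


def brute_force_roh(positions, codes, params):
    """Independent re-derivation of the scanning rules, pure python.

    Enumerates every window by loops, marks eligible SNPs by the
    window-hit proportion, builds maximal gap-split runs, and applies the
    count/length/density filters.
    """
    m = len(positions)
    w = params.window_snps
    if m < w:
        return []
    hom_windows = []
    for s in range(m - w + 1):
        block = codes[s:s + w]
        het = sum(1 for c in block if c == 1)
        mis = sum(1 for c in block if c == MISSING)
        hom_windows.append(het <= params.window_max_het
                           and mis <= params.window_max_missing)
    eligible = []
    for j in range(m):
        wins = [s for s in range(max(0, j - w + 1),
                                 min(j, m - w) + 1)]
        frac = sum(hom_windows[s] for s in wins) / len(wins)
        eligible.append(frac > params.window_hit_threshold)
    segments = []
    run = []
    for j in range(m):
        if not eligible[j]:
            if run:
                segments.append(run)
                run = []
            continue
        if run and positions[j] - positions[run[-1]] > params.max_gap_bp:
            segments.append(run)
            run = []
        run.append(j)
    if run:
        segments.append(run)
    out = []
    for run in segments:
        n = len(run)
        length = positions[run[-1]] - positions[run[0]] + 1
        if (n >= params.min_snps and length >= params.min_length_bp
                and length / n <= params.min_density_bp_per_snp):
            out.append((int(positions[run[0]]), int(positions[run[-1]]), n))
    return out


SMALL = RohParams(min_snps=10, min_length_bp=50_000,
                  min_density_bp_per_snp=50_000, max_gap_bp=200_000,
                  window_snps=10, window_max_het=1, window_max_missing=2,
                  window_hit_threshold=0.05)


class TestDetectRoh:
    def _matrix(self, codes_row, positions):
        codes = np.array([codes_row], dtype=np.int8)
        G = make_matrix(codes)
        from dataclasses import replace
        G.variants = [replace(v, pos=int(p))
                      for v, p in zip(G.variants, positions)]
        return G

    def test_sixty_homozygous_snps_one_roh(self):
        positions = 100_000 + np.arange(60) * 2500   # 150 kb span
        G = self._matrix([2] * 60, positions)
        segs = detect_roh(G, None, ("1", 1, 10_000_000))
        assert len(segs) == 1
        assert segs[0].n_snps == 60
        assert (segs[0].start, segs[0].end) == (positions[0], positions[-1])

    def test_forty_nine_snps_too_few(self):
        positions = 100_000 + np.arange(49) * 2500
        G = self._matrix([2] * 49, positions)
        with pytest.warns(UserWarning, match="fewer"):
            segs = detect_roh(G, None, ("1", 1, 10_000_000))
        assert segs == []

    def test_large_gap_splits_run(self):
        positions = list(100_000 + np.arange(30) * 2500)
        positions += [positions[-1] + 1_200_000 + i * 2500 for i in range(30)]
        G = self._matrix([2] * 60, np.array(positions))
        segs = detect_roh(G, None, ("1", 1, 10_000_000))
        assert segs == []  # each side has only 30 SNPs

    def test_sparse_snps_fail_density(self):
        positions = 100_000 + np.arange(60) * 60_000   # 1 SNP per 60 kb
        G = self._matrix([0] * 60, positions)
        segs = detect_roh(G, None, ("1", 1, 10_000_000))
        assert segs == []

    def test_few_heterozygotes_tolerated(self):
        row = [2] * 60
        row[30] = 1
        positions = 100_000 + np.arange(60) * 2500
        G = self._matrix(row, positions)
        segs = detect_roh(G, None, ("1", 1, 10_000_000))
        assert len(segs) == 1
        assert segs[0].n_het == 1

    def test_unknown_sample_rejected(self):
        G = self._matrix([2] * 60, 100_000 + np.arange(60) * 2500)
        with pytest.raises(ValueError, match="ghost"):
            detect_roh(G, ["ghost"], ("1", 1, 10_000_000))

    def test_empty_region_rejected(self):
        G = self._matrix([2] * 60, 100_000 + np.arange(60) * 2500)
        with pytest.raises(ValueError, match="no variants"):
            detect_roh(G, None, ("2", 1, 10_000_000))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 200))
        n_ind = int(rng.integers(1, 6))
        positions = np.sort(rng.choice(np.arange(1, 2_000_000, 500),
                                       size=m, replace=False))
        codes = rng.choice([0, 1, 2, MISSING], size=(n_ind, m),
                           p=[0.45, 0.07, 0.45, 0.03]).astype(np.int8)
        G = make_matrix(codes)
        from dataclasses import replace
        G.variants = [replace(v, pos=int(p))
                      for v, p in zip(G.variants, positions)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segs = detect_roh(G, None, ("1", 1, 3_000_000), SMALL)
        for i, s in enumerate(G.samples):
            expected = brute_force_roh(positions, list(codes[i]), SMALL)
            got = [(x.start, x.end, x.n_snps) for x in segs if x.sample == s]
            assert got == expected

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_relaxing_thresholds_keeps_segments(self, seed):
        rng = np.random.default_rng(seed)
        m = 120
        positions = np.sort(rng.choice(np.arange(1, 1_500_000, 500),
                                       size=m, replace=False))
        codes = rng.choice([0, 1, 2], size=(1, m),
                           p=[0.46, 0.08, 0.46]).astype(np.int8)
        G = make_matrix(codes)
        from dataclasses import replace
        G.variants = [replace(v, pos=int(p))
                      for v, p in zip(G.variants, positions)]
        import warnings
        relaxed = RohParams(min_snps=SMALL.min_snps - 3,
                            min_length_bp=SMALL.min_length_bp - 10_000,
                            min_density_bp_per_snp=SMALL.min_density_bp_per_snp,
                            max_gap_bp=SMALL.max_gap_bp + 100_000,
                            window_snps=SMALL.window_snps,
                            window_max_het=SMALL.window_max_het,
                            window_max_missing=SMALL.window_max_missing,
                            window_hit_threshold=SMALL.window_hit_threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strict = detect_roh(G, None, ("1", 1, 2_000_000), SMALL)
            loose = detect_roh(G, None, ("1", 1, 2_000_000), relaxed)
        covered = [(s.start, s.end) for s in loose]
        for s in strict:
            assert any(a <= s.start and s.end <= b for a, b in covered)


def test_hom_table_layout():
    from equigen.roh import hom_table
    seg = RohSegment("s0", "3", 107_308_144, 107_435_503, 120, 1, 0)
    df = hom_table([seg])
    assert list(df.columns) == ["FID", "IID", "CHR", "POS1", "POS2", "KB",
                                "NSNP"]
    assert df.loc[0, "KB"] == pytest.approx(127.36, abs=0.01)


class TestSharedRoh:
    def _geno(self, rows, positions=None):
        codes = np.array(rows, dtype=np.int8)
        G = make_matrix(codes)
        if positions is not None:
            from dataclasses import replace
            G.variants = [replace(v, pos=int(p))
                          for v, p in zip(G.variants, positions)]
        return G

    def test_interval_intersection(self):
        G = self._geno([[2, 2, 2], [2, 2, 2]], [100_000, 175_000, 225_000])
        segs = [RohSegment("s0", "1", 100_000, 200_000, 10, 0, 0),
                RohSegment("s1", "1", 150_000, 250_000, 10, 0, 0)]
        shared = shared_roh(segs, {"s0": "all", "s1": "all"}, G)
        both = [r for r in shared if r.n_carriers == 2]
        assert len(both) == 1
        assert (both[0].start, both[0].end) == (150_000, 200_000)

    def test_carrier_counting_two_of_three(self):
        G = self._geno([[2], [2], [2]], [150_000])
        segs = [RohSegment("s0", "1", 100_000, 200_000, 10, 0, 0),
                RohSegment("s1", "1", 120_000, 220_000, 10, 0, 0)]
        shared = shared_roh(segs, {s: "all" for s in ("s0", "s1", "s2")}, G)
        assert max(r.n_carriers for r in shared) == 2

    def test_allele_classes_discriminate_groups(self):
        # tall group homozygous minor, short group homozygous major
        G = self._geno([[2, 2], [2, 2], [0, 0]], [100_000, 150_000])
        segs = [RohSegment(s, "1", 90_000, 160_000, 10, 0, 0)
                for s in ("s0", "s1", "s2")]
        groups = {"s0": "top", "s1": "top", "s2": "bottom"}
        shared = shared_roh(segs, groups, G)
        r = shared[0]
        assert r.carriers_per_group == {"bottom": 1, "top": 2}
        assert r.groups_differ("top", "bottom")

    def test_missing_calls_do_not_break_class_equality(self):
        G = self._geno([[2, MISSING], [2, 2]], [100_000, 150_000])
        segs = [RohSegment(s, "1", 90_000, 160_000, 10, 0, 0)
                for s in ("s0", "s1")]
        shared = shared_roh(segs, {"s0": "a", "s1": "b"}, G)
        assert not shared[0].groups_differ("a", "b")

    def test_unknown_sample_in_groups(self):
        G = self._geno([[2]], [100_000])
        with pytest.raises(ValueError, match="ghost"):
            shared_roh([], {"ghost": "x"}, G)


class TestScanWindow:
    def _result(self, positions, p=1e-12, chrom="3"):
        table = pd.DataFrame({
            "chrom": chrom, "pos": positions,
            "id": [f"v{p_}" for p_ in positions],
            "alleles": "A/C", "maf": 0.4, "beta": 1.0, "se": 0.1,
            "p": p, "n_used": 100})
        return GwasResult(table, 1.0, 1e-8, len(positions))

    def test_paper_span_with_buffer(self):
        res = self._result([97_840_010, 105_000_000, 117_983_557])
        assert roh_scan_window(res, 100_000) == \
            ("3", 97_740_010, 118_083_557)

    def test_single_variant_span(self):
        res = self._result([5_000_000])
        assert roh_scan_window(res, 100_000) == ("3", 4_900_000, 5_100_000)

    def test_zero_buffer_identity(self):
        res = self._result([1_000_000, 2_000_000])
        assert roh_scan_window(res, 0) == ("3", 1_000_000, 2_000_000)

    def test_no_significant_variants_errors(self):
        res = self._result([1_000_000], p=0.9)
        with pytest.raises(ValueError, match="significant"):
            roh_scan_window(res, 0)
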