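"""Runs of homozygosity by scanning-window detection, and cross-individual
shared-segment analysis with allele-class discrimination.

The detector follows the published --homozyg algorithm of the standard
PLINK tool: a window of ``window_snps`` consecutive SNPs slides along the
region; a window is called homozygous when it contains at most
``window_max_het`` heterozygous and ``window_max_missing`` missing calls; a
SNP is ROH-eligible when the proportion of homozygous windows overlapping
it exceeds ``window_hit_threshold``.  Maximal runs of eligible SNPs are
split at inter-SNP gaps above ``max_gap_bp`` and then filtered by SNP
count, physical length and SNP density.  Segment endpoints are reported at
the outermost eligible SNPs (runs are not extended into flanking gaps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import MISSING, GenotypeMatrix


@dataclass
class RohParams:
    min_snps: int = 50
    min_length_bp: int = 100_000
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 1_000_000
    window_snps: int = 50
    window_max_het: int = 3
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05

    def __post_init__(self):
        for name in ("min_snps", "min_length_bp", "min_density_bp_per_snp",
                     "max_gap_bp", "window_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_max_het >= self.window_snps:
            raise ValueError("window_max_het must be below window_snps")


@dataclass
class RohSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class SharedRohRegion:
    chrom: str
    start: int
    end: int
    carriers: list[str]
    carriers_per_group: dict[str, int]
    # group -> representative homozygous genotype signature over the
    # interval's SNPs (minor-allele counts; None where every carrier is
    # missing); empty tuple if carriers within the group disagree
    allele_class_per_group: dict[str, tuple]

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    def groups_differ(self, group_a: str, group_b: str) -> bool:
        """True when the two groups carry distinguishable alleles
        (compared only over mutually non-missing SNPs)."""
        a = self.allele_class_per_group.get(group_a)
        b = self.allele_class_per_group.get(group_b)
        if not a or not b:
            return False
        return not _compatible(a, b)


def _compatible(sig_a: tuple, sig_b: tuple) -> bool:
    return all(x is None or y is None or x == y for x, y in zip(sig_a, sig_b))


def _merge_signatures(sigs: list[tuple]) -> tuple:
    """Consensus signature; empty tuple when carriers conflict."""
    if not sigs:
        return ()
    out = list(sigs[0])
    for s in sigs[1:]:
        for i, v in enumerate(s):
            if v is None:
                continue
            if out[i] is None:
                out[i] = v
            elif out[i] != v:
                return ()
    return tuple(out)


def detect_roh(G: GenotypeMatrix, sample_subset: list[str] | None,
               region: tuple[str, int, int],
               params: RohParams | None = None) -> list[RohSegment]:
    """Detect ROH per individual within a genomic region."""
    params = params if params is not None else RohParams()
    chrom, start, end = region
    idx = np.array([j for j, v in enumerate(G.variants)
                    if v.chrom == chrom and start <= v.pos <= end], dtype=int)
    if len(idx) == 0:
        raise ValueError(f"region {chrom}:{start}-{end} contains no variants")
    samples = sample_subset if sample_subset is not None else G.samples
    pos_of = {s: i for i, s in enumerate(G.samples)}
    unknown = [s for s in samples if s not in pos_of]
    if unknown:
        raise ValueError(f"unknown sample {unknown[0]!r}")
    m = len(idx)
    if m < params.window_snps:
        warnings.warn(
            f"region {chrom}:{start}-{end} has {m} SNPs, fewer than the "
            f"scanning window of {params.window_snps}; no ROH reported")
        return []
    positions = np.array([G.variants[j].pos for j in idx])
    segments: list[RohSegment] = []
    w = params.window_snps
    n_windows = m - w + 1
    for s in samples:
        codes = G.codes[pos_of[s], idx]
        het = (codes == 1).astype(int)
        mis = (codes == MISSING).astype(int)
        chet = np.concatenate([[0], np.cumsum(het)])
        cmis = np.concatenate([[0], np.cumsum(mis)])
        win_het = chet[w:] - chet[:-w]        # length n_windows
        win_mis = cmis[w:] - cmis[:-w]
        hom_win = ((win_het <= params.window_max_het)
                   & (win_mis <= params.window_max_missing)).astype(int)
        # windows overlapping SNP j: indices max(0, j-w+1) .. min(j, n_windows-1)
        chom = np.concatenate([[0], np.cumsum(hom_win)])
        j = np.arange(m)
        lo = np.maximum(0, j - w + 1)
        hi = np.minimum(j, n_windows - 1)
        n_overlap = hi - lo + 1
        n_hom = chom[hi + 1] - chom[lo]
        eligible = n_hom / n_overlap > params.window_hit_threshold
        segments.extend(_runs_to_segments(
            s, chrom, positions, eligible, het, mis, params))
    return segments


def _runs_to_segments(sample, chrom, positions, eligible, het, mis,
                      params: RohParams) -> list[RohSegment]:
    out = []
    m = len(positions)
    j = 0
    while j < m:
        if not eligible[j]:
            j += 1
            continue
        k = j
        while (k + 1 < m and eligible[k + 1]
               and positions[k + 1] - positions[k] <= params.max_gap_bp):
            k += 1
        n_snps = k - j + 1
        length = int(positions[k] - positions[j] + 1)
        if (n_snps >= params.min_snps and length >= params.min_length_bp
                and length / n_snps <= params.min_density_bp_per_snp):
            out.append(RohSegment(
                sample=sample, chrom=chrom, start=int(positions[j]),
                end=int(positions[k]), n_snps=int(n_snps),
                n_het=int(het[j:k + 1].sum()),
                n_missing=int(mis[j:k + 1].sum())))
        j = k + 1
    return out


def shared_roh(segments: list[RohSegment], groups: dict[str, str],
               G: GenotypeMatrix) -> list[SharedRohRegion]:
    """Maximal intervals carried by identical sets of individuals.

    The segment set is cut at every segment boundary; consecutive elementary
    intervals with the same carrier set are merged.  For each interval the
    allele class of a carrier is its genotype vector over the interval's
    SNPs; classes are compared only over mutually non-missing SNPs.
    Only intervals with at least two carriers are reported.
    """
    known = set(G.samples)
    for s in groups:
        if s not in known:
            raise ValueError(f"unknown sample {s!r} in groups map")
    if not segments:
        return []
    chroms = {seg.chrom for seg in segments}
    out: list[SharedRohRegion] = []
    pos_of = {s: i for i, s in enumerate(G.samples)}
    for chrom in sorted(chroms):
        segs = [s for s in segments if s.chrom == chrom]
        cuts = sorted({s.start for s in segs} | {s.end + 1 for s in segs})
        elementary = []
        for a, b in zip(cuts, cuts[1:]):
            carriers = sorted({s.sample for s in segs
                               if s.start <= a and b - 1 <= s.end})
            elementary.append((a, b - 1, tuple(carriers)))
        merged = []
        for a, b, carr in elementary:
            if merged and merged[-1][2] == carr and merged[-1][1] + 1 == a:
                merged[-1] = (merged[-1][0], b, carr)
            else:
                merged.append((a, b, carr))
        var_pos = np.array([v.pos for v in G.variants])
        var_chrom = np.array([v.chrom for v in G.variants])
        for a, b, carr in merged:
            if len(carr) < 2:
                continue
            idx = np.nonzero((var_chrom == chrom)
                             & (var_pos >= a) & (var_pos <= b))[0]
            sigs = {}
            for s in carr:
                codes = G.codes[pos_of[s], idx]
                sigs[s] = tuple(None if c == MISSING else int(c)
                                for c in codes)
            labels = sorted({groups.get(s, "all") for s in carr})
            carriers_per_group = {
                lab: sum(1 for s in carr if groups.get(s, "all") == lab)
                for lab in labels}
            allele_class = {
                lab: _merge_signatures(
                    [sigs[s] for s in carr if groups.get(s, "all") == lab])
                for lab in labels}
            out.append(SharedRohRegion(
                chrom=chrom, start=int(a), end=int(b), carriers=list(carr),
                carriers_per_group=carriers_per_group,
                allele_class_per_group=allele_class))
    return out


def hom_table(segments: list[RohSegment]):
    """Segments in the scanning tool's .hom column layout
    (FID, IID, CHR, POS1, POS2, KB, NSNP) for external cross-checking."""
    import pandas as pd

    return pd.DataFrame([{
        "FID": s.sample, "IID": s.sample, "CHR": s.chrom,
        "POS1": s.start, "POS2": s.end,
        "KB": round(s.length / 1000.0, 3), "NSNP": s.n_snps}
        for s in segments])


def roh_scan_window(result, buffer_bp: int = 100_000,
                    chrom: str | None = None) -> tuple[str, int, int]:
    """Region spanned by genome-wide significant variants, plus a buffer.

    ``result`` is a GwasResult; ``chrom`` defaults to the chromosome of the
    global top SNP.
    """
    sig = result.significant
    if chrom is None:
        if len(sig) == 0:
            raise ValueError("no genome-wide significant variants")
        chrom = str(result.top_snp()["chrom"])
    sub = sig[sig["chrom"] == chrom]
    if len(sub) == 0:
        raise ValueError(f"no genome-wide significant variants on {chrom}")
    return (chrom, int(sub["pos"].min()) - buffer_bp,
            int(sub["pos"].max()) + buffer_bp)
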