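"""Genomic relationship matrices over variant subsets.

The estimator is the per-SNP-standardised cross-product (VanRaden method 1
in its GCTA form): A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) /
(2 p_i (1 - p_i)), with p_i the sample frequency of the counted (minor)
allele and missing genotypes mean-imputed to 2 p_i before centring.  The
same cross-product expression is used on the diagonal.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import MISSING, GenotypeMatrix


@dataclass
class GrmMatrix:
    label: str
    samples: list[str]
    values: np.ndarray          # symmetric n x n
    n_variants_used: int

    def __post_init__(self):
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError(f"GRM shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if self.n_variants_used < 1:
            raise ValueError("GRM must be built from at least one variant")

    @property
    def n(self) -> int:
        return len(self.samples)

    def subset(self, sample_ids: Sequence[str]) -> "GrmMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GrmMatrix(self.label, list(sample_ids),
                         self.values[np.ix_(idx, idx)], self.n_variants_used)


@dataclass
class RegionSpec:
    """A QTL window and the (larger) interval excluded from the
    rest-of-chromosome GRM to absorb flanking LD."""

    label: str
    chrom: str
    window: tuple[int, int]
    exclusion: tuple[int, int]

    def __post_init__(self):
        ws, we = self.window
        es, ee = self.exclusion
        if not (es <= ws <= we <= ee):
            raise ValueError(
                f"region {self.label}: exclusion {self.exclusion} must "
                f"contain window {self.window}")

    @classmethod
    def around(cls, label: str, chrom: str, center_bp: int,
               window_halfwidth_bp: int, exclusion_halfwidth_bp: int
               ) -> "RegionSpec":
        return cls(label, chrom,
                   (center_bp - window_halfwidth_bp,
                    center_bp + window_halfwidth_bp),
                   (center_bp - exclusion_halfwidth_bp,
                    center_bp + exclusion_halfwidth_bp))


def _standardized(G: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Centred and scaled genotype columns; missing mean-imputed."""
    Z = G.codes[:, idx].astype(float)
    Z[Z == MISSING] = np.nan
    p = np.nanmean(Z, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        j = int(np.argmax((p <= 0) | (p >= 1)))
        raise ValueError(
            f"variant {G.variants[idx[j]].id} is monomorphic in the sample; "
            "filter before building the GRM")
    Z = np.where(np.isnan(Z), 2 * p, Z)
    return (Z - 2 * p) / np.sqrt(2 * p * (1 - p))


def compute_grm(G: GenotypeMatrix,
                variant_subset: Iterable[int] | Iterable[str] | None = None,
                label: str = "genomic") -> GrmMatrix:
    """GRM from the given variants (indices or ids; default all)."""
    if variant_subset is None:
        idx = np.arange(G.n_variants)
    else:
        subset = list(variant_subset)
        if len(subset) == 0:
            raise ValueError("empty variant subset")
        if isinstance(subset[0], str):
            idx = np.array([G.variant_index(v) for v in subset])
        else:
            idx = np.asarray(subset, dtype=int)
    Z = _standardized(G, idx)
    m = Z.shape[1]
    A = (Z @ Z.T) / m
    return GrmMatrix(label, list(G.samples), A, m)


def build_partitioned_grms(G: GenotypeMatrix,
                           regions: Sequence[RegionSpec] = (),
                           scheme: str = "loco") -> list[GrmMatrix]:
    """GRM sets for the partitioned designs.

    scheme="per_chromosome": one GRM per chromosome.
    scheme="loco": per chromosome, a GRM from all variants NOT on it.
    scheme="qtl_plus_rest": per region, a window GRM plus a
    rest-of-chromosome GRM that excludes the full exclusion interval.
    """
    chrom_of = np.array([v.chrom for v in G.variants])
    pos = np.array([v.pos for v in G.variants])
    chroms = G.chroms

    if scheme == "per_chromosome":
        return [compute_grm(G, np.nonzero(chrom_of == c)[0], label=f"chr{c}")
                for c in chroms]

    if scheme == "loco":
        # combine per-chromosome cross-products rather than recomputing
        zs = {c: _standardized(G, np.nonzero(chrom_of == c)[0]) for c in chroms}
        cross = {c: zs[c] @ zs[c].T for c in chroms}
        counts = {c: zs[c].shape[1] for c in chroms}
        out = []
        for c in chroms:
            m = sum(counts[d] for d in chroms if d != c)
            if m == 0:
                raise ValueError(f"no variants left out of chromosome {c}")
            A = sum(cross[d] for d in chroms if d != c) / m
            out.append(GrmMatrix(f"loco{c}", list(G.samples), A, m))
        return out

    if scheme == "qtl_plus_rest":
        # overlap check within each chromosome
        by_chrom: dict[str, list[RegionSpec]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for c, regs in by_chrom.items():
            regs = sorted(regs, key=lambda r: r.window[0])
            for a, b in zip(regs, regs[1:]):
                if a.window[1] >= b.window[0]:
                    raise ValueError(f"overlapping windows on chromosome {c}")
        out = []
        for r in regions:
            on_chrom = chrom_of == r.chrom
            in_win = on_chrom & (pos >= r.window[0]) & (pos <= r.window[1])
            in_excl = on_chrom & (pos >= r.exclusion[0]) & (pos <= r.exclusion[1])
            if not in_win.any():
                raise ValueError(f"region {r.label}: window contains no variants")
            out.append(compute_grm(G, np.nonzero(in_win)[0],
                                   label=f"{r.label}_window"))
            rest = on_chrom & ~in_excl
            if rest.any():
                out.append(compute_grm(G, np.nonzero(rest)[0],
                                       label=f"{r.label}_rest"))
        return out

    raise ValueError(f"unknown partition scheme {scheme!r}")


# ---------------------------------------------------------------------------
# persistence: plain TSV and the GCTA binary-triplet convention
# ---------------------------------------------------------------------------

def write_grm_tsv(grm: GrmMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#label=%s n_variants=%d\n" % (grm.label, grm.n_variants_used))
        fh.write("sample\t" + "\t".join(grm.samples) + "\n")
        for i, s in enumerate(grm.samples):
            fh.write(s + "\t" + "\t".join(f"{v:.10g}" for v in grm.values[i])
                     + "\n")


def read_grm_tsv(path: str | os.PathLike) -> GrmMatrix:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(kv.split("=") for kv in header.split())
        samples = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
    values = np.array(rows, dtype=float)
    return GrmMatrix(meta.get("label", "genomic"), samples, values,
                     int(meta.get("n_variants", 1)))


def write_grm_gcta(grm: GrmMatrix, prefix: str | os.PathLike) -> None:
    """Lower-triangle float32 .grm.bin plus .grm.id and .grm.N.bin."""
    prefix = str(prefix)
    n = grm.n
    tri = grm.values[np.tril_indices(n)]
    with open(prefix + ".grm.bin", "wb") as fh:
        fh.write(tri.astype("<f4").tobytes())
    with open(prefix + ".grm.N.bin", "wb") as fh:
        fh.write(np.full(tri.shape, grm.n_variants_used, dtype="<f4").tobytes())
    with open(prefix + ".grm.id", "w") as fh:
        for s in grm.samples:
            fh.write(f"{s}\t{s}\n")


def read_grm_gcta(prefix: str | os.PathLike, label: str = "genomic"
                  ) -> GrmMatrix:
    prefix = str(prefix)
    with open(prefix + ".grm.id") as fh:
        samples = [line.split()[1] for line in fh]
    n = len(samples)
    tri = np.frombuffer(open(prefix + ".grm.bin", "rb").read(), dtype="<f4")
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("GRM binary size does not match the id file")
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, -1).T
    try:
        nvar = int(np.frombuffer(
            open(prefix + ".grm.N.bin", "rb").read(), dtype="<f4")[0])
    except FileNotFoundError:
        nvar = 1
    return GrmMatrix(label, samples, values, max(nvar, 1))
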