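"""Genotype and phenotype containers plus readers/writers for VCF, PLINK text
and phenotype TSV files.

Genotypes are stored as minor-allele counts (0/1/2) with ``-1`` marking a
missing call.  The minor allele is fixed once, from the sample frequencies in
the input file, and is never re-polarised downstream, so conditional analyses
and LD computations stay on a consistent scale.  All coordinates are 1-based
with inclusive interval endpoints.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

AGE_CLASSES = ("<3", "3-4", "4-5", ">5")
SEXES = ("mare", "stallion")
EVENTS = ("AUC", "MPT", "SBR", "SPS")


@dataclass(frozen=True)
class VariantInfo:
    """A biallelic SNV with its minor-allele frequency.

    ``quality`` carries an imputation-quality score (a dosage-R2-like value)
    through the pipeline as metadata; it is never computed here.
    ``minor_is_alt`` records which of REF/ALT is the minor allele so that
    genotype codes can be written back to allele-based formats.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float
    quality: float | None = None
    minor_is_alt: bool = True

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"variant {self.id}: MAF {self.maf} outside [0, 0.5]")

    @property
    def minor_allele(self) -> str:
        return self.alt_allele if self.minor_is_alt else self.ref_allele

    @property
    def major_allele(self) -> str:
        return self.ref_allele if self.minor_is_alt else self.alt_allele


class GenotypeMatrix:
    """samples x variants matrix of minor-allele counts.

    ``codes`` is int8 with values {0, 1, 2, MISSING}.
    """

    def __init__(self, samples: Sequence[str], variants: Sequence[VariantInfo],
                 codes: np.ndarray, validate: bool = True):
        self.samples = list(samples)
        self.variants = list(variants)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        if validate:
            self.validate()

    # -- basic properties ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def chroms(self) -> list[str]:
        seen = {}
        for v in self.variants:
            seen.setdefault(v.chrom, None)
        return list(seen)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant id {variant_id!r} not in matrix") from None

    def dosage(self, variant_id: str, impute_missing: bool = False) -> np.ndarray:
        """Minor-allele count vector for one variant (float, NaN for missing)."""
        col = self.codes[:, self.variant_index(variant_id)].astype(float)
        col[col == MISSING] = np.nan
        if impute_missing and np.isnan(col).any():
            col[np.isnan(col)] = np.nanmean(col)
        return col

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = (self.codes > 2) | (self.codes < MISSING)
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        # variants sorted by position within each chromosome, ties forbidden
        last: dict[str, int] = {}
        for v in self.variants:
            prev = last.get(v.chrom)
            if prev is not None and v.pos <= prev:
                raise ValueError(
                    f"variants on {v.chrom} not strictly sorted: "
                    f"pos {prev} followed by {v.pos}")
            last[v.chrom] = v.pos
        maf = compute_maf(self, allow_all_missing=True)
        stored = np.array([v.maf for v in self.variants])
        ok = np.isnan(maf) | (np.abs(maf - stored) <= 1e-12)
        if not ok.all():
            i = int(np.argmin(ok))
            raise ValueError(
                f"stored MAF {stored[i]} of variant {self.variants[i].id} "
                f"disagrees with recomputed value {maf[i]}")

    def subset_variants(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = list(index)
        return GenotypeMatrix(self.samples, [self.variants[i] for i in idx],
                              self.codes[:, idx], validate=False)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        G = GenotypeMatrix(list(sample_ids), self.variants,
                           self.codes[idx, :], validate=False)
        # MAF metadata refers to the full load-time sample; keep it.
        return G


# ---------------------------------------------------------------------------
# allele frequency and filtering
# ---------------------------------------------------------------------------

def compute_maf(G: GenotypeMatrix, allow_all_missing: bool = False) -> np.ndarray:
    """Per-variant minor-allele frequency among non-missing calls.

    The result is min(f, 1 - f) of the counted allele's frequency, hence
    always in [0, 0.5] regardless of which allele the codes count.
    """
    codes = G.codes
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    counts = np.where(obs, codes, 0).sum(axis=0)
    if (n_obs == 0).any():
        if not allow_all_missing:
            i = int(np.argmax(n_obs == 0))
            raise ValueError(f"variant {G.variants[i].id} has no non-missing genotypes")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts / (2.0 * n_obs)
    return np.minimum(f, 1.0 - f)


def refresh_maf(G: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy whose VariantInfo.maf matches the current sample."""
    maf = compute_maf(G, allow_all_missing=True)
    variants = [replace(v, maf=float(m)) if np.isfinite(m) else v
                for v, m in zip(G.variants, maf)]
    return GenotypeMatrix(G.samples, variants, G.codes, validate=False)


def filter_variants(G: GenotypeMatrix, min_maf: float = 0.0,
                    keep_region: tuple[str, int, int] | None = None,
                    drop_region: tuple[str, int, int] | None = None,
                    max_missing: float | None = None) -> GenotypeMatrix:
    """Retain variants by MAF and 1-based inclusive genomic regions.

    ``keep_region`` restricts to variants inside the region; ``drop_region``
    removes variants inside it.  An empty result is allowed.
    """
    for reg in (keep_region, drop_region):
        if reg is not None and reg[1] > reg[2]:
            raise ValueError(f"region start {reg[1]} > end {reg[2]}")
    maf = compute_maf(G, allow_all_missing=True)
    keep = np.ones(G.n_variants, dtype=bool)
    keep &= np.nan_to_num(maf, nan=-1.0) >= min_maf
    if max_missing is not None:
        miss = (G.codes == MISSING).mean(axis=0)
        keep &= miss <= max_missing
    for i, v in enumerate(G.variants):
        if keep_region is not None:
            c, s, e = keep_region
            if not (v.chrom == c and s <= v.pos <= e):
                keep[i] = False
        if drop_region is not None:
            c, s, e = drop_region
            if v.chrom == c and s <= v.pos <= e:
                keep[i] = False
    return G.subset_variants(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _codes_from_alt_counts(alt_counts: np.ndarray, missing: np.ndarray
                           ) -> tuple[np.ndarray, float, bool]:
    n_obs = (~missing).sum()
    if n_obs == 0:
        # orientation undecidable; count ALT by convention
        return np.full(alt_counts.shape, MISSING, dtype=np.int8), float("nan"), True
    f_alt = alt_counts[~missing].sum() / (2.0 * n_obs)
    minor_is_alt = f_alt <= 0.5
    codes = np.where(missing, MISSING,
                     alt_counts if minor_is_alt else 2 - alt_counts)
    maf = f_alt if minor_is_alt else 1.0 - f_alt
    return codes.astype(np.int8), float(maf), bool(minor_is_alt)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a GT-only biallelic-SNV VCF into a GenotypeMatrix.

    The minor allele is determined from the file's own sample frequencies.
    A DR2 INFO field, when present, is carried as VariantInfo.quality.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"({rec.REF}/{','.join(rec.ALT)}) is not supported")
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(f"non-SNV record at {rec.CHROM}:{rec.POS}")
        gts = np.array(rec.genotypes, dtype=int)  # (n, 3): a0, a1, phased
        missing = (gts[:, 0] < 0) | (gts[:, 1] < 0)
        alt_counts = gts[:, 0] + gts[:, 1]
        codes, maf, minor_is_alt = _codes_from_alt_counts(alt_counts, missing)
        dr2 = rec.INFO.get("DR2")
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantInfo(
            id=vid, chrom=rec.CHROM, pos=rec.POS, ref_allele=rec.REF,
            alt_allele=rec.ALT[0], maf=0.0 if np.isnan(maf) else maf,
            quality=float(dr2) if dr2 is not None else None,
            minor_is_alt=minor_is_alt))
        cols.append(codes)
    codes = (np.stack(cols, axis=1) if cols
             else np.zeros((len(samples), 0), dtype=np.int8))
    G = GenotypeMatrix(samples, variants, codes, validate=False)
    _check_sorted(G, str(path))
    G.validate()
    return G


def _check_sorted(G: GenotypeMatrix, path: str) -> None:
    last: dict[str, int] = {}
    for v in G.variants:
        prev = last.get(v.chrom)
        if prev is not None and v.pos <= prev:
            raise ValueError(
                f"{path}: unsorted input on {v.chrom}: position {v.pos} "
                f"follows {prev}")
        last[v.chrom] = v.pos


def write_vcf(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with GT (and DR2 INFO where present)."""
    if G.n_samples == 0:
        raise ValueError("refusing to write a VCF with no samples")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DR2,Number=1,Type=Float,'
                 'Description="Imputation quality (pass-through)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for j, v in enumerate(G.variants):
            col = G.codes[:, j]
            # minor count -> ALT count
            alt = np.where(col == MISSING, MISSING,
                           col if v.minor_is_alt else 2 - col)
            gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            gts = "\t".join(gt_strings[int(a)] for a in alt)
            info = f"DR2={v.quality:g}" if v.quality is not None else "."
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------

def write_plink(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write space-separated .ped (two allele columns per variant) and .map."""
    if G.n_samples == 0:
        raise ValueError("refusing to write PLINK files with no samples")
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for v in G.variants:
            fh.write(f"{v.chrom} {v.id} 0 {v.pos}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, s in enumerate(G.samples):
            fields = [s, s, "0", "0", "0", "-9"]
            for j, v in enumerate(G.variants):
                c = int(G.codes[i, j])
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [v.major_allele, v.major_allele]
                elif c == 1:
                    fields += [v.major_allele, v.minor_allele]
                else:
                    fields += [v.minor_allele, v.minor_allele]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read PLINK text files; the minor allele is set from sample frequencies."""
    prefix = str(prefix)
    sites: list[tuple[str, str, int]] = []
    with open(prefix + ".map") as fh:
        for line in fh:
            chrom, vid, _, pos = line.split()
            sites.append((chrom, vid, int(pos)))
    samples: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(sites):
                raise ValueError(
                    f"{prefix}.ped: sample {parts[1]} has {len(alleles)} allele "
                    f"columns, expected {2 * len(sites)}")
            allele_rows.append([(alleles[2 * j], alleles[2 * j + 1])
                                for j in range(len(sites))])
    variants: list[VariantInfo] = []
    codes = np.zeros((len(samples), len(sites)), dtype=np.int8)
    for j, (chrom, vid, pos) in enumerate(sites):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"variant {vid} at {chrom}:{pos} has >2 alleles")
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        if len(alleles) == 0:
            raise ValueError(f"variant {vid} has no called genotypes")
        if len(alleles) == 1:
            minor, major = "N", alleles[0]  # monomorphic; placeholder minor
        else:
            minor, major = alleles[0], alleles[1]
        total = sum(counts.values())
        maf = counts.get(minor, 0) / total if total else 0.0
        if maf > 0.5:  # tie resolved the other way
            minor, major = major, minor
            maf = 1.0 - maf
        for i, row in enumerate(allele_rows):
            a, b = row[j]
            if a == "0" or b == "0":
                codes[i, j] = MISSING
            else:
                codes[i, j] = (a == minor) + (b == minor)
        variants.append(VariantInfo(
            id=vid, chrom=chrom, pos=pos, ref_allele=major, alt_allele=minor,
            maf=maf, minor_is_alt=True))
    G = GenotypeMatrix(samples, variants, codes, validate=False)
    _check_sorted(G, prefix + ".map")
    G.validate()
    return G


def read_genotypes(path: str | os.PathLike, format: str = "vcf") -> GenotypeMatrix:
    if format == "vcf":
        return read_vcf(path)
    if format == "plink_text":
        return read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path: str | os.PathLike,
                    format: str = "vcf") -> None:
    if format == "vcf":
        write_vcf(G, path)
    elif format == "plink_text":
        write_plink(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotypes and fixed-effect designs
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Phenotype/covariate table keyed by sample id.

    The underlying DataFrame has one row per sample with a ``sample`` column,
    one column per trait, and the covariate columns ``age_days``,
    ``age_class``, ``sex``, ``judge``, ``event`` (any of which may be absent
    if no model uses them).
    """

    df: pd.DataFrame

    def __post_init__(self):
        if "sample" not in self.df.columns:
            raise ValueError("phenotype table must have a 'sample' column")
        if self.df["sample"].duplicated().any():
            dup = self.df["sample"][self.df["sample"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in phenotype table")

    @property
    def samples(self) -> list[str]:
        return self.df["sample"].tolist()

    def trait(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise KeyError(f"trait {name!r} not in phenotype table")
        return self.df[name]

    def check_ordinal(self, name: str, defect: bool = False) -> None:
        """Validate an ordinal conformation score column (-3..+3, or 0..+3)."""
        vals = self.df[name].dropna()
        lo = 0 if defect else -3
        if not ((vals >= lo) & (vals <= 3) & (vals == vals.round())).all():
            raise ValueError(f"trait {name!r} has values outside the "
                             f"[{lo}, 3] integer scale")

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str}))


@dataclass
class ModelSpec:
    """Fixed-effect structure of a single-trait mixed model.

    covariates: quantitative columns of the phenotype table, a conditioning
    trait, or ``"snp:<variant id>"`` for a conditioning SNP dosage.
    factors: categorical fixed effects, one-hot encoded with the first level
    dropped (the intercept is always included).
    grm_names: labels of the variance components the model will carry.
    """

    trait: str
    covariates: list[str] = field(default_factory=list)
    factors: list[str] = field(default_factory=list)
    grm_names: list[str] = field(default_factory=lambda: ["genomic"])

    def build_design(self, pheno: PhenotypeTable,
                     G: GenotypeMatrix | None = None,
                     samples: Sequence[str] | None = None
                     ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
        """Return (y, X, sample_ids, column_names), complete-case.

        Rows are restricted to samples with the trait and every covariate
        observed; when ``samples`` is given the order and membership follow it.
        """
        df = pheno.df
        if samples is not None:
            df = df.set_index("sample").loc[list(samples)].reset_index()
        needed = [self.trait]
        for cov in self.covariates:
            if not cov.startswith("snp:"):
                needed.append(cov)
        needed += self.factors
        for colname in needed:
            if colname not in df.columns:
                raise ValueError(f"column {colname!r} missing from phenotype table")
        mask = df[needed].notna().all(axis=1).to_numpy()
        df = df.loc[mask]
        ids = df["sample"].tolist()
        y = df[self.trait].to_numpy(dtype=float)
        cols = [np.ones(len(df))]
        names = ["intercept"]
        for cov in self.covariates:
            if cov.startswith("snp:"):
                if G is None:
                    raise ValueError("SNP covariate requires a GenotypeMatrix")
                vec = G.dosage(cov[4:], impute_missing=True)
                pos = {s: i for i, s in enumerate(G.samples)}
                missing = [s for s in ids if s not in pos]
                if missing:
                    raise ValueError(f"sample {missing[0]!r} absent from genotypes")
                cols.append(vec[[pos[s] for s in ids]])
            else:
                cols.append(df[cov].to_numpy(dtype=float))
            names.append(cov)
        for fac in self.factors:
            levels = sorted(df[fac].astype(str).unique())
            for lev in levels[1:]:
                cols.append((df[fac].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{fac}[{lev}]")
        X = np.column_stack(cols)
        # drop columns that became collinear/constant after subsetting
        keep, rank = [], 0
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > rank:
                keep.append(j)
                rank += 1
        if len(keep) < X.shape[1]:
            X = X[:, keep]
            names = [names[j] for j in keep]
        return y, X, ids, names


def align_samples(G: GenotypeMatrix, pheno: PhenotypeTable) -> list[str]:
    """Samples present in both containers, in genotype order."""
    have = set(pheno.samples)
    return [s for s in G.samples if s in have]
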