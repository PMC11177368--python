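"""Founder-mosaic genotype and phenotype simulator with a planted major QTL.

The generator emulates a horse-breeding study cohort: a few thousand
individuals genotyped on LD-structured biallelic SNPs spread over several
chromosome-like segments, a height-like trait with mean ~167.6 and SD ~3.6
and heritability ~0.53, a major additive QTL (a nonsense variant at MAF
~0.45 adding ~2.7 units per minor allele), and ordinal conformation scores
on a -3..+3 (or 0..+3) scale with judge/event/sex/age fixed effects.

LD arises from a copying model: each individual haplotype is a mosaic of a
small founder pool, with switch points falling as a Poisson process along
the chromosome.  Shared founder segments are therefore identical by descent,
which is exactly the structure the ROH/IBD fine-mapping stage exploits.  The
founder haplotypes carrying the causal minor allele are made identical over
a window around the QTL ("single founder mutation"), so minor-allele
homozygotes are homozygous across that window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core_io import (MISSING, AGE_CLASSES, EVENTS, SEXES, GenotypeMatrix,
                      PhenotypeTable, VariantInfo)

# reference/alternate allele templates per consequence tag; the alternate
# (minor, trait-increasing) allele creates the consequence when substituted
# at the first base of the affected codon (GAA->TAA: E/*, ATT->TTT: I/F).
_CONSEQUENCE_ALLELES = {
    "stop_gained": ("G", "T"),
    "missense": ("A", "T"),
    "intergenic": ("A", "C"),
}


@dataclass
class CausalVariant:
    """A planted causal SNV.

    Exactly one of ``beta`` (trait units per minor allele, on the first
    trait's scale) or ``variance_fraction`` (share of phenotypic variance
    the variant should explain) must be given.  ``pleiotropy`` maps trait
    names to effect scalings relative to the first trait; traits absent
    from the map are unaffected.  An empty map means "first trait only".
    """

    chrom: str
    pos: int
    target_maf: float = 0.45
    beta: float | None = None
    variance_fraction: float | None = None
    consequence_tag: str = "stop_gained"
    pleiotropy: dict[str, float] = field(default_factory=dict)
    window_halfwidth_bp: int = 3_000_000
    exclusion_halfwidth_bp: int = 7_000_000
    n_window_variants: int = 300
    block_halfwidth_bp: int = 1_000_000

    def __post_init__(self):
        if not (0.0 < self.target_maf <= 0.5):
            raise ValueError(f"target_maf must be in (0, 0.5], got {self.target_maf}")
        if (self.beta is None) == (self.variance_fraction is None):
            raise ValueError("give exactly one of beta / variance_fraction")
        if self.consequence_tag not in _CONSEQUENCE_ALLELES:
            raise ValueError(f"unknown consequence tag {self.consequence_tag!r}")

    @property
    def window(self) -> tuple[int, int]:
        return (self.pos - self.window_halfwidth_bp,
                self.pos + self.window_halfwidth_bp)

    @property
    def exclusion(self) -> tuple[int, int]:
        return (self.pos - self.exclusion_halfwidth_bp,
                self.pos + self.exclusion_halfwidth_bp)

    @property
    def vid(self) -> str:
        return f"v{self.chrom}_{self.pos}"


@dataclass
class RegionEffect:
    """Planted causal variation spread over a QTL window.

    Effects are drawn for every variant inside the window under the
    standardized-genotype exchangeable model and rescaled so the window's
    genetic value explains exactly ``variance_fraction`` of the phenotypic
    variance.  With ``share_effects`` the same effect vector drives every
    trait in ``pleiotropy`` (scaled), giving a local genetic correlation
    of +-1 at the window.
    """

    chrom: str
    pos: int                       # window centre, bp
    variance_fraction: float
    window_halfwidth_bp: int = 3_000_000
    exclusion_halfwidth_bp: int = 7_000_000
    n_window_variants: int = 80    # dense variants added inside the window
    pleiotropy: dict[str, float] = field(default_factory=dict)
    share_effects: bool = True

    @property
    def window(self) -> tuple[int, int]:
        return (self.pos - self.window_halfwidth_bp,
                self.pos + self.window_halfwidth_bp)

    @property
    def exclusion(self) -> tuple[int, int]:
        return (self.pos - self.exclusion_halfwidth_bp,
                self.pos + self.exclusion_halfwidth_bp)

    @property
    def label(self) -> str:
        return f"region_{self.chrom}_{self.pos}"


@dataclass
class TraitSpec:
    """One simulated trait.

    ``fixed_effects`` is "age_only" (objectively measured trait: intercept
    plus a linear age-in-days covariate) or "full" (scored trait: age-class,
    sex, judge and event level effects).  ``ordinal`` turns the continuous
    phenotype into linear-profiling scores: "seven" for the -3..+3 scale,
    "defect" for 0..+3.
    """

    name: str
    mean: float = 167.6
    sd: float = 3.6
    h2: float = 0.528
    fixed_effects: str = "age_only"
    ordinal: str | None = None


@dataclass
class FixedEffectSpec:
    n_judges: int = 39
    judge_sd_frac: float = 0.5    # level-effect SD as a fraction of trait SD
    event_sd_frac: float = 0.5
    sex_sd_frac: float = 0.5
    age_class_sd_frac: float = 0.25
    age_slope_per_day: float = 0.001  # trait units per day, age_only traits


@dataclass
class SimConfig:
    n_individuals: int = 2000
    # (name, n_background_variants, length_bp)
    chromosomes: list[tuple[str, int, int]] = field(default_factory=lambda: [
        ("1", 1100, 120_000_000),
        ("2", 1100, 120_000_000),
        ("3", 1100, 120_000_000),
    ])
    n_founder_haplotypes: int = 40
    switch_rate: float = 1.0  # expected founder switches per Mb per haplotype
    causal_spec: list[CausalVariant] = field(default_factory=lambda: [
        CausalVariant(chrom="3", pos=107_558_421, target_maf=0.45, beta=2.68,
                      consequence_tag="stop_gained")])
    region_spec: list[RegionEffect] = field(default_factory=list)
    traits: list[TraitSpec] = field(default_factory=lambda: [TraitSpec("height")])
    fixed_effect_spec: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    ordinal_thresholds: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    min_maf: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for _, n, length in self.chromosomes:
            if length <= 0 or n <= 0:
                raise ValueError("chromosome lengths and variant counts must be > 0")
        for t in self.traits:
            if not (0.0 <= t.h2 < 1.0):
                raise ValueError(f"trait {t.name}: h2 must be in [0, 1)")

    @property
    def primary_trait(self) -> TraitSpec:
        return self.traits[0]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_ids: list[str]
    causal_positions: list[tuple[str, int]]
    causal_betas: dict[str, dict[str, float]]      # trait -> variant id -> beta
    carrier_founders: dict[str, list[int]]         # variant id -> founder indices
    polygenic_values: dict[str, np.ndarray]        # trait -> per-individual value
    genetic_values: dict[str, np.ndarray]          # trait -> total genetic value
    variance_components: dict[str, dict]           # trait -> bookkeeping dict
    realized_h2: dict[str, float]

    def to_json(self, path) -> None:
        out = {
            "causal_ids": self.causal_ids,
            "causal_positions": [list(p) for p in self.causal_positions],
            "causal_betas": self.causal_betas,
            "carrier_founders": self.carrier_founders,
            "variance_components": self.variance_components,
            "realized_h2": self.realized_h2,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, n: int, lo: int, hi: int,
                    taken: set[int]) -> np.ndarray:
    """n distinct random 1-based positions in [lo, hi] avoiding `taken`."""
    out: set[int] = set()
    while len(out) < n:
        cand = rng.integers(lo, hi + 1, size=2 * (n - len(out)))
        for p in cand:
            p = int(p)
            if p not in taken and p not in out:
                out.add(p)
                if len(out) == n:
                    break
    return np.sort(np.fromiter(out, dtype=np.int64))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate the genotype matrix and initialise the ground-truth record.

    Deterministic given ``cfg`` (including its seed).  Variants with MAF
    below ``cfg.min_maf`` are dropped, except planted causal variants.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    nf = cfg.n_founder_haplotypes

    all_variants: list[VariantInfo] = []
    all_codes: list[np.ndarray] = []
    carrier_founders: dict[str, list[int]] = {}
    causal_ids: list[str] = []
    causal_positions: list[tuple[str, int]] = []

    for chrom, n_bg, length in cfg.chromosomes:
        causals = [c for c in cfg.causal_spec if c.chrom == chrom]
        # --- variant positions: uniform background + dense QTL windows ----
        pos_list: list[int] = []
        is_dense = {}
        taken: set[int] = set()
        for c in causals:
            # reserve the two bases after the causal site so the toy gene
            # model's codon template cannot collide with another variant
            taken.update((c.pos, c.pos + 1, c.pos + 2))
        for c in causals:
            lo = max(1, c.window[0])
            hi = min(length, c.window[1])
            dense = _draw_positions(rng, c.n_window_variants - 1, lo, hi, taken)
            taken.update(int(p) for p in dense)
            for p in dense:
                is_dense[int(p)] = True
            pos_list.extend(int(p) for p in dense)
            pos_list.append(c.pos)
            is_dense[c.pos] = True
        for r in (r for r in cfg.region_spec if r.chrom == chrom):
            lo = max(1, r.window[0])
            hi = min(length, r.window[1])
            dense = _draw_positions(rng, r.n_window_variants, lo, hi, taken)
            taken.update(int(p) for p in dense)
            pos_list.extend(int(p) for p in dense)
        bg = _draw_positions(rng, n_bg, 1, length, taken)
        pos_list.extend(int(p) for p in bg)
        positions = np.sort(np.array(sorted(set(pos_list)), dtype=np.int64))
        m = len(positions)
        pos_index = {int(p): j for j, p in enumerate(positions)}

        # --- founder haplotypes -------------------------------------------
        base_freq = rng.beta(0.2, 0.2, size=m)
        founders = (rng.random((nf, m)) < base_freq).astype(np.int8)
        for c in causals:
            n_carrier = int(round(c.target_maf * nf))
            if n_carrier < 1 or n_carrier >= nf:
                raise ValueError(
                    f"target MAF {c.target_maf} not reachable with "
                    f"{nf} founder haplotypes; increase n_founder_haplotypes")
            carriers = rng.choice(nf, size=n_carrier, replace=False)
            block_lo = c.pos - c.block_halfwidth_bp
            block_hi = c.pos + c.block_halfwidth_bp
            in_block = (positions >= block_lo) & (positions <= block_hi)
            # the founder haplotypes that carry the causal minor allele are
            # identical over the block: allele 1 everywhere in the block;
            # non-carrier founders get a low allele-1 frequency there (the
            # founder mutation sits on a locally rare haplotype background)
            blk = np.nonzero(in_block)[0]
            non_carriers = np.setdiff1d(np.arange(nf), carriers)
            q_block = rng.beta(0.2, 0.8, size=len(blk))
            founders[np.ix_(non_carriers, blk)] = (
                rng.random((len(non_carriers), len(blk))) < q_block
            ).astype(np.int8)
            founders[np.ix_(carriers, blk)] = 1
            j_causal = pos_index[c.pos]
            founders[:, j_causal] = 0
            founders[carriers, j_causal] = 1
            carrier_founders[c.vid] = sorted(int(x) for x in carriers)
            causal_ids.append(c.vid)
            causal_positions.append((chrom, c.pos))

        # --- mosaic haplotypes --------------------------------------------
        gaps_mb = np.diff(positions) / 1e6
        p_switch = 1.0 - np.exp(-cfg.switch_rate * gaps_mb)
        n_hap = 2 * n
        switches = rng.random((n_hap, m - 1)) < p_switch if m > 1 else \
            np.zeros((n_hap, 0), dtype=bool)
        seg_idx = np.concatenate(
            [np.zeros((n_hap, 1), dtype=np.int32),
             np.cumsum(switches, axis=1, dtype=np.int32)], axis=1)
        max_seg = int(seg_idx.max()) + 1
        founder_draw = rng.integers(0, nf, size=(n_hap, max_seg))
        hap_founder = np.take_along_axis(founder_draw, seg_idx, axis=1)
        # haplotypes that carry the causal founder mutation keep the intact
        # founder haplotype across the homogeneous block (the unbroken
        # founder segment of the copying model), so minor-allele
        # homozygotes are runs-of-homozygosity-positive over the window
        for c in causals:
            j_causal = pos_index[c.pos]
            carriers = np.array(carrier_founders[c.vid])
            blk = np.nonzero((positions >= c.pos - c.block_halfwidth_bp)
                             & (positions <= c.pos + c.block_halfwidth_bp))[0]
            on_carrier = np.isin(hap_founder[:, j_causal], carriers)
            hap_founder[np.ix_(on_carrier, blk)] = \
                hap_founder[on_carrier, j_causal][:, None]
        alleles = founders[hap_founder, np.arange(m)[None, :]]
        geno1 = alleles[0::2] + alleles[1::2]  # allele-1 counts, n x m

        # --- orient to minor-allele counts --------------------------------
        f1 = geno1.mean(axis=0) / 2.0
        minor_is_1 = f1 <= 0.5
        codes = np.where(minor_is_1[None, :], geno1, 2 - geno1).astype(np.int8)
        maf = np.minimum(f1, 1.0 - f1)

        causal_pos_set = {c.pos: c for c in causals}
        keep = (maf >= cfg.min_maf) | np.isin(positions,
                                              list(causal_pos_set.keys()))
        bases = np.array(["A", "C", "G", "T"])
        for j in np.nonzero(keep)[0]:
            p = int(positions[j])
            c = causal_pos_set.get(p)
            if c is not None:
                if not minor_is_1[j]:  # minor allele must be the carrier allele
                    raise RuntimeError(
                        f"planted variant at {chrom}:{p} drifted above 0.5 "
                        "frequency; use a larger founder pool or cohort")
                major, minor = _CONSEQUENCE_ALLELES[c.consequence_tag]
            else:
                pick = rng.choice(4, size=2, replace=False)
                major, minor = bases[pick[0]], bases[pick[1]]
            all_variants.append(VariantInfo(
                id=f"v{chrom}_{p}", chrom=chrom, pos=p,
                ref_allele=major, alt_allele=minor,
                maf=float(maf[j]), minor_is_alt=True))
            all_codes.append(codes[:, j])

    samples = [f"ind{i:05d}" for i in range(n)]
    G = GenotypeMatrix(samples, all_variants,
                       np.stack(all_codes, axis=1), validate=False)
    G.validate()
    truth = SimTruth(
        causal_ids=causal_ids, causal_positions=causal_positions,
        causal_betas={}, carrier_founders=carrier_founders,
        polygenic_values={}, genetic_values={}, variance_components={},
        realized_h2={})
    return G, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _centered_levels(rng: np.random.Generator, k: int, sd: float) -> np.ndarray:
    eff = rng.normal(0.0, sd, size=k) if sd > 0 else np.zeros(k)
    return eff - eff.mean() if k > 1 else eff * 0.0


def _age_class(age_years: np.ndarray) -> np.ndarray:
    cls = np.full(age_years.shape, AGE_CLASSES[3], dtype=object)
    cls[age_years < 5] = AGE_CLASSES[2]
    cls[age_years < 4] = AGE_CLASSES[1]
    cls[age_years < 3] = AGE_CLASSES[0]
    return cls


def simulate_phenotypes(G: GenotypeMatrix, truth: SimTruth,
                        cfg: SimConfig) -> PhenotypeTable:
    """Simulate all configured traits on top of the generated genotypes.

    phenotype = fixed part + sum(causal beta * minor count) + polygenic + e.
    The polygenic part assigns independent N(0,1) effects to every variant
    outside the causal windows and rescales them so that the total genetic
    variance equals h2 * sd^2 per trait; the residual variance is
    (1 - h2) * sd^2.  The fixed part follows each trait's declared
    structure.  Ordinal traits are thresholded afterwards.
    """
    import pandas as pd

    rng = np.random.default_rng((cfg.seed + 1) << 8)
    n = G.n_samples
    fx = cfg.fixed_effect_spec

    age_years = rng.uniform(2.0, 10.0, size=n)
    age_days = age_years * 365.25
    sex = rng.choice(SEXES, size=n)
    judge = rng.integers(0, fx.n_judges, size=n)
    event = rng.integers(0, len(EVENTS), size=n)

    pos_of = {v.id: j for j, v in enumerate(G.variants)}
    causal_cols = {}
    for c in cfg.causal_spec:
        j = pos_of[c.vid]
        col = G.codes[:, j].astype(float)
        col[col == MISSING] = np.nan
        causal_cols[c.vid] = np.nan_to_num(col, nan=np.nanmean(col))

    def _standardize(idx: np.ndarray) -> np.ndarray:
        W = G.codes[:, idx].astype(float)
        W[W == MISSING] = np.nan
        p = np.nanmean(W, axis=0) / 2.0
        sd = np.sqrt(np.maximum(2 * p * (1 - p), 1e-12))
        return np.nan_to_num((W - 2 * p) / sd, nan=0.0)

    # variants eligible for polygenic effects: outside every causal window
    variant_chrom = np.array([v.chrom for v in G.variants])
    variant_pos = np.array([v.pos for v in G.variants])
    in_window = np.zeros(G.n_variants, dtype=bool)
    for item in list(cfg.causal_spec) + list(cfg.region_spec):
        lo, hi = item.window
        in_window |= ((variant_chrom == item.chrom)
                      & (variant_pos >= lo) & (variant_pos <= hi))
    region_idx = {}
    region_effects = {}
    for r in cfg.region_spec:
        lo, hi = r.window
        idx = np.nonzero((variant_chrom == r.chrom)
                         & (variant_pos >= lo) & (variant_pos <= hi))[0]
        if len(idx) == 0:
            raise ValueError(f"region {r.label}: no variants in window")
        region_idx[r.label] = idx
        if r.share_effects:
            region_effects[r.label] = rng.normal(size=len(idx))
    bg_idx = np.nonzero(~in_window)[0]
    # polygenic effects act on standardized genotypes (equal expected
    # variance per SNP), the exchangeability assumption GREML itself makes
    Z = _standardize(bg_idx)
    bg_chroms = variant_chrom[bg_idx]

    data = {"sample": G.samples, "age_days": age_days,
            "age_class": _age_class(age_years), "sex": sex,
            "judge": np.array([f"J{j:02d}" for j in judge]),
            "event": np.array([EVENTS[e] for e in event])}

    for t_i, trait in enumerate(cfg.traits):
        vp = trait.sd ** 2
        # causal effects on this trait
        betas: dict[str, float] = {}
        causal_part = np.zeros(n)
        window_vars: dict[str, float] = {}
        localized: list[tuple[str, np.ndarray]] = []
        for c in cfg.causal_spec:
            scale = (c.pleiotropy.get(trait.name, 1.0 if t_i == 0 else 0.0))
            if scale == 0.0:
                continue
            g = causal_cols[c.vid]
            vg = g.var()
            if vg == 0:
                raise ValueError(f"causal variant {c.vid} is monomorphic")
            if c.beta is not None:
                beta = c.beta * scale * (trait.sd / cfg.primary_trait.sd)
            else:
                beta = np.sqrt(c.variance_fraction * vp / vg) * scale
            betas[c.vid] = float(beta)
            contrib = beta * g
            causal_part = causal_part + contrib
            window_vars[c.vid] = float(contrib.var())
            localized.append((c.chrom, contrib))
        for r in cfg.region_spec:
            scale = (r.pleiotropy.get(trait.name, 1.0 if t_i == 0 else 0.0))
            if scale == 0.0:
                continue
            idx = region_idx[r.label]
            b_r = (region_effects[r.label] if r.share_effects
                   else rng.normal(size=len(idx)))
            u = _standardize(idx) @ b_r
            u = (u - u.mean()) / u.std()
            contrib = scale * np.sqrt(r.variance_fraction * vp) * u
            causal_part = causal_part + contrib
            window_vars[r.label] = float(contrib.var())
            localized.append((r.chrom, contrib))
        var_causal = float(causal_part.var())
        poly_target = trait.h2 * vp - var_causal
        if poly_target < -1e-9:
            raise ValueError(
                f"trait {trait.name}: causal variance {var_causal:.3f} exceeds "
                f"h2 * sd^2 = {trait.h2 * vp:.3f}")
        poly_target = max(poly_target, 0.0)
        if poly_target > 0 and len(bg_idx) > 0:
            b = rng.normal(size=len(bg_idx))
            raw = Z @ b
            poly_scale = np.sqrt(poly_target) / raw.std()
            poly = (raw - raw.mean()) * poly_scale
        else:
            b = np.zeros(len(bg_idx))
            poly_scale = 0.0
            poly = np.zeros(n)
        genetic = causal_part + poly
        resid_sd = np.sqrt((1.0 - trait.h2) * vp)
        resid = rng.normal(0.0, resid_sd, size=n) if resid_sd > 0 else np.zeros(n)

        # fixed part
        if trait.fixed_effects == "age_only":
            slope = fx.age_slope_per_day * (trait.sd / cfg.primary_trait.sd)
            fixed = trait.mean + slope * (age_days - age_days.mean())
        elif trait.fixed_effects == "full":
            age_eff = _centered_levels(rng, len(AGE_CLASSES),
                                       fx.age_class_sd_frac * trait.sd)
            sex_eff = _centered_levels(rng, len(SEXES), fx.sex_sd_frac * trait.sd)
            judge_eff = _centered_levels(rng, fx.n_judges,
                                         fx.judge_sd_frac * trait.sd)
            event_eff = _centered_levels(rng, len(EVENTS),
                                         fx.event_sd_frac * trait.sd)
            cls_idx = np.array([AGE_CLASSES.index(c) for c in data["age_class"]])
            sex_idx = np.array([SEXES.index(s) for s in sex])
            fixed = (trait.mean + age_eff[cls_idx] + sex_eff[sex_idx]
                     + judge_eff[judge] + event_eff[event])
        else:
            raise ValueError(f"unknown fixed-effect mode {trait.fixed_effects!r}")

        y = fixed + genetic - genetic.mean() + resid
        if trait.ordinal is not None:
            latent = (y - y.mean()) / y.std()
            if trait.ordinal == "seven":
                y = simulate_linear_scores(latent, cfg.ordinal_thresholds)
            elif trait.ordinal == "defect":
                y = simulate_linear_scores(latent, cfg.ordinal_thresholds,
                                           defect=True)
            else:
                raise ValueError(f"unknown ordinal mode {trait.ordinal!r}")
        data[trait.name] = y

        # ground-truth bookkeeping
        by_chrom: dict[str, float] = {}
        for chrom in G.chroms:
            part = np.zeros(n)
            sel = bg_chroms == chrom
            if sel.any() and poly_scale:
                part = part + (Z[:, sel] @ b[sel]) * poly_scale
            for c_chrom, contrib in localized:
                if c_chrom == chrom:
                    part = part + contrib
            by_chrom[chrom] = float(part.var())
        var_g = float(genetic.var())
        var_e = float(resid.var()) if resid_sd > 0 else 0.0
        truth.causal_betas[trait.name] = betas
        truth.polygenic_values[trait.name] = poly
        truth.genetic_values[trait.name] = genetic
        truth.variance_components[trait.name] = {
            "phenotypic": vp, "causal_total": var_causal,
            "polygenic": float(poly.var()), "residual": var_e,
            "by_chrom": by_chrom, "windows": window_vars,
            "window_fractions": {k: v / vp for k, v in window_vars.items()},
        }
        truth.realized_h2[trait.name] = var_g / (var_g + var_e) if var_g else 0.0

    return PhenotypeTable(pd.DataFrame(data))


def simulate_linear_scores(latent: np.ndarray | Sequence[float],
                           thresholds: Sequence[float],
                           defect: bool = False) -> np.ndarray:
    """Map a latent Gaussian column to ordinal linear-profiling scores.

    Seven-point mode needs 6 strictly increasing cut points and yields
    scores in -3..+3; defect mode needs 3 and yields 0..+3.
    """
    thr = np.asarray(thresholds, dtype=float)
    if defect:
        thr = thr[-3:] if len(thr) == 6 else thr
        if len(thr) != 3:
            raise ValueError("defect-trait mode needs 3 cut points")
        base = 0
    else:
        if len(thr) != 6:
            raise ValueError("seven-point mode needs 6 cut points")
        base = -3
    if not np.all(np.diff(thr) > 0):
        raise ValueError("thresholds must be strictly increasing")
    latent = np.asarray(latent, dtype=float)
    return (base + np.searchsorted(thr, latent, side="right")).astype(int)


def simulate_dataset(cfg: SimConfig
                     ) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Convenience wrapper: genotypes then phenotypes."""
    G, truth = simulate_genotypes(cfg)
    pheno = simulate_phenotypes(G, truth, cfg)
    return G, pheno, truth


# codon templates placing the causal substitution at the first codon base:
# GAA -> TAA is E/* (nonsense), ATT -> TTT is I/F (missense)
_CODON_TEMPLATE = {"stop_gained": "GAA", "missense": "ATT"}


def build_gene_model(G: GenotypeMatrix, cfg: SimConfig):
    """Toy gene model putting each coding causal variant inside a CDS.

    Each stop_gained/missense causal variant gets its own single-exon
    plus-strand transcript with a 300-bp CDS; the causal site lands on the
    first base of a codon whose reference content makes the planted minor
    allele produce the configured consequence.  The reference slice carries
    every simulated variant's reference allele, so annotation is
    consistent across the whole CDS.
    """
    from .annotate import GeneModel, Transcript

    rng = np.random.default_rng((cfg.seed + 2) << 8)
    bases = np.array(list("ACGT"))
    transcripts = []
    slices: dict[str, tuple[int, int]] = {}
    coding = [c for c in cfg.causal_spec if c.consequence_tag in _CODON_TEMPLATE]
    for c in coding:
        cds_start = c.pos - 99
        cds_end = cds_start + 299
        transcripts.append(Transcript(
            id=f"tx_{c.chrom}_{c.pos}", gene=f"gene_{c.chrom}_{c.pos}",
            chrom=c.chrom, strand="+",
            exons=[(cds_start, cds_end)], cds=[(cds_start, cds_end)]))
        lo, hi = slices.get(c.chrom, (cds_start, cds_end))
        slices[c.chrom] = (min(lo, cds_start), max(hi, cds_end))
    sequences = {}
    for chrom, (lo, hi) in slices.items():
        seq = rng.choice(bases, size=hi - lo + 1)
        for v in G.variants:
            if v.chrom == chrom and lo <= v.pos <= hi:
                seq[v.pos - lo] = v.ref_allele
        for c in coding:
            if c.chrom != chrom:
                continue
            codon = _CODON_TEMPLATE[c.consequence_tag]
            for k, b in enumerate(codon):
                seq[c.pos - lo + k] = b
        sequences[chrom] = (lo - 1, "".join(seq))
    model = GeneModel(transcripts, sequences)
    model.validate()
    return model
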