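"""Simulation studies that re-run the analysis designs end to end.

Each function builds a synthetic cohort under the study conditions (a
height-like trait, mean 167.6, SD 3.6, h2 0.528, a major QTL on the
ECA3-like chromosome), runs the corresponding analysis through the public
API, and returns the recovered quantities.  They power both the
acceptance checks and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .core_io import ModelSpec, filter_variants
from .grm import RegionSpec, build_partitioned_grms, compute_grm
from .gwas import conditional_gwas, run_mlm_loco
from .simulate import (CausalVariant, RegionEffect, SimConfig, TraitSpec,
                       build_gene_model, simulate_dataset)
from .varcomp import fit_bivariate, fit_greml, predict_gebv

ECA3_WINDOW_CENTER = 107_400_000
ECA1_WINDOW_CENTER = 55_200_000
ECA3_FRACTION = 0.171      # share of phenotypic variance in the 6-Mb window
ECA1_FRACTION = 0.087      # share in the 2-Mb window
CAUSAL_POS = 107_558_421
CAUSAL_BETA = 2.68         # trait units per minor allele
CAUSAL_MAF = 0.45


def _height_design(pheno):
    y = pheno.df["height"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y),
                         pheno.df["age_days"].to_numpy(dtype=float)])
    return y, X


def heritability_recovery(seeds, n=2000, snps_per_chrom=1700) -> list[float]:
    """Single-GRM GREML h2 estimates for a purely polygenic trait
    simulated at true h2 = 0.528."""
    out = []
    for seed in seeds:
        cfg = SimConfig(
            n_individuals=n,
            chromosomes=[(c, snps_per_chrom, 120_000_000)
                         for c in ("1", "2", "3")],
            causal_spec=[], seed=int(seed))
        G, pheno, _ = simulate_dataset(cfg)
        Gf = filter_variants(G, min_maf=0.01)
        y, X = _height_design(pheno)
        out.append(fit_greml(y, X, [compute_grm(Gf)]).h2)
    return out


def qtl_partition(seeds, n=2000) -> tuple[list[float], list[float]]:
    """Window-fraction recovery for the two planted QTL regions.

    Plants a 6-Mb window on chromosome 3 contributing 17.1% of phenotypic
    variance and a 2-Mb window on chromosome 1 contributing 8.7%, then
    fits GREML with five GRMs: each window, each rest-of-chromosome with
    its exclusion buffer (14 Mb / 4 Mb), and the remaining chromosome.
    Returns the two lists of estimated window fractions.
    """
    f3, f1 = [], []
    for seed in seeds:
        cfg = SimConfig(
            n_individuals=n, causal_spec=[],
            region_spec=[
                RegionEffect("3", ECA3_WINDOW_CENTER, ECA3_FRACTION,
                             window_halfwidth_bp=3_000_000,
                             exclusion_halfwidth_bp=7_000_000),
                RegionEffect("1", ECA1_WINDOW_CENTER, ECA1_FRACTION,
                             window_halfwidth_bp=1_000_000,
                             exclusion_halfwidth_bp=2_000_000,
                             n_window_variants=60),
            ],
            seed=int(seed))
        G, pheno, _ = simulate_dataset(cfg)
        Gf = filter_variants(G, min_maf=0.01)
        y, X = _height_design(pheno)
        regions = [
            RegionSpec.around("eca3", "3", ECA3_WINDOW_CENTER,
                              3_000_000, 7_000_000),
            RegionSpec.around("eca1", "1", ECA1_WINDOW_CENTER,
                              1_000_000, 2_000_000)]
        grms = build_partitioned_grms(Gf, regions, scheme="qtl_plus_rest")
        rest_idx = [j for j, v in enumerate(Gf.variants) if v.chrom == "2"]
        grms.append(compute_grm(Gf, rest_idx, label="chr2"))
        fit = fit_greml(y, X, grms)
        fr = dict(zip(fit.component_labels, fit.fractions))
        f3.append(float(fr["eca3_window"]))
        f1.append(float(fr["eca1_window"]))
    return f3, f1


def _planted_qtl_config(seed, n=2000, pleiotropic_second_trait=False,
                        variance_fraction=None):
    causal = CausalVariant(
        chrom="3", pos=CAUSAL_POS, target_maf=CAUSAL_MAF,
        beta=None if variance_fraction else CAUSAL_BETA,
        variance_fraction=variance_fraction,
        consequence_tag="stop_gained",
        pleiotropy={"height": 1.0, "frame_latent": 1.0}
        if pleiotropic_second_trait else {})
    traits = [TraitSpec("height")]
    if pleiotropic_second_trait:
        traits.append(TraitSpec("frame_latent"))
    return SimConfig(n_individuals=n, causal_spec=[causal], traits=traits,
                     seed=int(seed))


def effect_size_recovery(seeds, n=2000) -> list[float]:
    """MLM-LOCO GWAS effect estimates at the planted causal SNP."""
    out = []
    for seed in seeds:
        cfg = _planted_qtl_config(seed, n)
        G, pheno, truth = simulate_dataset(cfg)
        Gf = filter_variants(G, min_maf=0.01)
        spec = ModelSpec("height", covariates=["age_days"])
        loco = build_partitioned_grms(Gf, scheme="loco")
        res = run_mlm_loco(Gf, pheno, spec, loco, chromosomes=["3"])
        vid = truth.causal_ids[0]
        out.append(float(res.table.set_index("id").loc[vid, "beta"]))
    return out


def local_genetic_correlation(seeds, n=2000) -> list[float]:
    """QTL-window r_G for two traits sharing the planted causal variant
    with fully concordant effects and independent polygenic backgrounds."""
    out = []
    for seed in seeds:
        cfg = _planted_qtl_config(seed, n, pleiotropic_second_trait=True,
                                  variance_fraction=ECA3_FRACTION)
        G, pheno, _ = simulate_dataset(cfg)
        Gf = filter_variants(G, min_maf=0.01)
        y1, X = _height_design(pheno)
        y2 = pheno.df["frame_latent"].to_numpy(dtype=float)
        chrom = np.array([v.chrom for v in Gf.variants])
        pos = np.array([v.pos for v in Gf.variants])
        in_win = (chrom == "3") & (np.abs(pos - CAUSAL_POS) <= 3_000_000)
        in_excl = (chrom == "3") & (np.abs(pos - CAUSAL_POS) <= 7_000_000)
        K_win = compute_grm(Gf, np.nonzero(in_win)[0], label="qtl_window")
        K_rest = compute_grm(Gf, np.nonzero(~in_excl)[0], label="rest")
        biv = fit_bivariate(y1, y2, X, [K_win, K_rest])
        out.append(float(biv.rg[0]))
    return out


def null_scan_inflation(seed, n=2000, snps_per_chrom=1700) -> float:
    """Genomic inflation factor of a LOCO scan on a trait with no genetic
    component at all (pure calibration check)."""
    cfg = SimConfig(
        n_individuals=n,
        chromosomes=[(c, snps_per_chrom, 120_000_000)
                     for c in ("1", "2", "3")],
        causal_spec=[], traits=[TraitSpec("height", h2=0.0)],
        seed=int(seed))
    G, pheno, _ = simulate_dataset(cfg)
    Gf = filter_variants(G, min_maf=0.01)
    spec = ModelSpec("height", covariates=["age_days"])
    loco = build_partitioned_grms(Gf, scheme="loco")
    return run_mlm_loco(Gf, pheno, spec, loco).lambda_gc


def conditional_scan_removes_peak(seed, n=2000) -> bool:
    """True when conditioning on the top associated SNP leaves no
    genome-wide significant variant on the QTL chromosome."""
    cfg = _planted_qtl_config(seed, n)
    G, pheno, _ = simulate_dataset(cfg)
    Gf = filter_variants(G, min_maf=0.01)
    spec = ModelSpec("height", covariates=["age_days"])
    loco = build_partitioned_grms(Gf, scheme="loco")
    res = run_mlm_loco(Gf, pheno, spec, loco)
    top = str(res.top_snp()["id"])
    cond = conditional_gwas(Gf, pheno, spec, loco, condition=f"snp:{top}",
                            chromosomes=["3"])
    return bool((cond.table["p"] > res.threshold).all())


def candidate_recovery(seeds, n=2000, k=10) -> list[bool]:
    """Whether the planted nonsense variant survives the full fine-mapping
    chain (GWAS -> BLUP -> ROH -> annotation -> LD x IBD intersection)."""
    from .annotate import annotate_variants
    from .finemap import combine_candidates, ibd_candidate_set, ld_candidate_set

    hits = []
    for seed in seeds:
        cfg = _planted_qtl_config(seed, n)
        G, pheno, truth = simulate_dataset(cfg)
        Gf = filter_variants(G, min_maf=0.01)
        spec = ModelSpec("height", covariates=["age_days"])
        loco = build_partitioned_grms(Gf, scheme="loco")
        res = run_mlm_loco(Gf, pheno, spec, loco)
        top = str(res.top_snp()["id"])
        model = build_gene_model(G, cfg)
        sig = set(res.significant["id"])
        ann = annotate_variants([v for v in G.variants if v.id in sig],
                                model)
        ld_set = ld_candidate_set(Gf, res, [top], 0.8, annotations=ann)
        idx3 = [j for j, v in enumerate(Gf.variants) if v.chrom == "3"]
        restidx = [j for j, v in enumerate(Gf.variants) if v.chrom != "3"]
        grms = [compute_grm(Gf, idx3, label="chr3"),
                compute_grm(Gf, restidx, label="rest")]
        y, X, ids, _ = spec.build_design(pheno, Gf)
        fit = fit_greml(y, X, grms, sample_ids=ids)
        blup = predict_gebv(fit, y, X, grms)
        ibd = ibd_candidate_set(blup, "chr3", k, G, res, ann)
        report = combine_candidates(ld_set, ibd.variant_ids, res, Gf, ann,
                                    [top])
        hits.append(truth.causal_ids[0] in report.candidate_ids)
    return hits
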