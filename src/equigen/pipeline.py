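"""Configuration-driven orchestration of the whole analysis.

Stages communicate only through files in the output directory, so any
stage can be re-run from its predecessors' outputs:

    simulate -> grm -> greml -> gwas -> cond_gwas -> rg -> blup -> roh
             -> annotate -> finemap

Every run writes the resolved configuration and a structured log line per
stage (inputs, parameter values, variant counts in/out).  Identical
(config, seed) pairs reproduce byte-identical numeric tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import simulate as sim
from .annotate import GeneModel, annotate_variants, write_consequences_tsv
from .core_io import (GenotypeMatrix, ModelSpec, PhenotypeTable,
                      filter_variants, read_genotypes, write_genotypes)
from .finemap import (combine_candidates, ibd_candidate_set, ld_candidate_set)
from .grm import (GrmMatrix, RegionSpec, build_partitioned_grms, compute_grm,
                  read_grm_gcta, write_grm_gcta)
from .gwas import (GwasResult, conditional_gwas, manhattan_plot, qq_plot,
                   run_mlm_loco, summarize_regions)
from .roh import RohParams
from .varcomp import (fit_greml, fit_null_fixed_only, lrt_genetic_variance,
                      predict_gebv)

import pandas as pd


@dataclass
class TraitModel:
    name: str
    covariates: list[str] = field(default_factory=list)
    factors: list[str] = field(default_factory=list)

    def model_spec(self, grm_names=("genomic",)) -> ModelSpec:
        return ModelSpec(self.name, list(self.covariates), list(self.factors),
                         list(grm_names))


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None          # SimConfig overrides
    inputs: dict | None = None            # paths: genotypes/phenotypes/...
    traits: list[TraitModel] = field(default_factory=lambda: [
        TraitModel("height", covariates=["age_days"])])
    min_maf: float = 0.01
    alpha: float = 0.05
    r2_threshold: float = 0.8
    updown_distance_bp: int = 100_000
    k_extremes: int = 10
    merge_gap_bp: int = 1_000_000
    min_region_snps: int = 5
    qtl_window_halfwidth_bp: int = 3_000_000
    qtl_exclusion_halfwidth_bp: int = 7_000_000
    roh: RohParams = field(default_factory=RohParams)
    roh_buffer_bp: int = 100_000

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("give exactly one of 'simulate' / 'inputs'")

    @property
    def primary(self) -> TraitModel:
        return self.traits[0]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        traits = [TraitModel(**t) for t in raw.pop("traits", [])] or None
        roh = RohParams(**raw.pop("roh", {}))
        kwargs = {k: v for k, v in raw.items()}
        cfg = cls(**kwargs, roh=roh)
        if traits:
            cfg.traits = traits
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def sim_config(self) -> sim.SimConfig:
        block = dict(self.simulate or {})
        block.setdefault("seed", self.seed)
        if "causal_spec" in block:
            block["causal_spec"] = [sim.CausalVariant(**c)
                                    for c in block["causal_spec"]]
        if "region_spec" in block:
            block["region_spec"] = [sim.RegionEffect(**r)
                                    for r in block["region_spec"]]
        if "traits" in block:
            block["traits"] = [sim.TraitSpec(**t) for t in block["traits"]]
        if "chromosomes" in block:
            block["chromosomes"] = [tuple(c) for c in block["chromosomes"]]
        return sim.SimConfig(**block)


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._log_path = self.out / "pipeline.log"
        with open(self.out / "config.resolved.json", "w") as fh:
            json.dump(self.cfg.to_dict(), fh, indent=1, default=str)

    # -- plumbing --------------------------------------------------------
    def _log(self, stage: str, **info) -> None:
        rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
               **info}
        with open(self._log_path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")

    def _genotypes(self) -> GenotypeMatrix:
        if (self.out / "genotypes.vcf").exists():
            return read_genotypes(self.out / "genotypes.vcf", "vcf")
        if self.cfg.inputs:
            path = self.cfg.inputs["genotypes"]
            fmt = self.cfg.inputs.get("genotype_format", "vcf")
            return read_genotypes(path, fmt)
        raise FileNotFoundError("no genotypes; run the simulate stage first")

    def _phenotypes(self) -> PhenotypeTable:
        if (self.out / "phenotypes.tsv").exists():
            return PhenotypeTable.from_tsv(self.out / "phenotypes.tsv")
        if self.cfg.inputs:
            return PhenotypeTable.from_tsv(self.cfg.inputs["phenotypes"])
        raise FileNotFoundError("no phenotypes; run the simulate stage first")

    def _gene_model(self) -> GeneModel:
        if (self.out / "genes.gff3").exists():
            return GeneModel.from_gff3(self.out / "genes.gff3",
                                       self.out / "reference.fa")
        if self.cfg.inputs and "gene_model" in self.cfg.inputs:
            return GeneModel.from_gff3(self.cfg.inputs["gene_model"],
                                       self.cfg.inputs.get("reference"))
        raise FileNotFoundError("no gene model available")

    def _validate_traits(self, pheno: PhenotypeTable) -> None:
        for t in self.cfg.traits:
            if t.name not in pheno.df.columns:
                raise ValueError(
                    f"configured trait {t.name!r} absent from phenotype table")

    def _gwas_result(self, trait: str) -> GwasResult:
        path = self.out / f"gwas_{trait}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"run the gwas stage first ({path})")
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
        meta = json.loads((self.out / f"gwas_{trait}.meta.json").read_text())
        return GwasResult(table, meta["lambda_gc"], meta["threshold"],
                          meta["n_tests"], meta.get("condition"))

    def _store_gwas(self, res: GwasResult, name: str) -> None:
        res.to_tsv(self.out / f"{name}.tsv")
        with open(self.out / f"{name}.meta.json", "w") as fh:
            json.dump({"lambda_gc": res.lambda_gc, "threshold": res.threshold,
                       "n_tests": res.n_tests, "condition": res.condition},
                      fh)

    # -- stages ----------------------------------------------------------
    def stage_simulate(self) -> None:
        if self.cfg.simulate is None:
            raise ValueError("pipeline configured with external inputs; "
                             "there is nothing to simulate")
        scfg = self.cfg.sim_config()
        G, pheno, truth = sim.simulate_dataset(scfg)
        self._validate_traits(pheno)
        write_genotypes(G, self.out / "genotypes.vcf", "vcf")
        pheno.to_tsv(self.out / "phenotypes.tsv")
        truth.to_json(self.out / "truth.json")
        model = sim.build_gene_model(G, scfg)
        if model.transcripts:
            model.to_gff3(self.out / "genes.gff3", self.out / "reference.fa")
        self._log("simulate", n_samples=G.n_samples, n_variants=G.n_variants,
                  seed=scfg.seed)

    def stage_grm(self) -> None:
        G = self._genotypes()
        n_before = G.n_variants
        G = filter_variants(G, min_maf=self.cfg.min_maf)
        self._log("grm", variants_in=n_before, variants_after_maf=G.n_variants,
                  min_maf=self.cfg.min_maf)
        write_grm_gcta(compute_grm(G, label="genomic"), self.out / "genomic")
        for g in build_partitioned_grms(G, scheme="loco"):
            write_grm_gcta(g, self.out / g.label)
        for g in build_partitioned_grms(G, scheme="per_chromosome"):
            write_grm_gcta(g, self.out / g.label)

    def _load_grm(self, label: str) -> GrmMatrix:
        return read_grm_gcta(self.out / label, label=label)

    def stage_greml(self) -> None:
        G = self._genotypes()
        pheno = self._phenotypes()
        self._validate_traits(pheno)
        K = self._load_grm("genomic")
        rows = []
        for t in self.cfg.traits:
            spec = t.model_spec()
            y, X, ids, _ = spec.build_design(pheno, G)
            fit = fit_greml(y, X, [K.subset(ids)], sample_ids=ids)
            null = fit_null_fixed_only(y, X)
            lrt = lrt_genetic_variance(fit, null, self.cfg.alpha)
            (self.out / f"greml_{t.name}.hsq").write_text(
                fit.to_hsq_text()
                + f"LRT\t{lrt.lrt:.4f}\t\nPval\t{lrt.p_value:.4g}\t\n")
            rows.append({"trait": t.name, "h2": fit.h2,
                         "se": fit.fraction_se[0], "logL": fit.logL,
                         "p_lrt": lrt.p_value, "excluded": lrt.excluded,
                         "n": fit.n_used})
            self._log("greml", trait=t.name, h2=fit.h2, p_lrt=lrt.p_value)
        pd.DataFrame(rows).to_csv(self.out / "greml_summary.tsv", sep="\t",
                                  index=False, float_format="%.6g")

    def stage_gwas(self) -> None:
        G = self._genotypes()
        G = filter_variants(G, min_maf=self.cfg.min_maf)
        pheno = self._phenotypes()
        self._validate_traits(pheno)
        loco = [self._load_grm(f"loco{c}") for c in G.chroms]
        for t in self.cfg.traits:
            res = run_mlm_loco(G, pheno, t.model_spec(), loco, self.cfg.alpha)
            self._store_gwas(res, f"gwas_{t.name}")
            regions = summarize_regions(res, merge_gap_bp=self.cfg.merge_gap_bp,
                                        min_snps=self.cfg.min_region_snps)
            pd.DataFrame([dataclasses.asdict(r) for r in regions]).to_csv(
                self.out / f"regions_{t.name}.tsv", sep="\t", index=False)
            manhattan_plot(res, self.out / f"manhattan_{t.name}.png")
            qq_plot(res, self.out / f"qq_{t.name}.png")
            self._log("gwas", trait=t.name, n_tests=res.n_tests,
                      lambda_gc=res.lambda_gc,
                      n_significant=len(res.significant))

    def stage_cond_gwas(self) -> None:
        G = self._genotypes()
        G = filter_variants(G, min_maf=self.cfg.min_maf)
        pheno = self._phenotypes()
        loco = [self._load_grm(f"loco{c}") for c in G.chroms]
        primary = self.cfg.primary
        top_primary = str(self._gwas_result(primary.name).top_snp()["id"])
        for t in self.cfg.traits:
            own_top = str(self._gwas_result(t.name).top_snp()["id"])
            conditions = [f"snp:{own_top}"]
            if t.name != primary.name:
                conditions += [f"snp:{top_primary}", primary.name]
            for cond in conditions:
                res = conditional_gwas(G, pheno, t.model_spec(), loco, cond,
                                       self.cfg.alpha)
                tag = cond.replace("snp:", "snp_").replace(":", "_")
                self._store_gwas(res, f"cond_gwas_{t.name}__{tag}")
                self._log("cond_gwas", trait=t.name, condition=cond,
                          n_significant=len(res.significant))

    def _qtl_region(self) -> RegionSpec:
        top = self._gwas_result(self.cfg.primary.name).top_snp()
        return RegionSpec.around(
            "qtl", str(top["chrom"]), int(top["pos"]),
            self.cfg.qtl_window_halfwidth_bp,
            self.cfg.qtl_exclusion_halfwidth_bp)

    def stage_rg(self) -> None:
        from .varcomp import fit_bivariate

        if len(self.cfg.traits) < 2:
            self._log("rg", skipped="fewer than two traits")
            return
        G = self._genotypes()
        G = filter_variants(G, min_maf=self.cfg.min_maf)
        pheno = self._phenotypes()
        reg = self._qtl_region()
        chrom_of = np.array([v.chrom for v in G.variants])
        pos = np.array([v.pos for v in G.variants])
        in_win = ((chrom_of == reg.chrom) & (pos >= reg.window[0])
                  & (pos <= reg.window[1]))
        in_excl = ((chrom_of == reg.chrom) & (pos >= reg.exclusion[0])
                   & (pos <= reg.exclusion[1]))
        K_win = compute_grm(G, np.nonzero(in_win)[0], label="qtl_window")
        K_rest = compute_grm(G, np.nonzero(~in_excl)[0], label="rest_genome")
        K_all = self._load_grm("genomic")
        primary = self.cfg.primary
        rows = []
        for t in self.cfg.traits[1:]:
            spec = primary.model_spec()
            y1, X, ids, _ = spec.build_design(pheno, G)
            df = pheno.df.set_index("sample").loc[ids]
            y2 = df[t.name].to_numpy(dtype=float)
            ok = ~np.isnan(y2)
            ids_ok = [s for s, o in zip(ids, ok) if o]
            glob = fit_bivariate(y1[ok], y2[ok], X[ok],
                                 [K_all.subset(ids_ok)])
            local = fit_bivariate(y1[ok], y2[ok], X[ok],
                                  [K_win.subset(ids_ok),
                                   K_rest.subset(ids_ok)])
            rows.append({
                "trait_1": primary.name, "trait_2": t.name,
                "rg_global": glob.rg[0], "rg_global_se": glob.rg_se[0],
                "rg_qtl": local.rg[0], "rg_qtl_se": local.rg_se[0],
                "rg_rest": local.rg[1], "rg_rest_se": local.rg_se[1],
                "n": glob.n_used})
            self._log("rg", trait_pair=f"{primary.name}/{t.name}",
                      rg_qtl=rows[-1]["rg_qtl"])
        pd.DataFrame(rows).to_csv(self.out / "rg.tsv", sep="\t", index=False,
                                  float_format="%.6g")

    def stage_blup(self) -> None:
        G = self._genotypes()
        G = filter_variants(G, min_maf=self.cfg.min_maf)
        pheno = self._phenotypes()
        reg = self._qtl_region()
        qtl_chrom = reg.chrom
        spec = self.cfg.primary.model_spec()
        y, X, ids, _ = spec.build_design(pheno, G)
        K_chrom = self._load_grm(f"chr{qtl_chrom}").subset(ids)
        K_chrom.label = f"chr{qtl_chrom}"
        K_rest = self._load_grm(f"loco{qtl_chrom}").subset(ids)
        K_rest.label = f"loco{qtl_chrom}"
        fit = fit_greml(y, X, [K_chrom, K_rest], sample_ids=ids)
        blup = predict_gebv(fit, y, X, [K_chrom, K_rest])
        out = pd.DataFrame({"sample": ids,
                            f"gebv_chr{qtl_chrom}": blup.gebv[K_chrom.label],
                            "gebv_rest": blup.gebv[K_rest.label],
                            "gebv_total": blup.total})
        out.to_csv(self.out / "gebv.tsv", sep="\t", index=False,
                   float_format="%.6g")
        self._log("blup", qtl_chrom=qtl_chrom,
                  fractions=list(map(float, fit.fractions)))

    def stage_roh(self) -> None:
        from .roh import detect_roh, roh_scan_window, shared_roh

        G = self._genotypes()
        gebv = pd.read_csv(self.out / "gebv.tsv", sep="\t",
                           dtype={"sample": str})
        res = self._gwas_result(self.cfg.primary.name)
        region = roh_scan_window(res, self.cfg.roh_buffer_bp)
        col = f"gebv_chr{region[0]}"
        k = self.cfg.k_extremes
        ranked = gebv.sort_values(col)
        bottom = list(ranked["sample"].head(k))
        top = list(ranked["sample"].tail(k))
        segments = detect_roh(G, top + bottom, region, self.cfg.roh)
        groups = {s: "top" for s in top} | {s: "bottom" for s in bottom}
        shared = shared_roh(segments, groups, G)
        pd.DataFrame([dataclasses.asdict(s) for s in segments]).to_csv(
            self.out / "roh.tsv", sep="\t", index=False)
        rows = [{"chrom": r.chrom, "start": r.start, "end": r.end,
                 "n_carriers": r.n_carriers,
                 "top_carriers": r.carriers_per_group.get("top", 0),
                 "bottom_carriers": r.carriers_per_group.get("bottom", 0),
                 "classes_differ": r.groups_differ("top", "bottom")}
                for r in shared]
        pd.DataFrame(rows).to_csv(self.out / "shared_roh.tsv", sep="\t",
                                  index=False)
        self._log("roh", region=region, n_segments=len(segments),
                  n_shared=len(shared))

    def stage_annotate(self) -> None:
        G = self._genotypes()
        model = self._gene_model()
        res = self._gwas_result(self.cfg.primary.name)
        sig_ids = set(res.significant["id"])
        variants = [v for v in G.variants if v.id in sig_ids]
        records = annotate_variants(variants, model,
                                    self.cfg.updown_distance_bp)
        write_consequences_tsv(records, self.out / "consequences.tsv")
        self._log("annotate", n_variants=len(variants),
                  n_records=len(records))

    def stage_finemap(self) -> None:
        G = self._genotypes()
        Gf = filter_variants(G, min_maf=self.cfg.min_maf)
        pheno = self._phenotypes()
        res = self._gwas_result(self.cfg.primary.name)
        model = self._gene_model()
        sig_ids = set(res.significant["id"])
        ann = annotate_variants([v for v in G.variants if v.id in sig_ids],
                                model, self.cfg.updown_distance_bp)
        top = str(res.top_snp()["id"])
        ld_set = ld_candidate_set(Gf, res, [top], self.cfg.r2_threshold, ann)
        reg = self._qtl_region()
        spec = self.cfg.primary.model_spec()
        y, X, ids, _ = spec.build_design(pheno, Gf)
        K_chrom = self._load_grm(f"chr{reg.chrom}").subset(ids)
        K_rest = self._load_grm(f"loco{reg.chrom}").subset(ids)
        fit = fit_greml(y, X, [K_chrom, K_rest], sample_ids=ids)
        blup = predict_gebv(fit, y, X, [K_chrom, K_rest])
        ibd = ibd_candidate_set(blup, K_chrom.label, self.cfg.k_extremes, G,
                                res, ann, self.cfg.roh, self.cfg.roh_buffer_bp)
        report = combine_candidates(ld_set, ibd.variant_ids, res, Gf, ann,
                                    [top])
        report.to_tsv(self.out / "candidates.tsv")
        with open(self.out / "candidates.provenance.json", "w") as fh:
            json.dump({**report.provenance,
                       "ld_set": sorted(report.ld_set),
                       "ibd_set": sorted(report.ibd_set),
                       "top_snp": top,
                       "scan_region": list(ibd.scan_region)}, fh, indent=1)
        self._log("finemap", n_ld=len(ld_set), n_ibd=len(ibd.variant_ids),
                  n_final=len(report.table))

    STAGES = ["simulate", "grm", "greml", "gwas", "cond_gwas", "rg", "blup",
              "roh", "annotate", "finemap"]

    def run(self, stages: list[str] | None = None) -> Path:
        todo = stages if stages is not None else list(self.STAGES)
        if self.cfg.inputs is not None and "simulate" in todo:
            todo = [s for s in todo if s != "simulate"]
        for name in todo:
            if name not in self.STAGES:
                raise ValueError(f"unknown stage {name!r}")
            try:
                getattr(self, f"stage_{name}")()
            except Exception as e:
                self._log(name, failed=True, error=str(e))
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return self.out


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None) -> Path:
    return Pipeline(config).run(stages)
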