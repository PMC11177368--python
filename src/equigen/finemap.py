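"""Two-pronged candidate-causal-variant search.

The LD prong keeps genome-wide significant variants in high LD
(r2 > 0.8 by default) with the top associated SNP(s) and restricts them to
HIGH/MODERATE predicted impact.  The IBD prong ranks individuals by a
chromosomal gEBV component, detects ROH in the significant region for the
top-k and bottom-k individuals, intersects the top-k segments, and keeps
significant HIGH/MODERATE variants inside intervals shared by every top-k
individual.  The final report is the intersection of the two shortlists
with pairwise LD among finalists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix
from .gwas import GwasResult
from .roh import RohParams, SharedRohRegion, detect_roh, roh_scan_window, shared_roh
from .varcomp import BlupResult


def ld_r2(G: GenotypeMatrix, variant_a: str,
          variant_b_set: list[str]) -> dict[str, float]:
    """Squared Pearson correlation of minor-allele counts.

    Computed over mutually non-missing individuals per pair; monomorphic
    pairs yield NaN (flagged undefined).
    """
    a = G.dosage(variant_a)
    out = {}
    for vb in variant_b_set:
        b = G.dosage(vb)
        ok = ~(np.isnan(a) | np.isnan(b))
        x, y = a[ok], b[ok]
        if x.std() == 0 or y.std() == 0:
            out[vb] = float("nan")
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[vb] = float(r * r)
    return out


def ld_matrix(G: GenotypeMatrix, variant_ids: list[str]) -> pd.DataFrame:
    """Pairwise r2 among the given variants."""
    vals = {v: ld_r2(G, v, variant_ids) for v in variant_ids}
    return pd.DataFrame(vals).loc[variant_ids, variant_ids].T


def ld_candidate_set(G: GenotypeMatrix, gwas: GwasResult,
                     top_snps: list[str], r2_threshold: float = 0.8,
                     annotations=None) -> set[str]:
    """Significant variants with r2 above threshold to any top SNP.

    With ``annotations`` (ConsequenceRecord list) the set is additionally
    restricted to HIGH/MODERATE-impact variants — the LD shortlist.
    """
    sig_ids = list(gwas.significant["id"])
    if not sig_ids:
        return set()
    selected: set[str] = set()
    for top in top_snps:
        r2 = ld_r2(G, top, sig_ids)
        selected |= {v for v, val in r2.items()
                     if np.isfinite(val) and val > r2_threshold}
        if top in sig_ids:
            selected.add(top)
    if annotations is not None:
        from .annotate import impact_filter
        selected &= impact_filter(annotations, "MODERATE")
    return selected


@dataclass
class IbdCandidateResult:
    variant_ids: set[str]
    top_samples: list[str]
    bottom_samples: list[str]
    shared_top: list[SharedRohRegion]        # intervals shared by ALL top-k
    discriminating: list[SharedRohRegion]    # bottom carriers differ in class
    scan_region: tuple[str, int, int]


def ibd_candidate_set(blup: BlupResult, component: str, k: int,
                      G: GenotypeMatrix, gwas: GwasResult,
                      annotations, roh_params: RohParams | None = None,
                      buffer_bp: int = 100_000,
                      share_fraction: float = 1.0) -> IbdCandidateResult:
    """Candidate variants from ROH shared by the extreme-gEBV group.

    The procedure assumes (a) shared ROH reflect identity by descent,
    (b) a single founder mutation underlies the QTL, (c) the founder
    haplotype is enriched to homozygosity in one extreme-gEBV group, and
    (d) chromosomal gEBVs rank QTL genotypes better than raw phenotypes.
    """
    if component not in blup.gebv:
        raise ValueError(f"unknown gEBV component {component!r}")
    g = blup.gebv[component]
    if blup.sample_ids is None:
        raise ValueError("BLUP result carries no sample ids")
    if k > len(g) // 2:
        raise ValueError(f"k = {k} exceeds half the cohort")
    if float(np.std(g)) < 1e-9:
        raise ValueError(
            f"component {component!r} has (near-)zero variance; extreme-gEBV "
            "selection is degenerate")
    order = np.argsort(g)
    ids = np.asarray(blup.sample_ids)
    bottom = list(ids[order[:k]])
    top = list(ids[order[-k:]])

    region = roh_scan_window(gwas, buffer_bp)
    segments = detect_roh(G, top + bottom, region, roh_params)
    groups = {s: "top" for s in top}
    groups.update({s: "bottom" for s in bottom})
    shared = shared_roh(segments, groups, G)
    need = int(np.ceil(share_fraction * k))
    shared_top = [r for r in shared
                  if r.carriers_per_group.get("top", 0) >= need]
    discriminating = [r for r in shared_top
                      if r.carriers_per_group.get("bottom", 0) > 0
                      and r.groups_differ("top", "bottom")]

    from .annotate import impact_filter
    impactful = impact_filter(annotations, "MODERATE")
    sig = gwas.significant
    keep: set[str] = set()
    for _, row in sig.iterrows():
        if row["id"] not in impactful:
            continue
        for r in shared_top:
            if r.chrom == row["chrom"] and r.start <= row["pos"] <= r.end:
                keep.add(row["id"])
                break
    return IbdCandidateResult(keep, top, bottom, shared_top, discriminating,
                              region)


@dataclass
class CandidateReport:
    """Final fine-mapping output: candidates found by both prongs."""

    table: pd.DataFrame              # per candidate: position, stats, source
    pairwise_r2: pd.DataFrame
    ld_set: set[str]
    ibd_set: set[str]
    provenance: dict = field(default_factory=dict)

    @property
    def candidate_ids(self) -> list[str]:
        return list(self.table["id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def combine_candidates(ld_set: set[str], ibd_set: set[str],
                       gwas: GwasResult, G: GenotypeMatrix,
                       annotations=None,
                       top_snps: list[str] | None = None) -> CandidateReport:
    """Intersect the two candidate sets and rank by p then position."""
    final = sorted(ld_set & ibd_set)
    tbl = gwas.table[gwas.table["id"].isin(final)].copy()
    tbl = tbl.sort_values(["p", "pos"], kind="mergesort").reset_index(drop=True)
    if annotations is not None:
        cons = {}
        for r in annotations:
            best = cons.get(r.variant_id)
            rank = {"MODIFIER": 0, "LOW": 1, "MODERATE": 2, "HIGH": 3}
            if best is None or rank[r.impact] > rank[best.impact]:
                cons[r.variant_id] = r
        tbl["consequence"] = [getattr(cons.get(v), "consequence", None)
                              for v in tbl["id"]]
        tbl["impact"] = [getattr(cons.get(v), "impact", None)
                         for v in tbl["id"]]
        tbl["gene"] = [getattr(cons.get(v), "gene", None) for v in tbl["id"]]
        tbl["amino_acids"] = [getattr(cons.get(v), "amino_acids", None)
                              for v in tbl["id"]]
    if top_snps:
        r2_top = {v: max(ld_r2(G, v, top_snps).values())
                  for v in tbl["id"]} if len(tbl) else {}
        tbl["r2_to_top"] = [r2_top[v] for v in tbl["id"]]
    tbl["source"] = "both"
    pairwise = (ld_matrix(G, list(tbl["id"])) if len(tbl)
                else pd.DataFrame())
    return CandidateReport(
        tbl, pairwise, set(ld_set), set(ibd_set),
        provenance={"n_ld": len(ld_set), "n_ibd": len(ibd_set),
                    "n_final": len(final)})
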