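"""Mixed-linear-model association with leave-one-chromosome-out control.

For each chromosome the null model y = Xb + g- + e is fitted once by REML,
where g- has covariance s2_g * K_loco built from all other chromosomes.
Every SNP on the chromosome is then tested by a generalised-least-squares
Wald test on data rotated into the eigenbasis of the LOCO covariance (the
two-stage approximation used by the standard MLMA-LOCO tools).  Effects are
reported per copy of the minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, ModelSpec, PhenotypeTable
from .grm import GrmMatrix
from .varcomp import _fit_greml_single

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))   # 0.4549...


@dataclass
class GwasResult:
    table: pd.DataFrame      # chrom, pos, id, alleles, maf, beta, se, p, n_used
    lambda_gc: float
    threshold: float
    n_tests: int
    condition: str | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] <= self.threshold]

    def top_snp(self) -> pd.Series:
        """Lowest p, ties broken by lowest position."""
        t = self.table.sort_values(["p", "pos"], kind="mergesort")
        return t.iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class QtlRegion:
    chrom: str
    start: int
    end: int
    top_id: str
    top_pos: int
    top_p: float
    n_significant: int


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def genomic_inflation(p_values: np.ndarray) -> float:
    """Median association chi-square over its null median."""
    chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), 1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


def _scan_chromosome(ys, Xs, Gs, theta, lam, maf, n_obs):
    """Wald scan in the rotated (eigen) basis; returns beta, se, p arrays."""
    w = theta[0] * lam + theta[1]
    w = np.maximum(w, 1e-12)
    sw = 1.0 / np.sqrt(w)
    yw = ys * sw
    Xw = Xs * sw[:, None]
    Gw = Gs * sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    y_res = yw - Q @ (Q.T @ yw)
    G_res = Gw - Q @ (Q.T @ Gw)
    tt = np.einsum("ij,ij->j", G_res, G_res)
    tt = np.maximum(tt, 1e-12)
    beta = (G_res.T @ y_res) / tt
    se = 1.0 / np.sqrt(tt)
    z = beta / se
    p = stats.chi2.sf(z ** 2, 1)
    return beta, se, np.maximum(p, 1e-320)


def run_mlm_loco(G: GenotypeMatrix, pheno: PhenotypeTable, spec: ModelSpec,
                 loco_grms: list[GrmMatrix], alpha: float = 0.05,
                 chromosomes: list[str] | None = None,
                 condition_label: str | None = None) -> GwasResult:
    """MLM-LOCO association scan.

    ``loco_grms`` must contain, for every scanned chromosome ``c``, a GRM
    labelled ``loco{c}`` built from all variants not on ``c``.  Individuals
    with a missing genotype at a variant are dropped for that variant
    (exact GLS on the observed subset).
    """
    chroms = chromosomes if chromosomes is not None else G.chroms
    grm_by_label = {g.label: g for g in loco_grms}
    y_all, X_all, ids, _ = spec.build_design(pheno, G)
    pos_in_G = {s: i for i, s in enumerate(G.samples)}
    missing_ids = [s for s in ids if s not in pos_in_G]
    if missing_ids:
        raise ValueError(f"sample {missing_ids[0]!r} has no genotypes")
    row = np.array([pos_in_G[s] for s in ids])
    n = len(ids)

    frames = []
    all_chi2 = []
    total_tests = 0
    for chrom in chroms:
        key = f"loco{chrom}"
        if key not in grm_by_label:
            raise ValueError(f"no LOCO GRM for chromosome {chrom} "
                             f"(expected label {key!r})")
        K = grm_by_label[key].subset(ids)
        fit, (U, lam) = _fit_greml_single(y_all, X_all, K, sample_ids=ids)
        theta = np.array([fit.sigma2_g[0], fit.sigma2_e])
        idx = [j for j, v in enumerate(G.variants) if v.chrom == chrom]
        variants = [G.variants[j] for j in idx]
        codes = G.codes[row][:, idx].astype(float)
        codes[codes == MISSING] = np.nan
        has_missing = np.isnan(codes).any(axis=0)
        codes_f = np.nan_to_num(codes, nan=0.0)
        ys = U.T @ y_all
        Xs = U.T @ X_all
        Gs = U.T @ codes_f
        maf = np.array([v.maf for v in variants])
        beta, se, p = _scan_chromosome(ys, Xs, Gs, theta, lam, maf, n)
        n_used = np.full(len(idx), n)
        # exact GLS on the observed subset for variants with missing calls
        V = theta[0] * K.values + theta[1] * np.eye(n)
        for jj in np.nonzero(has_missing)[0]:
            obs = ~np.isnan(codes[:, jj])
            b, s, pv = _gls_single(y_all[obs], X_all[obs],
                                   codes[obs, jj], V[np.ix_(obs, obs)])
            beta[jj], se[jj], p[jj] = b, s, pv
            n_used[jj] = int(obs.sum())
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": [v.pos for v in variants],
            "id": [v.id for v in variants],
            "alleles": [f"{v.major_allele}/{v.minor_allele}" for v in variants],
            "maf": maf, "beta": beta, "se": se, "p": p, "n_used": n_used}))
        all_chi2.append(stats.chi2.isf(p, 1))
        total_tests += len(idx)

    table = pd.concat(frames, ignore_index=True)
    lam_gc = float(np.median(np.concatenate(all_chi2)) / _CHI2_MEDIAN)
    thr = bonferroni_threshold(total_tests, alpha)
    return GwasResult(table, lam_gc, thr, total_tests, condition_label)


def _gls_single(y, X, g, V):
    from scipy.linalg import cho_factor, cho_solve
    cf = cho_factor(V, lower=True)
    D = np.column_stack([X, g])
    VinvD = cho_solve(cf, D)
    A = D.T @ VinvD
    b = VinvD.T @ y
    coef = np.linalg.solve(A, b)
    var = np.linalg.inv(A)[-1, -1]
    beta = coef[-1]
    se = np.sqrt(var)
    p = stats.chi2.sf((beta / se) ** 2, 1)
    return beta, se, max(p, 1e-320)


def conditional_gwas(G: GenotypeMatrix, pheno: PhenotypeTable, spec: ModelSpec,
                     loco_grms: list[GrmMatrix],
                     condition: str, alpha: float = 0.05,
                     chromosomes: list[str] | None = None) -> GwasResult:
    """Re-scan with a conditioning covariate as an extra fixed effect.

    ``condition`` is either ``"snp:<variant id>"`` (the dosage of that SNP
    is added to the model and the SNP itself is skipped) or the name of a
    covariate trait in the phenotype table (e.g. conditioning a
    conformation trait on measured withers height).
    """
    import dataclasses

    if condition.startswith("snp:"):
        vid = condition[4:]
        if vid not in set(G.variant_ids):
            raise ValueError(f"conditioning SNP {vid!r} not in genotypes")
    else:
        if condition not in pheno.df.columns:
            raise ValueError(f"conditioning trait {condition!r} not in "
                             "phenotype table")
    spec2 = dataclasses.replace(spec, covariates=spec.covariates + [condition])
    res = run_mlm_loco(G, pheno, spec2, loco_grms, alpha, chromosomes,
                       condition_label=condition)
    if condition.startswith("snp:"):
        res.table = res.table[res.table["id"] != condition[4:]].reset_index(
            drop=True)
    return res


def summarize_regions(result: GwasResult, threshold: float | None = None,
                      merge_gap_bp: int = 1_000_000,
                      min_snps: int = 1) -> list[QtlRegion]:
    """Cluster genome-wide significant variants into QTL regions.

    Significant variants on the same chromosome separated by at most
    ``merge_gap_bp`` join one region; regions with fewer than ``min_snps``
    significant variants are dropped.  The top SNP has the minimal p-value,
    ties broken by lowest position.
    """
    thr = threshold if threshold is not None else result.threshold
    sig = result.table[result.table["p"] <= thr]
    regions: list[QtlRegion] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        gaps = np.diff(sub["pos"].to_numpy())
        cluster_id = np.concatenate([[0], np.cumsum(gaps > merge_gap_bp)])
        for cid in np.unique(cluster_id):
            blk = sub[cluster_id == cid]
            if len(blk) < min_snps:
                continue
            top = blk.sort_values(["p", "pos"], kind="mergesort").iloc[0]
            regions.append(QtlRegion(
                chrom=str(chrom), start=int(blk["pos"].min()),
                end=int(blk["pos"].max()), top_id=str(top["id"]),
                top_pos=int(top["pos"]), top_p=float(top["p"]),
                n_significant=len(blk)))
    regions.sort(key=lambda r: r.top_p)
    return regions


# ---------------------------------------------------------------------------
# plots (plumbing)
# ---------------------------------------------------------------------------

def manhattan_plot(result: GwasResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for i, (chrom, sub) in enumerate(result.table.groupby("chrom", sort=False)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub["p"]), s=4,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append((offset + sub["pos"].max() / 2, str(chrom)))
        offset += sub["pos"].max()
    ax.axhline(-np.log10(result.threshold), color="red", ls="--", lw=1)
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([c for _, c in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(result: GwasResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(result.table["p"].to_numpy())
    exp = -np.log10((np.arange(len(p)) + 0.5) / len(p))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(exp, -np.log10(p), ".", ms=3)
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected " + r"$-\log_{10} p$")
    ax.set_ylabel("observed " + r"$-\log_{10} p$")
    ax.set_title(f"lambda = {result.lambda_gc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
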