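import numpy as np
import pytest

from equigen.grm import GrmMatrix, compute_grm
from equigen.simulate import TraitSpec
from equigen.varcomp import (fit_bivariate, fit_greml, fit_null_fixed_only,
                             lrt_genetic_variance, predict_gebv)
from conftest import make_matrix, small_cohort_config


def reml_loglik_direct(y, X, V):
    """Independent dense evaluation of the restricted log-likelihood."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XtViX)[1]
                   + float(y @ P @ y))


def toy_problem(seed=0, n=50, m=80, h2=0.5):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    G = make_matrix(codes)
    K = compute_grm(G)
    Z = (codes - codes.mean(0)) / codes.std(0)
    g = Z @ rng.normal(size=m)
    g *= np.sqrt(h2) / g.std()
    y = 10.0 + g + rng.normal(0, np.sqrt(1 - h2), n)
    X = np.column_stack([np.ones(n), rng.uniform(0, 1, n)])
    return y, X, K


class TestFitGreml:
    def test_grid_search_oracle(self):
        """The REML solution beats a brute-force grid over (h2, V_P)."""
        y, X, K = toy_problem(seed=1)
        fit = fit_greml(y, X, [K])
        best = -np.inf
        vy = np.var(y)
        for h2 in np.arange(0.0, 1.0, 0.01):
            for vp in vy * np.array([0.6, 0.8, 0.9, 1.0, 1.1, 1.2, 1.4]):
                V = h2 * vp * K.values + (1 - h2) * vp * np.eye(len(y))
                best = max(best, reml_loglik_direct(y, X, V))
        assert fit.logL >= best - 1e-3

    def test_null_simulation_recovers_zero(self):
        from equigen.simulate import simulate_dataset
        cfg = small_cohort_config(seed=2, n=500, causal_spec=[],
                                  traits=[TraitSpec("height", h2=0.0)])
        G, pheno, _ = simulate_dataset(cfg)
        y = pheno.df["height"].to_numpy()
        X = np.column_stack([np.ones_like(y), pheno.df["age_days"]])
        fit = fit_greml(y, X, [compute_grm(G)])
        assert fit.fractions[0] <= 0.05

    def test_location_invariance_and_scale_equivariance(self):
        y, X, K = toy_problem(seed=3)
        f0 = fit_greml(y, X, [K])
        f_shift = fit_greml(y + 100.0, X, [K])
        assert f_shift.h2 == pytest.approx(f0.h2, abs=1e-6)
        f_scale = fit_greml(3.0 * y, X, [K])
        assert f_scale.sigma2_g[0] == pytest.approx(9 * f0.sigma2_g[0],
                                                    rel=1e-4)
        assert f_scale.h2 == pytest.approx(f0.h2, abs=1e-6)

    def test_split_genome_fractions_sum_to_single_grm_h2(self):
        # per-chromosome fractions add up to (about) the single-GRM h2
        from equigen.core_io import filter_variants
        from equigen.grm import build_partitioned_grms
        from equigen.simulate import simulate_dataset
        cfg = small_cohort_config(seed=4, n=800, causal_spec=[])
        G, pheno, _ = simulate_dataset(cfg)
        Gf = filter_variants(G, min_maf=0.01)
        y = pheno.df["height"].to_numpy()
        X = np.column_stack([np.ones_like(y), pheno.df["age_days"]])
        h2_single = fit_greml(y, X, [compute_grm(Gf)]).h2
        fit_multi = fit_greml(
            y, X, build_partitioned_grms(Gf, scheme="per_chromosome"))
        assert fit_multi.h2 == pytest.approx(h2_single, abs=0.05)

    def test_rank_deficient_design_rejected(self):
        y, X, K = toy_problem(seed=5)
        X_bad = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            fit_greml(y, X_bad, [K])

    def test_hsq_text_summary(self):
        y, X, K = toy_problem(seed=6)
        txt = fit_greml(y, X, [K]).to_hsq_text()
        assert txt.startswith("Source\tVariance\tSE")
        assert "V(genomic)/Vp" in txt


class TestLrt:
    def test_boundary_mixture_at_zero(self):
        y, X, K = toy_problem(seed=7)
        fit = fit_greml(y, X, [K])
        null = fit_null_fixed_only(y, X)
        # construct the degenerate case artificially
        fit_same = fit_greml(y, X, [K])
        fit_same.logL = null.logL
        res = lrt_genetic_variance(fit_same, null)
        assert res.p_value == pytest.approx(0.5)

    def test_chi2_tail_lookup(self):
        from scipy import stats
        y, X, K = toy_problem(seed=8)
        null = fit_null_fixed_only(y, X)
        fit = fit_greml(y, X, [K])
        fit.logL = null.logL + 3.84 / 2
        res = lrt_genetic_variance(fit, null)
        assert res.p_value == pytest.approx(0.5 * stats.chi2.sf(3.84, 1))
        assert res.p_value == pytest.approx(0.025, abs=5e-4)

    def test_exclusion_flag(self):
        y, X, K = toy_problem(seed=9)
        null = fit_null_fixed_only(y, X)
        fit = fit_greml(y, X, [K])
        fit.logL = null.logL + 0.3
        assert lrt_genetic_variance(fit, null).excluded


class TestBivariate:
    @staticmethod
    def _shared_genotype_traits(seed, n=400, m=500, h2=0.6, shared=False):
        """Two traits on one genotype matrix, with either the same or
        independent SNP effect vectors."""
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        K = compute_grm(make_matrix(codes))
        Z = (codes - codes.mean(0)) / codes.std(0)
        b1 = rng.normal(size=m)
        b2 = b1 if shared else rng.normal(size=m)

        def trait(b):
            g = Z @ b
            g *= np.sqrt(h2) / g.std()
            return g + rng.normal(0, np.sqrt(1 - h2), n)

        X = np.ones((n, 1))
        return trait(b1), trait(b2), X, K

    def test_fully_shared_architecture_gives_unit_correlation(self):
        y1, y2, X, K = self._shared_genotype_traits(10, shared=True)
        biv = fit_bivariate(y1, y2, X, [K])
        assert biv.rg[0] >= 0.9

    def test_independent_traits_give_small_correlation(self):
        vals = []
        for seed in (11, 12, 13):
            y1, y2, X, K = self._shared_genotype_traits(seed, shared=False)
            biv = fit_bivariate(y1, y2, X, [K])
            if biv.rg_defined[0]:
                vals.append(abs(biv.rg[0]))
        assert np.mean(vals) <= 0.3

    def test_degenerate_component_flagged(self):
        rng = np.random.default_rng(14)
        n = 80
        y1 = rng.normal(size=n)
        y2 = rng.normal(size=n)
        X = np.ones((n, 1))
        K = compute_grm(make_matrix(rng.integers(0, 3, (n, 60)).astype(np.int8)))
        biv = fit_bivariate(y1, y2, X, [K])
        if not biv.rg_defined[0]:
            assert np.isnan(biv.rg[0])


class TestBlup:
    def test_mixed_model_equation_oracle(self):
        """u-hat from the covariance formula equals the explicit MME solve.

        The GRM is centred, hence singular, so the equations are written
        for whitened effects u = L a with K = L L' (eigen square root) and
        a ~ N(0, s2g I); this keeps the coefficient matrix full rank.
        """
        y, X, K = toy_problem(seed=15, n=30, m=60)
        fit = fit_greml(y, X, [K])
        blup = predict_gebv(fit, y, X, [K])
        s2g, s2e = fit.sigma2_g[0], fit.sigma2_e
        n, p = X.shape
        lam_vals, U = np.linalg.eigh(K.values)
        keep = lam_vals > 1e-10
        L = U[:, keep] * np.sqrt(lam_vals[keep])
        q = L.shape[1]
        lam = s2e / s2g
        lhs = np.vstack([
            np.hstack([X.T @ X, X.T @ L]),
            np.hstack([L.T @ X, L.T @ L + lam * np.eye(q)])])
        rhs = np.concatenate([X.T @ y, L.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        u_mme = L @ sol[p:]
        assert np.allclose(blup.gebv[K.label], u_mme, atol=1e-8)
        assert np.allclose(blup.beta, sol[:p], atol=1e-8)

    def test_vanishing_component_gives_zero_gebv(self):
        y, X, K = toy_problem(seed=16, n=60, m=80)
        fit = fit_greml(y, X, [K])
        fit.sigma2_g = np.array([1e-9 * fit.V_P])
        blup = predict_gebv(fit, y, X, [K])
        assert np.max(np.abs(blup.gebv[K.label])) <= 1e-6 * np.std(y)

    def test_gebv_mean_near_zero(self):
        y, X, K = toy_problem(seed=17, n=100, m=150)
        fit = fit_greml(y, X, [K])
        blup = predict_gebv(fit, y, X, [K])
        assert abs(np.mean(blup.gebv[K.label])) <= 1e-6 * np.std(y) * 10

    def test_unconverged_fit_rejected(self):
        y, X, K = toy_problem(seed=18)
        fit = fit_greml(y, X, [K])
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            predict_gebv(fit, y, X, [K])

    def test_qtl_component_tracks_causal_dosage(self):
        from equigen.simulate import simulate_dataset
        cfg = small_cohort_config(seed=19, n=800)
        G, pheno, truth = simulate_dataset(cfg)
        from equigen.core_io import filter_variants
        Gf = filter_variants(G, min_maf=0.01)
        y = pheno.df["height"].to_numpy()
        X = np.column_stack([np.ones_like(y), pheno.df["age_days"]])
        idx3 = [j for j, v in enumerate(Gf.variants) if v.chrom == "3"]
        rest = [j for j, v in enumerate(Gf.variants) if v.chrom != "3"]
        grms = [compute_grm(Gf, idx3, label="chr3"),
                compute_grm(Gf, rest, label="rest")]
        fit = fit_greml(y, X, grms)
        blup = predict_gebv(fit, y, X, grms)
        d = G.dosage(truth.causal_ids[0])
        corr = np.corrcoef(blup.gebv["chr3"], d)[0, 1]
        assert corr >= 0.6
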