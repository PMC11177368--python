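"""Restricted maximum likelihood for GRM-structured mixed models.

Univariate and bivariate GREML by average-information REML with one
expectation-maximisation first step (the strategy of the common GREML
tools), likelihood-ratio tests for genetic variance, and BLUP prediction
of component-specific breeding values (gEBVs).

The model is y ~ N(X b, sum_c s2_c K_c + s2_e I).  For two traits the
observations are stacked and every component contributes a 2x2 genetic
(co)variance block, giving per-component genetic correlations such as the
QTL-window-specific r_G used in local-correlation analyses.

Variances are constrained to a small positive floor; convergence is
declared when the restricted log-likelihood moves by less than ``tol``.
Standard errors come from the inverse average-information matrix (delta
method for ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .grm import GrmMatrix

_FLOOR_FRAC = 1e-6


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------

def _inv_pd(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric positive-definite matrix."""
    c, info = sla.lapack.dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv, info = sla.lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet


class _Kron:
    """Derivative structure E (x) M of V with respect to one parameter.

    E is a t x t symmetric pattern over traits (t = 1 or 2); M is an n x n
    symmetric matrix or None for the identity.
    """

    def __init__(self, E: np.ndarray, M: np.ndarray | None, n: int):
        self.E = np.asarray(E, dtype=float)
        self.M = M
        self.n = n
        self.t = self.E.shape[0]

    def add_to(self, V: np.ndarray, coef: float) -> None:
        n = self.n
        for a in range(self.t):
            for b in range(self.t):
                if self.E[a, b] == 0:
                    continue
                blk = V[a * n:(a + 1) * n, b * n:(b + 1) * n]
                c = coef * self.E[a, b]
                if self.M is None:
                    blk[np.diag_indices(n)] += c
                else:
                    blk += c * self.M

    def matmat(self, W: np.ndarray) -> np.ndarray:
        n = self.n
        out = np.zeros_like(W)
        for a in range(self.t):
            acc = None
            for b in range(self.t):
                if self.E[a, b] == 0:
                    continue
                piece = self.E[a, b] * W[b * n:(b + 1) * n]
                acc = piece if acc is None else acc + piece
            if acc is not None:
                out[a * n:(a + 1) * n] = acc if self.M is None else self.M @ acc
        return out

    def trace_with(self, S: np.ndarray) -> float:
        """tr(S @ (E (x) M)) for symmetric S."""
        n = self.n
        tot = 0.0
        for a in range(self.t):
            for b in range(self.t):
                if self.E[a, b] == 0:
                    continue
                blk = S[a * n:(a + 1) * n, b * n:(b + 1) * n]
                if self.M is None:
                    tot += self.E[a, b] * np.trace(blk)
                else:
                    tot += self.E[a, b] * float(np.sum(blk * self.M))
        return tot


@dataclass
class _RemlState:
    theta: np.ndarray
    logL: float
    ai: np.ndarray
    score: np.ndarray
    Vinv: np.ndarray
    VinvX: np.ndarray
    XtVinvX_inv: np.ndarray
    Py: np.ndarray
    converged: bool
    n_iter: int


def _build_V(ops: list[_Kron], theta: np.ndarray, N: int) -> np.ndarray:
    V = np.zeros((N, N))
    for op, t in zip(ops, theta):
        op.add_to(V, t)
    return V


def _reml_logL(y, X, ops, theta) -> tuple[float, np.ndarray]:
    """Restricted log-likelihood (no score/AI) — used in step halving.

    Also returns the Cholesky factor so the accepted candidate's
    factorisation can be reused by the next full iteration.
    """
    N = len(y)
    V = _build_V(ops, theta, N)
    c, info = sla.lapack.dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    W = np.column_stack([X, y])
    VinvW = sla.cho_solve((c, True), W)
    VinvX, Vinvy = VinvW[:, :-1], VinvW[:, -1]
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    Xty = VinvX.T @ y
    yPy = float(y @ Vinvy) - float(Xty @ np.linalg.solve(XtVinvX, Xty))
    return -0.5 * (logdetV + logdetX + yPy), c


_triu_cache: dict[int, tuple] = {}


def _symmetrize_lower(a: np.ndarray) -> np.ndarray:
    """Mirror the lower triangle into the upper, in place."""
    n = a.shape[0]
    if n not in _triu_cache:
        _triu_cache.clear()           # keep at most one cached index set
        _triu_cache[n] = np.triu_indices(n, 1)
    iu = _triu_cache[n]
    a[iu] = a.T[iu]
    return a


def _reml_quantities(y, X, ops, theta, chol=None):
    N = len(y)
    if chol is None:
        V = _build_V(ops, theta, N)
        chol, info = sla.lapack.dpotrf(V, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("matrix not positive definite")
    logdetV = 2.0 * np.sum(np.log(np.diag(chol)))
    Vinv, info = sla.lapack.dpotri(chol, lower=1, overwrite_c=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    Vinv = _symmetrize_lower(Vinv)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    XtVinvX_inv = np.linalg.inv(XtVinvX)

    def project(v):
        return Vinv @ v - VinvX @ (XtVinvX_inv @ (VinvX.T @ v))

    Py = project(y)
    logL = -0.5 * (logdetV + logdetX + float(y @ Py))
    k = len(ops)
    score = np.zeros(k)
    APy = [op.matmat(Py[:, None])[:, 0] for op in ops]
    for i, op in enumerate(ops):
        tr_vinv_a = op.trace_with(Vinv)
        M = VinvX.T @ op.matmat(VinvX)
        tr_pa = tr_vinv_a - float(np.trace(XtVinvX_inv @ M))
        score[i] = -0.5 * (tr_pa - float(Py @ APy[i]))
    PAPy = [project(a) for a in APy]
    ai = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * float(APy[i] @ PAPy[j])
    return logL, score, ai, Vinv, VinvX, XtVinvX_inv, Py


def _moment_start(y: np.ndarray, X: np.ndarray,
                  mats: list[np.ndarray | None]) -> np.ndarray:
    """Moment-based starting values: project the OLS residual cross-product
    onto span{K_c, I} in the Frobenius inner product and clamp.

    Used only to initialise the REML iteration, never as an estimator.
    """
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    k = len(mats)
    G = np.zeros((k, k))
    b = np.zeros(k)
    for i, A in enumerate(mats):
        rA = r if A is None else A @ r
        b[i] = float(r @ rA)
        for j in range(i, k):
            B = mats[j]
            if A is None and B is None:
                G[i, j] = n
            elif A is None:
                G[i, j] = float(np.trace(B))
            elif B is None:
                G[i, j] = float(np.trace(A))
            else:
                G[i, j] = float(np.sum(A * B))
            G[j, i] = G[i, j]
    try:
        v = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        v = np.full(k, float(np.var(y)) / k)
    vp = float(np.var(y))
    return np.clip(v, 0.02 * vp, 2.0 * vp)


def _constrain(theta: np.ndarray, kinds: list[tuple], floor: float) -> np.ndarray:
    """Clamp variances to the floor.

    Covariances are left unconstrained: the total covariance V can stay
    positive definite even when a genetic correlation passes +-1 (the
    residual block keeps the traits distinguishable), and non-PD proposals
    are caught by step halving.  Correlations are clamped to [-1, 1]
    post hoc when reported.  kinds[i] is ("var",) or ("cov", i_v1, i_v2).
    """
    th = theta.copy()
    for i, kind in enumerate(kinds):
        if kind[0] == "var" and th[i] < floor:
            th[i] = floor
    return th


def _run_airemL(y, X, ops, theta0, kinds, max_iter=100, tol=1e-4,
                em_first=True) -> _RemlState:
    vp = float(np.var(y[:len(y)]))
    floor = _FLOOR_FRAC * vp
    theta = _constrain(np.asarray(theta0, dtype=float), kinds, floor)
    N = len(y)
    prev = None
    state = None
    best_state = None
    stall = 0
    carry_chol = None
    for it in range(max_iter):
        try:
            logL, score, ai, Vinv, VinvX, XtVinvX_inv, Py = _reml_quantities(
                y, X, ops, theta, chol=carry_chol)
        except np.linalg.LinAlgError:
            # a blindly accepted small step left the PD cone: fall back to
            # the best state seen so far
            if best_state is not None:
                return best_state
            raise
        carry_chol = None
        state = _RemlState(theta, logL, ai, score, Vinv, VinvX,
                           XtVinvX_inv, Py, False, it + 1)
        # the EM warm-up step can be tiny; only test convergence once at
        # least one average-information step has been taken
        if prev is not None and it >= 2 and abs(logL - prev) < tol:
            state.converged = True
            return state
        # constrained optima on the PD-cone boundary make the iteration
        # oscillate; accept the best visited point once the likelihood has
        # stopped improving for three consecutive iterations
        if best_state is None or logL > best_state.logL + tol:
            best_state = state
            stall = 0
        else:
            stall += 1
            if it >= 3 and stall >= 2:
                best_state.converged = True
                return best_state
        prev = logL
        if em_first and it == 0:
            delta = theta ** 2 * (2.0 * score) / N
        else:
            # active-set update: parameters pinned at the variance floor
            # with a downhill score are held fixed; the AI step is solved
            # over the free parameters only
            free = np.ones(len(theta), dtype=bool)
            for i, kind in enumerate(kinds):
                if kind[0] == "var":
                    if theta[i] <= floor * (1 + 1e-6) and score[i] < 0:
                        free[i] = False
            delta = np.zeros(len(theta))
            if free.any():
                try:
                    delta[free] = np.linalg.solve(ai[np.ix_(free, free)],
                                                  score[free])
                except np.linalg.LinAlgError:
                    delta[free] = (theta[free] ** 2 * 2.0 * score[free]) / N
        # step halving on non-PD or likelihood decrease
        step = 1.0
        new_theta = theta
        scale = max(float(np.max(np.abs(theta))), floor)
        if np.max(np.abs(delta)) < 0.02 * scale:
            # clearly small step: accept without an extra factorisation
            # (a bad proposal would surface as a likelihood drop next
            # iteration and be absorbed by the best-state tracking)
            new_theta = _constrain(theta + delta, kinds, floor)
        else:
            for _ in range(8):
                cand = _constrain(theta + step * delta, kinds, floor)
                try:
                    new_logL, cand_chol = _reml_logL(y, X, ops, cand)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                # tolerate small transient drops — the best visited state
                # is tracked and returned on stall
                if new_logL >= logL - 0.1 or step < 0.05:
                    new_theta = cand
                    carry_chol = cand_chol
                    break
                step *= 0.5
            else:
                # no acceptable step found; stay put and let the stall
                # rule terminate on the best visited state
                new_theta = theta
        # boundary case: constrained parameters can stop moving while the
        # likelihood still wiggles — treat a frozen theta as converged
        if it >= 2 and np.max(np.abs(new_theta - theta)) < 1e-8 * vp:
            theta = new_theta
            state.theta = theta
            state.converged = True
            return state
        theta = new_theta
    return state


# ---------------------------------------------------------------------------
# univariate GREML
# ---------------------------------------------------------------------------

@dataclass
class VarCompFit:
    """REML solution for a single trait.

    fractions[i] = sigma2_g[i] / V_P; with a single genome-wide GRM this is
    the SNP-based heritability.
    """

    component_labels: list[str]
    sigma2_g: np.ndarray
    sigma2_e: float
    se: np.ndarray              # SEs of (sigma2_g..., sigma2_e)
    logL: float
    converged: bool
    n_used: int
    fraction_se: np.ndarray = field(default=None)
    n_params: int = 0
    sample_ids: list[str] | None = None

    @property
    def V_P(self) -> float:
        return float(np.sum(self.sigma2_g) + self.sigma2_e)

    @property
    def fractions(self) -> np.ndarray:
        return self.sigma2_g / self.V_P

    @property
    def h2(self) -> float:
        return float(np.sum(self.sigma2_g) / self.V_P)

    def to_hsq_text(self) -> str:
        """GCTA .hsq-style summary table."""
        lines = ["Source\tVariance\tSE"]
        for lab, v, s in zip(self.component_labels, self.sigma2_g, self.se):
            lines.append(f"V({lab})\t{v:.6f}\t{s:.6f}")
        lines.append(f"V(e)\t{self.sigma2_e:.6f}\t{self.se[-1]:.6f}")
        lines.append(f"Vp\t{self.V_P:.6f}\t")
        for lab, f, s in zip(self.component_labels, self.fractions,
                             self.fraction_se):
            lines.append(f"V({lab})/Vp\t{f:.6f}\t{s:.6f}")
        lines.append(f"logL\t{self.logL:.4f}\t")
        lines.append(f"n\t{self.n_used}\t")
        return "\n".join(lines) + "\n"


def _check_alignment(y, X, grms: list[GrmMatrix]):
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("y and X have different numbers of rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X is rank deficient")
    for g in grms:
        if g.n != n:
            raise ValueError(
                f"GRM {g.label!r} has {g.n} samples but y has {n}")
    if n <= X.shape[1] + len(grms):
        raise ValueError("not enough observations for the model")


def _fraction_se(theta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Delta-method SEs of theta_i / sum(theta) for the genetic components."""
    total = theta.sum()
    k = len(theta)
    ses = np.zeros(k - 1)
    for i in range(k - 1):
        grad = np.full(k, -theta[i] / total ** 2)
        grad[i] += 1.0 / total
        ses[i] = np.sqrt(max(float(grad @ cov @ grad), 0.0))
    return ses


def fit_greml(y: np.ndarray, X: np.ndarray, grms: list[GrmMatrix],
              max_iter: int = 100, tol: float = 1e-4,
              sample_ids: list[str] | None = None) -> VarCompFit:
    """Univariate AI-REML with one or many GRM components.

    A single-GRM model is solved in the eigenbasis of the GRM (exact, much
    faster); multi-component models use dense AI-REML iterations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_alignment(y, X, grms)
    if len(grms) == 1:
        return _fit_greml_single(y, X, grms[0], max_iter, tol, sample_ids)[0]
    n = len(y)
    ops = [_Kron(np.array([[1.0]]), g.values, n) for g in grms]
    ops.append(_Kron(np.array([[1.0]]), None, n))
    k = len(grms)
    theta0 = _moment_start(y, X, [g.values for g in grms] + [None])
    kinds = [("var",)] * (k + 1)
    st = _run_airemL(y, X, ops, theta0, kinds, max_iter, tol)
    cov = _safe_inv(st.ai)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    fit = VarCompFit([g.label for g in grms], st.theta[:k], float(st.theta[k]),
                     se, st.logL, st.converged, n,
                     fraction_se=_fraction_se(st.theta, cov),
                     n_params=k + 1, sample_ids=sample_ids)
    return fit


def _safe_inv(a: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(a)


def _fit_greml_single(y, X, grm: GrmMatrix, max_iter=100, tol=1e-4,
                      sample_ids=None):
    """Single-GRM REML in the eigenbasis; returns (fit, (U, lam))."""
    lam, U = np.linalg.eigh(grm.values)
    lam = np.maximum(lam, 0.0)
    ys = U.T @ y
    Xs = U.T @ X
    n = len(y)
    vp = float(np.var(y))
    floor = _FLOOR_FRAC * vp
    theta = np.array([vp / 2, vp / 2])
    prev = None
    converged = False
    logL = np.nan
    ai = np.eye(2)
    for it in range(max_iter):
        w = theta[0] * lam + theta[1]
        if (w <= 0).any():
            w = np.maximum(w, 1e-10)
        wi = 1.0 / w
        VinvX = Xs * wi[:, None]
        XtVinvX = Xs.T @ VinvX
        XtVinvX_inv = np.linalg.inv(XtVinvX)
        Py = ys * wi - VinvX @ (XtVinvX_inv @ (VinvX.T @ ys))
        logL = -0.5 * (np.sum(np.log(w)) + np.linalg.slogdet(XtVinvX)[1]
                       + float(ys @ Py))
        if prev is not None and it >= 2 and abs(logL - prev) < tol:
            converged = True
            break
        prev = logL
        A = [lam, np.ones(n)]
        score = np.zeros(2)
        APy = [a * Py for a in A]
        for i in range(2):
            tr_vinv_a = float(np.sum(A[i] * wi))
            M = VinvX.T @ (A[i][:, None] * VinvX)
            tr_pa = tr_vinv_a - float(np.trace(XtVinvX_inv @ M))
            score[i] = -0.5 * (tr_pa - float(Py @ APy[i]))

        def project(v):
            return v * wi - VinvX @ (XtVinvX_inv @ (VinvX.T @ v))

        PAPy = [project(a) for a in APy]
        ai = np.array([[0.5 * float(APy[i] @ PAPy[j]) for j in range(2)]
                       for i in range(2)])
        if it == 0:
            delta = theta ** 2 * (2.0 * score) / n
        else:
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = theta ** 2 * (2.0 * score) / n
        step = 1.0
        for _ in range(8):
            cand = np.maximum(theta + step * delta, floor)
            wc = cand[0] * lam + cand[1]
            if (wc > 0).all():
                theta = cand
                break
            step *= 0.5
    cov = _safe_inv(ai)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    fit = VarCompFit([grm.label], theta[:1].copy(), float(theta[1]),
                     se, logL, converged, n,
                     fraction_se=_fraction_se(theta, cov),
                     n_params=2, sample_ids=sample_ids)
    return fit, (U, lam)


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    lrt: float
    df: int
    p_value: float
    excluded: bool     # trait shows no usable genetic variance (p > 0.05)


def lrt_genetic_variance(fit_full: VarCompFit, fit_null: VarCompFit,
                         alpha: float = 0.05) -> LrtResult:
    """LRT for dropping k genetic variance components.

    For k = 1 the null distribution is the boundary mixture
    0.5 chi2_0 + 0.5 chi2_1, so p = 0.5 Pr(chi2_1 >= LRT) (and p = 0.5 at
    LRT = 0); for k > 1 a plain chi2_k reference is used.
    """
    k = fit_full.n_params - fit_null.n_params
    if k < 1:
        raise ValueError("null model must drop at least one component")
    lrt = 2.0 * (fit_full.logL - fit_null.logL)
    if lrt < -1e-6:
        import warnings
        warnings.warn(f"full-model logL below null ({lrt:.3g}); LRT clipped to 0")
    lrt = max(lrt, 0.0)
    if k == 1:
        p = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 0.5
    else:
        p = stats.chi2.sf(lrt, k)
    return LrtResult(lrt, k, float(p), bool(p > alpha))


def fit_null_fixed_only(y: np.ndarray, X: np.ndarray) -> VarCompFit:
    """No-genetic-variance null model (plain fixed-effects regression)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    # restricted logL with V = s2*I at the REML residual variance:
    # -0.5 [ n log s2 + logdet(X'X) - p log s2 + (n - p) ]
    logL = -0.5 * ((n - p) * np.log(s2) + np.linalg.slogdet(X.T @ X)[1]
                   + (n - p))
    return VarCompFit([], np.zeros(0), s2, np.array([np.nan]), logL, True, n,
                      fraction_se=np.zeros(0), n_params=1)


# ---------------------------------------------------------------------------
# bivariate GREML
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    component_labels: list[str]
    # per component: genetic variances of the two traits and the covariance
    var1: np.ndarray
    var2: np.ndarray
    cov12: np.ndarray
    resid: tuple[float, float, float]     # (e1, e2, e12)
    rg: np.ndarray                        # per-component genetic correlation
    rg_se: np.ndarray
    rg_defined: np.ndarray                # False where a variance vanished
    logL: float
    converged: bool
    n_used: int


def fit_bivariate(y1: np.ndarray, y2: np.ndarray, X: np.ndarray,
                  grms: list[GrmMatrix], max_iter: int = 25,
                  tol: float = 1e-4) -> BivariateFit:
    """Bivariate AI-REML on complete cases (both traits observed).

    Starting values come from univariate fits per trait; covariances start
    at zero.  r_G per component is cov / sqrt(v1 v2), clamped to [-1, 1],
    flagged undefined when either variance is at (or near) the floor.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_alignment(y1, X, grms)
    if len(y2) != len(y1):
        raise ValueError("both traits must be observed on the same samples")
    n = len(y1)
    k = len(grms)

    # moment-based starting values per trait; covariances start at the
    # residual-correlation-scaled geometric mean of the variance starts
    mats = [g.values for g in grms] + [None]
    v1_0 = _moment_start(y1, X, mats)
    v2_0 = _moment_start(y2, X, mats)
    b1, *_ = np.linalg.lstsq(X, y1, rcond=None)
    b2, *_ = np.linalg.lstsq(X, y2, rcond=None)
    r12 = float(np.corrcoef(y1 - X @ b1, y2 - X @ b2)[0, 1])

    E11 = np.array([[1.0, 0.0], [0.0, 0.0]])
    E22 = np.array([[0.0, 0.0], [0.0, 1.0]])
    E12 = np.array([[0.0, 1.0], [1.0, 0.0]])
    ops: list[_Kron] = []
    theta0: list[float] = []
    kinds: list[tuple] = []
    for i, g in enumerate(grms):
        base = 3 * i
        ops += [_Kron(E11, g.values, n), _Kron(E22, g.values, n),
                _Kron(E12, g.values, n)]
        theta0 += [v1_0[i], v2_0[i],
                   0.5 * r12 * np.sqrt(v1_0[i] * v2_0[i])]
        kinds += [("var",), ("var",), ("cov", base, base + 1)]
    base = 3 * k
    ops += [_Kron(E11, None, n), _Kron(E22, None, n), _Kron(E12, None, n)]
    theta0 += [v1_0[k], v2_0[k], 0.5 * r12 * np.sqrt(v1_0[k] * v2_0[k])]
    kinds += [("var",), ("var",), ("cov", base, base + 1)]

    ys = np.concatenate([y1, y2])
    Xs = np.block([[X, np.zeros_like(X)], [np.zeros_like(X), X]])
    st = _run_airemL(ys, Xs, ops, np.array(theta0), kinds, max_iter, tol,
                     em_first=False)
    cov = _safe_inv(st.ai)

    var1 = st.theta[0:3 * k:3]
    var2 = st.theta[1:3 * k:3]
    cov12 = st.theta[2:3 * k:3]
    vp1 = float(np.var(y1))
    vp2 = float(np.var(y2))
    defined = (var1 > 1e-8 * vp1) & (var2 > 1e-8 * vp2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = cov12 / np.sqrt(var1 * var2)
    rg = np.clip(rg, -1.0, 1.0)
    rg[~defined] = np.nan
    rg_se = np.full(k, np.nan)
    for i in range(k):
        if not defined[i]:
            continue
        v1, v2, c = var1[i], var2[i], cov12[i]
        r = c / np.sqrt(v1 * v2)
        grad = np.zeros(len(st.theta))
        grad[3 * i] = -0.5 * r / v1
        grad[3 * i + 1] = -0.5 * r / v2
        grad[3 * i + 2] = 1.0 / np.sqrt(v1 * v2)
        rg_se[i] = np.sqrt(max(float(grad @ cov @ grad), 0.0))
    return BivariateFit(
        [g.label for g in grms], var1, var2, cov12,
        (float(st.theta[3 * k]), float(st.theta[3 * k + 1]),
         float(st.theta[3 * k + 2])),
        rg, rg_se, defined, st.logL, st.converged, n)


# ---------------------------------------------------------------------------
# BLUP
# ---------------------------------------------------------------------------

@dataclass
class BlupResult:
    sample_ids: list[str] | None
    component_labels: list[str]
    gebv: dict[str, np.ndarray]     # component label -> per-individual gEBV
    beta: np.ndarray                # fixed-effect estimates
    total: np.ndarray               # sum over components

    def component(self, label: str) -> np.ndarray:
        return self.gebv[label]


def predict_gebv(fit: VarCompFit, y: np.ndarray, X: np.ndarray,
                 grms: list[GrmMatrix]) -> BlupResult:
    """BLUP of the random effect of each GRM component.

    u_hat_c = s2_c K_c V^-1 (y - X beta_hat), with beta_hat the GLS
    estimate under the fitted V.  Equivalent to solving the mixed-model
    equations at the REML variance estimates.
    """
    if not fit.converged:
        raise ValueError("REML fit did not converge; refusing to BLUP")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_alignment(y, X, grms)
    if list(fit.component_labels) != [g.label for g in grms]:
        raise ValueError("GRM list does not match the fitted components")
    n = len(y)
    V = np.zeros((n, n))
    for s2, g in zip(fit.sigma2_g, grms):
        V += s2 * g.values
    V[np.diag_indices(n)] += fit.sigma2_e
    if fit.sigma2_e <= 0 and np.all(fit.sigma2_g <= 0):
        raise ValueError("all variance components are zero; V is singular")
    Vinv, _ = _inv_pd(V)
    VinvX = Vinv @ X
    beta = np.linalg.solve(X.T @ VinvX, VinvX.T @ y)
    resid = y - X @ beta
    Vinv_resid = Vinv @ resid
    gebv = {}
    total = np.zeros(n)
    for s2, g in zip(fit.sigma2_g, grms):
        u = s2 * (g.values @ Vinv_resid)
        gebv[g.label] = u
        total += u
    return BlupResult(fit.sample_ids, list(fit.component_labels), gebv, beta,
                      total)
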