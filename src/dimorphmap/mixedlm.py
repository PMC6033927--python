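"""Maximum-likelihood machinery for random-intercept linear mixed models.

Mass-univariate morphometry needs tens of thousands of mixed-model fits
(one per voxel), all sharing the same design matrix and grouping structure
and differing only in the response. This module exploits that: the model

    y = X beta + Z b + e,     b_g ~ N(0, sigma_b^2),  e ~ N(0, sigma_e^2 I)

with a random intercept per group (mouse) has a one-dimensional profiled
ML deviance in the variance ratio lam = sigma_b^2 / sigma_e^2, and for a
fixed ``lam`` the GLS solve reduces to group-sum corrections of the OLS
normal equations.  Profiling is done on a deterministic log-grid followed
by a fixed-iteration ternary refinement, vectorised over responses, so
results are independent of execution order and chunking.

Fitting is by maximum likelihood (not REML) throughout: likelihood-ratio
tests between models that differ in their fixed effects are only valid
under ML.

Also here: Wilks likelihood-ratio tests, Satterthwaite effective degrees
of freedom for fixed-effect contrasts, and Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

__all__ = [
    "MixedModelFit",
    "LRTResult",
    "RankDeficiencyError",
    "ConvergenceError",
    "NestingError",
    "fit_lme_ml",
    "fit_lme_ml_batch",
    "lrt",
    "lrt_batch",
    "satterthwaite_df",
    "satterthwaite_df_batch",
    "fdr_bh",
]

_LOGLAM_GRID = np.linspace(-6.0, 4.0, 51)
_REFINE_ITER = 35
_NEG_LRT_TOL = 1e-6


class RankDeficiencyError(ValueError):
    """Fixed-effect design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """Optimizer failed, or a likelihood ratio came out materially negative."""


class NestingError(ValueError):
    """Likelihood-ratio test requested between non-nested designs."""


@dataclasses.dataclass
class MixedModelFit:
    """ML fit of a random-intercept linear mixed model.

    ``sigma2_group`` is the random-intercept variance, ``sigma2_resid`` the
    residual variance; ``loglik`` is the maximised ML log-likelihood.
    """

    params: np.ndarray
    cov_params: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    loglik: float
    n_obs: int
    n_groups: int
    design_info: str = ""
    converged: bool = True
    # retained for Satterthwaite finite differencing
    _X: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _y: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _group_idx: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.params.size


@dataclasses.dataclass
class LRTResult:
    """Wilks likelihood-ratio test: D = -2 ln(L_reduced / L_full) ~ chi2_Q."""

    statistic: float
    df: int
    pvalue: float


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = np.unique(np.asarray(groups), return_inverse=True)
    return uniques.astype(np.intp), len(codes)


class _BatchProblem:
    """Sufficient statistics shared across responses for one design."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, group_idx: np.ndarray, n_groups: int):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.X, self.Y = X, Y
        self.N, self.p = X.shape
        self.V = Y.shape[1]
        self.G = n_groups
        self.XtX = X.T @ X
        self.XtY = X.T @ Y                       # (p, V)
        self.yty = np.einsum("nv,nv->v", Y, Y)   # (V,)
        S = np.zeros((n_groups, self.p))
        np.add.at(S, group_idx, X)
        self.S = S                               # group sums of X rows
        T = np.zeros((n_groups, self.V))
        np.add.at(T, group_idx, Y)
        self.T = T                               # group sums of Y rows
        self.ng = np.bincount(group_idx, minlength=n_groups).astype(float)

    def _weights(self, lam: np.ndarray) -> np.ndarray:
        # w_gv = lam_v / (1 + lam_v * n_g); shape (G, V)
        lam = np.broadcast_to(np.atleast_1d(lam), (self.V,))
        return lam[None, :] / (1.0 + lam[None, :] * self.ng[:, None])

    def gls(self, lam: np.ndarray):
        """GLS estimates and V-weighted residual quadratic form at ``lam``.

        Returns (beta (V,p), A (V,p,p) = X' Vlam^-1 X, q (V,) = r' Vlam^-1 r,
        logdet (V,) of Vlam) where Vlam = I + lam Z Z'.
        """
        w = self._weights(lam)
        A = self.XtX[None] - np.einsum("gv,gp,gq->vpq", w, self.S, self.S)
        b = self.XtY.T - np.einsum("gv,gv,gp->vp", w, self.T, self.S)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        rr = (
            self.yty
            - 2.0 * np.einsum("vp,pv->v", beta, self.XtY)
            + np.einsum("vp,pq,vq->v", beta, self.XtX, beta)
        )
        Rg = self.T - self.S @ beta.T            # group sums of residuals (G, V)
        q = rr - np.einsum("gv,gv->v", w, Rg**2)
        lam_b = np.broadcast_to(np.atleast_1d(lam), (self.V,))
        logdet = np.log1p(lam_b[None, :] * self.ng[:, None]).sum(axis=0)
        return beta, A, q, logdet

    def deviance(self, lam: np.ndarray) -> np.ndarray:
        """-2 x profiled ML log-likelihood at variance ratio ``lam``."""
        _, _, q, logdet = self.gls(lam)
        sigma2 = np.maximum(q, 1e-300) / self.N
        return self.N * np.log(2.0 * np.pi * sigma2) + logdet + self.N

    def loglik_at(self, lam: np.ndarray, sigma2_e: np.ndarray) -> np.ndarray:
        """ML log-likelihood with beta profiled but variances held fixed."""
        _, _, q, logdet = self.gls(lam)
        return -0.5 * (
            self.N * np.log(2.0 * np.pi * sigma2_e) + logdet + q / sigma2_e
        )

    def reml_deviance(self, lam: np.ndarray) -> np.ndarray:
        """-2 x profiled restricted log-likelihood at variance ratio ``lam``."""
        _, A, q, logdet = self.gls(lam)
        npar = self.N - self.p
        sigma2 = np.maximum(q, 1e-300) / npar
        _, logdetA = np.linalg.slogdet(A)
        return npar * np.log(2.0 * np.pi * sigma2) + logdet + logdetA + npar

    def restricted_loglik_at(self, lam: np.ndarray, sigma2_e: np.ndarray) -> np.ndarray:
        """Restricted log-likelihood with variances held fixed."""
        _, A, q, logdet = self.gls(lam)
        _, logdetA = np.linalg.slogdet(A)
        return -0.5 * (
            (self.N - self.p) * np.log(2.0 * np.pi * sigma2_e)
            + logdet + logdetA + q / sigma2_e
        )


def _optimize_lambda(prob: _BatchProblem, reml: bool = False) -> np.ndarray:
    """Deterministic grid + ternary search for the per-response optimal lam."""
    crit = prob.reml_deviance if reml else prob.deviance
    devs = np.stack([crit(10.0**g) for g in _LOGLAM_GRID])  # (K, V)
    best = np.nanargmin(devs, axis=0)
    lo = _LOGLAM_GRID[np.maximum(best - 1, 0)]
    hi = _LOGLAM_GRID[np.minimum(best + 1, len(_LOGLAM_GRID) - 1)]
    for _ in range(_REFINE_ITER):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        d1 = crit(10.0**m1)
        d2 = crit(10.0**m2)
        take = d1 < d2
        hi = np.where(take, m2, hi)
        lo = np.where(take, lo, m1)
    lam = 10.0 ** ((lo + hi) / 2.0)
    # boundary: a pure fixed-effects model (lam = 0) may beat the interior
    dev_interior = crit(lam)
    dev0 = crit(np.zeros(prob.V))
    return np.where(dev0 <= dev_interior, 0.0, lam)


def fit_lme_ml_batch(Y: np.ndarray, X: np.ndarray, groups) -> dict:
    """Fit the random-intercept model by ML for many responses at once.

    ``Y`` is (n_obs, n_responses); ``X`` (n_obs, p) and ``groups`` (n_obs,)
    are shared.  Returns a dict of per-response arrays: ``params`` (V, p),
    ``cov_params`` (V, p, p), ``sigma2_group``, ``sigma2_resid``,
    ``loglik``, ``lam``, ``converged``.
    """
    X = np.asarray(X, dtype=float)
    _check_full_rank(X)
    group_idx, n_groups = _group_codes(groups)
    if n_groups < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    prob = _BatchProblem(X, Y, group_idx, n_groups)
    lam = _optimize_lambda(prob)
    beta, A, q, logdet = prob.gls(lam)
    sigma2_e = np.maximum(q, 1e-300) / prob.N
    loglik = -0.5 * (prob.N * np.log(2.0 * np.pi * sigma2_e) + logdet + prob.N)
    cov = np.linalg.inv(A) * sigma2_e[:, None, None]
    converged = np.isfinite(loglik)
    return {
        "params": beta,
        "cov_params": cov,
        "sigma2_group": lam * sigma2_e,
        "sigma2_resid": sigma2_e,
        "loglik": loglik,
        "lam": lam,
        "converged": converged,
        "_prob": prob,
        "_group_idx": group_idx,
    }


def fit_lme_ml(y: np.ndarray, X: np.ndarray, groups, design_info: str = "") -> MixedModelFit:
    """ML fit of ``y = X beta + (1 | group) + e`` for a single response."""
    y = np.asarray(y, dtype=float).ravel()
    res = fit_lme_ml_batch(y[:, None], X, groups)
    group_idx, n_groups = _group_codes(groups)
    return MixedModelFit(
        params=res["params"][0],
        cov_params=res["cov_params"][0],
        sigma2_group=float(res["sigma2_group"][0]),
        sigma2_resid=float(res["sigma2_resid"][0]),
        loglik=float(res["loglik"][0]),
        n_obs=y.size,
        n_groups=n_groups,
        design_info=design_info,
        converged=bool(res["converged"][0]),
        _X=np.asarray(X, dtype=float),
        _y=y,
        _group_idx=group_idx,
    )


def _check_full_rank(X: np.ndarray) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= s[0] * 1e-10:
        raise RankDeficiencyError(
            "fixed-effect design matrix is rank deficient (condition ratio "
            f"{s[-1] / s[0]:.2e})"
        )


def _check_nested(X_full: np.ndarray, X_reduced: np.ndarray) -> None:
    coef, *_ = np.linalg.lstsq(X_full, X_reduced, rcond=None)
    resid = X_reduced - X_full @ coef
    scale = max(np.abs(X_reduced).max(), 1.0)
    if np.abs(resid).max() > 1e-8 * scale:
        raise NestingError("reduced design is not in the column space of the full design")


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> LRTResult:
    """Likelihood-ratio test D = -2 ln(L_p / L_f) against chi2_Q.

    Q is the difference in fixed-effect parameter counts.  Small negative
    D from optimizer noise is clamped to 0; a materially negative D means
    the 'full' optimum was missed and raises :class:`ConvergenceError`.
    """
    if full.n_obs != reduced.n_obs:
        raise NestingError("full and reduced models fit different data")
    if full._X is not None and reduced._X is not None:
        _check_nested(full._X, reduced._X)
    Q = full.params.size - reduced.params.size
    if Q < 0:
        raise NestingError("full model must have at least as many parameters")
    D = 2.0 * (full.loglik - reduced.loglik)
    if D < -_NEG_LRT_TOL:
        raise ConvergenceError(f"negative likelihood-ratio statistic {D:.3g}")
    D = max(D, 0.0)
    if Q == 0:
        # identical designs: D is 0 up to optimizer noise and p is 1
        return LRTResult(statistic=D, df=0, pvalue=1.0)
    return LRTResult(statistic=D, df=Q, pvalue=float(stats.chi2.sf(D, Q)))


def lrt_batch(loglik_full: np.ndarray, loglik_reduced: np.ndarray, df: int):
    """Vectorised LRT over many responses; returns (D, p) arrays.

    Negative statistics within the optimizer tolerance are clamped to 0;
    larger negatives become NaN (treated as non-converged voxels).
    """
    D = 2.0 * (np.asarray(loglik_full) - np.asarray(loglik_reduced))
    D = np.where((D < 0) & (D > -_NEG_LRT_TOL), 0.0, D)
    D = np.where(D < 0, np.nan, D)
    return D, stats.chi2.sf(D, df)


def _var_contrast(prob: _BatchProblem, c: np.ndarray, lam, sigma2_e):
    """Var(c' beta_hat) at fixed variance components, per response."""
    w = prob._weights(lam)
    A = prob.XtX[None] - np.einsum("gv,gp,gq->vpq", w, prob.S, prob.S)
    Ainv_c = np.linalg.solve(A, np.broadcast_to(c, (prob.V, prob.p))[..., None])[..., 0]
    return np.atleast_1d(sigma2_e) * np.einsum("p,vp->v", c, Ainv_c)


def reml_state(prob: _BatchProblem) -> dict:
    """REML variance components and their observed information for ``prob``.

    Contrast-independent: computed once per fitted problem and shared by
    every contrast tested against it.
    """
    N, p = prob.N, prob.p
    lam = _optimize_lambda(prob, reml=True)
    beta, _, q, _ = prob.gls(lam)
    s2e = np.maximum(q, 1e-300) / (N - p)
    s2b = lam * s2e
    interior = s2b > 1e-8 * s2e
    hb = np.where(interior, 1e-3 * s2b, 1.0)
    he = 1e-3 * s2e

    def l_of(db, de):
        b = np.maximum(s2b + db, 0.0)
        e = s2e + de
        return prob.restricted_loglik_at(b / e, e)

    l0 = l_of(0.0, 0.0)
    H11 = -(l_of(hb, 0.0) - 2.0 * l0 + l_of(-hb, 0.0)) / hb**2
    H22 = -(l_of(0.0, he) - 2.0 * l0 + l_of(0.0, -he)) / he**2
    H12 = -(
        l_of(hb, he) - l_of(hb, -he) - l_of(-hb, he) + l_of(-hb, -he)
    ) / (4.0 * hb * he)
    return {"lam": lam, "beta": beta, "s2b": s2b, "s2e": s2e,
            "hb": hb, "he": he, "interior": interior,
            "H11": H11, "H22": H22, "H12": H12}


def contrast_inference_batch(prob: _BatchProblem, c: np.ndarray, state: dict | None = None):
    """Estimate, SE and Satterthwaite df of a contrast, vectorised.

    Variance components for contrast inference are re-profiled under the
    restricted (REML) criterion at the same design — likelihood-ratio
    tests stay on the ML path, but t-type inference on fixed-effect
    contrasts uses REML variance components, whose information yields
    the classical effective df (e.g. m - 2 for a between-group contrast
    in a balanced m-group design).  df = 2 f^2 / (g' H^-1 g) with
    f = Var(c'beta), g its gradient in theta = (sigma_b^2, sigma_e^2)
    and H the observed REML information (finite differences).
    """
    c = np.asarray(c, dtype=float)
    V, N, p = prob.V, prob.N, prob.p
    if state is None:
        state = reml_state(prob)
    lam, s2b, s2e = state["lam"], state["s2b"], state["s2e"]
    est = state["beta"] @ c
    f0 = _var_contrast(prob, c, lam, s2e)
    se = np.sqrt(f0)

    df = np.full(V, float(N - p))
    interior = state["interior"]
    if interior.any():
        hb, he = state["hb"], state["he"]

        def f_of(db, de):
            b = np.maximum(s2b + db, 0.0)
            e = s2e + de
            return _var_contrast(prob, c, b / e, e)

        g1 = (f_of(hb, 0.0) - f_of(-hb, 0.0)) / (2.0 * hb)
        g2 = (f_of(0.0, he) - f_of(0.0, -he)) / (2.0 * he)
        H11, H22, H12 = state["H11"], state["H22"], state["H12"]
        det = H11 * H22 - H12**2
        ok = interior & (det > 0) & (H11 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            quad = (g1**2 * H22 - 2.0 * g1 * g2 * H12 + g2**2 * H11) / det
            cand = 2.0 * f0**2 / quad
        good = ok & np.isfinite(cand) & (quad > 0)
        df[good] = np.minimum(cand[good], float(N - p))
    return est, se, df


def satterthwaite_df_batch(prob: _BatchProblem, c: np.ndarray,
                           sigma2_group=None, sigma2_resid=None) -> np.ndarray:
    """Satterthwaite effective df for contrast ``c``, vectorised."""
    _, _, df = contrast_inference_batch(prob, c)
    return df


def satterthwaite_df(fit: MixedModelFit, contrast: np.ndarray) -> float:
    """Satterthwaite effective df of a fixed-effect contrast for one fit."""
    if fit._X is None or fit._y is None:
        raise ValueError("fit does not retain its data; cannot differentiate")
    cache = getattr(fit, "_reml_cache", None)
    if cache is None:
        prob = _BatchProblem(fit._X, fit._y[:, None], fit._group_idx, fit.n_groups)
        cache = (prob, reml_state(prob))
        fit._reml_cache = cache
    prob, state = cache
    _, _, df = contrast_inference_batch(prob, np.asarray(contrast, float), state)
    val = float(df[0])
    if not np.isfinite(val) or val <= 0:
        warnings.warn("singular variance-component information; using residual df")
        return float(fit.df_resid)
    return val


def contrast_test(fit: MixedModelFit, contrast: np.ndarray, one_sided: str | None = None):
    """t-test of ``c' beta = 0`` with Satterthwaite df (REML components).

    ``one_sided`` in {None, 'less', 'greater'} selects the alternative for
    the sign of the contrast estimate.
    """
    if fit._X is None or fit._y is None:
        raise ValueError("fit does not retain its data")
    c = np.asarray(contrast, dtype=float)
    cache = getattr(fit, "_reml_cache", None)
    if cache is None:
        prob = _BatchProblem(fit._X, fit._y[:, None], fit._group_idx, fit.n_groups)
        cache = (prob, reml_state(prob))
        fit._reml_cache = cache
    prob, state = cache
    est_a, se_a, df_a = contrast_inference_batch(prob, c, state)
    est, se, df = float(est_a[0]), float(se_a[0]), float(df_a[0])
    t = est / se if se > 0 else np.inf * np.sign(est)
    if one_sided == "less":
        p = stats.t.cdf(t, df)
    elif one_sided == "greater":
        p = stats.t.sf(t, df)
    else:
        p = 2.0 * stats.t.sf(abs(t), df)
    return est, se, t, df, float(p)


def fit_lme_ml2(y: np.ndarray, X: np.ndarray, groups, slope: np.ndarray) -> MixedModelFit:
    """ML fit with correlated-free random intercept and slope per group.

    Random structure: b0_g + b1_g * slope, with independent variances
    (sigma_b0^2, sigma_b1^2).  Profiled ML over the two variance ratios
    via a deterministic grid plus Nelder-Mead refinement.  Used for the
    random-growth robustness variant; noticeably slower than the
    intercept-only path, so intended for structure-level fits and small
    voxel masks.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    _check_full_rank(X)
    slope = np.asarray(slope, dtype=float).ravel()
    group_idx, G = _group_codes(groups)
    N, p = X.shape

    # per-group sufficient statistics for U_g = [1, slope_g]
    U = np.column_stack([np.ones(N), slope])
    C = np.zeros((G, 2, 2))
    UX = np.zeros((G, 2, p))
    Uy = np.zeros((G, 2))
    for g in range(G):
        m = group_idx == g
        Ug = U[m]
        C[g] = Ug.T @ Ug
        UX[g] = Ug.T @ X[m]
        Uy[g] = Ug.T @ y[m]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def deviance(logs):
        lam = 10.0 ** np.asarray(logs, dtype=float)
        rootD = np.sqrt(lam)
        # W_g = D^{1/2} (I + D^{1/2} C_g D^{1/2})^{-1} D^{1/2}; valid at lam=0
        M = np.eye(2)[None] + rootD[None, :, None] * C * rootD[None, None, :]
        Minv = np.linalg.inv(M)
        W = rootD[None, :, None] * Minv * rootD[None, None, :]
        A = XtX - np.einsum("gap,gab,gbq->pq", UX, W, UX)
        b = Xty - np.einsum("gap,gab,gb->p", UX, W, Uy)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        Ur = Uy - UX @ beta
        rr = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
        q = rr - np.einsum("ga,gab,gb->", Ur, W, Ur)
        if q <= 0:
            return np.inf
        sign, logdet = np.linalg.slogdet(M)
        if (sign <= 0).any():
            return np.inf
        return N * np.log(2.0 * np.pi * q / N) + float(logdet.sum()) + N

    grid = np.linspace(-6.0, 3.0, 10)
    best, best_dev = None, np.inf
    for g0 in grid:
        for g1 in grid:
            d = deviance((g0, g1))
            if d < best_dev:
                best, best_dev = (g0, g1), d
    from scipy.optimize import minimize

    opt = minimize(deviance, np.asarray(best), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400})
    logs = opt.x if opt.fun <= best_dev else np.asarray(best)
    dev = min(opt.fun, best_dev)

    lam = 10.0 ** logs
    rootD = np.sqrt(lam)
    M = np.eye(2)[None] + rootD[None, :, None] * C * rootD[None, None, :]
    W = rootD[None, :, None] * np.linalg.inv(M) * rootD[None, None, :]
    A = XtX - np.einsum("gap,gab,gbq->pq", UX, W, UX)
    b = Xty - np.einsum("gap,gab,gb->p", UX, W, Uy)
    beta = np.linalg.solve(A, b)
    Ur = Uy - UX @ beta
    q = yty - 2.0 * beta @ Xty + beta @ XtX @ beta - np.einsum("ga,gab,gb->", Ur, W, Ur)
    sigma2_e = q / N
    return MixedModelFit(
        params=beta,
        cov_params=np.linalg.inv(A) * sigma2_e,
        sigma2_group=float(lam[0] * sigma2_e),
        sigma2_resid=float(sigma2_e),
        loglik=-0.5 * dev,
        n_obs=N,
        n_groups=G,
        design_info="random intercept + slope",
        converged=bool(np.isfinite(dev)),
    )


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through in place."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = np.isfinite(flat)
    pv = flat[ok]
    if pv.size:
        if (pv < 0).any() or (pv > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        m = pv.size
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.empty(m)
        qs[order] = np.minimum(qv, 1.0)
        out = np.full(flat.shape, np.nan)
        out[ok] = qs
        q = out.reshape(p.shape)
    return q
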