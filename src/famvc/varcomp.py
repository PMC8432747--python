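"""Maximum-likelihood variance components for family data.

Quantitative traits follow the additive polygenic model

    y = m + X b + g + e,   g ~ N(0, sigma2_g * K),  e ~ N(0, sigma2_e * I)

where K is the expected additive relationship matrix (2*kinship), so the
phenotypic covariance is ``Sigma = sigma2_g * K + sigma2_e * I`` and the
narrow-sense heritability is ``h2 = sigma2_g / (sigma2_g + sigma2_e)``.
Because K is block-diagonal by family, each family block is eigendecomposed
once; for a given h2 the transformed observations are independent with
variances ``sigma2_t * (h2 * d + 1 - h2)`` (d the block eigenvalues), which
reduces the fit to a one-dimensional profile optimization over h2 with the
regression coefficients and total variance profiled out in closed form.

Binary traits use the liability-threshold model: a latent liability
``L = m + X b + a``, ``a ~ N(0, h2*K + (1-h2)*I)`` (total residual variance
1), with affection iff L > 0, so the model prevalence at reference covariates
is ``Phi(m)``.  Each family contributes the multivariate-normal rectangle
probability of its observed affection pattern, evaluated with a seeded
randomized quasi-Monte Carlo (Genz separation-of-variables) estimator so fits
are reproducible.  With probands supplied, each family's likelihood is
divided by the marginal probability of the proband(s)' observed affection
status — the classic single-ascertainment (proband) correction.

The heritability test compares sporadic (sigma2_g = 0) and polygenic fits;
because the null pins h2 to the boundary of its parameter space the LRT null
is the 1/2 chi2_0 + 1/2 chi2_1 mixture, giving p = 0.5 when the statistic
is 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .pedigree import KinshipMatrix

__all__ = [
    "PolygenicFit",
    "LRTResult",
    "fit_sporadic",
    "fit_polygenic_quant",
    "heritability_lrt",
    "h2_confint",
    "fit_liability_binary",
    "mvn_rectangle_prob",
    "RECTANGLE_DIM_CAP",
]

RECTANGLE_DIM_CAP = 25
_H2_HI = 0.9999


@dataclass
class PolygenicFit:
    """Result of a variance-components fit."""

    mean: float
    coeffs: dict
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    se: dict
    converged: bool
    n: int
    kind: str  # "quantitative" or "binary"
    diagnostics: dict = field(default_factory=dict)

    @property
    def h2_se(self):
        return self.se.get("h2")


@dataclass
class LRTResult:
    statistic: float
    pvalue: float
    null: str


def _as_matrix(K, n):
    if isinstance(K, KinshipMatrix):
        K = K.values
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError(f"kinship matrix shape {K.shape} does not match n={n}")
    return K


def _blocks(K):
    """Family blocks = connected components of the kinship sparsity graph."""
    ncomp, labels = connected_components(csr_matrix(K != 0), directed=False)
    return [np.flatnonzero(labels == c) for c in range(ncomp)]


def _design(X, n):
    """Prepend an intercept; X may be None, a DataFrame, or an array."""
    if X is None:
        return np.ones((n, 1)), ["intercept"]
    names = list(X.columns) if hasattr(X, "columns") else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    return np.column_stack([np.ones(n), Xa]), ["intercept"] + names


def _check_rank(X, names):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, rr = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(rr[j, j]) < 1e-8 * abs(rr[0, 0])]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad or names}")


def fit_sporadic(y, X=None) -> PolygenicFit:
    """ML fit of the model without a genetic component (independent normals).

    Equivalent to OLS with the ML variance estimate RSS/n; serves as the null
    model of the heritability LRT.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Xf, names = _design(X, n)
    if n < Xf.shape[1] + 1:
        raise ValueError("too few observations for the design")
    _check_rank(Xf, names)
    beta, _, _, _ = np.linalg.lstsq(Xf, y, rcond=None)
    resid = y - Xf @ beta
    s2 = float(resid @ resid) / n
    boundary = s2 < 1e-12
    if boundary:
        s2 = max(s2, 1e-12)
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    XtX_inv = np.linalg.inv(Xf.T @ Xf)
    beta_se = np.sqrt(np.diag(XtX_inv) * s2)
    se = {nm: float(sv) for nm, sv in zip(names, beta_se)}
    se["sigma2_e"] = float(s2 * np.sqrt(2.0 / n))
    se["h2"] = 0.0
    return PolygenicFit(
        mean=float(beta[0]),
        coeffs=dict(zip(names[1:], map(float, beta[1:]))),
        sigma2_g=0.0,
        sigma2_e=s2,
        h2=0.0,
        loglik=float(ll),
        se=se,
        converged=not boundary,
        n=n,
        kind="quantitative",
        diagnostics={"boundary_sigma2e": boundary},
    )


def _quant_profile(y, Xf, U_blocks, blocks):
    """Profile-likelihood evaluator over h2 (beta and total variance profiled).

    Rotating each family block into its kinship eigenbasis makes the model a
    weighted regression with weights ``h2*d + (1-h2)``.
    """
    n = y.size
    yt = np.empty(n)
    Xt = np.empty_like(Xf)
    d_all = np.empty(n)
    pos = 0
    for idx, (d, U) in zip(blocks, U_blocks):
        m = len(idx)
        yt[pos : pos + m] = U.T @ y[idx]
        Xt[pos : pos + m] = U.T @ Xf[idx]
        d_all[pos : pos + m] = d
        pos += m

    def pieces(h2):
        w = np.maximum(h2 * d_all + (1.0 - h2), 1e-12)
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        s2 = float((r * r / w).sum()) / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + np.log(w).sum() + n)
        return ll, beta, s2, XtWX

    return pieces


def fit_polygenic_quant(y, X, K, restarts=None) -> PolygenicFit:
    """ML polygenic fit for a quantitative trait.

    Parameters
    ----------
    y : array of trait values (no missing; filter upstream)
    X : covariate design (DataFrame or array) without intercept, or None
    K : KinshipMatrix or dense relationship matrix aligned with ``y``
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Km = _as_matrix(K, n)
    eigmin = np.linalg.eigvalsh(Km).min() if n <= 2000 else None
    if eigmin is not None and eigmin < -1e-6:
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {eigmin:.3g})")
    Xf, names = _design(X, n)
    _check_rank(Xf, names)
    blocks = _blocks(Km)
    U_blocks = []
    for idx in blocks:
        d, U = np.linalg.eigh(Km[np.ix_(idx, idx)])
        U_blocks.append((np.maximum(d, 0.0), U))
    pieces = _quant_profile(y, Xf, U_blocks, blocks)

    def neg_profile(h2):
        return -pieces(h2)[0]

    res = optimize.minimize_scalar(neg_profile, bounds=(0.0, _H2_HI), method="bounded",
                                   options={"xatol": 1e-10})
    h2_hat = float(res.x)
    # the bounded minimizer can miss a boundary optimum; compare explicitly
    cand = [(neg_profile(0.0), 0.0), (neg_profile(_H2_HI), _H2_HI), (res.fun, h2_hat)]
    cand.sort(key=lambda t: t[0])
    h2_hat = cand[0][1]
    ll, beta, s2, XtWX = pieces(h2_hat)

    se = _quant_se(pieces, h2_hat, s2, XtWX, names, n)
    sigma2_g = h2_hat * s2
    sigma2_e = (1.0 - h2_hat) * s2
    return PolygenicFit(
        mean=float(beta[0]),
        coeffs=dict(zip(names[1:], map(float, beta[1:]))),
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        h2=h2_hat if h2_hat > 1e-8 else 0.0,
        loglik=float(ll),
        se=se,
        converged=bool(res.success),
        n=n,
        kind="quantitative",
        diagnostics={"h2_boundary": h2_hat <= 1e-8 or h2_hat >= _H2_HI - 1e-8},
    )


def _quant_se(pieces, h2, s2, XtWX, names, n):
    """Wald SEs from the numeric Hessian of the (h2, log sigma2_total) surface
    with beta profiled out (valid: profiling yields the Schur complement)."""

    def ll_full(theta):
        h, ls = theta
        h = min(max(h, 1e-9), _H2_HI)
        llp, _, s2p, _ = pieces(h)
        s2v = np.exp(ls)
        # un-profile the total variance: ll(h, s2) from the profiled optimum
        return llp + 0.5 * n * (np.log(s2p / s2v) + 1.0 - s2p / s2v)

    theta0 = np.array([h2, np.log(s2)])
    eps = np.array([1e-4, 1e-4])
    H = np.zeros((2, 2))
    f0 = ll_full(theta0)
    for a in range(2):
        for b in range(a, 2):
            ea = np.zeros(2); ea[a] = eps[a]
            eb = np.zeros(2); eb[b] = eps[b]
            fpp = ll_full(theta0 + ea + eb)
            fpm = ll_full(theta0 + ea - eb)
            fmp = ll_full(theta0 - ea + eb)
            fmm = ll_full(theta0 - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * eps[a] * eps[b])
    se = {nm: np.nan for nm in names}
    try:
        cov = np.linalg.inv(-H)
        if cov[0, 0] > 0:
            se["h2"] = float(np.sqrt(cov[0, 0]))
        else:
            se["h2"] = np.nan
    except np.linalg.LinAlgError:
        se["h2"] = np.nan
    # covariate SEs from the GLS information at the optimum
    try:
        covb = np.linalg.inv(XtWX) * s2
        for j, nm in enumerate(names):
            se[nm] = float(np.sqrt(covb[j, j]))
    except np.linalg.LinAlgError:
        pass
    return se


def heritability_lrt(fit0: PolygenicFit, fit1: PolygenicFit, tol=1e-6) -> LRTResult:
    """Boundary-corrected LRT of h2 = 0 (sporadic vs polygenic).

    The statistic 2*(l1 - l0) is referred to the 1/2 chi2_0 + 1/2 chi2_1
    mixture, so a boundary fit (statistic 0) yields p = 0.5.
    """
    stat = 2.0 * (fit1.loglik - fit0.loglik)
    if stat < -tol:
        raise RuntimeError(
            f"polygenic log-likelihood below sporadic by {-stat/2:.3g}: optimization failure"
        )
    stat = max(stat, 0.0)
    p = 0.5 * stats.chi2.sf(stat, df=1) if stat > 0 else 0.5
    return LRTResult(statistic=float(stat), pvalue=float(p),
                     null="h2 = 0 (boundary mixture 0.5*chi2_0 + 0.5*chi2_1)")


def h2_confint(fit: PolygenicFit, level=0.95):
    """Wald interval for h2, truncated to [0, 1]."""
    se = fit.se.get("h2")
    if se is None or not np.isfinite(se):
        raise ValueError("fit carries no h2 standard error")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, fit.h2 - z * se)
    hi = min(1.0, fit.h2 + z * se)
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# MVN rectangle probabilities (Genz separation-of-variables, scrambled Sobol)
# ---------------------------------------------------------------------------

_PHI_EPS = 1e-14


def _genz_batch(lower, upper, chol, u):
    """Rectangle-probability integrand values for one batch of QMC points.

    ``u`` has shape (npts, max(1, d-1)).  Returns per-point products.
    """
    d = len(lower)
    npts = u.shape[0]
    prod = np.ones(npts)
    y = np.zeros((npts, d))
    a0 = lower[0] / chol[0, 0]
    b0 = upper[0] / chol[0, 0]
    da = stats.norm.cdf(a0)
    db = stats.norm.cdf(b0)
    prod *= db - da
    if d == 1:
        return prod
    lo = np.full(npts, da)
    hi = np.full(npts, db)
    for i in range(1, d):
        z = lo + u[:, i - 1] * (hi - lo)
        z = np.clip(z, _PHI_EPS, 1 - _PHI_EPS)
        y[:, i - 1] = stats.norm.ppf(z)
        mu = y[:, :i] @ chol[i, :i]
        cii = chol[i, i]
        if cii <= 0:
            cii = 1e-12
        da_i = stats.norm.cdf((lower[i] - mu) / cii)
        db_i = stats.norm.cdf((upper[i] - mu) / cii)
        prod *= db_i - da_i
        if i < d - 1:
            lo, hi = da_i, db_i
    return prod


def mvn_rectangle_prob(lower, upper, corr, seed=0, n_points=8192, n_batches=8,
                       dim_cap=RECTANGLE_DIM_CAP, return_se=False):
    """P(lower < Z < upper) for Z ~ N(0, corr), by randomized QMC.

    Uses Genz's separation-of-variables transform with ``n_batches``
    independently scrambled Sobol batches; the batch spread gives the Monte
    Carlo standard error.  Deterministic for a given ``seed``.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    if d > dim_cap:
        raise ValueError(
            f"rectangle dimension {d} exceeds the cap {dim_cap}; split the "
            "family or raise dim_cap"
        )
    corr = np.asarray(corr, dtype=float)
    if d == 1:
        s = np.sqrt(corr[0, 0]) if corr.size else 1.0
        p = stats.norm.cdf(upper[0] / s) - stats.norm.cdf(lower[0] / s)
        return (float(p), 0.0) if return_se else float(p)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(corr)
        if w.min() < -1e-8:
            raise ValueError("correlation matrix is not positive semidefinite")
        chol = np.linalg.cholesky(corr + (abs(w.min()) + 1e-10) * np.eye(d))
    per = max(16, n_points // n_batches)
    ests = np.empty(n_batches)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, d])
    child = ss.spawn(n_batches)
    for b in range(n_batches):
        sob = stats.qmc.Sobol(max(1, d - 1), scramble=True, seed=np.random.default_rng(child[b]))
        u = sob.random(per)
        ests[b] = _genz_batch(lower, upper, chol, u).mean()
    p = float(ests.mean())
    se = float(ests.std(ddof=1) / np.sqrt(n_batches))
    p = min(max(p, 0.0), 1.0)
    return (p, se) if return_se else p


# ---------------------------------------------------------------------------
# Liability-threshold fit for binary traits
# ---------------------------------------------------------------------------


def _family_seed(seed, tag):
    return (int(seed) * 1000003 + zlib.crc32(str(tag).encode())) & 0x7FFFFFFF


def fit_liability_binary(d, X, K, probands=None, ids=None, seed=0,
                         n_points=256, h2_starts=(0.05, 0.5, 0.9),
                         dim_cap=RECTANGLE_DIM_CAP, fixed_h2=None,
                         fixed_zero=()) -> PolygenicFit:
    """ML liability-threshold polygenic fit for a binary trait.

    Parameters
    ----------
    d : 0/1 affection status (no missing; filter upstream)
    X : covariate design without intercept (DataFrame/array) or None
    K : KinshipMatrix or dense relationship matrix aligned with ``d``
    probands : optional set of proband ids (with ``ids`` giving row ids) or a
        boolean array; each family's likelihood is divided by the marginal
        probability of its probands' affection status (ascertainment
        correction)
    fixed_h2 : optionally pin h2 (e.g. 0 for the sporadic/probit null)
    fixed_zero : names of covariate columns constrained to coefficient 0

    The total liability variance is fixed at 1, so the fitted intercept ``m``
    is the liability threshold location: model prevalence = Phi(m) at
    reference covariate values.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if not (np.any(d == 1) and np.any(d == 0)):
        raise ValueError("both affected and unaffected individuals are required")
    Km = _as_matrix(K, n)
    Xf, names = _design(X, n)
    _check_rank(Xf, names)
    free = np.array([nm not in set(fixed_zero) for nm in names])
    blocks = [idx for idx in _blocks(Km)]
    for idx in blocks:
        if len(idx) > dim_cap:
            raise ValueError(
                f"family of size {len(idx)} exceeds the rectangle dimension cap "
                f"{dim_cap}; split the family or raise dim_cap"
            )
    pro_mask = np.zeros(n, dtype=bool)
    if probands is not None and len(probands) > 0:
        if isinstance(probands, (set, frozenset, list, tuple)) and ids is not None:
            pset = set(probands)
            pro_mask = np.array([i in pset for i in ids])
        else:
            pro_mask = np.asarray(probands, dtype=bool)

    sign = 2.0 * d - 1.0  # +1 affected, -1 unaffected
    singles = np.array([idx[0] for idx in blocks if len(idx) == 1], dtype=int)
    multis = [idx for idx in blocks if len(idx) > 1]
    u_cache = []
    for bi, idx in enumerate(multis):
        rng = np.random.default_rng(_family_seed(seed, bi))
        sob = stats.qmc.Sobol(len(idx) - 1, scramble=True, seed=rng)
        u_cache.append(sob.random(n_points))

    def negloglik(theta_free):
        beta = np.zeros(len(names))
        if fixed_h2 is None:
            beta[free] = theta_free[:-1]
            h2 = float(np.clip(theta_free[-1], 0.0, _H2_HI))
        else:
            beta[free] = theta_free
            h2 = float(fixed_h2)
        mu = Xf @ beta
        ll = 0.0
        if singles.size:
            ps = np.maximum(stats.norm.cdf(sign[singles] * mu[singles]), 1e-300)
            ll += float(np.log(ps).sum())
        for bi, idx in enumerate(multis):
            m = len(idx)
            s = sign[idx]
            R = h2 * Km[np.ix_(idx, idx)] + (1.0 - h2) * np.eye(m)
            # flip signs so every bound is a lower bound (affected pattern)
            Rf = R * np.outer(s, s)
            lowerb = -s * mu[idx]
            upperb = np.full(m, np.inf)
            try:
                chol = np.linalg.cholesky(Rf)
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(Rf + 1e-8 * np.eye(m))
            vals = _genz_batch(lowerb, upperb, chol, u_cache[bi])
            p = max(float(vals.mean()), 1e-300)
            ll += np.log(p)
        if pro_mask.any():
            pj = np.maximum(stats.norm.cdf(sign[pro_mask] * mu[pro_mask]), 1e-300)
            ll -= float(np.log(pj).sum())
        return -ll

    # warm start from an independent probit fit
    import statsmodels.api as sm

    try:
        probit = sm.Probit(d, Xf[:, free]).fit(disp=0, maxiter=100)
        beta0 = np.asarray(probit.params, dtype=float)
    except Exception:
        beta0 = np.zeros(int(free.sum()))
        beta0[0] = stats.norm.ppf(max(min(d.mean(), 1 - 1e-6), 1e-6))

    nfree = int(free.sum())
    bounds = [(-10, 10)] * nfree
    best = None
    starts = [None] if fixed_h2 is not None else list(h2_starts)
    for h2s in starts:
        if fixed_h2 is None:
            x0 = np.concatenate([beta0, [h2s]])
            bnds = bounds + [(0.0, _H2_HI)]
        else:
            x0 = beta0.copy()
            bnds = bounds
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bnds,
                                options={"maxiter": 200, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    beta_full = np.zeros(len(names))
    beta_full[free] = theta[:nfree]
    h2_hat = float(np.clip(theta[-1], 0.0, _H2_HI)) if fixed_h2 is None else float(fixed_h2)
    ll = -float(best.fun)

    se = _binary_se(negloglik, best.x, names, free, fixed_h2)
    return PolygenicFit(
        mean=float(beta_full[0]),
        coeffs=dict(zip(names[1:], map(float, beta_full[1:]))),
        sigma2_g=h2_hat,
        sigma2_e=1.0 - h2_hat,
        h2=h2_hat if h2_hat > 1e-6 else 0.0,
        loglik=ll,
        se=se,
        converged=bool(best.success),
        n=n,
        kind="binary",
        diagnostics={
            "ascertainment_corrected": bool(pro_mask.any()),
            "n_probands": int(pro_mask.sum()),
            "h2_boundary": h2_hat <= 1e-6 or h2_hat >= _H2_HI - 1e-6,
        },
    )


def _binary_se(negloglik, xhat, names, free, fixed_h2):
    k = xhat.size
    eps = 1e-4
    H = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k); ea[a] = eps
            eb = np.zeros(k); eb[b] = eps
            H[a, b] = H[b, a] = (
                negloglik(xhat + ea + eb) - negloglik(xhat + ea - eb)
                - negloglik(xhat - ea + eb) + negloglik(xhat - ea - eb)
            ) / (4 * eps * eps)
    se = {}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        free_names = [nm for nm, f in zip(names, free) if f]
        for j, nm in enumerate(free_names):
            se[nm] = float(np.sqrt(diag[j])) if diag[j] > 0 else np.nan
        if fixed_h2 is None:
            se["h2"] = float(np.sqrt(diag[-1])) if diag[-1] > 0 else np.nan
        else:
            se["h2"] = 0.0
    except np.linalg.LinAlgError:
        se = {nm: np.nan for nm in names}
        se["h2"] = np.nan
    se.setdefault("intercept", np.nan)
    se["mean"] = se.get("intercept", np.nan)
    return se
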