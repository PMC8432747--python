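"""Bivariate polygenic models: genetic/environmental correlation of trait pairs.

For two quantitative traits the stacked model is

    [y1; y2] ~ N([X b1; X b2],  G (x) K + E (x) I)

with 2x2 genetic and environmental component matrices parameterized by
(sigma2_g1, sigma2_g2, rhoG) and (sigma2_e1, sigma2_e2, rhoE).  Rotating each
family block into its kinship eigenbasis decouples the 2n-dimensional normal
into independent 2-dimensional normals with covariance ``d*G + E`` (d the
block eigenvalues), so the likelihood is cheap; the regression coefficients
are profiled out by generalized least squares at every variance-parameter
evaluation.

The implied phenotypic correlation follows the classical decomposition

    rhoP = rhoG * sqrt(h2_i * h2_j) + rhoE * sqrt((1 - h2_i)(1 - h2_j)).

Shared genetic influence (pleiotropy) is tested by refitting with rhoG
constrained to 0 and referring 2*delta-log-likelihood to chi2 with 1 df.

Quantitative x binary pairs put the binary trait on the liability scale
(residual variance 1): each family contributes the Gaussian density of the
quantitative vector times the conditional rectangle probability of the
affection pattern given those values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .varcomp import (
    LRTResult,
    _as_matrix,
    _blocks,
    _design,
    _family_seed,
    _genz_batch,
    fit_liability_binary,
    fit_polygenic_quant,
    RECTANGLE_DIM_CAP,
)

__all__ = ["BivariateFit", "fit_bivariate", "implied_rhoP", "rhoG_zero_lrt"]

_RHO_CAP = 0.999


@dataclass
class BivariateFit:
    h2_1: float
    h2_2: float
    rhoG: float
    rhoE: float
    sigma2_g: tuple
    sigma2_e: tuple
    loglik: float
    converged: bool
    n: int
    kinds: tuple
    boundary: bool = False

    @property
    def rhoP(self):
        return implied_rhoP(self)


def implied_rhoP(fit: BivariateFit) -> float:
    """Phenotypic correlation implied by the genetic/environmental split."""
    h1, h2 = fit.h2_1, fit.h2_2
    return float(
        fit.rhoG * np.sqrt(h1 * h2) + fit.rhoE * np.sqrt((1 - h1) * (1 - h2))
    )


def _prep_quant(y1, y2, X, K):
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y1.size
    if y2.size != n:
        raise ValueError("traits must have equal length")
    Km = _as_matrix(K, n)
    Xf, names = _design(X, n)
    blocks = _blocks(Km)
    d_all = np.empty(n)
    y1t = np.empty(n)
    y2t = np.empty(n)
    Xt = np.empty_like(Xf)
    pos = 0
    for idx in blocks:
        m = len(idx)
        d, U = np.linalg.eigh(Km[np.ix_(idx, idx)])
        d_all[pos : pos + m] = np.maximum(d, 0.0)
        y1t[pos : pos + m] = U.T @ y1[idx]
        y2t[pos : pos + m] = U.T @ y2[idx]
        Xt[pos : pos + m] = U.T @ Xf[idx]
        pos += m
    return y1t, y2t, Xt, d_all, n, names


def _quant_loglik(theta, y1t, y2t, Xt, d_all, n, rhoG_fixed=None):
    lg1, lg2, le1, le2, zg, ze = theta
    sg1, sg2, se1, se2 = np.exp([lg1, lg2, le1, le2])
    rg = 0.0 if rhoG_fixed is not None else _RHO_CAP * np.tanh(zg)
    re = _RHO_CAP * np.tanh(ze)
    c11 = d_all * sg1 + se1
    c22 = d_all * sg2 + se2
    c12 = d_all * rg * np.sqrt(sg1 * sg2) + re * np.sqrt(se1 * se2)
    det = c11 * c22 - c12**2
    if np.any(det <= 0):
        return np.inf, None
    w11 = c22 / det
    w22 = c11 / det
    w12 = -c12 / det
    # GLS for (b1, b2): block normal equations with scalar 2x2 weights
    A11 = Xt.T @ (Xt * w11[:, None])
    A22 = Xt.T @ (Xt * w22[:, None])
    A12 = Xt.T @ (Xt * w12[:, None])
    r1 = Xt.T @ (w11 * y1t + w12 * y2t)
    r2 = Xt.T @ (w12 * y1t + w22 * y2t)
    p = Xt.shape[1]
    A = np.block([[A11, A12], [A12, A22]])
    try:
        bb = np.linalg.solve(A, np.concatenate([r1, r2]))
    except np.linalg.LinAlgError:
        return np.inf, None
    b1, b2 = bb[:p], bb[p:]
    e1 = y1t - Xt @ b1
    e2 = y2t - Xt @ b2
    quad = w11 * e1**2 + 2 * w12 * e1 * e2 + w22 * e2**2
    ll = -0.5 * (2 * n * np.log(2 * np.pi) + np.log(det).sum() + quad.sum())
    return -ll, (b1, b2)


def fit_bivariate(y1, y2, X, K, kinds=("quantitative", "quantitative"),
                  rhoG_fixed=None, seed=0, n_points=256) -> BivariateFit:
    """ML bivariate polygenic fit.

    ``kinds`` selects the likelihood: two quantitative traits use the exact
    eigen-decoupled Gaussian likelihood; ("quantitative", "binary") treats
    ``y2`` as an affection status on the liability scale.  ``rhoG_fixed=0``
    fits the constrained (no-pleiotropy) model.
    """
    if kinds == ("quantitative", "quantitative"):
        return _fit_bivariate_quant(y1, y2, X, K, rhoG_fixed)
    if kinds == ("quantitative", "binary"):
        return _fit_bivariate_mixed(y1, y2, X, K, rhoG_fixed, seed, n_points)
    raise ValueError(f"unsupported trait-kind pair {kinds}")


def _fit_bivariate_quant(y1, y2, X, K, rhoG_fixed):
    y1t, y2t, Xt, d_all, n, names = _prep_quant(y1, y2, X, K)
    f1 = fit_polygenic_quant(np.asarray(y1, float), X, K)
    f2 = fit_polygenic_quant(np.asarray(y2, float), X, K)

    def start(h2u, s2):
        sg = max(h2u, 0.02) * s2
        se = max(1 - h2u, 0.02) * s2
        return np.log(sg), np.log(se)

    lg1, le1 = start(f1.h2, f1.sigma2_g + f1.sigma2_e)
    lg2, le2 = start(f2.h2, f2.sigma2_g + f2.sigma2_e)
    r0 = np.corrcoef(y1t - Xt @ np.linalg.lstsq(Xt, y1t, rcond=None)[0],
                     y2t - Xt @ np.linalg.lstsq(Xt, y2t, rcond=None)[0])[0, 1]
    z0 = np.arctanh(np.clip(r0, -0.9, 0.9))

    def obj(theta):
        return _quant_loglik(theta, y1t, y2t, Xt, d_all, n, rhoG_fixed)[0]

    x0 = np.array([lg1, lg2, le1, le2, 0.0 if rhoG_fixed is None else 0.0, z0])
    if rhoG_fixed is None:
        x0[4] = z0
    bounds = [(-12, 6)] * 4 + [(-5, 5)] * 2
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    lg1, lg2, le1, le2, zg, ze = res.x
    sg1, sg2, se1, se2 = np.exp([lg1, lg2, le1, le2])
    rg = 0.0 if rhoG_fixed is not None else float(_RHO_CAP * np.tanh(zg))
    re = float(_RHO_CAP * np.tanh(ze))
    boundary = max(abs(rg), abs(re)) > 0.995
    return BivariateFit(
        h2_1=float(sg1 / (sg1 + se1)),
        h2_2=float(sg2 / (sg2 + se2)),
        rhoG=rg,
        rhoE=re,
        sigma2_g=(float(sg1), float(sg2)),
        sigma2_e=(float(se1), float(se2)),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n=n,
        kinds=("quantitative", "quantitative"),
        boundary=boundary,
    )


def _fit_bivariate_mixed(yq, d, X, K, rhoG_fixed, seed, n_points):
    """Quantitative x binary pair: Gaussian density times conditional
    liability rectangle, family by family."""
    yq = np.asarray(yq, dtype=float)
    d = np.asarray(d, dtype=float)
    n = yq.size
    Km = _as_matrix(K, n)
    Xf, names = _design(X, n)
    blocks = _blocks(Km)
    for idx in blocks:
        if len(idx) > RECTANGLE_DIM_CAP:
            raise ValueError("family exceeds the rectangle dimension cap")
    sign = 2.0 * d - 1.0
    u_cache = []
    for bi, idx in enumerate(blocks):
        rng = np.random.default_rng(_family_seed(seed, bi))
        sob = stats.qmc.Sobol(max(1, len(idx) - 1), scramble=True, seed=rng)
        u_cache.append(sob.random(n_points))

    fq = fit_polygenic_quant(yq, X, K)
    fb = fit_liability_binary(d, X, Km, seed=seed, n_points=n_points)
    p = Xf.shape[1]

    def unpack(theta):
        b1 = theta[:p]
        b2 = theta[p : 2 * p]
        lg1, le1 = theta[2 * p], theta[2 * p + 1]
        h2d = float(np.clip(theta[2 * p + 2], 0.0, 0.99))
        zg, ze = theta[2 * p + 3], theta[2 * p + 4]
        rg = 0.0 if rhoG_fixed is not None else _RHO_CAP * np.tanh(zg)
        re = _RHO_CAP * np.tanh(ze)
        return b1, b2, np.exp(lg1), np.exp(le1), h2d, rg, re

    def negloglik(theta):
        b1, b2, sg1, se1, h2d, rg, re = unpack(theta)
        mu1 = Xf @ b1
        mu2 = Xf @ b2
        ll = 0.0
        for bi, idx in enumerate(blocks):
            m = len(idx)
            Kb = Km[np.ix_(idx, idx)]
            S11 = sg1 * Kb + se1 * np.eye(m)
            S22 = h2d * Kb + (1 - h2d) * np.eye(m)
            S12 = rg * np.sqrt(sg1 * h2d) * Kb + re * np.sqrt(se1 * (1 - h2d)) * np.eye(m)
            try:
                c = np.linalg.cholesky(S11)
            except np.linalg.LinAlgError:
                return np.inf
            r1 = yq[idx] - mu1[idx]
            alpha = np.linalg.solve(S11, r1)
            ll += -0.5 * (m * np.log(2 * np.pi) + 2 * np.log(np.diag(c)).sum()
                          + r1 @ alpha)
            cmu = mu2[idx] + S12 @ alpha
            ccov = S22 - S12 @ np.linalg.solve(S11, S12)
            s = sign[idx]
            Rf = ccov * np.outer(s, s)
            lowerb = -s * cmu
            try:
                cc = np.linalg.cholesky(Rf)
            except np.linalg.LinAlgError:
                cc = np.linalg.cholesky(Rf + 1e-8 * np.eye(m))
            if m == 1:
                pr = stats.norm.cdf(-lowerb[0] / max(cc[0, 0], 1e-12))
            else:
                pr = float(_genz_batch(lowerb, np.full(m, np.inf), cc, u_cache[bi]).mean())
            ll += np.log(max(pr, 1e-300))
        return -ll

    x0 = np.zeros(2 * p + 5)
    x0[0] = fq.mean
    x0[1:p] = [fq.coeffs.get(nm, 0.0) for nm in names[1:]]
    x0[p] = fb.mean
    x0[p + 1 : 2 * p] = [fb.coeffs.get(nm, 0.0) for nm in names[1:]]
    x0[2 * p] = np.log(max(fq.sigma2_g, 1e-3))
    x0[2 * p + 1] = np.log(max(fq.sigma2_e, 1e-3))
    x0[2 * p + 2] = max(fb.h2, 0.05)
    bounds = ([(-10, 10)] * (2 * p) + [(-12, 6)] * 2 + [(0.0, 0.99)]
              + [(-5, 5)] * 2)
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 300, "ftol": 1e-9})
    b1, b2, sg1, se1, h2d, rg, re = unpack(res.x)
    return BivariateFit(
        h2_1=float(sg1 / (sg1 + se1)),
        h2_2=float(h2d),
        rhoG=float(rg),
        rhoE=float(re),
        sigma2_g=(float(sg1), float(h2d)),
        sigma2_e=(float(se1), float(1 - h2d)),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n=n,
        kinds=("quantitative", "binary"),
        boundary=max(abs(rg), abs(re)) > 0.995,
    )


def rhoG_zero_lrt(y1, y2, X, K, kinds=("quantitative", "quantitative"),
                  seed=0, n_points=256):
    """Pleiotropy test: unconstrained vs rhoG = 0 bivariate fit, chi2_1."""
    full = fit_bivariate(y1, y2, X, K, kinds=kinds, seed=seed, n_points=n_points)
    null = fit_bivariate(y1, y2, X, K, kinds=kinds, rhoG_fixed=0.0,
                         seed=seed, n_points=n_points)
    stat = 2.0 * (full.loglik - null.loglik)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return LRTResult(statistic=float(stat), pvalue=p, null="rhoG = 0"), full, null
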