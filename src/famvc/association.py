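"""Polygenic association of quantitative traits with a binary disease.

The disease is modelled on the liability scale (probit link with a polygenic
random effect); trait effects are per standard deviation of the
inverse-normalized trait.  Odds ratios follow the convention OR = exp(pi *
beta) applied to the risk-positive-oriented probit coefficient, and the
model's threshold parameter maps to a population prevalence through the
standard normal CDF.  Screening follows a two-stage scheme: fit the full
joint model, compute a constraint (likelihood-ratio) p-value per trait, carry
traits with p below a threshold into a refitted final model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .varcomp import PolygenicFit, fit_liability_binary

__all__ = [
    "AssociationResult",
    "covariate_pvalue_by_constraint",
    "screen_and_refit",
    "odds_ratio_from_probit",
    "prevalence_from_threshold",
    "prevalence_from_fit",
    "bonferroni",
]


@dataclass
class AssociationResult:
    trait: str
    beta: float
    beta_se: float
    odds_ratio: float
    or_low: float
    or_high: float
    pvalue: float
    stage: str  # "screen" or "final"


def covariate_pvalue_by_constraint(full_fit: PolygenicFit, d, X, K, covariate,
                                   probands=None, ids=None, seed=0,
                                   n_points=256, **fit_kw) -> float:
    """LRT p-value for one covariate: refit with its coefficient pinned at 0.

    The statistic 2*(l_full - l_constrained) is referred to chi2 with 1 df
    (the constrained coefficient is interior, unlike the h2 boundary test).
    """
    names = list(X.columns) if hasattr(X, "columns") else None
    if names is None or covariate not in names:
        raise KeyError(f"covariate {covariate!r} not in the model design")
    null_fit = fit_liability_binary(
        d, X, K, probands=probands, ids=ids, seed=seed, n_points=n_points,
        fixed_zero=(covariate,), **fit_kw
    )
    stat = 2.0 * (full_fit.loglik - null_fit.loglik)
    if not null_fit.converged and stat < 0:
        return float("nan")
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df=1))


def screen_and_refit(traits: pd.DataFrame, d, X, K, threshold=0.1,
                     probands=None, ids=None, seed=0, n_points=256,
                     sign_convention="reporting-positive", **fit_kw):
    """Two-stage polygenic screen of ``traits`` against the disease ``d``.

    Stage 1 fits the joint liability model with all candidate traits (plus
    the fixed covariates in ``X``) and computes a constraint p-value per
    trait; traits with p < ``threshold`` enter the final refit whose odds
    ratios (with 95% CIs) are reported.

    Returns ``(screen_results, final_results)`` lists of
    :class:`AssociationResult`.
    """
    trait_names = list(traits.columns)
    Xall = pd.concat([traits, X], axis=1) if X is not None else traits.copy()
    full = fit_liability_binary(d, Xall, K, probands=probands, ids=ids,
                                seed=seed, n_points=n_points, **fit_kw)
    screen = []
    for t in trait_names:
        p = covariate_pvalue_by_constraint(full, d, Xall, K, t,
                                           probands=probands, ids=ids,
                                           seed=seed, n_points=n_points, **fit_kw)
        beta = full.coeffs[t]
        se = full.se.get(t, float("nan"))
        orr, lo, hi = odds_ratio_from_probit(beta, sign_convention, se=se)
        screen.append(AssociationResult(t, beta, se, orr, lo, hi, p, "screen"))

    kept = [r.trait for r in screen if np.isfinite(r.pvalue) and r.pvalue < threshold]
    final = []
    if kept:
        Xfin = pd.concat([traits[kept], X], axis=1) if X is not None else traits[kept]
        fin = fit_liability_binary(d, Xfin, K, probands=probands, ids=ids,
                                   seed=seed, n_points=n_points, **fit_kw)
        for t in kept:
            p = covariate_pvalue_by_constraint(fin, d, Xfin, K, t,
                                               probands=probands, ids=ids,
                                               seed=seed, n_points=n_points, **fit_kw)
            beta = fin.coeffs[t]
            se = fin.se.get(t, float("nan"))
            orr, lo, hi = odds_ratio_from_probit(beta, sign_convention, se=se)
            final.append(AssociationResult(t, beta, se, orr, lo, hi, p, "final"))
    return screen, final


def odds_ratio_from_probit(beta, sign_convention="reporting-positive", se=None,
                           level=0.95):
    """OR = exp(pi * beta*) from a liability-scale probit coefficient.

    ``sign_convention`` states how ``beta`` is oriented: "reporting-positive"
    means a positive beta already indicates higher disease liability;
    "reporting-negative" is the convention of software that returns a
    negative coefficient for a positively associated covariate, so the sign
    is flipped before exponentiation.  With ``se`` given, a Wald CI on the
    beta scale is transformed through the same map.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    b = -beta if sign_convention == "reporting-negative" else beta
    orr = math.exp(math.pi * b)
    if se is None or not np.isfinite(se):
        return orr, float("nan"), float("nan")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = math.exp(math.pi * (b - z * se))
    hi = math.exp(math.pi * (b + z * se))
    return orr, lo, hi


def odds_ratio_probit_to_logit(beta):
    """Textbook probit-to-logit comparison value exp(beta * pi / sqrt(3)).

    The reporting convention above uses exp(pi*beta); the usual
    scale-matching factor between probit and logistic coefficients is
    pi/sqrt(3) ~= 1.814, not pi.  Both are exposed so the discrepancy between
    the two conventions can be quantified for any coefficient.
    """
    return math.exp(beta * math.pi / math.sqrt(3.0))


def prevalence_from_threshold(m, se=None, level=0.95):
    """Population prevalence implied by a liability threshold ``m``.

    ``m`` is the threshold-convention location (higher threshold = rarer
    disease): prevalence = Phi(-m).  With ``se``, the Wald interval of m is
    transformed through the same monotone map (bounds swap order).
    """
    prev = float(stats.norm.cdf(-m))
    if se is None:
        return prev
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(stats.norm.cdf(-(m + z * se)))
    hi = float(stats.norm.cdf(-(m - z * se)))
    return prev, lo, hi


def prevalence_from_fit(fit: PolygenicFit, level=0.95):
    """Prevalence (with CI) from a fitted liability model.

    The fit's intercept is the liability mean with the threshold at zero, so
    the threshold-convention location is ``-fit.mean``.
    """
    se = fit.se.get("intercept")
    return prevalence_from_threshold(-fit.mean, se=se, level=level)


def bonferroni(p, m_tests):
    """Bonferroni correction: min(1, p * m_tests), elementwise."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    out = np.minimum(1.0, p * m_tests)
    return float(out) if out.ndim == 0 else out
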