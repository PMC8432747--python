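"""Factor analysis of measured anthropometric traits.

Principal-factor extraction (iterated communalities on the reduced
correlation matrix) with the eigenvalue > 1 retention rule and varimax
rotation.  Derived ratio/composite traits should be excluded by the caller
before extraction — including near-deterministic functions of other traits
invites Heywood cases (communalities above 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = ["FactorSolution", "extract_factors", "varimax_rotate"]


@dataclass
class FactorSolution:
    loadings: pd.DataFrame  # traits x factors
    uniqueness: pd.Series
    eigenvalues: np.ndarray
    n_factors: int
    variance_explained: np.ndarray
    rotation: str  # "none" or "varimax"
    heywood: bool = False

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def total_variance_share(self) -> float:
        """Share of the summed communalities captured (relative to traits)."""
        return float(self.variance_explained.sum() / len(self.uniqueness))


def extract_factors(traits: pd.DataFrame, max_iter=50, tol=1e-4,
                    eig_tol=1e-8) -> FactorSolution:
    """Principal-factor extraction with the eigenvalue > 1 rule.

    Complete-case Pearson correlations; communalities start at squared
    multiple correlations and are iterated on the reduced correlation matrix
    (diagonal replaced by communalities) until stable.  Factors are retained
    while the reduced-matrix eigenvalue exceeds 1 (tolerance ``eig_tol``).
    A communality exceeding 1 (Heywood case) stops the iteration at the last
    valid step and flags the solution.
    """
    data = traits.dropna()
    names = list(traits.columns)
    R = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    eigR = np.linalg.eigvalsh(R)
    if eigR.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")

    p = R.shape[0]
    # squared multiple correlations as starting communalities
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 0.995)

    heywood = False
    loadings = None
    eigvals = None
    n_factors = 0
    prev_h2 = h2.copy()
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        k = int(np.sum(w > 1.0 + eig_tol))
        if k == 0:
            loadings = np.empty((p, 0))
            eigvals = w
            n_factors = 0
            break
        L = V[:, :k] * np.sqrt(np.maximum(w[:k], 0.0))
        new_h2 = (L**2).sum(axis=1)
        if np.any(new_h2 > 1.0):
            heywood = True
            warnings.warn("Heywood case: communality > 1; stopping at last valid step")
            break
        loadings, eigvals, n_factors = L, w, k
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        prev_h2, h2 = h2, new_h2
    if loadings is None:  # Heywood on the very first step
        Rr = R.copy()
        np.fill_diagonal(Rr, prev_h2)
        w, V = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        k = max(int(np.sum(w > 1.0 + eig_tol)), 1)
        loadings = V[:, :k] * np.sqrt(np.maximum(w[:k], 0.0))
        eigvals, n_factors = w, k

    comm = (loadings**2).sum(axis=1)
    uniq = np.clip(1.0 - comm, 0.0, 1.0)
    var_exp = (loadings**2).sum(axis=0)
    return FactorSolution(
        loadings=pd.DataFrame(loadings, index=names,
                              columns=[f"factor{j+1}" for j in range(n_factors)]),
        uniqueness=pd.Series(uniq, index=names),
        eigenvalues=eigvals,
        n_factors=n_factors,
        variance_explained=var_exp,
        rotation="none",
        heywood=heywood,
    )


def varimax_rotate(solution: FactorSolution) -> FactorSolution:
    """Varimax-rotate a factor solution (identity for < 2 factors).

    Orthogonal rotation leaves communalities, uniqueness and the total
    variance explained unchanged; only the per-factor split moves.
    """
    if solution.n_factors < 2:
        return FactorSolution(
            loadings=solution.loadings.copy(),
            uniqueness=solution.uniqueness.copy(),
            eigenvalues=solution.eigenvalues,
            n_factors=solution.n_factors,
            variance_explained=solution.variance_explained.copy(),
            rotation="varimax",
            heywood=solution.heywood,
        )
    L = solution.loadings.to_numpy()
    Lrot, T = rotate_factors(L, "varimax")
    # canonical orientation: dominant sign positive, factors by variance
    signs = np.sign(Lrot.sum(axis=0))
    signs[signs == 0] = 1.0
    Lrot = Lrot * signs
    var_exp = (Lrot**2).sum(axis=0)
    order = np.argsort(var_exp)[::-1]
    Lrot = Lrot[:, order]
    var_exp = var_exp[order]
    return FactorSolution(
        loadings=pd.DataFrame(Lrot, index=solution.loadings.index,
                              columns=[f"factor{j+1}" for j in range(solution.n_factors)]),
        uniqueness=solution.uniqueness.copy(),
        eigenvalues=solution.eigenvalues,
        n_factors=solution.n_factors,
        variance_explained=var_exp,
        rotation="varimax",
        heywood=solution.heywood,
    )


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of the variance of squared
    loadings (used by tests to compare rotations)."""
    L2 = L**2
    return float(np.sum(L2.var(axis=0)))
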