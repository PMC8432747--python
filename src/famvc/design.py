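"""Study-design calculations for family-based heritability studies.

Two closed-form quantities: the GREML-style post-hoc power to detect a
target heritability given the variance of genetic relatedness among the
sampled individuals, and the one-sample normal-approximation sample size to
detect an elevated disease prevalence against a reference proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "greml_power", "prevalence_sample_size"]


@dataclass
class PowerSpec:
    n: int
    var_pi: float  # variance of pairwise genetic relatedness
    h2_target: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.var_pi <= 0:
            raise ValueError("var_pi must be positive")
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def greml_power(spec: PowerSpec) -> float:
    """Power to detect h2 > 0 from relatedness variation.

    The sampling standard error of the REML heritability estimate is
    approximately ``sqrt(2 / (n^2 * var_pi))``; power is the normal tail
    probability ``Phi(h2/SE - z_{1-alpha/2})`` (two-sided test).
    """
    se = math.sqrt(2.0 / (spec.n**2 * spec.var_pi))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(spec.h2_target / se - z))


def prevalence_sample_size(p0: float, p1: float, alpha: float = 0.05,
                           power: float = 0.80) -> int:
    """One-sample size to detect proportion ``p1`` against reference ``p0``.

    n = ceil((z_{1-a/2} sqrt(p0 q0) + z_{1-b} sqrt(p1 q1))^2 / (p1 - p0)^2)
    """
    if not 0 < p0 < 1 or not 0 < p1 < 1:
        raise ValueError("proportions must lie in (0, 1)")
    if p1 <= p0:
        raise ValueError("p1 must exceed p0")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    num = (za * math.sqrt(p0 * (1 - p0)) + zb * math.sqrt(p1 * (1 - p1))) ** 2
    return int(math.ceil(num / (p1 - p0) ** 2))
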