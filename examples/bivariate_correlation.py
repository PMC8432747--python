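"""Decompose a trait-trait correlation into genetic and environmental parts.

Two traits are simulated with genetic correlation 0.6 and environmental
correlation 0.2.  The bivariate polygenic fit recovers both, and the implied
phenotypic correlation rhoP = rhoG*sqrt(h2_i h2_j) +
rhoE*sqrt((1-h2_i)(1-h2_j)) matches the raw Pearson correlation.  The
pleiotropy test constrains rhoG to 0 and refers 2*delta-log-likelihood to
chi-square(1).
"""

import numpy as np

from famvc import TraitSpec, default_config, generate_phenotypes, kinship_matrix
from famvc import rhoG_zero_lrt, simulate_pedigree_set

rg = np.eye(3); rg[0, 1] = rg[1, 0] = 0.6
re = np.eye(3); re[0, 1] = re[1, 0] = 0.2
cfg = default_config(n_families=100, seed=21,
                     traits=[TraitSpec("a", 0.5), TraitSpec("b", 0.4)],
                     rhoG=rg, rhoE=re)
ped = simulate_pedigree_set(cfg)
_, panel = generate_phenotypes(ped, cfg)
kin = kinship_matrix(ped)

lrt, fit, _ = rhoG_zero_lrt(panel["a"].to_numpy(), panel["b"].to_numpy(),
                            None, kin.values)
print(f"rhoG = {fit.rhoG:.2f} (true 0.6)   rhoE = {fit.rhoE:.2f} (true 0.2)")
print(f"h2: {fit.h2_1:.2f}, {fit.h2_2:.2f} (true 0.5, 0.4)")
print(f"implied rhoP = {fit.rhoP:.2f}; empirical = "
      f"{np.corrcoef(panel['a'], panel['b'])[0, 1]:.2f}")
print(f"rhoG=0 test: chi2 = {lrt.statistic:.1f}, p = {lrt.pvalue:.2e}")
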