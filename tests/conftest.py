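import numpy as np
import pandas as pd
import pytest

from famvc.pedigree import pedigree_from_frame


def nuclear_plus(m):
    """Relationship matrix for a 2-founder family with m-2 full-sib children."""
    K = np.eye(m)
    for i in range(2, m):
        K[0, i] = K[i, 0] = 0.5
        K[1, i] = K[i, 1] = 0.5
        for j in range(2, i):
            K[i, j] = K[j, i] = 0.5
    return K


@pytest.fixture(scope="session")
def three_gen_pedigree():
    """8 members, 3 generations: grandparents, their sons f and u, f's wife m,
    f x m children c1, c2, and an unrelated founder n."""
    df = pd.DataFrame(
        {
            "id": ["gf", "gm", "f", "m", "c1", "c2", "u", "n"],
            "father": [None, None, "gf", None, "f", "f", "gf", None],
            "mother": [None, None, "gm", None, "m", "m", "gm", None],
            "sex": ["male", "female", "male", "female", "male", "female", "male", "male"],
            "family": ["A"] * 8,
        }
    )
    return pedigree_from_frame(df)


@pytest.fixture(scope="session")
def sib_design():
    """100 families x 10 members (2 founders + 8 full sibs) as a block matrix."""
    from scipy.linalg import block_diag

    Kf = nuclear_plus(10)
    return Kf, block_diag(*[Kf] * 100)


def simulate_polygenic(rng, Kf, n_fam, h2, n_traits=1, rho_g=None, rho_e=None):
    """Draw unit-variance polygenic trait(s) on n_fam copies of family block Kf."""
    m = Kf.shape[0]
    L = np.linalg.cholesky(Kf + 1e-12 * np.eye(m))
    if n_traits == 1:
        g = np.concatenate([L @ rng.standard_normal(m) for _ in range(n_fam)])
        e = rng.standard_normal(n_fam * m)
        return np.sqrt(h2) * g + np.sqrt(1 - h2) * e
    h2 = np.atleast_1d(h2)
    G = rho_g * np.sqrt(np.outer(h2, h2))
    E = rho_e * np.sqrt(np.outer(1 - h2, 1 - h2))
    MG = np.linalg.cholesky(G + 1e-12 * np.eye(n_traits))
    ME = np.linalg.cholesky(E + 1e-12 * np.eye(n_traits))
    cols = []
    for _ in range(n_fam):
        g = (L @ rng.standard_normal((m, n_traits))) @ MG.T
        e = rng.standard_normal((m, n_traits)) @ ME.T
        cols.append(g + e)
    return np.vstack(cols)
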