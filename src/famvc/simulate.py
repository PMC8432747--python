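"""Synthetic extended-family study fixtures with known ground truth.

Generates multi-generation pedigrees, correlated additive polygenic
quantitative traits, a liability-threshold disease, covariates, and
proband-based ascertainment, echoing every generating parameter so the
analysis pipeline can be validated against truth.

Genetic effects are drawn per family as ``L Z M_G'`` with ``L`` the Cholesky
factor of the family's expected additive relationship block and ``M_G`` the
Cholesky factor of the genetic component matrix ``G`` (equivalent in
distribution to gene dropping for additive effects, and exact);
environmental effects use the identity in place of ``L``.  Each trait has
unit total variance on the standardized scale before covariate effects and
is then mapped to its natural units by sex-specific location/scale.

The disease is one more column of the joint panel: its standardized value is
a liability, and affection means liability above ``Phi^{-1}(1 - K)`` for
configured prevalence ``K``.  Genetic sharing between the disease and named
quantitative traits enters through the joint genetic correlation matrix.

Ascertainment modes:

``single-proband`` (default)
    Families enter the sample through a proband: a family's retention
    probability is proportional to its number of affected members (the
    classic single-ascertainment limit) and the proband is a random affected
    member.  The proband status-conditioning correction is consistent under
    exactly this sampling.
``complete``
    Every family with at least one affected member is retained and the first
    affected member is recorded as proband.  Note that status conditioning
    over-corrects under this design; it is provided for sensitivity checks.
``none``
    No selection, no probands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, pedigree_from_frame, kinship_matrix

__all__ = [
    "TraitSpec",
    "SimConfig",
    "default_config",
    "simulate_pedigree_set",
    "simulate_quant_traits",
    "simulate_binary_trait",
    "generate_phenotypes",
    "ascertain_families",
    "generate_study_fixture",
]


@dataclass
class TraitSpec:
    name: str
    h2: float
    female_mean: float = 0.0
    female_sd: float = 1.0
    male_mean: float = 0.0
    male_sd: float = 1.0
    age_slope: float = 0.0  # per year of (age - 48), on the standardized scale
    positive: bool = False  # clip natural-scale values to be strictly positive


# Trait panel mimicking an anthropometric + glycemic family study:
# 13 measured anthropometrics and 5 quantitative glycemic traits, with
# heritabilities in the range such studies report, plus sex-specific
# location/scale for natural units.
DEFAULT_TRAITS = [
    TraitSpec("height", 0.73, 152.51, 6.55, 166.80, 7.54, 0.0, True),
    TraitSpec("weight", 0.52, 68.58, 13.38, 77.52, 14.68, 0.01, True),
    TraitSpec("muac", 0.20, 29.35, 4.17, 29.07, 3.87, 0.01, True),
    TraitSpec("waist", 0.49, 92.83, 12.76, 94.62, 11.86, 0.01, True),
    TraitSpec("hip", 0.49, 104.30, 10.79, 100.81, 8.82, 0.01, True),
    TraitSpec("calf_circ", 0.39, 33.67, 4.17, 33.92, 3.69, 0.01, True),
    TraitSpec("sft_biceps", 0.40, 17.17, 7.67, 12.92, 6.80, 0.01, True),
    TraitSpec("sft_triceps", 0.39, 26.57, 6.91, 19.81, 7.20, 0.01, True),
    TraitSpec("sft_subscapular", 0.29, 30.64, 9.92, 28.43, 10.02, 0.01, True),
    TraitSpec("sft_abdominal", 0.28, 36.04, 11.09, 37.66, 11.72, 0.01, True),
    TraitSpec("sft_suprailiac", 0.29, 31.79, 10.21, 29.51, 12.02, 0.01, True),
    TraitSpec("sft_medialcalf", 0.40, 24.97, 9.70, 25.07, 9.94, 0.01, True),
    TraitSpec("sft_lateralcalf", 0.38, 29.37, 8.86, 25.67, 9.21, 0.01, True),
    TraitSpec("fpg", 0.21, 101.95, 42.17, 101.95, 42.17, 0.02, True),
    TraitSpec("rbg", 0.24, 125.43, 50.76, 125.43, 50.76, 0.02, True),
    TraitSpec("fpi", 0.10, 13.84, 6.04, 13.84, 6.04, 0.0, True),
    TraitSpec("scp", 0.06, 2.84, 2.0, 2.84, 2.0, 0.0, True),
    TraitSpec("hba1c", 0.16, 6.06, 1.29, 6.06, 1.29, 0.02, True),
]

DISEASE = "t2d"

# Latent-factor loadings generating the default genetic correlation matrix:
# a body-size factor, an adiposity factor, and a disease-liability factor.
# rho = Lambda Lambda'; the construction guarantees positive semidefiniteness
# and reproduces the headline cross-trait values (e.g. biceps skinfold x
# disease genetic correlation 0.77).
_G_FACTORS = {
    #                 size  adip  disease
    "height":         (0.45, 0.00, 0.00),
    "weight":         (0.70, 0.30, 0.10),
    "muac":           (0.50, 0.30, 0.00),
    "waist":          (0.60, 0.30, 0.343),
    "hip":            (0.60, 0.30, 0.10),
    "calf_circ":      (0.50, 0.30, 0.00),
    "sft_biceps":     (0.10, 0.40, 0.880),
    "sft_triceps":    (0.10, 0.60, 0.10),
    "sft_subscapular":(0.10, 0.60, 0.20),
    "sft_abdominal":  (0.10, 0.60, 0.430),
    "sft_suprailiac": (0.10, 0.60, 0.35),
    "sft_medialcalf": (0.10, 0.60, 0.35),
    "sft_lateralcalf":(0.10, 0.60, 0.10),
    "fpg":            (0.00, 0.10, 0.60),
    "rbg":            (0.00, 0.10, 0.60),
    "fpi":            (0.00, 0.20, 0.40),
    "scp":            (0.00, 0.10, 0.30),
    "hba1c":          (0.00, 0.10, 0.60),
    DISEASE:          (0.00, 0.00, 0.875),
}

_E_FACTORS = {
    # one shared environmental factor plus a disease-environment factor with
    # negative loadings for the skinfolds that show negative rhoE
    "height":         (0.20, 0.00),
    "weight":         (0.50, 0.10),
    "muac":           (0.40, 0.00),
    "waist":          (0.50, 0.20),
    "hip":            (0.45, 0.05),
    "calf_circ":      (0.40, 0.00),
    "sft_biceps":     (0.35, -0.21),
    "sft_triceps":    (0.40, 0.00),
    "sft_subscapular":(0.40, 0.15),
    "sft_abdominal":  (0.40, 0.05),
    "sft_suprailiac": (0.40, 0.05),
    "sft_medialcalf": (0.35, -0.23),
    "sft_lateralcalf":(0.35, 0.00),
    "fpg":            (0.10, 0.40),
    "rbg":            (0.10, 0.40),
    "fpi":            (0.10, 0.30),
    "scp":            (0.05, 0.20),
    "hba1c":          (0.10, 0.40),
    DISEASE:          (0.00, 0.90),
}


def _corr_from_factors(names, table):
    lam = np.array([table[n] for n in names], dtype=float)
    rho = lam @ lam.T
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class SimConfig:
    n_families: int = 112
    family_size_min: int = 3
    family_size_cap: int = 20
    family_size_mean: float = 10.3
    generations: int = 3
    traits: list = field(default_factory=lambda: list(DEFAULT_TRAITS))
    rhoG: np.ndarray | None = None  # (n_traits+1) incl. disease, or None
    rhoE: np.ndarray | None = None
    prevalence: float = 0.35
    disease_h2: float = 0.35
    ascertainment: str = "single-proband"  # or "complete", "none"
    female_prob: float = 0.59
    smoking_prob: float = 0.04
    missing_prob: float = 0.0
    seed: int = 0

    def trait_names(self):
        return [t.name for t in self.traits]

    def panel_names(self):
        return self.trait_names() + [DISEASE]

    def resolve_corr(self):
        names = self.panel_names()
        rg = self.rhoG if self.rhoG is not None else _corr_from_factors(names, _G_FACTORS)
        re = self.rhoE if self.rhoE is not None else _corr_from_factors(names, _E_FACTORS)
        for label, r in (("rhoG", rg), ("rhoE", re)):
            r = np.asarray(r, dtype=float)
            if r.shape != (len(names), len(names)):
                raise ValueError(f"{label} must be {len(names)}x{len(names)}")
            if np.linalg.eigvalsh(r).min() < -1e-8:
                raise ValueError(f"{label} matrix is not positive semidefinite")
        return np.asarray(rg, float), np.asarray(re, float)

    def validate(self):
        if self.family_size_min < 3 or self.family_size_cap < self.family_size_min:
            raise ValueError("family sizes must satisfy 3 <= min <= cap")
        if not (self.family_size_min <= self.family_size_mean <= self.family_size_cap):
            raise ValueError("family_size_mean outside [min, cap]: infeasible")
        if not 2 <= self.generations <= 4:
            raise ValueError("generations must be 2-4")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for t in self.traits:
            if not 0 <= t.h2 < 1:
                raise ValueError(f"trait {t.name}: h2 must lie in [0, 1)")
        if not 0 <= self.disease_h2 < 1:
            raise ValueError("disease_h2 must lie in [0, 1)")
        self.resolve_corr()
        return self


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides).validate()


# ---------------------------------------------------------------------------
# Pedigree generation
# ---------------------------------------------------------------------------


def _draw_family_size(rng, cfg: SimConfig) -> int:
    # lognormal-ish right-skew truncated to [min, cap]
    mu = np.log(cfg.family_size_mean) - 0.125
    for _ in range(1000):
        s = int(round(rng.lognormal(mu, 0.5)))
        if cfg.family_size_min <= s <= cfg.family_size_cap:
            return s
    raise ValueError("family-size distribution infeasible under the bounds")


def _build_family(rng, cfg: SimConfig, fam_id: str):
    size = _draw_family_size(rng, cfg)
    rows = []
    counter = [0]

    def new_id():
        counter[0] += 1
        return f"{fam_id}_{counter[0]}"

    def add(father, mother, sex, gen):
        iid = new_id()
        rows.append({"id": iid, "father": father, "mother": mother,
                     "sex": sex, "family": fam_id, "generation": gen})
        return iid

    f0 = add(None, None, "male", 0)
    m0 = add(None, None, "female", 0)
    frontier = [(f0, m0, 0)]
    couples = [(f0, m0, 0)]
    while len(rows) < size:
        if frontier:
            father, mother, gen = frontier.pop(0)
            n_kids = min(1 + rng.poisson(1.6), size - len(rows))
        else:
            # drawn size not yet reached: extend an existing sibship
            father, mother, gen = couples[rng.integers(len(couples))]
            n_kids = 1
        kids = []
        for _ in range(n_kids):
            sex = "female" if rng.random() < cfg.female_prob else "male"
            kids.append((add(father, mother, sex, gen + 1), sex))
        for kid, sex in kids:
            if len(rows) >= size or gen + 1 >= cfg.generations - 1:
                continue
            if rng.random() < 0.6:  # kid marries in a spouse (new founder)
                spouse_sex = "male" if sex == "female" else "female"
                spouse = add(None, None, spouse_sex, gen + 1)
                couple = (kid, spouse) if sex == "male" else (spouse, kid)
                frontier.append((*couple, gen + 1))
                couples.append((*couple, gen + 1))
    return rows


def simulate_pedigree_set(cfg: SimConfig) -> Pedigree:
    """Generate ``cfg.n_families`` extended families (deterministic per seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for f in range(cfg.n_families):
        rows.extend(_build_family(rng, cfg, f"F{f+1:03d}"))
    df = pd.DataFrame(rows).drop(columns=["generation"])
    df["phenotyped"] = True
    if cfg.missing_prob > 0:
        df["phenotyped"] = rng.random(len(df)) >= cfg.missing_prob
    return pedigree_from_frame(df)


# ---------------------------------------------------------------------------
# Phenotype generation
# ---------------------------------------------------------------------------


def _simulate_panel(ped: Pedigree, cfg: SimConfig, rng) -> pd.DataFrame:
    """Joint standardized panel (all quantitative traits + disease liability)."""
    names = cfg.panel_names()
    h2 = np.array([t.h2 for t in cfg.traits] + [cfg.disease_h2])
    rg, re = cfg.resolve_corr()
    G = rg * np.sqrt(np.outer(h2, h2))
    E = re * np.sqrt(np.outer(1 - h2, 1 - h2))
    MG = np.linalg.cholesky(G + 1e-10 * np.eye(len(names)))
    ME = np.linalg.cholesky(E + 1e-10 * np.eye(len(names)))

    kin = kinship_matrix(ped)
    values = np.empty((ped.n, len(names)))
    t = ped.table
    pos_of = {iid: i for i, iid in enumerate(ped.ids)}
    for fam in ped.families:
        members = ped.family_members(fam)
        idx = [pos_of[i] for i in members]
        Kb = kin.submatrix(members)
        L = np.linalg.cholesky(Kb + 1e-10 * np.eye(len(idx)))
        Zg = rng.standard_normal((len(idx), len(names)))
        Ze = rng.standard_normal((len(idx), len(names)))
        values[idx] = (L @ Zg) @ MG.T + Ze @ ME.T
    return pd.DataFrame(values, columns=names, index=ped.ids)


def _covariate_frame(ped: Pedigree, cfg: SimConfig, rng) -> pd.DataFrame:
    t = ped.table
    gen = t["generation"].to_numpy()
    age = np.empty(ped.n)
    top = int(gen.max()) if ped.n else 0
    # founders oldest; each later generation ~27 years younger
    base = rng.uniform(62, 80, size=ped.n)
    age = base - 27.0 * gen + rng.normal(0, 4, size=ped.n)
    age = np.clip(age, 20.0, 95.0)
    sex = t["sex"].to_numpy()
    hb = np.where(sex == "female",
                  rng.normal(12.1, 1.3, ped.n),
                  rng.normal(13.2, 1.5, ped.n))
    smoking = rng.random(ped.n) < cfg.smoking_prob
    return pd.DataFrame(
        {"age": np.round(age, 1), "sex": sex, "hemoglobin": np.round(hb, 2),
         "smoking": smoking.astype(int)},
        index=ped.ids,
    )


def generate_phenotypes(ped: Pedigree, cfg: SimConfig):
    """Full phenotype table (natural units) plus the standardized panel.

    Returns ``(pheno, panel)``: ``pheno`` holds one row per individual with
    id, family, covariates, natural-scale traits and disease status; ``panel``
    is the underlying standardized joint draw (incl. the disease liability).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 17]))
    panel = _simulate_panel(ped, cfg, rng)
    cov = _covariate_frame(ped, cfg, rng)
    out = pd.DataFrame({"id": ped.ids, "family": ped.table["family"].to_numpy()},
                       index=ped.ids)
    out = pd.concat([out, cov], axis=1)
    age_c = cov["age"].to_numpy() - 48.0
    female = (cov["sex"] == "female").to_numpy()
    for spec in cfg.traits:
        z = panel[spec.name].to_numpy() + spec.age_slope * age_c
        mean = np.where(female, spec.female_mean, spec.male_mean)
        sd = np.where(female, spec.female_sd, spec.male_sd)
        vals = mean + sd * z
        if spec.positive:
            vals = np.maximum(vals, 0.05 * np.abs(mean) + 0.01)
        out[spec.name] = np.round(vals, 2)
    thr = stats.norm.ppf(1.0 - cfg.prevalence)
    out[DISEASE] = (panel[DISEASE].to_numpy() > thr).astype(int)
    return out, panel


def simulate_quant_traits(ped: Pedigree, cfg: SimConfig) -> pd.DataFrame:
    """Quantitative trait columns only (natural units)."""
    pheno, _ = generate_phenotypes(ped, cfg)
    return pheno.drop(columns=[DISEASE])


def simulate_binary_trait(ped: Pedigree, cfg: SimConfig):
    """Disease status column plus its generating parameters."""
    pheno, panel = generate_phenotypes(ped, cfg)
    truth = {
        "prevalence": cfg.prevalence,
        "disease_h2": cfg.disease_h2,
        "threshold": float(stats.norm.ppf(1.0 - cfg.prevalence)),
        "affected_total": int(pheno[DISEASE].sum()),
    }
    return pheno[["id", "family", DISEASE]], truth


# ---------------------------------------------------------------------------
# Ascertainment
# ---------------------------------------------------------------------------


def ascertain_families(ped: Pedigree, disease: pd.Series, mode="single-proband",
                       seed=0):
    """Select families through affected members.

    ``disease`` is indexed by individual id.  Returns ``(pedigree, probands)``
    with probands a list of ids (one per retained family; empty for mode
    "none").  See the module docstring for the sampling semantics of each
    mode.
    """
    if mode == "none":
        return ped, []
    rng = np.random.default_rng(seed)
    keep_ids = []
    probands = []
    for fam in ped.families:
        members = ped.family_members(fam)
        phenotyped = [m for m in members if m in disease.index]
        aff = [m for m in phenotyped if disease.loc[m] == 1]
        if not aff:
            continue
        if mode == "single-proband":
            # retention probability proportional to the number of affected
            if rng.random() >= len(aff) / max(len(phenotyped), 1):
                continue
            proband = aff[rng.integers(len(aff))]
        elif mode == "complete":
            proband = aff[0]
        else:
            raise ValueError(f"unknown ascertainment mode {mode!r}")
        keep_ids.extend(members)
        probands.append(proband)
    if not keep_ids:
        raise RuntimeError("no family retained; raise the prevalence")
    return ped.subset(keep_ids), probands


# ---------------------------------------------------------------------------
# End-to-end fixture
# ---------------------------------------------------------------------------


def generate_study_fixture(preset="t2d-family-study", seed=0, outdir=None):
    """Generate a complete ascertained family-study fixture.

    The "t2d-family-study" preset: 112 retained extended families (sizes 3-20,
    three generations), the 18-trait quantitative panel with heritabilities
    between 0.06 and 0.73, a liability disease with prevalence 0.35 and
    h2 0.35 genetically linked to the panel (biceps skinfold rhoG 0.77),
    single-proband ascertainment.  Returns a dict with the pedigree,
    phenotype table, probands and ground truth; with ``outdir`` also writes
    pedigree.csv, phenotypes.csv and ground_truth.json.
    """
    if preset != "t2d-family-study":
        raise ValueError(f"unknown preset {preset!r}")
    target = 112
    cfg = default_config(n_families=5 * target, seed=int(seed) & 0x7FFFFFFF)
    ped = simulate_pedigree_set(cfg)
    pheno, panel = generate_phenotypes(ped, cfg)
    disease = pheno.set_index("id")[DISEASE]
    kept, probands = ascertain_families(ped, disease, mode=cfg.ascertainment,
                                        seed=cfg.seed + 1)
    fams = kept.families[:target]
    kept = kept.subset([i for f in fams for i in kept.family_members(f)])
    probands = probands[: len(fams)]
    keep = set(kept.ids)
    pheno = pheno[pheno["id"].isin(keep)].reset_index(drop=True)

    h2_map = {t.name: t.h2 for t in cfg.traits}
    rg, _ = cfg.resolve_corr()
    names = cfg.panel_names()
    truth = {
        "seed": int(seed),
        "n_families": len(fams),
        "n_individuals": int(len(pheno)),
        "trait_h2": h2_map,
        "disease_h2": cfg.disease_h2,
        "prevalence": cfg.prevalence,
        "rhoG_biceps_disease": float(rg[names.index("sft_biceps"), names.index(DISEASE)]),
        "ascertainment": cfg.ascertainment,
        "probands": probands,
        "affected_per_family": {
            f: int(disease.loc[[i for i in kept.family_members(f)]].sum())
            for f in fams
        },
    }
    result = {"pedigree": kept, "phenotypes": pheno, "probands": probands,
              "truth": truth, "config": cfg}
    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ped_out = kept.table[["id", "father", "mother", "sex", "family", "phenotyped"]]
        ped_out.to_csv(outdir / "pedigree.csv", index=False)
        pheno.to_csv(outdir / "phenotypes.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=str)
        result["paths"] = {k: str(outdir / f"{k}.csv") for k in ("pedigree", "phenotypes")}
    return result
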