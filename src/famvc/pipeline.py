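"""End-to-end analysis pipeline driven by a single configuration mapping.

Stages run in dependency order: pedigree -> kinship -> trait derivation ->
univariate heritability (quantitative + disease) -> association screen ->
bivariate pairs -> heritability curves -> factor analysis.  Every stage's
output lands in the run directory; a manifest records the configuration,
seeds and package version so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .association import bonferroni, prevalence_from_fit, screen_and_refit
from .bivariate import fit_bivariate, rhoG_zero_lrt
from .curves import heritability_curve
from .factors import extract_factors, varimax_rotate
from .io import fit_summary_row, fit_to_json, summary_table, write_kinship
from .pedigree import filter_min_phenotyped, kinship_matrix, read_pedigree
from .traits import build_covariates, derive_indexes, flag_anemia, inverse_normalize
from .varcomp import (
    fit_liability_binary,
    fit_polygenic_quant,
    fit_sporadic,
    h2_confint,
    heritability_lrt,
)

log = logging.getLogger("famvc.pipeline")

DEFAULTS = {
    "min_phenotyped": 3,
    "covariates": ["age", "sex", "age_sex", "age2", "age2_sex", "anemia", "smoking"],
    "seed": 0,
    "bonferroni_m": None,  # default: number of traits tested
    "curve_grid_points": 25,
    "curve_bandwidth": 0.4,
    "mvn_points": 256,
    "stages": ["heritability"],
    "disease": "t2d",
    "traits": None,  # default: all numeric trait columns
    "factor_traits": None,
    "curve_traits": [],
    "bivariate_pairs": [],
    "association_traits": [],
}


class ConfigError(ValueError):
    pass


def _load_config(config):
    if isinstance(config, (str, pathlib.Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = dict(DEFAULTS)
    merged.update(config or {})
    return merged


def _prepare(cfg):
    ped = read_pedigree(cfg["pedigree"])
    pheno = pd.read_csv(cfg["phenotypes"])
    pheno["id"] = pheno["id"].astype(str)
    ped, report = filter_min_phenotyped(ped, pheno, cfg["min_phenotyped"])
    keep = [i for i in ped.ids if i in set(pheno["id"])]
    pheno = pheno.set_index("id").loc[keep].reset_index()
    ped = ped.subset(pheno["id"])
    # align pedigree row order with the phenotype table
    ped.table = ped.table.set_index("id").loc[pheno["id"]].reset_index()
    ped.__post_init__()
    pheno = derive_indexes(pheno) if "height" in pheno.columns else pheno
    if "hemoglobin" in pheno.columns and "anemia" not in pheno.columns:
        pheno["anemia"] = np.asarray(
            flag_anemia(pheno["hemoglobin"], pheno["sex"]), dtype=float
        )
    kin = kinship_matrix(ped)
    cov_names = [c for c in cfg["covariates"]
                 if c in ("age", "sex", "age_sex", "age2", "age2_sex")
                 or c in pheno.columns]
    X = build_covariates(pheno, cov_names)
    return ped, pheno, kin, X, report


def _trait_columns(cfg, pheno):
    if cfg["traits"]:
        missing = [t for t in cfg["traits"] if t not in pheno.columns]
        if missing:
            raise ConfigError(f"unknown trait column(s): {missing}")
        return list(cfg["traits"])
    skip = {"id", "family", "age", "sex", "hemoglobin", "smoking", "anemia",
            cfg["disease"]}
    return [c for c in pheno.columns
            if c not in skip and pd.api.types.is_numeric_dtype(pheno[c])]


def run_pipeline(config, outdir) -> pathlib.Path:
    """Execute the configured stages; returns the output directory."""
    cfg = _load_config(config)
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ped, pheno, kin, X, report = _prepare(cfg)
        traits = _trait_columns(cfg, pheno)
    except (KeyError, ValueError) as e:
        (out / "FAILED").write_text(str(e))
        raise ConfigError(str(e)) from e

    seed = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "n_individuals": int(len(pheno)),
        "families": report,
        "traits": traits,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    write_kinship(kin, out / "kinship.tsv")
    stages = cfg["stages"]

    if "heritability" in stages:
        rows = []
        raw_p = []
        for t in traits:
            y = inverse_normalize(pheno[t])
            ok = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
            f0 = fit_sporadic(y[ok], X[ok])
            f1 = fit_polygenic_quant(y[ok], X[ok], kin.values[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))])
            lrt = heritability_lrt(f0, f1)
            ci = h2_confint(f1) if np.isfinite(f1.se.get("h2", np.nan)) else (np.nan, np.nan)
            rows.append(fit_summary_row(t, f1, ci=ci, p_uncorrected=lrt.pvalue))
            raw_p.append(lrt.pvalue)
        m = cfg["bonferroni_m"] or len(traits)
        for row, p in zip(rows, raw_p):
            row["p_corrected"] = float(bonferroni(p, m))
        summary_table(rows).to_csv(out / "heritability.tsv", sep="\t", index=False)

    disease = cfg["disease"]
    probands = cfg.get("probands") or []
    if "disease" in stages and disease in pheno.columns:
        d = pheno[disease].to_numpy(dtype=float)
        fit = fit_liability_binary(d, X, kin.values, probands=set(probands),
                                   ids=list(pheno["id"]), seed=seed,
                                   n_points=cfg["mvn_points"])
        prev = prevalence_from_fit(fit)
        payload = fit_to_json(fit)
        payload["prevalence"] = prev if isinstance(prev, float) else list(prev)
        with open(out / "disease_fit.json", "w") as fh:
            json.dump(payload, fh, indent=1)

    if "association" in stages and cfg["association_traits"]:
        tr = pd.DataFrame({t: inverse_normalize(pheno[t]) for t in cfg["association_traits"]})
        d = pheno[disease].to_numpy(dtype=float)
        screen, final = screen_and_refit(tr, d, X, kin.values,
                                         probands=set(probands),
                                         ids=list(pheno["id"]), seed=seed,
                                         n_points=cfg["mvn_points"])
        pd.DataFrame([vars(r) for r in screen + final]).to_csv(
            out / "association.tsv", sep="\t", index=False)

    if "bivariate" in stages and cfg["bivariate_pairs"]:
        rows = []
        for t1, t2 in cfg["bivariate_pairs"]:
            y1 = inverse_normalize(pheno[t1])
            y2 = inverse_normalize(pheno[t2])
            lrt, full, _ = rhoG_zero_lrt(y1, y2, X, kin.values)
            rows.append({"trait_i": t1, "trait_j": t2, "rhoG": full.rhoG,
                         "rhoG_p": lrt.pvalue, "rhoE": full.rhoE,
                         "h2_i": full.h2_1, "h2_j": full.h2_2,
                         "rhoP": full.rhoP})
        pd.DataFrame(rows).to_csv(out / "bivariate.tsv", sep="\t", index=False)

    if "curves" in stages and cfg["curve_traits"]:
        for t in cfg["curve_traits"]:
            curve = heritability_curve(
                pheno[t].to_numpy(dtype=float), X, kin.values,
                n_points_grid=cfg["curve_grid_points"],
                bandwidth=cfg["curve_bandwidth"], seed=seed,
                n_points_mvn=cfg["mvn_points"],
            )
            curve.to_frame().to_csv(out / f"curve_{t}.tsv", sep="\t", index=False)

    if "factors" in stages:
        ftraits = cfg["factor_traits"] or [t for t in traits if not t.startswith(("bmi", "whr", "whtr", "str"))]
        sol = varimax_rotate(extract_factors(pheno[ftraits]))
        sol.loadings.to_csv(out / "factor_loadings.tsv", sep="\t")
        sol.uniqueness.rename("uniqueness").to_csv(out / "factor_uniqueness.tsv", sep="\t")
        manifest["factors"] = {
            "n_factors": sol.n_factors,
            "variance_explained": sol.variance_explained.tolist(),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
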