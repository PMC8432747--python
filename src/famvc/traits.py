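"""Derived anthropometric/metabolic traits, covariate designs, normalization.

Composite indexes follow the standard clinical definitions: BMI = weight /
height(m)^2, WHR = waist / hip, WHtR = waist / height, STR = subscapular /
triceps skinfold.  Percent body fat comes from the four-site Durnin-Womersley
body-density equations (log10 of the biceps+triceps+subscapular+suprailiac
skinfold sum with age/sex-specific coefficients) converted by the Siri
equation.  HOMA indexes use the classic Matthews constants in mg/dl units.
Quantitative traits are inverse-normalized with the rank-based Blom transform
before model fitting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "derive_indexes",
    "durnin_womersley_fat",
    "homa_indexes",
    "flag_anemia",
    "inverse_normalize",
    "build_covariates",
    "DEFAULT_COVARIATES",
    "DW_COEFFICIENTS",
]

DEFAULT_COVARIATES = ("age", "sex", "age_sex", "age2", "age2_sex", "anemia", "smoking")

# Durnin & Womersley (1974) four-skinfold body-density coefficients
# density = c - m * log10(sum of biceps, triceps, subscapular, suprailiac in mm)
# keyed by sex and age band (years); youngest published band starts at 17.
DW_COEFFICIENTS = {
    "male": [
        ((17, 19), 1.1620, 0.0630),
        ((20, 29), 1.1631, 0.0632),
        ((30, 39), 1.1422, 0.0544),
        ((40, 49), 1.1620, 0.0700),
        ((50, 200), 1.1715, 0.0779),
    ],
    "female": [
        ((17, 19), 1.1549, 0.0678),
        ((20, 29), 1.1599, 0.0717),
        ((30, 39), 1.1423, 0.0632),
        ((40, 49), 1.1333, 0.0612),
        ((50, 200), 1.1339, 0.0645),
    ],
}


def _ratio(num, den, name):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
        out[ok] = num[ok] / den[ok]
    if np.any(np.isfinite(num) & (den == 0)):
        warnings.warn(f"zero denominator while deriving {name}; set to missing")
    return out


def derive_indexes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add BMI, WHR, WHtR and STR columns; missing inputs propagate."""
    out = pheno.copy()
    height_m = np.asarray(out["height"], dtype=float) / 100.0
    out["bmi"] = _ratio(out["weight"], height_m**2, "bmi")
    out["whr"] = _ratio(out["waist"], out["hip"], "whr")
    out["whtr"] = _ratio(out["waist"], out["height"], "whtr")
    out["str"] = _ratio(out["sft_subscapular"], out["sft_triceps"], "str")
    return out


def _dw_density(total: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    density = np.full(total.shape, np.nan)
    for i in range(total.size):
        if not np.isfinite(total.flat[i]) or not np.isfinite(age.flat[i]):
            continue
        bands = DW_COEFFICIENTS[str(sex.flat[i])]
        if age.flat[i] < bands[0][0][0]:
            raise ValueError(
                f"age {age.flat[i]} below the youngest Durnin-Womersley band "
                f"({bands[0][0][0]}-{bands[0][0][1]} years)"
            )
        for (lo, hi), c, m in bands:
            if lo <= age.flat[i] <= hi:
                density.flat[i] = c - m * np.log10(total.flat[i])
                break
    return density


def durnin_womersley_fat(biceps, triceps, subscapular, suprailiac, age, sex):
    """Percent body fat from the four skinfolds via Siri's equation.

    ``sex`` is "male"/"female" (scalar or array).  All four skinfolds are in
    mm, age in years (>= 17, the youngest published band).
    """
    arrays = [np.atleast_1d(np.asarray(x, dtype=float)) for x in (biceps, triceps, subscapular, suprailiac)]
    total = arrays[0] + arrays[1] + arrays[2] + arrays[3]
    age_a = np.atleast_1d(np.asarray(age, dtype=float))
    sex_a = np.atleast_1d(np.asarray(sex, dtype=object))
    age_a, sex_a, total = np.broadcast_arrays(age_a, sex_a, total)
    density = _dw_density(np.array(total), np.array(age_a), np.array(sex_a))
    fat = (4.95 / density - 4.50) * 100.0
    return fat if fat.size > 1 else float(fat[0])


def homa_indexes(fpg, fpi):
    """HOMA-IR and HOMA-beta from fasting glucose (mg/dl) and insulin (IU/ml).

    HOMA-IR = FPG*FPI/405; HOMA-beta = 360*FPI/(FPG-63), undefined (missing)
    at FPG <= 63.
    """
    fpg = np.asarray(fpg, dtype=float)
    fpi = np.asarray(fpi, dtype=float)
    homa_ir = fpg * fpi / 405.0
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_b = np.where(fpg > 63.0, 360.0 * fpi / (fpg - 63.0), np.nan)
    if np.any(np.isfinite(fpg) & (fpg <= 63.0)):
        warnings.warn("FPG <= 63 mg/dl: HOMA-beta undefined, set to missing")
    if homa_ir.ndim == 0:
        return float(homa_ir), float(homa_b)
    return homa_ir, homa_b


def flag_anemia(hemoglobin, sex):
    """Anemia flag: hemoglobin < 12 g/dl (females) or < 13 g/dl (males)."""
    hb = np.asarray(hemoglobin, dtype=float)
    sex_a = np.asarray(sex, dtype=object)
    cut = np.where(sex_a == "male", 13.0, 12.0)
    out = np.where(np.isfinite(hb), hb < cut, np.nan)
    if out.ndim == 0:
        return float(out) if np.isnan(out) else bool(out)
    return out


def inverse_normalize(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    z_i = Phi^-1((r_i - 3/8) / (n + 1/4)) over the non-missing entries, with
    averaged ranks on ties; missing values are preserved.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("inverse_normalize needs at least 2 non-missing values")
    if np.ptp(x[ok]) == 0:
        raise ValueError("inverse_normalize undefined for a constant vector")
    ranks = stats.rankdata(x[ok], method="average")
    out = np.full(x.shape, np.nan)
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def build_covariates(pheno: pd.DataFrame, spec=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Assemble the covariate design (no intercept column).

    Age is centered at the sample mean before powers and interactions are
    formed; sex is coded female=0, male=1; anemia and smoking are 0/1.
    """
    cols = {}
    age = None
    if any(c.startswith("age") for c in spec):
        age = np.asarray(pheno["age"], dtype=float)
        age = age - np.nanmean(age)
    sex = None
    if any("sex" in c for c in spec):
        sex = np.asarray(pheno["sex"].map({"female": 0.0, "male": 1.0}) if pheno["sex"].dtype == object else pheno["sex"], dtype=float)
    for name in spec:
        if name == "age":
            cols[name] = age
        elif name == "sex":
            cols[name] = sex
        elif name == "age_sex":
            cols[name] = age * sex
        elif name == "age2":
            cols[name] = age**2
        elif name == "age2_sex":
            cols[name] = age**2 * sex
        else:
            if name not in pheno.columns:
                raise KeyError(f"covariate {name!r} not present in phenotype table")
            cols[name] = np.asarray(pheno[name], dtype=float)
        if not np.any(np.isfinite(cols[name])):
            raise ValueError(f"covariate {name!r} is entirely missing")
    return pd.DataFrame(cols, index=pheno.index)
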