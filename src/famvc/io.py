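"""Serialization of fit results and kinship matrices."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .pedigree import KinshipMatrix
from .varcomp import PolygenicFit

__all__ = ["fit_to_json", "fit_summary_row", "write_kinship", "summary_table"]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def fit_to_json(fit: PolygenicFit, path=None):
    """Full fit record (estimates, SEs, log-likelihood, metadata) as JSON."""
    payload = _jsonable(fit)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return payload


def fit_summary_row(trait: str, fit: PolygenicFit, ci=None, p_uncorrected=None,
                    p_corrected=None) -> dict:
    """Flat per-trait summary row (trait, h2, CI, p-values)."""
    row = {
        "trait": trait,
        "h2": round(fit.h2, 4),
        "h2_se": round(fit.se.get("h2", float("nan")), 4),
        "loglik": fit.loglik,
        "n": fit.n,
        "converged": fit.converged,
    }
    if ci is not None:
        row["ci_low"], row["ci_high"] = (round(ci[0], 4), round(ci[1], 4))
    if p_uncorrected is not None:
        row["p_uncorrected"] = p_uncorrected
    if p_corrected is not None:
        row["p_corrected"] = p_corrected
    return row


def summary_table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows)


def write_kinship(kin: KinshipMatrix, path, dense_path=None):
    """Sparse 3-column text (id1, id2, relatedness); optional dense CSV."""
    kin.to_sparse_frame().to_csv(path, sep="\t", index=False)
    if dense_path is not None:
        pd.DataFrame(kin.values, index=kin.ids, columns=kin.ids).to_csv(dense_path)
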