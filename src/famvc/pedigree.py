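"""Pedigree reading, validation, kinship, and relationship classification.

A pedigree is a set of individuals with optional father/mother links, a sex,
and a family label.  Kinship is computed by the recursive tabular method:
founders are assumed non-inbred and mutually unrelated, ``phi_ii = 1/2`` for a
founder, and for a non-founder j with parents f and m,

    phi_ij = (phi_if + phi_im) / 2          (i already processed)
    phi_jj = 1/2 * (1 + phi_fm)

Individuals are processed in generation (topological) order so that both
parents of j precede j.  The matrix stored and returned everywhere is the
expected additive relationship ``2 * phi`` (1 on a non-inbred diagonal, 0.5
for parent-offspring and full sibs, ...), block-diagonal by family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "kinship_matrix",
    "classify_relationships",
    "filter_min_phenotyped",
    "RELATIONSHIP_CLASSES",
]

MISSING_PARENT = {"0", "", "na", "nan", "none"}

MALE_CODES = {"1", "m", "male"}
FEMALE_CODES = {"2", "f", "female"}

RELATIONSHIP_CLASSES = (
    "parent-offspring",
    "sibling",
    "half-sibling",
    "grandparent-grandchild",
    "avuncular",
    "third degree",
    "fourth degree",
    "fifth degree",
    "other",
)


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad parent links)."""


def _norm_sex(value) -> str:
    s = str(value).strip().lower()
    if s in MALE_CODES:
        return "male"
    if s in FEMALE_CODES:
        return "female"
    raise PedigreeError(f"unrecognized sex code {value!r}")


@dataclass
class Pedigree:
    """A validated multi-family pedigree.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per individual with columns ``id``, ``father``, ``mother``
        (None when unknown), ``sex`` ("male"/"female"), ``family``,
        ``phenotyped`` (bool) and ``generation`` (0 for founders).
    """

    table: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {iid: i for i, iid in enumerate(self.table["id"])}

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def families(self) -> list:
        return list(dict.fromkeys(self.table["family"]))

    def family_members(self, family) -> list:
        return list(self.table.loc[self.table["family"] == family, "id"])

    def founders(self) -> list:
        t = self.table
        mask = t["father"].isna() & t["mother"].isna()
        return list(t.loc[mask, "id"])

    def parents(self, iid):
        row = self.table.iloc[self._index[iid]]
        father = row["father"] if pd.notna(row["father"]) else None
        mother = row["mother"] if pd.notna(row["mother"]) else None
        return father, mother

    def graph(self) -> nx.DiGraph:
        """Parent -> child directed graph over all families."""
        g = nx.DiGraph()
        g.add_nodes_from(self.table["id"])
        for _, row in self.table.iterrows():
            for p in (row["father"], row["mother"]):
                if pd.notna(p):
                    g.add_edge(p, row["id"])
        return g

    def subset(self, ids) -> "Pedigree":
        keep = set(ids)
        sub = self.table[self.table["id"].isin(keep)].reset_index(drop=True)
        return Pedigree(sub)


def _build_pedigree(df: pd.DataFrame) -> Pedigree:
    df = df.copy()
    df["id"] = df["id"].astype(str).str.strip()
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise PedigreeError(f"duplicate individual id(s): {dups}")

    for col in ("father", "mother"):
        vals = df[col].astype(str).str.strip()
        vals = vals.where(~vals.str.lower().isin(MISSING_PARENT), other=None)
        df[col] = vals

    df["sex"] = [_norm_sex(s) for s in df["sex"]]
    df["family"] = df["family"].astype(str).str.strip()
    if "phenotyped" not in df.columns:
        df["phenotyped"] = True
    df["phenotyped"] = df["phenotyped"].astype(bool)

    known = dict(zip(df["id"], zip(df["sex"], df["family"])))

    # materialize unknown co-parents as anonymous founders so recursion works
    extra_rows = []
    anon = 0
    for i in df.index:
        f, m = df.at[i, "father"], df.at[i, "mother"]
        if (f is None) != (m is None):
            anon += 1
            new_id = f"_anon{anon}"
            missing_col = "mother" if m is None else "father"
            extra_rows.append(
                {
                    "id": new_id,
                    "father": None,
                    "mother": None,
                    "sex": "female" if missing_col == "mother" else "male",
                    "family": df.at[i, "family"],
                    "phenotyped": False,
                }
            )
            df.at[i, missing_col] = new_id
    if extra_rows:
        df = pd.concat([df, pd.DataFrame(extra_rows)], ignore_index=True)
        known.update(
            {r["id"]: (r["sex"], r["family"]) for r in extra_rows}
        )

    bad_rows = []
    for i in df.index:
        iid = df.at[i, "id"]
        fam = df.at[i, "family"]
        for col, want in (("father", "male"), ("mother", "female")):
            p = df.at[i, col]
            if p is None:
                continue
            if p == iid:
                raise PedigreeError(f"individual {iid!r} listed as its own {col}")
            if p not in known:
                raise PedigreeError(
                    f"individual {iid!r}: {col} {p!r} not present in the file"
                )
            psex, pfam = known[p]
            if pfam != fam:
                raise PedigreeError(
                    f"individual {iid!r}: {col} {p!r} belongs to family {pfam!r}, "
                    f"not {fam!r}"
                )
            if psex != want:
                bad_rows.append((iid, col, p, psex))
    if bad_rows:
        lines = ", ".join(f"{iid}: {col}={p} has sex {s}" for iid, col, p, s in bad_rows)
        raise PedigreeError(f"sex-inconsistent parent link(s): {lines}")

    ped = Pedigree(df.reset_index(drop=True))
    g = ped.graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise PedigreeError(f"pedigree contains an ancestry cycle: {cyc}")

    gen = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        gen[node] = 0 if not preds else 1 + max(gen[p] for p in preds)
    ped.table["generation"] = [gen[i] for i in ped.table["id"]]
    return ped


def read_pedigree(path, column_map: dict | None = None) -> Pedigree:
    """Read a PED-style delimited text file into a validated :class:`Pedigree`.

    The file must carry columns id, father, mother, sex, family (any order;
    a header row is required).  Comma or tab delimiting is autodetected.
    ``column_map`` maps the canonical names to the file's column names, e.g.
    ``{"id": "IID", "family": "FID"}`` for PLINK-ordered files.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    cmap = {k: v.lower() for k, v in (column_map or {}).items()}
    cols = {}
    for canon in ("id", "father", "mother", "sex", "family"):
        src = cmap.get(canon, canon)
        if src not in raw.columns:
            raise PedigreeError(f"missing required column {src!r} in {path}")
        cols[canon] = raw[src]
    df = pd.DataFrame(cols)
    if "phenotyped" in raw.columns:
        df["phenotyped"] = raw["phenotyped"].str.lower().isin({"1", "true", "yes"})
    return _build_pedigree(df)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Validate an in-memory frame with columns id/father/mother/sex/family."""
    return _build_pedigree(df)


@dataclass
class KinshipMatrix:
    """Expected additive relationship matrix ``2 * phi`` over ordered ids."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def pair(self, a, b) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids) -> np.ndarray:
        idx = [self._index[i] for i in ids]
        return self.values[np.ix_(idx, idx)]

    def to_sparse_frame(self) -> pd.DataFrame:
        """Long-format nonzero upper triangle (id1, id2, relatedness)."""
        i, j = np.nonzero(np.triu(self.values))
        return pd.DataFrame(
            {
                "id1": [self.ids[a] for a in i],
                "id2": [self.ids[b] for b in j],
                "relatedness": self.values[i, j],
            }
        )


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Recursive tabular kinship for the whole pedigree (block by family)."""
    n = ped.n
    ids = ped.ids
    idx = {iid: i for i, iid in enumerate(ids)}
    phi = np.zeros((n, n))

    order = ped.table.sort_values("generation", kind="stable")
    fam_of = dict(zip(ped.table["id"], ped.table["family"]))
    done: list = []
    for _, row in order.iterrows():
        j = idx[row["id"]]
        f = idx[row["father"]] if pd.notna(row["father"]) else None
        m = idx[row["mother"]] if pd.notna(row["mother"]) else None
        if f is None and m is None:
            phi[j, j] = 0.5
        else:
            phi[j, j] = 0.5 * (1.0 + phi[f, m])
        for iid in done:
            i = idx[iid]
            if fam_of[iid] != row["family"]:
                continue
            if f is None and m is None:
                val = 0.0
            else:
                pf = phi[i, f] if f is not None else 0.0
                pm = phi[i, m] if m is not None else 0.0
                val = 0.5 * (pf + pm)
            phi[i, j] = phi[j, i] = val
        done.append(row["id"])
    return KinshipMatrix(ids, 2.0 * phi)


def _ancestor_sets(ped: Pedigree):
    g = ped.graph()
    parents = {i: set(g.predecessors(i)) for i in ped.ids}
    grandparents = {i: set().union(*(parents[p] for p in parents[i])) if parents[i] else set() for i in ped.ids}
    return parents, grandparents


def classify_relationships(ped: Pedigree, phenotyped_only: bool = True) -> pd.Series:
    """Count phenotyped related pairs (2phi > 0) per relationship class.

    Path structure separates the degree-1/2 classes that share a kinship value
    (sibling vs parent-offspring at 0.5; grandparent-grandchild vs avuncular vs
    half-sibling at 0.25); remoter pairs are binned by kinship degree
    ``n = round(-log2(2phi))`` into third/fourth/fifth degree.  Anything not
    matching a listed class lands in "other" — never silently dropped.
    """
    kin = kinship_matrix(ped)
    parents, grandparents = _ancestor_sets(ped)
    t = ped.table
    use = t[t["phenotyped"]] if phenotyped_only else t
    counts = {c: 0 for c in RELATIONSHIP_CLASSES}

    ids_by_family: dict = {}
    for iid, fam in zip(use["id"], use["family"]):
        ids_by_family.setdefault(fam, []).append(iid)

    for fam, members in ids_by_family.items():
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i], members[b_i]
                r = kin.pair(a, b)
                if r <= 0:
                    continue
                counts[_classify_pair(a, b, r, parents, grandparents)] += 1
    return pd.Series(counts)


def _classify_pair(a, b, r, parents, grandparents) -> str:
    if a in parents[b] or b in parents[a]:
        return "parent-offspring"
    shared = parents[a] & parents[b]
    if parents[a] and parents[a] == parents[b] and math.isclose(r, 0.5):
        return "sibling"
    if shared and math.isclose(r, 0.25):
        return "half-sibling"
    if a in grandparents[b] or b in grandparents[a]:
        return "grandparent-grandchild" if math.isclose(r, 0.25) else "other"
    # avuncular: one is a full or half sib of the other's parent
    for x, y in ((a, b), (b, a)):
        for p in parents[y]:
            if parents[x] and parents[p] and (parents[x] & parents[p]):
                if math.isclose(r, 0.25):
                    return "avuncular"
    degree = round(-math.log2(r))
    if math.isclose(r, 2.0 ** -degree, rel_tol=1e-9):
        if degree == 3:
            return "third degree"
        if degree == 4:
            return "fourth degree"
        if degree == 5:
            return "fifth degree"
    return "other"


def filter_min_phenotyped(ped: Pedigree, pheno: pd.DataFrame | None, k: int = 3):
    """Keep families with at least ``k`` phenotyped members.

    ``pheno`` (optional) is a phenotype table with an ``id`` column; an
    individual counts as phenotyped when it appears there, otherwise the
    pedigree's own ``phenotyped`` flag is used.  Returns ``(pedigree, report)``
    where report holds retained/dropped family counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t = ped.table
    if pheno is not None:
        have = set(pheno["id"].astype(str))
        flag = t["id"].isin(have)
    else:
        flag = t["phenotyped"]
    per_family = flag.groupby(t["family"]).sum()
    keep_fams = set(per_family[per_family >= k].index)
    keep_ids = t.loc[t["family"].isin(keep_fams), "id"]
    report = {
        "retained_families": len(keep_fams),
        "dropped_families": int(len(per_family) - len(keep_fams)),
        "retained_individuals": int(len(keep_ids)),
    }
    if not keep_fams:
        warnings.warn("no family has enough phenotyped members; result is empty")
    return ped.subset(keep_ids), report
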