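"""Supervision targets from omics tables.

Three kinds of binary per-patient labels drive the slide classifiers:

* gene point-mutation status, for genes mutated in at least 3% of patients;
* gene copy-number alteration (CNA) status, for genes altered in more than
  5% of patients;
* pathway activity: for each of the canonical signaling pathways, a
  per-patient score v = (1/N_gene) * sum_n w_n * u_n over member genes,
  where u_n is the gene's expression (or CNA) level and w_n is +1 for an
  oncogene and -1 for a tumor suppressor; the label is 1 iff v > 0.

Pathway membership and oncogene/suppressor roles are user-supplied data
(a TSV with columns pathway, gene, role), not hard-coded biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_KINDS = {"expression", "cna", "point_mutation"}


@dataclass
class OmicsTable:
    """A genes x patients matrix of one omics kind."""

    values: pd.DataFrame  # index: genes, columns: patients
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {sorted(VALID_KINDS)}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene names")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate patient ids")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "OmicsTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0), kind)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class PathwayDefinition:
    """Membership of one pathway: (gene, weight) with weight +1 for an
    oncogene and -1 for a tumor suppressor."""

    pathway_id: str
    members: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")
        if any(w not in (1, -1) for _, w in self.members):
            raise ValueError("member weights must be +1 or -1")

    @property
    def n_genes(self) -> int:
        return len(self.members)


def load_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Read a pathway TSV with columns pathway, gene, role."""
    df = pd.read_csv(path, sep="\t")
    role_to_w = {"oncogene": 1, "suppressor": -1}
    defs = []
    for pid, grp in df.groupby("pathway", sort=True):
        members = [(str(r.gene), role_to_w[str(r.role)]) for r in grp.itertuples()]
        defs.append(PathwayDefinition(str(pid), members))
    return defs


def save_pathway_definitions(defs: Sequence[PathwayDefinition], path: str | Path) -> None:
    rows = []
    for d in defs:
        for gene, w in d.members:
            rows.append((d.pathway_id, gene, "oncogene" if w == 1 else "suppressor"))
    pd.DataFrame(rows, columns=["pathway", "gene", "role"]).to_csv(
        path, sep="\t", index=False)


@dataclass
class PathwayActivity:
    """Per-patient pathway activity scores v and binary labels l (= v > 0)."""

    v: pd.DataFrame  # patients x pathways
    l: pd.DataFrame  # patients x pathways, 0/1
    source: str  # "expression" | "cna"


def select_genes(table: OmicsTable, min_prevalence: float,
                 strict: bool = False) -> list[str]:
    """Genes whose altered-patient fraction passes the prevalence threshold.

    ``strict=False`` keeps genes altered in at least the threshold fraction
    (the point-mutation rule, >=3%); ``strict=True`` requires strictly more
    (the CNA rule, >5%). Output is sorted by descending prevalence, ties by
    gene name.
    """
    if table.values.empty:
        return []
    vals = table.values.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("select_genes expects a binarized table")
    prev = pd.Series(vals.mean(axis=1), index=table.values.index)
    kept = prev[prev > min_prevalence] if strict else prev[prev >= min_prevalence]
    order = sorted(kept.index, key=lambda g: (-kept[g], g))
    return order


def binarize_alterations(table: OmicsTable, convention: str = "nonzero") -> OmicsTable:
    """Collapse calls to altered (1) / unaltered (0) per gene and patient.

    Point mutations: any nonzero call is altered. CNA under the discrete
    GISTIC-style {-2,-1,0,1,2} coding: ``nonzero`` treats any nonzero call
    as altered; ``level2`` requires a deep deletion or high amplification
    (|call| >= 2).
    """
    vals = table.values
    if table.kind == "point_mutation":
        binary = (vals != 0).astype(int)
    elif table.kind == "cna":
        arr = vals.to_numpy()
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError("discrete CNA convention requires integer calls")
        level = {"nonzero": 1, "level2": 2}.get(convention)
        if level is None:
            raise ValueError(f"unknown CNA convention {convention!r}")
        binary = (vals.abs() >= level).astype(int)
    else:
        raise ValueError("binarize_alterations applies to mutation or CNA tables")
    return OmicsTable(binary, "point_mutation" if table.kind == "point_mutation" else "cna")


def pathway_activity(table: OmicsTable, defs: Iterable[PathwayDefinition]) -> PathwayActivity:
    """Score each pathway per patient: v = mean over member genes of w * u.

    u is the expression or CNA level, w the oncogene(+1)/suppressor(-1)
    weight. Member genes absent from the table (or NaN for a patient) are
    dropped from that mean with the denominator adjusted, with a warning;
    a pathway with no member present at all is an error. The binary label
    is 1 iff v > 0 (v == 0 is inactive).
    """
    if table.kind not in ("expression", "cna"):
        raise ValueError("pathway activity needs an expression or CNA table")
    patients = table.patients
    v_cols, ids = {}, []
    for d in defs:
        present = [(g, w) for g, w in d.members if g in table.values.index]
        if not present:
            raise ValueError(f"pathway {d.pathway_id!r} has no member gene in the table")
        missing = [g for g, _ in d.members if g not in table.values.index]
        if missing:
            warnings.warn(
                f"pathway {d.pathway_id!r}: member genes absent from table, "
                f"dropped from the mean: {missing}")
        genes = [g for g, _ in present]
        w = np.array([w for _, w in present], dtype=float)
        u = table.values.loc[genes].to_numpy(dtype=float)  # (n_members, n_patients)
        weighted = w[:, None] * u
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanmean(weighted, axis=0)
        v_cols[d.pathway_id] = v
        ids.append(d.pathway_id)
    v_df = pd.DataFrame(v_cols, index=patients, columns=ids)
    l_df = (v_df > 0).astype(int)
    return PathwayActivity(v_df, l_df, table.kind)


def make_label_table(tasks: Sequence[tuple[str, str]],
                     mutations: OmicsTable | None = None,
                     cna: OmicsTable | None = None,
                     expr_activity: PathwayActivity | None = None,
                     cna_activity: PathwayActivity | None = None,
                     known_patients: Iterable[str] | None = None) -> pd.DataFrame:
    """Assemble one binary label column per prediction task.

    ``tasks`` entries are (kind, name) with kind in {"point", "cna",
    "pathway-expr", "pathway-cna"}; columns are named ``{name}_{kind}``.
    If ``known_patients`` (e.g. the feature-cache roster) is given,
    labeled patients without cached features are reported in a warning.
    """
    columns = {}
    patients: list[str] | None = None

    def _patients_of(p):
        nonlocal patients
        if patients is None:
            patients = list(p)
        return patients

    for kind, name in tasks:
        if kind == "point":
            if mutations is None:
                raise ValueError("point task requested without a mutation table")
            src = binarize_alterations(mutations)
            col = src.values.loc[name].astype(int)
            idx = _patients_of(src.patients)
        elif kind == "cna":
            if cna is None:
                raise ValueError("cna task requested without a CNA table")
            src = binarize_alterations(cna)
            col = src.values.loc[name].astype(int)
            idx = _patients_of(src.patients)
        elif kind == "pathway-expr":
            if expr_activity is None:
                raise ValueError("pathway-expr task requested without activities")
            col = expr_activity.l[name]
            idx = _patients_of(list(expr_activity.l.index))
        elif kind == "pathway-cna":
            if cna_activity is None:
                raise ValueError("pathway-cna task requested without activities")
            col = cna_activity.l[name]
            idx = _patients_of(list(cna_activity.l.index))
        else:
            raise ValueError(f"unknown task kind {kind!r}")
        columns[f"{name}_{kind}"] = np.asarray(col.loc[idx] if hasattr(col, "loc") else col)

    if patients is None:
        return pd.DataFrame(index=pd.Index([], name="patient_id"))
    out = pd.DataFrame(columns, index=pd.Index(patients, name="patient_id"))
    if known_patients is not None:
        missing = sorted(set(patients) - set(known_patients))
        if missing:
            warnings.warn(f"labeled patients absent from feature cache: {missing}")
    return out
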