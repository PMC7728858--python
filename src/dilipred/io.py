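"""Readers/writers for profile matrices, metadata and drug-level label tables.

Canonical on-disk formats are tab-delimited text:

* wide matrix — row 1 = profile ids, column 1 = gene ids;
* metadata    — columns profile_id, drug_id, dose, duration, cell_line;
* label table — columns drug_id, label (0/1).

Drug ids are assumed pre-reconciled (one label per drug_id); synonym
resolution against external chemical registries is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyJoinError, FormatError
from .profiles import LABEL_COLUMN, METADATA_COLUMNS, ProfileSet


@dataclass(frozen=True)
class JoinReport:
    """Bookkeeping of a label join: what matched and what was dropped."""

    n_matched: int
    n_dropped: int
    dropped_drug_ids: tuple[str, ...]
    n_positive_profiles: int
    n_negative_profiles: int


def write_profile_set(profiles: ProfileSet, matrix_path, metadata_path) -> None:
    """Persist a ProfileSet as the canonical wide matrix + metadata pair."""
    mat = pd.DataFrame(
        profiles.values, index=profiles.gene_ids, columns=profiles.profile_ids
    )
    mat.index.name = "gene_id"
    mat.to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = profiles.metadata.reset_index()
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.10g")


def read_profile_set(matrix_path, metadata_path) -> ProfileSet:
    """Read and validate the wide matrix + metadata pair.

    Column order follows the matrix file.  Raises :class:`FormatError` naming
    the offending ids/cells on any shape, id or parse problem.
    """
    try:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # malformed delimited text
        raise FormatError(f"cannot parse matrix file {matrix_path}: {exc}") from exc
    non_numeric = mat.columns[[not np.issubdtype(dt, np.number) for dt in mat.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad_rows = mat.index[pd.to_numeric(mat[col], errors="coerce").isna()].tolist()
        raise FormatError(
            f"non-numeric matrix cell(s) in column {col!r}, row(s) {bad_rows[:5]}"
        )
    meta = pd.read_csv(metadata_path, sep="\t")
    if "profile_id" not in meta.columns:
        raise FormatError("metadata file lacks a profile_id column")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata file lacks column(s) {missing_cols}")
    meta = meta.astype({"profile_id": str, "drug_id": str, "cell_line": str})
    dup = meta["profile_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"duplicate metadata profile ids: {meta.loc[dup, 'profile_id'].tolist()[:10]}"
        )
    meta = meta.set_index("profile_id")
    profile_ids = [str(c) for c in mat.columns]
    absent = [p for p in profile_ids if p not in meta.index]
    if absent:
        raise FormatError(f"metadata missing profile ids: {absent[:10]}")
    return ProfileSet(
        values=mat.to_numpy(dtype=float),
        gene_ids=[str(g) for g in mat.index],
        profile_ids=profile_ids,
        metadata=meta,
    )


def read_label_table(path) -> pd.DataFrame:
    """Read a drug-level DILI label table (columns drug_id, label)."""
    tab = pd.read_csv(path, sep="\t")
    return validate_label_table(tab)


def validate_label_table(tab: pd.DataFrame) -> pd.DataFrame:
    if not {"drug_id", "label"}.issubset(tab.columns):
        raise FormatError("label table needs columns drug_id and label")
    tab = tab.astype({"drug_id": str})
    if tab["drug_id"].duplicated().any():
        dups = tab.loc[tab["drug_id"].duplicated(), "drug_id"].tolist()
        raise FormatError(f"duplicate drug ids in label table: {dups[:10]}")
    if not tab["label"].isin([0, 1]).all():
        raise FormatError("labels must be binary 0/1")
    return tab[["drug_id", "label"]].copy()


def join_labels(profiles: ProfileSet, labels: pd.DataFrame) -> tuple[ProfileSet, JoinReport]:
    """Join drug-level DILI labels onto profiles by drug_id.

    Profiles whose drug has a label are retained (with that label); unmatched
    profiles are dropped.  Matrix values are untouched.  Idempotent.
    """
    labels = validate_label_table(labels)
    label_by_drug = dict(zip(labels["drug_id"], labels["label"].astype(int)))
    keep_mask = profiles.metadata["drug_id"].astype(str).isin(label_by_drug)
    kept_ids = [p for p, k in zip(profiles.profile_ids, keep_mask) if k]
    if not kept_ids:
        raise EmptyJoinError("no profile's drug_id matches the label table")
    dropped_drugs = tuple(
        sorted(set(profiles.metadata.loc[~keep_mask, "drug_id"].astype(str)))
    )
    joined = profiles.subset(kept_ids)
    joined.metadata = joined.metadata.copy()
    joined.metadata[LABEL_COLUMN] = (
        joined.metadata["drug_id"].astype(str).map(label_by_drug).astype(int)
    )
    y = joined.metadata[LABEL_COLUMN]
    report = JoinReport(
        n_matched=len(kept_ids),
        n_dropped=profiles.n_profiles - len(kept_ids),
        dropped_drug_ids=dropped_drugs,
        n_positive_profiles=int((y == 1).sum()),
        n_negative_profiles=int((y == 0).sum()),
    )
    return joined, report


def write_gene_list(genes, path) -> None:
    """One gene id per line (ready for external enrichment services)."""
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")
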