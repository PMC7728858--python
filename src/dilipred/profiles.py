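"""The ProfileSet container: a genes x profiles Z-score matrix with metadata.

Rows are landmark genes, columns are treatment profiles (one per
drug/dose/duration/cell-line combination); values are moderated Z-scores, the
differential-expression statistic the assay reports, already
variance-standardized, so no further scaling is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("drug_id", "dose", "duration", "cell_line")
LABEL_COLUMN = "dili_label"


@dataclass
class ProfileSet:
    """Expression matrix (genes x profiles) plus per-profile treatment metadata.

    ``metadata`` is indexed by profile_id, aligned with the matrix columns,
    with columns drug_id, dose, duration, cell_line and, once drug-level DILI
    labels have been joined, dili_label in {0, 1}.
    """

    values: np.ndarray = field(repr=False)
    gene_ids: list[str]
    profile_ids: list[str]
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.profile_ids = [str(p) for p in self.profile_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix (genes x profiles)")
        n_genes, n_profiles = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for a {n_genes}-row matrix"
            )
        if len(self.profile_ids) != n_profiles:
            raise ValueError(
                f"{len(self.profile_ids)} profile ids for a {n_profiles}-column matrix"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.profile_ids)) != n_profiles:
            raise ValueError("duplicate profile ids")
        missing = [p for p in self.profile_ids if p not in self.metadata.index]
        if missing:
            raise ValueError(f"metadata missing profile ids: {missing[:10]}")
        # align metadata rows with matrix column order
        self.metadata = self.metadata.loc[self.profile_ids]
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        if LABEL_COLUMN in self.metadata.columns:
            lab = self.metadata[LABEL_COLUMN].dropna()
            if not lab.isin([0, 1]).all():
                raise ValueError("dili_label entries must be 0/1")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.values.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Feature matrix in estimator orientation: profiles x genes."""
        return self.values.T

    @property
    def has_labels(self) -> bool:
        return LABEL_COLUMN in self.metadata.columns and self.metadata[LABEL_COLUMN].notna().all()

    @property
    def labels(self) -> np.ndarray:
        """Per-profile 0/1 DILI labels (requires a completed label join)."""
        if not self.has_labels:
            raise ValueError("profile set has no (complete) dili_label column")
        return self.metadata[LABEL_COLUMN].to_numpy(dtype=int)

    @property
    def drug_ids(self) -> np.ndarray:
        return self.metadata["drug_id"].to_numpy(dtype=str)

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) profiles."""
        y = self.labels
        return int((y == 1).sum()), int((y == 0).sum())

    # ------------------------------------------------------------------
    def subset(self, profile_ids) -> "ProfileSet":
        """Restrict to the given profiles, in the given order."""
        ids = [str(p) for p in profile_ids]
        pos = {p: i for i, p in enumerate(self.profile_ids)}
        missing = [p for p in ids if p not in pos]
        if missing:
            raise KeyError(f"unknown profile ids: {missing[:10]}")
        cols = [pos[p] for p in ids]
        return ProfileSet(
            values=self.values[:, cols],
            gene_ids=list(self.gene_ids),
            profile_ids=ids,
            metadata=self.metadata.loc[ids].copy(),
        )

    def drug_label_table(self) -> pd.DataFrame:
        """Per-drug label table derived from the profile metadata."""
        tab = (
            self.metadata.groupby("drug_id")[LABEL_COLUMN]
            .agg(["nunique", "first"])
        )
        if (tab["nunique"] > 1).any():
            bad = tab.index[tab["nunique"] > 1].tolist()
            raise ValueError(f"drugs with conflicting labels: {bad[:10]}")
        return pd.DataFrame(
            {"drug_id": tab.index, "label": tab["first"].astype(int)}
        ).reset_index(drop=True)

    def copy(self) -> "ProfileSet":
        return ProfileSet(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            profile_ids=list(self.profile_ids),
            metadata=self.metadata.copy(),
        )
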