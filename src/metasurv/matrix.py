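"""Sample-by-feature omics matrix with per-feature provenance.

The container wraps a pandas DataFrame (rows = patients, columns = features)
and carries two per-feature annotations: the *block* a feature came from
(clinical / transcriptomics / proteomics-like) and its *kind* (numeric or
categorical).  Blocks matter because imputation and missing-value injection
are block-specific, and because downstream omics-combination experiments
select features by block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass
class OmicsMatrix:
    """Named patients x features matrix with block and kind annotations.

    Parameters
    ----------
    data
        DataFrame indexed by patient ID, columns are feature names.
        May contain NaN before imputation (numeric columns only).
    block_tags
        Per-feature block label, aligned with ``data.columns``.
    feature_kinds
        Per-feature ``"numeric"`` or ``"categorical"``, aligned with columns.
    """

    data: pd.DataFrame
    block_tags: pd.Series = field(default=None)
    feature_kinds: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.block_tags is None:
            self.block_tags = pd.Series("block0", index=self.data.columns)
        if self.feature_kinds is None:
            self.feature_kinds = pd.Series(NUMERIC, index=self.data.columns)
        self.block_tags = self.block_tags.reindex(self.data.columns)
        self.feature_kinds = self.feature_kinds.reindex(self.data.columns)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient IDs")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature names")

    # -- convenience accessors -------------------------------------------
    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.feature_kinds[c] == NUMERIC]

    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.feature_kinds[c] == CATEGORICAL]

    def values(self) -> np.ndarray:
        """Numeric view of the matrix (requires all-numeric columns)."""
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.data.copy(), self.block_tags.copy(), self.feature_kinds.copy()
        )

    def select_features(self, names) -> "OmicsMatrix":
        names = list(names)
        return OmicsMatrix(
            self.data[names],
            self.block_tags[names],
            self.feature_kinds[names],
        )

    def select_patients(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(
            self.data.loc[list(ids)],
            self.block_tags,
            self.feature_kinds,
        )

    # -- TSV dialect ------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write patients x features TSV (first column = patient ID)."""
        self.data.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path, block: str = "block0", kinds=None) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        kind_series = None
        if kinds is not None:
            kind_series = pd.Series(kinds, index=df.columns)
        else:
            # object-dtype columns are categorical, the rest numeric
            kind_series = pd.Series(
                [CATEGORICAL if df[c].dtype == object else NUMERIC for c in df.columns],
                index=df.columns,
            )
        return cls(df, pd.Series(block, index=df.columns), kind_series)
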