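"""Imputation, encoding, scaling, correlation filtering and multi-omics integration.

Pipeline order is fixed: impute -> encode -> drop leakage -> z-score ->
correlation filter.  Integration inner-joins blocks on patient ID and then
re-runs the z-score and the correlation filter on the merged matrix, so that
redundancy *across* omics blocks is removed as well.

The correlation filter drops a feature when its absolute Pearson correlation
with any *retained earlier* feature exceeds the threshold (default 0.7),
scanning columns left to right.  This greedy rule is deterministic and
order-stable: reordering columns changes which member of a redundant pair
survives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import NUMERIC, OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_THRESHOLD = 0.7


@dataclass
class PreprocessReport:
    """Provenance record of every preprocessing decision."""

    imputed_cell_count: int = 0
    encoded_feature_names: dict = field(default_factory=dict)  # name -> level map
    dropped_features: list = field(default_factory=list)  # (name, reason)
    correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD
    stages: list = field(default_factory=list)

    def drop(self, name: str, reason: str) -> None:
        self.dropped_features.append((name, reason))

    def merge(self, other: "PreprocessReport") -> None:
        self.imputed_cell_count += other.imputed_cell_count
        self.encoded_feature_names.update(other.encoded_feature_names)
        self.dropped_features.extend(other.dropped_features)
        self.stages.extend(other.stages)

    def to_dict(self) -> dict:
        return {
            "imputed_cell_count": int(self.imputed_cell_count),
            "encoded_feature_names": self.encoded_feature_names,
            "dropped_features": [list(t) for t in self.dropped_features],
            "correlation_threshold": self.correlation_threshold,
            "stages": self.stages,
        }


def impute_knn(matrix: OmicsMatrix, k: int = 1) -> tuple[OmicsMatrix, PreprocessReport]:
    """Fill missing numeric cells from the nearest complete donor row.

    Distance between two rows is the Euclidean distance over the numeric
    features observed in *both* rows.  With ``k=1`` the missing cell takes
    the donor's value directly; ties in distance go to the lowest row index.
    A row sharing no observed numeric feature with any eligible donor falls
    back to the column median.

    Categorical cells are never touched.
    """
    if k != 1:
        raise NotImplementedError("only k=1 nearest-neighbour imputation is supported")
    out = matrix.copy()
    report = PreprocessReport()
    report.stages.append("impute")
    num_cols = matrix.numeric_columns()
    if not num_cols:
        return out, report
    X = out.data[num_cols].to_numpy(dtype=float)
    n = X.shape[0]
    observed = ~np.isnan(X)
    all_missing = ~observed.any(axis=0)
    if all_missing.any():
        bad = [num_cols[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"column(s) entirely missing, cannot impute: {bad}")
    medians = np.nanmedian(X, axis=0)
    rows_with_missing = np.flatnonzero(~observed.all(axis=1))
    filled = X.copy()
    for i in rows_with_missing:
        obs_i = observed[i]
        missing_j = np.flatnonzero(~obs_i)
        # donors must be observed in the target column and share >=1 observed
        # feature with row i for the distance to be defined
        shared = observed & obs_i[None, :]
        shared_count = shared.sum(axis=1)
        diffs = np.where(shared, X - X[i], 0.0)
        with np.errstate(invalid="ignore"):
            dists = np.sqrt(np.nansum(diffs**2, axis=1))
        dists[shared_count == 0] = np.inf
        dists[i] = np.inf
        for j in missing_j:
            cand = dists.copy()
            cand[~observed[:, j]] = np.inf
            best = int(np.argmin(cand))  # argmin takes the lowest index on ties
            if np.isinf(cand[best]):
                filled[i, j] = medians[j]
            else:
                filled[i, j] = X[best, j]
            report.imputed_cell_count += 1
    out.data[num_cols] = filled
    return out, report


def encode_labels(matrix: OmicsMatrix) -> tuple[OmicsMatrix, PreprocessReport]:
    """Map each categorical column to integers 0..L-1 by lexicographic level order."""
    out = matrix.copy()
    report = PreprocessReport()
    report.stages.append("encode")
    for col in matrix.categorical_columns():
        levels = sorted(out.data[col].dropna().astype(str).unique())
        mapping = {lvl: i for i, lvl in enumerate(levels)}
        out.data[col] = out.data[col].astype(str).map(mapping).astype(float)
        out.feature_kinds[col] = NUMERIC
        report.encoded_feature_names[col] = mapping
    return out, report


def drop_leakage(
    matrix: OmicsMatrix, leak_names: list[str]
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Remove outcome-leaking columns (e.g. vital status) by name."""
    report = PreprocessReport()
    report.stages.append("drop_leakage")
    keep = list(matrix.feature_names)
    for name in leak_names:
        if name in keep:
            keep.remove(name)
            report.drop(name, "vital_status")
        else:
            warnings.warn(f"leakage column {name!r} not present", stacklevel=2)
    return matrix.select_features(keep), report


def zscore(
    matrix: OmicsMatrix, stats_from: OmicsMatrix | None = None
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Standardize each column to mean 0, sd 1 (ddof=1); drop constant columns.

    ``stats_from`` supplies the mean/sd (e.g. the fitting cohort) so the same
    transform can be applied to held-out patients.
    """
    report = PreprocessReport()
    report.stages.append("zscore")
    ref = matrix if stats_from is None else stats_from
    X = ref.data.to_numpy(dtype=float)
    if np.isnan(matrix.data.to_numpy(dtype=float)).any():
        raise ValueError("zscore requires a fully imputed matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep_mask = sd > 0
    for name, ok in zip(ref.feature_names, keep_mask):
        if not ok:
            report.drop(str(name), "zero_variance")
    keep = [c for c, ok in zip(ref.feature_names, keep_mask) if ok]
    sub = matrix.select_features(keep)
    sub.data = (sub.data - mu[keep_mask]) / sd[keep_mask]
    return sub, report


def filter_correlated(
    matrix: OmicsMatrix, threshold: float = DEFAULT_CORRELATION_THRESHOLD
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Drop features correlated above ``threshold`` with an earlier retained feature.

    Scans columns in order; a candidate is dropped if |Pearson r| with any
    already-retained column exceeds the threshold.  Survivors keep their
    original order, so the output is idempotent under re-filtering.
    """
    report = PreprocessReport()
    report.stages.append("filter_correlated")
    report.correlation_threshold = threshold
    X = matrix.values()
    if np.isnan(X).any():
        raise ValueError("correlation filter requires a fully imputed matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    norms[norms == 0] = 1.0  # constant columns correlate with nothing
    U = Xc / norms
    kept: list[int] = []
    for j in range(p):
        if kept:
            r = np.abs(U[:, kept].T @ U[:, j])
            if (r > threshold).any():
                report.drop(str(matrix.feature_names[j]), "high_correlation")
                continue
        kept.append(j)
    return matrix.select_features(matrix.feature_names[kept]), report


def integrate(
    matrices: list[OmicsMatrix], threshold: float = DEFAULT_CORRELATION_THRESHOLD
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Inner-join blocks on patient ID, then re-standardize and re-filter.

    Feature-name collisions across blocks are resolved by prefixing the
    block tag.
    """
    if not matrices:
        raise ValueError("no matrices to integrate")
    ids = matrices[0].patient_ids
    for m in matrices[1:]:
        ids = ids.intersection(m.patient_ids)
    if len(ids) == 0:
        raise ValueError("no patients shared across blocks")
    ids = matrices[0].patient_ids[matrices[0].patient_ids.isin(ids)]

    seen: set[str] = set()
    frames, tags, kinds = [], [], []
    for m in matrices:
        sub = m.select_patients(ids)
        rename = {}
        for c in sub.feature_names:
            if c in seen:
                rename[c] = f"{sub.block_tags[c]}:{c}"
        if rename:
            sub = OmicsMatrix(
                sub.data.rename(columns=rename),
                sub.block_tags.rename(index=rename),
                sub.feature_kinds.rename(index=rename),
            )
        seen.update(sub.feature_names)
        frames.append(sub.data)
        tags.append(sub.block_tags)
        kinds.append(sub.feature_kinds)
    merged = OmicsMatrix(pd.concat(frames, axis=1), pd.concat(tags), pd.concat(kinds))
    merged, rep_z = zscore(merged)
    merged, rep_f = filter_correlated(merged, threshold)
    report = PreprocessReport()
    report.stages.append("integrate")
    report.merge(rep_z)
    report.merge(rep_f)
    return merged, report


def preprocess_block(
    matrix: OmicsMatrix,
    leak_names: list[str] | None = None,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Full single-block pipeline: impute -> encode -> drop leakage -> zscore -> filter."""
    report = PreprocessReport()
    m, r = impute_knn(matrix)
    report.merge(r)
    m, r = encode_labels(m)
    report.merge(r)
    m, r = drop_leakage(m, leak_names or [])
    report.merge(r)
    m, r = zscore(m)
    report.merge(r)
    m, r = filter_correlated(m, threshold)
    report.merge(r)
    return m, report
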