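"""Feature tables, cohort metadata, normalization, filtering, and PCA.

The in-memory containers are thin wrappers around :class:`pandas.DataFrame`
with the orientation fixed to *samples in rows, features in columns*.  On
disk, tables default to the QIIME-style orientation (features in rows,
samples in the header) but both orientations are supported symmetrically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: Closed vocabulary of diagnostic groups.
GROUPS = ("CRC", "adenoma", "control", "advanced_adenoma", "nonadvanced_adenoma")

ValueKind = Literal["count", "concentration", "normalized"]
Orientation = Literal["features_in_rows", "samples_in_rows"]

METADATA_COLUMNS = ("group", "age", "sex", "bmi", "smoking")


class TableError(ValueError):
    """Raised when a feature table or metadata file violates its contract."""


@dataclass
class FeatureTable:
    """One omics layer: a samples x features value matrix with identifiers.

    Parameters
    ----------
    layer_name:
        Tag identifying the omics layer (e.g. ``"microbiota"``).
    values:
        DataFrame with sample IDs as index and feature IDs as columns.
    value_kind:
        ``"count"`` (nonnegative integers), ``"concentration"``
        (nonnegative reals) or ``"normalized"`` (autoscaled).
    """

    layer_name: str
    values: pd.DataFrame
    value_kind: ValueKind = "count"

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise TableError(f"duplicate sample ID {dup!r} in layer {self.layer_name!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise TableError(f"duplicate feature ID {dup!r} in layer {self.layer_name!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableError(f"non-numeric values in layer {self.layer_name!r}")
        if self.value_kind == "count":
            if np.any(arr < 0) or np.any(arr != np.round(arr)):
                raise TableError(
                    f"count table {self.layer_name!r} must hold nonnegative integers"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.layer_name, self.values.copy(), self.value_kind)


@dataclass
class CohortMetadata:
    """Per-sample diagnostic group plus matched covariates.

    ``table`` is indexed by sample ID with columns
    ``group, age, sex, bmi, smoking``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise TableError(f"metadata missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise TableError("duplicate sample IDs in metadata")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise TableError(
                f"unknown group label(s) {sorted(bad)}; allowed: {list(GROUPS)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def subset(self, sample_ids: Sequence[str]) -> "CohortMetadata":
        return CohortMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a PCA fit."""

    scores: np.ndarray          # (n_samples, k)
    loadings: np.ndarray        # (n_features, k), column-orthonormal
    explained_variance_fractions: np.ndarray  # (k,), non-increasing, sums <= 1
    mean_: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# I/O


def read_feature_table(
    path: str | Path,
    layer_name: str,
    orientation: Orientation = "features_in_rows",
    value_kind: ValueKind = "count",
) -> FeatureTable:
    """Read a TSV feature table.

    The default orientation matches QIIME-style exports: feature IDs in the
    first column, sample IDs in the header.  ``samples_in_rows`` reads the
    transposed layout.  Parse failures report the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise TableError(f"{path}: malformed TSV: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise TableError(f"{path}: duplicated ID {dup!r} in first column")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise TableError(f"{path}: duplicated ID {dup!r} in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        # +2: one for the header line, one for 1-based numbering
        raise TableError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at line {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    if orientation == "features_in_rows":
        numeric = numeric.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    numeric.index = numeric.index.astype(str).rename(None)
    numeric.columns = numeric.columns.astype(str).rename(None)
    if value_kind == "count":
        arr = numeric.to_numpy()
        if np.all(arr == np.round(arr)):
            numeric = numeric.astype(np.int64)
    return FeatureTable(layer_name, numeric, value_kind)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    orientation: Orientation = "features_in_rows",
) -> None:
    """Write a TSV feature table ('.' decimal, UTF-8)."""
    if orientation == "features_in_rows":
        df = table.values.T.copy()
        df.index.name = "feature_id"
    else:
        df = table.values.copy()
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path: str | Path) -> CohortMetadata:
    """Read the cohort metadata TSV (``sample_id group age sex bmi smoking``)."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.index = df.index.astype(str)
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Alignment and preprocessing


def align_samples(
    tables: Sequence[FeatureTable],
    meta: CohortMetadata,
    groups: tuple[str, str] | None = None,
) -> tuple[list[FeatureTable], CohortMetadata]:
    """Restrict tables and metadata to their shared samples, in one order.

    If ``groups`` is given, samples are additionally restricted to those two
    diagnostic groups; each group must retain at least one sample.  Row order
    follows the metadata.
    """
    if groups is not None:
        for g in groups:
            if g not in GROUPS:
                raise TableError(f"unknown group {g!r}; allowed: {list(GROUPS)}")
    shared = [s for s in meta.sample_ids if all(s in t.values.index for t in tables)]
    dropped = set(meta.sample_ids) - set(shared)
    for t in tables:
        dropped |= set(t.sample_ids) - set(shared)
    if dropped:
        logger.warning("align_samples: dropping %d sample(s): %s",
                       len(dropped), sorted(dropped))
    if groups is not None:
        grp = meta.groups
        shared = [s for s in shared if grp[s] in groups]
        for g in groups:
            if not any(grp[s] == g for s in shared):
                raise TableError(f"no samples left in group {g!r} after alignment")
    if not shared:
        raise TableError("no shared samples across tables and metadata")
    aligned = [
        FeatureTable(t.layer_name, t.values.loc[shared].copy(), t.value_kind)
        for t in tables
    ]
    return aligned, meta.subset(shared)


def autoscale(table: FeatureTable) -> FeatureTable:
    """Standardize each feature to mean 0, SD 1 (auto scaling).

    The sample SD uses the n-1 denominator.  Zero-variance features are
    dropped with a warning; it is an error if nothing remains.
    """
    if table.n_samples < 2:
        raise TableError("autoscale requires at least 2 samples")
    X = table.matrix
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise TableError(f"all features in {table.layer_name!r} have zero variance")
    if not keep.all():
        dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
        warnings.warn(
            f"autoscale({table.layer_name}): dropped {len(dropped)} "
            f"zero-variance feature(s): {dropped[:10]}",
            stacklevel=2,
        )
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=1)
    df = pd.DataFrame(
        Z,
        index=table.values.index,
        columns=[f for f, k in zip(table.feature_ids, keep) if k],
    )
    return FeatureTable(table.layer_name, df, "normalized")


def filter_sparse_features(table: FeatureTable, min_prevalence: float) -> FeatureTable:
    """Remove features nonzero in fewer than ``min_prevalence`` of samples."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must lie in [0, 1]")
    prevalence = (table.matrix != 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    if removed:
        logger.info(
            "filter_sparse_features(%s): removed %d feature(s) below prevalence %.3g",
            table.layer_name, len(removed), min_prevalence,
        )
    return FeatureTable(
        table.layer_name, table.values.loc[:, keep].copy(), table.value_kind
    )


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample proportions (rows sum to 1)."""
    if table.value_kind != "count":
        raise TableError("relative_abundance expects a count table")
    X = table.matrix
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise TableError(
            f"zero-total sample(s): {[table.sample_ids[i] for i in zero]}"
        )
    df = pd.DataFrame(
        X / totals[:, None], index=table.values.index, columns=table.values.columns
    )
    return FeatureTable(table.layer_name, df, "concentration")


def run_pca(table: FeatureTable, n_components: int | None = None) -> PcaResult:
    """PCA of an autoscaled table (scores, orthonormal loadings, variance fractions)."""
    if table.value_kind != "normalized":
        raise TableError("run_pca expects an autoscaled (normalized) table")
    n, p = table.values.shape
    max_k = min(n - 1, p)
    if n_components is None:
        n_components = max_k
    if n_components > max_k:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)={max_k}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(table.matrix)
    return PcaResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_fractions=pca.explained_variance_ratio_,
        mean_=pca.mean_,
    )
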