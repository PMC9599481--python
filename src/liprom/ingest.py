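"""Reading concentration tables, QC filtering and half-minimum imputation.

Quantifiability filtering removes features with more than ``max_missing``
missing values or a QC coefficient of variation above ``max_cv``; boundary
values are retained (the removal thresholds are strict inequalities).
Remaining missing cells are imputed with one half of the per-feature
minimum observed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import GroupDesign, QuantTable, TableError

DEFAULT_MAX_MISSING = 0.30
DEFAULT_MAX_CV = 0.30


@dataclass
class QcSummary:
    """Per-feature QC metrics and the keep/remove verdict."""

    table: pd.DataFrame  # index feature_id; columns cv, missing_fraction, kept

    @property
    def kept_features(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])

    @property
    def removed_features(self) -> list[str]:
        return list(self.table.index[~self.table["kept"]])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index_label="feature_id")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_quant_table(
    path: str | Path, meta_path: str | Path, sep: str = ","
) -> QuantTable:
    """Read a wide concentration table plus its feature metadata file.

    The data file has sample ids in the first column and one column per
    feature; empty cells are missing values.  The metadata file maps
    ``feature_id`` to ``layer``, ``lipid_class`` and ``units``.
    """
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values = values.astype(float)
    meta = pd.read_csv(meta_path, sep=sep, index_col=0, keep_default_na=False)
    meta.index = meta.index.astype(str)
    return QuantTable(values, meta)


def write_quant_table(
    table: QuantTable, path: str | Path, meta_path: str | Path, sep: str = ","
) -> None:
    """Inverse of :func:`read_quant_table` (blank cells for missing)."""
    table.values.to_csv(path, sep=sep)
    table.feature_meta.to_csv(meta_path, sep=sep)


def read_design(path: str | Path, reference: str = "NL", sep: str = ",") -> GroupDesign:
    """Read a two-column sample,group design file."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise TableError(f"design file {path} needs sample and group columns")
    assignment = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    return GroupDesign(assignment, reference=reference)


def write_design(design: GroupDesign, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {"sample_id": design.assignment.index, "group": design.assignment.values}
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# QC metrics and filtering
# ---------------------------------------------------------------------------

def compute_cv(qc_table: QuantTable) -> pd.Series:
    """Per-feature coefficient of variation over QC replicates.

    CV = sample standard deviation / mean, missing cells excluded.
    Features with zero mean or fewer than 2 observed replicates get NaN
    (undefined, flagged).  Requires at least 3 QC replicate rows.
    """
    if qc_table.n_samples < 3:
        raise TableError("compute_cv needs at least 3 QC replicates")
    vals = qc_table.values
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    n_obs = vals.notna().sum(axis=0)
    cv = sd / mean.where(mean > 0)
    cv[n_obs < 2] = np.nan
    return cv.rename("cv")


def class_cv_summary(qc_table: QuantTable) -> pd.Series:
    """Median per-feature CV by lipid class (reporting convenience)."""
    cv = compute_cv(qc_table)
    meta = qc_table.feature_meta
    lipids = meta.index[meta["layer"] == "lipid"]
    return cv.loc[lipids].groupby(meta.loc[lipids, "lipid_class"]).median()


def qc_summary(
    table: QuantTable,
    cv: pd.Series,
    max_missing: float = DEFAULT_MAX_MISSING,
    max_cv: float = DEFAULT_MAX_CV,
) -> QcSummary:
    """Combine missingness and CV into a keep/remove verdict per feature.

    A feature is kept iff missing_fraction <= max_missing and cv <= max_cv
    (strict removal above either threshold; NaN CV counts as failing).
    """
    miss = table.missing_fraction()
    cv_aligned = cv.reindex(table.feature_ids)
    kept = (miss <= max_missing) & (cv_aligned <= max_cv)
    out = pd.DataFrame(
        {
            "cv": cv_aligned,
            "missing_fraction": miss,
            "kept": kept.fillna(False).astype(bool),
        }
    ).rename_axis("feature_id")
    return QcSummary(out)


def filter_features(
    table: QuantTable,
    qc: QcSummary,
    max_missing: float = DEFAULT_MAX_MISSING,
    max_cv: float = DEFAULT_MAX_CV,
) -> tuple[QuantTable, QcSummary]:
    """Drop features failing the missingness/CV quantifiability rule.

    ``qc`` must cover every feature of the table.  The verdict is
    recomputed against the supplied thresholds so that QcSummary.kept
    always matches the returned table.
    """
    missing = [f for f in table.feature_ids if f not in qc.table.index]
    if missing:
        raise TableError(f"QC summary lacks features: {missing}")
    refreshed = qc_summary(
        table, qc.table["cv"], max_missing=max_missing, max_cv=max_cv
    )
    kept = refreshed.kept_features
    return table.subset_features(kept), refreshed


def impute_half_min(table: QuantTable) -> QuantTable:
    """Impute missing cells with half the per-feature minimum observed value.

    Observed cells are untouched.  A feature with no observed value at all
    cannot be imputed and raises (it should have been filtered).
    """
    vals = table.values.copy()
    all_missing = vals.columns[vals.isna().all(axis=0)].tolist()
    if all_missing:
        raise TableError(f"cannot impute all-missing features: {all_missing}")
    fill = vals.min(axis=0, skipna=True) / 2.0
    vals = vals.fillna(fill)
    return QuantTable(vals, table.feature_meta.copy())


def ingest(
    table: QuantTable,
    qc_table: QuantTable,
    max_missing: float = DEFAULT_MAX_MISSING,
    max_cv: float = DEFAULT_MAX_CV,
) -> tuple[QuantTable, QcSummary]:
    """Full QC stage: CV from replicates, filter, impute."""
    cv = compute_cv(qc_table)
    summary = qc_summary(table, cv, max_missing=max_missing, max_cv=max_cv)
    filtered, summary = filter_features(
        table, summary, max_missing=max_missing, max_cv=max_cv
    )
    return impute_half_min(filtered), summary
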