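"""Data-processing pipeline: categorical encoding, median imputation, and
z-score outlier capping.

The protocol is: encode the two categorical columns (TZ, BP) as 0/1, impute
missing numeric cells with the column median, then cap cells whose z-score
(computed from the pre-replacement column statistics, population standard
deviation) exceeds +/-3 at mean +/- 3*std.  The target column CBT is never
altered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ENCODING_MAPS",
    "PreprocessReport",
    "encode_categoricals",
    "impute_median",
    "cap_outliers_zscore",
    "preprocess_table",
    "default_numeric_columns",
]

#: fixed category -> integer maps
ENCODING_MAPS: dict[str, dict[str, int]] = {
    "TZ": {"A.M.": 0, "P.M.": 1},
    "BP": {"standing": 0, "lying down": 1},
}

TARGET_COLUMN = "CBT"


@dataclass
class PreprocessReport:
    """Bookkeeping of what preprocessing changed."""

    n_imputed_per_column: dict[str, int] = field(default_factory=dict)
    n_outliers_capped_per_column: dict[str, int] = field(default_factory=dict)
    column_means: dict[str, float] = field(default_factory=dict)
    column_stds: dict[str, float] = field(default_factory=dict)
    encoding_maps: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _normalize_label(value: str) -> str:
    return str(value).strip().lower()


def encode_categoricals(
    table: pd.DataFrame,
    columns: dict[str, dict[str, int]] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Encode categorical columns by their fixed 0/1 maps.

    Matching is case-insensitive after trimming whitespace.  Columns that
    are already numeric 0/1 pass through unchanged (encoding is idempotent).
    An unseen label raises ``ValueError`` naming the offending value.
    """
    maps = ENCODING_MAPS if columns is None else columns
    out = table.copy()
    applied: dict[str, dict[str, int]] = {}
    for col, mapping in maps.items():
        if col not in out.columns:
            continue
        applied[col] = dict(mapping)
        series = out[col]
        if pd.api.types.is_numeric_dtype(series):
            codes = set(pd.unique(series.dropna()))
            if not codes <= set(float(v) for v in mapping.values()):
                bad = sorted(codes - set(float(v) for v in mapping.values()))
                raise ValueError(f"column {col!r}: unexpected encoded value(s) {bad}")
            out[col] = series.astype(float)
            continue
        lowered = {_normalize_label(k): v for k, v in mapping.items()}

        def encode_one(value, col=col, lowered=lowered):
            if pd.isna(value):
                raise ValueError(f"column {col!r}: missing categorical value")
            key = _normalize_label(value)
            if key not in lowered:
                raise ValueError(f"column {col!r}: unseen category label {value!r}")
            return float(lowered[key])

        out[col] = series.map(encode_one)
    return out, applied


def default_numeric_columns(table: pd.DataFrame) -> list[str]:
    """Numeric columns eligible for imputation/capping (excludes the target,
    encoded categoricals, and row metadata)."""
    skip = {TARGET_COLUMN, "day", "hour"} | set(ENCODING_MAPS)
    return [
        c for c in table.columns
        if c not in skip and pd.api.types.is_numeric_dtype(table[c])
    ]


def impute_median(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    report: PreprocessReport | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Replace missing cells in ``columns`` with the column median."""
    out = table.copy()
    if columns is None:
        columns = default_numeric_columns(out)
    if TARGET_COLUMN in columns:
        raise ValueError(f"target column {TARGET_COLUMN!r} must not be imputed")
    report = report or PreprocessReport(encoding_maps=dict(ENCODING_MAPS))
    for col in columns:
        series = out[col]
        n_missing = int(series.isna().sum())
        if n_missing == len(series):
            raise ValueError(f"column {col!r} is entirely missing; median undefined")
        if n_missing:
            out[col] = series.fillna(series.median())
        report.n_imputed_per_column[col] = n_missing
    return out, report


def cap_outliers_zscore(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    threshold: float = 3.0,
    report: PreprocessReport | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Cap cells whose |z| exceeds ``threshold`` at mean +/- threshold*std.

    Statistics (mean, population std) are computed once from the
    pre-replacement data and are not recomputed between replacements.  High
    outliers go to mean + threshold*std; low outliers symmetrically to
    mean - threshold*std.  Zero-variance columns are left untouched.
    """
    out = table.copy()
    if columns is None:
        columns = default_numeric_columns(out)
    if TARGET_COLUMN in columns:
        raise ValueError(f"target column {TARGET_COLUMN!r} must not be capped")
    report = report or PreprocessReport(encoding_maps=dict(ENCODING_MAPS))
    for col in columns:
        x = out[col].to_numpy(float)
        if np.isnan(x).any():
            raise ValueError(f"column {col!r} still has missing cells; impute first")
        mean = float(np.mean(x))
        std = float(np.std(x))  # population formula (divide by n)
        report.column_means[col] = mean
        report.column_stds[col] = std
        if std == 0.0 or not np.isfinite(std):
            logger.info("column %r has zero variance; no outliers flagged", col)
            report.n_outliers_capped_per_column[col] = 0
            continue
        z = (x - mean) / std
        high = z > threshold
        low = z < -threshold
        x = np.where(high, mean + threshold * std, x)
        x = np.where(low, mean - threshold * std, x)
        out[col] = x
        report.n_outliers_capped_per_column[col] = int(high.sum() + low.sum())
    return out, report


def preprocess_table(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    threshold: float = 3.0,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full protocol: encode, impute, cap.  Returns table and report."""
    encoded, maps = encode_categoricals(table)
    report = PreprocessReport(encoding_maps=maps)
    imputed, report = impute_median(encoded, columns, report)
    capped, report = cap_outliers_zscore(imputed, columns, threshold, report)
    return capped, report
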