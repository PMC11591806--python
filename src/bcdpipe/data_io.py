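"""Labeled tabular data: containers, readers and report writers.

The universal currency of the pipeline is :class:`LabeledTable`, a dense
numeric instance matrix with one categorical label per row.  Two file
dialects are supported: generic headered CSV, and the Wisconsin breast
cancer (original) cytology file — comma separated, a leading sample-ID
column, nine integer features on a 1-10 scale, ``?`` for a missing value,
and class codes 2 (benign) / 4 (malignant).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig  # noqa: F401  (re-exported: config lives with I/O)

logger = logging.getLogger(__name__)

BENIGN = "benign"
MALIGNANT = "malignant"

#: class-code mapping of the WBCD dialect; a bijection on {2, 4}
WBCD_CLASS_CODES = {2: BENIGN, 4: MALIGNANT}
WBCD_CLASS_LABELS = {v: k for k, v in WBCD_CLASS_CODES.items()}

WBCD_FEATURE_NAMES = (
    "clump_thickness",
    "uniformity_cell_size",
    "uniformity_cell_shape",
    "marginal_adhesion",
    "single_epithelial_cell_size",
    "bare_nuclei",
    "bland_chromatin",
    "normal_nucleoli",
    "mitoses",
)


class ParseError(ValueError):
    """Raised for malformed input files (bad field counts, codes, cells)."""


@dataclass
class LabeledTable:
    """A numeric instance matrix with class labels.

    values : (n, b) float array, no missing entries
    labels : length-n array of label strings
    feature_names : length-b names
    instance_ids : length-n opaque identifiers (duplicates allowed; the row
        index is the primary key)
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    instance_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, b = self.values.shape
        if n < 1 or b < 1:
            raise ValueError("table must have at least one row and one feature")
        if len(self.labels) != n:
            raise ValueError("labels length must match row count")
        if len(self.feature_names) != b:
            raise ValueError("feature_names length must match column count")
        if not self.instance_ids:
            self.instance_ids = [str(i) for i in range(n)]
        if len(self.instance_ids) != n:
            raise ValueError("instance_ids length must match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no missing entries)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def b(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def subset_rows(self, idx: Sequence[int] | np.ndarray) -> "LabeledTable":
        idx = np.asarray(idx, dtype=int)
        return LabeledTable(
            self.values[idx],
            self.labels[idx],
            list(self.feature_names),
            [self.instance_ids[i] for i in idx],
        )

    def subset_features(self, idx: Sequence[int] | np.ndarray) -> "LabeledTable":
        idx = np.asarray(idx, dtype=int)
        return LabeledTable(
            self.values[:, idx],
            self.labels,
            [self.feature_names[i] for i in idx],
            list(self.instance_ids),
        )


def read_wbcd(path: str | Path) -> LabeledTable:
    """Read a file in the WBCD dialect, dropping rows with missing values.

    Each row has 11 comma-separated fields: sample ID, nine integer
    features, and the class code (2=benign, 4=malignant).  Rows containing
    the missing marker ``?`` are dropped, never imputed; the load summary
    is logged.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    labels: list[str] = []
    n_read = 0
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 11:
                raise ParseError(
                    f"{path}:{lineno}: expected 11 comma-separated fields, got {len(fields)}"
                )
            n_read += 1
            if "?" in fields:
                n_dropped += 1
                continue
            try:
                code = int(fields[-1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: class code {fields[-1]!r} is not an integer")
            if code not in WBCD_CLASS_CODES:
                raise ParseError(f"{path}:{lineno}: unknown class code {code} (expected 2 or 4)")
            try:
                feats = [float(v) for v in fields[1:-1]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric feature value ({exc})")
            ids.append(fields[0])
            rows.append(feats)
            labels.append(WBCD_CLASS_CODES[code])
    logger.info("read %d rows from %s: kept %d, dropped %d with missing values",
                n_read, path, n_read - n_dropped, n_dropped)
    if not rows:
        raise ParseError(f"{path}: no complete rows after dropping missing values")
    return LabeledTable(np.array(rows), np.array(labels, dtype=object),
                        list(WBCD_FEATURE_NAMES), ids)


def read_csv_labeled(path: str | Path, label_column: str) -> LabeledTable:
    """Read a generic headered CSV; every non-label column is a feature.

    Rows containing any missing value are dropped with a logged count; a
    non-numeric feature cell raises :class:`ParseError` naming row/column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ParseError(f"{path}: label column {label_column!r} not in header")
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise ParseError(f"{path}: no feature columns besides the label")
    for col in feature_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row}, column {col!r}"
            )
        df[col] = coerced
    n_read = len(df)
    complete = df.dropna()
    n_dropped = n_read - len(complete)
    if n_dropped:
        logger.info("dropped %d of %d rows with missing values from %s", n_dropped, n_read, path)
    if complete.empty:
        raise ParseError(f"{path}: no complete rows after dropping missing values")
    return LabeledTable(
        complete[feature_cols].to_numpy(dtype=float),
        complete[label_column].astype(str).to_numpy(dtype=object),
        feature_cols,
        [str(i) for i in complete.index],
    )


def write_wbcd(table: LabeledTable, path: str | Path) -> None:
    """Write a two-class table in the WBCD dialect (codes 2/4, integer features)."""
    unknown = set(table.labels) - set(WBCD_CLASS_LABELS)
    if unknown:
        raise ValueError(f"labels {unknown} have no WBCD class code")
    with open(path, "w") as fh:
        for i in range(table.n):
            feats = ",".join(str(int(round(v))) for v in table.values[i])
            fh.write(f"{table.instance_ids[i]},{feats},{WBCD_CLASS_LABELS[table.labels[i]]}\n")


def write_report(report: Any, path: str | Path) -> None:
    """Write a report object (anything with ``to_dict``, or a mapping) as JSON."""
    doc = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
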