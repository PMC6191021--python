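"""Delimited-text readers/writers for prediction tables and result tables.

A prediction table is a CSV file with optional ``#``-prefixed metadata
lines, then a header: required columns ``sample_id``, ``fold``,
``label``; optional ``repeat``; every remaining column is one
configuration's out-of-sample predictions.  Fold ids are 1-based on
disk.  Empty cells mark predictions that were never produced.
"""

from __future__ import annotations

import io as _io
import sys
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import FoldPartition, PredictionTensor

RESERVED = ("sample_id", "repeat", "fold", "label")


def read_metadata(path) -> Dict[str, str]:
    """The ``# key = value`` lines preceding the header, as a dict."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_prediction_table(path) -> Tuple[PredictionTensor, np.ndarray, FoldPartition]:
    """Parse a prediction table into (tensor, labels, fold partition)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = [c for c in ("sample_id", "fold", "label") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    config_cols = [c for c in df.columns if c not in RESERVED]
    if not config_cols:
        raise ValueError(f"{path}: no configuration columns found")
    if "repeat" not in df.columns:
        df = df.assign(repeat=1)
    dup = df.duplicated(subset=["sample_id", "repeat"])
    if dup.any():
        row = df.index[dup][0]
        raise ValueError(
            f"{path}: duplicate (sample_id, repeat) at data row {row + 1}"
        )
    sample_ids = df["sample_id"].unique()  # first-appearance order
    repeats = np.sort(df["repeat"].unique())
    n, r, c = len(sample_ids), len(repeats), len(config_cols)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    repeat_pos = {s: i for i, s in enumerate(repeats)}
    counts = df.groupby("repeat", sort=False)["sample_id"].nunique()
    if counts.nunique() != 1 or counts.iloc[0] != n:
        raise ValueError(f"{path}: repeats cover different sample sets")

    values = np.full((n, c, r), np.nan, dtype=object)
    fold_of = np.full((n, r), -1, dtype=int)
    labels = np.empty(n, dtype=object)
    for _, row in df.iterrows():
        i = sample_pos[row["sample_id"]]
        k = repeat_pos[row["repeat"]]
        fold = int(row["fold"])
        if fold < 1:
            raise ValueError(f"{path}: fold ids must be >= 1 (sample {row['sample_id']})")
        fold_of[i, k] = fold - 1
        labels[i] = row["label"]
        for j, col in enumerate(config_cols):
            values[i, j, k] = row[col]
    missing = np.frompyfunc(lambda v: v is np.nan or pd.isna(v), 1, 1)(values).astype(
        bool
    )
    values = np.where(missing, 0, values)
    try:
        values = values.astype(float)
        labels_arr = labels.astype(float)
        if np.allclose(labels_arr, labels_arr.astype(int)):
            labels_arr = labels_arr.astype(int)
    except (TypeError, ValueError):
        labels_arr = labels
    k_max = int(fold_of.max()) + 1
    for rep in range(r):
        present = np.unique(fold_of[:, rep])
        if not np.array_equal(present, np.arange(k_max)):
            raise ValueError(
                f"{path}: fold ids of repeat {repeats[rep]} do not form 1..K"
            )
    tensor = PredictionTensor(values, fold_of, list(config_cols), missing)
    partition = FoldPartition(fold_of[:, 0], k_max)
    return tensor, np.asarray(labels_arr), partition


def write_prediction_table(
    path, tensor: PredictionTensor, y, metadata: Optional[Dict] = None
) -> None:
    """Write a tensor (with labels) as a prediction table CSV."""
    y = np.asarray(y)
    rows = []
    for rep in range(tensor.n_repeats):
        for i in range(tensor.n_samples):
            row = {
                "sample_id": i + 1,
                "fold": int(tensor.fold_of[i, rep]) + 1,
                "label": y[i],
            }
            if tensor.n_repeats > 1:
                row["repeat"] = rep + 1
            for j, cid in enumerate(tensor.configuration_ids):
                if tensor.missing_mask[i, j, rep]:
                    row[cid] = ""
                else:
                    v = tensor.values[i, j, rep]
                    # shortest round-trip repr so read -> write is lossless
                    row[cid] = repr(float(v)) if isinstance(v, (float, np.floating)) else v
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False)


def write_result_table(path_or_none, df: pd.DataFrame, metadata: Optional[Dict] = None):
    """Write a tidy result table with metadata lines; None means stdout."""
    buf = _io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key} = {value}\n")
    df.to_csv(buf, index=False)
    if path_or_none is None:
        sys.stdout.write(buf.getvalue())
    else:
        with open(path_or_none, "w") as fh:
            fh.write(buf.getvalue())
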