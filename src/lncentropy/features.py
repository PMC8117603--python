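"""Assemble per-transcript feature vectors into a labeled table.

Two feature sets are supported:

* ``integrated35`` — 1 length + 4 ORF + 30 information-theory features,
* ``kmer84``       — the 84-dimensional k-mer frequency baseline.

Tables are plain pandas DataFrames with ``id`` and ``label`` columns
followed by the feature columns in a fixed, documented order, so they
round-trip through CSV byte-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import (
    ENTROPY_FEATURE_NAMES,
    EntropyConfig,
    entropy_feature_block,
    gte_order_clamped,
)
from .io_prep import Dataset
from .kmers import KMER_FEATURE_NAMES, kmer_feature_block
from .orf import ORF_FEATURE_NAMES, orf_feature_block

FEATURE_SETS = ("integrated35", "kmer84")

INTEGRATED35_COLUMNS: tuple[str, ...] = ORF_FEATURE_NAMES + ENTROPY_FEATURE_NAMES
KMER84_COLUMNS: tuple[str, ...] = KMER_FEATURE_NAMES

assert len(INTEGRATED35_COLUMNS) == 35
assert len(KMER84_COLUMNS) == 84


def feature_names(feature_set: str) -> tuple[str, ...]:
    if feature_set == "integrated35":
        return INTEGRATED35_COLUMNS
    if feature_set == "kmer84":
        return KMER84_COLUMNS
    raise ValueError(f"unknown feature set {feature_set!r}; expected one of {FEATURE_SETS}")


def build_feature_table(
    ds: Dataset,
    feature_set: str = "integrated35",
    cfg: EntropyConfig | None = None,
) -> pd.DataFrame:
    """One row per transcript, in dataset order; deterministic.

    Raises with the offending transcript id if any sequence violates a
    feature precondition (e.g. too short for the gapped-MI block).
    """
    names = feature_names(feature_set)
    cfg = cfg or EntropyConfig()
    rows = []
    clamped = 0
    for rec in ds.records:
        try:
            if feature_set == "integrated35":
                vec = np.concatenate(
                    [orf_feature_block(rec.seq), entropy_feature_block(rec.seq, cfg)]
                )
                if any(gte_order_clamped(len(rec.seq), k) for k in cfg.gte_orders):
                    clamped += 1
            else:
                vec = kmer_feature_block(rec.seq)
        except ValueError as err:
            raise ValueError(f"transcript {rec.id!r}: {err}") from err
        rows.append(vec)
    table = pd.DataFrame(rows, columns=list(names))
    table.insert(0, "id", ds.ids())
    table.insert(1, "label", [r.label for r in ds.records])
    table.attrs["feature_set"] = feature_set
    table.attrs["gte_clamped_records"] = clamped
    return table


def write_feature_csv(table: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    if "id" not in table.columns or "label" not in table.columns:
        raise ValueError(f"{path}: feature CSV must have 'id' and 'label' columns")
    cols = tuple(c for c in table.columns if c not in ("id", "label"))
    if cols == INTEGRATED35_COLUMNS:
        table.attrs["feature_set"] = "integrated35"
    elif cols == KMER84_COLUMNS:
        table.attrs["feature_set"] = "kmer84"
    else:
        raise ValueError(f"{path}: columns match neither feature set")
    return table


def split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix, binary labels (lncRNA = 1), and feature names."""
    names = [c for c in table.columns if c not in ("id", "label")]
    if table["label"].isna().any():
        missing = table.loc[table["label"].isna(), "id"].tolist()
        raise ValueError(f"unlabeled rows: {missing[:5]}")
    y = (table["label"] == "lncRNA").to_numpy(dtype=int)
    X = table[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    return X, y, names
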