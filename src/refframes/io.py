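"""Readers and writers for the toolkit's interchange formats.

Canonical interchange is TSV: feature tables (taxa-as-rows by default, the
common biom convention, normalized internally to samples x taxa), QIIME2-
style sample metadata (sample id in the first column), two-column
load/copy-number tables, clr differentials, rank-plot exports, and JSON run
manifests.  BIOM tables (HDF5 or JSON dialect) are read via biom-format;
writing stays TSV-only so artifacts are diff-able.  All writes are atomic:
content goes to a temporary file in the destination directory and is
renamed into place.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import DifferentialSet, FeatureTable

__all__ = [
    "read_feature_table",
    "read_metadata",
    "read_value_column",
    "write_differentials",
    "read_differentials",
    "write_tsv",
    "write_manifest",
]


def _atomic_write(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Atomically write a DataFrame as TSV."""
    _atomic_write(Path(path), df.to_csv(sep="\t", index=index))


def read_feature_table(path, format: str = "tsv",
                       taxa_as_rows: bool = True) -> FeatureTable:
    """Read a count table from TSV or BIOM into samples x taxa form.

    TSV dialect: tab-delimited with a header row; the first column holds
    taxon ids when ``taxa_as_rows`` (default) else sample ids.  BIOM input
    (HDF5 or JSON) is always observation x sample, per the BIOM convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom":
        import biom
        bt = biom.load_table(str(path))
        df = bt.to_dataframe(dense=True)  # observations x samples
        counts = df.to_numpy().T
        sample_ids, taxon_ids = list(df.columns), list(df.index)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        if df.empty:
            raise ValueError(f"empty feature table: {path}")
        row_kind = "taxon" if taxa_as_rows else "sample"
        dupes = df.index[df.index.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicated {row_kind} ids: {dupes}")
        if taxa_as_rows:
            df = df.T
        sample_ids, taxon_ids = list(df.index), list(df.columns)
        counts = np.empty(df.shape)
        for j, col in enumerate(df.columns):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                i = int(np.nonzero(vals.isna().to_numpy())[0][0])
                raise ValueError(
                    f"non-numeric count at sample {df.index[i]!r}, "
                    f"taxon {col!r} in {path}")
            counts[:, j] = vals.to_numpy()
        neg = np.argwhere(counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at sample {sample_ids[i]!r}, "
                f"taxon {taxon_ids[j]!r} in {path}")
    else:
        raise ValueError(f"unknown feature-table format {format!r}")

    for kind, ids in (("sample", sample_ids), ("taxon", taxon_ids)):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicated {kind} ids: {dupes}")
    return FeatureTable(np.asarray(counts), tuple(map(str, sample_ids)),
                        tuple(map(str, taxon_ids)))


def read_metadata(path, feature_table: FeatureTable | None = None) -> pd.DataFrame:
    """Read QIIME2-style sample metadata: sample id first column, TSV.

    Columns that parse fully as numbers become continuous (float); any
    non-numeric token demotes the column to categorical with a warning.
    When a feature table is given, its samples must all have metadata
    (error); extra metadata samples only warn.
    """
    import warnings

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicated sample ids in metadata: {dupes}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.notna().all():
            df[col] = numeric.astype(float)
        elif numeric.notna().any():
            warnings.warn(
                f"metadata column {col!r} mixes numeric and non-numeric "
                f"tokens; treated as categorical", UserWarning, stacklevel=2)
    if feature_table is not None:
        missing = [s for s in feature_table.sample_ids if s not in df.index]
        if missing:
            raise ValueError(f"feature-table samples missing from metadata: "
                             f"{missing}")
        extra = [s for s in df.index if s not in feature_table.sample_ids]
        if extra:
            warnings.warn(f"metadata samples absent from the feature table "
                          f"(ignored): {extra}", UserWarning, stacklevel=2)
    return df


def read_value_column(path) -> pd.Series:
    """Read a two-column TSV (identifier, value) as a float Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"expected exactly two columns in {path}, "
                         f"got {df.shape[1] + 1}")
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return s


def write_differentials(diffs: DifferentialSet, path) -> None:
    """Write clr differentials as TSV: feature id, then one column per covariate."""
    df = diffs.clr_dataframe()
    df.index.name = "featureid"
    sums = df.to_numpy().sum(axis=0)
    if np.abs(sums).max() > 1e-6:
        raise ValueError("clr differential columns must sum to 0")
    _atomic_write(Path(path), df.to_csv(sep="\t", float_format="%.12g"))


def read_differentials(path) -> pd.DataFrame:
    """Read a differentials TSV back as a feature-indexed DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_manifest(path, config: Mapping) -> None:
    """Serialize the resolved run configuration (incl. seed) as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    _atomic_write(Path(path), json.dumps(dict(config), indent=2,
                                         sort_keys=True, default=_default) + "\n")
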