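"""TSV matrix round-trips and JSON truth serialisation.

Matrix dialect: tab-separated, genes as rows, first column the gene id
(header ``gene``), sample columns headed ``condition:replicate``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, LabeledMatrix

__all__ = ["read_matrix", "write_matrix", "write_json", "read_json"]


def write_matrix(path: str | Path, matrix: LabeledMatrix) -> None:
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path, kind: str = "expression") -> LabeledMatrix:
    """Load a TSV matrix; duplicate gene ids are preserved (collapsing is the
    preprocessing step's job), duplicate sample headers and ragged rows are
    errors naming the location."""
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ValueError(f"{path}: empty matrix file")
    header = header_line.rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) == 0:
        raise ValueError(f"{path}: no sample columns")
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate sample headers {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = samples
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: ragged or missing values at gene {bad!r}")
    if kind == "counts":
        return CountMatrix(df)
    if kind == "expression":
        return ExpressionMatrix(df)
    raise ValueError(f"unknown matrix kind {kind!r}")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(path: str | Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
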