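"""Readers and writers for the formats the tool touches.

Dense matrices travel as CSV/TSV with a header row and a row-name column.
Sparse count matrices use the Matrix Market triplet layout — a directory with
``matrix.mtx`` (genes × cells, the 10x convention, transposed to
cells-as-rows on load), ``genes.tsv`` and ``barcodes.tsv``.  Output tables
carry a provenance header comment (config hash + seed); comment lines
starting with ``#`` are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import DataMatrix
from .preprocess import CountMatrix

__all__ = [
    "read_matrix",
    "read_dense",
    "read_mtx_dir",
    "write_dense",
    "write_mtx_dir",
    "read_labels",
    "write_labels",
    "provenance_header",
]


def provenance_header(config: dict, seed: int | None = None) -> str:
    """One comment line with a stable hash of the run configuration."""
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    seed_part = f" seed={seed}" if seed is not None else ""
    return f"# npca config_hash={digest}{seed_part}"


def _check_dense(df: pd.DataFrame, path: str) -> None:
    if df.isna().any().any():
        i, j = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"{path}: missing value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}; missing data are not supported"
        )
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric column(s): {non_numeric[:5]}")


def read_dense(path: str, sep: str | None = None) -> DataMatrix:
    """Read a CSV/TSV with header row and row-name column into a DataMatrix."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    _check_dense(df, str(path))
    return DataMatrix.from_dataframe(df)


def write_dense(X: DataMatrix, path: str, sep: str = "\t", header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        X.to_dataframe().to_csv(fh, sep=sep, index_label="id")


def read_mtx_dir(path: str) -> CountMatrix:
    """Read a Matrix Market triplet directory (genes × cells) into a
    cells-as-rows CountMatrix."""
    mtx = os.path.join(path, "matrix.mtx")
    genes_f = os.path.join(path, "genes.tsv")
    barcodes_f = os.path.join(path, "barcodes.tsv")
    for f in (mtx, genes_f, barcodes_f):
        if not os.path.exists(f):
            raise FileNotFoundError(f"expected {os.path.basename(f)} in {path}")
    mat = spio.mmread(mtx)
    genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).tolist()
    mat = sparse.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix.mtx is {mat.shape} but genes.tsv has {len(genes)} rows "
            f"and barcodes.tsv has {len(barcodes)}"
        )
    counts = np.asarray(mat.T.todense())
    return CountMatrix(counts=counts, gene_names=genes, cell_ids=barcodes)


def write_mtx_dir(C: CountMatrix, path: str) -> None:
    """Write a CountMatrix as a 10x-style triplet directory."""
    os.makedirs(path, exist_ok=True)
    spio.mmwrite(
        os.path.join(path, "matrix.mtx"), sparse.coo_matrix(C.counts.T)
    )
    pd.Series(C.gene_names).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(C.cell_ids).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
    )


def read_matrix(path: str, fmt: str = "auto") -> Union[DataMatrix, CountMatrix]:
    """Dispatch: ``csv``/``tsv`` → DataMatrix, ``mtx`` (a triplet directory)
    → CountMatrix.  ``auto`` decides from the path."""
    if fmt == "auto":
        fmt = "mtx" if os.path.isdir(path) else (
            "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
        )
    if fmt == "mtx":
        return read_mtx_dir(path)
    if fmt in ("csv", "tsv"):
        return read_dense(path, sep="," if fmt == "csv" else "\t")
    raise ValueError(f"unknown format {fmt!r}; choose csv, tsv or mtx")


def read_labels(path: str) -> np.ndarray:
    """Labels: one integer per line, or a two-column id/label TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    col = df.iloc[:, -1]
    return col.to_numpy(dtype=np.int64)


def write_labels(labels: np.ndarray, path: str, ids: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        if ids is None:
            for v in labels:
                fh.write(f"{int(v)}\n")
        else:
            for i, v in zip(ids, labels):
                fh.write(f"{i}\t{int(v)}\n")
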