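"""Readers and writers for the on-disk artifact formats.

Count matrices use the 10x-style MatrixMarket triplet convention::

    <dir>/matrix.mtx      coordinate integer, 1-based indices, genes x libraries
    <dir>/features.tsv    one gene identifier per line (optional 2nd col: symbol)
    <dir>/barcodes.tsv    one library barcode per line

Indices are 1-based on disk and 0-based in memory.  Annotations, gene tables
and simulation truth are plain TSV files with a header row.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .model import (
    ANNOTATION_COLUMNS,
    CountMatrix,
    FormatError,
    InputError,
    make_gene_table,
    validate_annotations,
    validate_gene_table,
)

__all__ = [
    "read_counts_triplet",
    "write_counts_triplet",
    "read_annotations",
    "write_annotations",
    "read_gene_table",
    "write_gene_table",
    "read_truth",
    "write_truth",
]

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts_triplet(dir_path) -> CountMatrix:
    """Read a MatrixMarket triplet directory into a :class:`CountMatrix`."""
    dir_path = Path(dir_path)
    for name in (MATRIX_FILE, FEATURES_FILE, BARCODES_FILE):
        if not (dir_path / name).is_file():
            raise InputError(f"missing file {dir_path / name}")
    try:
        mat = scipy.io.mmread(dir_path / MATRIX_FILE)
    except Exception as exc:
        raise FormatError(f"invalid MatrixMarket file: {exc}") from exc
    mat = sp.csc_matrix(mat)
    if mat.nnz:
        if np.any(mat.data < 0):
            raise FormatError("matrix.mtx contains negative entries")
        if not np.issubdtype(mat.data.dtype, np.integer) and not np.allclose(
            mat.data, np.round(mat.data)
        ):
            raise FormatError("matrix.mtx contains non-integer entries")
    gene_ids = _read_id_column(dir_path / FEATURES_FILE)
    library_ids = _read_id_column(dir_path / BARCODES_FILE)
    if mat.shape != (len(gene_ids), len(library_ids)):
        raise FormatError(
            f"matrix.mtx is {mat.shape[0]}x{mat.shape[1]} but sidecars list "
            f"{len(gene_ids)} features and {len(library_ids)} barcodes"
        )
    return CountMatrix(mat.astype(np.int64), gene_ids, library_ids)


def write_counts_triplet(matrix: CountMatrix, dir_path) -> None:
    """Write a :class:`CountMatrix` as a MatrixMarket triplet directory.

    Zero counts are never emitted as explicit entries, so the header nnz
    equals the number of nonzeros.
    """
    dir_path = Path(dir_path)
    try:
        dir_path.mkdir(parents=True, exist_ok=True)
        coo = matrix.counts.tocoo()
        coo.eliminate_zeros()
        scipy.io.mmwrite(
            os.fspath(dir_path / MATRIX_FILE), coo, field="integer", symmetry="general"
        )
        with open(dir_path / FEATURES_FILE, "w") as fh:
            for g in matrix.gene_ids:
                fh.write(f"{g}\n")
        with open(dir_path / BARCODES_FILE, "w") as fh:
            for b in matrix.library_ids:
                fh.write(f"{b}\n")
    except OSError as exc:
        raise IOError(f"cannot write triplet to {dir_path}: {exc}") from exc


def write_annotations(ann: pd.DataFrame, path) -> None:
    validate_annotations(ann)
    ann.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"library_id": str, "condition": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"annotation file missing columns {sorted(missing)}")
    ann["est_cells"] = pd.array(
        pd.to_numeric(ann["est_cells"], errors="coerce"), dtype="Int64"
    )
    validate_annotations(ann)
    return ann


def write_gene_table(table: pd.DataFrame, path) -> None:
    validate_gene_table(table)
    out = table.copy()
    out["flags"] = [",".join(sorted(fl)) for fl in out["flags"]]
    out.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    flags = {
        gid: [f for f in fl.split(",") if f]
        for gid, fl in zip(raw["gene_id"], raw["flags"])
    }
    return make_gene_table(raw["gene_id"], raw["gene_symbol"], flags)


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out["member_states"] = [
        ",".join(str(s) for s in states) for states in out["member_states"]
    ]
    out["member_positions"] = [
        ",".join(f"{p:.6f}" for p in pos) for pos in out["member_positions"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    raw["member_states"] = [
        [s for s in str(x).split(",") if s] for x in raw["member_states"]
    ]
    raw["member_positions"] = [
        [float(p) for p in str(x).split(",") if p] for x in raw["member_positions"]
    ]
    raw["is_sticky"] = raw["is_sticky"].astype(bool)
    return raw
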