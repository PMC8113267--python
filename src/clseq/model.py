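"""Core domain types: count matrices, library annotations and gene tables.

A :class:`CountMatrix` stores raw UMI counts as a sparse genes-by-libraries
matrix with ordered, unique gene and library identifiers.  Library metadata
travels as a pandas ``DataFrame`` with a fixed column schema (see
``ANNOTATION_COLUMNS``) so it can round-trip through plain TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "LibraryKind",
    "ANNOTATION_COLUMNS",
    "GENE_FLAGS",
    "make_annotations",
    "refresh_annotations",
    "validate_annotations",
    "make_gene_table",
    "validate_gene_table",
    "merge_datasets",
    "ClseqError",
    "InputError",
    "FormatError",
]


class ClseqError(Exception):
    """Base class for package errors."""


class InputError(ClseqError):
    """Invalid arguments or unsatisfiable preconditions."""


class FormatError(ClseqError):
    """Malformed on-disk artifact."""


#: Allowed values for the ``kind`` annotation column.
LibraryKind = ("single", "cluster", "spot", "ambiguous")

#: Canonical column order of an annotation table.
ANNOTATION_COLUMNS = (
    "library_id",
    "kind",
    "condition",
    "total_umi",
    "n_genes_detected",
    "mito_fraction",
    "est_cells",
)

#: Allowed gene flags.
GENE_FLAGS = frozenset({"mitochondrial", "sex_linked", "cell_cycle", "marker"})


@dataclass
class CountMatrix:
    """Sparse genes x libraries UMI count matrix.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_genes, n_libraries)``.
        Stored internally as CSC.
    gene_ids
        Unique gene identifiers, one per row.
    library_ids
        Unique library barcodes, one per column.
    """

    counts: sp.csc_matrix
    gene_ids: np.ndarray
    library_ids: np.ndarray

    def __init__(self, counts, gene_ids, library_ids):
        counts = sp.csc_matrix(counts)
        gene_ids = np.asarray(gene_ids, dtype=object)
        library_ids = np.asarray(library_ids, dtype=object)
        if counts.shape != (gene_ids.size, library_ids.size):
            raise InputError(
                f"counts shape {counts.shape} does not match "
                f"{gene_ids.size} genes x {library_ids.size} libraries"
            )
        if counts.nnz:
            data = counts.data
            if np.any(data < 0):
                raise InputError("counts must be non-negative")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise InputError("counts must be integral")
                counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if len(set(gene_ids)) != gene_ids.size:
            raise InputError("gene_ids are not unique")
        if len(set(library_ids)) != library_ids.size:
            raise InputError("library_ids are not unique")
        counts.eliminate_zeros()
        self.counts = counts
        self.gene_ids = gene_ids
        self.library_ids = library_ids

    # -- basic geometry -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_libraries(self) -> int:
        return self.library_ids.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    # -- derived per-library statistics ---------------------------------

    def total_umi(self) -> np.ndarray:
        """Column sums (total UMI per library)."""
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.int64)

    def n_genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per library."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel().astype(np.int64)

    def mito_fraction(self, mito_mask: np.ndarray) -> np.ndarray:
        """Fraction of counts from genes flagged by ``mito_mask``.

        Libraries with zero total get fraction 0.
        """
        mito_mask = np.asarray(mito_mask, dtype=bool)
        if mito_mask.size != self.n_genes:
            raise InputError("mito_mask length must equal the number of genes")
        total = self.total_umi().astype(float)
        mito = np.asarray(self.counts[mito_mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / total, 0.0)
        return frac

    # -- subsetting -----------------------------------------------------

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"gene {exc.args[0]!r} not present in matrix") from None

    def library_index(self, library_ids) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.library_ids)}
        try:
            return np.array([lookup[b] for b in library_ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"library {exc.args[0]!r} not present in matrix") from None

    def subset_genes(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(self.counts[keep, :], self.gene_ids[keep], self.library_ids)

    def subset_libraries(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(self.counts[:, keep], self.gene_ids, self.library_ids[keep])

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.shape == other.shape
            and (self.gene_ids == other.gene_ids).all()
            and (self.library_ids == other.library_ids).all()
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class LibraryAnnotation:
    """Metadata for a single library (one annotation-table row)."""

    library_id: str
    kind: str = "ambiguous"
    condition: str = "na"
    total_umi: int = 0
    n_genes_detected: int = 0
    mito_fraction: float = 0.0
    est_cells: int | None = None


def make_annotations(
    matrix: CountMatrix,
    kind: str | np.ndarray = "ambiguous",
    condition: str | np.ndarray = "na",
    mito_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build a fresh annotation table with QC totals computed from counts."""
    n = matrix.n_libraries
    mito = (
        matrix.mito_fraction(mito_mask)
        if mito_mask is not None
        else np.zeros(n, dtype=float)
    )
    ann = pd.DataFrame(
        {
            "library_id": matrix.library_ids,
            "kind": np.broadcast_to(np.asarray(kind, dtype=object), (n,)).copy(),
            "condition": np.broadcast_to(np.asarray(condition, dtype=object), (n,)).copy(),
            "total_umi": matrix.total_umi(),
            "n_genes_detected": matrix.n_genes_detected(),
            "mito_fraction": mito,
            "est_cells": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    validate_annotations(ann, matrix)
    return ann


def refresh_annotations(ann: pd.DataFrame, matrix: CountMatrix) -> pd.DataFrame:
    """Recompute total_umi / n_genes_detected from the (possibly subset) matrix."""
    ann = ann.set_index("library_id").loc[list(matrix.library_ids)].reset_index()
    ann["total_umi"] = matrix.total_umi()
    ann["n_genes_detected"] = matrix.n_genes_detected()
    return ann


def validate_annotations(ann: pd.DataFrame, matrix: CountMatrix | None = None) -> None:
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise InputError(f"annotation table is missing columns {sorted(missing)}")
    if ann["library_id"].duplicated().any():
        raise InputError("annotation table has duplicate library_id values")
    bad_kind = set(ann["kind"]) - set(LibraryKind)
    if bad_kind:
        raise InputError(f"unknown library kinds {sorted(bad_kind)}")
    mf = ann["mito_fraction"].to_numpy(dtype=float)
    if np.any((mf < 0) | (mf > 1)):
        raise InputError("mito_fraction values must lie in [0, 1]")
    est = pd.to_numeric(ann["est_cells"], errors="coerce")
    if (est.dropna() < 1).any():
        raise InputError("est_cells must be >= 1 when present")
    if matrix is not None:
        if list(ann["library_id"]) != list(matrix.library_ids):
            raise InputError("annotation rows do not match matrix libraries")
        if not np.array_equal(
            ann["total_umi"].to_numpy(dtype=np.int64), matrix.total_umi()
        ):
            raise InputError("total_umi does not equal matrix column sums")


def make_gene_table(
    gene_ids,
    gene_symbols=None,
    flags: dict | None = None,
) -> pd.DataFrame:
    """Build a gene table; ``flags`` maps gene_id -> iterable of flag names."""
    gene_ids = list(gene_ids)
    if gene_symbols is None:
        gene_symbols = gene_ids
    flags = flags or {}
    rows = []
    for gid, sym in zip(gene_ids, gene_symbols):
        fl = frozenset(flags.get(gid, ()))
        rows.append({"gene_id": gid, "gene_symbol": sym, "flags": fl})
    table = pd.DataFrame(rows, columns=["gene_id", "gene_symbol", "flags"])
    validate_gene_table(table)
    return table


def validate_gene_table(table: pd.DataFrame) -> None:
    if table["gene_id"].duplicated().any():
        raise InputError("gene table has duplicate gene_id values")
    for fl in table["flags"]:
        extra = set(fl) - GENE_FLAGS
        if extra:
            raise InputError(f"unknown gene flags {sorted(extra)}")


def gene_flag_mask(table: pd.DataFrame, matrix: CountMatrix, flag: str) -> np.ndarray:
    """Boolean mask over matrix genes carrying ``flag`` in the gene table."""
    if flag not in GENE_FLAGS:
        raise InputError(f"unknown gene flag {flag!r}")
    flagged = {
        gid for gid, fl in zip(table["gene_id"], table["flags"]) if flag in fl
    }
    return np.array([g in flagged for g in matrix.gene_ids], dtype=bool)


def merge_datasets(
    matrices: list[CountMatrix],
    annotations: list[pd.DataFrame],
    union_genes: bool = False,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Merge several datasets into one matrix plus one annotation table.

    The gene axis is the intersection of gene sets, ordered as in the first
    input (``union_genes=True`` switches to a zero-filled union).  Libraries
    are concatenated; colliding barcodes get a ``-<k>`` source suffix.
    """
    if not matrices:
        raise InputError("need at least one input dataset")
    if len(matrices) != len(annotations):
        raise InputError("matrices and annotations must align")
    if len(matrices) == 1:
        validate_annotations(annotations[0], matrices[0])
        return matrices[0], annotations[0].copy()

    gene_sets = [set(m.gene_ids) for m in matrices]
    if union_genes:
        genes = list(matrices[0].gene_ids)
        seen = set(genes)
        for m in matrices[1:]:
            for g in m.gene_ids:
                if g not in seen:
                    genes.append(g)
                    seen.add(g)
    else:
        common = set.intersection(*gene_sets)
        if not common:
            raise InputError("gene intersection across datasets is empty")
        genes = [g for g in matrices[0].gene_ids if g in common]

    # barcode collision -> suffix by source ordinal
    all_ids = [list(m.library_ids) for m in matrices]
    flat = [b for ids in all_ids for b in ids]
    collides = {b for b in flat if flat.count(b) > 1} if len(flat) < 5000 else None
    if collides is None:  # large inputs: vectorized duplicate detection
        s = pd.Series(flat)
        collides = set(s[s.duplicated(keep=False)])

    blocks = []
    lib_ids: list[str] = []
    ann_parts = []
    for k, (m, ann) in enumerate(zip(matrices, annotations), start=1):
        validate_annotations(ann, m)
        lookup = {g: i for i, g in enumerate(m.gene_ids)}
        block = sp.lil_matrix((len(genes), m.n_libraries), dtype=np.int64)
        present = [(row, lookup[g]) for row, g in enumerate(genes) if g in lookup]
        if present:
            rows, srcs = zip(*present)
            block[list(rows), :] = m.counts[list(srcs), :]
        new_ids = [f"{b}-{k}" if b in collides else b for b in m.library_ids]
        lib_ids.extend(new_ids)
        part = ann.copy()
        part["library_id"] = new_ids
        ann_parts.append(part)
        blocks.append(sp.csc_matrix(block))

    merged = CountMatrix(sp.hstack(blocks, format="csc"), genes, lib_ids)
    merged_ann = pd.concat(ann_parts, ignore_index=True)
    if not union_genes:
        # gene subsetting may change totals only if inputs had private genes
        merged_ann = refresh_annotations(merged_ann, merged)
    validate_annotations(merged_ann, merged)
    return merged, merged_ann
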