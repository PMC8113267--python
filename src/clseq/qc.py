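"""Library- and gene-level quality control.

Libraries are partitioned by total UMI into singles (below a low threshold),
clusters (above a high threshold) and an ambiguous middle band that is
excluded downstream.  Basic per-library filters drop low-complexity and
high-mitochondrial libraries.  Gene-level helpers remove blacklisted genes,
score gene sets against expression-matched controls, regress out covariates
and gate libraries on marker thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CountMatrix, InputError, gene_flag_mask, refresh_annotations

__all__ = [
    "QcThresholds",
    "classify_library_kind",
    "basic_filters",
    "estimate_cluster_sizes",
    "remove_blacklisted_genes",
    "gene_set_score",
    "regress_out",
    "gate_by_markers",
]


@dataclass(frozen=True)
class QcThresholds:
    """QC cutoffs; defaults follow the published filtering rules."""

    min_genes: int = 200
    max_mito_fraction: float = 0.05
    cluster_umi_min: int = 35_000
    single_umi_max: int = 9_500

    def __post_init__(self):
        if not self.cluster_umi_min > self.single_umi_max > 0:
            raise InputError("need cluster_umi_min > single_umi_max > 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise InputError("max_mito_fraction must lie in [0, 1]")


def classify_library_kind(
    matrix: CountMatrix,
    annotations: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Set ``kind`` from total UMI: strictly above ``cluster_umi_min`` is a
    cluster, strictly below ``single_umi_max`` a single, in between ambiguous.

    Existing ``spot`` annotations are left untouched (spots come from a
    different capture technology and carry their kind from upstream).
    """
    ann = refresh_annotations(annotations, matrix)
    total = ann["total_umi"].to_numpy()
    kind = np.where(
        total > thresholds.cluster_umi_min,
        "cluster",
        np.where(total < thresholds.single_umi_max, "single", "ambiguous"),
    ).astype(object)
    keep_spot = ann["kind"].to_numpy() == "spot"
    ann["kind"] = np.where(keep_spot, "spot", kind)
    return ann


def basic_filters(
    matrix: CountMatrix,
    annotations: pd.DataFrame,
    gene_table: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Drop libraries with too few detected genes or too much mitochondrial
    signal; returns (matrix, annotations, report).

    The report maps each removed library id to its list of failed rules.
    Mito fractions are computed on raw counts.
    """
    mito_mask = gene_flag_mask(gene_table, matrix, "mitochondrial")
    n_genes = matrix.n_genes_detected()
    mito_frac = matrix.mito_fraction(mito_mask)
    removed: dict[str, list[str]] = {}
    for i, lib in enumerate(matrix.library_ids):
        reasons = []
        if n_genes[i] < thresholds.min_genes:
            reasons.append("min_genes")
        if mito_frac[i] > thresholds.max_mito_fraction:
            reasons.append("max_mito_fraction")
        if reasons:
            removed[lib] = reasons
    keep = np.array([lib not in removed for lib in matrix.library_ids])
    if not keep.any():
        raise InputError("no libraries survive basic QC filters")
    out = matrix.subset_libraries(keep)
    ann = refresh_annotations(annotations, out)
    ann["mito_fraction"] = mito_frac[keep]
    report = {
        "n_input": int(matrix.n_libraries),
        "n_kept": int(out.n_libraries),
        "removed": removed,
        "n_removed_min_genes": sum("min_genes" in r for r in removed.values()),
        "n_removed_mito": sum("max_mito_fraction" in r for r in removed.values()),
    }
    return out, ann, report


def estimate_cluster_sizes(
    matrix: CountMatrix, annotations: pd.DataFrame, min_singles: int = 10
) -> pd.DataFrame:
    """Estimate cells per cluster as total UMI over the median single-library
    UMI, rounded and floored at 2."""
    ann = annotations.copy()
    singles = ann.loc[ann["kind"] == "single", "total_umi"].to_numpy()
    if singles.size == 0:
        raise InputError("no single libraries available for size estimation")
    if singles.size < min_singles:
        raise InputError(
            f"need >= {min_singles} single libraries, found {singles.size}"
        )
    med = float(np.median(singles))
    is_cluster = ann["kind"] == "cluster"
    est = np.maximum(
        2, np.round(ann.loc[is_cluster, "total_umi"].to_numpy() / med)
    ).astype(int)
    ann["est_cells"] = ann["est_cells"].astype("Int64")
    ann.loc[is_cluster, "est_cells"] = est
    return ann


def remove_blacklisted_genes(
    matrix: CountMatrix,
    gene_table: pd.DataFrame,
    flags: frozenset[str] | set[str] = frozenset({"sex_linked"}),
) -> CountMatrix:
    """Drop genes carrying any of the given flags (empty flag set: no-op)."""
    if not flags:
        return matrix
    drop = np.zeros(matrix.n_genes, dtype=bool)
    for flag in flags:
        drop |= gene_flag_mask(gene_table, matrix, flag)
    if drop.all():
        raise InputError("blacklist removes every gene (empty gene axis)")
    return matrix.subset_genes(~drop)


def gene_set_score(
    normalized: np.ndarray,
    gene_ids,
    gene_set,
    rng: np.random.Generator,
    n_control_bins: int = 25,
    control_genes=None,
) -> np.ndarray:
    """Per-library gene-set score: mean expression over the set minus the mean
    over an expression-matched control set.

    Genes are ranked by dataset-mean expression and split into
    ``n_control_bins`` equal-count bins; each set gene contributes one random
    control gene from its own bin.  ``control_genes`` overrides the random
    draw (used mainly for calibration checks).
    """
    gene_ids = list(gene_ids)
    if len(gene_set) == 0:
        raise InputError("gene_set is empty")
    index = {g: i for i, g in enumerate(gene_ids)}
    try:
        set_idx = np.array([index[g] for g in gene_set], dtype=int)
    except KeyError as exc:
        raise InputError(f"gene {exc.args[0]!r} not in matrix") from None
    normalized = np.asarray(normalized, dtype=float)

    if control_genes is not None:
        ctrl_idx = np.array([index[g] for g in control_genes], dtype=int)
    else:
        mean_expr = normalized.mean(axis=1)
        order = np.argsort(mean_expr, kind="stable")
        bins = np.empty(len(gene_ids), dtype=int)
        bins[order] = np.minimum(
            (np.arange(len(gene_ids)) * n_control_bins) // len(gene_ids),
            n_control_bins - 1,
        )
        by_bin: dict[int, np.ndarray] = {
            b: np.flatnonzero(bins == b) for b in np.unique(bins)
        }
        ctrl_idx = np.array(
            [rng.choice(by_bin[bins[i]]) for i in set_idx], dtype=int
        )
    return normalized[set_idx, :].mean(axis=0) - normalized[ctrl_idx, :].mean(axis=0)


def regress_out(normalized: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Remove covariate directions from each gene by OLS, keeping gene means.

    Covariates are centered; each gene's expression is regressed on them with
    an intercept and replaced by residuals plus the fitted intercept (the
    gene's mean).  Collinear covariate columns are dropped with a warning.
    """
    x = np.asarray(normalized, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] == x.shape[1]:
        pass
    elif cov.shape[1] == x.shape[1]:
        cov = cov.T
    else:
        raise InputError("covariate rows must align with libraries")
    cov = cov - cov.mean(axis=0, keepdims=True)

    # greedy rank filter: keep columns that increase the design rank
    kept: list[int] = []
    for j in range(cov.shape[1]):
        trial = cov[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
    if len(kept) < cov.shape[1]:
        warnings.warn(
            f"dropped {cov.shape[1] - len(kept)} collinear covariate column(s)",
            stacklevel=2,
        )
    gene_means = x.mean(axis=1, keepdims=True)
    if not kept:
        return x.copy()
    design = cov[:, kept]
    centered = x - gene_means
    beta, *_ = np.linalg.lstsq(design, centered.T, rcond=None)
    resid = centered.T - design @ beta
    return resid.T + gene_means


def gate_by_markers(
    normalized: np.ndarray,
    gene_ids,
    library_ids,
    rules: list[tuple[str, float]],
) -> list[str]:
    """Library ids strictly exceeding every (gene, min_value) rule.

    An empty rule list retains everything.
    """
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    keep = np.ones(len(library_ids), dtype=bool)
    for gene, min_value in rules:
        if gene not in index:
            raise InputError(f"gate rule gene {gene!r} not in matrix")
        keep &= np.asarray(normalized)[index[gene], :] > min_value
    return [lib for lib, k in zip(library_ids, keep) if k]
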