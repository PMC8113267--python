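"""Normalization, marker detection and per-state signature profiles.

Marker detection is a one-vs-rest two-sided Wilcoxon rank-sum per gene
(exact enumeration for small tie-free groups, normal approximation with tie
correction otherwise), Benjamini-Hochberg adjusted across genes within each
state.  Fold changes are natural-log ratios of group means of
``expm1(normalized)`` with a pseudocount of 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .model import CountMatrix, InputError

__all__ = [
    "normalize_log1p",
    "find_markers",
    "top_markers",
    "build_signatures",
    "row_zscore",
]

DEFAULT_SCALE = 10_000.0


def normalize_log1p(matrix: CountMatrix, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Library-size normalize to ``scale`` counts and log-transform.

    Returns a dense genes x libraries array of ``ln(1 + count * scale / total)``.
    """
    total = matrix.total_umi().astype(float)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise InputError(
            f"library {matrix.library_ids[zero[0]]!r} has zero total counts"
        )
    dense = matrix.dense().astype(float)
    return np.log1p(dense * (scale / total)[None, :])


def _wilcoxon_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene for groups ``a`` (genes x n1) vs ``b``.

    Exact null enumeration when both groups have <= 10 libraries and the
    gene has no cross-group ties; otherwise the normal approximation with
    tie correction.  Genes with zero rank variance (all values tied) get p=1.
    """
    n1, n2 = a.shape[1], b.shape[1]
    exact_ok = n1 <= 10 and n2 <= 10
    pvals = np.ones(a.shape[0])
    if exact_ok:
        for g in range(a.shape[0]):
            x, y = a[g], b[g]
            combined = np.concatenate([x, y])
            if np.all(combined == combined[0]):
                continue  # fully tied: p = 1
            has_ties = np.unique(combined).size < combined.size
            method = "exact" if not has_ties else "asymptotic"
            res = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method=method, use_continuity=True
            )
            p = float(res.pvalue)
            pvals[g] = 1.0 if np.isnan(p) else min(p, 1.0)
        return pvals
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), np.minimum(p, 1.0), 1.0)
    return p


def find_markers(
    normalized: np.ndarray,
    gene_ids,
    state_labels,
    logfc_min: float = 0.25,
    padj_max: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """One-vs-rest differential expression per state.

    Returns a DataFrame with columns ``gene_id, state, log_fc, p_value,
    p_adjusted, is_marker``; a gene is a marker for a state iff
    ``log_fc > logfc_min`` and ``p_adjusted < padj_max``.
    """
    normalized = np.asarray(normalized, dtype=float)
    gene_ids = np.asarray(list(gene_ids), dtype=object)
    labels = np.asarray(list(state_labels), dtype=object)
    if labels.size != normalized.shape[1]:
        raise InputError("state_labels must align with libraries")
    states = sorted(set(labels), key=str)
    if len(states) < 2:
        raise InputError("need at least 2 states")
    for s in states:
        if (labels == s).sum() < min_group:
            raise InputError(f"state {s!r} has fewer than {min_group} libraries")

    frames = []
    expr = np.expm1(normalized)
    for s in states:
        in_s = labels == s
        a, b = normalized[:, in_s], normalized[:, ~in_s]
        mean_in = expr[:, in_s].mean(axis=1)
        mean_out = expr[:, ~in_s].mean(axis=1)
        log_fc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        pvals = _wilcoxon_pvalues(a, b)
        padj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "state": s,
                    "log_fc": log_fc,
                    "p_value": pvals,
                    "p_adjusted": padj,
                    "is_marker": (log_fc > logfc_min) & (padj < padj_max),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def top_markers(de_results: pd.DataFrame, top_n: int = 20) -> dict[str, list[str]]:
    """Per-state ordered marker lists, truncated to ``top_n``.

    Sort key: ascending adjusted p, then descending log fold change, then
    gene id.
    """
    passing = de_results[de_results["is_marker"]]
    out: dict[str, list[str]] = {}
    for s, grp in passing.groupby("state", sort=True):
        ranked = grp.sort_values(
            ["p_adjusted", "log_fc", "gene_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        out[s] = list(ranked["gene_id"].head(top_n))
    return out


def row_zscore(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score each row; rows with zero variance become all zeros."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(~(sd > 0), z.shape)] = 0.0
    return z


def build_signatures(
    normalized: np.ndarray,
    gene_ids,
    state_labels,
    marker_lists: dict[str, list[str]],
) -> pd.DataFrame:
    """Row-standardized per-state mean expression over the union marker set.

    Returns a genes x states DataFrame (index: gene id, columns: states);
    each row is z-scored across states, constant rows are all zeros.
    """
    if not marker_lists or all(len(v) == 0 for v in marker_lists.values()):
        raise InputError("marker lists are empty")
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    union: list[str] = []
    seen = set()
    for s in sorted(marker_lists, key=str):
        for g in marker_lists[s]:
            if g not in index:
                raise InputError(f"signature gene {g!r} not in matrix")
            if g not in seen:
                union.append(g)
                seen.add(g)
    labels = np.asarray(list(state_labels), dtype=object)
    states = sorted(set(labels), key=str)
    rows = np.array([index[g] for g in union], dtype=int)
    normalized = np.asarray(normalized, dtype=float)
    means = np.column_stack(
        [normalized[np.ix_(rows, np.flatnonzero(labels == s))].mean(axis=1) for s in states]
    )
    z = row_zscore(means)
    return pd.DataFrame(z, index=union, columns=states)
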