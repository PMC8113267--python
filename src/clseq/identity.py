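"""Identity assignment of multi-cell query libraries against single-cell
state references.

Queries and reference cells are correlated (Pearson) over a marker gene set
on row-standardized normalized expression; per-state mean correlations are
tested by shuffling query group labels; states passing both the correlation
and permutation thresholds form the pure/mixed/unassigned call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .model import InputError
from .signatures import row_zscore

__all__ = [
    "AssignmentResult",
    "CorrelationResult",
    "correlate_to_reference",
    "correlate_to_states",
    "group_queries",
    "permutation_test",
    "assign_identities",
    "assign_consensus",
    "score_cells",
    "compare_composition",
    "assignments_to_frame",
    "frame_to_assignments",
]


@dataclass
class AssignmentResult:
    """Identity call for one query library or query group."""

    library_id: str
    states: tuple[str, ...]
    r: np.ndarray
    p_perm: np.ndarray
    call: str  # "pure" | "mixed" | "unassigned"
    call_states: tuple[str, ...]
    n_perm: int
    seed: int | None = None
    members: tuple[str, ...] = field(default_factory=tuple)

    def r_of(self, state) -> float:
        return float(self.r[self.states.index(str(state))])


def _pearson_columns(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Pearson r between every column of q and every column of r.

    Constant columns correlate as 0 (with a warning), not NaN.
    """
    qc = q - q.mean(axis=0, keepdims=True)
    rc = r - r.mean(axis=0, keepdims=True)
    qn = np.linalg.norm(qc, axis=0)
    rn = np.linalg.norm(rc, axis=0)
    if np.any(qn == 0) or np.any(rn == 0):
        warnings.warn(
            "constant profile over the correlation gene set; r defined as 0",
            stacklevel=3,
        )
    qn = np.where(qn == 0, 1.0, qn)
    rn = np.where(rn == 0, 1.0, rn)
    out = (qc / qn).T @ (rc / rn)
    return np.clip(out, -1.0, 1.0)


@dataclass
class CorrelationResult:
    """Query-to-reference correlation bundle.

    ``state_means``: query x state mean Pearson r over each state's
    reference cells (the quantity thresholded for identity calls).
    ``r_matrix``: full query x reference-cell r matrix (permutation input).
    ``profile_corr``: query x state r against per-state mean reference
    profiles — a lower-noise feature used for grouping queries.
    """

    state_means: pd.DataFrame
    r_matrix: np.ndarray
    ref_states: np.ndarray
    profile_corr: pd.DataFrame


def correlate_to_reference(
    query_normalized: np.ndarray,
    query_ids,
    reference_normalized: np.ndarray,
    reference_states,
    gene_ids,
    gene_set,
) -> CorrelationResult:
    """Correlate each query against each reference cell over ``gene_set``.

    Expression rows (genes) are standardized by the reference distribution
    (mean/sd over reference cells) before correlating; per-state mean r is
    the average over that state's reference cells.
    """
    gene_ids = list(gene_ids)
    gene_set = list(gene_set)
    if len(gene_set) < 3:
        raise InputError("correlation gene set must contain >= 3 genes")
    index = {g: i for i, g in enumerate(gene_ids)}
    try:
        rows = np.array([index[g] for g in gene_set], dtype=int)
    except KeyError as exc:
        raise InputError(f"gene {exc.args[0]!r} not in matrix") from None
    q = np.asarray(query_normalized, dtype=float)[rows, :]
    r = np.asarray(reference_normalized, dtype=float)[rows, :]
    ref_states = np.asarray([str(s) for s in reference_states], dtype=object)
    if ref_states.size != r.shape[1]:
        raise InputError("reference_states must align with reference libraries")

    # standardize each gene by the reference distribution (the reference
    # cells define the coordinate system; queries are projected into it —
    # multi-cell queries would otherwise distort the per-gene scale)
    mu = r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    qz, rz = (q - mu) / sd, (r - mu) / sd
    r_matrix = _pearson_columns(qz, rz)

    states = sorted(set(ref_states), key=str)
    state_means = pd.DataFrame(
        {s: r_matrix[:, ref_states == s].mean(axis=1) for s in states},
        index=list(query_ids),
    )
    profiles = np.column_stack(
        [rz[:, ref_states == s].mean(axis=1) for s in states]
    )
    profile_corr = pd.DataFrame(
        _pearson_columns(qz, profiles), index=list(query_ids), columns=states
    )
    return CorrelationResult(state_means, r_matrix, ref_states, profile_corr)


def correlate_to_states(*args, **kwargs) -> pd.DataFrame:
    """Per-query per-state mean Pearson r (convenience wrapper)."""
    return correlate_to_reference(*args, **kwargs).state_means


def group_queries(
    state_corr: pd.DataFrame,
    n_groups: int | None = None,
    height: float | None = None,
) -> np.ndarray:
    """Group queries by average-linkage clustering of their state-correlation
    vectors under (1 - Pearson) distance.

    Exactly one of ``n_groups`` / ``height`` must be given.  Group labels are
    renumbered 0..k-1 by first occurrence, so the output is deterministic in
    the input order.
    """
    vecs = state_corr.to_numpy(dtype=float)
    n = vecs.shape[0]
    if n < 2:
        raise InputError("need >= 2 queries to group")
    if (n_groups is None) == (height is None):
        raise InputError("specify exactly one of n_groups or height")
    if n_groups is not None and n_groups > n:
        raise InputError(f"n_groups={n_groups} exceeds {n} queries")

    centered = vecs - vecs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    unit = centered / norms[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    link = scipy.cluster.hierarchy.linkage(condensed, method="average")
    if n_groups is not None:
        raw = scipy.cluster.hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    else:
        raw = scipy.cluster.hierarchy.fcluster(link, t=height, criterion="distance")
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, g in enumerate(raw):
        labels[i] = remap.setdefault(int(g), len(remap))
    return labels


def permutation_test(
    r_matrix: np.ndarray,
    group_labels,
    reference_states,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values for the group-by-state mean correlation.

    The observed statistic is the mean of the query-by-reference correlation
    submatrix for each (group, state).  The null shuffles group labels across
    queries; ``p = (1 + #[T_perm >= T_obs]) / (1 + n_perm)``.
    """
    r_matrix = np.asarray(r_matrix, dtype=float)
    groups = np.asarray(list(group_labels))
    ref_states = np.asarray([str(s) for s in reference_states], dtype=object)
    if groups.size != r_matrix.shape[0]:
        raise InputError("group labels must align with query rows")
    if ref_states.size != r_matrix.shape[1]:
        raise InputError("reference states must align with reference columns")
    uniq_groups = pd.unique(groups)
    if uniq_groups.size < 2:
        raise InputError("permutation null undefined with a single group")
    states = sorted(set(ref_states), key=str)

    # mean r per query per state, then group means of those
    state_cols = np.column_stack(
        [r_matrix[:, ref_states == s].mean(axis=1) for s in states]
    )
    weights = np.zeros((uniq_groups.size, groups.size))
    for gi, g in enumerate(uniq_groups):
        idx = np.flatnonzero(groups == g)
        weights[gi, idx] = 1.0 / idx.size
    obs = weights @ state_cols

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs, dtype=np.int64)
    n_q = groups.size
    for _ in range(n_perm):
        t_perm = weights @ state_cols[rng.permutation(n_q)]
        exceed += t_perm >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(pvals, index=list(uniq_groups), columns=states)


def assign_identities(
    state_corr: pd.DataFrame,
    p_perm: pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
    members: dict | None = None,
) -> list[AssignmentResult]:
    """Call pure/mixed/unassigned identities from aligned r and p tables.

    A state is called iff ``r > r_min`` and ``p < p_max``; one passing state
    is a pure call, two or more a mixed call, none leaves the query
    unassigned.  Rows of ``state_corr`` and ``p_perm`` must share index and
    columns (library ids or group ids by states).
    """
    if list(state_corr.columns) != list(p_perm.columns):
        raise InputError("r and p tables must share the state axis")
    if list(state_corr.index) != list(p_perm.index):
        raise InputError("r and p tables must share the query/group axis")
    states = tuple(str(s) for s in state_corr.columns)
    results = []
    for key in state_corr.index:
        r = state_corr.loc[key].to_numpy(dtype=float)
        p = p_perm.loc[key].to_numpy(dtype=float)
        passing = tuple(
            s for s, ri, pi in zip(states, r, p) if ri > r_min and pi < p_max
        )
        call = (
            "unassigned"
            if len(passing) == 0
            else ("pure" if len(passing) == 1 else "mixed")
        )
        results.append(
            AssignmentResult(
                library_id=str(key),
                states=states,
                r=r,
                p_perm=p,
                call=call,
                call_states=passing,
                n_perm=n_perm,
                seed=seed,
                members=tuple(members.get(key, ())) if members else (),
            )
        )
    return results


def assign_consensus(
    correlation: CorrelationResult,
    resolutions=(6, 8, 10, 12, 14, 16, 18),
    r_min: float = 0.6,
    p_max: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[AssignmentResult]:
    """Per-library identity calls by consensus over grouping resolutions.

    Query grouping by hierarchical clustering is sensitive to the requested
    group count when boundary libraries form a composition continuum, so the
    group-level call is repeated at several resolutions and each library's
    final call set is the union of the states its group passed at any
    resolution.  Queries are grouped on their state-profile correlations
    (lower noise than per-cell means); thresholds are applied to group-mean
    per-state correlations as usual.
    """
    state_corr = correlation.state_means
    query_ids = list(state_corr.index)
    states = tuple(str(s) for s in state_corr.columns)
    final: dict[str, set] = {q: set() for q in query_ids}
    for k, n_groups in enumerate(resolutions):
        ng = min(int(n_groups), len(query_ids))
        if ng < 2:
            continue
        groups = group_queries(correlation.profile_corr, n_groups=ng)
        if pd.unique(groups).size < 2:
            continue
        p_group = permutation_test(
            correlation.r_matrix,
            groups,
            correlation.ref_states,
            n_perm=n_perm,
            seed=seed * 100003 + k,
        )
        group_corr = state_corr.groupby(groups).mean().loc[p_group.index]
        members = {
            g: [q for q, gg in zip(query_ids, groups) if gg == g]
            for g in p_group.index
        }
        for a in assign_identities(
            group_corr, p_group, r_min=r_min, p_max=p_max,
            n_perm=n_perm, members=members,
        ):
            for lib in a.members:
                final[lib] |= set(a.call_states)
    results = []
    for q in query_ids:
        passing = tuple(s for s in states if s in final[q])
        call = (
            "unassigned"
            if len(passing) == 0
            else ("pure" if len(passing) == 1 else "mixed")
        )
        results.append(
            AssignmentResult(
                library_id=str(q),
                states=states,
                r=state_corr.loc[q].to_numpy(dtype=float),
                p_perm=np.full(len(states), np.nan),
                call=call,
                call_states=passing,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def score_cells(
    normalized: np.ndarray,
    gene_ids,
    marker_lists: dict[str, list[str]],
    tau: float = 0.25,
) -> pd.DataFrame:
    """Per-cell state scores and hybrid calls from signature marker lists.

    ``score(cell, s)`` is the mean row-z expression over state s's markers
    (z across cells).  The primary call is the argmax; a cell is ``hybrid``
    when its top two scores both exceed ``tau`` and ``unassigned`` when no
    score does.
    """
    if not marker_lists:
        raise InputError("marker lists are empty")
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    z = row_zscore(np.asarray(normalized, dtype=float))
    states = sorted(marker_lists, key=str)
    scores = {}
    for s in states:
        genes = marker_lists[s]
        if not genes:
            raise InputError(f"state {s!r} has an empty marker list")
        try:
            rows = np.array([index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise InputError(f"marker gene {exc.args[0]!r} not in matrix") from None
        scores[s] = z[rows, :].mean(axis=0)
    table = pd.DataFrame(scores)
    vals = table.to_numpy()
    order = np.argsort(-vals, axis=1)
    top1 = vals[np.arange(len(table)), order[:, 0]]
    top2 = (
        vals[np.arange(len(table)), order[:, 1]]
        if vals.shape[1] > 1
        else np.full(len(table), -np.inf)
    )
    primary = [states[i] for i in order[:, 0]]
    secondary = [states[i] for i in order[:, 1]] if vals.shape[1] > 1 else [""] * len(table)
    call = np.where(
        top1 <= tau, "unassigned", np.where(top2 > tau, "hybrid", "pure")
    )
    table["primary"] = primary
    table["secondary"] = secondary
    table["call"] = call
    table["hybrid_pair"] = [
        "+".join(sorted((a, b))) if c == "hybrid" else ""
        for a, b, c in zip(primary, secondary, call)
    ]
    return table


def assignments_to_frame(assignments: list[AssignmentResult]) -> pd.DataFrame:
    """Flatten assignments for TSV round-tripping."""
    if not assignments:
        return pd.DataFrame(
            columns=["library_id", "call", "call_states", "n_perm", "members"]
        )
    states = assignments[0].states
    rows = []
    for a in assignments:
        row = {
            "library_id": a.library_id,
            "call": a.call,
            "call_states": "+".join(a.call_states),
            "n_perm": a.n_perm,
            "members": ",".join(a.members),
        }
        for s, ri, pi in zip(a.states, a.r, a.p_perm):
            row[f"r_{s}"] = ri
            row[f"p_{s}"] = pi
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_assignments(frame: pd.DataFrame) -> list[AssignmentResult]:
    """Inverse of :func:`assignments_to_frame`."""
    states = tuple(
        c[len("r_") :] for c in frame.columns if c.startswith("r_")
    )
    out = []
    for _, row in frame.iterrows():
        call_states = tuple(
            s for s in str(row["call_states"]).split("+") if s and s != "nan"
        )
        members = tuple(
            m for m in str(row.get("members", "")).split(",") if m and m != "nan"
        )
        out.append(
            AssignmentResult(
                library_id=str(row["library_id"]),
                states=states,
                r=np.array([row[f"r_{s}"] for s in states], dtype=float),
                p_perm=np.array([row[f"p_{s}"] for s in states], dtype=float),
                call=str(row["call"]),
                call_states=call_states,
                n_perm=int(row["n_perm"]),
                members=members,
            )
        )
    return out


def compare_composition(
    assignments: list[AssignmentResult],
    condition_by_library: dict[str, str],
) -> pd.DataFrame:
    """Tabulate call-state composition by condition; Fisher-test two conditions.

    Each assignment contributes one count per called state (pure calls one
    state, mixed calls each of theirs).  With exactly two conditions, each
    state gets a two-sided Fisher exact p (state vs rest by condition),
    BH-adjusted across states; otherwise the table is descriptive.
    """
    rows = []
    for a in assignments:
        if a.library_id not in condition_by_library:
            raise InputError(f"no condition for {a.library_id!r}")
        cond = condition_by_library[a.library_id]
        for s in a.call_states:
            rows.append((cond, s))
    conditions = sorted(set(condition_by_library.values()))
    states = sorted({s for a in assignments for s in a.states}, key=str)
    counts = pd.DataFrame(0, index=states, columns=conditions, dtype=int)
    for cond, s in rows:
        counts.loc[s, cond] += 1
    if not conditions:
        raise InputError("no conditions supplied")
    totals = counts.sum(axis=0)
    out = counts.copy()
    for cond in conditions:
        out[f"prop_{cond}"] = (
            counts[cond] / totals[cond] if totals[cond] > 0 else 0.0
        )
    if len(conditions) == 2 and (totals > 0).all():
        c1, c2 = conditions
        pvals, odds, flags = [], [], []
        for s in states:
            a = counts.loc[s, c1]
            b = totals[c1] - a
            c = counts.loc[s, c2]
            d = totals[c2] - c
            # odds of state membership in the second condition vs the first
            o, p = scipy.stats.fisher_exact([[c, d], [a, b]], alternative="two-sided")
            pvals.append(p)
            odds.append(o)
            flags.append(
                f"absent in {c2}" if c == 0 and a > 0 else (
                    f"absent in {c1}" if a == 0 and c > 0 else ""
                )
            )
        out["odds_ratio"] = odds
        out["p_value"] = pvals
        out["p_adjusted"] = multipletests(pvals, method="fdr_bh")[1]
        out["note"] = flags
    return out
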