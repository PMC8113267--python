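"""Synthetic 1D tissue simulator with ground truth.

Cells live on a rostro-caudal axis in ``[0, 1]`` tiled by state domains.
Single libraries are one cell; cluster libraries are the element-wise sum of
a handful of spatially contiguous cells, with a small rate of "sticky"
artifact clusters whose members ignore position.  Expression is
negative-binomial over a log-normal baseline with marker genes upregulated
per state.  Everything is reproducible from one integer seed via named
child seed-sequences, so adding libraries never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import CountMatrix, InputError, make_annotations

__all__ = [
    "Interval",
    "Knockout",
    "TissueModel",
    "GeneModel",
    "HYBRID_LABEL",
    "build_gene_model",
    "state_probabilities",
    "sample_library_size",
    "sample_cell",
    "generate_dataset",
    "replay_cluster_cells",
    "apply_knockout",
    "true_adjacency",
    "true_order",
]

#: Truth label for cells expressing the averaged two-state program after a
#: knockout; deliberately not a plain state number.
HYBRID_LABEL = "hybrid"


@dataclass(frozen=True)
class Interval:
    """One contiguous domain interval ``[start, end)`` owned by ``state``."""

    state: int
    start: float
    end: float


@dataclass(frozen=True)
class Knockout:
    removed_state: int
    hybrid_pair: tuple[int, int]


def _default_layout() -> tuple[Interval, ...]:
    return (
        Interval(1, 0.00, 0.30),
        Interval(2, 0.30, 0.50),
        Interval(3, 0.50, 0.70),
        Interval(4, 0.70, 1.00),
    )


@dataclass(frozen=True)
class TissueModel:
    """Parameters of the synthetic tissue and its expression model."""

    n_states: int = 4
    domain_layout: tuple[Interval, ...] = field(default_factory=_default_layout)
    mixing_width: float = 0.03
    n_genes: int = 2000
    markers_per_state: int = 30
    marker_fold_change: float = 4.0
    baseline_log_mean: float = 0.0
    baseline_log_sigma: float = 1.0
    nb_dispersion: float = 2.0
    single_umi_median: float = 6000.0
    libsize_sigma: float = 0.25
    cluster_size_mean: float = 6.0
    cluster_size_min: int = 2
    cluster_window: float = 0.03
    sticky_rate: float = 0.02
    adjacent_bleed: float = 0.0
    knockout: Knockout | None = None
    knockout_active: bool = False

    def __post_init__(self):
        layout = tuple(
            iv if isinstance(iv, Interval) else Interval(*iv)
            for iv in self.domain_layout
        )
        object.__setattr__(self, "domain_layout", layout)
        if self.knockout is not None and not isinstance(self.knockout, Knockout):
            ko = self.knockout
            object.__setattr__(
                self, "knockout", Knockout(ko[0], tuple(ko[1]))  # type: ignore[index]
            )
        self.validate()

    def validate(self) -> None:
        layout = sorted(self.domain_layout, key=lambda iv: iv.start)
        if not layout:
            raise InputError("domain_layout is empty")
        if not math.isclose(layout[0].start, 0.0) or not math.isclose(
            layout[-1].end, 1.0
        ):
            raise InputError("domain_layout must cover [0, 1]")
        for a, b in zip(layout, layout[1:]):
            if not math.isclose(a.end, b.start):
                raise InputError("domain intervals must tile [0, 1] without gaps")
        states = {iv.state for iv in layout}
        if states != set(range(1, self.n_states + 1)):
            raise InputError("layout states must be exactly 1..n_states")
        if self.mixing_width < 0:
            raise InputError("mixing_width must be >= 0")
        if self.markers_per_state * self.n_states > self.n_genes:
            raise InputError("markers_per_state * n_states must be <= n_genes")
        if self.marker_fold_change < 1:
            raise InputError("marker_fold_change must be >= 1")
        if not 0 <= self.sticky_rate <= 1:
            raise InputError("sticky_rate must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise InputError("nb_dispersion must be > 0 (math.inf for Poisson)")
        if not 0 <= self.adjacent_bleed < 1:
            raise InputError("adjacent_bleed must lie in [0, 1)")

    def sorted_layout(self) -> list[Interval]:
        return sorted(self.domain_layout, key=lambda iv: iv.start)


def apply_knockout(model: TissueModel) -> TissueModel:
    """Activate the configured knockout: the removed state's domain now emits
    the averaged expression program of the hybrid pair and is never labeled
    with the removed state in the truth table."""
    ko = model.knockout
    if ko is None:
        raise InputError("model has no knockout configured")
    if not 1 <= ko.removed_state <= model.n_states:
        raise InputError(f"removed_state {ko.removed_state} not in 1..{model.n_states}")
    for s in ko.hybrid_pair:
        if not 1 <= s <= model.n_states:
            raise InputError(f"hybrid state {s} not in 1..{model.n_states}")
    return replace(model, knockout_active=True)


# --------------------------------------------------------------------------
# gene-level expression model


@dataclass(frozen=True)
class GeneModel:
    """Realized per-gene parameters derived from a TissueModel and a seed."""

    gene_ids: tuple[str, ...]
    baseline: np.ndarray  # relative baseline expression, sums to 1
    marker_sets: dict[int, np.ndarray]  # state -> marker gene indices
    rel_expr: dict[str, np.ndarray]  # state label -> normalized expression

    def markers_of(self, state: int) -> np.ndarray:
        return self.marker_sets[state]


def build_gene_model(model: TissueModel, seed: int) -> GeneModel:
    """Draw baselines and assign marker blocks, deterministically from seed.

    State ``s`` owns the contiguous marker block
    ``[(s-1)*M, s*M)`` so that simulated truth is trivially inspectable.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0)))
    G, S, M = model.n_genes, model.n_states, model.markers_per_state
    baseline = rng.lognormal(model.baseline_log_mean, model.baseline_log_sigma, size=G)
    baseline /= baseline.sum()
    marker_sets = {
        s: np.arange((s - 1) * M, s * M, dtype=int) for s in range(1, S + 1)
    }
    # states whose domains touch express each other's markers at a reduced
    # fold (f ** adjacent_bleed), mimicking a developmental continuum in
    # which neighboring programs are correlated
    adjacency = true_adjacency(model)
    rel = {}
    for s in range(1, S + 1):
        v = baseline.copy()
        v[marker_sets[s]] *= model.marker_fold_change
        if model.adjacent_bleed > 0:
            bleed = model.marker_fold_change ** model.adjacent_bleed
            for t in range(1, S + 1):
                if t != s and frozenset((s, t)) in adjacency:
                    v[marker_sets[t]] *= bleed
        rel[str(s)] = v / v.sum()
    if model.knockout is not None:
        a, b = model.knockout.hybrid_pair
        h = (rel[str(a)] + rel[str(b)]) / 2.0
        rel[HYBRID_LABEL] = h / h.sum()
    gene_ids = tuple(f"g{i:04d}" for i in range(G))
    return GeneModel(gene_ids, baseline, marker_sets, rel)


# --------------------------------------------------------------------------
# tissue geometry


def state_probabilities(model: TissueModel, position: float) -> np.ndarray:
    """State membership probabilities at a position on the axis.

    With ``mixing_width == 0`` this is the indicator of the containing
    interval (half-open; the last interval is closed).  With positive width,
    mass ``1 / (1 + exp(d / w))`` leaks across each boundary of the
    containing interval, where ``d`` is the distance to that boundary — so a
    position exactly on a boundary splits 50/50.
    """
    if not 0.0 <= position <= 1.0:
        raise InputError(f"position {position} outside [0, 1]")
    layout = model.sorted_layout()
    idx = len(layout) - 1
    for i, iv in enumerate(layout):
        if position < iv.end:
            idx = i
            break
    p = np.zeros(model.n_states)
    w = model.mixing_width
    if w == 0:
        p[layout[idx].state - 1] = 1.0
        return p
    self_mass = 1.0
    # leak across the left boundary (to the previous interval's state)
    if idx > 0:
        d = position - layout[idx].start
        leak = 1.0 / (1.0 + math.exp(d / w))
        p[layout[idx - 1].state - 1] += leak
        self_mass -= leak
    if idx < len(layout) - 1:
        d = layout[idx].end - position
        leak = 1.0 / (1.0 + math.exp(d / w))
        p[layout[idx + 1].state - 1] += leak
        self_mass -= leak
    p[layout[idx].state - 1] += max(self_mass, 0.0)
    total = p.sum()
    return p / total


def true_adjacency(model: TissueModel) -> set[frozenset[int]]:
    """State pairs whose domains share a boundary in the layout."""
    layout = model.sorted_layout()
    pairs = set()
    for a, b in zip(layout, layout[1:]):
        if a.state != b.state:
            pairs.add(frozenset((a.state, b.state)))
    return pairs


def true_order(model: TissueModel) -> tuple[int, ...]:
    """Sequence of distinct states along the axis (run-length collapsed)."""
    order: list[int] = []
    for iv in model.sorted_layout():
        if not order or order[-1] != iv.state:
            order.append(iv.state)
    return tuple(order)


# --------------------------------------------------------------------------
# sampling


def sample_library_size(model: TissueModel, rng: np.random.Generator) -> int:
    """Per-cell UMI total: log-normal with median ``single_umi_median``."""
    size = rng.lognormal(math.log(model.single_umi_median), model.libsize_sigma)
    return max(1, int(round(size)))


def sample_cell(
    model: TissueModel,
    gene_model: GeneModel,
    state: int | str,
    libsize: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one cell's UMI vector: NB(mean = libsize * p_g, dispersion theta).

    ``state`` may be a state number or the hybrid label.  An infinite
    dispersion collapses to Poisson.
    """
    if libsize <= 0:
        raise InputError("libsize must be > 0")
    key = str(state)
    if key not in gene_model.rel_expr:
        raise InputError(f"unknown state {state!r}")
    mean = libsize * gene_model.rel_expr[key]
    theta = model.nb_dispersion
    if math.isinf(theta):
        return rng.poisson(mean)
    lam = rng.gamma(theta, mean / theta)
    return rng.poisson(lam)


def _draw_state(
    model: TissueModel, position: float, rng: np.random.Generator
) -> str:
    p = state_probabilities(model, position)
    s = int(rng.choice(model.n_states, p=p)) + 1
    if (
        model.knockout_active
        and model.knockout is not None
        and s == model.knockout.removed_state
    ):
        return HYBRID_LABEL
    return str(s)


def _simulate_cluster(
    model: TissueModel, gene_model: GeneModel, seed: int, j: int
) -> tuple[dict, np.ndarray]:
    """Draw cluster ``j`` from its own child stream; returns the truth record
    and the member-by-gene count matrix (the library column is its sum)."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2, j)))
    anchor = float(rng.uniform(0, 1))
    extra = model.cluster_size_mean - model.cluster_size_min
    k = model.cluster_size_min + (int(rng.poisson(extra)) if extra > 0 else 0)
    sticky = bool(rng.uniform() < model.sticky_rate)
    if sticky:
        positions = rng.uniform(0, 1, size=k)
    else:
        positions = np.clip(
            anchor + rng.normal(0.0, model.cluster_window, size=k), 0.0, 1.0
        )
    states = []
    member_counts = np.zeros((k, model.n_genes), dtype=np.int64)
    for m, pos in enumerate(positions):
        state = _draw_state(model, float(pos), rng)
        libsize = sample_library_size(model, rng)
        member_counts[m] = sample_cell(model, gene_model, state, libsize, rng)
        states.append(state)
    record = {
        "library_id": f"C{j:04d}",
        "kind": "cluster",
        "anchor": anchor,
        "is_sticky": sticky,
        "member_positions": [float(p) for p in positions],
        "member_states": states,
    }
    return record, member_counts


def replay_cluster_cells(model: TissueModel, seed: int, j: int) -> np.ndarray:
    """Re-draw cluster ``j``'s member cell count vectors (deterministic replay);
    lets conservation be asserted externally against the emitted matrix."""
    gene_model = build_gene_model(model, seed)
    _, member_counts = _simulate_cluster(model, gene_model, seed, j)
    return member_counts


def generate_dataset(
    model: TissueModel,
    n_singles: int,
    n_clusters: int,
    seed: int,
    condition: str = "control",
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate single and cluster libraries with full ground truth.

    Returns ``(counts, annotations, truth)``.  The truth table records, per
    library: member positions, member state labels, the cluster anchor and
    the sticky flag.  Cluster counts are exactly the sum of their member
    cells' draws.
    """
    if n_singles < 0 or n_clusters < 0:
        raise InputError("library counts must be >= 0")
    gene_model = build_gene_model(model, seed)
    G = model.n_genes
    columns = np.zeros((G, n_singles + n_clusters), dtype=np.int64)
    records = []

    for i in range(n_singles):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1, i)))
        pos = float(rng.uniform(0, 1))
        state = _draw_state(model, pos, rng)
        libsize = sample_library_size(model, rng)
        columns[:, i] = sample_cell(model, gene_model, state, libsize, rng)
        records.append(
            {
                "library_id": f"S{i:04d}",
                "kind": "single",
                "anchor": pos,
                "is_sticky": False,
                "member_positions": [pos],
                "member_states": [state],
            }
        )

    for j in range(n_clusters):
        record, member_counts = _simulate_cluster(model, gene_model, seed, j)
        columns[:, n_singles + j] = member_counts.sum(axis=0)
        records.append(record)

    lib_ids = [r["library_id"] for r in records]
    counts = CountMatrix(sp.csc_matrix(columns), list(gene_model.gene_ids), lib_ids)
    annotations = make_annotations(counts, kind="ambiguous", condition=condition)
    truth = pd.DataFrame.from_records(
        records,
        columns=[
            "library_id",
            "kind",
            "anchor",
            "is_sticky",
            "member_positions",
            "member_states",
        ],
    )
    return counts, annotations, truth
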