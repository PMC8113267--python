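"""State-adjacency graph from mixed identity calls and 1D seriation.

Every mixed call votes for all state pairs it contains; pairs supported by
at least ``min_support`` calls become graph edges.  Seriation searches state
permutations exhaustively for orders that keep supported pairs adjacent,
reporting all minimum-cost orders modulo reversal.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .identity import AssignmentResult
from .model import InputError

__all__ = [
    "StateAdjacencyGraph",
    "OrderingResult",
    "build_adjacency",
    "seriate",
    "evaluate_against_truth",
    "render_report",
]


@dataclass
class StateAdjacencyGraph:
    """States as nodes; support-weighted adjacency edges from mixed calls."""

    states: tuple[str, ...]
    support: dict[frozenset, int]  # raw support per unordered pair
    min_support: int

    @property
    def edges(self) -> dict[frozenset, int]:
        return {
            pair: n for pair, n in self.support.items() if n >= self.min_support
        }

    @property
    def forbidden(self) -> set[frozenset]:
        """Observed state pairs with zero raw support."""
        out = set()
        for a, b in itertools.combinations(self.states, 2):
            pair = frozenset((a, b))
            if self.support.get(pair, 0) == 0:
                out.add(pair)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.states)
        for pair, n in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, support=n)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"state_a": min(pair), "state_b": max(pair), "support": n}
            for pair, n in sorted(
                self.edges.items(), key=lambda kv: tuple(sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["state_a", "state_b", "support"])


@dataclass
class OrderingResult:
    """Minimum-cost linear orders of states (modulo reversal)."""

    orders: list[tuple[str, ...]]
    cost: int
    exhaustive: bool = True


def build_adjacency(
    assignments: list[AssignmentResult],
    states=None,
    min_support: int = 2,
) -> StateAdjacencyGraph:
    """Count pair support from mixed calls over the known state universe."""
    if states is None:
        universe: list[str] = []
        for a in assignments:
            for s in a.states:
                if s not in universe:
                    universe.append(s)
        states = sorted(universe)
    states = tuple(str(s) for s in states)
    support: dict[frozenset, int] = {}
    for a in assignments:
        if a.call != "mixed":
            continue
        for x, y in itertools.combinations(sorted(a.call_states), 2):
            pair = frozenset((x, y))
            support[pair] = support.get(pair, 0) + 1
    return StateAdjacencyGraph(states=states, support=support, min_support=min_support)


def _order_cost(order: tuple[str, ...], edges: set[frozenset]) -> int:
    pos = {s: i for i, s in enumerate(order)}
    return sum(1 for pair in edges if abs(pos[min(pair)] - pos[max(pair)]) != 1)


def seriate(
    graph: StateAdjacencyGraph,
    max_exhaustive: int = 9,
) -> OrderingResult:
    """Exhaustively search state orders minimizing violated supported edges.

    Cost of an order is the number of retained edges whose endpoints are not
    adjacent in it.  All minimum-cost orders are returned, de-duplicated
    modulo reversal and sorted lexicographically.
    """
    states = tuple(sorted(graph.states))
    if len(states) > max_exhaustive:
        raise InputError(
            f"{len(states)} states exceeds exhaustive limit {max_exhaustive}; "
            "reduce the state universe or raise max_exhaustive"
        )
    edges = set(graph.edges)
    best_cost: int | None = None
    best: list[tuple[str, ...]] = []
    for perm in itertools.permutations(states):
        if perm > perm[::-1]:
            continue  # canonical representative modulo reversal
        cost = _order_cost(perm, edges)
        if best_cost is None or cost < best_cost:
            best_cost, best = cost, [perm]
        elif cost == best_cost:
            best.append(perm)
    best.sort()
    if best_cost is None:
        raise InputError("graph has no states to order")
    return OrderingResult(orders=best, cost=int(best_cost), exhaustive=True)


def evaluate_against_truth(
    graph: StateAdjacencyGraph,
    ordering: OrderingResult,
    true_pairs: set[frozenset],
    true_state_order: tuple,
) -> dict:
    """Compare inferred adjacency and order against simulation truth.

    ``true_pairs`` is the set of state pairs whose domains touch;
    ``true_state_order`` the run-length-collapsed state sequence along the
    axis.  Order matching is reversal-invariant.
    """
    true_pairs = {frozenset(str(s) for s in pair) for pair in true_pairs}
    truth_states = {s for pair in true_pairs for s in pair} | {
        str(s) for s in true_state_order
    }
    if not truth_states <= set(graph.states):
        raise InputError("truth states are not a subset of the graph's universe")
    inferred = set(graph.edges)
    truth_order = tuple(str(s) for s in true_state_order)
    order_match = any(
        o == truth_order or o == truth_order[::-1] for o in ordering.orders
    )
    support_rows = [
        {
            "state_a": min(pair),
            "state_b": max(pair),
            "support": graph.support.get(pair, 0),
            "is_true_boundary": pair in true_pairs,
        }
        for pair in sorted(
            set(graph.support) | true_pairs, key=lambda p: tuple(sorted(p))
        )
    ]
    return {
        "adjacency_match": inferred == true_pairs,
        "order_match": order_match,
        "missing_edges": sorted(tuple(sorted(p)) for p in true_pairs - inferred),
        "extra_edges": sorted(tuple(sorted(p)) for p in inferred - true_pairs),
        "support_table": support_rows,
    }


def render_report(
    assignments: list[AssignmentResult],
    graph: StateAdjacencyGraph,
    ordering: OrderingResult,
    out_path,
    parameters: dict | None = None,
    evaluation: dict | None = None,
) -> dict:
    """Write a structured JSON run report; returns the report dict."""
    calls = {"pure": 0, "mixed": 0, "unassigned": 0}
    for a in assignments:
        calls[a.call] += 1
    report = {
        "parameters": parameters or {},
        "n_assignments": len(assignments),
        "call_counts": calls,
        "edge_table": graph.edge_table().to_dict(orient="records"),
        "forbidden_pairs": sorted(tuple(sorted(p)) for p in graph.forbidden),
        "min_support": graph.min_support,
        "optimal_orders": [list(o) for o in ordering.orders],
        "order_cost": ordering.cost,
    }
    if evaluation is not None:
        report["evaluation"] = evaluation
    out_path = Path(out_path)
    try:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    except OSError as exc:
        raise IOError(f"cannot write report to {out_path}: {exc}") from exc
    return report
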