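"""Staged pipeline: simulate -> qc -> signatures -> assign -> graph.

Each stage reads only prior-stage artifacts from the output directory and is
skipped when its outputs already exist, so deleting a late artifact and
re-running regenerates only what is missing.  A manifest records the config
hash, seed and a checksum per artifact; identical configs reproduce
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import identity, io, qc, signatures, spatial
from .config import RunConfig, config_hash
from .model import ClseqError, InputError
from .simulate import generate_dataset, true_adjacency, true_order

__all__ = ["run_pipeline", "DependencyError", "stage_outputs"]

log = logging.getLogger("clseq")


class DependencyError(ClseqError):
    """A stage's required input artifact is missing."""


STAGE_OUTPUTS = {
    "simulate": ["sim/matrix.mtx", "sim/features.tsv", "sim/barcodes.tsv",
                 "sim/annotations.tsv", "sim/truth.tsv", "sim/labels.tsv"],
    "qc": ["qc/matrix.mtx", "qc/features.tsv", "qc/barcodes.tsv",
           "qc/annotations.tsv", "qc/qc_report.json"],
    "signatures": ["signatures/markers.tsv", "signatures/signatures.tsv",
                   "signatures/marker_lists.json"],
    "assign": ["assign/assignments.tsv", "assign/state_correlations.tsv",
               "assign/composition.tsv"],
    "graph": ["graph/edges.tsv", "graph/orders.json", "graph/report.json"],
}

STAGE_INPUTS = {
    "simulate": [],
    "qc": ["sim/matrix.mtx", "sim/annotations.tsv"],
    "signatures": ["qc/matrix.mtx", "qc/annotations.tsv", "sim/labels.tsv"],
    "assign": ["qc/matrix.mtx", "qc/annotations.tsv", "sim/labels.tsv",
               "signatures/marker_lists.json"],
    "graph": ["assign/assignments.tsv"],
}


def stage_outputs(cfg: RunConfig, stage: str) -> list[Path]:
    return [Path(cfg.out_dir) / rel for rel in STAGE_OUTPUTS[stage]]


def _stage_seed(seed: int, stage: str) -> int:
    codes = {"simulate": 1, "qc": 2, "signatures": 3, "assign": 4, "graph": 5}
    return int(
        np.random.SeedSequence((int(seed), 100 + codes[stage])).generate_state(1)[0]
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, rels: list[str], stage: str) -> None:
    for rel in rels:
        if not (out / rel).is_file():
            raise DependencyError(
                f"stage {stage!r} requires missing artifact {out / rel}"
            )


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    executed = []
    for stage in cfg.stages:
        t0 = time.monotonic()
        outputs = stage_outputs(cfg, stage)
        if not force and all(p.is_file() for p in outputs):
            log.info("stage=%s status=skipped (outputs present)", stage)
            continue
        _require(out, STAGE_INPUTS[stage], stage)
        globals()[f"_run_{stage}"](cfg, out)
        executed.append(stage)
        log.info("stage=%s status=done elapsed=%.2fs", stage, time.monotonic() - t0)

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stages_requested": list(cfg.stages),
        "stages_executed": executed,
        "artifacts": {
            rel: _checksum(out / rel)
            for stage in cfg.stages
            for rel in STAGE_OUTPUTS[stage]
            if (out / rel).is_file()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --------------------------------------------------------------------------


def _run_simulate(cfg: RunConfig, out: Path) -> None:
    sim = cfg.simulate
    counts, ann, truth = generate_dataset(
        sim.model,
        sim.n_singles,
        sim.n_clusters,
        seed=_stage_seed(cfg.seed, "simulate"),
        condition=sim.condition,
    )
    io.write_counts_triplet(counts, out / "sim")
    io.write_annotations(ann, out / "sim" / "annotations.tsv")
    io.write_truth(truth, out / "sim" / "truth.tsv")
    # reference state labels for single libraries (simulation ground truth
    # stands in for an upstream single-cell clustering)
    singles = truth[truth["kind"] == "single"]
    labels = pd.DataFrame(
        {
            "library_id": singles["library_id"],
            "state": [states[0] for states in singles["member_states"]],
        }
    )
    labels.to_csv(out / "sim" / "labels.tsv", sep="\t", index=False)


def _run_qc(cfg: RunConfig, out: Path) -> None:
    counts = io.read_counts_triplet(out / "sim")
    ann = io.read_annotations(out / "sim" / "annotations.tsv")
    gene_table_path = out / "sim" / "genes.tsv"
    if gene_table_path.is_file():
        gene_table = io.read_gene_table(gene_table_path)
    else:
        from .model import make_gene_table

        gene_table = make_gene_table(list(counts.gene_ids))
    ann = qc.classify_library_kind(counts, ann, cfg.qc)
    counts2, ann2, report = qc.basic_filters(counts, ann, gene_table, cfg.qc)
    keep = ann2["kind"] != "ambiguous"
    counts3 = counts2.subset_libraries(keep.to_numpy())
    ann3 = ann2.loc[keep].reset_index(drop=True)
    report["n_ambiguous_excluded"] = int((~keep).sum())
    if (ann3["kind"] == "single").sum() >= 10:
        ann3 = qc.estimate_cluster_sizes(counts3, ann3)
    io.write_counts_triplet(counts3, out / "qc")
    io.write_annotations(ann3, out / "qc" / "annotations.tsv")
    with open(out / "qc" / "qc_report.json", "w") as fh:
        json.dump(report, fh, indent=2)


def _load_reference(out: Path):
    counts = io.read_counts_triplet(out / "qc")
    ann = io.read_annotations(out / "qc" / "annotations.tsv")
    labels = pd.read_csv(out / "sim" / "labels.tsv", sep="\t", dtype=str)
    label_map = dict(zip(labels["library_id"], labels["state"]))
    is_single = (ann["kind"] == "single").to_numpy()
    single_ids = counts.library_ids[is_single]
    # UMI classification can mislabel the odd tiny cluster as a single;
    # libraries without a reference label are excluded from the reference
    labeled = [b for b in single_ids if b in label_map]
    if not labeled:
        raise InputError("no labeled single libraries available as reference")
    return counts, ann, label_map


def _run_signatures(cfg: RunConfig, out: Path) -> None:
    counts, ann, label_map = _load_reference(out)
    norm = signatures.normalize_log1p(counts)
    is_single = (ann["kind"] == "single").to_numpy()
    single_idx = np.array(
        [i for i in np.flatnonzero(is_single) if counts.library_ids[i] in label_map]
    )
    states = [label_map[b] for b in counts.library_ids[single_idx]]
    de = signatures.find_markers(
        norm[:, single_idx],
        counts.gene_ids,
        states,
        logfc_min=cfg.signatures.logfc_min,
        padj_max=cfg.signatures.padj_max,
    )
    tops = signatures.top_markers(de, top_n=cfg.signatures.top_n)
    prof = signatures.build_signatures(
        norm[:, single_idx], counts.gene_ids, states, tops
    )
    (out / "signatures").mkdir(parents=True, exist_ok=True)
    de.to_csv(out / "signatures" / "markers.tsv", sep="\t", index=False)
    prof.to_csv(out / "signatures" / "signatures.tsv", sep="\t", index_label="gene_id")
    with open(out / "signatures" / "marker_lists.json", "w") as fh:
        json.dump(tops, fh, indent=2)


def _run_assign(cfg: RunConfig, out: Path) -> None:
    counts, ann, label_map = _load_reference(out)
    with open(out / "signatures" / "marker_lists.json") as fh:
        tops = json.load(fh)
    gene_set = sorted({g for genes in tops.values() for g in genes})
    norm = signatures.normalize_log1p(counts)
    kinds = ann["kind"].to_numpy()
    ref_idx = np.array(
        [
            i
            for i in np.flatnonzero(kinds == "single")
            if counts.library_ids[i] in label_map
        ]
    )
    query_idx = np.flatnonzero((kinds == "cluster") | (kinds == "spot"))
    if query_idx.size == 0:
        raise InputError("no cluster/spot query libraries after QC")
    query_ids = list(counts.library_ids[query_idx])
    ref_states = [label_map[b] for b in counts.library_ids[ref_idx]]
    corr = identity.correlate_to_reference(
        norm[:, query_idx], query_ids, norm[:, ref_idx], ref_states,
        counts.gene_ids, gene_set,
    )
    acfg = cfg.assign
    seed = _stage_seed(cfg.seed, "assign")
    if acfg.resolutions is not None:
        lib_rows = identity.assign_consensus(
            corr, resolutions=acfg.resolutions, r_min=acfg.r_min,
            p_max=acfg.p_max, n_perm=acfg.n_perm, seed=seed,
        )
    else:
        groups = identity.group_queries(
            corr.profile_corr, n_groups=acfg.n_groups, height=acfg.height
        )
        p_group = identity.permutation_test(
            corr.r_matrix, groups, corr.ref_states, n_perm=acfg.n_perm, seed=seed
        )
        group_corr = corr.state_means.groupby(groups).mean().loc[p_group.index]
        members = {
            g: [q for q, gg in zip(query_ids, groups) if gg == g]
            for g in p_group.index
        }
        group_assignments = identity.assign_identities(
            group_corr, p_group, r_min=acfg.r_min, p_max=acfg.p_max,
            n_perm=acfg.n_perm, seed=seed, members=members,
        )
        lib_rows = []
        for a in group_assignments:
            for lib in a.members:
                lib_rows.append(
                    identity.AssignmentResult(
                        library_id=lib, states=a.states,
                        r=corr.state_means.loc[lib].to_numpy(dtype=float),
                        p_perm=a.p_perm, call=a.call, call_states=a.call_states,
                        n_perm=a.n_perm, seed=seed, members=(str(a.library_id),),
                    )
                )
    (out / "assign").mkdir(parents=True, exist_ok=True)
    identity.assignments_to_frame(lib_rows).to_csv(
        out / "assign" / "assignments.tsv", sep="\t", index=False
    )
    corr.state_means.to_csv(
        out / "assign" / "state_correlations.tsv", sep="\t", index_label="library_id"
    )
    cond = dict(zip(ann["library_id"], ann["condition"]))
    comp = identity.compare_composition(lib_rows, cond)
    comp.to_csv(out / "assign" / "composition.tsv", sep="\t", index_label="state")


def _run_graph(cfg: RunConfig, out: Path) -> None:
    frame = pd.read_csv(out / "assign" / "assignments.tsv", sep="\t")
    assignments = identity.frame_to_assignments(frame)
    graph = spatial.build_adjacency(assignments, min_support=cfg.graph.min_support)
    ordering = spatial.seriate(graph)
    evaluation = None
    truth_path = out / "sim" / "truth.tsv"
    if truth_path.is_file():
        model = cfg.simulate.model
        try:
            evaluation = spatial.evaluate_against_truth(
                graph, ordering, true_adjacency(model), true_order(model)
            )
        except InputError as exc:
            # e.g. knockout runs where a truth state never appears in calls
            evaluation = {"error": str(exc)}
    (out / "graph").mkdir(parents=True, exist_ok=True)
    graph.edge_table().to_csv(out / "graph" / "edges.tsv", sep="\t", index=False)
    with open(out / "graph" / "orders.json", "w") as fh:
        json.dump(
            {"orders": [list(o) for o in ordering.orders], "cost": ordering.cost},
            fh, indent=2,
        )
    spatial.render_report(
        assignments, graph, ordering, out / "graph" / "report.json",
        parameters={"min_support": cfg.graph.min_support, "seed": cfg.seed},
        evaluation=evaluation,
    )
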