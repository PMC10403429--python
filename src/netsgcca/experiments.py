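"""Experiment harness: gamma sweeps, graph probes, degree/distance
analyses, and survival-guided evaluation.

Each function wraps the model in the resampling or perturbation protocol
used to interrogate what the graph penalty contributes: how selection
counts move with gamma, what happens when the graph's labels are permuted
or its edges removed, and whether model components predict survival.
Child seeds are derived as ``base_seed + run_index`` so individual runs
are reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import Block, GraphPenaltyConfig
from .graph import (PriorGraph, align_graph, graph_summary, pairwise_distances,
                    permute_labels, remove_edges)
from .model import NetSGCCA, NetSGCCAResults, SolverSettings
from .stability import SelectionRun, bootstrap_indices, dice, pairwise_stability
from .survival import SurvivalData, residual_block, survival_evaluation

logger = logging.getLogger(__name__)

__all__ = [
    "fit_once",
    "bootstrap_selection",
    "sweep_gamma",
    "graph_probe",
    "degree_analysis",
    "survival_eval",
]


def fit_once(blocks, sparsity, gamma: float = 0.0, graph: PriorGraph | None = None,
             target_block: str | None = None, variant: str = "normalized",
             n_components: int = 1, settings: SolverSettings | None = None,
             design=None, scale: bool = True) -> NetSGCCAResults:
    """Fit netSGCCA once; gamma = 0 (or no graph) gives plain SGCCA."""
    penalty = None
    if gamma > 0:
        if graph is None:
            raise ValueError("gamma > 0 requires a graph")
        if target_block is None:
            target_block = blocks[0].name
        penalty = GraphPenaltyConfig(target_block=target_block, gamma=gamma,
                                     laplacian_variant=variant)
    model = NetSGCCA(blocks, design=design, sparsity=sparsity,
                     penalty=penalty, graph=graph, scale=scale)
    return model.fit(n_components=n_components, settings=settings)


def bootstrap_selection(blocks, sparsity, gamma, graph, target_block=None,
                        variant: str = "normalized", n_runs: int = 20,
                        fraction: float = 0.85, strata=None, seed: int = 0,
                        settings: SolverSettings | None = None,
                        index_sets=None) -> list[SelectionRun]:
    """Refit on subsamples (without replacement) and record selections.

    ``index_sets`` overrides the subsample draw so probe runs can reuse the
    reference runs' samples.
    """
    n = blocks[0].n_samples
    if index_sets is None:
        index_sets = bootstrap_indices(n, fraction, n_runs, strata=strata,
                                       seed=seed)
    if settings is None:
        settings = SolverSettings()
    runs = []
    for r, idx in enumerate(index_sets):
        sub = [b.subset_samples(idx) for b in blocks]
        run_settings = SolverSettings(**{**settings.__dict__,
                                         "seed": settings.seed + r})
        res = fit_once(sub, sparsity, gamma=gamma, graph=graph,
                       target_block=target_block, variant=variant,
                       settings=run_settings)
        runs.append(SelectionRun(
            run_id=r,
            selected={nm: res.selected(nm) for nm in res.block_names},
            sample_indices=np.asarray(idx),
        ))
    return runs


def sweep_gamma(blocks, sparsity, gammas, graph, target_block=None,
                variant: str = "normalized", n_runs: int = 10,
                fraction: float = 0.85, strata=None, seed: int = 0,
                settings: SolverSettings | None = None) -> pd.DataFrame:
    """Selection counts and stability per gamma over shared subsamples.

    Returns one row per gamma with median/mean selected count on the
    penalized block and mean pairwise Dice/nPOG across the runs.
    """
    gammas = list(gammas)
    if len(gammas) < 2:
        raise ValueError("sweep needs at least 2 gamma values")
    if target_block is None:
        target_block = blocks[0].name
    n = blocks[0].n_samples
    index_sets = bootstrap_indices(n, fraction, n_runs, strata=strata, seed=seed)
    p_target = {b.name: b.n_features for b in blocks}[target_block]
    rows = []
    for gamma in gammas:
        runs = bootstrap_selection(
            blocks, sparsity, gamma, graph, target_block=target_block,
            variant=variant, settings=settings, index_sets=index_sets)
        counts = [len(r.selected[target_block]) for r in runs]
        rep = pairwise_stability(runs, universe_sizes={target_block: p_target})
        rows.append({
            "gamma": gamma,
            "median_selected": float(np.median(counts)),
            "mean_selected": float(np.mean(counts)),
            "mean_dice": rep.mean_dice[target_block],
            "mean_npog": (rep.mean_npog or {}).get(target_block, np.nan),
            "n_runs": len(runs),
        })
    return pd.DataFrame(rows)


def graph_probe(blocks, sparsity, gamma, graph, probe: str,
                target_block=None, variant: str = "normalized",
                n_runs: int = 10, fraction: float = 0.85, strata=None,
                seed: int = 0, settings: SolverSettings | None = None,
                remove_fraction: float = 0.5,
                reference_runs: list[SelectionRun] | None = None) -> dict:
    """Compare selection under a perturbed graph with the intact one.

    ``probe`` is one of permute | remove_random | remove_inner |
    remove_outer | isolate.  The probe refits on the *same* subsamples as
    the reference; inner/outer/isolate act per run on the reference run's
    selected set.  Reports per-run Dice between reference and probe
    selections, selected counts, and graph density before/after.
    """
    if target_block is None:
        target_block = blocks[0].name
    n = blocks[0].n_samples
    index_sets = bootstrap_indices(n, fraction, n_runs, strata=strata, seed=seed)
    if reference_runs is None:
        reference_runs = bootstrap_selection(
            blocks, sparsity, gamma, graph, target_block=target_block,
            variant=variant, settings=settings, index_sets=index_sets)
    else:
        index_sets = [r.sample_indices for r in reference_runs]

    subsetwise = probe in ("remove_inner", "remove_outer", "isolate")
    if probe == "permute":
        probe_graph = permute_labels(graph, seed=seed + 10_000)
    elif probe == "remove_random":
        probe_graph = remove_edges(graph, "random", fraction=remove_fraction,
                                   seed=seed + 10_000)
    elif not subsetwise:
        raise ValueError(f"unknown probe {probe!r}")

    dice_vs_ref, probe_counts, ref_counts, densities = [], [], [], []
    target_names = {b.name: b for b in blocks}[target_block].feature_names
    for r, ref in enumerate(reference_runs):
        if subsetwise:
            mode = {"remove_inner": "inner", "remove_outer": "outer",
                    "isolate": "isolate"}[probe]
            subset = ref.selected[target_block] & set(graph.nodes)
            if not subset:
                logger.warning("run %d: empty reference selection, probe skipped", r)
                continue
            g_r = remove_edges(graph, mode, node_subset=subset)
        else:
            g_r = probe_graph
        run_settings = None
        if settings is not None:
            run_settings = SolverSettings(**{**settings.__dict__,
                                             "seed": settings.seed + r})
        sub = [b.subset_samples(ref.sample_indices) for b in blocks]
        res = fit_once(sub, sparsity, gamma=gamma, graph=g_r,
                       target_block=target_block, variant=variant,
                       settings=run_settings)
        sel = res.selected(target_block)
        dice_vs_ref.append(dice(sel, ref.selected[target_block]))
        probe_counts.append(len(sel))
        ref_counts.append(len(ref.selected[target_block]))
        densities.append(graph_summary(align_graph(g_r, target_names))["density"])
    ref_density = graph_summary(align_graph(graph, target_names))["density"]
    return {
        "probe": probe,
        "dice_vs_reference": dice_vs_ref,
        "mean_dice_vs_reference": float(np.mean(dice_vs_ref)) if dice_vs_ref else np.nan,
        "reference_counts": ref_counts,
        "probe_counts": probe_counts,
        "reference_density": ref_density,
        "probe_densities": densities,
    }


def degree_analysis(result: NetSGCCAResults, graph: PriorGraph,
                    block: str | None = None, component: int = 0,
                    max_distance: int = 5) -> dict:
    """Degree / weight / distance tables for the selected features.

    Returns three frames: per-selected-feature degree in the full aligned
    graph and in the selected-features subgraph; weights binned by log2
    degree; and mean |w_i - w_j| by shortest-path-distance bucket over
    selected pairs (unreachable pairs excluded).
    """
    if block is None:
        block = result.block_names[0]
    j = result.block_names.index(block)
    feats = result.model.blocks[j].feature_names
    aligned = align_graph(graph, feats)
    w = dict(zip(feats, result.weights[component][j]))
    selected = sorted(result.selected(block, component=component))

    sub = aligned.g.subgraph(selected)
    deg_rows = [{"feature": f,
                 "full_degree": aligned.g.degree[f],
                 "subgraph_degree": sub.degree[f],
                 "weight": w[f]} for f in selected]
    degrees = pd.DataFrame(deg_rows,
                           columns=["feature", "full_degree",
                                    "subgraph_degree", "weight"])

    wb_rows = []
    for f in selected:
        d = aligned.g.degree[f]
        wb_rows.append({"feature": f, "degree": d,
                        "log2_degree_bin": int(np.floor(np.log2(d))) if d > 0 else -1,
                        "weight": w[f], "abs_weight": abs(w[f])})
    weight_by_degree = pd.DataFrame(
        wb_rows, columns=["feature", "degree", "log2_degree_bin",
                          "weight", "abs_weight"])

    dist_rows = []
    if selected:
        dists = pairwise_distances(aligned, selected)
        buckets: dict[int, list[float]] = {}
        for i, u in enumerate(selected):
            for v in selected[i + 1:]:
                d = dists[(u, v)]
                if not np.isfinite(d) or d == 0:
                    continue
                key = int(min(d, max_distance))
                buckets.setdefault(key, []).append(abs(w[u] - w[v]))
        for d in sorted(buckets):
            dist_rows.append({"distance": d,
                              "mean_abs_weight_difference": float(np.mean(buckets[d])),
                              "n_pairs": len(buckets[d])})
    weight_by_distance = pd.DataFrame(
        dist_rows, columns=["distance", "mean_abs_weight_difference", "n_pairs"])
    return {"degrees": degrees, "weight_by_degree": weight_by_degree,
            "weight_by_distance": weight_by_distance}


def survival_eval(blocks, surv: SurvivalData, sparsity, gamma: float = 0.0,
                  graph: PriorGraph | None = None, target_block=None,
                  variant: str = "normalized", test_fraction: float = 0.15,
                  n_components: int = 1, seed: int = 0,
                  settings: SolverSettings | None = None,
                  cox_penalizer: float = 0.0) -> dict:
    """End-to-end survival-guided evaluation.

    Splits samples into train/test stratified by event status, appends the
    null-deviance-residual block (training phase only, linked to every
    block), fits, scores train and test sets on the omics blocks, and fits
    a Cox model on the training components.  Reports train ("validation")
    and test c-index and per-block selected counts.
    """
    n = blocks[0].n_samples
    rng = np.random.default_rng(seed)
    test_idx = []
    for lab in (0, 1):
        grp = np.flatnonzero(surv.event == lab)
        k = int(round(test_fraction * len(grp)))
        test_idx.extend(rng.choice(grp, size=k, replace=False))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)

    train_blocks = [b.subset_samples(train_idx) for b in blocks]
    test_blocks = [b.subset_samples(test_idx) for b in blocks]
    surv_train = surv.subset(train_idx)
    surv_test = surv.subset(test_idx)

    res_block = residual_block(surv_train, train_blocks[0].sample_ids)
    fit_blocks = train_blocks + [res_block]
    sp = list(np.asarray(sparsity, dtype=float)) + [1.0]

    res = fit_once(fit_blocks, sp, gamma=gamma, graph=graph,
                   target_block=target_block, variant=variant,
                   n_components=n_components, settings=settings)

    omics_names = [b.name for b in blocks]
    train_scores = res.transform({b.name: b for b in train_blocks}, partial=True)
    test_scores = res.transform({b.name: b for b in test_blocks}, partial=True)
    Xtr = np.column_stack([train_scores[nm] for nm in omics_names])
    Xte = np.column_stack([test_scores[nm] for nm in omics_names])

    ev = survival_evaluation(Xtr, Xte, surv_train, surv_test,
                             penalizer=cox_penalizer)
    return {
        "c_index_validation": ev["c_index_train"],
        "c_index_test": ev["c_index_test"],
        "selected_counts": {nm: len(res.selected(nm)) for nm in res.block_names},
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "result": res,
    }
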