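"""Canned benchmark experiments on synthetic data.

Each function builds its own data via :mod:`enclasc.synthetic_data`, runs
the classifier and returns plain numbers, so results are reproducible from
a single seed. The study conditions are fixed here once:

* self-projection: 2000 cells × 500 genes, five balanced types, the
  plate-like generator defaults, 100 selected features, 5-fold stratified
  cross-validation;
* rare-class ablation: the droplet-like reference/query split of
  :func:`enclasc.synthetic_data.make_rare_class_split` (5000 reference
  cells with the designated type at 0.4%, a 1000-cell query with that type
  at 30%), run with and without the few-sample stage;
* sparsity: the self-projection dataset with a stated fraction of its
  non-zero entries zeroed;
* stabilization: one 80/20 split of a noisy 1500-cell dataset with weak
  markers, classified by the 10-member voted ensemble and by a single
  network under a series of master seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_selection import FeatureSelectionConfig, compute_gene_scores, rank_genes
from .io_data import ExpressionDataset
from .nn_ensemble import (
    TrainingConfig,
    fit_ensemble,
    predict_ensemble,
    predict_member,
    train_member,
)
from .pipeline import RunConfig, SelfProjectionResult, classify, evaluate, fit, self_project
from .synthetic_data import SimulationConfig, corrupt_dropout, make_rare_class_split, simulate


def self_projection_benchmark(
    seed: int = 0, corruption: float = 0.0
) -> SelfProjectionResult:
    """5-fold self-projection on the balanced five-type dataset."""
    data = simulate(SimulationConfig(seed=seed))
    if corruption > 0:
        data = corrupt_dropout(data, corruption, seed=seed + 1)
    return self_project(data, folds=5, config=RunConfig(seed=seed))


@dataclass
class RareClassResult:
    """Outcome of one rare-class run (one few-sample flag setting)."""

    rare_recall: float
    p_o: float
    kappa: float
    assigned_rate: float


def rare_class_ablation(seed: int = 0) -> dict[bool, RareClassResult]:
    """The few-sample module ablation on the rare-dominated query split."""
    reference, query = make_rare_class_split(seed=seed)
    unlabelled = ExpressionDataset(query.values, query.gene_names, query.cell_ids)
    rare_rows = [i for i, l in enumerate(query.labels) if l == "type_0"]
    out: dict[bool, RareClassResult] = {}
    for enabled in (True, False):
        config = RunConfig(seed=seed, few_sample_enabled=enabled)
        bundle = fit(reference, query.gene_names, config)
        predictions = classify(bundle, unlabelled)
        report = evaluate(query.labels, predictions)
        recall = float(
            np.mean([predictions[i] == "type_0" for i in rare_rows])
        )
        out[enabled] = RareClassResult(
            rare_recall=recall,
            p_o=report.p_o,
            kappa=report.kappa,
            assigned_rate=report.assigned_rate,
        )
    return out


def stabilization_benchmark(
    n_seeds: int = 20, seed: int = 0
) -> dict[str, np.ndarray]:
    """Kappa of the voted ensemble vs a single network over master seeds.

    The data split and selected features are fixed; only the network
    training seeds vary, so the spread measures training stochasticity.
    """
    config = SimulationConfig(
        n_cells=1500,
        marker_fold_change=2.0,
        dropout_midpoint=3.0,
        dropout_steepness=1.5,
        seed=seed,
    )
    data = simulate(config)
    rng = np.random.default_rng(seed)
    order = rng.permutation(data.n_cells)
    split = int(0.8 * data.n_cells)
    reference = data.subset_cells(order[:split])
    query = data.subset_cells(order[split:])
    scores, _ = compute_gene_scores(reference, FeatureSelectionConfig())
    selected = rank_genes(scores)[:100]
    x_ref = np.log1p(reference.subset_genes(selected).values)
    x_query = np.log1p(query.subset_genes(selected).values)
    classes = sorted(set(reference.labels))
    kappa_ensemble = []
    kappa_single = []
    for s in range(n_seeds):
        training = TrainingConfig()
        ensemble = fit_ensemble(
            x_ref, reference.labels, training, master_seed=seed + s
        )
        pred = predict_ensemble(ensemble, x_query)
        kappa_ensemble.append(evaluate(query.labels, pred).kappa)
        network = train_member(
            x_ref, reference.labels, classes, training, seed=seed + 10_000 + s
        )
        pred = predict_member(network, x_query, training.gamma, classes)
        kappa_single.append(evaluate(query.labels, pred).kappa)
    return {
        "ensemble": np.asarray(kappa_ensemble),
        "single": np.asarray(kappa_single),
    }
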