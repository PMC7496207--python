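"""The joint prediction cascade, evaluation metrics and self-projection.

Fitting runs three stages on a labelled reference: (1) dropout-residual
feature selection on the genes shared with the query; (2) if any cell type
is a few-sample class (≤ 0.5% of reference cells), the pairing-based rare
class learner; (3) the 10-member bootstrap MLP ensemble on all reference
cells. Classification is a cascade: a query cell confidently assigned by
the few-sample stage (max score > γ) keeps that label and never reaches the
ensemble; all other cells are voted on by the ensemble; cells rejected by
both stages are "unassigned".

Performance is summarized by Cohen's kappa over the assigned cells —
kappa = (p_o − p_e)/(1 − p_e) with p_o the accuracy among assigned cells and
p_e = Σ_c a_c·b_c / n² the chance agreement from the per-class true (a_c)
and predicted (b_c) counts — together with the assigned rate, the fraction
of query cells given a concrete class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .feature_selection import FeatureSelectionConfig, compute_gene_scores, rank_genes
from .few_sample import (
    FewSampleConfig,
    FewSampleModel,
    assign_few_sample,
    fit_few_sample,
    score_query_cells,
)
from .io_data import UNASSIGNED, ExpressionDataset
from .nn_ensemble import MLP, EnsembleModel, TrainingConfig, fit_ensemble, predict_ensemble


@dataclass
class RunConfig:
    """All settings of one classification run."""

    feature_selection: FeatureSelectionConfig = field(
        default_factory=FeatureSelectionConfig
    )
    few_sample: FewSampleConfig = field(default_factory=FewSampleConfig)
    ensemble: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0
    few_sample_enabled: bool = True
    log1p_network_features: bool = True


@dataclass
class ModelBundle:
    """A fitted cascade, ready to classify queries with the same genes."""

    selected_genes: list[str]
    few_sample_model: FewSampleModel | None
    ensemble: EnsembleModel
    config: RunConfig


@dataclass
class EvalReport:
    """Confusion counts and agreement statistics over assigned cells.

    ``true_counts`` (a_c) and ``predicted_counts`` (b_c) are per-class
    counts among the assigned cells only. ``kappa`` is NaN when no cell was
    assigned.
    """

    true_counts: dict[str, int]
    predicted_counts: dict[str, int]
    n_assigned: int
    n_query: int
    p_o: float
    p_e: float
    kappa: float
    assigned_rate: float


def fit(
    reference: ExpressionDataset,
    query_genes: list[str],
    config: RunConfig | None = None,
) -> ModelBundle:
    """Fit the full cascade on a labelled reference.

    ``query_genes`` is the query dataset's gene list; feature scores are
    computed on the reference restricted to the shared genes.
    """
    config = config or RunConfig()
    if reference.labels is None:
        raise ValueError("reference dataset must carry labels")
    shared = [g for g in reference.gene_names if g in set(query_genes)]
    if not shared:
        raise ValueError("no shared genes between reference and query")
    ref_shared = reference.subset_genes(shared)
    fs_config = config.feature_selection
    scores, _ = compute_gene_scores(ref_shared, fs_config)
    ranked = rank_genes(scores)
    if fs_config.n_features > len(ranked):
        warnings.warn(
            f"requested {fs_config.n_features} features but only "
            f"{len(ranked)} shared genes; using all of them",
            RuntimeWarning,
            stacklevel=2,
        )
    selected = ranked[: min(fs_config.n_features, len(ranked))]
    ref_selected = ref_shared.subset_genes(selected)

    few_model = None
    if config.few_sample_enabled:
        fs = FewSampleConfig(
            **{
                **asdict(config.few_sample),
                "seed": config.seed,
            }
        )
        few_model = fit_few_sample(ref_selected.values, reference.labels, fs)

    X = ref_selected.values
    if config.log1p_network_features:
        X = np.log1p(X)
    ensemble = fit_ensemble(
        X, reference.labels, config.ensemble, master_seed=config.seed
    )
    return ModelBundle(
        selected_genes=selected,
        few_sample_model=few_model,
        ensemble=ensemble,
        config=config,
    )


def classify(bundle: ModelBundle, query: ExpressionDataset) -> list[str]:
    """Classify every query cell; returns class names or "unassigned"."""
    missing = [g for g in bundle.selected_genes if g not in set(query.gene_names)]
    if missing:
        raise ValueError(f"query is missing selected genes: {missing}")
    if query.n_cells == 0:
        return []
    query_selected = query.subset_genes(bundle.selected_genes)
    predictions = [UNASSIGNED] * query.n_cells
    remaining = np.arange(query.n_cells)
    if bundle.few_sample_model is not None:
        scores = score_query_cells(bundle.few_sample_model, query_selected.values)
        few_pred = assign_few_sample(scores, bundle.few_sample_model.config)
        for i, label in enumerate(few_pred):
            if label != UNASSIGNED:
                predictions[i] = label
        remaining = np.asarray(
            [i for i, label in enumerate(few_pred) if label == UNASSIGNED], dtype=int
        )
    if len(remaining):
        X = query_selected.values[remaining]
        if bundle.config.log1p_network_features:
            X = np.log1p(X)
        ens_pred = predict_ensemble(bundle.ensemble, X)
        for i, label in zip(remaining, ens_pred):
            predictions[i] = label
    return predictions


def evaluate(true_labels: list[str], predicted_labels: list[str]) -> EvalReport:
    """Kappa and assigned rate of a prediction vector against the truth.

    Kappa is computed over assigned cells only; the assigned rate is taken
    over all query cells. With zero assigned cells kappa and both agreement
    rates are NaN.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    n_query = len(true_labels)
    pairs = [
        (t, p) for t, p in zip(true_labels, predicted_labels) if p != UNASSIGNED
    ]
    n = len(pairs)
    if n == 0:
        return EvalReport({}, {}, 0, n_query, float("nan"), float("nan"),
                          float("nan"), 0.0)
    classes = sorted({t for t, _ in pairs} | {p for _, p in pairs})
    a = {c: sum(1 for t, _ in pairs if t == c) for c in classes}
    b = {c: sum(1 for _, p in pairs if p == c) for c in classes}
    correct = sum(1 for t, p in pairs if t == p)
    p_o = correct / n
    p_e = sum(a[c] * b[c] for c in classes) / (n * n)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return EvalReport(
        true_counts=a,
        predicted_counts=b,
        n_assigned=n,
        n_query=n_query,
        p_o=p_o,
        p_e=p_e,
        kappa=kappa,
        assigned_rate=n / n_query,
    )


@dataclass
class SelfProjectionResult:
    """Per-fold reports plus kappa / assigned-rate summaries."""

    reports: list[EvalReport]
    mean_kappa: float
    var_kappa: float
    mean_assigned_rate: float
    var_assigned_rate: float


def self_project(
    dataset: ExpressionDataset,
    folds: int = 5,
    config: RunConfig | None = None,
) -> SelfProjectionResult:
    """Stratified k-fold self-projection within one labelled dataset.

    Each fold is held out as the query while the rest is the reference;
    fold assignment is stratified by cell type and seeded from the run
    config. Classes smaller than the fold count may be absent from some
    training folds (warning, not an error).
    """
    config = config or RunConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if dataset.labels is None:
        raise ValueError("dataset must carry labels for self-projection")
    labels = np.asarray(dataset.labels, dtype=object)
    counts = {c: int((labels == c).sum()) for c in set(dataset.labels)}
    small = [c for c, k in counts.items() if k < folds]
    if small:
        warnings.warn(
            f"classes smaller than the fold count may miss some training "
            f"folds: {sorted(small)}",
            RuntimeWarning,
            stacklevel=2,
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        splits = list(splitter.split(np.zeros(dataset.n_cells), labels))
    for train_rows, test_rows in splits:
        reference = dataset.subset_cells(train_rows)
        query = dataset.subset_cells(test_rows)
        truth = [dataset.labels[i] for i in test_rows]
        query_unlabelled = ExpressionDataset(
            query.values, query.gene_names, query.cell_ids
        )
        bundle = fit(reference, query_unlabelled.gene_names, config)
        predictions = classify(bundle, query_unlabelled)
        reports.append(evaluate(truth, predictions))
    kappas = np.asarray([r.kappa for r in reports])
    rates = np.asarray([r.assigned_rate for r in reports])
    return SelfProjectionResult(
        reports=reports,
        mean_kappa=float(np.nanmean(kappas)),
        var_kappa=float(np.nanvar(kappas)),
        mean_assigned_rate=float(rates.mean()),
        var_assigned_rate=float(rates.var()),
    )


# -- persistence -----------------------------------------------------------


def save_bundle(bundle: ModelBundle, directory: str | Path) -> None:
    """Persist a fitted bundle: config JSON, gene list, member weights."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "selected_genes": bundle.selected_genes,
        "class_order": bundle.ensemble.class_order,
        "gamma": bundle.ensemble.gamma,
        "bootstrap_seeds": bundle.ensemble.bootstrap_seeds,
        "seed": bundle.config.seed,
        "few_sample_enabled": bundle.config.few_sample_enabled,
        "log1p_network_features": bundle.config.log1p_network_features,
        "feature_selection": asdict(bundle.config.feature_selection),
        "few_sample": {
            k: v
            for k, v in asdict(bundle.config.few_sample).items()
            if k != "booster_params"
        },
        "has_few_sample_model": bundle.few_sample_model is not None,
    }
    (directory / "bundle.json").write_text(json.dumps(meta, indent=2))
    arrays = {}
    for m, net in enumerate(bundle.ensemble.members):
        for l, (w, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"member{m}_w{l}"] = w
            arrays[f"member{m}_b{l}"] = b
    if bundle.few_sample_model is not None:
        fsm = bundle.few_sample_model
        arrays["few_sample_reference_values"] = fsm.reference_values
        (directory / "few_sample.json").write_text(
            json.dumps(
                {"classes": fsm.classes, "reference_labels": fsm.reference_labels}
            )
        )
        fsm.booster.save_model(str(directory / "pair_regressor.txt"))
    np.savez(directory / "weights.npz", **arrays)


def load_bundle(directory: str | Path) -> ModelBundle:
    """Load a bundle written by :func:`save_bundle`."""
    import lightgbm

    directory = Path(directory)
    meta = json.loads((directory / "bundle.json").read_text())
    arrays = np.load(directory / "weights.npz")
    fs_config = FeatureSelectionConfig(**meta["feature_selection"])
    few_config = FewSampleConfig(**meta["few_sample"])
    config = RunConfig(
        feature_selection=fs_config,
        few_sample=few_config,
        seed=meta["seed"],
        few_sample_enabled=meta["few_sample_enabled"],
        log1p_network_features=meta["log1p_network_features"],
    )
    n_in = len(meta["selected_genes"])
    n_classes = len(meta["class_order"])
    members = []
    m = 0
    while f"member{m}_w0" in arrays:
        net = MLP(n_in, n_classes, config.ensemble.spec, seed=0)
        layers = len(net.weights)
        net.weights = [arrays[f"member{m}_w{l}"] for l in range(layers)]
        net.biases = [arrays[f"member{m}_b{l}"] for l in range(layers)]
        members.append(net)
        m += 1
    ensemble = EnsembleModel(
        members=members,
        bootstrap_seeds=list(meta["bootstrap_seeds"]),
        class_order=list(meta["class_order"]),
        gamma=meta["gamma"],
        config=config.ensemble,
    )
    few_model = None
    if meta["has_few_sample_model"]:
        extra = json.loads((directory / "few_sample.json").read_text())
        booster = lightgbm.Booster(model_file=str(directory / "pair_regressor.txt"))
        few_model = FewSampleModel(
            classes=list(extra["classes"]),
            booster=booster,
            reference_values=arrays["few_sample_reference_values"],
            reference_labels=list(extra["reference_labels"]),
            config=few_config,
        )
    return ModelBundle(
        selected_genes=list(meta["selected_genes"]),
        few_sample_model=few_model,
        ensemble=ensemble,
        config=config,
    )
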