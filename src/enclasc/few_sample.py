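"""Few-sample (rare cell type) learning by sample pairing.

Cell types holding at most 0.5% of the reference cells are too small for a
conventional classifier. This module augments them by pairing: every ordered
pair of rare-class reference cells becomes one training sample whose feature
vector is the two cells' selected-gene vectors concatenated (2×D features)
and whose label is 1 iff the two cells share a type. A LightGBM regressor is
trained on these n×n pairs. At query time each query cell is paired with
every rare reference cell (n×M pairs); the regressor's pair scores c_ij are
aggregated per rare class x as a Pearson-weighted mean

    score(x, i) = sum_j r_ij c_ij / sum_j r_ij        (j over class x)

where r_ij is the Pearson correlation of the two cells' selected-gene
vectors. Negative correlations are clamped to zero before weighting; if all
weights of a class vanish the unweighted mean of c_ij is used. A query cell
is assigned to its argmax class only when the maximum score strictly exceeds
the confidence threshold γ; otherwise it is passed on to the neural-network
ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lightgbm
import numpy as np
import pandas as pd

from .io_data import UNASSIGNED, ExpressionDataset

#: Gradient-boosting settings used for the pair regressor.
DEFAULT_BOOSTER_PARAMS: dict = {
    "boosting_type": "gbdt",
    "objective": "regression",
    "metric": ["l2", "auc"],
    "learning_rate": 0.05,
    "verbose": -1,
}


@dataclass
class FewSampleConfig:
    """Settings for rare-class detection, pairing and scoring.

    class_fraction_threshold
        A class is "few-sample" iff its cell count does not exceed this
        fraction of the reference (boundary inclusive). Default 0.005.
    gamma
        Confidence threshold the maximum class score must strictly exceed
        for assignment. Default 0.7, shared with the ensemble stage.
    booster_params
        LightGBM parameters; merged over :data:`DEFAULT_BOOSTER_PARAMS`.
    n_boost_rounds
        Boosting rounds for the pair regressor. Default 100.
    pair_log1p
        Compute Pearson correlations (and pair features) on log1p-transformed
        selected-gene values instead of raw values. Default off.
    seed
        Seed forwarded to LightGBM for reproducibility.
    """

    class_fraction_threshold: float = 0.005
    gamma: float = 0.7
    booster_params: dict = field(default_factory=dict)
    n_boost_rounds: int = 100
    pair_log1p: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_fraction_threshold < 1.0:
            raise ValueError("class_fraction_threshold must be in (0, 1)")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if self.n_boost_rounds < 1:
            raise ValueError("n_boost_rounds must be >= 1")

    def resolved_booster_params(self) -> dict:
        params = dict(DEFAULT_BOOSTER_PARAMS)
        params.update(self.booster_params)
        params.setdefault("seed", self.seed)
        params.setdefault("deterministic", True)
        params.setdefault("num_threads", 1)
        return params


@dataclass
class FewSampleScores:
    """Per-query-cell class scores plus the underlying pair quantities.

    ``scores`` is an (M × n_classes) DataFrame (columns = few-sample class
    names); ``r`` and ``c`` are (M × n) matrices of Pearson correlations and
    clipped regressor predictions against the n rare reference cells, whose
    classes are listed in ``reference_classes``.
    """

    scores: pd.DataFrame
    r: np.ndarray
    c: np.ndarray
    reference_classes: list[str]


@dataclass
class FewSampleModel:
    """Trained pairing model: rare classes, booster and reference cells."""

    classes: list[str]
    booster: lightgbm.Booster
    reference_values: np.ndarray  # (n_rare, D) selected-gene values
    reference_labels: list[str]
    config: FewSampleConfig


def identify_few_sample_classes(
    labels: list[str], config: FewSampleConfig | None = None
) -> set[str]:
    """Classes whose count does not exceed threshold × N (inclusive)."""
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    config = config or FewSampleConfig()
    counts = pd.Series(labels).value_counts()
    cutoff = config.class_fraction_threshold * len(labels)
    return set(counts.index[counts <= cutoff])


def _pair_features(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    return np.hstack([left, right])


def build_pair_training_set(
    values: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """All n×n ordered pairs of rare-class cells, with same-class labels.

    ``values`` is the (n, D) selected-gene matrix of the few-sample cells.
    Returns ``(X, y)`` with X of shape (n², 2D) — row ``j*n + k`` pairs left
    cell j with right cell k (self-pairs included, labelled 1) — and y in
    {0, 1} with 1 iff the two cells share a class.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("too few rare cells to pair (need >= 2)")
    if len(labels) != n:
        raise ValueError("labels must match the number of cells")
    left = np.repeat(values, n, axis=0)
    right = np.tile(values, (n, 1))
    X = _pair_features(left, right)
    lab = np.asarray(labels, dtype=object)
    y = (np.repeat(lab, n) == np.tile(lab, n)).astype(float)
    return X, y


def build_pair_test_set(
    reference_values: np.ndarray, query_values: np.ndarray
) -> np.ndarray:
    """All n×M reference-left, query-right pairs.

    Row ``j*M + i`` pairs reference cell j (left) with query cell i (right).
    """
    reference_values = np.asarray(reference_values, dtype=float)
    query_values = np.asarray(query_values, dtype=float)
    n, m = reference_values.shape[0], query_values.shape[0]
    if m == 0:
        return np.empty((0, reference_values.shape[1] + query_values.shape[1]))
    left = np.repeat(reference_values, m, axis=0)
    right = np.tile(query_values, (n, 1))
    return _pair_features(left, right)


def train_pair_regressor(
    X: np.ndarray, y: np.ndarray, config: FewSampleConfig | None = None
) -> lightgbm.Booster:
    """Fit the gradient-boosted pair regressor on labelled pairs."""
    config = config or FewSampleConfig()
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("pair labels degenerate: need both 0 and 1 pairs")
    train_set = lightgbm.Dataset(np.asarray(X, dtype=float), label=y)
    params = config.resolved_booster_params()
    return lightgbm.train(params, train_set, num_boost_round=config.n_boost_rounds)


def _pearson_rows(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation of every query row with every reference row.

    Zero-variance rows yield r = 0 (with a warning) rather than NaN.
    """
    q = query - query.mean(axis=1, keepdims=True)
    r_ = reference - reference.mean(axis=1, keepdims=True)
    q_norm = np.linalg.norm(q, axis=1)
    r_norm = np.linalg.norm(r_, axis=1)
    if np.any(q_norm == 0) or np.any(r_norm == 0):
        warnings.warn(
            "zero-variance expression vector: Pearson r undefined, using 0",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (q @ r_.T) / np.outer(q_norm, r_norm)
    corr[~np.isfinite(corr)] = 0.0
    return corr


def aggregate_scores(
    c: np.ndarray, r: np.ndarray, reference_labels: list[str]
) -> pd.DataFrame:
    """Pearson-weighted per-class mean of pair predictions.

    ``c`` and ``r`` are (M × n) matrices of clipped pair predictions and
    Pearson correlations against n reference cells with ``reference_labels``.
    For each class x, score(x, i) = Σ_j w_ij c_ij / Σ_j w_ij over x's cells
    with w = max(r, 0); when every weight of a class vanishes for a cell,
    the unweighted mean of that class's c is used instead.
    """
    m = c.shape[0]
    weights = np.clip(r, 0.0, None)
    labels = np.asarray(reference_labels, dtype=object)
    classes = sorted(set(reference_labels))
    scores = np.zeros((m, len(classes)))
    for k, cls in enumerate(classes):
        cols = labels == cls
        w = weights[:, cols]
        cv = c[:, cols]
        w_sum = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            weighted = (w * cv).sum(axis=1) / w_sum
        fallback = cv.mean(axis=1) if cv.shape[1] else np.zeros(m)
        scores[:, k] = np.where(w_sum > 0, weighted, fallback)
    return pd.DataFrame(scores, columns=classes)


def score_query_cells(
    model: FewSampleModel, query_values: np.ndarray
) -> FewSampleScores:
    """Pearson-weighted class scores for every query cell.

    ``query_values`` is the (M, D) selected-gene matrix of the query, on the
    same genes in the same order as the model's reference cells.
    """
    ref = np.asarray(model.reference_values, dtype=float)
    qry = np.asarray(query_values, dtype=float)
    if model.config.pair_log1p:
        ref = np.log1p(ref)
        qry = np.log1p(qry)
    n, m = ref.shape[0], qry.shape[0]
    pairs = build_pair_test_set(ref, qry)
    c = np.zeros((m, n))
    if m > 0:
        raw = model.booster.predict(pairs)
        # row j*M + i holds pair (ref j, query i); clip to the label range
        c = np.clip(raw.reshape(n, m).T, 0.0, 1.0)
    r = _pearson_rows(qry, ref) if m > 0 else np.zeros((0, n))
    frame = aggregate_scores(c, r, model.reference_labels)
    return FewSampleScores(
        scores=frame, r=r, c=c, reference_classes=list(model.reference_labels)
    )


def assign_few_sample(
    scores: FewSampleScores, config: FewSampleConfig | None = None
) -> list[str]:
    """Assign each query cell to its argmax class iff max score > γ.

    Equal-score ties above γ go to the lexicographically smaller class name
    (class columns are sorted, so the first argmax wins).
    """
    config = config or FewSampleConfig()
    out: list[str] = []
    table = scores.scores
    if table.shape[1] == 0:
        return [UNASSIGNED] * table.shape[0]
    # sorted columns make argmax ties fall to the smaller class name
    table = table[sorted(table.columns)]
    values = table.to_numpy()
    classes = list(table.columns)
    for row in values:
        best = int(np.argmax(row))
        out.append(classes[best] if row[best] > config.gamma else UNASSIGNED)
    return out


def fit_few_sample(
    reference_values: np.ndarray,
    labels: list[str],
    config: FewSampleConfig | None = None,
) -> FewSampleModel | None:
    """Detect rare classes and train the pairing model.

    ``reference_values`` holds the full reference on the D selected genes.
    Returns ``None`` when no class is below the threshold or the rare cells
    are too few / too homogeneous to form a usable pair training set.
    """
    config = config or FewSampleConfig()
    rare = identify_few_sample_classes(labels, config)
    if not rare:
        return None
    mask = np.asarray([l in rare for l in labels])
    values = np.asarray(reference_values, dtype=float)[mask]
    rare_labels = [l for l in labels if l in rare]
    if values.shape[0] < 2:
        warnings.warn(
            "fewer than 2 rare-class cells: few-sample stage disabled",
            RuntimeWarning,
            stacklevel=2,
        )
        return None
    feats = np.log1p(values) if config.pair_log1p else values
    X, y = build_pair_training_set(feats, rare_labels)
    if len(np.unique(y)) < 2:
        warnings.warn(
            "single rare class: pair labels degenerate, few-sample stage disabled",
            RuntimeWarning,
            stacklevel=2,
        )
        return None
    booster = train_pair_regressor(X, y, config)
    return FewSampleModel(
        classes=sorted(rare),
        booster=booster,
        reference_values=values,
        reference_labels=rare_labels,
        config=config,
    )
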