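"""Bootstrap voting ensemble of small multilayer perceptrons.

Ten identical MLPs (input D → 128 → 64 → 32 → C; relu hidden activations,
softmax output; dropout 0.25 after the first hidden layer and 0.5 after the
second) are each trained on an independent bootstrap resample holding 30% of
the reference cells, drawn with replacement. At query time each member
assigns a cell to its argmax class only when the maximum softmax probability
strictly exceeds γ; a cell receives a final class only when strictly more
than half of the 10 members agree on that same class, otherwise it is
"unassigned".

The networks are implemented directly in NumPy: four dense layers trained
with categorical cross-entropy under Adam, with inverted dropout during
training. At this size (tens of thousands of parameters) a deep-learning
framework adds nothing but weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import UNASSIGNED


@dataclass
class MLPSpec:
    """Architecture of one ensemble member.

    Hidden widths, activations and dropout placements are fixed by design:
    relu hidden layers of 128, 64 and 32 units, softmax output over the C
    reference classes, dropout 0.25 after the first hidden layer and 0.5
    after the second.
    """

    hidden: tuple[int, ...] = (128, 64, 32)
    dropout: tuple[float, ...] = (0.25, 0.5, 0.0)


@dataclass
class TrainingConfig:
    """Optimization settings shared by all members."""

    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    bootstrap_fraction: float = 0.3
    n_members: int = 10
    gamma: float = 0.7
    stratified: bool = False
    spec: MLPSpec = field(default_factory=MLPSpec)


class MLP:
    """A small dense softmax classifier trained with Adam.

    Weights use He initialization; dropout is inverted (activations scaled
    by 1/(1−rate) at train time) so inference needs no rescaling.
    """

    def __init__(self, n_in: int, n_classes: int, spec: MLPSpec, seed: int):
        self.spec = spec
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        widths = [n_in, *spec.hidden, n_classes]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        self.biases = [np.zeros(w) for w in widths[1:]]
        self._rng = rng

    # -- forward -----------------------------------------------------------
    def _forward(self, X, dropout_rng=None):
        acts = [X]
        h = X
        n_layers = len(self.weights)
        for l in range(n_layers - 1):
            h = np.maximum(h @ self.weights[l] + self.biases[l], 0.0)
            if dropout_rng is not None and self.spec.dropout[l] > 0:
                keep = 1.0 - self.spec.dropout[l]
                mask = dropout_rng.random(h.shape) < keep
                h = h * mask / keep
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        acts.append(probs)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; rows sum to 1."""
        return self._forward(np.asarray(X, dtype=float))[-1]

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainingConfig) -> "MLP":
        """Train on integer class targets ``y`` with cross-entropy + Adam."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        onehot = np.eye(self.n_classes)[y]
        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _ in range(config.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                grads = self._grads(X[idx], onehot[idx])
                t += 1
                lr_t = config.learning_rate * (
                    np.sqrt(1 - beta2**t) / (1 - beta1**t)
                )
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
        return self

    def _grads(self, X, onehot):
        acts = self._forward(X, dropout_rng=self._rng)
        probs = acts[-1]
        batch = X.shape[0]
        delta = (probs - onehot) / batch
        grads_w = []
        grads_b = []
        for l in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[l].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if l > 0:
                delta = (delta @ self.weights[l].T) * (acts[l] > 0)
        grads_w.reverse()
        grads_b.reverse()
        return grads_w + grads_b


@dataclass
class EnsembleModel:
    """The trained voting ensemble."""

    members: list[MLP]
    bootstrap_seeds: list[int]
    class_order: list[str]
    gamma: float
    config: TrainingConfig


def bootstrap_training_sets(
    n_cells: int,
    seeds: list[int],
    fraction: float = 0.3,
    labels: list[str] | None = None,
) -> list[np.ndarray]:
    """One index list per seed, drawn uniformly with replacement.

    Each list holds ``round(fraction · n_cells)`` indices (round half-up).
    With ``labels`` given, draws are stratified by class: each class
    contributes with-replacement draws in proportion to its size.
    """
    size = int(np.floor(fraction * n_cells + 0.5))
    out = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        if labels is None:
            out.append(rng.integers(0, n_cells, size=size))
        else:
            lab = np.asarray(labels, dtype=object)
            picks = []
            for cls in sorted(set(labels)):
                rows = np.flatnonzero(lab == cls)
                k = int(np.floor(len(rows) / n_cells * size + 0.5))
                if k > 0:
                    picks.append(rng.choice(rows, size=k, replace=True))
            idx = np.concatenate(picks) if picks else np.empty(0, dtype=int)
            out.append(idx)
    return out


def train_member(
    X: np.ndarray,
    y_labels: list[str],
    class_order: list[str],
    config: TrainingConfig,
    seed: int,
) -> MLP:
    """Train one MLP on the given subset; features are the selected genes."""
    class_index = {c: i for i, c in enumerate(class_order)}
    y = np.asarray([class_index[l] for l in y_labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset collapsed to a single class")
    net = MLP(X.shape[1], len(class_order), config.spec, seed)
    return net.fit(X, y, config)


def predict_member(
    network: MLP, query_features: np.ndarray, gamma: float, class_order: list[str]
) -> list[str]:
    """Argmax class per cell iff max softmax probability strictly exceeds γ."""
    if query_features.shape[1] != network.weights[0].shape[0]:
        raise ValueError(
            f"feature-order mismatch: network expects "
            f"{network.weights[0].shape[0]} features, got {query_features.shape[1]}"
        )
    probs = network.predict_proba(query_features)
    best = probs.argmax(axis=1)
    out = []
    for i, b in enumerate(best):
        out.append(class_order[b] if probs[i, b] > gamma else UNASSIGNED)
    return out


def vote(member_predictions: list[list[str]]) -> list[str]:
    """Strict-majority vote over the 10 member predictions per cell.

    A cell gets class x iff strictly more than half of the members (≥ 6 of
    10) predicted x; "unassigned" member votes never count toward a class.
    """
    n_members = len(member_predictions)
    n_cells = len(member_predictions[0]) if n_members else 0
    if any(len(p) != n_cells for p in member_predictions):
        raise ValueError("member predictions must have equal length")
    needed = n_members // 2 + 1
    out = []
    for i in range(n_cells):
        counts: dict[str, int] = {}
        for pred in member_predictions:
            label = pred[i]
            if label != UNASSIGNED:
                counts[label] = counts.get(label, 0) + 1
        winner = UNASSIGNED
        for label in sorted(counts):
            if counts[label] >= needed:
                winner = label
                break
        out.append(winner)
    return out


def fit_ensemble(
    X: np.ndarray,
    labels: list[str],
    config: TrainingConfig | None = None,
    master_seed: int = 0,
) -> EnsembleModel:
    """Train the full bootstrap ensemble on the reference's selected genes.

    Member seeds derive deterministically from ``master_seed`` (master +
    member index). A bootstrap resample that collapses to one class is
    redrawn with a fresh seed, up to 5 attempts per member.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    class_order = sorted(set(labels))
    members: list[MLP] = []
    used_seeds: list[int] = []
    for member in range(config.n_members):
        seed = master_seed + member
        for attempt in range(5):
            idx = bootstrap_training_sets(
                X.shape[0],
                [seed],
                config.bootstrap_fraction,
                labels if config.stratified else None,
            )[0]
            sub_labels = [labels[i] for i in idx]
            if len(set(sub_labels)) >= 2:
                break
            seed += 1009 * config.n_members  # fresh draw, disjoint from other members
        else:
            raise ValueError(
                f"bootstrap for member {member} collapsed to one class 5 times"
            )
        members.append(
            train_member(X[idx], sub_labels, class_order, config, seed=seed)
        )
        used_seeds.append(seed)
    return EnsembleModel(
        members=members,
        bootstrap_seeds=used_seeds,
        class_order=class_order,
        gamma=config.gamma,
        config=config,
    )


def predict_ensemble(model: EnsembleModel, query_features: np.ndarray) -> list[str]:
    """Vote the members' γ-thresholded predictions for every query cell."""
    preds = [
        predict_member(net, query_features, model.gamma, model.class_order)
        for net in model.members
    ]
    return vote(preds)
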