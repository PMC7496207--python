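"""Synthetic scRNA-seq data with class structure, overdispersion and dropout.

The generative model is the standard single-cell toy model: counts are drawn
from a negative binomial whose mean is gene- and class-specific (each class
up-shifts its own block of marker genes by a fold change), then zeroed by a
Bernoulli "dropout" whose probability follows a logistic curve decreasing in
the gene's mean expression — lowly expressed genes drop out more, as in real
droplet data. A separate corruption operator zeroes an exact fraction of the
non-zero entries, emulating increased technical sparsity.

This simulator is a test fixture: it reproduces the qualitative features the
classifier relies on (separable type signatures, mean-dependent zeros, rare
classes), not the empirical distributions of any real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_data import ExpressionDataset


@dataclass
class SimulationConfig:
    """Settings of the synthetic population.

    class_proportions must sum to 1; entries below 0.005 create few-sample
    classes. Each class's expression profile differs from the shared base in
    two ways: its own marker block is up-shifted by ``marker_fold_change``,
    and every gene's mean is modulated by a class-specific lognormal factor
    with log-sd ``class_profile_sigma`` — cell types differ broadly across
    the transcriptome, not only in a handful of markers. Each cell carries a
    lognormal library-size factor of log-sd ``library_size_sigma`` scaling
    all of its gene means, as sequencing depth does. ``sibling_map`` makes
    selected classes closely related: ``{0: 2}`` gives class 0 the broad
    profile of class 2 up to a mild lognormal jitter of log-sd
    ``sibling_sigma`` (its own marker block is still up-shifted), emulating
    transcriptionally similar cell types. dropout_steepness
    acts as a temperature: the per-entry dropout probability is
    sigmoid((dropout_midpoint − μ)/dropout_steepness) in the class-specific
    gene mean μ, so small steepness with midpoint 0 gives near-zero extra
    dropout. dispersion is the negative-binomial shape θ (variance
    μ + μ²/θ).
    """

    n_cells: int = 2000
    n_genes: int = 500
    class_proportions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    n_marker_genes_per_class: int = 20
    marker_fold_change: float = 8.0
    class_profile_sigma: float = 0.4
    library_size_sigma: float = 0.35
    sibling_map: dict | None = None
    sibling_sigma: float = 0.15
    dispersion: float = 2.0
    dropout_midpoint: float = 1.0
    dropout_steepness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(p <= 0 for p in self.class_proportions):
            raise ValueError("class proportions must be positive")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must be > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def _class_counts(n_cells: int, proportions: tuple[float, ...]) -> list[int]:
    counts = [int(round(p * n_cells)) for p in proportions]
    # distribute the rounding remainder over the largest classes
    order = np.argsort(proportions)[::-1]
    i = 0
    while sum(counts) != n_cells:
        counts[order[i % len(counts)]] += 1 if sum(counts) < n_cells else -1
        i += 1
    if any(c == 0 for c in counts):
        raise ValueError("class proportions too small for n_cells")
    return counts


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    # negative binomial with mean μ and shape θ: p = θ/(θ+μ)
    return rng.negative_binomial(theta, theta / (theta + mean))


def _dropout_prob(mean: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    if steepness <= 0:
        return (mean < midpoint).astype(float)
    z = np.clip((midpoint - mean) / steepness, -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


def class_mean_matrix(config: SimulationConfig) -> np.ndarray:
    """Per-class per-gene negative-binomial means, shape (C, n_genes).

    Base gene means are lognormal; class c's marker block (a disjoint slice
    of ``n_marker_genes_per_class`` genes) is multiplied by the fold change,
    and all genes are modulated by a class-specific lognormal factor of
    log-sd ``class_profile_sigma``.
    """
    rng = np.random.default_rng(config.seed)
    n_classes = len(config.class_proportions)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    means = np.tile(base, (n_classes, 1))
    if config.class_profile_sigma > 0:
        means *= rng.lognormal(
            mean=0.0,
            sigma=config.class_profile_sigma,
            size=(n_classes, config.n_genes),
        )
    sibling_map = config.sibling_map or {}
    for child, parent in sibling_map.items():
        if not (0 <= child < n_classes and 0 <= parent < n_classes):
            raise ValueError("sibling_map indices out of range")
        means[child] = means[parent] * rng.lognormal(
            0.0, config.sibling_sigma, size=config.n_genes
        )
    k = config.n_marker_genes_per_class
    if k * n_classes > config.n_genes:
        raise ValueError("not enough genes for disjoint marker blocks")
    for c in range(n_classes):
        # a sibling subtype carries its parent's marker block, not one of
        # its own — subtypes of a lineage share the lineage markers
        block = sibling_map.get(c, c)
        means[c, block * k : (block + 1) * k] *= config.marker_fold_change
    return means


def simulate(config: SimulationConfig) -> ExpressionDataset:
    """Draw a labelled synthetic population. Fully reproducible from seed."""
    counts_per_class = _class_counts(config.n_cells, config.class_proportions)
    means = class_mean_matrix(config)
    rng = np.random.default_rng(config.seed + 1)
    blocks = []
    labels: list[str] = []
    for c, n_c in enumerate(counts_per_class):
        mu = means[c]
        cell_mu = np.tile(mu, (n_c, 1))
        if config.library_size_sigma > 0:
            depth = rng.lognormal(0.0, config.library_size_sigma, size=n_c)
            cell_mu = cell_mu * depth[:, None]
        counts = _nb_counts(rng, cell_mu, config.dispersion)
        p_drop = _dropout_prob(mu, config.dropout_midpoint, config.dropout_steepness)
        keep = rng.random(counts.shape) >= p_drop[None, :]
        blocks.append(counts * keep)
        labels.extend([f"type_{c}"] * n_c)
    values = np.vstack(blocks).astype(float)
    gene_names = [f"gene_{j}" for j in range(config.n_genes)]
    cell_ids = [f"cell_{i}" for i in range(config.n_cells)]
    return ExpressionDataset(values, gene_names, cell_ids, labels)


def corrupt_dropout(
    data: ExpressionDataset, fraction: float, seed: int = 0
) -> ExpressionDataset:
    """Zero exactly ``floor(fraction × nnz)`` non-zero entries, chosen
    uniformly without replacement. Zeros, names and labels are untouched."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    values = data.values.copy()
    rows, cols = np.nonzero(values)
    nnz = len(rows)
    n_zero = int(np.floor(fraction * nnz))
    if n_zero > 0:
        rng = np.random.default_rng(seed)
        pick = rng.choice(nnz, size=n_zero, replace=False)
        values[rows[pick], cols[pick]] = 0.0
    return replace(data, values=values)


def make_rare_class_split(
    config: SimulationConfig | None = None,
    n_reference: int = 5000,
    n_query: int = 1000,
    rare_reference_fraction: float = 0.004,
    rare_query_fraction: float = 0.3,
    other_rare_reference_fractions: tuple[float, ...] = (0.002, 0.003),
    companion_query_fraction: float = 0.4,
    seed: int = 0,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """A reference/query split where cell types that are rare in the
    reference dominate the query.

    The construction mirrors projecting a reference atlas rich in one
    lineage onto a query from a different protocol whose bulk consists of
    cell types the reference holds only marginally:

    * ``type_0`` is the designated rare class — ``rare_reference_fraction``
      of the reference (at most 0.5%, triggering the few-sample rule) but
      ``rare_query_fraction`` of the query. It is a subtype of the abundant
      class ``type_2``: same broad profile and marker block, differing only
      by a mild lognormal jitter (``sibling_map``/``sibling_sigma``), the
      way a rare subtype resembles its abundant relative — so a classifier
      trained on a handful of its cells absorbs it into the relative.
    * ``type_1`` and ``type_5`` are further rare classes at
      ``other_rare_reference_fractions`` of the reference; real tissues
      hold several rare types at once, their unequal sizes and cross-class
      pairs giving the pair learner a richer training signal. (With exactly
      two rare classes of exactly equal size the same-class pair label is
      an XOR of the two cells' types, which no single greedy tree split can
      enter.) ``type_5``, a subtype of common ``type_4``, also fills
      ``companion_query_fraction`` of the query: queries dominated by the
      reference's few-sample classes are precisely the regime the pairing
      module exists for.
    * The parent classes ``type_2`` and ``type_4`` are absent from the
      query — reference and query compositions differ, as across
      laboratories — and the remaining common class fills the rest of both
      splits.

    The union of the two splits is one simulated population. The default
    generator settings are droplet-like (sparser than the plate-like base
    defaults).
    """
    if config is None:
        config = SimulationConfig(
            class_proportions=(1 / 6,) * 6,
            sibling_map={0: 2, 5: 4},
            sibling_sigma=0.05,
            dropout_midpoint=3.0,
            dropout_steepness=1.5,
            seed=seed,
        )
    n_classes = len(config.class_proportions)
    if n_classes < 6:
        raise ValueError("need at least 6 classes (three rare, three common)")
    rare_ids = [0, 1, n_classes - 1]
    common_ids = [c for c in range(n_classes) if c not in rare_ids]
    counts_ref = [0] * n_classes
    counts_query = [0] * n_classes
    counts_ref[0] = max(2, int(round(rare_reference_fraction * n_reference)))
    for frac, c in zip(other_rare_reference_fractions, rare_ids[1:]):
        counts_ref[c] = max(2, int(round(frac * n_reference)))
    counts_query[0] = int(round(rare_query_fraction * n_query))
    counts_query[rare_ids[-1]] = int(round(companion_query_fraction * n_query))
    common_ref = n_reference - sum(counts_ref)
    common_query = n_query - sum(counts_query)
    for c in common_ids:
        counts_ref[c] = int(round(common_ref / len(common_ids)))
    # parents of the rare subtypes stay out of the query
    parents = set((config.sibling_map or {}).values())
    query_ids = [c for c in common_ids if c not in parents] or common_ids[1:2]
    for c in query_ids:
        counts_query[c] = int(round(common_query / len(query_ids)))
    counts_ref[common_ids[-1]] += n_reference - sum(counts_ref)
    counts_query[query_ids[-1]] += n_query - sum(counts_query)
    totals = [r + q for r, q in zip(counts_ref, counts_query)]
    n_total = sum(totals)
    pop_config = replace(
        config,
        n_cells=n_total,
        class_proportions=tuple(t / n_total for t in totals),
        seed=seed,
    )
    population = simulate(pop_config)
    labels = np.asarray(population.labels, dtype=object)
    rng = np.random.default_rng(seed + 17)
    ref_rows: list[np.ndarray] = []
    query_rows: list[np.ndarray] = []
    for c in range(n_classes):
        rows = np.flatnonzero(labels == f"type_{c}")
        rows = rng.permutation(rows)
        ref_rows.append(rows[: counts_ref[c]])
        query_rows.append(rows[counts_ref[c] : counts_ref[c] + counts_query[c]])
    reference = population.subset_cells(np.sort(np.concatenate(ref_rows)))
    query = population.subset_cells(np.sort(np.concatenate(query_rows)))
    return reference, query
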