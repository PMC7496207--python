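# Methods

This note records the model, the choices made where the design was open,
what the synthetic data does and does not emulate, and the conditions under
which the benchmark numbers are computed.

## Classification model

The classifier is a cascade of a pairing-based rare-class learner and a
bootstrap ensemble of small softmax networks, both operating on a panel of
genes chosen by a dropout-residual score. The README gives the formulas;
here are the contracts and edge rules.

**Feature scoring.** Scores are computed on the reference dataset
restricted to the genes shared with the query; the query contributes only
gene presence. This avoids leaking query expression into training while
still guaranteeing the panel exists in both datasets. The logarithm is
natural by default (configurable; the base rescales both residuals by a
common factor and affects the ranking only through the α mix). The OLS fit
of F on D carries an intercept, so the ΔF₁ residuals sum to zero; ΔF₂ ≥ 0
by Jensen's inequality — both are asserted in the test suite. Ranking ties
break by gene name for determinism. Two degenerate inputs are rejected:
fewer than two genes, and all genes sharing one dropout rate (the line fit
is undefined). If K exceeds the shared-gene count the panel truncates with
a warning. An alternative mode intersects the reference's and query's own
top-K rankings instead of ranking once on the reference; the reference-only
ranking is the default because it uses strictly less query information.

**Few-sample stage.** The 0.5% class-size threshold is inclusive ("does
not exceed"); γ-gates are strict ("greater than"). Self-pairs are included
in the n×n pair training set with label 1 — the n×n count requires them.
The pair regressor keeps LightGBM defaults except the settings listed in
the README; 100 boosting rounds by default (the round count is a free
parameter here). Pair predictions are clipped to [0, 1] at use time, since
a regression objective can overshoot the label range. Pearson correlations
are computed on the raw selected-gene vectors by default (`pair_log1p`
switches to log1p); negative correlations are clamped to zero before
weighting, because the published weighted mean is undefined for
non-positive weight sums, and when every weight of a class vanishes the
unweighted mean of that class's pair predictions is used. Scores exist
only for few-sample classes — the pair test set contains only rare
reference cells, so no other class is scoreable. Equal-score ties above γ
go to the lexicographically smaller class name. With zero or one rare
class the stage disables itself (a single rare class makes every pair
label 1, which no regressor can use) and all cells pass to the ensemble.

**Ensemble stage.** Exactly ten members; each trains on
round(0.3·N) indices drawn uniformly with replacement (round half-up),
seeded as master seed + member index. Resampling is unstratified by
default (`stratified` optional); a resample that collapses to one class is
redrawn with a shifted seed, up to five attempts. The networks are
implemented directly in NumPy — four dense layers with He initialization,
inverted dropout, categorical cross-entropy and Adam (learning rate 1e-3,
50 epochs, batch size 64 by default; all configurable and persisted). At
this size a deep-learning framework adds nothing but weight, and the pure
NumPy path keeps training bit-reproducible from the seed. Member votes of
"unassigned" never count toward a class; a cell needs ≥ 6 of 10 members on
the same class. Two classes cannot both reach 6 votes, so no tie rule is
needed.

**Cascade and metrics.** Cells confidently assigned by the few-sample
stage never reach the ensemble; cells rejected by both stages are
"unassigned", which is a reserved token that reference labels may not use.
The network stage consumes log1p-transformed selected-gene values (raw
counts make a relu/softmax network numerically fragile; the transform is
the field's standard variance stabilization and is configurable). Kappa is
computed over assigned cells only; the assigned rate over all query cells;
with zero assigned cells kappa is NaN and the assigned rate 0. Class
counts a_c and b_c are taken over the classes present among assigned
cells. Self-projection uses stratified, seeded k-fold splits; classes
smaller than the fold count warn rather than error.

## Synthetic data

The generator draws negative-binomial counts (shape θ, default 2) whose
mean is gene- and class-specific: a shared lognormal base profile, a
class-specific lognormal modulation of every gene (log-sd 0.4 — cell types
differ across the whole transcriptome, not only in markers), a disjoint
marker block per class up-shifted by a fold change (default 8), and a
per-cell lognormal library-size factor (log-sd 0.35). Technical dropout
zeroes each entry with probability sigmoid((midpoint − μ)/steepness) in
the class-level gene mean μ: lowly expressed genes drop out more, and the
steepness acts as a temperature, so steepness → 0 with midpoint 0 recovers
pure counting noise. The plate-like defaults (midpoint 1.0, steepness 0.5)
give ≈ 55% zeros; the droplet-like settings used by the rare-class split
(midpoint 3.0, steepness 1.5) give ≈ 77%.

`corrupt_dropout` zeroes exactly ⌊fraction·nnz⌋ non-zero entries chosen
uniformly without replacement (floor, since no rounding rule is canonical)
and never touches zeros, names or labels.

`make_rare_class_split` builds the rare-class study condition: a 5000-cell
reference with the designated type at 0.4%, two further rare types at 0.2%
and 0.3% (several rare types at once, with unequal sizes — two rare
classes of exactly equal size make the same-class pair label an XOR of the
two cells' types, which no greedy tree split can enter), and a 1000-cell
query holding the designated type at 30% and a companion rare type at 40%.
The designated and companion types are subtypes of abundant relatives:
they share the relative's marker block and differ only by a mild lognormal
jitter (log-sd 0.05), and the parent types are absent from the query. This
mirrors the hard real-world regime of projecting a reference rich in one
lineage onto a query dominated by types the reference holds only
marginally: a handful of subtype cells cannot outweigh the parent's prior
in the networks, so without the pairing stage the subtype is confidently
absorbed into the parent, while the pairing stage — trained only within
the rare set — recognizes it.

What the simulator does **not** model: batch effects, ambient RNA,
doublets, continuous differentiation trajectories, and any real tissue's
empirical count distributions. Passing tests therefore demonstrate the
pipeline's mechanics and its qualitative behaviours (sparsity robustness,
rare-class rescue, ensemble stabilization), not performance on any
particular real dataset.

A known property inherited from the pairing design: query cells of types
absent from the pair training set are out-of-distribution for the pair
regressor and can be aliased into a rare class with high confidence —
tree ensembles extrapolate to leaf extremes, so the γ-gate cannot always
reject them. On related types this doubles as a feature (novel types
associate with their nearest rare relative); on unrelated types it costs
accuracy, which bounds the with-module accuracy by the share of such cells
in the query.

## Benchmark conditions

All benchmark experiments live in `enclasc.experiments` and are seeded end
to end; `scripts/acceptance.py` re-runs them and prints the numbers.

* **Self-projection**: 2000 cells × 500 genes, five balanced types,
  plate-like defaults, K = 100, 5-fold stratified cross-validation.
* **Sparsity**: the same dataset with 50% of non-zero entries zeroed
  before self-projection.
* **Rare-class ablation**: the `make_rare_class_split` condition above,
  classified with and without the few-sample stage; reported are the rare
  type's recall and the accuracy among assigned cells.
* **Stabilization**: one 80/20 split of a noisy 1500-cell dataset (weak
  markers, droplet-like dropout); kappa of the voted ensemble versus a
  single network trained on the full reference, across 20 master seeds.
  Problem sizes are kept at this scale so the full suite runs in minutes
  on one CPU.

## Limitations

* The pair regressor's scores are not calibrated probabilities; γ = 0.7
  is a heuristic shared with the softmax gate.
* The few-sample stage requires at least two rare classes of unequal
  composition to form a learnable pair training set.
* No library-size normalization or batch correction is applied anywhere;
  expression values are taken as given, and reference and query are
  assumed comparable in scale.
* Gene matching is exact string equality (optional uppercasing); no
  ortholog or alias resolution.
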