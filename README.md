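# enclasc

Supervised cell-type annotation for single-cell RNA-seq. Given a labelled
reference expression matrix and an unlabelled query, `enclasc` assigns each
query cell a reference cell type — or the reserved label `unassigned` when
no stage of the classifier is confident — using an ensemble design aimed at
two notorious failure modes of reference-based annotation: technical
dropout and rare ("few-sample") cell types.

## Method

Four stages run as a cascade.

**1. Dropout-residual feature selection.** For gene *j* with per-cell
expression *E_ij* over *n* cells, let *D_j* be the dropout rate (fraction
of exact zeros) and

    F(j)  = log(Σ_i E_ij / n + 1)
    F̃₁(j) = a·D_j + b                      (OLS fit of F on D)
    F̃₂(j) = Σ_i log(E_ij + 1) / n

The residuals ΔF₁ = F − F̃₁ (expression above what the gene's dropout rate
predicts) and ΔF₂ = F − F̃₂ (≥ 0 by Jensen's inequality; an entropy-like
dispersion term) combine into the score **G(j) = α·ΔF₁ + (1−α)·ΔF₂** with
α = 0.5. The top *K* = 100 genes by G among those shared by reference and
query are the feature panel.

**2. Few-sample learning.** Cell types holding ≤ 0.5% of reference cells
are paired exhaustively: each ordered pair of rare-class cells is one
training sample with 2×D concatenated features, labelled 1 iff the two
cells share a type (n rare cells → n² pairs). A LightGBM regressor (gbdt,
regression objective, learning rate 0.05) learns this same-type function.
Each query cell *i* is paired with every rare reference cell *j*; the pair
predictions c_ij, clipped to [0, 1], are aggregated per rare class *x* as a
Pearson-weighted mean

    score(x, i) = Σ_j r_ij·c_ij / Σ_j r_ij        (j over class x)

with negative correlations clamped to zero. A query cell whose maximum
score strictly exceeds γ = 0.7 takes that class and skips stage 3.

**3. Voting neural-network ensemble.** Ten multilayer perceptrons
(D → 128 → 64 → 32 → C; relu, softmax, dropout 0.25 and 0.5 after the first
two hidden layers) are each trained on a bootstrap resample of 30% of the
reference, drawn with replacement. A member votes for a class only when its
maximum softmax probability strictly exceeds γ; a cell is assigned only
when more than half of the 10 members agree on the same class.

**4. Evaluation.** Performance is reported as Cohen's kappa over the
assigned cells — kappa = (p_o − p_e)/(1 − p_e), with p_e = Σ_c a_c·b_c / n²
from the per-class true (a_c) and predicted (b_c) counts — and the assigned
rate, the fraction of query cells given a concrete class.

A seeded synthetic-data module (negative-binomial counts, class-specific
profiles and markers, mean-dependent logistic dropout, library-size
variation, an exact sparsity-corruption operator and a rare-class
reference/query split generator) makes the whole pipeline testable without
any downloads.

## Worked example

```python
import enclasc as ec

# a labelled synthetic population: 2000 cells, 500 genes, 5 balanced types
data = ec.simulate(ec.SimulationConfig(seed=0))

# 5-fold self-projection: train on 4 folds, classify the 5th
result = ec.self_project(data, folds=5, config=ec.RunConfig(seed=0))
print(f"mean kappa {result.mean_kappa:.4f}  "
      f"mean assigned rate {result.mean_assigned_rate:.4f}")
```

prints

```
mean kappa 1.0000  mean assigned rate 1.0000
```

i.e. on well-separated synthetic types every held-out cell is assigned and
every assignment agrees with the truth (kappa 1 = perfect chance-corrected
agreement). The same run on data with half of the non-zero entries zeroed
(`ec.corrupt_dropout(data, 0.5, seed=1)`) yields mean kappa 0.996 — the
dropout-residual panel and the voting ensemble barely feel the added
sparsity.

The same workflow is available from the shell:

```sh
enclasc simulate --out sim --seed 3
enclasc train --reference sim/expression.csv --labels sim/labels.csv \
              --query sim/expression.csv --model-dir model --seed 1
enclasc classify --model-dir model --query sim/expression.csv --out pred.csv
enclasc evaluate --truth sim/labels.csv --predictions pred.csv
```

Dense CSV/TSV (either orientation) and MatrixMarket triplets with
gene/barcode sidecars are accepted; predictions are written as
`cell_id,predicted_label` with `unassigned` for rejected cells.

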