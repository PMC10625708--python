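# cellstate

Supervised cell-state classification and marker-gene discovery for
single-cell RNA-seq count matrices.

Annotating cell types in plant scRNA-seq data is hard: the matrices are
high-dimensional and sparse, good marker genes are scarce for many crop
tissues, and manual annotation is poorly reproducible across labs. Given a
labeled cells × genes count matrix — for example a rice root-tip atlas with
six subpopulations (Stele, Cortex, Endodermis, Epidermis, Root hair,
Epidermis NRH) at severe class imbalance — `cellstate` trains a classifier
that predicts the cell state of new cells and, as a by-product, yields a
compact, interpretable panel of marker genes.

## Method

The pipeline, all operating on the log2(count + 1) layer:

1. **Gene scoring.** Each gene *i* gets one importance score from one of
   three scorers:
   - *F-score* (supervised), the multiclass generalization
     `F_i = Σ_c (x̄_i^(c) − x̄_i)² / Σ_c [1/(n_c − 1) Σ_k (x_ki^(c) − x̄_i^(c))²]`,
     between-class spread of class means over pooled within-class variance;
   - *MIC*, the maximal information coefficient between the gene's
     expression and the integer-encoded label: the maximum over all grids
     with `kx·ky ≤ n^0.6` of `I(X;Y)/log min(kx, ky)`, computed from scratch
     with an exact dynamic program over candidate cut points (see
     `docs/methods.md`);
   - *CV²* (unsupervised), the squared coefficient of variation `s²/x̄²`.

   Genes scoring ≤ 0 are dropped; the rest are ranked descending.
2. **Incremental feature selection (IFS).** Nested top-k prefixes of the
   ranking are swept over a size grid; each prefix is scored by stratified
   five-fold cross-validated accuracy for four base learners — RBF SVM
   (Platt-calibrated), random forest, XGBoost, LightGBM — and the best
   (size, learner) pair is selected.
3. **Soft-voting ensemble.** The four learners, fitted on the selected gene
   subset, are combined by a weighted average of their class-probability
   outputs (default weights 1, 1, 1, 1); the predicted state is the argmax.
4. **Evaluation.** Confusion matrix; accuracy; per-class and macro-averaged
   precision, recall, and F1; one-vs-rest ROC with trapezoid AUC.
5. **Marker analysis.** Per-subpopulation mean profiles of the selected
   genes, Pearson correlation between subpopulation profiles, and an
   in-class vs rest-of-cells specificity table with per-class top-k
   shortlists.

A bundled synthetic generator (negative-binomial counts, log-normal baseline
means, planted class-specific markers, Bernoulli dropout, the 3,463-cell
six-class imbalance of a real rice root-tip atlas) makes every stage
testable end to end without downloading data.

## Worked example

```python
from cellstate import (SyntheticSpec, generate, normalize_dataset, stratified_split,
                       rank_genes, run_ifs, fit_ensemble, default_specs,
                       predict, predict_proba, evaluate_predictions)

spec = SyntheticSpec(class_sizes=(40, 80, 60),
                     class_names=("Stele", "Cortex", "Epidermis"),
                     n_genes=300, n_markers_per_class=6, seed=42)
raw, truth = generate(spec)
data = normalize_dataset(raw)
train, test = stratified_split(data, test_fraction=0.3, seed=42)

ranked = rank_genes(train, "fscore")
print(f"{len(ranked)} genes kept; top gene: {ranked.gene_ids[0]} (F = {ranked.scores[0]:.2f})")

curve = run_ifs(train, ranked, grid=(10, 20, 40), folds=5, seed=42)
opt = curve.optimum
print(f"IFS optimum: {opt.size} genes with {opt.family} (CV accuracy {opt.cv_accuracy:.3f})")

model = fit_ensemble(train, ranked.gene_ids[:opt.size], default_specs(42))
report = evaluate_predictions(list(test.labels), list(predict(model, test.matrix)),
                              predict_proba(model, test.matrix), classes=model.class_names)
print(f"test accuracy {report.accuracy:.3f}, macro F1 {report.macro_f1:.3f}")
```

prints

```
300 genes kept; top gene: LOC_Os07g12820 (F = 0.47)
IFS optimum: 40 genes with svm (CV accuracy 0.905)
test accuracy 0.889, macro F1 0.874
```

On this deliberately small example every gene keeps a positive F-score, IFS
picks the largest size on the grid (all 18 planted markers plus hedging
noise genes), and the ensemble classifies ~89% of held-out cells correctly;
larger, stronger-signal runs (below) reach >98%.

The same pipeline is scriptable from a shell — `cellstate simulate | rank |
ifs | train | predict | evaluate | markers | bench` — reading dense CSV or
Matrix Market matrices plus a two-column barcode→label TSV, and writing TSV
and JSON outputs with the resolved configuration saved next to them.

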