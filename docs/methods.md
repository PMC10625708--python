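# Methods

This note documents the models, conventions, and numerical choices behind
`cellstate`, in the order the pipeline uses them.

## Data model and normalization

An `ExpressionMatrix` is a dense cells × genes array with unique cell and
gene IDs and an explicit layer tag: `raw_counts` (non-negative integers) or
`log2p1`. Normalization replaces each count v by log2(v + 1); it is the only
transformation applied, and re-normalizing is a hard error so a matrix can
never be transformed twice. All scorers, learners, and marker analyses
operate on the `log2p1` layer.

The stratified 70/30 split draws, per class, `round(n_c × test_fraction)`
test cells (half-away-from-zero rounding), repaired into `[1, n_c − 1]` so
both splits retain every class — necessary because the smallest class in
the target composition has only 121 cells and per-class metrics must be
computable on both sides. The split is seeded; classes with a single cell
are rejected.

## Gene scorers

**Multiclass F-score.** `F_i = Σ_c (x̄_i^(c) − x̄_i)² / Σ_c [1/(n_c − 1)
Σ_k (x_ki^(c) − x̄_i^(c))²]`, the sum-over-classes generalization that
reduces exactly to the classical two-class F-score. Conventions: a gene
that is constant everywhere (0/0) scores 0 and is filtered; a gene with
zero pooled within-class variance but unequal class means scores +inf and
ranks first — it is a perfect discriminator, and capping it would be
arbitrary. Any class of size 1 is an error (the n_c − 1 denominator).

**CV².** Sample variance (n − 1 denominator) over squared mean, label-free.
Genes with mean 0 score 0. Computed on the normalized layer like the other
scorers, so all three rankings are comparable inputs to the same IFS stage.

**MIC.** Implemented from scratch (see below).

**Filtering and ranking.** Scores ≤ 0 are dropped ("non-informative genes
must not survive"); the rest sort by descending score with ties broken by
gene ID ascending, so rankings are deterministic across runs and platforms.

## MIC

For vectors x, y of length n the search considers every grid shape
(kx, ky), kx, ky ≥ 2, kx·ky ≤ B(n) = n^alpha (default alpha = 0.6; n ≥ 11
so that B ≥ 4). For one orientation the y-axis is equipartitioned into ky
bins and the x-axis partition is optimized; both orientations are computed
and the characteristic matrix is symmetrized by taking the larger value.
Each entry is `I_max / log min(kx, ky)` (natural logs; the ratio is
base-invariant) and MIC is the maximum entry, clipped to [0, 1].

Numerical/convention details:

- *Ties.* Grid lines may only fall between distinct values, so tied
  observations always share a bin. Equipartition targets `round(j·n/k)` and
  snaps each boundary rightward to the nearest legal cut; bins can
  therefore be unequal (or fewer than k) under heavy ties, e.g. on an
  integer-coded label axis.
- *Dynamic program.* For a fixed row binning, a column spanning sorted
  positions (s, t] contributes `Σ_r c_r log c_r − T log T`; summed over
  columns this equals `−n·H(rows|cols)`, making the objective additive, so
  the DP over candidate cut positions is exact: `G[t, l] = max_s G[s, l−1]
  + h(s, t)` and `I(l) = H(rows) + G[n, l]/n`, with a running max over
  l ≤ kx because grids may leave bins empty. Exactness is verified against
  exhaustive enumeration of all cut placements on small inputs.
- *Superclumps.* When candidate cuts exceed `c·kx` (default c = 15) they are
  thinned to an equispaced subset — the standard accuracy/speed compromise.
  On count data the candidate set is naturally small (few distinct values),
  so gene-versus-label scoring is exact in practice.
- *Categorical labels.* `mic_scores` encodes classes as integers 0..C−1 in
  `class_names` order; bins on that axis are contiguous groupings of
  classes. This is a documented convention: MIC is grid-based and needs a
  numeric axis, and any class is isolable with at most 3 label bins.

MIC is invariant under strictly monotone transforms of either variable — in
particular log2(count+1) — which the tests exercise directly.

## Incremental feature selection

Default size grid {10, 20, …, 500} ∪ {1000, 2000, 5000, 7000, 14000,
20000}, clipped to the ranked-list length and fully configurable. Folds are
stratified, shuffled, and seeded. Learner hyperparameters are library
defaults plus a seed and single-threaded execution. The optimum is the
argmax of CV accuracy with ties resolved to the smaller size, then the
canonical learner order svm < random_forest < xgboost < lightgbm (prefer
cheaper models when accuracy is equal).

The ranking is computed once on the training split, outside the CV loop.
This is the classical IFS formulation; it mildly flatters the *curve*
because held-out fold cells contributed to the ranking, which is why the
final numbers are always taken from a test split the ranking never saw.

## Base learners and the voting ensemble

- svm: RBF-kernel SVC wrapped in `CalibratedClassifierCV(ensemble=False)`
  (Platt calibration on internal five-fold splits) so it emits class
  probabilities;
- random_forest: 100 trees;
- xgboost / lightgbm: 100 boosting rounds, histogram method.

Voting is *soft*: the ensemble probability is the weighted mean of member
probability rows (renormalized to sum 1) and the prediction is the argmax,
ties resolving to the earliest class in `class_names`. Soft voting is
chosen over hard majority because downstream ROC analysis needs continuous
scores. Consequences tested as algebraic identities: scaling all weights is
a no-op; one nonzero weight reproduces that member exactly. Default weights
are uniform (1, 1, 1, 1). Saved models are joblib archives carrying the
members, specs, weights, gene subset, class names, and a format version;
loading any other payload is an error.

## Evaluation

Per-class TP/FN/FP/TN come from one-vs-rest marginalization of the C × C
confusion matrix; accuracy = trace/total. Headline precision/recall/F1 are
macro averages (unweighted over classes): on an imbalanced task micro
averaging would collapse recall onto accuracy and hide minority-class
failures. F1 is per-class F1 averaged (macro-F1) by default; forming F1
from the macro precision and recall is available as `f1_mode="from_macro"`.
Ratios that are 0/0 are reported as 0 and flagged in
`MetricsReport.undefined` rather than silently dropped. ROC is a one-vs-rest
threshold sweep with trapezoid AUC; a class absent from the evaluated cells
has undefined AUC (NaN, flagged).

## Marker analysis

Subpopulation profiles are arithmetic means per class on the normalized
layer. Profile correlation is plain Pearson between class profiles across
the gene panel; constant profiles are flagged NaN. Specificity compares the
in-class mean with the mean over all other cells — a mean rather than a sum
so classes of very different sizes are comparable; the sum is exposed as an
option. The ratio uses epsilon = 1e-9 in the denominator to avoid division
by zero for genes silent outside their class. Per-class ranks (ties by gene
ID) support top-k shortlists.

## Synthetic data

`SyntheticSpec` defaults are the benchmark study conditions: six classes at
121/1000/1000/1000/131/211 cells, 2,000 genes, 10 markers per class, fold
change 16, NB dispersion 0.5 (variance = mu + mu²/r, so r → inf is the
Poisson limit), dropout 0.3, log-normal baseline means with
(mu, sigma) = (−0.7, 1.0) on the log scale — a median baseline of ~0.5
counts per cell, typical of UMI data. Gene IDs are LOC_Os-style strings and
barcodes are 14-mer nucleotide strings so I/O paths are tested against
realistic identifiers.

What the generator does *not* model: batch effects, doublets, library-size
variation between cells, gene-gene correlation beyond the class structure,
and trajectory/continuous states. Passing the benchmark therefore shows
that the pipeline recovers planted discrete class signal under imbalance,
over-dispersion, and dropout — not that it is robust to batch confounding
or continuous differentiation, which real atlases exhibit.

`benchmark_run` wires the whole pipeline (generate → normalize → 70/30
split → rank → IFS → ensemble → test metrics) and reports planted-marker
recovery per scorer alongside the classification metrics.

## Problem sizes and runtime choices

The benchmark and acceptance script use the full 3,463-cell × 2,000-gene
composition with an IFS grid of {40, 80, 120} — three points bracketing the
60 planted markers — and five-fold CV; one run takes well under a minute
for ranking (MIC ≈ 7 s for 2,000 genes) and a few tens of seconds for the
learner sweep. Unit tests use smaller compositions (tens to hundreds of
cells) chosen so every contract stays exercised with sub-second fixtures.

## Known limitations

- The F-score +inf convention deviates from "scores are finite" purism;
  downstream ranking handles it, but exports serialize it as `inf`.
- MIC on very long, mostly-distinct vectors falls back to the superclump
  approximation (as in the reference algorithm); only small-n exactness is
  guaranteed and tested.
- IFS does not re-rank inside folds; see above for the bias discussion.
- LightGBM emits a harmless feature-name warning when fitted on plain
  arrays (upstream behavior); the test configuration filters it.
- The CLI `rank`/`ifs`/`train` commands operate on the dataset they are
  given; splitting into train/test is the caller's responsibility (or use
  `bench`, which performs the split internally).
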