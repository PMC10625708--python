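"""Synthetic labeled scRNA-seq counts with planted class-specific markers.

The generator emulates the data model the pipeline assumes: a sparse,
severely imbalanced cells x genes count matrix in which each cell state
over-expresses a known set of marker genes.  Counts are negative binomial —
gene-specific mean, common dispersion — with independent Bernoulli dropout
to zero, the standard zero-inflated over-dispersed model for UMI counts.
Baseline gene means are log-normal; a marker gene's mean is multiplied by
``marker_fold_change`` in the cells of its own class only.

The default class sizes (121 / 1000 / 1000 / 1000 / 131 / 211 cells across
six root-tip subpopulations, 3,463 cells in total) reproduce the class
composition of the rice root-tip atlas this pipeline targets, so every test
sees the same imbalance structure as the real task.

Dispersion uses the "size" parameterization: variance = mu + mu^2 / r, so
``nb_dispersion -> inf`` recovers Poisson counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, LabeledDataset, Layer

DEFAULT_CLASS_NAMES = (
    "Root_hair",
    "Epidermis",
    "Stele",
    "Cortex",
    "Epidermis_NRH",
    "Endodermis",
)
DEFAULT_CLASS_SIZES = (121, 1000, 1000, 1000, 131, 211)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the defaults are the benchmark study conditions."""

    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    n_genes: int = 2000
    n_markers_per_class: int = 10
    marker_fold_change: float = 16.0
    baseline_mean_log: tuple[float, float] = (-0.7, 1.0)  # lognormal (mu, sigma)
    nb_dispersion: float = 0.5
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_sizes) != len(self.class_names):
            raise ValueError("class_sizes: length differs from class_names")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class_sizes: every class needs at least one cell")
        if len(self.class_names) < 2:
            raise ValueError("class_names: need at least 2 classes")
        if self.n_genes < 1:
            raise ValueError("n_genes: must be positive")
        if self.n_markers_per_class * len(self.class_names) > self.n_genes:
            raise ValueError("n_markers_per_class: total markers exceed n_genes")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change: must be > 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion: must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate: must be in [0, 1)")
        if self.baseline_mean_log[1] < 0:
            raise ValueError("baseline_mean_log: sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: marker IDs per class, baseline means, and the spec."""

    markers: dict[str, tuple[str, ...]]
    baseline_means: np.ndarray
    spec: SyntheticSpec

    @property
    def all_markers(self) -> frozenset[str]:
        return frozenset(g for ms in self.markers.values() for g in ms)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "markers": {c: list(ms) for c, ms in self.markers.items()},
            "baseline_means": self.baseline_means.tolist(),
            "spec": {
                **{k: v for k, v in asdict(self.spec).items()},
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _gene_ids(n: int) -> tuple[str, ...]:
    # LOC_Os-style IDs so downstream I/O sees realistic identifiers
    return tuple(f"LOC_Os{(i % 12) + 1:02d}g{10000 + i * 10:05d}" for i in range(n))


def _barcodes(n: int, rng: np.random.Generator) -> tuple[str, ...]:
    alphabet = np.array(list("ACGT"))
    codes = rng.integers(0, 4, size=(n, 14))
    seen: set[str] = set()
    out: list[str] = []
    for row in codes:
        bc = "".join(alphabet[row]) + "-1"
        while bc in seen:  # vanishingly rare at 4^14 combinations
            bc = "".join(alphabet[rng.integers(0, 4, size=14)]) + "-1"
        seen.add(bc)
        out.append(bc)
    return tuple(out)


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Draw a raw-count :class:`LabeledDataset` plus its ground-truth manifest.

    Deterministic per ``spec.seed``: the same spec yields byte-identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = sum(spec.class_sizes)
    n_classes = len(spec.class_names)
    gene_ids = _gene_ids(spec.n_genes)
    mu_log, sigma_log = spec.baseline_mean_log
    baseline = rng.lognormal(mu_log, sigma_log, size=spec.n_genes)

    marker_idx = rng.choice(
        spec.n_genes, size=spec.n_markers_per_class * n_classes, replace=False
    )
    markers = {
        cls: tuple(
            gene_ids[g]
            for g in sorted(
                marker_idx[ci * spec.n_markers_per_class : (ci + 1) * spec.n_markers_per_class]
            )
        )
        for ci, cls in enumerate(spec.class_names)
    }

    labels = np.repeat(np.arange(n_classes), spec.class_sizes)
    mean = np.tile(baseline, (n_cells, 1))
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    for ci, cls in enumerate(spec.class_names):
        cols = [gene_pos[g] for g in markers[cls]]
        mean[np.ix_(labels == ci, cols)] *= spec.marker_fold_change

    r = spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.float64)
    if spec.dropout_rate > 0:
        counts[rng.random(size=counts.shape) < spec.dropout_rate] = 0.0

    matrix = ExpressionMatrix(
        _barcodes(n_cells, rng), gene_ids, counts, Layer.RAW_COUNTS
    )
    dataset = LabeledDataset(
        matrix, tuple(spec.class_names[c] for c in labels), spec.class_names
    )
    return dataset, GroundTruth(markers, baseline, spec)


# ---------------------------------------------------------------------------
# end-to-end benchmark harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """How the benchmark drives the pipeline (not the data-generating model)."""

    scorers: tuple[str, ...] = ("fscore", "mic")
    selection_scorer: str = "mic"
    recovery_top_k: int = 120
    grid: tuple[int, ...] = (40, 80, 120)
    folds: int = 5
    test_fraction: float = 0.3
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0


@dataclass
class BenchmarkReport:
    """Marker recovery per scorer plus end-to-end test-set performance."""

    spec: SyntheticSpec
    config: PipelineConfig
    recovery: dict[str, float]  # scorer -> fraction of planted markers in top-k
    ifs_optimum: tuple[int, str, float]  # (size, learner, cv accuracy)
    member_test_accuracy: dict[str, float]
    ensemble_metrics: "object"  # MetricsReport

    def to_dict(self) -> dict:
        m = self.ensemble_metrics
        return {
            "seed": self.spec.seed,
            "pipeline_seed": self.config.seed,
            "recovery_top_k": self.config.recovery_top_k,
            "recovery": self.recovery,
            "ifs_optimum": {
                "size": self.ifs_optimum[0],
                "learner": self.ifs_optimum[1],
                "cv_accuracy": self.ifs_optimum[2],
            },
            "member_test_accuracy": self.member_test_accuracy,
            "ensemble": m.to_dict(),
        }


def marker_recovery(ranked_genes: Sequence[str], truth: GroundTruth, top_k: int) -> float:
    """Fraction of planted markers appearing in the top-k of a ranking."""
    top = set(ranked_genes[:top_k])
    planted = truth.all_markers
    return len(top & planted) / len(planted)


def benchmark_run(
    spec: SyntheticSpec, config: PipelineConfig = PipelineConfig()
) -> BenchmarkReport:
    """Generate -> normalize -> split -> rank -> IFS -> ensemble -> evaluate."""
    from .evaluation import evaluate_predictions
    from .ifs import run_ifs
    from .io import normalize_dataset, stratified_split
    from .models import FAMILIES, default_specs, fit_ensemble, predict, predict_proba
    from .ranking import rank_genes

    dataset, truth = generate(spec)
    dataset = normalize_dataset(dataset)
    train, test = stratified_split(dataset, config.test_fraction, config.seed)

    rankings = {m: rank_genes(train, m) for m in config.scorers}
    recovery = {
        m: marker_recovery(r.gene_ids, truth, config.recovery_top_k)
        for m, r in rankings.items()
    }

    ranked = rankings[config.selection_scorer]
    curve = run_ifs(
        train,
        ranked,
        grid=config.grid,
        folds=config.folds,
        seed=config.seed,
    )
    opt = curve.optimum
    subset = ranked.gene_ids[: opt.size]

    model = fit_ensemble(train, subset, default_specs(config.seed), config.weights)
    y_true = list(test.labels)
    member_acc = {}
    X_test = model._restrict(test.matrix)
    y_codes = test.label_codes()
    for fam, member in zip(FAMILIES, model.members):
        member_acc[fam] = float(np.mean(member.predict(X_test) == y_codes))
    proba = predict_proba(model, test.matrix)
    pred = predict(model, test.matrix)
    report = evaluate_predictions(y_true, list(pred), proba, classes=model.class_names)

    return BenchmarkReport(
        spec=spec,
        config=config,
        recovery=recovery,
        ifs_optimum=(opt.size, opt.family, opt.cv_accuracy),
        member_test_accuracy=member_acc,
        ensemble_metrics=report,
    )
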