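"""Incremental feature selection (IFS).

Given a fixed ranking of genes, IFS sweeps nested top-k prefixes, scores each
prefix for every base learner by stratified k-fold cross-validated accuracy,
and selects the (size, learner) with the best accuracy.  Ties go to the
smaller subset, then to the canonical learner order
svm < random_forest < xgboost < lightgbm.

The ranking is computed once on the training split and held fixed across
folds.  Ranking outside the CV loop slightly flatters the curve (the fold
held out for scoring also contributed to the ranking); the end-of-pipeline
numbers that matter are computed on a test split the ranking never saw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import LabeledDataset, Layer
from .models import FAMILIES, BaseLearnerSpec, build_estimator
from .ranking import RankedGeneList

DEFAULT_SIZES = tuple(range(10, 501, 10)) + (1000, 2000, 5000, 7000, 14000, 20000)


@dataclass(frozen=True)
class IFSEntry:
    size: int
    family: str
    cv_accuracy: float


@dataclass(frozen=True)
class IFSCurve:
    """CV accuracy over (subset size, learner), plus the selected optimum."""

    method: str
    entries: tuple[IFSEntry, ...]
    optimum: IFSEntry

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "method": self.method,
                "learner": [e.family for e in self.entries],
                "size": [e.size for e in self.entries],
                "cv_accuracy": [e.cv_accuracy for e in self.entries],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IFSCurve":
        df = pd.read_csv(path, sep="\t")
        entries = tuple(
            IFSEntry(int(r.size), str(r.learner), float(r.cv_accuracy))
            for r in df.itertuples()
        )
        return cls(str(df["method"].iloc[0]), entries, select_optimum(entries))


def make_grid(n_ranked: int, sizes: Sequence[int] | None = None) -> tuple[int, ...]:
    """Subset sizes to sweep: the (configurable) size set clipped to [1, n_ranked]."""
    if n_ranked < 1:
        raise ValueError("n_ranked must be >= 1")
    candidate = DEFAULT_SIZES if sizes is None else tuple(sizes)
    grid = tuple(sorted({int(s) for s in candidate if 1 <= s <= n_ranked}))
    if not grid:
        raise ValueError(f"grid is empty after clipping to [1, {n_ranked}]")
    return grid


def make_folds(
    labels: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds; every cell appears in exactly one held-out set."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(labels), 1)), labels))


def cv_accuracy(
    train: LabeledDataset,
    ranked: RankedGeneList,
    size: int,
    spec: BaseLearnerSpec,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy over stratified folds using the top-``size`` genes."""
    if train.matrix.layer != Layer.LOG2P1:
        raise ValueError("cv_accuracy expects the normalized (log2p1) layer")
    if size > len(ranked):
        raise ValueError(f"size {size} exceeds ranked list length {len(ranked)}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    sizes = train.class_sizes()
    small = [c for c, n in sizes.items() if n < folds]
    if small:
        raise ValueError(f"classes smaller than {folds} folds: {small}")
    idx = train.matrix.gene_index(ranked.gene_ids[:size])
    X = train.matrix.values[:, idx]
    y = train.label_codes()
    accs = []
    for tr, te in make_folds(y, folds, seed):
        est = build_estimator(spec)
        est.fit(X[tr], y[tr])
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def select_optimum(entries: Sequence[IFSEntry]) -> IFSEntry:
    """Argmax accuracy; ties -> smallest size, then canonical learner order."""
    return min(
        entries,
        key=lambda e: (-e.cv_accuracy, e.size, FAMILIES.index(e.family)),
    )


def run_ifs(
    train: LabeledDataset,
    ranked: RankedGeneList,
    specs: Sequence[BaseLearnerSpec] | None = None,
    grid: Sequence[int] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> IFSCurve:
    """Cross-validate every (size, learner) pair and select the optimum."""
    from .models import default_specs

    specs = tuple(specs) if specs is not None else default_specs(seed)
    sizes = make_grid(len(ranked), grid)
    entries = []
    for spec in specs:
        for size in sizes:
            acc = cv_accuracy(train, ranked, size, spec, folds=folds, seed=seed)
            entries.append(IFSEntry(size, spec.family, acc))
    entries = tuple(entries)
    return IFSCurve(ranked.method, entries, select_optimum(entries))
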