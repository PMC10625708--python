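"""Per-gene importance scoring and ranking.

Three scorers, all producing one non-negative score per gene on the
log2(count+1) layer:

* ``fscore`` — supervised: between-class spread of the gene's class means
  over its pooled within-class variance, summed over classes (the standard
  multiclass generalization, which reduces to the textbook two-class
  F-score);
* ``cv2`` — unsupervised variability: sample variance over squared mean;
* ``mic`` — dependence on the label, delegated to :mod:`cellstate.mic`.

Genes scoring <= 0 are uninformative by construction and are dropped before
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LabeledDataset, ExpressionMatrix, Layer

METHODS = ("fscore", "cv2", "mic")


@dataclass(frozen=True)
class GeneScoreTable:
    """One importance score per gene for a single scoring method."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        scores = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", scores)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(scores) != len(self.gene_ids):
            raise ValueError("scores not aligned with gene_ids")
        if np.any(np.isnan(scores)):
            raise ValueError("NaN scores")


@dataclass(frozen=True)
class RankedGeneList:
    """Genes with strictly positive scores, in deterministic descending order.

    Ties are broken by gene ID, lexicographically ascending.
    """

    gene_ids: tuple[str, ...]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        scores = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", scores)
        if np.any(scores <= 0):
            raise ValueError("ranked list contains non-positive scores")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores not non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> tuple[str, ...]:
        return self.gene_ids[:k]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "score": self.scores,
                "rank": np.arange(1, len(self.gene_ids) + 1),
                "method": self.method,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["gene_id"]), df["score"].to_numpy(), str(df["method"].iloc[0]))


def _require_normalized(m: ExpressionMatrix, op: str) -> None:
    if m.layer != Layer.LOG2P1:
        raise ValueError(f"{op} expects the normalized (log2p1) layer; got {m.layer.value}")


def fscore_scores(d: LabeledDataset) -> GeneScoreTable:
    """Multiclass F-score per gene.

    For gene i with overall mean m_i, class means m_i^c over classes c of
    size n_c:

        F_i = sum_c (m_i^c - m_i)^2
              / sum_c [ 1/(n_c - 1) * sum_k (x_ki^c - m_i^c)^2 ]

    A gene that is constant everywhere has 0/0, which scores 0 (and is later
    filtered).  A gene whose classes are internally constant but have unequal
    means scores +inf — a perfect discriminator.
    """
    _require_normalized(d.matrix, "fscore_scores")
    X = d.matrix.values
    codes = d.label_codes()
    sizes = np.bincount(codes, minlength=d.n_classes)
    if np.any(sizes < 2):
        bad = d.class_names[int(np.argmin(sizes))]
        raise ValueError(f"class {bad!r} has a single cell; F-score needs n_c >= 2")
    overall = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for ci in range(d.n_classes):
        Xc = X[codes == ci]
        mc = Xc.mean(axis=0)
        num += (mc - overall) ** 2
        den += ((Xc - mc) ** 2).sum(axis=0) / (len(Xc) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(num == 0) & (den == 0)] = 0.0
    return GeneScoreTable(d.matrix.gene_ids, scores, "fscore")


def cv2_scores(m: ExpressionMatrix) -> GeneScoreTable:
    """Squared coefficient of variation per gene: s^2 / mean^2 (label-free).

    Uses the sample variance (n - 1 denominator); genes with mean 0 score 0.
    """
    _require_normalized(m, "cv2_scores")
    if m.n_cells < 2:
        raise ValueError("cv2_scores needs at least 2 cells")
    mean = m.values.mean(axis=0)
    var = m.values.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = var / mean**2
    scores[mean == 0] = 0.0
    return GeneScoreTable(m.gene_ids, scores, "cv2")


def filter_and_rank(t: GeneScoreTable) -> RankedGeneList:
    """Drop genes with score <= 0, sort descending (ties: gene ID ascending)."""
    keep = np.flatnonzero(t.scores > 0)
    if len(keep) == 0:
        raise ValueError("no gene has a positive score; nothing to rank")
    genes = np.asarray(t.gene_ids, dtype=object)[keep]
    scores = t.scores[keep]
    order = sorted(range(len(keep)), key=lambda i: (-scores[i], genes[i]))
    return RankedGeneList(tuple(genes[order]), scores[order], t.method)


def score_genes(d: LabeledDataset, method: str, mic_params=None) -> GeneScoreTable:
    """Dispatch to one of the three scorers by name."""
    if method == "fscore":
        return fscore_scores(d)
    if method == "cv2":
        return cv2_scores(d.matrix)
    if method == "mic":
        from .mic import DEFAULT_PARAMS, mic_scores

        return mic_scores(d, mic_params or DEFAULT_PARAMS)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def rank_genes(d: LabeledDataset, method: str, mic_params=None) -> RankedGeneList:
    """Score, filter, and rank in one call."""
    return filter_and_rank(score_genes(d, method, mic_params))
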