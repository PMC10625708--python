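"""Post-hoc marker-gene analysis on a chosen gene subset.

Three views of a marker set on the normalized (log2(count+1)) layer:

* per-subpopulation mean expression profiles;
* Pearson correlation between subpopulation profiles across the marker genes
  (well-separated cell states should correlate weakly with one another);
* in-class vs rest-of-cells specificity: for each (gene, class), the mean in
  the class against the mean over all other cells, and their ratio.  The
  rest-of-cells aggregate is a mean by default, so classes of very different
  sizes stay comparable; the sum is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LabeledDataset, Layer

EPSILON = 1e-9  # guards the specificity ratio against an all-zero rest mean


@dataclass(frozen=True)
class SubpopulationProfile:
    """classes x genes mean expression plus per-class cell counts."""

    means: pd.DataFrame  # index = classes, columns = genes
    n_cells: dict[str, int]


def _check_normalized(d: LabeledDataset, op: str) -> None:
    if d.matrix.layer != Layer.LOG2P1:
        raise ValueError(f"{op} expects the normalized (log2p1) layer")


def subpopulation_profiles(d: LabeledDataset, genes: Sequence[str]) -> SubpopulationProfile:
    """Arithmetic mean expression of each gene within each subpopulation."""
    _check_normalized(d, "subpopulation_profiles")
    idx = d.matrix.gene_index(genes)
    X = d.matrix.values[:, idx]
    codes = d.label_codes()
    rows = [X[codes == ci].mean(axis=0) for ci in range(d.n_classes)]
    means = pd.DataFrame(rows, index=list(d.class_names), columns=list(genes))
    return SubpopulationProfile(means, d.class_sizes())


def profile_correlation(p: SubpopulationProfile) -> pd.DataFrame:
    """Pearson correlation between subpopulation profiles (classes x classes).

    Constant profiles have undefined correlation; their entries are NaN.
    """
    M = p.means.to_numpy()
    if M.shape[1] < 2:
        raise ValueError("profile correlation needs at least 2 genes")
    sd = M.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(M)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=p.means.index, columns=p.means.index)


def specificity_table(
    d: LabeledDataset,
    genes: Sequence[str],
    rest: str = "mean",
    epsilon: float = EPSILON,
) -> pd.DataFrame:
    """In-class vs rest expression per (gene, class).

    Returns a long-form table with columns ``gene``, ``class``, ``in_mean``,
    ``rest_<agg>``, ``ratio`` (= in_mean / (rest_mean + epsilon)) and
    ``rank`` (1..G within each class, by descending ratio, ties by gene ID).
    """
    _check_normalized(d, "specificity_table")
    if rest not in ("mean", "sum"):
        raise ValueError(f"rest must be 'mean' or 'sum', got {rest!r}")
    idx = d.matrix.gene_index(genes)
    X = d.matrix.values[:, idx]
    codes = d.label_codes()
    records = []
    for ci, cls in enumerate(d.class_names):
        inside = codes == ci
        in_mean = X[inside].mean(axis=0)
        rest_mean = X[~inside].mean(axis=0)
        rest_val = rest_mean if rest == "mean" else X[~inside].sum(axis=0)
        ratio = in_mean / (rest_mean + epsilon)
        for g, im, rv, r in zip(genes, in_mean, rest_val, ratio):
            records.append({"gene": g, "class": cls, "in_mean": im, f"rest_{rest}": rv, "ratio": r})
    df = pd.DataFrame.from_records(records)
    df = df.sort_values(
        ["class", "ratio", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    df["rank"] = df.groupby("class").cumcount() + 1
    return df.reset_index(drop=True)


def top_markers(table: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """The k most class-specific genes per class (mirrors a top-20 shortlist)."""
    return (
        table[table["rank"] <= k]
        .sort_values(["class", "rank"])
        .reset_index(drop=True)
    )


def write_profiles(p: SubpopulationProfile, path: str | Path) -> None:
    p.means.to_csv(path, sep="\t", index_label="class")


def write_correlation(corr: pd.DataFrame, path: str | Path) -> None:
    corr.to_csv(path, sep="\t", index_label="class")


def write_marker_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
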