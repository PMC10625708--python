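"""Maximal information coefficient (MIC), implemented from scratch.

MIC asks: over all two-dimensional grids whose resolution ``kx * ky`` stays
below a budget ``B(n) = n**alpha``, how much normalized mutual information
can a grid extract from the scatter of two variables?  For each grid shape
one axis is equipartitioned and the other is optimized by dynamic
programming over candidate cut points; both orientations are tried.  Each
entry of the resulting characteristic matrix is ``I_max / log(min(kx, ky))``
and MIC is the largest entry, a number in [0, 1] that equals 1 for any
noiseless functional relationship and 0 for a constant.

Grid lines can only fall *between* distinct values, so tied observations are
never split across bins.  When the number of candidate cut points exceeds
``c * k`` they are thinned to an equispaced subset ("superclumps"), the usual
speed/accuracy compromise; with the default ``c = 15`` the search is exact on
small inputs, which is what the brute-force oracle tests exploit.

Internally entropies use natural logarithms; the normalization ratio is
base-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MICParams:
    """Search-budget parameters.

    alpha
        Grid budget exponent: shapes satisfy ``kx * ky <= n**alpha``.
    c
        Candidate-cut multiplier: the DP considers at most ``c * k`` cut
        positions when optimizing a ``k``-bin axis.
    """

    alpha: float = 0.6
    c: int = 15

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.c < 1:
            raise ValueError(f"c must be a positive integer, got {self.c}")

    def budget(self, n: int) -> float:
        return float(n) ** self.alpha


DEFAULT_PARAMS = MICParams()


def _xlogx(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a * np.log(np.where(a > 0, a, 1.0))


def mutual_information(joint_counts) -> float:
    """Mutual information (in nats) of a joint count table.

    ``I = sum p(x,y) * log(p(x,y) / (p(x) p(y)))`` with ``0 * log 0 := 0``;
    algebraically identical to ``H(X) - H(X|Y)``.
    """
    a = np.asarray(joint_counts, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("joint_counts must be a 2-D table")
    if np.any(a < 0):
        raise ValueError("joint_counts contains a negative cell")
    if not np.array_equal(a, np.floor(a)):
        raise ValueError("joint_counts must be integers")
    n = a.sum()
    if n < 1:
        raise ValueError("total count must be >= 1")
    p = a / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.where(mask, p / np.where(mask, px * py, 1.0), 1.0)
    return float(max(np.sum(p[mask] * np.log(ratio[mask])), 0.0))


# ---------------------------------------------------------------------------
# grid machinery
# ---------------------------------------------------------------------------


def _legal_cuts(v_sorted: np.ndarray) -> np.ndarray:
    """Positions where a cut does not split tied values, plus the end ``n``."""
    n = len(v_sorted)
    change = np.flatnonzero(v_sorted[1:] != v_sorted[:-1]) + 1
    return np.append(change, n)


def _equipartition_edges(legal: np.ndarray, n: int, k: int) -> tuple[int, ...]:
    """Interior bin edges for a ~balanced k-bin split, snapped right off ties."""
    edges: list[int] = []
    prev = 0
    for j in range(1, k):
        t = int(round(j * n / k))
        if t <= prev:
            t = prev + 1
        t = int(legal[np.searchsorted(legal, t)])
        if t >= n:
            break
        edges.append(t)
        prev = t
    return tuple(edges)


def _rows_from_edges(order: np.ndarray, edges: tuple[int, ...], n: int) -> np.ndarray:
    """Bin id per *original* point index, given sorted-order bin edges."""
    row = np.empty(n, dtype=np.int64)
    starts = (0,) + edges
    ends = edges + (n,)
    for r, (a, b) in enumerate(zip(starts, ends)):
        row[order[a:b]] = r
    return row


def _thin_bounds(bounds: np.ndarray, n: int, cap: int) -> np.ndarray:
    """Keep at most ``cap`` candidate bin-end positions, nearest to equispaced."""
    if len(bounds) <= cap:
        return bounds
    targets = np.round(np.arange(1, cap + 1) * n / cap)
    pos = np.searchsorted(bounds, targets)
    pos = np.clip(pos, 0, len(bounds) - 1)
    left = bounds[np.maximum(pos - 1, 0)]
    right = bounds[pos]
    picked = np.where(np.abs(targets - left) <= np.abs(right - targets), left, right)
    picked = np.unique(picked)
    if picked[-1] != n:
        picked = np.append(picked, n)
    return picked.astype(np.int64)


def _optimize_free_axis(
    row_seq: np.ndarray, legal: np.ndarray, n: int, n_rows: int, kmax: int, cap: int
) -> np.ndarray:
    """Best mutual information using at most ``l`` free-axis bins, l = 0..kmax.

    ``row_seq`` holds the fixed-axis bin id of each point in free-axis sorted
    order; ``legal`` the candidate bin-end positions.  The dynamic program is
    additive: for a column spanning points (s, t] with per-row counts ``c_r``
    and total ``T``, its contribution is ``sum_r c_r log c_r - T log T``, and
    the sum over columns equals ``-n * H(rows | columns)``, so
    ``I = H(rows) + best / n``.
    """
    out = np.zeros(kmax + 1)
    bounds = _thin_bounds(legal, n, cap)
    m = len(bounds)
    if m < 2:
        return out  # a single bin carries no information
    b = np.concatenate([[0], bounds])
    # per-column row counts between consecutive candidate boundaries
    seg_of_point = np.repeat(np.arange(m), np.diff(b))
    counts = np.bincount(seg_of_point * n_rows + row_seq, minlength=m * n_rows)
    counts = counts.reshape(m, n_rows)
    cum = np.vstack([np.zeros((1, n_rows)), np.cumsum(counts, axis=0)])  # (m+1, R)
    diff = cum[None, :, :] - cum[:, None, :]  # [i, j] = counts in (b_i, b_j]
    tot = (b[None, :] - b[:, None]).astype(np.float64)
    h = _xlogx(diff).sum(axis=-1) - _xlogx(tot)
    h[np.tril_indices(m + 1)] = -np.inf  # only i < j spans are columns
    marginal = cum[-1]
    h_rows = math.log(n) - float(_xlogx(marginal).sum()) / n
    best = np.full(kmax + 1, -np.inf)
    G = h[0].copy()  # exactly one column ending at each boundary
    best[1] = G[-1]
    for l in range(2, min(kmax, m) + 1):
        G = (G[:, None] + h).max(axis=0)
        best[l] = G[-1]
    with np.errstate(invalid="ignore"):
        scores = h_rows + best / n
    scores[0] = 0.0
    scores[1] = 0.0  # one bin: I is exactly 0 by definition
    np.maximum.accumulate(scores, out=out[: len(scores)])
    if kmax >= len(scores):
        out[len(scores) :] = out[len(scores) - 1]
    return np.maximum(out, 0.0)


def _orientation_scores(
    free: np.ndarray,
    fixed: np.ndarray,
    order_free: np.ndarray,
    order_fixed: np.ndarray,
    B: float,
    c: int,
) -> dict[tuple[int, int], float]:
    """Max mutual information (nats) per (free-axis bins, fixed-axis bins)."""
    n = len(free)
    legal_free = _legal_cuts(free[order_free])
    legal_fixed = _legal_cuts(fixed[order_fixed])
    out: dict[tuple[int, int], float] = {}
    cache: dict[tuple[int, ...], np.ndarray] = {}
    ky_max = int(B // 2)
    for ky in range(2, ky_max + 1):
        kx_max = int(B // ky)
        edges = _equipartition_edges(legal_fixed, n, ky)
        if not edges:
            continue  # fixed axis effectively constant: no 2-bin split exists
        scores = cache.get(edges)
        if scores is None:
            rows = _rows_from_edges(order_fixed, edges, n)[order_free]
            scores = _optimize_free_axis(
                rows, legal_free, n, len(edges) + 1, kx_max, cap=max(c * kx_max, 2)
            )
            cache[edges] = scores
        for l in range(2, kx_max + 1):
            out[(l, ky)] = float(scores[min(l, len(scores) - 1)])
    return out


def grid_shapes(n: int, params: MICParams = DEFAULT_PARAMS) -> list[tuple[int, int]]:
    """All (kx, ky) with kx, ky >= 2 and kx * ky <= n**alpha."""
    B = params.budget(n)
    return [
        (kx, ky)
        for kx in range(2, int(B // 2) + 1)
        for ky in range(2, int(B // kx) + 1)
    ]


def characteristic_matrix(
    x, y, params: MICParams = DEFAULT_PARAMS
) -> dict[tuple[int, int], float]:
    """Normalized maximal-information value for every admissible grid shape.

    Entry ``(kx, ky)`` is the larger of the two axis orientations'
    ``I_max / log(min(kx, ky))``, and the matrix is symmetrized so that
    ``M[kx, ky] == M[ky, kx]``.  All entries lie in [0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    B = params.budget(n)
    if B < 4:
        raise ValueError(
            f"grid budget n**alpha = {B:.2f} < 4; need n >= {math.ceil(4 ** (1 / params.alpha))}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    shapes = grid_shapes(n, params)
    ox = np.argsort(x, kind="stable")
    oy = np.argsort(y, kind="stable")
    if x[ox[0]] == x[ox[-1]] or y[oy[0]] == y[oy[-1]]:
        return {s: 0.0 for s in shapes}  # a constant axis carries no information
    sx = _orientation_scores(x, y, ox, oy, B, params.c)  # kx columns on x
    sy = _orientation_scores(y, x, oy, ox, B, params.c)  # ky columns on y
    M: dict[tuple[int, int], float] = {}
    for kx, ky in shapes:
        i = max(sx.get((kx, ky), 0.0), sy.get((ky, kx), 0.0))
        M[(kx, ky)] = min(max(i / math.log(min(kx, ky)), 0.0), 1.0)
    for kx, ky in shapes:
        if (ky, kx) in M:
            v = max(M[(kx, ky)], M[(ky, kx)])
            M[(kx, ky)] = M[(ky, kx)] = v
    return M


def mic(x, y, params: MICParams = DEFAULT_PARAMS) -> float:
    """Maximal information coefficient between two real vectors (in [0, 1])."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("x and y must be 1-D vectors")
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    M = characteristic_matrix(x, y, params)
    return max(M.values(), default=0.0)


def mic_scores(dataset, params: MICParams = DEFAULT_PARAMS):
    """MIC between every gene and the integer-encoded cell-state label.

    Labels are encoded 0..C-1 in ``class_names`` order; on that axis the grid
    bins reduce to groupings of adjacent classes, which makes the score a
    well-defined dependence measure for a categorical target.
    """
    from .io import Layer
    from .ranking import GeneScoreTable

    if dataset.matrix.layer != Layer.LOG2P1:
        raise ValueError("mic_scores expects the normalized (log2p1) layer")
    codes = dataset.label_codes().astype(np.float64)
    values = dataset.matrix.values
    scores = np.array([mic(values[:, j], codes, params) for j in range(values.shape[1])])
    return GeneScoreTable(dataset.matrix.gene_ids, scores, "mic")
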