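"""MIC: mutual-information identities, normalization bounds, DP optimality."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cellstate import MICParams, characteristic_matrix, mic, mic_scores, mutual_information
from cellstate.mic import (
    _equipartition_edges,
    _legal_cuts,
    _rows_from_edges,
    grid_shapes,
)
from cellstate.ranking import filter_and_rank
from cellstate.io import Layer

from conftest import make_dataset


def exhaustive_characteristic_matrix(x, y, params):
    """Brute-force oracle: optimal free-axis partition by enumerating all cuts."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    B = params.budget(n)
    shapes = grid_shapes(n, params)

    def orientation(free, fixed):
        of = np.argsort(free, kind="stable")
        ofix = np.argsort(fixed, kind="stable")
        legal_free = _legal_cuts(free[of])
        legal_fixed = _legal_cuts(fixed[ofix])
        out = {}
        for ky in range(2, int(B // 2) + 1):
            edges = _equipartition_edges(legal_fixed, n, ky)
            if not edges:
                continue
            rows = _rows_from_edges(ofix, edges, n)[of]
            n_rows = len(edges) + 1
            interior = list(legal_free[:-1])
            for kx in range(2, int(B // ky) + 1):
                best = 0.0
                for ncut in range(1, min(kx - 1, len(interior)) + 1):
                    for combo in itertools.combinations(interior, ncut):
                        bounds = [0, *combo, n]
                        table = np.zeros((len(bounds) - 1, n_rows), dtype=int)
                        for j in range(len(bounds) - 1):
                            for r in rows[bounds[j] : bounds[j + 1]]:
                                table[j, r] += 1
                        best = max(best, mutual_information(table))
                out[(kx, ky)] = best
        return out

    A = orientation(x, y)
    Bo = orientation(y, x)
    M = {}
    for kx, ky in shapes:
        i = max(A.get((kx, ky), 0.0), Bo.get((ky, kx), 0.0))
        M[(kx, ky)] = min(max(i / math.log(min(kx, ky)), 0.0), 1.0)
    for kx, ky in shapes:
        if (ky, kx) in M:
            v = max(M[(kx, ky)], M[(ky, kx)])
            M[(kx, ky)] = M[(ky, kx)] = v
    return M


def small_instances():
    """Seeded mixed-type instances small enough for exhaustive search."""
    rng = np.random.default_rng(2024)
    out = []
    for trial in range(12):
        n = int(rng.integers(11, 20))
        kind = trial % 3
        if kind == 0:
            x, y = rng.normal(size=n), rng.normal(size=n)
        elif kind == 1:  # heavy ties
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 3, size=n).astype(float)
        else:  # dependent
            x = rng.normal(size=n)
            y = x + rng.normal(scale=0.3, size=n)
        out.append((x, y, MICParams()))
    # larger n with the budget held at B <= 6
    for n in (24, 30):
        alpha = math.log(6) / math.log(n)
        x = rng.normal(size=n)
        y = rng.integers(0, 3, size=n).astype(float)
        out.append((x, y, MICParams(alpha=alpha)))
    return out


class TestMutualInformation:
    def test_perfect_dependence_is_one_bit(self):
        assert mutual_information([[5, 0], [0, 5]]) == pytest.approx(math.log(2))

    def test_product_table_is_zero(self):
        assert mutual_information([[4, 4], [4, 4]]) == pytest.approx(0.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            mutual_information([[1, -1], [0, 2]])

    @given(st.integers(0, 2**32 - 1))
    def test_two_formula_forms_agree(self, seed):
        # sum p log(p / px py) must equal H(X) - H(X|Y) to 1e-12
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 9, size=(3, 4))
        if table.sum() == 0:
            table[0, 0] = 1
        i_direct = mutual_information(table)
        p = table / table.sum()
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        h_x = -sum(v * math.log(v) for v in px if v > 0)
        h_x_given_y = 0.0
        for j in range(p.shape[1]):
            if py[j] == 0:
                continue
            for i in range(p.shape[0]):
                if p[i, j] > 0:
                    h_x_given_y -= p[i, j] * math.log(p[i, j] / py[j])
        assert i_direct == pytest.approx(h_x - h_x_given_y, abs=1e-12)


class TestMic:
    def test_noiseless_relation_saturates(self):
        x = np.linspace(0, 1, 100)  # 100 distinct values
        assert mic(x, x) == pytest.approx(1.0)

    def test_constant_vector_scores_zero(self):
        rng = np.random.default_rng(0)
        assert mic(np.full(50, 3.0), rng.normal(size=50)) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=60), rng.normal(size=60)
        assert mic(x, y) == mic(y, x)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            v = mic(rng.normal(size=40), rng.normal(size=40))
            assert 0.0 <= v <= 1.0

    def test_length_mismatch_and_small_n_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mic(np.arange(12), np.arange(11))
        with pytest.raises(ValueError, match="budget"):
            mic(np.arange(5.0), np.arange(5.0))

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = x + rng.normal(scale=0.5, size=80)
        base = mic(x, y)
        assert mic(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        ranks = np.argsort(np.argsort(y)).astype(float)
        assert mic(x, ranks) == pytest.approx(base, abs=1e-12)

    def test_dp_equals_exhaustive_partition_search(self):
        for x, y, params in small_instances():
            got = characteristic_matrix(x, y, params)
            want = exhaustive_characteristic_matrix(x, y, params)
            for shape, v in want.items():
                assert got[shape] == pytest.approx(v, abs=1e-9), (shape, len(x))

    def test_independent_samples_stay_low(self):
        # sanity bound: at n=200, independent noise rarely exceeds MIC 0.3
        rng = np.random.default_rng(99)
        low = sum(mic(rng.normal(size=200), rng.normal(size=200)) < 0.3 for _ in range(100))
        assert low >= 95


class TestMicScores:
    def test_exclusive_gene_ranks_first(self):
        rng = np.random.default_rng(5)
        n_per = 20
        labels = np.repeat([f"c{i}" for i in range(6)], n_per)
        n = len(labels)
        X = np.abs(rng.normal(scale=0.3, size=(n, 21)))  # 20 noise genes + 1 marker
        X[:, 0] = 0.0
        X[labels == "c0", 0] = rng.uniform(2, 4, size=n_per)
        d = make_dataset(X, labels)
        table = mic_scores(d)
        assert table.scores[0] > 0.5
        assert filter_and_rank(table).gene_ids[0] == "g0"

    def test_constant_gene_zero_and_filtered(self):
        X = np.ones((24, 2))
        X[:, 1] = np.random.default_rng(0).uniform(size=24)
        d = make_dataset(X, ["a"] * 12 + ["b"] * 12)
        table = mic_scores(d)
        assert table.scores[0] == 0.0
        assert "g0" not in filter_and_rank(table).gene_ids

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.gamma(1, 1, size=(30, 4))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        d = make_dataset(X, labels)
        perm = rng.permutation(30)
        d2 = make_dataset(X[perm], labels[perm])
        np.testing.assert_allclose(mic_scores(d).scores, mic_scores(d2).scores, atol=1e-12)

    def test_requires_normalized_layer(self):
        d = make_dataset(np.ones((12, 2)), ["a"] * 6 + ["b"] * 6, layer=Layer.RAW_COUNTS)
        with pytest.raises(ValueError, match="normalized"):
            mic_scores(d)
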