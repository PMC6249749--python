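"""Structural indices against brute-force and exhaustive oracles."""

import itertools
import math

import numpy as np
import pytest

from mycorrnet import (
    DegenerateMatrixError,
    SpeciesMatrix,
    UndefinedIndexError,
    c_score,
    connectance,
    h2prime,
    network_summary,
    weighted_nodf,
)


def _random_matrix(rng, shape=(6, 6), high=8, ensure_valid=True):
    a = rng.integers(0, high, size=shape)
    if ensure_valid:
        # no all-zero row/column (pruned matrices are the metric inputs)
        for i in range(shape[0]):
            if a[i].sum() == 0:
                a[i, rng.integers(0, shape[1])] = 1
        for j in range(shape[1]):
            if a[:, j].sum() == 0:
                a[rng.integers(0, shape[0]), j] = 1
    return a


# ---------------------------------------------------------------- oracles


def connectance_oracle(a):
    n, m = a.shape
    return sum(1 for i in range(n) for j in range(m) if a[i, j] > 0) / (n * m)


def wnodf_oracle(a):
    """Independent pair-by-pair implementation of weighted NODF."""

    def pair(u, v):
        # u, v: 1-D arrays; u must have the strictly larger total
        positive = [k for k in range(len(v)) if v[k] > 0]
        if not positive:
            return 0.0
        hits = sum(1 for k in positive if v[k] < u[k])
        return 100.0 * hits / len(positive)

    total, n_pairs = 0.0, 0
    for axis in (0, 1):
        mat = a if axis == 0 else a.T
        sums = mat.sum(axis=1)
        for i, j in itertools.combinations(range(mat.shape[0]), 2):
            n_pairs += 1
            if sums[i] > sums[j]:
                total += pair(mat[i], mat[j])
            elif sums[j] > sums[i]:
                total += pair(mat[j], mat[i])
    return total / n_pairs


def cscore_oracle(a):
    b = a > 0
    n_otus = b.shape[1]
    vals = []
    for i, j in itertools.combinations(range(n_otus), 2):
        ri, rj = b[:, i].sum(), b[:, j].sum()
        s = (b[:, i] & b[:, j]).sum()
        vals.append((ri - s) * (rj - s))
    return float(np.mean(vals))


def _enumerate_matrices(row_sums, col_sums):
    """All non-negative integer matrices with the given marginals."""
    n, m = len(row_sums), len(col_sums)

    def rows(remaining_cols, i):
        if i == n:
            if all(c == 0 for c in remaining_cols):
                yield []
            return
        for row in _compositions(row_sums[i], m, remaining_cols):
            rest = [c - r for c, r in zip(remaining_cols, row)]
            for tail in rows(rest, i + 1):
                yield [row] + tail

    def _compositions(total, parts, caps):
        if parts == 1:
            if total <= caps[0]:
                yield [total]
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in _compositions(total - first, parts - 1, caps[1:]):
                yield [first] + rest

    yield from (np.array(mat) for mat in rows(list(col_sums), 0))


def _entropy(a):
    total = a.sum()
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def h2prime_exhaustive(a):
    """H2' with exact entropy extremes from exhaustive marginal enumeration."""
    r, c = a.sum(axis=1), a.sum(axis=0)
    entropies = [_entropy(m) for m in _enumerate_matrices(list(r), list(c))]
    h_min, h_max = min(entropies), max(entropies)
    if h_max - h_min < 1e-12:
        return None
    return float(np.clip((h_max - _entropy(a)) / (h_max - h_min), 0, 1))


# ----------------------------------------------------------------- tests


class TestConnectance:
    def test_half_filled(self):
        assert connectance(np.array([[1, 0], [0, 1]])) == 0.5

    def test_full(self):
        assert connectance(np.ones((3, 4))) == 1.0

    def test_matches_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = _random_matrix(rng, (10, 10))
            assert connectance(a) == connectance_oracle(a)

    def test_degenerate_refused(self):
        with pytest.raises(DegenerateMatrixError):
            connectance(np.array([[1, 1]]))


class TestH2Prime:
    def test_perfect_specialization(self):
        value, parts = h2prime(np.diag([5, 5]))
        assert value == pytest.approx(1.0, abs=1e-9)
        assert parts.h2_min <= parts.h2_raw <= parts.h2_max + 1e-9

    def test_perfect_generalization(self):
        value, _ = h2prime(np.full((2, 2), 5))
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_matches_exhaustive_oracle_on_small_matrices(self):
        rng = np.random.default_rng(33)
        checked = 0
        while checked < 25:
            a = _random_matrix(rng, (3, 3), high=3)
            if a.sum() > 12 or a.sum() < 4:
                continue
            expected = h2prime_exhaustive(a)
            if expected is None:
                continue
            value, _ = h2prime(a)
            assert value == pytest.approx(expected, abs=0.02)
            checked += 1

    def test_specific_marginals_fixture(self):
        # marginals (6,3,1) / (5,4,1), as concentrated as a diagonal fill allows
        a = np.array([[5, 1, 0], [0, 3, 0], [0, 0, 1]])
        assert a.sum(axis=1).tolist() == [6, 3, 1]
        assert a.sum(axis=0).tolist() == [5, 4, 1]
        value, _ = h2prime(a)
        assert value == pytest.approx(h2prime_exhaustive(a), abs=0.02)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a = _random_matrix(rng, (5, 6))
        v1, _ = h2prime(a)
        v2, _ = h2prime(a[rng.permutation(5)][:, rng.permutation(6)])
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_integer_scaling_invariance(self):
        rng = np.random.default_rng(3)
        a = _random_matrix(rng, (4, 5))
        v1, _ = h2prime(a)
        v2, _ = h2prime(a * 7)
        assert v1 == pytest.approx(v2, abs=0.02)

    def test_undefined_when_marginals_fix_entropy(self):
        with pytest.raises(UndefinedIndexError):
            h2prime(np.array([[1, 0], [0, 1]]))


class TestWeightedNodf:
    def test_tied_marginals_score_zero(self):
        assert weighted_nodf(np.array([[1, 0], [0, 1]])) == 0.0

    def test_perfectly_nested(self):
        assert weighted_nodf(np.array([[4, 2, 1], [3, 1, 0], [2, 0, 0]])) == 100.0

    def test_checkerboard_blocks_score_zero(self):
        a = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        assert weighted_nodf(a) == 0.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            a = _random_matrix(rng, (6, 6))
            assert weighted_nodf(a) == pytest.approx(wnodf_oracle(a), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        a = _random_matrix(rng, (6, 7))
        assert weighted_nodf(a) == pytest.approx(
            weighted_nodf(a[rng.permutation(6)][:, rng.permutation(7)]), abs=1e-12
        )

    def test_binary_matrices_score_zero(self):
        # the weighted pair rule needs the poorer cell strictly below the
        # richer one, which 0/1 matrices can never satisfy — a known property
        # of the weighted NODF variant
        a = np.array(
            [[1, 1, 1, 1, 1], [1, 1, 1, 1, 0], [1, 1, 1, 0, 0], [1, 1, 0, 0, 0]]
        )
        assert weighted_nodf(a) == 0.0

    def test_weighted_nested_with_decreasing_marginals(self):
        a = np.array(
            [[5, 4, 3, 2, 1], [4, 3, 2, 1, 0], [3, 2, 1, 0, 0], [2, 1, 0, 0, 0]]
        )
        assert weighted_nodf(a) == 100.0


class TestCScore:
    def test_disjoint_hosts(self):
        assert c_score(np.array([[1, 0], [0, 1]])) == 1.0

    def test_identical_hosts(self):
        assert c_score(np.array([[1, 1], [1, 1]])) == 0.0

    def test_zero_iff_all_host_set_pairs_nested(self):
        # C_ij = (r_i - S_ij)(r_j - S_ij) vanishes exactly when one OTU's
        # host set contains the other's; identical sets are the special case.
        rng = np.random.default_rng(15)
        column = (rng.random(6) < 0.6).astype(int)
        column[0] = 1
        identical = np.tile(column[:, None], (1, 4))
        assert c_score(identical) == 0.0
        nested = np.array([[1, 1], [0, 1]])
        assert c_score(nested) == 0.0
        crossing = np.array([[1, 0], [1, 1], [0, 1]])
        assert c_score(crossing) > 0

    def test_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            a = (_random_matrix(rng, (8, 12), high=2) > 0).astype(int)
            assert c_score(a) == pytest.approx(cscore_oracle(a), abs=1e-12)

    def test_weighted_input_binarized(self):
        rng = np.random.default_rng(18)
        a = _random_matrix(rng, (6, 6), high=9)
        assert c_score(a) == c_score((a > 0).astype(int))

    def test_plant_permutation_invariance(self):
        rng = np.random.default_rng(19)
        a = _random_matrix(rng, (7, 5))
        assert c_score(a) == pytest.approx(c_score(a[rng.permutation(7)]), abs=1e-12)


class TestNetworkSummary:
    def _matrix(self, assoc):
        assoc = np.asarray(assoc)
        return SpeciesMatrix(
            plant_labels=[f"p{i}" for i in range(assoc.shape[0])],
            otu_ids=[f"o{j}" for j in range(assoc.shape[1])],
            assoc=assoc,
            forest_id="f1",
        )

    def test_counts_and_ratio(self):
        s = network_summary(self._matrix([[1, 2, 0], [0, 1, 3]]))
        assert (s.n_plants, s.n_otus) == (2, 3)
        assert s.fungus_plant_ratio == 1.5

    def test_degenerate_indices_flagged_not_zero(self):
        s = network_summary(self._matrix([[1, 2, 3, 4, 5]]))
        assert s.n_plants == 1 and s.n_otus == 5
        for name in ("connectance", "h2prime", "wnodf", "cscore"):
            assert getattr(s, name) is None
            assert name in s.undefined

    def test_consistent_with_individual_metrics(self):
        rng = np.random.default_rng(20)
        m = self._matrix(_random_matrix(rng, (5, 8)))
        s = network_summary(m)
        assert s.connectance == connectance(m)
        assert s.h2prime == h2prime(m)[0]
        assert s.wnodf == weighted_nodf(m)
        assert s.cscore == c_score(m)
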