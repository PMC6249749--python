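"""Structural indices of bipartite plant-fungus networks.

Four indices summarize a plant x OTU association matrix:

connectance
    Fraction of realized links among all plant-OTU pairs.
H2'
    Network-level interaction specificity: the Shannon entropy of the
    interaction proportions, rescaled between the minimum and maximum entropy
    achievable under the observed marginal totals.  0 = maximally generalized,
    1 = maximally specialized.
weighted NODF
    Weighted nestedness (0-100): the degree to which partner sets of
    poorer rows/columns are weighted subsets of richer ones.
C-score
    Mean checkerboard score over OTU pairs on the binarized matrix; high
    values indicate differentiated host ranges within the fungal community.

The marginal-constrained entropy extremes for H2' are found heuristically
(even-distribution rounding for the maximum, greedy concentration for the
minimum); on small matrices the heuristics are validated in the test suite
against exhaustive enumeration of all integer matrices with the observed
marginals.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMatrixError, UndefinedIndexError
from .tables import SpeciesMatrix

#: Swap refinement of the max-entropy filling is exact search over all 2x2
#: submatrices, quadratic in the cell count per pass; above this cell count
#: the largest-remainder rounding is already entropy-tight (integer
#: granularity is fine relative to the totals) and the search is skipped.
_SWAP_REFINE_MAX_CELLS = 100


@dataclass
class H2Parts:
    """Entropy terms behind H2': observed and marginal-constrained extremes (nats)."""

    h2_raw: float
    h2_min: float
    h2_max: float


@dataclass
class NetworkIndices:
    """Bundle of structural indices for one network; undefined entries carry a reason."""

    n_plants: int
    n_otus: int
    fungus_plant_ratio: float
    connectance: float | None = None
    h2prime: float | None = None
    wnodf: float | None = None
    cscore: float | None = None
    undefined: dict = field(default_factory=dict)


def _as_matrix(m: SpeciesMatrix | np.ndarray, require_nondegenerate: bool = True):
    if isinstance(m, SpeciesMatrix):
        a = np.asarray(m.assoc, dtype=np.float64)
        degenerate = m.degenerate
    else:
        a = np.asarray(m, dtype=np.float64)
        degenerate = a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2
    if require_nondegenerate and degenerate:
        raise DegenerateMatrixError(
            f"matrix of shape {a.shape} is too small for network indices"
        )
    return a


def connectance(m: SpeciesMatrix | np.ndarray) -> float:
    """Proportion of nonzero cells."""
    a = _as_matrix(m)
    return float(np.count_nonzero(a) / a.size)


def _entropy(values: np.ndarray, total: float) -> float:
    """Shannon entropy (nats) of values/total, zeros ignored."""
    p = np.asarray(values, dtype=np.float64)
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def _max_entropy_filling(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Integer matrix with marginals (r, c) of near-maximal entropy.

    Start from the real-valued independence expectations r_i c_j / m, round by
    largest remainder while preserving both marginals, then (for small
    matrices) refine with improving 2x2 swaps until a local maximum.
    """
    r = np.asarray(r, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    total = int(r.sum())
    assert total == int(c.sum())
    expected = np.outer(r, c) / total
    filled = np.floor(expected).astype(np.int64)
    row_def = (r - filled.sum(axis=1)).tolist()
    col_def = (c - filled.sum(axis=0)).tolist()
    remaining = sum(row_def)
    if remaining:
        remainder = (expected - filled).ravel()
        order = np.argsort(-remainder, kind="stable")
        rows, cols = np.divmod(order, len(c))
        rows = rows.tolist()
        cols = cols.tolist()
        for i, j in zip(rows, cols):
            if row_def[i] > 0 and col_def[j] > 0:
                filled[i, j] += 1
                row_def[i] -= 1
                col_def[j] -= 1
                remaining -= 1
                if remaining == 0:
                    break
        # Greedy pass may strand deficits in incompatible cells; close them
        # with a transportation fill (any assignment preserves marginals).
        while remaining:
            i = max(range(len(row_def)), key=row_def.__getitem__)
            j = max(range(len(col_def)), key=col_def.__getitem__)
            k = min(row_def[i], col_def[j])
            filled[i, j] += k
            row_def[i] -= k
            col_def[j] -= k
            remaining -= k
    if filled.size <= _SWAP_REFINE_MAX_CELLS:
        _refine_swaps(filled)
    return filled


def _plogp(x: float) -> float:
    return x * math.log(x) if x > 0 else 0.0


def _refine_swaps(a: np.ndarray, max_iter: int = 500) -> None:
    """In-place 2x2 swap hill climbing on entropy; preserves both marginals."""
    n, m = a.shape
    for _ in range(max_iter):
        best_gain = 1e-12
        best = None
        # Moving one unit from (i1,j1),(i2,j2) to (i1,j2),(i2,j1) keeps the
        # marginals; the entropy gain depends only on the four cell values.
        for i1 in range(n):
            for i2 in range(i1 + 1, n):
                for j1 in range(m):
                    for j2 in range(m):
                        if j1 == j2:
                            continue
                        p = a[i1, j1]
                        t = a[i2, j2]
                        if p < 1 or t < 1:
                            continue
                        q = a[i1, j2]
                        s = a[i2, j1]
                        old = _plogp(p) + _plogp(q) + _plogp(s) + _plogp(t)
                        new = (
                            _plogp(p - 1)
                            + _plogp(q + 1)
                            + _plogp(s + 1)
                            + _plogp(t - 1)
                        )
                        gain = old - new  # entropy = -sum plogp
                        if gain > best_gain:
                            best_gain = gain
                            best = (i1, i2, j1, j2)
        if best is None:
            return
        i1, i2, j1, j2 = best
        a[i1, j1] -= 1
        a[i2, j2] -= 1
        a[i1, j2] += 1
        a[i2, j1] += 1


def _min_entropy_filling(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Greedy concentration: place min(remaining row, col) at the largest marginals.

    Max-heaps keyed by (-value, index) reproduce numpy argmax tie-breaking
    (first index wins) in O((n+m) log) rather than repeated scans.
    """
    row_heap = [(-int(v), i) for i, v in enumerate(np.asarray(r)) if v > 0]
    col_heap = [(-int(v), j) for j, v in enumerate(np.asarray(c)) if v > 0]
    heapq.heapify(row_heap)
    heapq.heapify(col_heap)
    values = []
    while row_heap:
        neg_rv, i = heapq.heappop(row_heap)
        neg_cv, j = heapq.heappop(col_heap)
        v = min(-neg_rv, -neg_cv)
        values.append(v)
        if -neg_rv > v:
            heapq.heappush(row_heap, (neg_rv + v, i))
        if -neg_cv > v:
            heapq.heappush(col_heap, (neg_cv + v, j))
    return np.asarray(values, dtype=np.int64)


def h2prime(m: SpeciesMatrix | np.ndarray) -> tuple[float, H2Parts]:
    """Network-level interaction specificity H2' with its entropy terms.

    H2' = (H2_max - H2) / (H2_max - H2_min), clipped to [0, 1], where H2 is
    the entropy of the observed interaction proportions and H2_min/H2_max are
    the extremes achievable by integer matrices with the observed marginal
    totals.
    """
    a = _as_matrix(m)
    total = a.sum()
    if total <= 0:
        raise DegenerateMatrixError("H2' undefined for an empty matrix")
    a_int = np.round(a).astype(np.int64)
    r = a_int.sum(axis=1)
    c = a_int.sum(axis=0)
    h2_raw = _entropy(a, total)
    h2_max = _entropy(_max_entropy_filling(r, c).ravel(), total)
    h2_min = _entropy(_min_entropy_filling(r, c), total)
    parts = H2Parts(h2_raw=h2_raw, h2_min=h2_min, h2_max=h2_max)
    if h2_max - h2_min <= 1e-12:
        raise UndefinedIndexError(
            "H2' undefined: marginals admit a single entropy value"
        )
    value = (h2_max - h2_raw) / (h2_max - h2_min)
    return float(np.clip(value, 0.0, 1.0)), parts


def _pair_contributions(a: np.ndarray) -> tuple[float, int]:
    """Weighted-NODF contributions over all unordered row pairs of ``a``.

    For a pair with strictly larger total in row u, the score is 100 times the
    fraction of the poorer row's positive cells that are positive and strictly
    smaller than the corresponding cell of u; pairs with tied totals score 0.
    """
    n = a.shape[0]
    if n < 2:
        return 0.0, 0
    totals = a.sum(axis=1)
    d = (a > 0).sum(axis=1).astype(np.float64)  # positive cells per row
    # counts[u, v] = #{k : 0 < a[v,k] < a[u,k]}
    av = a[np.newaxis, :, :]
    au = a[:, np.newaxis, :]
    counts = ((av > 0) & (av < au)).sum(axis=2).astype(np.float64)
    richer = totals[:, np.newaxis] > totals[np.newaxis, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(richer & (d[np.newaxis, :] > 0), counts / d[np.newaxis, :], 0.0)
    return float(100.0 * scores.sum()), n * (n - 1) // 2


def weighted_nodf(m: SpeciesMatrix | np.ndarray) -> float:
    """Weighted NODF nestedness in [0, 100]: mean pair score over all row pairs
    and all column pairs."""
    a = _as_matrix(m)
    row_sum, row_pairs = _pair_contributions(a)
    col_sum, col_pairs = _pair_contributions(a.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def c_score(m: SpeciesMatrix | np.ndarray) -> float:
    """Mean checkerboard score over unordered OTU pairs on the binarized matrix.

    For OTUs i, j with host counts r_i, r_j and S_ij shared hosts,
    C_ij = (r_i - S_ij)(r_j - S_ij); the score is the raw mean of C_ij.
    """
    a = _as_matrix(m)
    if a.shape[1] < 2:
        raise DegenerateMatrixError("C-score needs at least two OTUs")
    b = (a > 0).astype(np.float64)
    shared = b.T @ b  # S_ij, with diagonal r_i
    r = np.diag(shared)
    cmat = (r[:, np.newaxis] - shared) * (r[np.newaxis, :] - shared)
    n_otus = b.shape[1]
    return float(cmat.sum() / (n_otus * (n_otus - 1)))


METRIC_FUNCTIONS = {
    "connectance": connectance,
    "h2prime": lambda m: h2prime(m)[0],
    "wnodf": weighted_nodf,
    "cscore": c_score,
}


def network_summary(m: SpeciesMatrix) -> NetworkIndices:
    """Counts plus all indices; individually undefined indices are recorded
    with their reason instead of failing the bundle."""
    out = NetworkIndices(
        n_plants=m.n_plants,
        n_otus=m.n_otus,
        fungus_plant_ratio=m.n_otus / m.n_plants if m.n_plants else float("nan"),
    )
    for name in ("connectance", "h2prime", "wnodf", "cscore"):
        try:
            setattr(out, name, float(METRIC_FUNCTIONS[name](m)))
        except (DegenerateMatrixError, UndefinedIndexError) as exc:
            out.undefined[name] = str(exc)
    return out
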