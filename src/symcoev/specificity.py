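"""Quantitative specificity of genotype-by-genotype interaction matrices.

An interaction matrix (rows = genotypes of one species, columns = genotypes
of its partner, entries = adaptation/resistance degrees) is *specific* when
reaction norms cross: some genotype pair of either species swaps rank
depending on which partner genotype it faces.  Formally, q is specific iff
there are rows r, r' and columns c, c' with

    q[r][c] > q[r'][c]   and   q[r][c'] < q[r'][c'],

or the analogous condition on a pair of columns.  Non-specific matrices are
exactly those whose rows form a chain under coordinatewise weak dominance
and whose columns do too (ties allowed); equivalently, those that can be
brought to a doubly-monotone form by permuting rows and columns.

The *specificity index* S(q) is the minimal additive (entrywise L1)
disturbance that turns q into a non-specific matrix.  For 2x2 matrices with
entries in [0,1] the index ranges over [0,1], is 0 exactly for non-specific
matrices such as the gene-for-gene pattern, and attains 1 only at the
matching-alleles matrix and its mirror image.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "SpecificityResult",
    "CrossingWitness",
    "is_specific",
    "specificity_2x2",
    "specificity_2x2_batch",
    "specificity_general",
    "specificity_oracle",
]

#: Enumerate row/column orders exactly up to this many (row!, col!) pairs.
_EXACT_ENUMERATION_LIMIT = 4000


@dataclass(frozen=True)
class CrossingWitness:
    """A pair of rows and columns exhibiting a crossing.

    ``axis`` is 0 when the named rows' reaction norms cross (host-side
    specialisation) and 1 when the named columns' norms cross.
    """

    rows: tuple[int, int]
    cols: tuple[int, int]
    axis: int


@dataclass(frozen=True)
class SpecificityResult:
    index: float
    is_specific: bool
    witness: Optional[CrossingWitness] = None
    converged: bool = True
    bounds: Optional[tuple[float, float]] = None


def _as_matrix(q) -> np.ndarray:
    arr = np.asarray(q, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(
            f"interaction matrix needs at least 2 rows and 2 columns, got shape {arr.shape}"
        )
    return arr


def _find_row_crossing(q: np.ndarray) -> Optional[tuple[int, int, int, int]]:
    m = q.shape[0]
    for r, r2 in itertools.combinations(range(m), 2):
        d = q[r] - q[r2]
        pos = np.flatnonzero(d > 0)
        neg = np.flatnonzero(d < 0)
        if pos.size and neg.size:
            c, c2 = int(pos[0]), int(neg[0])
            return r, r2, c, c2
    return None


def is_specific(q) -> tuple[bool, Optional[CrossingWitness]]:
    """Decide whether the matrix exhibits any crossing of reaction norms.

    Returns the verdict together with a witness (rows, columns, axis) when
    a crossing exists.  Ties never count as crossings.
    """
    arr = _as_matrix(q)
    hit = _find_row_crossing(arr)
    if hit is not None:
        r, r2, c, c2 = hit
        return True, CrossingWitness(rows=(r, r2), cols=(c, c2), axis=0)
    hit = _find_row_crossing(arr.T)
    if hit is not None:
        c, c2, r, r2 = hit
        return True, CrossingWitness(rows=(r, r2), cols=(c, c2), axis=1)
    return False, None


def specificity_2x2_batch(q: np.ndarray) -> np.ndarray:
    """Vectorised closed-form index for a stack of 2x2 matrices (..., 2, 2).

    The minimal L1 disturbance must independently cancel the row crossing
    and the column crossing (each requires at least the smaller of the two
    rank-gap magnitudes on its axis), and the larger of the two costs is
    always sufficient, so the index is the max of the two closed forms.
    """
    q = np.asarray(q, dtype=float)
    d1 = q[..., 0, 0] - q[..., 1, 0]
    d2 = q[..., 0, 1] - q[..., 1, 1]
    e1 = q[..., 0, 0] - q[..., 0, 1]
    e2 = q[..., 1, 0] - q[..., 1, 1]
    row_term = np.where(d1 * d2 < 0, np.minimum(np.abs(d1), np.abs(d2)), 0.0)
    col_term = np.where(e1 * e2 < 0, np.minimum(np.abs(e1), np.abs(e2)), 0.0)
    return np.maximum(row_term, col_term)


def specificity_2x2(q) -> SpecificityResult:
    """Closed-form specificity index of a 2x2 matrix with entries in [0,1]."""
    arr = _as_matrix(q)
    if arr.shape != (2, 2):
        raise ValueError(f"specificity_2x2 needs a 2x2 matrix, got {arr.shape}")
    if not np.all((arr >= 0) & (arr <= 1)):
        raise ValueError(
            "entries must lie in [0, 1]; use specificity_general for "
            "unconstrained matrices"
        )
    specific, witness = is_specific(arr)
    index = float(specificity_2x2_batch(arr)) if specific else 0.0
    return SpecificityResult(index=index, is_specific=specific, witness=witness)


def _l1_monotone_projection(q: np.ndarray) -> float:
    """Minimal L1 distance from q to a matrix non-increasing along both axes.

    Solved as a linear program (variables: target entries x, unconstrained,
    plus absolute-deviation slacks t):  min sum t  s.t.  |x - q| <= t and
    x[i+1,j] <= x[i,j], x[i,j+1] <= x[i,j].
    """
    m, n = q.shape
    mn = m * n
    # variable vector z = [x (mn), t (mn)]
    c = np.concatenate([np.zeros(mn), np.ones(mn)])
    rows_A, cols_A, vals, b = [], [], [], []
    k = 0

    def add(coords_vals, rhs):
        nonlocal k
        for j, v in coords_vals:
            rows_A.append(k)
            cols_A.append(j)
            vals.append(v)
        b.append(rhs)
        k += 1

    flat = q.ravel()
    for idx in range(mn):
        add([(idx, 1.0), (mn + idx, -1.0)], flat[idx])     # x - t <= q
        add([(idx, -1.0), (mn + idx, -1.0)], -flat[idx])   # -x - t <= -q
    for i in range(m):
        for j in range(n):
            idx = i * n + j
            if i + 1 < m:
                add([((i + 1) * n + j, 1.0), (idx, -1.0)], 0.0)
            if j + 1 < n:
                add([(i * n + j + 1, 1.0), (idx, -1.0)], 0.0)
    from scipy.sparse import coo_matrix

    A = coo_matrix((vals, (rows_A, cols_A)), shape=(k, 2 * mn))
    bounds = [(None, None)] * mn + [(0, None)] * mn
    res = linprog(c, A_ub=A, b_ub=np.array(b), bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": 1e-10,
                           "dual_feasibility_tolerance": 1e-10})
    if not res.success:  # pragma: no cover - HiGHS is reliable on these LPs
        raise RuntimeError(f"monotone projection LP failed: {res.message}")
    return float(res.fun)


def _candidate_orders(values: np.ndarray, limit: int) -> list[tuple[int, ...]]:
    """Row orders to try: all permutations when affordable, otherwise the
    mean-sorted order plus its adjacent-swap neighbourhood."""
    m = len(values)
    if math.factorial(m) <= limit:
        return [tuple(p) for p in itertools.permutations(range(m))]
    base = tuple(np.argsort(-values, kind="stable"))
    orders = {base}
    for i in range(m - 1):
        swapped = list(base)
        swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
        orders.add(tuple(swapped))
    return sorted(orders)


def specificity_general(q, tolerance: float = 1e-9) -> SpecificityResult:
    """Specificity index of an arbitrary m x n real matrix.

    The non-specific set is the union, over row orders pi and column orders
    sigma, of the cones of matrices non-increasing along both axes after
    permutation; the index is the minimum over (pi, sigma) of the exact L1
    projection distance onto each cone.  Order pairs are enumerated
    exhaustively for small matrices; for larger ones a sorted-order
    neighbourhood search is used and ``converged=False`` signals that the
    reported index is an upper bound only.
    """
    arr = _as_matrix(q)
    specific, witness = is_specific(arr)
    if not specific:
        return SpecificityResult(index=0.0, is_specific=False, witness=None)
    m, n = arr.shape
    exact = math.factorial(m) * math.factorial(n) <= _EXACT_ENUMERATION_LIMIT
    row_orders = _candidate_orders(arr.mean(axis=1),
                                   _EXACT_ENUMERATION_LIMIT)
    col_orders = _candidate_orders(arr.mean(axis=0),
                                   max(1, _EXACT_ENUMERATION_LIMIT // len(row_orders)))
    best = np.inf
    for pi in row_orders:
        sub = arr[list(pi), :]
        for sigma in col_orders:
            val = _l1_monotone_projection(sub[:, list(sigma)])
            if val < best:
                best = val
            if best <= tolerance:
                break
        if best <= tolerance:
            break
    index = max(best, 0.0)
    return SpecificityResult(index=index, is_specific=True, witness=witness,
                             converged=exact)


def _batch_nonspecific_mask(X: np.ndarray) -> np.ndarray:
    """Boolean mask over a stack (B, m, n): True where no crossing exists."""
    B, m, n = X.shape
    ok = np.ones(B, dtype=bool)
    for r, r2 in itertools.combinations(range(m), 2):
        d = X[:, r, :] - X[:, r2, :]
        ok &= ~((d.max(axis=1) > 0) & (d.min(axis=1) < 0))
    for c, c2 in itertools.combinations(range(n), 2):
        d = X[:, :, c] - X[:, :, c2]
        ok &= ~((d.max(axis=1) > 0) & (d.min(axis=1) < 0))
    return ok


@functools.lru_cache(maxsize=8)
def _nonspecific_grid_candidates(m: int, n: int, grid_step: float,
                                 max_candidates: int) -> np.ndarray:
    """All non-specific matrices with entries on {0, step, ..., 1}, flat
    (K, m*n).  Cached so repeated oracle calls enumerate only once."""
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 12)
    G = len(grid)
    total = G ** (m * n)
    if total > max_candidates:
        raise ValueError(
            f"grid search over {total} candidate matrices refused "
            f"(limit {max_candidates}); use a coarser grid or a smaller matrix"
        )
    kept = []
    chunk = 200_000
    shape = (G,) * (m * n)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        digits = np.stack(np.unravel_index(idx, shape), axis=1)
        X = grid[digits]                       # (B, m*n)
        mask = _batch_nonspecific_mask(X.reshape(-1, m, n))
        if mask.any():
            kept.append(X[mask])
    return np.concatenate(kept)


def specificity_oracle(q, grid_step: float = 0.05,
                       max_candidates: int = 6_000_000) -> tuple[float, float]:
    """Brute-force bounds on the index by exhaustive grid search.

    Enumerates every matrix whose entries lie on the grid {0, step, ..., 1},
    keeps the non-specific ones, and takes the minimal L1 distance g to q.
    Because clipping to [0,1] and grid-rounding both preserve weak
    dominance, the true minimum lies in [max(0, g - m*n*step/2), g].

    Only feasible for small matrices; larger instances are refused.
    """
    arr = _as_matrix(q)
    if not np.all((arr >= 0) & (arr <= 1)):
        raise ValueError("oracle assumes entries in [0, 1]")
    specific, _ = is_specific(arr)
    if not specific:
        return (0.0, 0.0)
    m, n = arr.shape
    candidates = _nonspecific_grid_candidates(m, n, float(grid_step),
                                              int(max_candidates))
    upper = float(np.abs(candidates - arr.ravel()).sum(axis=1).min())
    lower = max(0.0, upper - m * n * grid_step / 2)
    return (lower, upper)
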