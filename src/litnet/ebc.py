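"""Ensemble information-theoretic co-clustering of the incidence matrix.

The base learner is information-theoretic co-clustering (ITCC): the matrix
is normalized to a joint distribution p(X, Y) over (entity pair, path) and
row/column cluster assignments are alternately updated to minimize

    KL( p(X, Y) || q(X, Y) ),   q(x, y) = p(xh, yh) p(x | xh) p(y | yh),

which equals the mutual-information loss I(X; Y) - I(Xh; Yh).  A single
run is a local optimum that depends on its random initialization, so the
ensemble repeats the fit many times (2000 by default) and records, for
every pair of columns, the number of runs in which they landed in the same
column cluster.  That co-clustering count matrix is the similarity
structure the theme dendrograms are built from.

Numerical conventions: 0 log 0 = 0 throughout; argmin ties break toward
the lowest cluster index; empty clusters may persist (no reseeding).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_LOG_FLOOR = -1.0e30  # stands in for log 0 inside dot products


@dataclass
class EBCConfig:
    """Ensemble configuration: cluster counts, run count, seeds, stopping."""

    K: int
    L: int
    n_runs: int = 2000
    base_seed: int = 0
    max_iterations: int = 25
    tolerance: float = 1e-9

    def __post_init__(self):
        if self.K < 1 or self.L < 1 or self.n_runs < 1:
            raise ValueError("K, L and n_runs must all be >= 1")


#: Default (K, L) per relationship type for full-scale corpora.
DEFAULT_KL = {
    "chemical-gene": (100, 100),
    "chemical-disease": (150, 170),
    "gene-disease": (190, 150),
    "gene-gene": (90, 70),
}


@dataclass
class Cocluster:
    """One ITCC fit: assignments plus the mutual-information loss."""

    row_assignment: np.ndarray  # shape (n_rows,), values in 0..K-1
    col_assignment: np.ndarray
    objective: float
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class EnsembleCocluster:
    """Symmetric path x path co-clustering counts across ensemble runs."""

    counts: np.ndarray
    n_runs: int

    def __post_init__(self):
        c = self.counts
        if not np.array_equal(c, c.T):
            raise ValueError("co-clustering counts must be symmetric")
        if not np.array_equal(np.diag(c), np.full(c.shape[0], self.n_runs)):
            raise ValueError("diagonal must equal n_runs")
        if c.min() < 0 or c.max() > self.n_runs:
            raise ValueError("counts must lie in [0, n_runs]")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_runs


def _as_dense(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        matrix = matrix.todense()
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if (m < 0).any():
        raise ValueError("matrix must be nonnegative")
    if (m.sum(axis=1) == 0).any() or (m.sum(axis=0) == 0).any():
        raise ValueError("matrix must have no all-zero rows or columns")
    return m


def _mutual_information(joint: np.ndarray) -> float:
    """I(X; Y) in nats of a joint probability table (0 log 0 = 0)."""
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = np.ones_like(joint)
    np.divide(joint, px @ py, out=ratio, where=mask)
    return float(np.sum(joint[mask] * np.log(ratio[mask])))


def _cluster_joint(p: np.ndarray, rows: np.ndarray, cols: np.ndarray, K: int, L: int) -> np.ndarray:
    """p(xh, yh): aggregate the joint over cluster memberships."""
    row_ind = np.zeros((p.shape[0], K))
    row_ind[np.arange(p.shape[0]), rows] = 1.0
    col_ind = np.zeros((p.shape[1], L))
    col_ind[np.arange(p.shape[1]), cols] = 1.0
    return row_ind.T @ p @ col_ind


def objective(matrix, row_assignment: Sequence[int], col_assignment: Sequence[int]) -> float:
    """Mutual-information loss I(X;Y) - I(Xh;Yh) of a co-clustering.

    Zero when every row and column is its own cluster (nothing is lost) and
    equal to I(X;Y) when everything is merged into single clusters.
    """
    m = _as_dense(matrix)
    rows = np.asarray(row_assignment, dtype=int)
    cols = np.asarray(col_assignment, dtype=int)
    K = int(rows.max()) + 1
    L = int(cols.max()) + 1
    p = m / m.sum()
    return _mutual_information(p) - _mutual_information(_cluster_joint(p, rows, cols, K, L))


def _safe_log(a: np.ndarray) -> np.ndarray:
    out = np.full_like(a, _LOG_FLOOR)
    np.log(a, out=out, where=a > 0)
    return out


def itcc(
    matrix,
    K: int,
    L: int,
    seed: int,
    max_iterations: int = 25,
    tolerance: float = 1e-9,
) -> Cocluster:
    """Fit one information-theoretic co-clustering by alternating sweeps.

    Starts from random assignments, updates all rows then all columns once
    per iteration, and stops when the objective improves by at most
    ``tolerance`` or ``max_iterations`` is reached.  The batch sweeps are
    then polished by steepest-descent moves evaluated on the exact
    objective (only I(Xh;Yh) changes when a row or column moves, so each
    candidate move costs O(KL)); this escapes the fixed points the batch
    update is known to stall in.  The objective is non-increasing across
    iterations.

    The fit is equivariant under column permutations: the matrix is
    brought into a canonical row/column order (by color refinement with
    content tie-breaks) before the seeded random initialization is drawn,
    identical columns are kept co-assigned (equal conditionals share the
    batch argmax, and the polish stage moves identical slices as a
    group), and the assignments are mapped back to the input order.
    """
    m = _as_dense(matrix)
    n_rows, n_cols = m.shape
    if K > n_rows or L > n_cols:
        raise ValueError(f"K={K}, L={L} exceed matrix dimensions {m.shape}")
    canon_rows, canon_cols = _canonical_order(m)
    m = m[np.ix_(canon_rows, canon_cols)]
    rng = np.random.default_rng(seed)
    # uniform random init, redrawn if a cluster starts empty: the batch
    # update cannot repopulate an empty cluster, so a degenerate draw
    # would forfeit the run.  (Clusters emptied later stay empty.)
    rows = rng.integers(0, K, size=n_rows)
    while len(np.unique(rows)) < K:
        rows = rng.integers(0, K, size=n_rows)
    cols = rng.integers(0, L, size=n_cols)
    while len(np.unique(cols)) < L:
        cols = rng.integers(0, L, size=n_cols)

    p = m / m.sum()
    px = p.sum(axis=1)  # row marginals
    py = p.sum(axis=0)
    # Conditionals used in the update scores; rows/cols of the original
    # matrix have positive marginals by precondition.
    p_y_given_x = p / px[:, None]
    p_x_given_y = (p / py[None, :]).T  # shape (n_cols, n_rows)

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iterations):
        # --- row sweep -------------------------------------------------
        rows = _update(p_y_given_x, cols, L, _cluster_joint(p, rows, cols, K, L))
        # --- column sweep ----------------------------------------------
        cols = _update(p_x_given_y, rows, K, _cluster_joint(p, rows, cols, K, L).T)
        obj = _mutual_information(p) - _mutual_information(
            _cluster_joint(p, rows, cols, K, L)
        )
        trace.append(obj)
        if prev - obj <= tolerance:
            break
        prev = obj
    rows, cols = _polish(p, rows, cols, K, L)
    final = _mutual_information(p) - _mutual_information(_cluster_joint(p, rows, cols, K, L))
    trace.append(min(final, trace[-1]))
    # map assignments back to the caller's row/column order
    rows_out = np.empty(n_rows, dtype=np.int64)
    cols_out = np.empty(n_cols, dtype=np.int64)
    rows_out[canon_rows] = rows
    cols_out[canon_cols] = cols
    return Cocluster(rows_out, cols_out, trace[-1], trace)


_canon_cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


def _canonical_order(m: np.ndarray, rounds: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Column-permutation-invariant canonical row/column ordering.

    Columns are ordered by (refinement color, exact content): a column's
    content does not change when columns are shuffled, so this order is
    invariant under any column permutation, with ties only between
    byte-identical columns.  Rows are then ordered by (refinement color,
    content read in the canonical column order), which is likewise
    invariant.  The refinement colors come from the classic color-
    refinement scheme (recolor each row by the multiset of
    (column color, value) pairs, and vice versa).  Cached per matrix
    since the ordering is seed-independent.
    """
    cache_key = hashlib.blake2b(m.tobytes() + bytes(m.shape), digest_size=16).digest()
    if cache_key in _canon_cache:
        return _canon_cache[cache_key]
    n_rows, n_cols = m.shape
    row_color = [hashlib.blake2b(np.sort(m[i]).tobytes(), digest_size=8).digest() for i in range(n_rows)]
    col_color = [hashlib.blake2b(np.sort(m[:, j]).tobytes(), digest_size=8).digest() for j in range(n_cols)]
    for _ in range(rounds):
        new_row = [
            hashlib.blake2b(
                row_color[i]
                + b"".join(sorted(col_color[j] + m[i, j].tobytes() for j in range(n_cols))),
                digest_size=8,
            ).digest()
            for i in range(n_rows)
        ]
        new_col = [
            hashlib.blake2b(
                col_color[j]
                + b"".join(sorted(row_color[i] + m[i, j].tobytes() for i in range(n_rows))),
                digest_size=8,
            ).digest()
            for j in range(n_cols)
        ]
        row_color, col_color = new_row, new_col
    canon_cols = np.array(
        sorted(range(n_cols), key=lambda j: (col_color[j], m[:, j].tobytes()))
    )
    canon_rows = np.array(
        sorted(range(n_rows), key=lambda i: (row_color[i], m[i, canon_cols].tobytes()))
    )
    if len(_canon_cache) > 64:
        _canon_cache.clear()
    _canon_cache[cache_key] = (canon_rows, canon_cols)
    return canon_rows, canon_cols


def _group_indices(m: np.ndarray, axis: int) -> list[np.ndarray]:
    """Indices grouped by identical slice content, in a stable content order.

    The group order key is the sorted value vector (invariant to
    permutations of the other dimension); groups with equal multisets are
    ordered by their exact content.
    """
    buckets: dict[bytes, list[int]] = {}
    order_key: dict[bytes, bytes] = {}
    n = m.shape[axis]
    for i in range(n):
        vec = m[i] if axis == 0 else m[:, i]
        ident = vec.tobytes()
        buckets.setdefault(ident, []).append(i)
        order_key[ident] = np.sort(vec).tobytes()
    ordered = sorted(buckets, key=lambda ident: (order_key[ident], ident))
    return [np.asarray(buckets[ident]) for ident in ordered]


def _polish(
    p: np.ndarray, rows: np.ndarray, cols: np.ndarray, K: int, L: int,
    min_gain: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Steepest-descent group moves maximizing I(Xh;Yh) until stable.

    Candidates are (group of identical rows/columns, target cluster)
    pairs; at each step the single move with the largest mutual-
    information gain is applied.  Moving identical slices jointly keeps
    them co-assigned, and gain-ordered selection makes the refinement
    independent of element order.
    """
    rows = rows.copy()
    cols = cols.copy()
    row_groups = _group_indices(p, axis=0)
    col_groups = _group_indices(p, axis=1)
    while True:
        joint = _cluster_joint(p, rows, cols, K, L)
        current = _mutual_information(joint)
        col_ind = np.zeros((p.shape[1], L))
        col_ind[np.arange(p.shape[1]), cols] = 1.0
        row_profiles = p @ col_ind  # (n_rows, L)
        row_ind = np.zeros((p.shape[0], K))
        row_ind[np.arange(p.shape[0]), rows] = 1.0
        col_profiles = p.T @ row_ind  # (n_cols, K)

        best = None  # (gain, side, group_pos, target)
        for side, groups, assign, profiles, table in (
            (0, row_groups, rows, row_profiles, joint),
            (1, col_groups, cols, col_profiles, joint.T),
        ):
            for gpos, members in enumerate(groups):
                a = assign[members[0]]
                profile = profiles[members].sum(axis=0)
                for b in range(table.shape[0]):
                    if b == a:
                        continue
                    trial = table.copy()
                    trial[a] -= profile
                    trial[b] += profile
                    np.clip(trial, 0.0, None, out=trial)
                    gain = _mutual_information(trial) - current
                    if gain > min_gain and (best is None or gain > best[0]):
                        best = (gain, side, gpos, b)
        if best is None:
            return rows, cols
        _, side, gpos, target = best
        if side == 0:
            rows[row_groups[gpos]] = target
        else:
            cols[col_groups[gpos]] = target


def _update(cond: np.ndarray, other_assign: np.ndarray, n_other: int, joint: np.ndarray) -> np.ndarray:
    """One side's reassignment sweep.

    ``cond`` is p(other | this) with shape (n_this, n_other_elements);
    ``joint`` is the cluster-level joint p(this-cluster, other-cluster).
    Each element moves to the cluster minimizing the KL divergence between
    its conditional and the cluster's model conditional, which reduces to
    maximizing  sum_oh  cond_agg[x, oh] * log p(oh | this-cluster).
    """
    n_this_clusters = joint.shape[0]
    n_elements = cond.shape[0]
    # aggregate the conditional over the other side's clusters
    agg = np.zeros((n_elements, n_other))
    for oh in range(n_other):
        members = other_assign == oh
        if members.any():
            agg[:, oh] = cond[:, members].sum(axis=1)
    this_marginal = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        model = np.where(this_marginal > 0, joint / this_marginal, 0.0)
    score = agg @ _safe_log(model).T  # (n_elements, n_this_clusters)
    return np.argmax(score, axis=1)


def run_ensemble(matrix, config: EBCConfig) -> EnsembleCocluster:
    """Run ``n_runs`` independent ITCC fits and tally column co-clustering.

    Run i uses seed ``base_seed + i``; the count matrix entry (j, j') is
    the number of runs in which columns j and j' shared a column cluster.
    Deterministic given ``base_seed``.
    """
    m = _as_dense(matrix)
    n_cols = m.shape[1]
    counts = np.zeros((n_cols, n_cols), dtype=int)
    for run in range(config.n_runs):
        fit = itcc(
            m,
            config.K,
            config.L,
            seed=config.base_seed + run,
            max_iterations=config.max_iterations,
            tolerance=config.tolerance,
        )
        same = fit.col_assignment[:, None] == fit.col_assignment[None, :]
        counts += same
    return EnsembleCocluster(counts, config.n_runs)


def select_kl(
    matrix,
    k_grid: Sequence[int],
    l_grid: Sequence[int],
    config: EBCConfig | None = None,
    pilot_runs: int = 20,
) -> tuple[int, int]:
    """Choose (K, L) from a grid by ensemble stability.

    For each grid point a small pilot ensemble is run and its co-clustering
    frequencies f scored by mean |f - 0.5| over off-diagonal pairs: a
    configuration whose ensemble keeps confidently co-assigning (or
    separating) the same columns scores high, one whose co-assignments look
    like coin flips scores low.  Returns the maximizing grid point (ties:
    first in ``product(k_grid, l_grid)`` order).
    """
    if not k_grid or not l_grid:
        raise ValueError("k_grid and l_grid must be non-empty")
    base_seed = config.base_seed if config is not None else 0
    best = None
    best_score = -np.inf
    for K, L in product(k_grid, l_grid):
        pilot = EBCConfig(K=K, L=L, n_runs=pilot_runs, base_seed=base_seed)
        ens = run_ensemble(matrix, pilot)
        f = ens.frequencies
        off = ~np.eye(f.shape[0], dtype=bool)
        score = float(np.abs(f[off] - 0.5).mean()) if off.any() else 0.0
        logger.info("select_kl: K=%d L=%d stability=%.4f", K, L, score)
        if score > best_score:
            best, best_score = (K, L), score
    return best
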