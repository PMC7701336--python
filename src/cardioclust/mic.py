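"""Maximal information coefficient (MIC).

MIC measures dependence between two real variables as the maximal normalized
mutual information over all two-dimensional grids whose cell count is bounded
by ``B(n) = n ** alpha``:

    MIC = max over (p, q) with p * q <= B(n) of  I*(p, q) / log2(min(p, q))

where ``I*(p, q)`` is the largest mutual information achievable by any grid
with ``p`` columns and ``q`` rows.  MIC is 0 for independent variables and
tends to 1 for noiseless functional relationships.

Two computation routes are provided:

* ``method="approx"`` — the characteristic-matrix dynamic-programming
  approximation: one axis is equipartitioned, the other is optimized exactly
  by dynamic programming over at most ``c * p`` "superclumps" (runs of points
  merged in sorted order).  This is the standard algorithm for cohort-scale
  data.
* ``method="exact"`` — the global optimum: the axis with fewer bins is
  enumerated exhaustively over all contiguous partitions (cuts are only ever
  placed between distinct values) and the other axis is optimized by the same
  dynamic program, which is exact once no clump merging is applied.  Feasible
  for small n; used by default below ``n = 60``.

Both routes maximize over the two orientations of the grid.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from numba import njit

__all__ = ["mic", "mic_approx", "mic_exact"]


class MICInputError(ValueError):
    """Raised when inputs are unsuitable for MIC estimation."""


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _equipartition(vals_sorted, q):
    """Greedy equipartition of sorted values into up to ``q`` rows.

    Tied values are never split across rows; row sizes adapt so the remaining
    points are spread evenly over the remaining rows.  Returns the per-point
    row assignment (in sorted order).
    """
    n = vals_sorted.shape[0]
    rows = np.zeros(n, np.int64)
    i = 0
    curr_row = 0
    curr_size = 0
    desired = n / q
    while i < n:
        j = i
        while j < n and vals_sorted[j] == vals_sorted[i]:
            j += 1
        s = j - i
        if curr_size != 0 and abs(curr_size + s - desired) >= abs(curr_size - desired):
            curr_row += 1
            curr_size = 0
            rem = q - curr_row
            if rem < 1:
                rem = 1
            desired = (n - i) / rem
        for t in range(i, j):
            rows[t] = curr_row
        curr_size += s
        i = j
    return rows


@njit(cache=True)
def _clump_cumcounts(x_sorted, rows_by_xorder, q, max_clumps):
    """Cumulative per-row counts at clump boundaries along the x axis.

    Points are grouped into clumps: ties in x are inseparable, and maximal
    runs of consecutive points sharing the same row are merged (cutting inside
    such a run is never optimal).  If more than ``max_clumps`` clumps result,
    they are merged into ``max_clumps`` superclumps by size equipartition.

    Returns an (m+1, q) float array of cumulative row counts, where m is the
    number of (super)clumps.
    """
    n = x_sorted.shape[0]
    # clump id per point
    clump_id = np.empty(n, np.int64)
    # first pass: group x-ties, note mixed-row tie groups
    cid = -1
    prev_row = -2  # sentinel: no open clump
    i = 0
    while i < n:
        j = i
        while j < n and x_sorted[j] == x_sorted[i]:
            j += 1
        # row of this tie group, or -1 if mixed
        r = rows_by_xorder[i]
        uniform = True
        for t in range(i + 1, j):
            if rows_by_xorder[t] != r:
                uniform = False
                break
        if uniform and r == prev_row and cid >= 0:
            pass  # extend current clump
        else:
            cid += 1
            prev_row = r if uniform else -2
        if not uniform:
            prev_row = -2  # mixed groups never merge with neighbours
        for t in range(i, j):
            clump_id[t] = cid
        i = j
    n_clumps = cid + 1

    # clump sizes
    sizes = np.zeros(n_clumps, np.int64)
    for t in range(n):
        sizes[clump_id[t]] += 1

    if n_clumps > max_clumps:
        # merge into superclumps: equipartition over clump sizes
        super_of = np.zeros(n_clumps, np.int64)
        curr = 0
        curr_size = 0
        assigned = 0
        desired = n / max_clumps
        for cidx in range(n_clumps):
            s = sizes[cidx]
            if curr_size != 0 and abs(curr_size + s - desired) >= abs(curr_size - desired):
                curr += 1
                curr_size = 0
                rem = max_clumps - curr
                if rem < 1:
                    rem = 1
                desired = (n - assigned) / rem
            super_of[cidx] = curr
            curr_size += s
            assigned += s
        m = curr + 1
        for t in range(n):
            clump_id[t] = super_of[clump_id[t]]
    else:
        m = n_clumps

    cum = np.zeros((m + 1, q), np.float64)
    for t in range(n):
        cum[clump_id[t] + 1, rows_by_xorder[t]] += 1.0
    for b in range(1, m + 1):
        for r in range(q):
            cum[b, r] += cum[b - 1, r]
    return cum


@njit(cache=True)
def _optimize_axis(cum, max_p):
    """Maximize sum over columns of sum_r c_r*log2(c_r/coltot) (= -n*H(rows|cols))
    over contiguous partitions of the clumps into exactly l columns, l=1..max_p.

    ``cum``: (m+1, q) cumulative per-row counts at clump boundaries.
    Returns best[l] for l in 0..max_p (best[0], best[1] are the trivial cases).
    """
    m = cum.shape[0] - 1
    q = cum.shape[1]
    NEG = -1e300

    # cost[s, t]: column score of the slice of clumps (s, t]
    cost = np.zeros((m + 1, m + 1), np.float64)
    for s in range(m + 1):
        for t in range(s + 1, m + 1):
            tot = 0.0
            for r in range(q):
                tot += cum[t, r] - cum[s, r]
            v = 0.0
            if tot > 0.0:
                for r in range(q):
                    c = cum[t, r] - cum[s, r]
                    if c > 0.0:
                        v += c * np.log2(c / tot)
            cost[s, t] = v

    best = np.full(max_p + 1, NEG)
    f_prev = np.full(m + 1, NEG)
    for t in range(1, m + 1):
        f_prev[t] = cost[0, t]
    if max_p >= 1:
        best[1] = f_prev[m]
    f_cur = np.full(m + 1, NEG)
    top = max_p if max_p < m else m
    for l in range(2, top + 1):
        for t in range(l, m + 1):
            bv = NEG
            for s in range(l - 1, t):
                v = f_prev[s] + cost[s, t]
                if v > bv:
                    bv = v
            f_cur[t] = bv
        best[l] = f_cur[m]
        tmp = f_prev
        f_prev = f_cur
        f_cur = tmp
    # partitions into more columns than clumps are impossible; inherit the
    # best achievable value (MI is monotone under refinement anyway)
    for l in range(top + 1, max_p + 1):
        best[l] = best[top]
    return best


@njit(cache=True)
def _entropy_rows(cum):
    """H(rows) in bits from the cumulative count matrix."""
    q = cum.shape[1]
    n = 0.0
    for r in range(q):
        n += cum[cum.shape[0] - 1, r]
    h = 0.0
    for r in range(q):
        c = cum[cum.shape[0] - 1, r]
        if c > 0.0:
            h -= (c / n) * np.log2(c / n)
    return h


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _validate(x, y, alpha):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise MICInputError("x and y must have equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise MICInputError("inputs must be finite")
    n = x.shape[0]
    b = n ** alpha
    if b < 4.0:
        raise MICInputError(f"n={n} too small: B(n)={b:.2f} < 4 admits no 2x2 grid")
    return x, y, n, int(np.floor(b))


def _best_over_grid(cum, q_real, max_p, n):
    """Max over column counts p of normalized MI, given fixed rows."""
    if q_real < 2:
        return 0.0
    h_rows = _entropy_rows(cum)
    best_vals = _optimize_axis(cum, max_p)
    out = 0.0
    for p in range(2, max_p + 1):
        mi = h_rows + best_vals[p] / n
        denom = np.log2(min(p, q_real))
        v = mi / denom
        if v > out:
            out = v
    return out


def mic_approx(x, y, alpha: float = 0.6, c: float = 15.0) -> float:
    """MIC via the equipartition + superclump dynamic-programming heuristic."""
    x, y, n, b = _validate(x, y, alpha)
    best = 0.0
    for a_vals, b_vals in ((x, y), (y, x)):
        # rows on b_vals (equipartitioned), columns on a_vals (optimized)
        order_b = np.argsort(b_vals, kind="mergesort")
        order_a = np.argsort(a_vals, kind="mergesort")
        a_sorted = a_vals[order_a]
        for q in range(2, b // 2 + 1):
            max_p = b // q
            if max_p < 2:
                break
            rows_sorted = _equipartition(b_vals[order_b], q)
            q_real = int(rows_sorted.max()) + 1
            if q_real < 2:
                continue
            rows_by_index = np.empty(n, np.int64)
            rows_by_index[order_b] = rows_sorted
            rows_by_xorder = rows_by_index[order_a]
            max_clumps = max(int(c * max_p), 2 * max_p)
            cum = _clump_cumcounts(a_sorted, rows_by_xorder, q_real, max_clumps)
            val = _best_over_grid(cum, q_real, max_p, n)
            if val > best:
                best = val
    if best < 1e-12:
        best = 0.0
    return float(min(best, 1.0))


def _cut_candidates(vals_sorted) -> np.ndarray:
    """Indices i such that a cut may be placed after point i (value changes)."""
    return np.nonzero(np.diff(vals_sorted) != 0)[0]


def mic_exact(x, y, alpha: float = 0.6) -> float:
    """Globally optimal MIC for small n.

    For each admissible grid shape, all contiguous partitions of the
    fewer-bin axis are enumerated; the other axis is optimized exactly by
    dynamic programming with cuts allowed at every value boundary.
    """
    x, y, n, b = _validate(x, y, alpha)
    best = 0.0
    # q = bins on the enumerated axis, p = bins on the DP-optimized axis;
    # enumerate the smaller side: q <= sqrt(b)
    for a_vals, b_vals in ((x, y), (y, x)):
        order_b = np.argsort(b_vals, kind="mergesort")
        order_a = np.argsort(a_vals, kind="mergesort")
        a_sorted = a_vals[order_a]
        b_sorted = b_vals[order_b]
        cuts = _cut_candidates(b_sorted)
        if len(cuts) == 0:
            continue
        q = 2
        while q * q <= b:
            max_p = b // q
            if max_p < q:
                break
            if len(cuts) >= q - 1:
                rows_by_index = np.empty(n, np.int64)
                for combo in combinations(cuts, q - 1):
                    rows_sorted = np.zeros(n, np.int64)
                    for r, cpos in enumerate(combo):
                        rows_sorted[cpos + 1 :] = r + 1
                    rows_by_index[order_b] = rows_sorted
                    rows_by_xorder = rows_by_index[order_a]
                    cum = _clump_cumcounts(a_sorted, rows_by_xorder, q, n + 1)
                    val = _best_over_grid(cum, q, max_p, n)
                    if val > best:
                        best = val
            q += 1
    if best < 1e-12:  # clamp accumulated floating-point noise
        best = 0.0
    return float(min(best, 1.0))


def mic(x, y, alpha: float = 0.6, c: float = 15.0, method: str = "auto") -> float:
    """Maximal information coefficient of two numeric vectors.

    Parameters
    ----------
    x, y : array-like, equal length n; requires ``n ** alpha >= 4``.
    alpha : grid-size exponent; the grid cell count is bounded by ``n**alpha``.
    c : superclump factor of the approximate search (ignored in exact mode).
    method : "auto" (exact for n <= 60, approximate otherwise), "exact", or
        "approx".
    """
    if method == "auto":
        n = np.asarray(x).size
        method = "exact" if n <= 60 else "approx"
    if method == "exact":
        return mic_exact(x, y, alpha=alpha)
    if method == "approx":
        return mic_approx(x, y, alpha=alpha, c=c)
    raise ValueError(f"unknown method {method!r}")
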