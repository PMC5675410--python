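"""Circular binary segmentation (CBS) of marker-level copy-number values.

The algorithm recursively tests, within each current segment, every circular
arc ``(i, j]`` of the marker sequence for a mean shift between the arc and its
complement, using the max over arcs of the squared mean-shift statistic

    V(i, j) = (D_j - D_i)^2 / (l (n - l)),        l = j - i,

where ``D`` is the prefix sum of mean-centered values. ``V`` is a monotone
transform of the usual two-sample t statistic when the variance is estimated
globally, and the permutation test below is invariant to that scaling.
Significance of the best arc is assessed by permuting the marker values within
the segment and comparing the permuted maxima against the observed maximum;
the split is accepted when the permutation p-value ``(1 + k) / (1 + m)`` falls
below ``alpha``.

Two accelerations keep genome-scale use tractable without changing decisions
for clearly significant or clearly null splits:

* sequential stopping: permutation stops as soon as the exceedance count
  guarantees p >= alpha (early rejection, decision-identical to the full
  test), and stops accepting once ``n_perm_cap`` permutations have produced
  few enough exceedances that the p-value bound is already below ``alpha``;
* a dyadic prefix-sum bound certifies in O(n log n) per permutation that no
  arc of the shuffled sequence can reach the observed maximum, skipping the
  O(n^2) scan for strong splits.

No split-undo/pruning pass is applied after segmentation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["segment_values", "max_arc_statistic"]


@njit(cache=True)
def _max_arc(D, n, min_width, inv):
    """Max of V(i, j) over arcs with min_width <= l <= n - min_width."""
    best = -1.0
    bi = -1
    bj = -1
    for i in range(0, n - min_width + 1):
        di = D[i]
        for j in range(i + min_width, n + 1):
            l = j - i
            if l > n - min_width:
                break
            d = D[j] - di
            v = d * d * inv[l]
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _any_arc_exceeds(D, n, min_width, inv, threshold):
    """1 if some arc reaches ``threshold``; scans with early exit."""
    for i in range(0, n - min_width + 1):
        di = D[i]
        for j in range(i + min_width, n + 1):
            l = j - i
            if l > n - min_width:
                break
            d = D[j] - di
            if d * d * inv[l] >= threshold:
                return 1
    return 0


@njit(cache=True)
def _dyadic_bound(D, n, min_width, inv):
    """Upper bound on the max arc statistic, O(n log n).

    Any arc of length l has |D_j - D_i| bounded by the prefix-sum range over
    index windows of extent <= l; block maxima/minima at dyadic scales bound
    that range for every l in [L/2, L).
    """
    bound = 0.0
    L = 2 * min_width
    while L // 2 <= n - min_width:
        lo = max(L // 2, min_width)
        hi = min(L - 1, n - min_width)
        if lo <= hi:
            # inv is u-shaped in l: extremes dominate
            inv_max = inv[lo] if inv[lo] > inv[hi] else inv[hi]
            # block max/min of D with block size L; a window of extent <= L
            # spans at most two consecutive blocks
            nb = (n + 1 + L - 1) // L
            m2 = 0.0
            prev_max = -1e300
            prev_min = 1e300
            for b in range(nb):
                s = b * L
                e = min(s + L, n + 1)
                bmax = -1e300
                bmin = 1e300
                for k in range(s, e):
                    if D[k] > bmax:
                        bmax = D[k]
                    if D[k] < bmin:
                        bmin = D[k]
                if b > 0:
                    pair_max = bmax if bmax > prev_max else prev_max
                    pair_min = bmin if bmin < prev_min else prev_min
                    r = pair_max - pair_min
                    if r > m2:
                        m2 = r
                else:
                    r = bmax - bmin
                    if r > m2:
                        m2 = r
                prev_max = bmax
                prev_min = bmin
            v = m2 * m2 * inv_max
            if v > bound:
                bound = v
        L *= 2
    return bound


def _prefix(values: np.ndarray) -> np.ndarray:
    d = values - values.mean()
    D = np.empty(values.size + 1)
    D[0] = 0.0
    np.cumsum(d, out=D[1:])
    return D


def max_arc_statistic(values: np.ndarray, min_width: int = 2):
    """Best circular arc of ``values``: returns ``(stat, i, j)``.

    The arc is ``values[i:j]``; its complement is the circular remainder.
    Exposed mainly for exhaustive-oracle testing.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2 * min_width:
        return 0.0, -1, -1
    inv = np.zeros(n + 1)
    ls = np.arange(1, n)
    inv[1:n] = 1.0 / (ls * (n - ls))
    return _max_arc(_prefix(values), n, min_width, inv)


def _perm_pvalue(values, obs, min_width, inv, alpha, n_perm, n_perm_cap, rng):
    """Sequential permutation p-value for the observed max arc statistic.

    The split decision is made at a budget of M = min(n_perm, n_perm_cap)
    permutations: the split is significant iff the Monte-Carlo p-value
    (1 + k) / (1 + M) would fall below alpha, i.e. iff the exceedance count
    k stays at or below k_accept = ceil(alpha (M + 1)) - 2.  Permutation
    stops as soon as k exceeds that bound (early rejection, decision-
    identical to running all M permutations).  Returns the p-value at the
    stopping point; its resolution is 1 / (M + 1).
    """
    n = values.size
    d = values - values.mean()
    M = min(n_perm, n_perm_cap)
    # largest k with (1 + k) / (1 + M) < alpha
    k_accept = int(np.ceil(alpha * (M + 1))) - 2
    k = 0
    m = 0
    shuffled = d.copy()
    D = np.empty(n + 1)
    while m < M:
        rng.shuffle(shuffled)
        D[0] = 0.0
        np.cumsum(shuffled, out=D[1:])
        if _dyadic_bound(D, n, min_width, inv) >= obs:
            k += _any_arc_exceeds(D, n, min_width, inv, obs)
        m += 1
        if k > k_accept:
            return (1.0 + k) / (1.0 + m)  # cannot reach p < alpha at M
    return (1.0 + k) / (1.0 + M)


def segment_values(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    min_width: int = 2,
    seed: int | np.random.Generator | None = 0,
    n_perm_cap: int = 199,
) -> list[tuple[int, int, float]]:
    """Segment one chromosome's ordered marker values.

    Parameters
    ----------
    values : 1-D array of marker-level copy numbers, in genomic order.
    alpha : significance level for accepting a split.
    n_perm : maximum number of permutations per tested split.
    min_width : minimum markers in an arc and its complement.
    seed : int seed or a ``numpy.random.Generator``.
    n_perm_cap : permutation count at which an apparently significant split
        is accepted early; the attainable p-value resolution is
        ``1 / (n_perm_cap + 1)`` and must be below ``alpha``.

    Returns
    -------
    list of ``(start_index, end_index_exclusive, mean)`` tiling ``values``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if 1.0 / (min(n_perm, n_perm_cap) + 1) >= alpha:
        raise ValueError(
            "permutation resolution 1/(min(n_perm, n_perm_cap)+1) must be "
            "finer than alpha"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = values.size
    out: list[tuple[int, int, float]] = []
    stack = [(0, n)]
    while stack:
        s, e = stack.pop()
        seg = values[s:e]
        m = e - s
        split = None
        if m >= 2 * min_width and np.ptp(seg) > 0:
            inv = np.zeros(m + 1)
            ls = np.arange(1, m)
            inv[1:m] = 1.0 / (ls * (m - ls))
            obs, i, j = _max_arc(_prefix(seg), m, min_width, inv)
            if obs > 0:
                p = _perm_pvalue(seg, obs, min_width, inv, alpha, n_perm,
                                 n_perm_cap, rng)
                if p < alpha:
                    split = (i, j)
        if split is None:
            out.append((s, e, float(seg.mean())))
        else:
            i, j = split
            pieces = []
            if i > 0:
                pieces.append((s, s + i))
            pieces.append((s + i, s + j))
            if j < m:
                pieces.append((s + j, e))
            # LIFO: push in reverse so left-most piece is processed first
            for piece in reversed(pieces):
                stack.append(piece)
    out.sort()
    return out
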