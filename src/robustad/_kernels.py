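"""Compiled inner loops for the rank-based scores.

Each stratum (diagonal) k of the contact matrix is compared against flank
entries at the same genomic distance.  The kernels sort each flank once and
count threshold crossings with binary search — O(n log n) per stratum —
instead of enumerating all inside x flank pairs.  The all-pairs reference
implementations live in :mod:`robustad.reference` and must agree exactly.

Comparisons use the multiplicative forms ``m_in > gamma * m_out`` and
``gamma * m_in < m_out`` so that fast path and reference share identical
float semantics.
"""

import numpy as np
from numba import njit

MODE_BOTH = 0
MODE_LEFT = 1
MODE_RIGHT = 2


@njit(cache=False)
def _count_below(f, m, gamma, x):
    """#(gamma * f[i] < x) for sorted f[:m]."""
    lo, hi = 0, m
    while lo < hi:
        mid = (lo + hi) // 2
        if gamma * f[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=False)
def _count_above(f, m, x):
    """#(f[i] > x) for sorted f[:m]."""
    lo, hi = 0, m
    while lo < hi:
        mid = (lo + hi) // 2
        if f[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return m - lo


@njit(cache=False)
def interval_stratum_scores(M, a, b, gamma, excl, mode):
    """Per-stratum rank scores S^k for interval [a, b], k = 1..b-a.

    mode: 0 both flanks (TAD score), 1 left flank only, 2 right flank only.
    excl: (m, 2) int64 array of inclusive sub-intervals whose internal pairs
    are excluded (a pair (i, i+k) is excluded iff both ends lie in a region).
    Out-of-range or NaN entries are skipped; empty comparisons give 0.
    """
    n = M.shape[0]
    span = b - a
    out = np.zeros(span)
    fbuf = np.empty(2 * span + 2)
    for k in range(1, span + 1):
        m = 0
        if mode != MODE_RIGHT:  # left flank: pairs (i, i+k), a-k <= i <= a-1
            lo = a - k
            if lo < 0:
                lo = 0
            for i in range(lo, a):
                if i + k <= n - 1:
                    v = M[i, i + k]
                    if not np.isnan(v):
                        fbuf[m] = v
                        m += 1
        if mode != MODE_LEFT:  # right flank: pairs (i, i+k), b-k+1 <= i <= b
            lo = b - k + 1
            if lo < 0:
                lo = 0
            for i in range(lo, b + 1):
                if i + k <= n - 1:
                    v = M[i, i + k]
                    if not np.isnan(v):
                        fbuf[m] = v
                        m += 1
        if m == 0:
            continue
        f = np.sort(fbuf[:m])
        num = 0
        den = 0
        for i in range(a, b - k + 1):
            if i < 0 or i + k > n - 1:
                continue
            v = M[i, i + k]
            if np.isnan(v):
                continue
            skip = False
            for e in range(excl.shape[0]):
                if i >= excl[e, 0] and i + k <= excl[e, 1]:
                    skip = True
                    break
            if skip:
                continue
            gt = _count_below(f, m, gamma, v)
            lt = _count_above(f, m, gamma * v)
            num += gt - lt
            den += gt + lt
        if den > 0:
            out[k - 1] = num / den
    return out


@njit(cache=False)
def interval_base_counts(M, a, b, gamma):
    """Per-stratum, per-entry comparison counts for [a, b], no exclusions.

    For each stratum k the both-flank array is sorted once and every inside
    entry's decisive-comparison counts (gt - lt, gt + lt) are accumulated
    into prefix sums over the inside index, so any contiguous run of inside
    entries can later be removed in O(1).  Returns (cum_num, cum_den, offs):
    stratum k's prefix sums live at ``cum[offs[k-1] : offs[k]]`` with length
    (#inside entries + 1); entries that are missing or out of range
    contribute zero.
    """
    n = M.shape[0]
    span = b - a
    fbuf = np.empty(2 * span + 2)
    total = 0
    for k in range(1, span + 1):
        total += span - k + 2
    cum_num = np.zeros(total, dtype=np.int64)
    cum_den = np.zeros(total, dtype=np.int64)
    offs = np.zeros(span + 1, dtype=np.int64)
    pos = 0
    for k in range(1, span + 1):
        offs[k - 1] = pos
        m = 0
        lo = a - k
        if lo < 0:
            lo = 0
        for i in range(lo, a):
            if i + k <= n - 1:
                v = M[i, i + k]
                if not np.isnan(v):
                    fbuf[m] = v
                    m += 1
        lo = b - k + 1
        if lo < 0:
            lo = 0
        for i in range(lo, b + 1):
            if i + k <= n - 1:
                v = M[i, i + k]
                if not np.isnan(v):
                    fbuf[m] = v
                    m += 1
        f = np.sort(fbuf[:m])
        cum_num[pos] = 0
        cum_den[pos] = 0
        for ri in range(span - k + 1):  # inside entry (a+ri, a+ri+k)
            i = a + ri
            dnum = 0
            dden = 0
            if m > 0 and i >= 0 and i + k <= n - 1:
                v = M[i, i + k]
                if not np.isnan(v):
                    gt = _count_below(f, m, gamma, v)
                    lt = _count_above(f, m, gamma * v)
                    dnum = gt - lt
                    dden = gt + lt
            cum_num[pos + ri + 1] = cum_num[pos + ri] + dnum
            cum_den[pos + ri + 1] = cum_den[pos + ri] + dden
        pos += span - k + 2
    offs[span] = pos
    return cum_num, cum_den, offs


@njit(cache=False)
def counts_minus_exclusions(a, b, cum_num, cum_den, offs, excl):
    """Stratum scores of [a, b] after removing excluded inside entries.

    excl holds maximal inclusive sub-intervals, pairwise non-overlapping
    except possibly at shared endpoint bins; an inside pair (i, i+k) is
    removed iff both ends fall in one region.  Prefix-sum subtraction makes
    each variant O(strata x regions) and bit-identical to a direct scan.
    """
    span = b - a
    out = np.zeros(span)
    for k in range(1, span + 1):
        base = offs[k - 1]
        last = span - k + 1
        nm = cum_num[base + last]
        dn = cum_den[base + last]
        for e in range(excl.shape[0]):
            lo = excl[e, 0] - a
            if lo < 0:
                lo = 0
            hi = excl[e, 1] - k - a
            if hi > last - 1:
                hi = last - 1
            if hi >= lo:
                nm -= cum_num[base + hi + 1] - cum_num[base + lo]
                dn -= cum_den[base + hi + 1] - cum_den[base + lo]
        if dn > 0:
            out[k - 1] = nm / dn
    return out


@njit(cache=False)
def boundary_tracks(M, gamma, wmin, wmax):
    """Left and right boundary score tracks L_a, R_b for every bin.

    L_a = max over w in [wmin, wmax] of the left boundary score of [a, a+w];
    R_b symmetric over [b-w, b].  Returns (L, R) arrays of length n.
    """
    n = M.shape[0]
    L = np.zeros(n)
    R = np.zeros(n)
    sc = np.empty((wmax + 1, wmax + 1))
    fbuf = np.empty(wmax + 1)
    for a in range(n):
        # left boundary at a: flank strata are pairs crossing the a-edge
        for k in range(1, wmax + 1):
            m = 0
            lo = a - k
            if lo < 0:
                lo = 0
            for i in range(lo, a):
                if i + k <= n - 1:
                    v = M[i, i + k]
                    if not np.isnan(v):
                        fbuf[m] = v
                        m += 1
            f = np.sort(fbuf[:m])
            num = 0
            den = 0
            for w in range(k, wmax + 1):
                i = a + w - k  # inside entry added when the window grows to w
                if m > 0 and i + k <= n - 1:
                    v = M[i, i + k]
                    if not np.isnan(v):
                        gt = _count_below(f, m, gamma, v)
                        lt = _count_above(f, m, gamma * v)
                        num += gt - lt
                        den += gt + lt
                sc[k, w] = num / den if den > 0 else 0.0
        best = -2.0
        for w in range(wmin, wmax + 1):
            tot = 0.0
            for k in range(1, w + 1):
                tot += sc[k, w]
            val = tot / w
            if val > best:
                best = val
        L[a] = best

        b = a
        # right boundary at b: flank strata cross the b-edge
        for k in range(1, wmax + 1):
            m = 0
            lo = b - k + 1
            if lo < 0:
                lo = 0
            for i in range(lo, b + 1):
                if i + k <= n - 1:
                    v = M[i, i + k]
                    if not np.isnan(v):
                        fbuf[m] = v
                        m += 1
            f = np.sort(fbuf[:m])
            num = 0
            den = 0
            for w in range(k, wmax + 1):
                i = b - w  # inside entry added when the window grows to w
                if m > 0 and i >= 0 and i + k <= n - 1:
                    v = M[i, i + k]
                    if not np.isnan(v):
                        gt = _count_below(f, m, gamma, v)
                        lt = _count_above(f, m, gamma * v)
                        num += gt - lt
                        den += gt + lt
                sc[k, w] = num / den if den > 0 else 0.0
        best = -2.0
        for w in range(wmin, wmax + 1):
            tot = 0.0
            for k in range(1, w + 1):
                tot += sc[k, w]
            val = tot / w
            if val > best:
                best = val
        R[b] = best
    return L, R
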