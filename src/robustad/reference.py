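"""All-pairs reference implementations of the rank scores.

These materialize the full inside x flank comparison matrix per stratum
(numpy broadcasting; no sorting, no binary search, no prefix sums) and
exist solely to validate the fast kernels in :mod:`robustad._kernels`.
They share the float comparison semantics (``m_in > gamma * m_out``,
``gamma * m_in < m_out``) but nothing else.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "stratum_score_allpairs",
    "tad_score_allpairs",
    "boundary_score_allpairs",
    "boundary_tracks_allpairs",
]


def _entries(M, lo, hi, k):
    """Non-missing entries m[i, i+k] for lo <= i <= hi, clipped in range."""
    n = M.shape[0]
    vals = [M[i, i + k] for i in range(max(lo, 0), min(hi, n - 1 - k) + 1)]
    return np.array([v for v in vals if np.isfinite(v)])


def _counts(inside, flank, gamma):
    """(signed, total) decisive comparison counts of inside x flank."""
    if len(inside) == 0 or len(flank) == 0:
        return 0, 0
    gt = inside[:, None] > gamma * flank[None, :]
    lt = gamma * inside[:, None] < flank[None, :]
    return int(gt.sum()) - int(lt.sum()), int(gt.sum()) + int(lt.sum())


def _inside(M, a, b, k, excl):
    n = M.shape[0]
    vals = []
    for i in range(max(a, 0), min(b - k, n - 1 - k) + 1):
        v = M[i, i + k]
        if not np.isfinite(v):
            continue
        if any(i >= ea and i + k <= eb for ea, eb in excl):
            continue
        vals.append(v)
    return np.array(vals)


def _stratum_counts(M, a, b, k, gamma, excl):
    inside = _inside(M, a, b, k, excl)
    left = _entries(M, a - k, a - 1, k)
    right = _entries(M, b - k + 1, b, k)
    nl, dl = _counts(inside, left, gamma)
    nr, dr = _counts(inside, right, gamma)
    return nl, dl, nr, dr


def stratum_score_allpairs(M, a, b, k, gamma=1.0, side="both", excl=()):
    nl, dl, nr, dr = _stratum_counts(M, a, b, k, gamma, excl)
    if side == "left":
        num, den = nl, dl
    elif side == "right":
        num, den = nr, dr
    else:
        num, den = nl + nr, dl + dr
    return num / den if den else 0.0


def tad_score_allpairs(M, a, b, gamma=1.0, excl=()):
    span = b - a
    tot = 0.0
    for k in range(1, span + 1):
        tot += (span + k + 1) * stratum_score_allpairs(M, a, b, k, gamma, "both", excl)
    return tot * 2.0 / (3.0 * (1 + span) * span)


def boundary_score_allpairs(M, a, b, side, gamma=1.0):
    span = b - a
    return sum(
        stratum_score_allpairs(M, a, b, k, gamma, side) for k in range(1, span + 1)
    ) / span


def all_interval_scores_allpairs(M, a, b, gamma=1.0, excl=()):
    """(S, S_left, S_right) of [a, b] in one stratum sweep."""
    span = b - a
    tot = wl = wr = 0.0
    for k in range(1, span + 1):
        nl, dl, nr, dr = _stratum_counts(M, a, b, k, gamma, excl)
        if dl + dr:
            tot += (span + k + 1) * (nl + nr) / (dl + dr)
        if dl:
            wl += nl / dl
        if dr:
            wr += nr / dr
    return (
        tot * 2.0 / (3.0 * (1 + span) * span),
        wl / span,
        wr / span,
    )


def boundary_tracks_allpairs(M, gamma=1.0, w_min=10, w_max=50):
    """Brute-force L/R tracks: max over windows of the one-sided scores."""
    n = M.shape[0]
    L = np.zeros(n)
    R = np.zeros(n)
    for p in range(n):
        L[p] = max(
            boundary_score_allpairs(M, p, p + w, "left", gamma)
            for w in range(w_min, w_max + 1)
        )
        R[p] = max(
            boundary_score_allpairs(M, p - w, p, "right", gamma)
            for w in range(w_min, w_max + 1)
        )
    return L, R
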