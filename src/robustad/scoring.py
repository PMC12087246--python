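"""Nonparametric boundary and TAD scores.

The central statistic is a distance-stratified (diagonal-wise) rank-sum
comparison between interactions inside a candidate domain [a, b] and
interactions crossing its boundaries at the same genomic distance.  For
stratum k the inside entries are D_k(a, b) = {(i, i+k): a <= i, i+k <= b};
the left flank is D_k(a-k, a+k-1) and the right flank D_k(b-k+1, b+k) — the
pairs at distance k that straddle the a- or b-edge.  The stratum score is

    S^k = (#(m_in > g*m_out) - #(g*m_in < m_out)) /
          (#(m_in > g*m_out) + #(g*m_in < m_out))

over all inside x flank pairs, where the fold-gap g >= 1 widens the tie
band; g = 1 reduces to a Wilcoxon-style comparison.  S^k is +1 when every
inside interaction beats every flank interaction by at least a factor g, -1
in the mirrored case, and 0 when no comparison is decisive (denominator 0).

The TAD score weights strata by the entry count b-a+k+1 used on diagonal k:

    S_[a,b] = 2 / (3 (1+b-a)(b-a)) * sum_k (b-a+k+1) S^k

Boundary scores S^L / S^R use only the corresponding flank as background and
average strata uniformly.  Comparisons involving missing (NaN) or
out-of-range entries are skipped; pairs falling entirely inside an excluded
sub-domain (both ends within one exclusion region) are removed from the
inside set, so a strong nested sub-TAD does not inflate its parent's score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .contact_io import ContactMap

__all__ = [
    "ScoreParams",
    "ExclusionSet",
    "stratum_tad_score",
    "stratum_entry_count",
    "tad_score",
    "boundary_stratum_scores",
    "boundary_score",
    "MIN_TAD_SPAN",
]

#: smallest valid TAD spans 3 bins inclusive, i.e. b - a >= 2
MIN_TAD_SPAN = 2

_SIDES = {"left": _kernels.MODE_LEFT, "right": _kernels.MODE_RIGHT}
_EMPTY_EXCL = np.empty((0, 2), dtype=np.int64)


@dataclass(frozen=True)
class ScoreParams:
    """Scoring parameters.

    gamma : minimum fold-gap between inside and flank interactions for a
        comparison to count (>= 1; 1 = plain rank comparison).
    w_min, w_max : window range in bins over which boundary scores are
        maximized (defaults 10 and 50, i.e. 50-250 kb at 5 kb resolution).
    """

    gamma: float = 1.0
    w_min: int = 10
    w_max: int = 50

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if not (1 <= self.w_min <= self.w_max):
            raise ValueError("need 1 <= w_min <= w_max")


@dataclass(frozen=True)
class ExclusionSet:
    """Inclusive bin intervals of already-fixed nested sub-TADs.

    Intervals must be pairwise non-crossing (nested or disjoint).  An inside
    pair (i, j) is excluded iff both i and j lie within one region; flank
    entries are never excluded.
    """

    regions: tuple = field(default=())

    def __post_init__(self) -> None:
        regs = tuple(sorted((int(a), int(b)) for a, b in self.regions))
        for a, b in regs:
            if b < a:
                raise ValueError(f"invalid exclusion region ({a}, {b})")
        # adjacent sub-TADs may share a single boundary bin; only genuine
        # partial overlaps (two or more shared bins) are rejected
        for (a1, b1), (a2, b2) in zip(regs, regs[1:]):
            if a1 < a2 < b1 < b2:
                raise ValueError("crossing exclusion regions")
        object.__setattr__(self, "regions", regs)

    def as_array(self) -> np.ndarray:
        if not self.regions:
            return _EMPTY_EXCL
        return np.asarray(self.regions, dtype=np.int64).reshape(-1, 2)


def _check_interval(a: int, b: int) -> None:
    if a >= b:
        raise ValueError(f"need a < b, got a={a}, b={b}")


def _check_stratum(a: int, b: int, k: int) -> None:
    if not 1 <= k <= b - a:
        raise ValueError(f"stratum k={k} out of range 1..{b - a}")


def stratum_tad_score(
    cmap: ContactMap,
    a: int,
    b: int,
    k: int,
    params: ScoreParams = ScoreParams(),
    excl: ExclusionSet | None = None,
) -> float:
    """Stratum-k TAD score of [a, b] against both flanks; in [-1, 1]."""
    _check_interval(a, b)
    _check_stratum(a, b, k)
    earr = excl.as_array() if excl is not None else _EMPTY_EXCL
    sk = _kernels.interval_stratum_scores(
        cmap.values, a, b, params.gamma, earr, _kernels.MODE_BOTH
    )
    return float(sk[k - 1])


def stratum_entry_count(a: int, b: int, k: int) -> int:
    """Nominal entry count on diagonal k: (b-a-k+1) inside + 2k flank."""
    _check_interval(a, b)
    _check_stratum(a, b, k)
    return b - a + k + 1


def tad_score(
    cmap: ContactMap,
    a: int,
    b: int,
    params: ScoreParams = ScoreParams(),
    excl: ExclusionSet | None = None,
) -> float:
    """Weighted per-stratum TAD score S_[a,b] in [-1, 1]."""
    _check_interval(a, b)
    span = b - a
    if span < MIN_TAD_SPAN:
        raise ValueError(f"TAD [{a}, {b}] spans fewer than 3 bins")
    earr = excl.as_array() if excl is not None else _EMPTY_EXCL
    sk = _kernels.interval_stratum_scores(
        cmap.values, a, b, params.gamma, earr, _kernels.MODE_BOTH
    )
    k = np.arange(1, span + 1)
    return float(np.sum((span + k + 1) * sk) * 2.0 / (3.0 * (1 + span) * span))


def boundary_stratum_scores(
    cmap: ContactMap,
    a: int,
    b: int,
    k: int,
    side: str,
    params: ScoreParams = ScoreParams(),
    return_defined: bool = False,
):
    """Stratum-k boundary score with only the chosen flank as background.

    With ``return_defined=True`` also reports whether the flank had any
    usable entries (False at chromosome edges, where the score defaults 0).
    """
    _check_interval(a, b)
    _check_stratum(a, b, k)
    mode = _SIDES[side]
    sk = _kernels.interval_stratum_scores(
        cmap.values, a, b, params.gamma, _EMPTY_EXCL, mode
    )
    score = float(sk[k - 1])
    if not return_defined:
        return score
    n = cmap.n_bins
    if side == "left":
        idx = [i for i in range(max(a - k, 0), a) if i + k <= n - 1]
    else:
        idx = [i for i in range(max(b - k + 1, 0), b + 1) if i + k <= n - 1]
    defined = any(np.isfinite(cmap.values[i, i + k]) for i in idx)
    return score, defined


def boundary_score(
    cmap: ContactMap,
    a: int,
    b: int,
    side: str,
    params: ScoreParams = ScoreParams(),
) -> float:
    """One-sided boundary score: unweighted mean of strata k = 1..b-a."""
    _check_interval(a, b)
    mode = _SIDES[side]
    sk = _kernels.interval_stratum_scores(
        cmap.values, a, b, params.gamma, _EMPTY_EXCL, mode
    )
    return float(np.mean(sk))
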