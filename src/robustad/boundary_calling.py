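"""FDR-controlled boundary calling from score tracks.

A left boundary score L_a = max_w S^L_[a, a+w] is computed for every bin
(and symmetrically R_b over [b-w, b]); local maxima of the tracks, at least
``min_separation`` bins apart, form the candidate set.  Significance is
assessed against a decoy contact map obtained by shuffling each diagonal's
values in place: the shuffle destroys domains while preserving the
distance-decay profile exactly, so candidate scores from the decoy estimate
the null.  Candidates are accepted at a target-decoy FDR level alpha.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from . import _kernels
from .contact_io import ContactMap
from .scoring import ScoreParams

__all__ = [
    "BoundaryTrack",
    "BoundaryCall",
    "compute_boundary_track",
    "find_candidate_peaks",
    "make_decoy",
    "fdr_select",
    "auto_alpha",
    "call_boundaries",
]

#: minimum distance between two domain boundaries, in bins (25 kb at 5 kb)
DEFAULT_MIN_SEPARATION = 5

#: read-depth cutoff separating the two default FDR levels
_DEPTH_CUTOFF = 300_000_000


@dataclass
class BoundaryTrack:
    """Per-bin left (L_a) and right (R_b) boundary scores for one sample."""

    chrom: str
    resolution: int
    left_scores: np.ndarray
    right_scores: np.ndarray
    params: ScoreParams

    @property
    def n_bins(self) -> int:
        return len(self.left_scores)

    def side(self, side: str) -> np.ndarray:
        return self.left_scores if side == "left" else self.right_scores


@dataclass
class BoundaryCall:
    """A candidate or accepted boundary position."""

    bin: int
    side: str
    score: float
    passed_fdr: bool = False
    q_estimate: float = 1.0


def compute_boundary_track(cmap: ContactMap, params: ScoreParams = ScoreParams()) -> BoundaryTrack:
    """Boundary score tracks maximized over windows w_min..w_max."""
    if cmap.n_bins <= params.w_min:
        raise ValueError(
            f"map has {cmap.n_bins} bins; need more than w_min={params.w_min}"
        )
    if params.w_max >= cmap.n_bins:
        raise ValueError("w_max must be smaller than the number of bins")
    L, R = _kernels.boundary_tracks(
        cmap.values, params.gamma, params.w_min, params.w_max
    )
    return BoundaryTrack(cmap.chrom, cmap.resolution, L, R, params)


def find_candidate_peaks(
    track: BoundaryTrack,
    side: str,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list[BoundaryCall]:
    """Local maxima of one score track, >= min_separation bins apart.

    Plateaus resolve to their leftmost bin; among conflicting peaks the
    higher one is kept (greedy suppression by height).
    """
    x = np.asarray(track.side(side), dtype=np.float64)
    peaks, props = find_peaks(x, distance=min_separation, plateau_size=1)
    pos = props["left_edges"]
    return [BoundaryCall(bin=int(p), side=side, score=float(x[p])) for p in pos]


def make_decoy(cmap: ContactMap, max_diagonal: int | None = None, seed: int = 0) -> ContactMap:
    """Diagonal-wise shuffled decoy map.

    Each diagonal k = 1..max_diagonal keeps its multiset of non-missing
    values but permutes their positions uniformly at random; symmetry is
    preserved.  Deeper diagonals (unused by scoring) are left untouched.
    """
    n = cmap.n_bins
    if max_diagonal is None:
        max_diagonal = n - 1
    max_diagonal = min(max_diagonal, n - 1)
    rng = np.random.default_rng(seed)
    v = cmap.values.copy()
    for k in range(1, max_diagonal + 1):
        idx = np.arange(n - k)
        d = v[idx, idx + k]
        ok = np.isfinite(d)
        vals = d[ok]
        perm = rng.permutation(len(vals))
        d[ok] = vals[perm]
        v[idx, idx + k] = d
        v[idx + k, idx] = d
    return ContactMap(
        chrom=cmap.chrom,
        resolution=cmap.resolution,
        values=v,
        depth_hint=cmap.depth_hint,
    )


def fdr_select(
    target_calls: list[BoundaryCall],
    decoy_calls: list[BoundaryCall],
    alpha: float,
) -> list[BoundaryCall]:
    """Accept target calls at target-decoy FDR <= alpha.

    FDR(t) = #{decoy >= t} / max(1, #{target >= t}); a call with score s is
    accepted iff some threshold t <= s has FDR(t) <= alpha, and carries
    q_estimate = min_{t <= s} FDR(t) (monotone q-value smoothing).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if not target_calls:
        return []
    tscores = np.array([c.score for c in target_calls])
    dscores = np.array([c.score for c in decoy_calls]) if decoy_calls else np.empty(0)
    order = np.argsort(-tscores)  # descending
    sorted_scores = tscores[order]
    n_target = np.arange(1, len(sorted_scores) + 1)
    if len(dscores):
        ds_asc = np.sort(dscores)
        n_decoy = len(ds_asc) - np.searchsorted(ds_asc, sorted_scores, side="left")
    else:
        n_decoy = np.zeros(len(sorted_scores))
    fdr = n_decoy / np.maximum(1, n_target)
    # q(s) = min FDR over thresholds t <= s (suffix minimum in score order):
    # the best FDR among accepting sets that include the call
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    accepted: list[BoundaryCall] = []
    for rank, oi in enumerate(order):
        call = target_calls[oi]
        call.q_estimate = float(q[rank])
        call.passed_fdr = bool(q[rank] <= alpha)
        if call.passed_fdr:
            accepted.append(call)
    return sorted(accepted, key=lambda c: c.bin)


def auto_alpha(depth_hint: int | None) -> float:
    """Default FDR level by depth: 0.05 above 300M valid pairs, else 0.1."""
    if depth_hint is not None and depth_hint > _DEPTH_CUTOFF:
        return 0.05
    return 0.1


def call_boundaries(
    cmap: ContactMap,
    params: ScoreParams = ScoreParams(),
    alpha: float | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    seed: int = 13,
    max_decoy_diagonal: int | None = None,
):
    """Full single-sample boundary calling: track -> peaks -> decoy FDR.

    Returns (track, accepted_left, accepted_right).  The decoy is shuffled
    up to 3 * w_max diagonals by default (deeper strata are never scored)
    and seeded from ``seed`` plus the chromosome name.
    """
    if alpha is None:
        alpha = auto_alpha(cmap.depth_hint)
    if max_decoy_diagonal is None:
        max_decoy_diagonal = 3 * params.w_max
    decoy_seed = (seed + zlib.crc32(cmap.chrom.encode()) % 100_000) % (2**31)
    decoy = make_decoy(cmap, max_diagonal=max_decoy_diagonal, seed=decoy_seed)
    track = compute_boundary_track(cmap, params)
    decoy_track = compute_boundary_track(decoy, params)
    accepted = {}
    for side in ("left", "right"):
        target = find_candidate_peaks(track, side, min_separation)
        background = find_candidate_peaks(decoy_track, side, min_separation)
        accepted[side] = fdr_select(target, background, alpha)
    return track, accepted["left"], accepted["right"]
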