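"""Comparison metrics for TAD partitions and boundary sets.

The Measure of Concordance (MoC) compares two partitions of a chromosome
into disjoint domains (innermost, level-0 TADs only, since the metric does
not handle overlaps).  For partitions P = {P_i}, Q = {Q_j} with N_P, N_Q
domains and F_ij the overlap of P_i with Q_j (lengths in bins):

    MoC(P, Q) = 1                                     if N_P = N_Q = 1
              = (sum_ij |F_ij|^2 / (|P_i| |Q_j|) - 1) / (sqrt(N_P N_Q) - 1)

ranging from 0 (no concordance) to 1 (identical partitions).  The literal
formula can go slightly negative for overlap-free partitions; the returned
value is clamped to [0, 1] with the raw value available on request.

Boundary similarity uses a tolerance-aware Jaccard index: boundaries are
matched greedily by distance (side-respecting, each used at most once)
within +/- tol bins, and J = matched / (|A| + |B| - matched).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Partition", "moc", "boundary_jaccard", "boundary_recall"]


@dataclass
class Partition:
    """Disjoint inclusive bin intervals (innermost TADs) on one chromosome."""

    tads: list[tuple[int, int]]

    def __post_init__(self) -> None:
        tads = sorted((int(a), int(b)) for a, b in self.tads)
        for a, b in tads:
            if b < a:
                raise ValueError(f"invalid interval ({a}, {b})")
        for (_, b1), (a2, _) in zip(tads, tads[1:]):
            if a2 <= b1:
                raise ValueError("overlapping intervals in partition")
        self.tads = tads

    @property
    def n(self) -> int:
        return len(self.tads)


def moc(P: Partition, Q: Partition, clamp: bool = True) -> float:
    """Measure of Concordance between two disjoint TAD partitions."""
    if P.n == 0 or Q.n == 0:
        raise ValueError("partitions must be non-empty")
    if P.n == 1 and Q.n == 1:
        return 1.0
    total = 0.0
    for a1, b1 in P.tads:
        for a2, b2 in Q.tads:
            ov = min(b1, b2) - max(a1, a2) + 1
            if ov > 0:
                total += ov * ov / ((b1 - a1 + 1) * (b2 - a2 + 1))
    raw = (total - 1.0) / (np.sqrt(P.n * Q.n) - 1.0)
    if not clamp:
        return float(raw)
    return float(min(1.0, max(0.0, raw)))


def _greedy_match(a_pos: np.ndarray, b_pos: np.ndarray, tol: int) -> int:
    """Greedy nearest-pair matching within +/- tol; each position used once."""
    pairs = [
        (abs(int(x) - int(y)), i, j)
        for i, x in enumerate(a_pos)
        for j, y in enumerate(b_pos)
        if abs(int(x) - int(y)) <= tol
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            matched += 1
    return matched


def _split_sides(records):
    """Accept (bin, side) records or plain bins (treated as one side)."""
    lefts, rights = [], []
    for rec in records:
        if isinstance(rec, (tuple, list)):
            b, side = rec
            (lefts if side == "left" else rights).append(b)
        elif hasattr(rec, "side"):
            (lefts if rec.side == "left" else rights).append(rec.bin)
        else:
            lefts.append(rec)
    return np.asarray(lefts), np.asarray(rights)


def boundary_jaccard(A, B, tol: int = 1) -> float:
    """Tolerance-aware, side-respecting Jaccard index of two boundary sets."""
    al, ar = _split_sides(A)
    bl, br = _split_sides(B)
    n_a = len(al) + len(ar)
    n_b = len(bl) + len(br)
    if n_a == 0 and n_b == 0:
        return 1.0
    matched = _greedy_match(al, bl, tol) + _greedy_match(ar, br, tol)
    return matched / (n_a + n_b - matched)


def boundary_recall(truth, called, tol: int = 1) -> float:
    """Fraction of true boundaries with a matched call within +/- tol bins."""
    tl, tr = _split_sides(truth)
    cl, cr = _split_sides(called)
    n_true = len(tl) + len(tr)
    if n_true == 0:
        return 1.0
    return (_greedy_match(tl, cl, tol) + _greedy_match(tr, cr, tol)) / n_true
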