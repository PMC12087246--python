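"""Assembly of predicted boundaries into an optimal nested TAD hierarchy.

Left and right boundary calls are paired by a dynamic program patterned on
the Nussinov RNA-folding recursion.  Over the sorted boundary multiset
(b_1..b_n, padded with unpairable chromosome-end sentinels), the table cell
T_ij holds the maximum total TAD score achievable strictly within
[b_i, b_j]:

    T_ij = max_{i<k<j}  T_ik + T_kj + delta_k(i, j)

where delta_k(i, j) = S_[b_i, b_j] if b_i is a left call, b_j a right call,
the interval spans >= 3 bins, and the score clears the pairing threshold
lambda; otherwise 0.  Nested sub-TADs already fixed below a pair are
excluded when scoring it, so delta depends on the sub-solution chosen at
the split k; cells are filled shortest-span-first.

Because of that dependence, committing each cell to a single optimal
sub-solution is not quite exact: occasionally a slightly worse sub-solution
(e.g. declining a marginal sub-TAD) enables a higher parent score.  Each
cell therefore keeps a small Pareto set of candidates — the best total per
exclusion fingerprint — which restores exact global optimality at modest
cost: a candidate more than 1.0 below its cell's best can be discarded
(its fingerprint influences at most one future pairing bonus, which lies in
[0, 1]), and cells that no valid ancestor pair can enclose collapse to a
single candidate.  Backtracking from the full range (padded with unpairable
chromosome-end sentinels) yields the hierarchy that maximizes the sum of
scores of all TADs; partial overlaps are forbidden, so the output is always
a forest of nested/disjoint domains.  Boundaries absent from the optimum
are dropped as likely false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import _kernels
from .contact_io import ContactMap
from .scoring import MIN_TAD_SPAN, ScoreParams

__all__ = ["TAD", "TADHierarchy", "assemble", "enumerate_hierarchies", "annotate_levels"]

DEFAULT_LAMBDA = 0.2

#: default TAD size cap: 600 bins = 3 Mb at 5 kb resolution.  Domains larger
#: than this are rare in mammalian genomes, and scoring a candidate pair is
#: quadratic in its span, so the cap keeps assembly tractable; pass
#: ``max_tad_bins=None`` to lift it.
DEFAULT_MAX_TAD_BINS = 600


@dataclass
class TAD:
    chrom: str
    resolution: int
    left_bin: int
    right_bin: int
    score: float
    level: int = 0
    parent: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_bin, self.right_bin)


@dataclass
class TADHierarchy:
    """Forest of nested domains; level 0 = innermost (no smaller TAD inside)."""

    tads: list[TAD]
    total_score: float = 0.0

    def __len__(self) -> int:
        return len(self.tads)

    def level0(self) -> list[TAD]:
        return [t for t in self.tads if t.level == 0]


class _Node:
    __slots__ = ("bin", "is_left", "is_right")

    def __init__(self, bin_, is_left, is_right):
        self.bin = bin_
        self.is_left = is_left
        self.is_right = is_right


def _build_nodes(lefts, rights, n_bins):
    pos = {}
    for b in lefts:
        pos.setdefault(int(b), [False, False])[0] = True
    for b in rights:
        pos.setdefault(int(b), [False, False])[1] = True
    nodes = [_Node(b, *flags) for b, flags in sorted(pos.items())]
    # sentinels cover the whole boundary list but can never pair
    return [_Node(-1, False, False)] + nodes + [_Node(n_bins, False, False)]


class _Scorer:
    """Memoized exclusion-aware TAD scorer over one contact map.

    Scans each interval once (per-stratum flank arrays + comparison counts)
    and scores every exclusion variant by subtracting the excluded entries'
    counts — bit-identical to a direct rescan, but O(excluded) per variant.
    """

    def __init__(self, cmap: ContactMap, params: ScoreParams):
        self.cmap = cmap
        self.params = params
        self._cache: dict = {}
        self._base_key: tuple | None = None
        self._base = None

    @staticmethod
    def _fingerprint(a, b, children):
        # only maximal sub-intervals affect which pairs are excluded; the
        # (a, -b) sort guarantees a contained interval always follows its
        # container, so checking the last kept interval suffices, and the
        # result is overlap-free as prefix-sum subtraction requires
        regs = sorted(children, key=lambda r: (r[0], -r[1]))
        maximal = []
        for reg in regs:
            if maximal and reg[0] >= maximal[-1][0] and reg[1] <= maximal[-1][1]:
                continue
            maximal.append(reg)
        return (a, b, tuple(maximal))

    def score(self, a: int, b: int, children) -> float:
        key = self._fingerprint(a, b, children)
        if key not in self._cache:
            if self._base_key != (a, b):
                self._base = _kernels.interval_base_counts(
                    self.cmap.values, a, b, self.params.gamma
                )
                self._base_key = (a, b)
            cum_num, cum_den, offs = self._base
            excl = np.asarray(key[2], dtype=np.int64).reshape(-1, 2)
            sk = _kernels.counts_minus_exclusions(a, b, cum_num, cum_den, offs, excl)
            span = b - a
            k = np.arange(1, span + 1)
            self._cache[key] = float(
                np.sum((span + k + 1) * sk) * 2.0 / (3.0 * (1 + span) * span)
            )
        return self._cache[key]


class _Cand:
    """One Pareto candidate of a DP cell: best achievable total for one
    exclusion fingerprint (the maximal fixed sub-intervals), with backtrack
    links to the child candidates it was built from."""

    __slots__ = ("total", "fp", "k", "left", "right", "pair_s")

    def __init__(self, total, fp, k, left, right, pair_s):
        self.total = total
        self.fp = fp
        self.k = k
        self.left = left
        self.right = right
        self.pair_s = pair_s


def _prune(cands: dict, enclosable: bool) -> list:
    vals = list(cands.values())
    best = max(c.total for c in vals)
    if not enclosable:
        # no ancestor pair can ever see this cell's fingerprint: only the
        # best total survives (deterministic tie-break on the fingerprint)
        top = [c for c in vals if c.total >= best - 1e-12]
        top.sort(key=lambda c: c.fp)
        return [top[0]]
    keep = [c for c in vals if c.total > best - 1.0 - 1e-12]
    keep.sort(key=lambda c: (-c.total, c.fp))
    return keep


def assemble(
    cmap: ContactMap,
    lefts,
    rights,
    params: ScoreParams = ScoreParams(),
    lam: float = DEFAULT_LAMBDA,
    max_tad_bins: int | None = DEFAULT_MAX_TAD_BINS,
) -> TADHierarchy:
    """Globally optimal nested pairing of left/right boundary calls.

    Ties in the split argmax resolve to the smallest k; a valid pairing is
    preferred over not pairing at equal score.  Deterministic.
    """
    lefts = [int(b) for b in lefts]
    rights = [int(b) for b in rights]
    if lefts != sorted(lefts) or rights != sorted(rights):
        raise ValueError("boundary lists must be sorted")
    if not lefts and not rights:
        return TADHierarchy([], 0.0)
    nodes = _build_nodes(lefts, rights, cmap.n_bins)
    m = len(nodes)
    scorer = _Scorer(cmap, params)

    def pairable(i: int, j: int) -> bool:
        bi, bj = nodes[i].bin, nodes[j].bin
        if not (nodes[i].is_left and nodes[j].is_right):
            return False
        if bj - bi < MIN_TAD_SPAN:
            return False
        if max_tad_bins is not None and bj - bi + 1 > max_tad_bins:
            return False
        return True

    # a cell's exclusion fingerprint can matter only if some ancestor pair
    # can enclose it; otherwise only its best total survives
    left_before = np.zeros(m, dtype=bool)
    flag = False
    for i in range(m):
        flag = flag or nodes[i].is_left
        left_before[i] = flag
    right_after = np.zeros(m, dtype=bool)
    flag = False
    for j in range(m - 1, -1, -1):
        flag = flag or nodes[j].is_right
        right_after[j] = flag

    # Pareto candidates per cell: fingerprint -> _Cand.  A candidate more
    # than 1.0 below the cell's best total can never win, because its
    # fingerprint influences at most one future pairing bonus delta in
    # [0, 1]; this prune keeps the DP exact.
    cells: list[list] = [[None] * m for _ in range(m)]

    for i in range(m - 1):
        j = i + 1
        cands = {(): _Cand(0.0, (), -1, None, None, None)}
        if pairable(i, j):
            s = scorer.score(nodes[i].bin, nodes[j].bin, ())
            if s >= lam:
                fp = ((nodes[i].bin, nodes[j].bin),)
                cands[fp] = _Cand(s, fp, -1, None, None, s)
        cells[i][j] = _prune(cands, enclosable=left_before[i] and right_after[j])

    for span in range(2, m):
        for i in range(m - span):
            j = i + span
            can_pair = pairable(i, j)
            cands: dict = {}
            best_pair_total = -np.inf
            for k in range(i + 1, j):
                for cl in cells[i][k]:
                    for cr in cells[k][j]:
                        base = cl.total + cr.total
                        fp0 = cl.fp + cr.fp
                        cur = cands.get(fp0)
                        if cur is None or base > cur.total + 1e-12:
                            cands[fp0] = _Cand(base, fp0, k, cl, cr, None)
                        if can_pair and base + 1.0 > best_pair_total:
                            s = scorer.score(nodes[i].bin, nodes[j].bin, fp0)
                            if s >= lam:
                                tot = base + s
                                if tot > best_pair_total:
                                    best_pair_total = tot
                                    fp = ((nodes[i].bin, nodes[j].bin),)
                                    cur = cands.get(fp)
                                    if cur is None or tot > cur.total + 1e-12:
                                        cands[fp] = _Cand(tot, fp, k, cl, cr, s)
            cells[i][j] = _prune(
                cands, enclosable=left_before[i] and right_after[j]
            )

    # backtrack the best root candidate, collecting every paired cell
    root = cells[0][m - 1][0]
    raw: list[tuple[int, int, float]] = []
    stack = [root]
    while stack:
        c = stack.pop()
        if c.pair_s is not None:
            raw.append((c.fp[0][0], c.fp[0][1], c.pair_s))
        if c.left is not None:
            stack.append(c.left)
        if c.right is not None:
            stack.append(c.right)
    tads = [
        TAD(cmap.chrom, cmap.resolution, a, b, s) for a, b, s in sorted(set(raw))
    ]
    hierarchy = annotate_levels(tads)
    hierarchy.total_score = float(root.total)
    return hierarchy


def enumerate_hierarchies(lefts, rights, scorer, n_bins, lam=DEFAULT_LAMBDA,
                          max_tad_bins=None):
    """Exhaustive test oracle: best non-crossing pairing by brute force.

    ``scorer(a, b, children)`` must score interval [a, b] with the given
    child intervals excluded.  Enumerates every subset of candidate (L, R)
    pairs without partial overlaps (shared endpoints allowed), scoring each
    pair with all strictly nested pairs of the subset excluded; refuses more
    than 10 distinct boundaries.
    """
    positions = sorted(set(lefts) | set(rights))
    if len(positions) > 10:
        raise ValueError("enumeration oracle limited to 10 boundaries")
    lefts = set(lefts)
    rights = set(rights)
    cand = [
        (a, b)
        for a in sorted(lefts)
        for b in sorted(rights)
        if b - a >= MIN_TAD_SPAN
        and (max_tad_bins is None or b - a + 1 <= max_tad_bins)
    ]

    def crossing(p, q):
        (a1, b1), (a2, b2) = p, q
        return (a1 < a2 <= b1 < b2) and not (a2 == b1) or \
               (a2 < a1 <= b2 < b1) and not (a1 == b2)

    best_total = 0.0
    best_set: list = []

    def total_of(chosen):
        tot = 0.0
        for a, b in chosen:
            children = [
                (a2, b2)
                for a2, b2 in chosen
                if (a2, b2) != (a, b) and a <= a2 and b2 <= b and (b2 - a2) < (b - a)
            ]
            s = scorer(a, b, children)
            if s < lam:
                return None  # pairing below threshold is not a valid hierarchy
            tot += s
        return tot

    def recurse(idx, chosen):
        nonlocal best_total, best_set
        if idx == len(cand):
            tot = total_of(chosen)
            if tot is not None and tot > best_total + 1e-12:
                best_total = tot
                best_set = list(chosen)
            return
        recurse(idx + 1, chosen)
        p = cand[idx]
        if all(not crossing(p, q) for q in chosen):
            chosen.append(p)
            recurse(idx + 1, chosen)
            chosen.pop()

    recurse(0, [])
    return best_total, sorted(best_set)


def annotate_levels(tads: list[TAD]) -> TADHierarchy:
    """Assign nesting levels and parent links to a non-crossing TAD set.

    Level 0 = contains no smaller TAD; a parent's level is 1 + the maximum
    level among its children.  Parent = smallest strictly containing TAD.
    """
    order = sorted(range(len(tads)), key=lambda i: (tads[i].left_bin, -tads[i].right_bin))
    for i, j in combinations(range(len(tads)), 2):
        a1, b1 = tads[i].span
        a2, b2 = tads[j].span
        if (a1 < a2 <= b1 < b2 and a2 != b1) or (a2 < a1 <= b2 < b1 and a1 != b2):
            raise ValueError(f"crossing TADs {tads[i].span} and {tads[j].span}")
    for idx in order:
        t = tads[idx]
        parent = None
        for jdx in range(len(tads)):
            if jdx == idx:
                continue
            o = tads[jdx]
            if o.left_bin <= t.left_bin and t.right_bin <= o.right_bin and \
                    (o.right_bin - o.left_bin) > (t.right_bin - t.left_bin):
                if parent is None or (
                    (o.right_bin - o.left_bin)
                    < (tads[parent].right_bin - tads[parent].left_bin)
                ):
                    parent = jdx
        t.parent = parent
    # levels bottom-up: process by increasing size
    by_size = sorted(range(len(tads)), key=lambda i: tads[i].right_bin - tads[i].left_bin)
    for idx in by_size:
        children = [j for j in range(len(tads)) if tads[j].parent == idx]
        tads[idx].level = 1 + max((tads[j].level for j in children), default=-1)
    return TADHierarchy(sorted(tads, key=lambda t: (t.left_bin, t.right_bin)))
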