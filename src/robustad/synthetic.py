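"""Synthetic Hi-C contact maps with planted (optionally nested) TADs.

The generative model is the simplest one with the right rank structure for
a distance-stratified caller: expected contacts follow a power-law distance
decay, E_ij proportional to (|i-j| + 1)^(-decay_exponent), multiplied by
the enrichment fold of every planted TAD containing both bins (nested TADs
multiply, so a child sits on its parent's elevated background — exactly the
situation the parent-score exclusion rule addresses).  The expected matrix
is scaled so its upper triangle sums to the requested read depth, sampled
with independent Poisson noise, and symmetrized.  Outside planted TADs the
expected value on each diagonal is position-independent, the property the
diagonal-shuffle decoy relies on.

Panel replicates share the planted truth up to a per-sample boundary jitter
and draw independent noise, emulating a reference panel of related samples.

Not emulated: A/B compartments, loops/corner dots, stripes, and
coverage-bias artifacts of real data; conclusions from these simulations
concern the algorithm, not experimental robustness to such features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contact_io import ContactMap

__all__ = [
    "PlantedTAD",
    "SimSpec",
    "SimTruth",
    "simulate_map",
    "simulate_panel",
    "random_tad_layout",
    "nested_tad_layout",
]


@dataclass(frozen=True)
class PlantedTAD:
    a: int
    b: int
    fold: float = 2.5

    def __post_init__(self) -> None:
        if self.b - self.a < 2:
            raise ValueError("planted TAD must span at least 3 bins")
        if self.fold < 1:
            raise ValueError("enrichment fold must be >= 1")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated chromosome.

    depth is the expected total valid read pairs on the upper triangle;
    planted intervals must be pairwise nested or disjoint.
    """

    n_bins: int = 1000
    resolution: int = 5000
    decay_exponent: float = 1.0
    planted_tads: tuple = field(default=())
    depth: float = 10_000_000.0
    chrom: str = "chrSim"
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 3 or self.depth <= 0:
            raise ValueError("invalid simulation spec")
        tads = tuple(self.planted_tads)
        for t in tads:
            if not (0 <= t.a and t.b < self.n_bins):
                raise ValueError(f"planted TAD ({t.a}, {t.b}) outside map")
        for t1 in tads:
            for t2 in tads:
                if t1.a < t2.a <= t1.b < t2.b:
                    raise ValueError("crossing planted TADs")
        object.__setattr__(self, "planted_tads", tads)


@dataclass
class SimTruth:
    """Ground truth of a simulated map."""

    tads: list[PlantedTAD]

    @property
    def lefts(self) -> list[int]:
        return sorted(t.a for t in self.tads)

    @property
    def rights(self) -> list[int]:
        return sorted(t.b for t in self.tads)

    def boundaries(self) -> list[tuple[int, str]]:
        return [(t.a, "left") for t in self.tads] + [(t.b, "right") for t in self.tads]


def random_tad_layout(
    n_bins: int,
    n_tads: int,
    fold: float = 2.5,
    size_range: tuple[int, int] = (20, 40),
    gap_range: tuple[int, int] = (10, 20),
    seed: int = 0,
) -> tuple[PlantedTAD, ...]:
    """Disjoint TADs of 100-200 kb (at 5 kb bins) separated by open gaps."""
    rng = np.random.default_rng(seed)
    tads, pos = [], 10
    while len(tads) < n_tads and pos < n_bins - size_range[1] - 10:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
        if pos + size >= n_bins - 10:
            break
        tads.append(PlantedTAD(pos, pos + size, fold))
        pos += size + gap
    return tuple(tads)


def nested_tad_layout(
    n_bins: int,
    parent_fold: float = 2.5,
    child_fold: float = 2.0,
    seed: int = 0,
) -> tuple[PlantedTAD, ...]:
    """Two-level hierarchy: each parent TAD carries one nested child."""
    rng = np.random.default_rng(seed)
    tads, pos = [], 10
    while pos < n_bins - 90:
        psize = int(rng.integers(50, 71))
        if pos + psize >= n_bins - 10:
            break
        tads.append(PlantedTAD(pos, pos + psize, parent_fold))
        ca = pos + int(rng.integers(3, 10))
        cb = min(ca + int(rng.integers(15, 26)), pos + psize - 3)
        tads.append(PlantedTAD(ca, cb, child_fold))
        pos += psize + int(rng.integers(12, 20))
    return tuple(tads)


def _expected_matrix(spec: SimSpec) -> np.ndarray:
    n = spec.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    E = (d + 1.0) ** (-spec.decay_exponent)
    for t in spec.planted_tads:
        E[t.a : t.b + 1, t.a : t.b + 1] *= t.fold
    E *= spec.depth / np.triu(E).sum()
    return E


def simulate_map(spec: SimSpec, seed: int = 0) -> tuple[ContactMap, SimTruth]:
    """Sample one contact map and return it with its planted truth."""
    rng = np.random.default_rng(seed)
    E = _expected_matrix(spec)
    n = spec.n_bins
    iu = np.triu_indices(n)
    counts = rng.poisson(E[iu]).astype(np.float64)
    v = np.zeros((n, n))
    v[iu] = counts
    v = v + np.triu(v, 1).T
    if spec.normalize:
        # one-shot correction toward equal coverage, ICE-flavoured
        cov = v.sum(axis=0)
        cov[cov == 0] = np.nan
        scale = np.sqrt(cov / np.nanmean(cov))
        v = v / np.outer(scale, scale)
    cmap = ContactMap(
        chrom=spec.chrom,
        resolution=spec.resolution,
        values=v,
        depth_hint=int(spec.depth),
    )
    return cmap, SimTruth(list(spec.planted_tads))


def _jitter_tads(tads, jitter: int, n_bins: int, rng) -> list[PlantedTAD]:
    out = []
    for t in sorted(tads, key=lambda t: (t.a, -t.b)):
        for _ in range(100):
            da = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            db = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            a, b = t.a + da, t.b + db
            if not (0 <= a and b < n_bins and b - a >= 2):
                continue
            cand = PlantedTAD(a, b, t.fold)
            if all(
                not (o.a < cand.a <= o.b < cand.b or cand.a < o.a <= cand.b < o.b)
                for o in out
            ):
                out.append(cand)
                break
        else:
            out.append(t)  # jitter kept breaking nesting; keep the original
    return out


def simulate_panel(
    spec: SimSpec,
    n_samples: int,
    jitter: int = 0,
    depth_per_sample: float | None = None,
    seed: int = 0,
    sample_specific_rate: float = 0.0,
) -> list[tuple[ContactMap, SimTruth]]:
    """Replicate maps sharing the planted TADs up to boundary jitter.

    Each replicate jitters every boundary independently by up to +/- jitter
    bins (rejecting moves that would create crossings), optionally drops
    each TAD with probability ``sample_specific_rate``, and draws
    independent Poisson noise at ``depth_per_sample``.
    """
    if n_samples < 1:
        raise ValueError("need at least one panel sample")
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_samples):
        tads = _jitter_tads(spec.planted_tads, jitter, spec.n_bins, rng)
        if sample_specific_rate > 0:
            tads = [t for t in tads if rng.random() > sample_specific_rate] or tads
        sub = replace(
            spec,
            planted_tads=tuple(tads),
            depth=depth_per_sample or spec.depth,
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(simulate_map(sub, seed=sub_seed))
    return out
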