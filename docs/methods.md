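# Methods

## Model and scores

The input is a symmetric, normalized intra-chromosomal contact matrix
`M = {m_ij}` at fixed bin resolution `r`. Because Hi-C contact frequency
decays steeply with genomic distance, all comparisons are made *within*
distance strata: stratum `k` is the set of matrix entries `(i, i+k)`.

For a candidate domain `[a, b]` (inclusive bin indices; a boundary bin is
the furthermost bin *inside* the domain), the stratum-`k` inside set is
`D_k(a, b) = {(i, i+k): a ≤ i, i+k ≤ b}` and the backgrounds are the flank
sets `D_k(a−k, a+k−1)` (pairs straddling the `a` edge) and
`D_k(b−k+1, b+k)` (straddling `b`). Each inside × flank pair contributes
`+1` if `m_in > γ·m_out`, `−1` if `γ·m_in < m_out`, nothing otherwise;
the stratum score is the sum over contributions divided by the count of
decisive comparisons, i.e. a signed rank-sum statistic in `[−1, 1]` (at
the default `γ = 1`, a Wilcoxon-style comparison; larger `γ` widens the
tie band, and values up to ~1.3 behave similarly). The TAD score is the
weighted stratum average

    S_[a,b] = 2 / (3 (1+b−a)(b−a)) · Σ_{k=1}^{b−a} (b−a+k+1) · S^k_[a,b],

where `b−a+k+1` is the nominal number of entries used on diagonal `k` and
the normalizer is their total. One-sided boundary scores use only the
corresponding flank as background and average strata uniformly. Both
comparison directions are implemented multiplicatively
(`m_in > γ·m_out`, `γ·m_in < m_out`) so the fast path and the all-pairs
reference oracle agree bit-for-bit in floating point.

Per-bin boundary tracks maximize the one-sided scores over window sizes
`w = w_min … w_max` (defaults 10 and 50 bins = 50–250 kb at 5 kb): wide
enough for a stable rank statistic, not so wide that windows routinely
overrun the domain being tested.

**Missing data.** Bins with no coverage are flagged missing (NaN), never
zero-filled; comparisons touching a missing entry are skipped in both the
numerator and denominator. Zeros from unmappability would otherwise bias
every rank comparison downward. At chromosome edges, strata use only
in-range flank entries; a fully out-of-range flank yields a stratum score
of 0 (flagged as undefined on request). These skip rules are a design
choice where the method definition is silent; the oracle-equivalence
tests pin them down explicitly.

## Boundary calling and FDR control

Candidate boundaries are local maxima of the `L`/`R` tracks
(`scipy.signal.find_peaks`) at least 5 bins (25 kb) apart; plateaus
resolve to their leftmost bin. Significance comes from a decoy contact
map: each diagonal's non-missing values are permuted in place (up to
3·w_max diagonals — deeper strata are never scored), which destroys all
domain structure while preserving the distance-decay profile *exactly*
(every diagonal keeps its value multiset). The same track-and-peak
pipeline runs on the decoy, and candidates are accepted at target–decoy
FDR level α using the standard estimator
`FDR(t) = #{decoy ≥ t} / max(1, #{target ≥ t})` with q-values
`q(s) = min_{t ≤ s} FDR(t)`. The default α is 0.05 when the map's
valid-pair depth exceeds 300M and 0.1 otherwise; FDR control is per
chromosome (scores are chromosome-local), with one decoy per chromosome
seeded from the run seed plus a stable hash of the chromosome name.

## Reference-panel refinement

A reference panel stores, per sample and resolution, the boundary-score
tracks and FDR-accepted calls of the single-sample pipeline (a directory
with a JSON manifest plus one compressed array file per sample; panels
are resolution-specific and grow by appending samples). For a study call
at bin `b`, the locally matched chromosome conformations (LMCCs) are the
panel samples with an accepted same-side call within ±5 bins. Over the
10-bin window `[b−5, b+4]` (the even window is resolved left-heavy; the
parity is not dictated by the method definition), the refined score at
each bin is the mean of the study track and every LMCC track — uniformly,
or weighted by `log10(depth)` in depth mode (raw depths would let one
deep sample dominate; unknown depths fall back to uniform). The call
moves to the argmax of the refined scores, ties resolving to the bin
nearest the original call, then leftmost. With no LMCC the call is
returned unchanged, which makes an empty panel bit-identical to
single-sample mode — an interpretability guarantee the test suite asserts
end-to-end.

## Nested assembly

Accepted boundaries form a sorted multiset `b_1 … b_n` (a bin may carry
both sides), padded with unpairable chromosome-end sentinels. A
Nussinov-style dynamic program fills `T_ij`, the best total TAD score
strictly within `[b_i, b_j]`, via
`T_ij = max_{i<k<j} T_ik + T_kj + δ(i, j)`, where `δ` is `S_[b_i,b_j]`
when `b_i` is a left call, `b_j` a right call, the interval spans ≥ 3
bins, and the score clears `λ = 0.2` (near the weakest boundary scores
that still replicate); else 0. When a pair is scored, interactions
belonging to its already-fixed sub-TADs (both endpoints inside one
sub-interval) are excluded, so a strong nested child cannot inflate its
parent; the union of all fixed descendants is excluded, reduced to the
maximal intervals, which is equivalent and cheaper. Flank entries are
never excluded.

Because δ depends on which sub-TADs the chosen split has fixed, a DP that
commits each cell to a single best sub-solution is *not* exactly optimal:
in roughly 1–2% of random instances, declining a marginal child raises
the parent's exclusion-aware score by more than the child contributes.
Each cell therefore keeps a small Pareto set of candidates — the best
total per exclusion fingerprint. Two prunings keep this exact and cheap:
a candidate more than 1.0 below its cell's best can never win (its
fingerprint influences at most one future pairing bonus, which lies in
[0, 1]), and cells that no side-valid ancestor pair can enclose collapse
to their single best candidate. The result provably maximizes the total
TAD score; the test suite checks it against exhaustive enumeration over
all non-crossing pairings on hundreds of random instances, including
nested-enrichment instances where the exclusion rule changes the winner.

Numerical details: interval scoring is done once per pair as per-stratum
prefix sums of each inside entry's comparison counts, so every exclusion
variant is an O(1)-per-(stratum, region) subtraction, bit-identical to a
direct rescan. Split ties prefer the smaller `k`; pairing is preferred at
equal score; the output is deterministic. Domains larger than
`max_tad_bins = 600` bins (3 Mb at 5 kb) are not considered by default —
a deliberate size prior matching how comparable callers are configured,
and necessary because pair scoring is quadratic in span; `None` lifts it.
Reported levels: level 0 = contains no smaller TAD; a parent's level is
1 + its deepest child's. TADs sharing one boundary bin are allowed
(boundaries may serve multiple domains); only genuine partial overlaps
are forbidden.

## Synthetic data

The generator plants ground-truth hierarchies in the simplest model with
the right rank structure: expected counts
`E_ij ∝ (|i−j|+1)^(−α)` (default decay exponent α = 1, the typical Hi-C
regime), multiplied by the enrichment fold of every planted TAD
containing both bins — nested folds multiply, reproducing the
child-on-elevated-parent situation the exclusion rule addresses. `E` is
scaled so the upper triangle sums to the requested depth, sampled with
independent Poisson noise, and symmetrized; an optional one-shot
coverage correction mimics ICE-normalized input. Off-TAD, each
diagonal's expectation is position-independent — exactly the
exchangeability the decoy shuffle relies on. Panel replicates share the
planted truth up to a per-sample boundary jitter and draw independent
noise.

Default study conditions used by the tests and the acceptance script:
flat recovery uses 1000-bin maps with 20 disjoint TADs of 20–40 bins
(100–200 kb) at fold 2.5 and depth 10⁷ pairs ("dense": ~100 counts per
entry in the first strata); nested runs use 500-bin maps of 50–70-bin
parents each holding one 15–25-bin child (folds 2.5 × 2.0) at depth
5·10⁶; FDR calibration uses 800-bin domain-free maps at 3·10⁶; panel
benefit uses 600-bin/10-TAD studies at 3·10⁵ against five 5·10⁶-deep
replicates. Map sizes are kept at a few hundred to a thousand bins so a
full multi-seed run completes in minutes on one CPU.

What the simulations do *not* emulate: A/B compartments, loops/corner
dots, stripes, restriction-site and mappability biases, or
translocations. Passing tests therefore demonstrate correctness of the
statistics and algorithms under the stated generative model, not
robustness to every artifact of real Hi-C libraries.

## Parameters at a glance

| parameter | default | units | meaning |
|---|---|---|---|
| `γ` (gamma) | 1.0 | fold | minimum inside/flank gap for a decisive comparison |
| `w_min`, `w_max` | 10, 50 | bins | boundary-score window range (50–250 kb at 5 kb) |
| min. separation | 5 | bins | minimum distance between boundary peaks (25 kb) |
| `α` (alpha) | auto 0.05/0.1 | — | target–decoy FDR level, by depth (300M cutoff) |
| LMCC window | 5 | bins | panel match radius for refinement |
| refinement window | 10 | bins | `[b−5, b+4]`, averaged across LMCC samples |
| `λ` (lambda) | 0.2 | score | minimum TAD score to pair two boundaries |
| min. TAD size | 3 | bins | smaller intervals are invalid |
| `max_tad_bins` | 600 | bins | TAD size cap (3 Mb at 5 kb); `None` disables |

## Known limitations

* Scoring assumes the input is already normalized; no balancing is done.
* Pair scoring is O(span²); very boundary-dense chromosomes without the
  size cap can be slow (the Discussion-stage idea of subsampling
  comparisons for very large domains is not implemented).
* The Pareto candidate sets are provably sufficient but can grow on maps
  with many near-tied marginal sub-TADs; in practice they stay small.
* Cross-resolution panel reuse is unsupported by design: a panel is
  specific to its resolution.
* Inter-chromosomal maps, loop/stripe calling, and partially overlapping
  domain models are out of scope.
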