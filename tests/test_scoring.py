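import numpy as np
import pytest

from robustad import reference as ref
from robustad.contact_io import ContactMap
from robustad.scoring import (
    ExclusionSet,
    ScoreParams,
    boundary_score,
    boundary_stratum_scores,
    stratum_entry_count,
    stratum_tad_score,
    tad_score,
)

P = ScoreParams(w_min=2, w_max=5)


def _map_from(values):
    v = np.asarray(values, dtype=float)
    return ContactMap("chrT", 5000, (v + v.T) / 2)


def _diag_map(diag1, n, base=1.0):
    """Map whose first diagonal is `diag1` and everything else is `base`."""
    v = np.full((n, n), base)
    for i, x in enumerate(diag1):
        v[i, i + 1] = v[i + 1, i] = x
    return ContactMap("chrT", 5000, v)


class TestStratumScore:
    def test_hand_worked_first_stratum(self):
        # interval [0,3], k=1: inside entries {5,3,4}; flanks would need
        # bins -1 and 4, so embed in a 6-bin map shifted by one:
        # interval [1,4], inside diag entries at (1,2),(2,3),(3,4) = 5,3,4,
        # flanks (0,1)=4 and (4,5)=2 -> 6 comparisons, one tie (4 vs 4),
        # numerator 4-1=3, denominator 5
        cm = _diag_map([4, 5, 3, 4, 2], n=6, base=100.0)
        s = stratum_tad_score(cm, 1, 4, 1, P)
        assert s == pytest.approx(0.6)

    def test_all_inside_greater_gives_one(self):
        cm = _diag_map([1, 9, 9, 9, 1], n=6, base=0.5)
        assert stratum_tad_score(cm, 1, 4, 1, P) == 1.0

    def test_constant_matrix_all_ties_gives_zero(self):
        cm = _map_from(np.full((12, 12), 3.0))
        assert stratum_tad_score(cm, 2, 8, 2, P) == 0.0

    def test_antisymmetry_swapping_inside_and_flank(self):
        cm = _diag_map([7, 1, 2, 3, 8], n=6, base=0.5)
        s_fwd = stratum_tad_score(cm, 1, 4, 1, P)
        swapped = _diag_map([2, 7, 8, 7, 3], n=6, base=0.5)
        # swapped multisets: inside {7,8,7} vs flank {2,3} mirrors
        # inside {1,2,3} vs flank {7,8}
        orig = _diag_map([7, 1, 2, 3, 8], n=6, base=0.5)
        assert stratum_tad_score(orig, 1, 4, 1, P) == -1.0
        assert stratum_tad_score(swapped, 1, 4, 1, P) == 1.0
        assert s_fwd == -1.0

    def test_invalid_arguments(self, random_map):
        cm = random_map(n=20)
        with pytest.raises(ValueError):
            stratum_tad_score(cm, 5, 5, 1, P)
        with pytest.raises(ValueError):
            stratum_tad_score(cm, 2, 6, 5, P)


class TestEntryCount:
    @pytest.mark.parametrize("a,b,k,expected", [(0, 3, 1, 5), (0, 3, 3, 7)])
    def test_printed_formula(self, a, b, k, expected):
        assert stratum_entry_count(a, b, k) == expected

    @pytest.mark.parametrize("span", range(1, 51))
    def test_total_entries_identity(self, span):
        total = sum(stratum_entry_count(0, span, k) for k in range(1, span + 1))
        assert total == 3 * (1 + span) * span // 2


class TestTadScore:
    def test_weighted_sum_hand_example(self, monkeypatch):
        # span 2 with stratum scores 0.5 and -0.2: (4*0.5 + 5*(-0.2))/9 = 1/9
        from robustad import scoring

        def fake(values, a, b, gamma, excl, mode):
            return np.array([0.5, -0.2])

        monkeypatch.setattr(scoring._kernels, "interval_stratum_scores", fake)
        cm = _map_from(np.full((10, 10), 1.0))
        assert tad_score(cm, 0, 2, P) == pytest.approx(1 / 9)

    def test_trivial_normalization(self, random_map):
        cm = _map_from(np.full((20, 20), 2.0))
        assert tad_score(cm, 3, 10, P) == 0.0

    def test_minimum_size(self, random_map):
        cm = random_map(n=20)
        with pytest.raises(ValueError, match="3 bins"):
            tad_score(cm, 4, 5, P)
        tad_score(cm, 4, 6, P)  # 3-bin TAD is valid

    def test_enriched_block_scores_high(self, block_map):
        cm = block_map(n=60, blocks=((20, 40),), fold=5.0)
        assert tad_score(cm, 20, 40, ScoreParams()) > 0.8
        assert tad_score(cm, 5, 15, ScoreParams()) < 0.3


class TestExclusion:
    def test_exclusion_removes_enriched_child(self, block_map):
        # strong sub-TAD inflates the parent score; excluding it lowers it
        cm = block_map(n=80, blocks=((30, 50), (35, 45)), fold=3.0)
        s_with = tad_score(cm, 30, 50, ScoreParams(), ExclusionSet(((35, 45),)))
        s_without = tad_score(cm, 30, 50, ScoreParams())
        assert s_with <= s_without

    def test_exclusion_matches_reference(self, random_map):
        cm = random_map(n=30, seed=5)
        s = tad_score(cm, 5, 20, P, ExclusionSet(((8, 14),)))
        s_ref = ref.tad_score_allpairs(cm.values, 5, 20, excl=[(8, 14)])
        assert s == pytest.approx(s_ref, abs=1e-12)

    def test_crossing_regions_rejected(self):
        with pytest.raises(ValueError, match="crossing"):
            ExclusionSet(((0, 10), (5, 15)))
        ExclusionSet(((0, 10), (10, 15)))  # shared endpoint bin is fine


class TestBoundaryScores:
    def test_left_stratum_matches_two_sided_arithmetic(self):
        cm = _diag_map([4, 5, 3, 4, 2], n=6, base=100.0)
        # left flank {4}: comparisons 5>4, 3<4, 4=4 -> (1-1)/2 = 0
        assert boundary_stratum_scores(cm, 1, 4, 1, "left", P) == 0.0

    def test_edge_flank_undefined_flag(self, random_map):
        cm = random_map(n=20)
        s, defined = boundary_stratum_scores(
            cm, 0, 4, 2, "left", P, return_defined=True
        )
        assert s == 0.0 and not defined
        _, defined = boundary_stratum_scores(cm, 5, 9, 2, "left", P, return_defined=True)
        assert defined

    def test_boundary_score_is_stratum_mean(self, random_map):
        cm = random_map(n=30, seed=2)
        manual = np.mean(
            [boundary_stratum_scores(cm, 10, 15, k, "right", P) for k in range(1, 6)]
        )
        assert boundary_score(cm, 10, 15, "right", P) == pytest.approx(manual)


class TestProperties:
    def test_scores_bounded(self, random_map):
        for seed in range(5):
            cm = random_map(n=25, seed=seed)
            for a in range(0, 18, 3):
                b = a + 6
                assert -1 <= tad_score(cm, a, b, P) <= 1
                assert -1 <= boundary_score(cm, a, b, "left", P) <= 1
                assert -1 <= boundary_score(cm, a, b, "right", P) <= 1

    def test_rank_invariance_per_diagonal_transform(self, random_map):
        cm = random_map(n=30, seed=11)
        v = cm.values.copy()
        n = v.shape[0]
        rng = np.random.default_rng(0)
        for k in range(n):  # strictly increasing transform per diagonal
            c = rng.uniform(0.5, 2.0)
            idx = np.arange(n - k)
            v[idx, idx + k] = np.exp(c * v[idx, idx + k]) + k
            v[idx + k, idx] = v[idx, idx + k]
        tm = ContactMap("chrT", 5000, v)
        for a in range(0, 20, 4):
            b = a + 7
            assert tad_score(tm, a, b, P) == tad_score(cm, a, b, P)
            assert boundary_score(tm, a, b, "left", P) == boundary_score(
                cm, a, b, "left", P
            )

    def test_gamma_widens_tie_band(self, random_map):
        cm = random_map(n=30, seed=4)
        # with huge gamma every comparison ties -> all scores 0
        huge = ScoreParams(gamma=1e6, w_min=2, w_max=5)
        assert tad_score(cm, 5, 15, huge) == 0.0

    def test_missing_entries_skipped_not_zeroed(self, random_map):
        cm = random_map(n=30, seed=8, missing=(12,))
        zeroed = cm.values.copy()
        zeroed[12, :] = 0.0
        zeroed[:, 12] = 0.0
        cz = ContactMap("chrT", 5000, zeroed)
        s_skip = tad_score(cm, 8, 18, P)
        s_zero = tad_score(cz, 8, 18, P)
        assert s_skip == pytest.approx(ref.tad_score_allpairs(cm.values, 8, 18))
        assert s_skip != s_zero  # zero-filling biases the rank comparisons
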