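import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methdiff import dmr
from tests.conftest import make_sample


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40))
def test_bh_qvalues_dominate_pvalues_and_stay_bounded(pvals):
    """BH q-values lie in [p, 1] and preserve the ordering of the p-values."""
    q = dmr.bh_adjust(pvals)
    p = np.asarray(pvals)
    assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


def fisher_exact_bruteforce(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration of fixed-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    den = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    num_obs = nums[a - lo]
    return sum(x for x in nums if x <= num_obs) / den


class TestEnumerateWindows:
    def test_single_window(self):
        assert dmr.enumerate_windows(1000, 1000, 100) == [(1, 1000, False)]

    def test_full_windows_only(self):
        assert dmr.enumerate_windows(1200, 1000, 100) == [
            (1, 1000, False),
            (101, 1100, False),
            (201, 1200, False),
        ]

    def test_partial_tail_emitted_and_flagged(self):
        wins = dmr.enumerate_windows(1250, 1000, 100)
        assert wins[-1] == (301, 1250, True)
        assert all(not p for *_se, p in wins[:-1])

    def test_short_chromosome_single_partial(self):
        assert dmr.enumerate_windows(700, 1000, 100) == [(1, 700, True)]

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            dmr.enumerate_windows(5000, 1000, 2000)


class TestFisher:
    def test_identical_proportions_give_one(self):
        assert dmr.fisher_window_test(5, 5, 5, 5) == 1.0

    def test_extreme_table_equals_enumeration(self):
        assert dmr.fisher_window_test(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)

    def test_sample_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b == 0 or c + d == 0:
                continue
            assert dmr.fisher_window_test(a, b, c, d) == pytest.approx(
                dmr.fisher_window_test(c, d, a, b), rel=1e-12
            )

    def test_matches_integer_enumeration_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if a + b == 0 or c + d == 0:
                continue
            assert dmr.fisher_window_test(a, b, c, d) == pytest.approx(
                fisher_exact_bruteforce(a, b, c, d), abs=1e-9
            )

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            if a + b == 0 or c + d == 0:
                continue
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert dmr.fisher_window_test(a, b, c, d) == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            dmr.fisher_window_test(0, 0, 5, 5)


class TestBH:
    def test_hand_computation(self):
        assert dmr.bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_equal_ps_unchanged(self):
        assert dmr.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_p(self):
        assert dmr.bh_adjust([0.07]) == pytest.approx([0.07])

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        q = dmr.bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        # same permutation applied to p and q: adjustment is order-preserving
        perm = rng.permutation(100)
        assert dmr.bh_adjust(p[perm]) == pytest.approx(q[perm])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            dmr.bh_adjust([0.5, 1.2])


def _rows(spec, chrom="Chr01"):
    tris = {"CG": "CGA", "CHG": "CAG", "CHH": "CTT"}
    return [
        (chrom, pos, "+", m, u, ctx, tris[ctx]) for pos, m, u, ctx in spec
    ]


class TestCallDmrs:
    def test_identical_samples_no_dmrs(self):
        spec = [(p, 5, 5, "CG") for p in range(100, 5000, 40)]
        a = make_sample(_rows(spec), "A", 0.0, {"Chr01": 5000})
        b = make_sample(_rows(spec), "B", 0.0, {"Chr01": 5000})
        windows, dmrs = dmr.call_dmrs(a, b)
        assert len(dmrs) == 0
        assert (windows["p"] == 1.0).all()

    def test_single_differential_block_yields_one_dmr(self):
        base = [(p, 2, 18, "CG") for p in range(100, 8000, 40)]
        shifted = [
            (p, 18 if 3000 <= p <= 4000 else 2, 2 if 3000 <= p <= 4000 else 18, "CG")
            for p in range(100, 8000, 40)
        ]
        a = make_sample(_rows(shifted), "A", 0.0, {"Chr01": 8000})
        b = make_sample(_rows(base), "B", 0.0, {"Chr01": 8000})
        windows, dmrs = dmr.call_dmrs(a, b)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.start <= 3000 and d.end >= 4000
        assert d.ml_a > d.ml_b

    def test_depth_filter_applies_to_both_samples(self):
        spec_a = [(100, 20, 0, "CG")]
        spec_b = [(100, 0, 3, "CG")]  # depth 3 in B: site ineligible
        a = make_sample(_rows(spec_a), "A", 0.0, {"Chr01": 1000})
        b = make_sample(_rows(spec_b), "B", 0.0, {"Chr01": 1000})
        windows, dmrs = dmr.call_dmrs(a, b, min_depth=5)
        assert windows.empty and not dmrs

    def test_disjoint_chromosomes_error(self):
        a = make_sample(_rows([(100, 5, 5, "CG")], chrom="Chr01"), "A", 0.0)
        b = make_sample(_rows([(100, 5, 5, "CG")], chrom="Chr02"), "B", 0.0)
        with pytest.raises(ValueError):
            dmr.call_dmrs(a, b)


class TestMerge:
    def win(self, start, end, direction="hypo", q=0.01, chrom="Chr01"):
        return {
            "chrom": chrom,
            "start": start,
            "end": end,
            "a_meth": 10,
            "a_unmeth": 90,
            "b_meth": 50,
            "b_unmeth": 50,
            "q": q,
            "direction": direction,
        }

    def test_overlapping_same_direction_merge(self):
        sw = pd.DataFrame([self.win(1001, 2000), self.win(1501, 2500)])
        merged = dmr.merge_windows(sw)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (1001, 2500)
        assert merged[0].n_windows == 2

    def test_book_ended_merge_and_gap_break(self):
        sw = pd.DataFrame([self.win(1, 1000), self.win(1001, 2000), self.win(2002, 3000)])
        merged = dmr.merge_windows(sw)
        assert [(d.start, d.end) for d in merged] == [(1, 2000), (2002, 3000)]

    def test_opposite_directions_never_merge(self):
        sw = pd.DataFrame([self.win(1001, 2000, "hypo"), self.win(1501, 2500, "hyper")])
        merged = dmr.merge_windows(sw)
        assert len(merged) == 2
        assert {d.direction for d in merged} == {"hypo", "hyper"}

    def test_merge_idempotent_and_order_independent(self):
        wins = [self.win(1, 1000), self.win(501, 1500), self.win(5000, 6000, "hyper")]
        for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            merged = dmr.merge_windows(pd.DataFrame([wins[i] for i in perm]))
            assert [(d.chrom, d.start, d.end, d.direction) for d in merged] == [
                ("Chr01", 1, 1500, "hypo"),
                ("Chr01", 5000, 6000, "hyper"),
            ]
        # per-direction results are pairwise non-overlapping
        hypo = [d for d in merged if d.direction == "hypo"]
        for x, y in zip(hypo, hypo[1:]):
            assert x.end < y.start

    def test_min_q_propagates(self):
        sw = pd.DataFrame([self.win(1, 1000, q=0.04), self.win(501, 1500, q=0.002)])
        assert dmr.merge_windows(sw)[0].min_q == 0.002


class TestEffectSummary:
    def test_hand_arithmetic_delta(self):
        a = make_sample(_rows([(500, 80, 20, "CG")]), "A", 0.0, {"Chr01": 1000})
        b = make_sample(_rows([(500, 20, 80, "CG")]), "B", 0.0, {"Chr01": 1000})
        d = dmr.Dmr("Chr01", 1, 1000, "hyper", 1, 0.01, 0.8, 0.2)
        summary = dmr.dmr_effect_summary(d, a, b)
        assert summary["delta"] == pytest.approx(0.6)

    def test_hypo_dmr_has_negative_delta(self, small_sim):
        _, dmrs = dmr.call_dmrs(small_sim["a"], small_sim["b"])
        hypo = [d for d in dmrs if d.direction == "hypo"]
        assert hypo, "simulation should produce hypo DMRs"
        for d in hypo[:3]:
            s = dmr.dmr_effect_summary(d, small_sim["a"], small_sim["b"])
            assert s["delta"] < 0
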