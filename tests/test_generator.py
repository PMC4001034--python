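import numpy as np
import pytest

from connset import (
    CSAGenerator,
    IntervalSet,
    MaskSpec,
    SIZE_UNKNOWN,
    cross,
    cset,
    delta,
    interval_set_from_ids,
    random_mask,
)
from connset.values import constant

from helpers import (
    FIG2A_PAIRS,
    brute_force_pairs,
    random_expression,
    stream_pairs,
    window,
)


def _gen(expr, win=None):
    g = CSAGenerator(expr)
    if win is not None:
        g.set_mask(win)
    return g


class TestArity:
    def test_bare_mask_reports_zero(self, m_fig2):
        assert _gen(m_fig2).arity() == 0

    def test_two_value_sets_report_two(self, m_fig2):
        assert _gen(cset(m_fig2, constant(1.0), constant(0.1))).arity() == 2

    def test_constant_over_lifetime(self, m_fig2):
        g = _gen(m_fig2, window(5))
        before = g.arity()
        g.start()
        while g.next() is not None:
            pass
        assert g.arity() == before == 0


class TestSize:
    def test_delta_cut_to_seven(self):
        g = _gen(delta(), window(7))
        assert g.size() == 7

    def test_explicit_mask_counts_pairs_in_window(self, m_fig2):
        assert _gen(m_fig2, window(5)).size() == 6
        assert _gen(m_fig2, window(2, 5)).size() == 4

    def test_random_mask_size_is_unknown_sentinel(self):
        assert _gen(random_mask(0.1, 0), window(5)).size() == SIZE_UNKNOWN

    def test_size_before_masks_errors(self, m_fig2):
        with pytest.raises(RuntimeError, match="set_mask"):
            _gen(m_fig2).size()

    def test_intersection_with_cross_narrows_the_window(self):
        expr = delta() & cross(IntervalSet.range(0, 7), IntervalSet.range(0, 7))
        assert _gen(expr, window(20)).size() == 7


class TestIterationOrder:
    def test_worked_example_stream_is_target_major(self, m_fig2):
        assert stream_pairs(m_fig2, window(5)) == FIG2A_PAIRS

    def test_delta_diagonal_ascending(self):
        assert stream_pairs(delta(), window(7)) == [(k, k) for k in range(7)]

    def test_values_attached_in_stream(self, m_fig2):
        got = [(c.source, c.target, c.values)
               for c in _gen(cset(m_fig2, constant(9.0)), window(5))]
        assert got == [(i, j, (9.0,)) for i, j in FIG2A_PAIRS]

    @pytest.mark.parametrize("trial", range(6))
    def test_streams_strictly_increase_in_target_major_order(self, trial):
        rng = np.random.default_rng(40 + trial)
        pairs = stream_pairs(random_expression(rng, 2), window(15))
        keys = [(j, i) for i, j in pairs]
        assert keys == sorted(keys) and len(set(keys)) == len(keys)


class TestProtocolStates:
    def test_next_before_start_errors(self, m_fig2):
        g = _gen(m_fig2, window(5))
        with pytest.raises(RuntimeError, match="start"):
            g.next()

    def test_set_mask_mid_iteration_errors(self, m_fig2):
        g = _gen(m_fig2, window(5))
        g.start()
        g.next()
        with pytest.raises(RuntimeError, match="mid-iteration"):
            g.set_mask(window(5))

    def test_exhaustion_is_stable(self, m_fig2):
        g = _gen(m_fig2, window(5))
        g.start()
        while g.next() is not None:
            pass
        assert [g.next() for _ in range(5)] == [None] * 5

    def test_start_restarts_from_the_beginning(self, m_fig2):
        g = _gen(m_fig2, window(5))
        g.start()
        first = g.next()
        g.start()
        assert g.next() == first

    def test_replay_identical_streams(self):
        expr = cset(random_mask(0.3, seed=2), constant(1.5))
        a = [(c.source, c.target, c.values) for c in _gen(expr, window(12))]
        b = [(c.source, c.target, c.values) for c in _gen(expr, window(12))]
        assert a == b

    def test_empty_target_set_exhausts_immediately(self, m_fig2):
        g = _gen(m_fig2)
        g.set_mask(MaskSpec(IntervalSet.range(0, 5), IntervalSet()))
        g.start()
        assert g.next() is None


class TestWindowing:
    def test_window_restricts_sources(self, m_fig2):
        assert stream_pairs(m_fig2, window(2, 5)) == [(0, 1), (1, 1), (1, 2), (0, 4)]


class TestRankPartitioning:
    def test_two_rank_parity_split_of_worked_example(self, m_fig2):
        src = IntervalSet.range(0, 5)
        masks = [
            MaskSpec(src, interval_set_from_ids([0, 2, 4])),
            MaskSpec(src, interval_set_from_ids([1, 3])),
        ]
        g = CSAGenerator(m_fig2)
        g.set_masks(masks, 0)
        assert {(c.source, c.target) for c in g} == {(1, 2), (3, 2), (0, 4)}
        g.set_masks(masks, 1)
        assert {(c.source, c.target) for c in g} == {(0, 1), (1, 1), (2, 3)}

    def test_single_rank_equals_set_mask(self, m_fig2):
        g1 = _gen(m_fig2, window(5))
        g2 = CSAGenerator(m_fig2)
        g2.set_masks([window(5)], 0)
        assert [(c.source, c.target) for c in g1] == [(c.source, c.target) for c in g2]

    def test_local_rank_out_of_range(self, m_fig2):
        with pytest.raises(ValueError, match="out of range"):
            CSAGenerator(m_fig2).set_masks([window(5)], 1)

    def test_overlapping_target_masks_warn_but_run(self, m_fig2):
        src = IntervalSet.range(0, 5)
        masks = [MaskSpec(src, IntervalSet.range(0, 3)),
                 MaskSpec(src, IntervalSet.range(2, 5))]
        g = CSAGenerator(m_fig2)
        with pytest.warns(UserWarning, match="overlap"):
            g.set_masks(masks, 0)
        assert list(g) is not None

    @pytest.mark.parametrize("n_ranks", [1, 2, 3, 7])
    @pytest.mark.parametrize("trial", range(4))
    def test_partition_completeness_and_disjointness(self, n_ranks, trial):
        rng = np.random.default_rng(1000 * n_ranks + trial)
        expr = random_expression(rng, 2)
        n = 50 if trial == 0 else 10
        src = IntervalSet.range(0, n)
        serial = set(stream_pairs(expr, MaskSpec(src, IntervalSet.range(0, n))))
        masks = []
        for r in range(n_ranks):
            local = [j for j in range(n) if j % n_ranks == r]
            masks.append(MaskSpec(src, interval_set_from_ids(local) if local else IntervalSet()))
        g = CSAGenerator(expr)
        union: set = set()
        for r in range(n_ranks):
            g.set_masks(masks, r)
            got = {(c.source, c.target) for c in g}
            assert not (union & got), "per-rank streams must be disjoint"
            union |= got
        assert union == serial

    def test_rho_membership_identical_across_rank_layouts(self):
        # The random mask realization must not depend on who asks.
        m = random_mask(0.4, seed=6)
        whole = set(stream_pairs(m, window(20)))
        for n_ranks in (2, 5):
            got = set()
            for r in range(n_ranks):
                local = [j for j in range(20) if j % n_ranks == r]
                got |= set(stream_pairs(
                    m, MaskSpec(IntervalSet.range(0, 20), interval_set_from_ids(local))
                ))
            assert got == whole
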