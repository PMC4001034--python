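import numpy as np
import pytest

from connset import (
    CSAGenerator,
    Network,
    Population,
    cg_connect,
    cset,
    delta,
    network_stats,
    random_mask,
    rank_of_target,
)
from connset.values import constant, uniform_random

from helpers import FIG2A_PAIRS

GIDS = [11, 12, 13, 14, 15]


@pytest.fixture
def g_fig2(m_fig2):
    return CSAGenerator(m_fig2)


class TestRankOfTarget:
    def test_single_rank_takes_everything(self):
        assert rank_of_target(5, 1) == 0

    def test_modulo_assignment(self):
        assert rank_of_target(5, 2) == 1

    @pytest.mark.parametrize("n_ranks", [1, 2, 3, 5])
    def test_partition_is_disjoint_and_exhaustive(self, n_ranks):
        buckets = [set() for _ in range(n_ranks)]
        for j in range(40):
            buckets[rank_of_target(j, n_ranks)].add(j)
        assert set().union(*buckets) == set(range(40))
        assert sum(len(b) for b in buckets) == 40


class TestCgConnect:
    def test_worked_example_maps_indices_to_gids(self, g_fig2):
        net = cg_connect(Network(), g_fig2, GIDS, GIDS, {}, n_ranks=1)
        got = {(c.source_gid, c.target_gid) for c in net.connections}
        assert len(net.connections) == 6
        assert {(11, 12), (11, 15)} <= got
        assert got == {(11 + i, 11 + j) for i, j in FIG2A_PAIRS}

    @pytest.mark.parametrize("n_ranks", [1, 2, 3, 7])
    def test_stored_set_is_rank_invariant(self, m_fig2, n_ranks):
        serial = cg_connect(Network(), CSAGenerator(m_fig2), GIDS, GIDS, {}, 1)
        multi = cg_connect(Network(), CSAGenerator(m_fig2), GIDS, GIDS, {}, n_ranks)
        key = lambda n: sorted((c.source_gid, c.target_gid, c.params) for c in n.connections)
        assert key(serial) == key(multi)

    @pytest.mark.parametrize("n_ranks", [1, 3, 7])
    def test_rank_invariance_with_random_mask_and_values(self, n_ranks):
        expr = cset(random_mask(0.3, seed=5), constant(2.0), uniform_random(0, 1, seed=8))
        pmap = {"weight": 0, "delay": 1}
        gids = list(range(1, 31))
        serial = cg_connect(Network(), CSAGenerator(expr), gids, gids, pmap, 1)
        multi = cg_connect(Network(), CSAGenerator(expr), gids, gids, pmap, n_ranks)
        key = lambda n: sorted((c.source_gid, c.target_gid, c.params) for c in n.connections)
        assert key(serial) == key(multi)

    def test_param_map_names_every_stored_connection(self, m_fig2):
        expr = cset(m_fig2, constant(1.0), constant(0.1))
        net = cg_connect(Network(), CSAGenerator(expr), GIDS, GIDS,
                         {"weight": 0, "delay": 1})
        for c in net.connections:
            assert c.param_dict() == {"weight": 1.0, "delay": 0.1}

    def test_param_map_index_out_of_range(self, m_fig2):
        expr = cset(m_fig2, constant(1.0))
        with pytest.raises(ValueError, match="out of range"):
            cg_connect(Network(), CSAGenerator(expr), GIDS, GIDS, {"delay": 1})

    def test_duplicate_param_indices_rejected(self, m_fig2):
        expr = cset(m_fig2, constant(1.0), constant(2.0))
        with pytest.raises(ValueError, match="distinct"):
            cg_connect(Network(), CSAGenerator(expr), GIDS, GIDS,
                       {"weight": 0, "delay": 0})

    def test_strict_mode_reproduces_historical_arity_restriction(self, m_fig2):
        expr = cset(m_fig2, constant(1.0))
        with pytest.raises(ValueError, match="arities 0 and 2"):
            cg_connect(Network(strict_arity=True), CSAGenerator(expr), GIDS, GIDS,
                       {"weight": 0})
        # arity 0 and 2 both pass in strict mode
        cg_connect(Network(strict_arity=True), CSAGenerator(m_fig2), GIDS, GIDS, {})
        cg_connect(Network(strict_arity=True),
                   CSAGenerator(cset(m_fig2, constant(1.0), constant(0.1))),
                   GIDS, GIDS, {"weight": 0, "delay": 1})

    def test_custom_rank_assignment_preserves_invariance(self, m_fig2):
        block = lambda j, R: min(j * R // 5, R - 1)  # block partition of 5 targets
        serial = cg_connect(Network(), CSAGenerator(m_fig2), GIDS, GIDS, {}, 1)
        multi = cg_connect(Network(), CSAGenerator(m_fig2), GIDS, GIDS, {}, 3,
                           rank_assign=block)
        key = lambda n: sorted((c.source_gid, c.target_gid) for c in n.connections)
        assert key(serial) == key(multi)

    def test_population_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            Population([1, 1, 2])
        with pytest.raises(ValueError, match="non-empty"):
            Population([])
        with pytest.raises(ValueError, match="positive"):
            Population([0, 1])


class TestNetworkStats:
    def test_worked_example_counts_and_in_degree(self, g_fig2):
        net = cg_connect(Network(), g_fig2, GIDS, GIDS, {})
        stats = network_stats(net)
        assert stats["total"] == 6
        # index 2 maps to GID 13 and has two inbound pairs: (1,2),(3,2)
        assert stats["in_degree"][13] == 2
        assert stats["multi_edges"] == {}

    def test_empty_network(self):
        assert network_stats(Network())["total"] == 0

    def test_delta_over_seven(self):
        gids = list(range(1, 8))
        net = cg_connect(Network(), CSAGenerator(delta()), gids, gids, {})
        assert network_stats(net)["total"] == 7

    def test_multi_edges_are_stored_and_flagged(self, m_fig2):
        net = cg_connect(Network(), CSAGenerator(m_fig2), GIDS, GIDS, {})
        cg_connect(net, CSAGenerator(m_fig2), GIDS, GIDS, {})
        stats = network_stats(net)
        assert stats["total"] == 12
        assert stats["multi_edges"][(11, 12)] == 2

    def test_param_ranges(self, m_fig2):
        expr = cset(m_fig2, uniform_random(0.0, 1.0, seed=3))
        net = cg_connect(Network(), CSAGenerator(expr), GIDS, GIDS, {"weight": 0})
        lo, hi = network_stats(net)["param_ranges"]["weight"]
        assert 0.0 <= lo <= hi < 1.0


class TestExport:
    def test_tsv_table_has_named_columns(self, tmp_path, m_fig2):
        expr = cset(m_fig2, constant(1.0), constant(0.1))
        net = cg_connect(Network(), CSAGenerator(expr), GIDS, GIDS,
                         {"weight": 0, "delay": 1})
        out = tmp_path / "net.tsv"
        net.write_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == ["source_gid", "target_gid", "delay", "weight"]
        assert len(out.read_text().splitlines()) == 7

    def test_mtx_adjacency_round_trips(self, tmp_path, m_fig2):
        import scipy.io

        net = cg_connect(Network(), CSAGenerator(m_fig2), GIDS, GIDS, {})
        out = tmp_path / "net.mtx"
        net.write_mtx(out)
        m = scipy.io.mmread(out).tocoo()
        assert m.nnz == 6
        assert set(zip(m.row.tolist(), m.col.tolist())) == {
            (11 + i, 11 + j) for i, j in FIG2A_PAIRS
        }
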