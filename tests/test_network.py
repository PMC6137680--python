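import math

import numpy as np
import pandas as pd
import pytest

from transdrug.io import SourceEdgeTable
from transdrug.network import (
    CurationError,
    canonicalize,
    degree_table,
    enrichment_frame,
    exclusive_substrates,
    exclusively_shared,
    family_enrichment,
    largest_component,
    merge_sources,
    shared_substrates,
)
from transdrug.synth import generate_network_fixture


def _table(rows):
    return SourceEdgeTable(pd.DataFrame(rows, columns=["source", "compound", "transporter"]))


class TestMergeSources:
    def test_same_pair_from_three_sources_gets_support_three(self):
        t = _table(
            [["drugbank", "mtx", "SLC19A1"], ["kegg", "mtx", "SLC19A1"], ["iuphar", "mtx", "SLC19A1"]]
        )
        net = merge_sources([t])
        assert net.edges == {("SLC19A1", "mtx"): 3}

    def test_aliases_collapse_to_one_canonical_compound(self):
        # the same drug under trade and chemical names from different sources
        tables = [
            _table([["drugbank", "YM155", "SLC35F2"]]),
            _table([["literature", "sepantronium bromide", "SLC35F2"]]),
        ]
        aliases = {"YM155": "sepantronium bromide"}
        net = merge_sources(tables, aliases)
        assert net.edges == {("SLC35F2", "sepantronium bromide"): 2}

    def test_empty_input_gives_empty_network(self):
        net = merge_sources([])
        assert net.n_edges == 0 and not net.transporters

    def test_duplicate_rows_from_one_source_count_once(self):
        t = _table([["db", "x", "T"], ["db", "x", "T"]])
        assert merge_sources([t]).edges == {("T", "x"): 1}

    def test_alias_cycle_detected(self):
        with pytest.raises(CurationError, match="cycle"):
            canonicalize("a", {"a": "b", "b": "a"})

    def test_empty_canonical_name_rejected(self):
        with pytest.raises(CurationError, match="empty"):
            canonicalize("a", {"a": " "})


class TestDegreeAndSubstrates:
    def test_hub_ranks_first(self):
        net, _ = generate_network_fixture(5, 20, seed=2)
        t_deg, _ = degree_table(net)
        assert t_deg["degree"].iloc[0] == t_deg["degree"].max()
        assert list(t_deg["degree"]) == sorted(t_deg["degree"], reverse=True)

    def test_empty_network_gives_empty_tables(self):
        from transdrug.io import TransportNetwork

        t_deg, c_deg = degree_table(TransportNetwork(set(), set(), {}))
        assert len(t_deg) == 0 and len(c_deg) == 0

    def test_degree_sums_equal_edge_count(self):
        net, _ = generate_network_fixture(10, 50, seed=4)
        t_deg, c_deg = degree_table(net)
        assert t_deg["degree"].sum() == c_deg["degree"].sum() == net.n_edges

    @pytest.mark.parametrize("seed", range(4))
    def test_fixture_statistics_match_generator_truth(self, seed):
        net, truth = generate_network_fixture(10, 60, seed=seed)
        t_deg, c_deg = degree_table(net)
        assert dict(zip(t_deg["transporter"], t_deg["degree"])) == truth["transporter_degrees"]
        assert dict(zip(c_deg["compound"], c_deg["degree"])) == truth["compound_degrees"]
        assert sorted(exclusive_substrates(net, truth["hub"])) == truth["exclusive_hub_substrates"]
        t1, t2 = truth["pair"]
        assert sorted(exclusively_shared(net, t1, t2)) == truth["exclusively_shared_pair"]
        assert sorted(shared_substrates(net, t1, t2)) == truth["shared_pair"]

    def test_exclusive_substrates_have_degree_one(self):
        net, truth = generate_network_fixture(8, 40, seed=1)
        _, c_deg = degree_table(net)
        degs = dict(zip(c_deg["compound"], c_deg["degree"]))
        for c in exclusive_substrates(net, truth["hub"]):
            assert degs[c] == 1

    def test_shared_is_superset_of_exclusively_shared(self):
        net, truth = generate_network_fixture(8, 40, seed=6)
        t1, t2 = truth["pair"]
        assert exclusively_shared(net, t1, t2) <= shared_substrates(net, t1, t2)


class TestLargestComponent:
    def test_matches_generator_bfs_truth(self):
        for seed in range(4):
            net, truth = generate_network_fixture(9, 45, seed=seed)
            sub = largest_component(net)
            assert sorted(sub.transporters | sub.compounds) == truth["largest_component_nodes"]

    def test_connected_network_is_identity(self):
        from transdrug.io import TransportNetwork

        net = TransportNetwork({"T1", "T2"}, {"c"}, {("T1", "c"): 1, ("T2", "c"): 1})
        sub = largest_component(net)
        assert sub.edges == net.edges

    def test_larger_component_wins(self):
        from transdrug.io import TransportNetwork

        net = TransportNetwork(
            {"T1", "T2"},
            {"a", "b", "c", "d", "e"},
            {("T1", "a"): 1, ("T1", "b"): 1, ("T1", "c"): 1, ("T2", "d"): 1},
        )
        sub = largest_component(net)
        assert sub.transporters == {"T1"}
        assert sub.compounds == {"a", "b", "c"}


def exact_upper_tail(M, K, N, k):
    """Exhaustive hypergeometric P(X >= k) from binomial coefficients."""
    total = math.comb(M, N)
    return sum(math.comb(K, i) * math.comb(M - K, N - i) for i in range(k, min(K, N) + 1)) / total


class TestFamilyEnrichment:
    def test_certain_event_has_p_one(self):
        background = {f"g{i}": "FAM" for i in range(6)}
        res = family_enrichment(set(background), background)
        assert res[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        background = {f"g{i}": ("FAM" if i < 5 else "OTHER") for i in range(20)}
        node_set = {f"g{i}" for i in range(4)} | {f"g{i}" for i in range(10, 16)}  # 4 of FAM
        res = {r.family: r for r in family_enrichment(node_set, background)}
        assert res["FAM"].in_component == 4
        assert res["FAM"].p_value == pytest.approx(exact_upper_tail(20, 5, 10, 4), abs=1e-12)
        assert res["OTHER"].p_value == pytest.approx(exact_upper_tail(20, 15, 10, 6), abs=1e-12)

    def test_all_p_one_flags_nothing(self):
        # every family fully contained and node set = background -> p = 1 everywhere
        background = {f"g{i}": f"F{i % 10}" for i in range(30)}
        res = family_enrichment(set(background), background)
        assert all(r.fdr == pytest.approx(1.0) for r in res)
        assert not any(r.significant for r in res)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(15)]
        fams = rng.choice(["A", "B", "C"], size=15)
        background = dict(zip(genes, fams))
        node_set = set(rng.choice(genes, size=7, replace=False))
        res1 = {r.family: r.p_value for r in family_enrichment(node_set, background)}
        relabel = {g: f"x{g}" for g in genes}
        res2 = {
            r.family: r.p_value
            for r in family_enrichment(
                {relabel[g] for g in node_set}, {relabel[g]: f for g, f in background.items()}
            )
        }
        assert res1 == res2

    def test_bh_values_dominate_raw_p(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(25)]
        background = dict(zip(genes, rng.choice(["A", "B", "C", "D"], size=25)))
        node_set = set(rng.choice(genes, size=10, replace=False))
        res = family_enrichment(node_set, background)
        for r in res:
            assert r.fdr >= r.p_value - 1e-15
        frame = enrichment_frame(res).sort_values("p_value")
        assert frame["fdr"].is_monotonic_increasing

    def test_node_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            family_enrichment({"zzz"}, {"g": "F"})
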