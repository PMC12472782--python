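"""Edge-table parsing, induced components, hypergeometric enrichment."""

import numpy as np
import pytest
from scipy import stats

from proteopipe import (hypergeometric_enrichment, induced_subgraph, read_gmt,
                        read_string_edges)


def write_edges(tmp_path, rows):
    path = tmp_path / "edges.tsv"
    lines = ["protein1\tprotein2\tcombined_score"]
    lines += [f"{a}\t{b}\t{s}" for a, b, s in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestEdgeTable:
    def test_toy_file_all_edges(self, tmp_path):
        g = read_string_edges(write_edges(tmp_path, [("A", "B", 100), ("B", "C", 500),
                                                     ("C", "D", 900)]), min_score=0)
        assert g.number_of_edges() == 3

    def test_reversed_duplicate_keeps_max_score(self, tmp_path):
        g = read_string_edges(write_edges(tmp_path, [("A", "B", 300), ("B", "A", 700)]),
                              min_score=0)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["combined_score"] == 700

    def test_min_score_filter_matches_manual_count(self, tmp_path):
        rows = [("A", "B", 200), ("B", "C", 699), ("C", "D", 700), ("D", "E", 950)]
        g = read_string_edges(write_edges(tmp_path, rows), min_score=700)
        assert g.number_of_edges() == sum(s >= 700 for *_, s in rows)

    def test_self_loops_dropped(self, tmp_path):
        g = read_string_edges(write_edges(tmp_path, [("A", "A", 900), ("A", "B", 900)]),
                              min_score=0)
        assert list(g.edges) == [("A", "B")]

    def test_malformed_score_reports_line(self, tmp_path):
        path = write_edges(tmp_path, [("A", "B", 500), ("B", "C", "high")])
        with pytest.raises(ValueError, match="line 3"):
            read_string_edges(path)


class TestInducedSubgraph:
    def test_hand_traceable_chain(self, tmp_path):
        g = read_string_edges(write_edges(tmp_path, [("A", "B", 900), ("B", "C", 900),
                                                     ("C", "D", 900)]), min_score=0)
        comps = induced_subgraph(g, {"A", "B", "D"}, min_component=2)
        assert comps == [{"A", "B"}]  # D is isolated once C is excluded

    def test_empty_significant_set(self, tmp_path):
        g = read_string_edges(write_edges(tmp_path, [("A", "B", 900)]), min_score=0)
        assert induced_subgraph(g, set()) == []

    def test_full_node_set_recovers_graph_components(self, tmp_path):
        import networkx as nx
        rows = [("A", "B", 900), ("B", "C", 900), ("X", "Y", 900), ("Y", "Z", 900),
                ("P", "Q", 900)]
        g = read_string_edges(write_edges(tmp_path, rows), min_score=0)
        comps = induced_subgraph(g, g.nodes, min_component=1)
        oracle = sorted((set(c) for c in nx.connected_components(g)),
                        key=lambda c: (-len(c), min(c)))
        assert comps == oracle

    def test_partition_property(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [(f"N{a}", f"N{b}", 900)
                for a, b in rng.integers(0, 30, (60, 2)) if a != b]
        g = read_string_edges(write_edges(tmp_path, rows), min_score=0)
        significant = {f"N{i}" for i in range(0, 30, 2)}
        comps = induced_subgraph(g, significant, min_component=1)
        union = set().union(*comps) if comps else set()
        assert union == significant & set(g.nodes)
        assert sum(len(c) for c in comps) == len(union)  # disjoint


class TestEnrichment:
    def test_enumerated_tail_probability(self):
        # universe 10, term 4, selected 5, overlap 4: p = C(4,4)C(6,1)/C(10,5) = 6/252
        universe = [f"g{i}" for i in range(10)]
        term = set(universe[:4])
        selected = universe[:4] + [universe[9]]
        table = hypergeometric_enrichment(selected, {"T": {"name": "t", "genes": term}},
                                          universe)
        assert table.loc[0, "p_value"] == pytest.approx(6 / 252)

    def test_zero_overlap_and_whole_universe_terms(self):
        universe = [f"g{i}" for i in range(8)]
        terms = {"small": {"name": "s", "genes": {universe[0]}},
                 "all": {"name": "a", "genes": set(universe)}}
        table = hypergeometric_enrichment(universe[4:], terms, universe).set_index("term_id")
        assert table.loc["small", "p_value"] == pytest.approx(1.0)
        assert table.loc["all", "p_value"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"a"}, {}, set())

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(40)]
        term = set(rng.choice(universe, 12, replace=False))
        selected = set(rng.choice(universe, 10, replace=False))
        p1 = hypergeometric_enrichment(selected, {"T": {"name": "t", "genes": term}},
                                       universe).loc[0, "p_value"]
        relabel = {g: f"x{i}" for i, g in enumerate(universe)}
        p2 = hypergeometric_enrichment({relabel[g] for g in selected},
                                       {"T": {"name": "t",
                                              "genes": {relabel[g] for g in term}}},
                                       [relabel[g] for g in universe]).loc[0, "p_value"]
        assert p1 == pytest.approx(p2)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(2)
        n_draws = 20_000
        for _ in range(5):
            M = int(rng.integers(20, 60))
            K = int(rng.integers(3, M // 2))
            N = int(rng.integers(3, M // 2))
            universe = [f"g{i}" for i in range(M)]
            term = set(universe[:K])
            selected = list(rng.choice(universe, N, replace=False))
            obs = len(term & set(selected))
            p = hypergeometric_enrichment(selected, {"T": {"name": "t", "genes": term}},
                                          universe).loc[0, "p_value"]
            # resample overlaps by permuting the term-membership indicator
            indicator = np.tile(np.arange(M) < K, (n_draws, 1))
            rng.permuted(indicator, axis=1, out=indicator)
            p_mc = (indicator[:, :N].sum(axis=1) >= obs).mean()
            se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
            assert abs(p_mc - p) <= 3 * se + 1e-9

    def test_top_flag_limits_per_category(self):
        universe = [f"g{i}" for i in range(30)]
        terms = {f"T{i}": {"name": f"t{i}", "genes": set(universe[i:i + 5])}
                 for i in range(25)}
        table = hypergeometric_enrichment(universe[:6], terms, universe, top_n=20)
        assert table["top"].sum() == 20
        assert (table.loc[table["top"], "rank"] <= 20).all()


def test_read_gmt_round_structure(tmp_path):
    path = tmp_path / "anno.gmt"
    path.write_text("GO:1\tsynapse\tA\tB\tC\nKEGG:2\tglycolysis\tB\tD\n")
    terms = read_gmt(path)
    assert terms["GO:1"]["genes"] == {"A", "B", "C"}
    assert terms["KEGG:2"]["name"] == "glycolysis"
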