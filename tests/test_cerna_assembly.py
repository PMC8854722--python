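import itertools

import pytest

from cerna_forge.cerna_assembly import (
    build_edges,
    build_triads,
    edge_partition,
    export_network,
)
from cerna_forge.io_formats import read_network_graphml
from cerna_forge.sponge_matcher import SpongeSite
from cerna_forge.target_scoring import DuplexAlignment


def tsite(mirna, target, score=1.0, start=0):
    return DuplexAlignment(mirna, target, (start, start + 21), "|" * 21, score)


def ssite(mirna, ncrna, cls="lncRNA", start=0):
    return SpongeSite(mirna, ncrna, cls, (start, start + 21), "|" * 21, 0, 0, 0)


class TestBuildEdges:
    def test_no_de_features_no_edges(self):
        edges = build_edges([tsite("m1", "g1")], [ssite("m1", "l1")], set(), {})
        assert edges == []

    def test_minimal_two_edge_network(self):
        edges = build_edges(
            [tsite("m1", "g1")],
            [ssite("m1", "l1")],
            {"m1"},
            {"mRNA": {"g1"}, "lncRNA": {"l1"}},
        )
        assert edge_partition(edges) == {
            "miRNA-mRNA": 1, "miRNA-lncRNA": 1, "miRNA-circRNA": 0, "total": 2,
        }

    def test_edges_deduplicated_with_site_count_and_best_score(self):
        edges = build_edges(
            [tsite("m1", "g1", 3.0, 0), tsite("m1", "g1", 1.5, 50)],
            [],
            {"m1"},
            {"mRNA": {"g1"}},
        )
        assert len(edges) == 1
        assert edges[0].n_sites == 2
        assert edges[0].best_score == 1.5

    def test_non_de_mirna_excluded(self):
        edges = build_edges(
            [tsite("m1", "g1")], [], set(), {"mRNA": {"g1"}}
        )
        assert edges == []

    def test_unknown_sponge_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            build_edges([], [ssite("m1", "x1", cls="tRNA")], {"m1"}, {})

    def test_matches_naive_join_on_random_fixtures(self, rng):
        mirnas = [f"m{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(10)]
        lncs = [f"l{i}" for i in range(6)]
        for _ in range(15):
            targets = [
                tsite(mirnas[int(rng.integers(6))], genes[int(rng.integers(10))])
                for _ in range(int(rng.integers(1, 25)))
            ]
            sponges = [
                ssite(mirnas[int(rng.integers(6))], lncs[int(rng.integers(6))])
                for _ in range(int(rng.integers(1, 15)))
            ]
            de_m = {m for m in mirnas if rng.random() < 0.5}
            de_p = {
                "mRNA": {g for g in genes if rng.random() < 0.5},
                "lncRNA": {l for l in lncs if rng.random() < 0.5},
                "circRNA": set(),
            }
            edges = build_edges(targets, sponges, de_m, dict(de_p))
            want = {
                (s.mirna_id, s.target_id, "mRNA")
                for s in targets
                if s.mirna_id in de_m and s.target_id in de_p["mRNA"]
            } | {
                (s.mirna_id, s.ncrna_id, "lncRNA")
                for s in sponges
                if s.mirna_id in de_m and s.ncrna_id in de_p["lncRNA"]
            }
            assert {(e.mirna_id, e.partner_id, e.partner_class) for e in edges} == want

    def test_partition_sums_to_total(self, rng):
        edges = build_edges(
            [tsite("m1", "g1"), tsite("m2", "g2")],
            [ssite("m1", "l1"), ssite("m2", "c1", cls="circRNA")],
            {"m1", "m2"},
            {"mRNA": {"g1", "g2"}, "lncRNA": {"l1"}, "circRNA": {"c1"}},
        )
        part = edge_partition(edges)
        assert part["miRNA-mRNA"] + part["miRNA-lncRNA"] + part["miRNA-circRNA"] == part["total"]


class TestBuildTriads:
    def edges_for(self, sponge_map, target_map):
        targets = [tsite(m, g) for m, gs in target_map.items() for g in gs]
        sponges = [ssite(m, l) for m, ls in sponge_map.items() for l in ls]
        all_m = set(sponge_map) | set(target_map)
        de_p = {
            "mRNA": {g for gs in target_map.values() for g in gs},
            "lncRNA": {l for ls in sponge_map.values() for l in ls},
            "circRNA": set(),
        }
        return build_edges(targets, sponges, all_m, de_p)

    def test_disjoint_mirnas_yield_no_triads(self):
        edges = self.edges_for({"m1": ["l1"]}, {"m2": ["g1"]})
        assert build_triads(edges) == []

    def test_two_sponges_three_targets_give_six_triads(self):
        edges = self.edges_for({"m1": ["l1", "l2"]}, {"m1": ["g1", "g2", "g3"]})
        triads = build_triads(edges)
        assert len(triads) == 6
        assert {(t.cerna_id, t.mrna_id) for t in triads} == set(
            itertools.product(["l1", "l2"], ["g1", "g2", "g3"])
        )

    def test_count_equals_sum_of_products(self, rng):
        for _ in range(10):
            sponge_map = {
                f"m{i}": [f"l{j}" for j in range(int(rng.integers(0, 4)))]
                for i in range(5)
            }
            target_map = {
                f"m{i}": [f"g{j}" for j in range(int(rng.integers(0, 5)))]
                for i in range(5)
            }
            edges = self.edges_for(sponge_map, target_map)
            want = sum(
                len(sponge_map.get(m, [])) * len(target_map.get(m, []))
                for m in set(sponge_map) | set(target_map)
            )
            assert len(build_triads(edges)) == want

    def test_removing_a_mirna_removes_exactly_its_edges_and_triads(self):
        edges = self.edges_for(
            {"m1": ["l1"], "m2": ["l2"]}, {"m1": ["g1"], "m2": ["g2", "g3"]}
        )
        triads = build_triads(edges)
        without = [e for e in edges if e.mirna_id != "m2"]
        triads_without = build_triads(without)
        assert {t for t in triads if t.mirna_id != "m2"} == set(triads_without)
        assert len(triads) - len(triads_without) == 2


class TestExport:
    def test_empty_network_writes_valid_files(self, tmp_path):
        summary = export_network([], [], str(tmp_path) + "/")
        assert summary["edges"]["total"] == 0
        assert (tmp_path / "network.sif").read_text() == ""
        g = read_network_graphml(tmp_path / "network.graphml")
        assert g.number_of_nodes() == 0

    def test_roundtrip_preserves_classes_and_edge_count(self, tmp_path):
        edges = build_edges(
            [tsite("m1", "g1")],
            [ssite("m1", "l1"), ssite("m1", "c1", cls="circRNA")],
            {"m1"},
            {"mRNA": {"g1"}, "lncRNA": {"l1"}, "circRNA": {"c1"}},
        )
        triads = build_triads(edges)
        summary = export_network(edges, triads, str(tmp_path) + "/")
        sif = (tmp_path / "network.sif").read_text().splitlines()
        assert len(sif) == len(edges) == summary["edges"]["total"]
        g = read_network_graphml(tmp_path / "network.graphml")
        assert g.nodes["c1"]["rna_class"] == "circRNA"
        assert g.number_of_edges() == len(edges)

    def test_export_is_byte_deterministic(self, tmp_path):
        edges = build_edges(
            [tsite("m1", "g1")], [ssite("m1", "l1")],
            {"m1"}, {"mRNA": {"g1"}, "lncRNA": {"l1"}},
        )
        export_network(edges, build_triads(edges), str(tmp_path) + "/a_")
        export_network(list(reversed(edges)), build_triads(edges), str(tmp_path) + "/b_")
        for name in ("edges.tsv", "network.sif", "network.graphml", "summary.json"):
            assert (tmp_path / f"a_{name}").read_bytes() == (
                tmp_path / f"b_{name}"
            ).read_bytes()
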