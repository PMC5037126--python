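import random

import pytest

from desatnet import align, network
from desatnet.align import PairAlignment
from desatnet.network import (
    apply_threshold,
    build_network,
    connected_components,
    major_clusters,
    threshold_sweep,
)
from desatnet.repnode import RepNode
from desatnet.seqio import ProteinRecord

from conftest import random_protein


def toy_alignment(u, v, logE):
    return PairAlignment(u, v, 500, 200.0, logE, 80.0, 400, 400, 400)


def toy_ssn(edge_spec, n_nodes=5, sizes=None, stringency=-5.0):
    """SSN over nodes N1..Nk with given (u, v, logE) edges."""
    rng = random.Random(0)
    sizes = sizes or {}
    records, nodes = [], []
    for i in range(1, n_nodes + 1):
        rid = f"N{i}"
        members = [rid] + [f"N{i}m{j}" for j in range(sizes.get(rid, 1) - 1)]
        for mid in members:
            records.append(random_protein(rng, 60, mid))
        nodes.append(RepNode(rid, tuple(members)))
    alignments = [toy_alignment(u, v, le) for u, v, le in edge_spec]
    return build_network(nodes, alignments, records, stringency)


class TestBuildNetwork:
    def test_single_passing_edge(self):
        ssn = toy_ssn([("N1", "N2", -10.0)], n_nodes=2)
        assert ssn.edges == [("N1", "N2", -10.0)]

    def test_no_edges(self):
        ssn = toy_ssn([], n_nodes=3)
        assert ssn.edges == []
        assert len(ssn.node_ids) == 3

    def test_edges_above_stringency_dropped(self):
        ssn = toy_ssn([("N1", "N2", -3.0)], n_nodes=2)
        assert ssn.edges == []

    def test_duplicate_pair_is_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            toy_ssn([("N1", "N2", -10.0), ("N2", "N1", -12.0)], n_nodes=2)

    def test_unknown_node_is_error(self):
        with pytest.raises(ValueError, match="non-representative"):
            toy_ssn([("N1", "N9", -10.0)], n_nodes=2)

    def test_self_edge_is_error(self):
        with pytest.raises(ValueError, match="self-edge"):
            toy_ssn([("N1", "N1", -10.0)], n_nodes=2)


class TestApplyThreshold:
    def test_paper_overview_threshold(self):
        ssn = toy_ssn(
            [("N1", "N2", -10.0), ("N2", "N3", -20.0), ("N3", "N4", -60.0)],
            n_nodes=4,
        )
        strict = apply_threshold(ssn, -13.0)
        assert [e[2] for e in strict.edges] == [-20.0, -60.0]

    def test_fd_resolution_threshold(self):
        ssn = toy_ssn([("N1", "N2", -20.0), ("N2", "N3", -60.0)], n_nodes=3)
        assert [e[2] for e in apply_threshold(ssn, -56.0).edges] == [-60.0]

    def test_equal_threshold_is_identity(self):
        ssn = toy_ssn([("N1", "N2", -10.0)], n_nodes=2)
        same = apply_threshold(ssn, ssn.stringency)
        assert same.edges == ssn.edges

    def test_nodes_never_removed(self):
        ssn = toy_ssn([("N1", "N2", -10.0)], n_nodes=4)
        assert apply_threshold(ssn, -60.0).node_ids == ssn.node_ids

    def test_loosening_is_error(self):
        ssn = toy_ssn([], n_nodes=2, stringency=-13.0)
        with pytest.raises(ValueError, match="loosen"):
            apply_threshold(ssn, -5.0)

    def test_boundary_edge_retained_at_equal_logE(self):
        ssn = toy_ssn([("N1", "N2", -13.0)], n_nodes=2)
        assert apply_threshold(ssn, -13.0).edges


class TestConnectedComponents:
    def test_two_components(self):
        ssn = toy_ssn(
            [("N1", "N2", -10.0), ("N2", "N3", -10.0), ("N4", "N5", -10.0)]
        )
        part = connected_components(ssn)
        groups = {
            label: set(info.node_ids) for label, info in part.clusters.items()
        }
        assert groups == {"N1": {"N1", "N2", "N3"}, "N4": {"N4", "N5"}}

    def test_edgeless_network_gives_singletons(self):
        part = connected_components(toy_ssn([], n_nodes=5))
        assert len(part.clusters) == 5
        assert all(info.node_count == 1 for info in part.clusters.values())

    def test_complete_graph_single_component(self):
        edges = [
            (f"N{i}", f"N{j}", -30.0) for i in range(1, 5) for j in range(i + 1, 5)
        ]
        part = connected_components(toy_ssn(edges, n_nodes=4))
        assert len(part.clusters) == 1

    def test_protein_counts_sum_to_corpus(self):
        sizes = {"N1": 5, "N2": 3}
        ssn = toy_ssn([("N1", "N2", -10.0)], n_nodes=4, sizes=sizes)
        part = connected_components(ssn)
        total = sum(info.protein_count for info in part.clusters.values())
        assert total == 5 + 3 + 1 + 1

    def test_labels_invariant_to_node_order(self):
        spec = [("N2", "N5", -10.0), ("N1", "N3", -20.0)]
        a = connected_components(toy_ssn(spec))
        b = connected_components(toy_ssn(list(reversed(spec))))
        assert dict(a.assignment) == dict(b.assignment)


class TestThresholdSweep:
    def test_single_threshold_matches_components(self):
        ssn = toy_ssn([("N1", "N2", -10.0), ("N2", "N3", -40.0)])
        ((t, part),) = threshold_sweep(ssn, [-5.0])
        direct = connected_components(apply_threshold(ssn, -5.0))
        assert dict(part.assignment) == dict(direct.assignment)

    def test_paper_preset_accepted(self):
        ssn = toy_ssn([("N1", "N2", -70.0)])
        out = threshold_sweep(ssn, list(network.PAPER_SWEEP))
        assert [t for t, _ in out] == list(network.PAPER_SWEEP)

    def test_refinement_along_sweep(self, small_build):
        sweep = threshold_sweep(small_build.ssn, [-5.0, -20.0, -60.0, -100.0])
        for (_, loose), (_, strict) in zip(sweep, sweep[1:]):
            for label, info in strict.clusters.items():
                parents = {loose.assignment[n] for n in info.node_ids}
                assert len(parents) == 1  # strict cluster inside one loose cluster

    def test_component_count_nondecreasing(self, small_build):
        sweep = threshold_sweep(small_build.ssn, [-5.0, -20.0, -60.0, -100.0])
        counts = [len(p.clusters) for _, p in sweep]
        assert counts == sorted(counts)

    def test_non_monotone_list_rejected(self):
        ssn = toy_ssn([])
        with pytest.raises(ValueError, match="decreasing"):
            threshold_sweep(ssn, [-5.0, -5.0])


class TestMajorClusters:
    def test_strict_cut_at_paper_default(self):
        sizes = {"N1": 60, "N2": 51, "N3": 50, "N4": 3}
        part = connected_components(toy_ssn([], n_nodes=4, sizes=sizes))
        majors = major_clusters(part, 50)
        assert [part.clusters[l].protein_count for l in majors] == [60, 51]

    def test_all_below_cut(self):
        part = connected_components(toy_ssn([], n_nodes=3))
        assert major_clusters(part, 50) == []

    def test_zero_cut_returns_all(self):
        part = connected_components(toy_ssn([], n_nodes=3))
        assert len(major_clusters(part, 0)) == 3


class TestExport:
    def test_edge_tsv_roundtrip(self, tmp_path, small_build):
        base = tmp_path / "ssn"
        network.export_graph(small_build.ssn, base, "edge-tsv")
        back = network.import_edge_tsv(base.with_suffix(".edges.tsv"))
        original = sorted(
            small_build.alignments, key=lambda a: (a.query_id, a.subject_id)
        )
        retained = [a for a in original if a.logE <= small_build.ssn.stringency]
        assert back == retained

    def test_node_table_one_row_per_repnode(self, tmp_path, small_build):
        import pandas as pd

        base = tmp_path / "ssn"
        network.export_graph(small_build.ssn, base, "edge-tsv")
        nodes = pd.read_csv(base.with_suffix(".nodes.tsv"), sep="\t")
        assert len(nodes) == len(small_build.repnodes)
        assert set(nodes.columns) >= {
            "rep_id", "size", "has_characterized", "kingdom_majority",
        }

    def test_graphml_and_xgmml_written(self, tmp_path, small_build):
        g = tmp_path / "ssn.graphml"
        network.export_graph(small_build.ssn, g, "graphml")
        assert g.stat().st_size > 0
        x = tmp_path / "ssn.xgmml"
        network.export_graph(small_build.ssn, x, "xgmml")
        text = x.read_text()
        assert text.count("<node ") == len(small_build.repnodes)
        assert text.count("<edge ") == len(small_build.ssn.edges)

    def test_unknown_format_rejected(self, tmp_path, small_build):
        with pytest.raises(ValueError, match="format"):
            network.export_graph(small_build.ssn, tmp_path / "x", "gexf")


def test_save_load_roundtrip(tmp_path, small_build):
    network.save_build(
        tmp_path / "net", small_build.records, small_build.repnodes,
        small_build.ssn,
    )
    records, repnodes, ssn = network.load_build(tmp_path / "net")
    assert repnodes == small_build.repnodes
    assert ssn.edges == small_build.ssn.edges
    assert ssn.stringency == small_build.ssn.stringency
    assert sorted(r.id for r in records) == sorted(
        r.id for r in small_build.records
    )
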