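"""Nearest-gene mapping, network inference, intersection and export."""

import numpy as np
import pytest

from pairscan import (
    AssociationResult,
    GeneAnnotation,
    export_network,
    infer_network,
    intersect_networks,
    nearest_gene,
    read_network_tsv,
)


@pytest.fixture()
def annotation():
    return GeneAnnotation.from_records(
        [
            ("G1", "6", 1000, 2000),
            ("G2", "6", 5000, 6000),
            ("G3", "6", 9000, 9500),
            ("GX", "7", 100, 200),
        ]
    )


def _result(snp_i, snp_j, p=1e-15, imp=1e6, pattern=1):
    return AssociationResult(
        snp_i=snp_i, snp_j=snp_j, pattern_id=pattern, chi2=60.0,
        p_pair=p, log10_p_pair=np.log10(p), odds_ratio=2.0,
        p_single_i=1e-4, p_single_j=1e-5,
        improvement=imp, log10_improvement=np.log10(imp),
    )


class TestNearestGene:
    def test_inside_gene_is_distance_zero(self, annotation):
        assert nearest_gene("6", 1500, annotation) == ("G1", 0)

    def test_between_genes_takes_nearer(self, annotation):
        assert nearest_gene("6", 2100, annotation) == ("G1", 100)
        assert nearest_gene("6", 4800, annotation) == ("G2", 200)

    def test_equidistant_tie_prefers_smaller_start(self, annotation):
        # position 3500 is 1500 from G1's end and 1500 from G2's start
        assert nearest_gene("6", 3500, annotation) == ("G1", 1500)

    def test_no_gene_on_chromosome(self, annotation):
        assert nearest_gene("12", 500, annotation) is None

    def test_matches_linear_scan_oracle(self, annotation, rng):
        table = annotation.table
        for pos in rng.integers(1, 12000, size=25):
            pos = int(pos)
            best = None
            for row in table.itertuples(index=False):
                if row.chrom != "6":
                    continue
                gap = max(row.start - pos, 0, pos - row.end)
                key = (gap, row.start, row.gene_id)
                if best is None or key < best:
                    best = key
            gene, dist = nearest_gene("6", pos, annotation)
            assert (dist, gene) == (best[0], best[2])

    def test_bed_coordinates_convert_to_one_based(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("6\t999\t2000\tG1\n")
        ann = GeneAnnotation.read_bed(bed)
        # BED start 999 (0-based) is base 1000 (1-based); both ends inclusive
        assert nearest_gene("6", 1000, ann) == ("G1", 0)
        assert nearest_gene("6", 2000, ann) == ("G1", 0)
        assert nearest_gene("6", 2001, ann) == ("G1", 1)


LOCI = {
    "rs1": ("6", 1500),   # G1
    "rs2": ("6", 1900),   # G1
    "rs3": ("6", 5500),   # G2
    "rs4": ("6", 9100),   # G3
    "rs5": ("9", 100),    # unmappable
}


class TestInference:
    def test_toy_edge_set_matches_hand_enumeration(self, annotation):
        results = [
            _result("rs1", "rs3"),
            _result("rs2", "rs3"),  # same gene pair as above -> one edge
            _result("rs3", "rs4"),
            _result("rs1", "rs2"),  # both in G1 -> self-loop
            _result("rs1", "rs5"),  # rs5 unmappable -> dropped
        ]
        net = infer_network(results, LOCI, annotation)
        assert net.edge_keys() == {("G1", "G2"), ("G2", "G3"), ("G1", "G1")}
        assert net.self_loops() == {("G1", "G1")}
        assert len(net.graph.edges["G1", "G2"]["supports"]) == 2

    def test_max_distance_drops_far_snps(self, annotation):
        loci = {"rsA": ("6", 2000), "rsB": ("6", 2900)}  # rsB is 900 from G1
        near = infer_network([_result("rsA", "rsB")], loci, annotation, max_distance=1000)
        far = infer_network([_result("rsA", "rsB")], loci, annotation, max_distance=500)
        assert near.n_edges == 1
        assert far.n_edges == 0

    def test_best_support_statistics_aggregate(self, annotation):
        results = [
            _result("rs1", "rs3", p=1e-20, imp=1e3),
            _result("rs2", "rs3", p=1e-15, imp=1e9),
        ]
        net = infer_network(results, LOCI, annotation)
        edge = net.graph.edges["G1", "G2"]
        assert edge["best_p"] == 1e-20
        assert edge["best_improvement"] == 1e9


def _net(annotation, pairs):
    return infer_network([_result(a, b) for a, b in pairs], LOCI, annotation)


class TestIntersection:
    def test_disjoint_networks_empty(self, annotation):
        a = _net(annotation, [("rs1", "rs3")])
        b = _net(annotation, [("rs3", "rs4")])
        assert intersect_networks(a, b).n_edges == 0

    def test_identical_networks_preserved(self, annotation):
        a = _net(annotation, [("rs1", "rs3"), ("rs3", "rs4")])
        out = intersect_networks(a, a)
        assert out.edge_keys() == a.edge_keys()

    def test_self_loops_dropped_on_request(self, annotation):
        # {G1G2, G2G3, G1G1} vs {G1G2, G1G1}: intersection drops the loop
        a = _net(annotation, [("rs1", "rs3"), ("rs3", "rs4"), ("rs1", "rs2")])
        b = _net(annotation, [("rs1", "rs3"), ("rs1", "rs2")])
        assert intersect_networks(a, b, drop_self_loops=True).edge_keys() == {("G1", "G2")}
        kept = intersect_networks(a, b, drop_self_loops=False)
        assert kept.edge_keys() == {("G1", "G2"), ("G1", "G1")}

    def test_commutative(self, annotation):
        a = _net(annotation, [("rs1", "rs3"), ("rs3", "rs4")])
        b = _net(annotation, [("rs3", "rs4")])
        assert intersect_networks(a, b).edge_keys() == intersect_networks(b, a).edge_keys()


class TestExport:
    def test_edge_tsv_roundtrip(self, annotation, tmp_path):
        net = _net(annotation, [("rs1", "rs3"), ("rs2", "rs3"), ("rs3", "rs4")])
        path = tmp_path / "net.tsv"
        export_network(net, path, "edge-tsv")
        back = read_network_tsv(path)
        assert back.edge_keys() == net.edge_keys(include_self_loops=False)
        for u, v in back.edge_keys():
            assert back.graph.edges[u, v]["supports"] == net.graph.edges[u, v]["supports"]
            assert back.graph.edges[u, v]["best_p"] == net.graph.edges[u, v]["best_p"]

    def test_self_loops_excluded_by_default(self, annotation, tmp_path):
        net = _net(annotation, [("rs1", "rs2"), ("rs1", "rs3")])  # one loop, one edge
        path = tmp_path / "net.tsv"
        export_network(net, path, "edge-tsv")
        assert read_network_tsv(path).edge_keys() == {("G1", "G2")}

    def test_sif_line_count_equals_edges(self, annotation, tmp_path):
        net = _net(annotation, [("rs1", "rs3"), ("rs3", "rs4")])
        path = tmp_path / "net.sif"
        export_network(net, path, "sif")
        assert len(path.read_text().splitlines()) == 2

    def test_empty_network_header_only(self, tmp_path):
        from pairscan.network import GeneNetwork

        path = tmp_path / "empty.tsv"
        export_network(GeneNetwork.empty(), path, "edge-tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("gene_a")
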