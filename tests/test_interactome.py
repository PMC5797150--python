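"""Interaction-table parsing, evidence filtering, and network assembly."""

import pytest

from polyphenome import (
    FormatError,
    InteractionRecord,
    ParameterError,
    degree_histogram,
    filter_interactions,
    merge,
    parse_bindingdb_like,
    parse_sif_like,
    parse_stitch_like,
    source_overlap,
)
from polyphenome.interactome import summary, to_graphml, write_edge_list

STITCH_HEADER = "compound_id\tprotein_id\texperimental\tdatabase\tprediction\ttextmining\tcombined_score\n"


@pytest.fixture
def stitch_file(tmp_path):
    path = tmp_path / "stitch.tsv"
    path.write_text(
        STITCH_HEADER
        + "quercetin\tCYP1A2\t900\t0\t0\t150\t920\n"
        + "quercetin\tabcb1\t0\t0\t0\t950\t950\n"       # textmining-only
        + "resveratrol\tSIRT1\t700\t200\t0\t0\t890\n"   # combined below 0.9
    )
    return path


class TestParsers:
    def test_stitch_scaling_and_channels(self, stitch_file):
        records = parse_stitch_like(stitch_file)
        assert len(records) == 3
        first = records[0]
        assert first.combined_score == pytest.approx(0.92)
        assert first.channels == {"experimental": 0.9, "database": 0.0,
                                  "prediction": 0.0, "textmining": 0.15}
        # protein ids normalized to uppercase symbols
        assert records[1].protein_id == "ABCB1"

    def test_stitch_score_900_is_0p9(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text(STITCH_HEADER + "c\tP1\t0\t0\t0\t0\t900\n")
        assert parse_stitch_like(path)[0].combined_score == 0.9

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(STITCH_HEADER)
        assert parse_stitch_like(path) == []

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "broken.tsv"
        path.write_text("compound_id\tprotein_id\tcombined_score\nc\tP\t900\n")
        with pytest.raises(FormatError, match="experimental"):
            parse_stitch_like(path)

    def test_out_of_range_score_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(STITCH_HEADER + "c\tP1\t0\t0\t0\t0\t1500\n")
        with pytest.raises(FormatError, match=":2"):
            parse_stitch_like(path)

    def test_sif_triples(self, tmp_path):
        path = tmp_path / "pc.sif"
        path.write_text("quercetin\tinteracts-with\tCYP1A2\n")
        records = parse_sif_like(path)
        assert len(records) == 1
        rec = records[0]
        assert (rec.compound_id, rec.protein_id, rec.source_db) == (
            "quercetin", "CYP1A2", "pathway_commons_like")
        assert rec.combined_score is None and not rec.channels

    def test_sif_malformed_line_number(self, tmp_path):
        path = tmp_path / "pc.sif"
        path.write_text("ok\trel\tP1\nbroken line\n")
        with pytest.raises(FormatError, match=":2"):
            parse_sif_like(path)

    def test_bindingdb_keeps_any_affinity(self, tmp_path):
        path = tmp_path / "bdb.tsv"
        path.write_text("compound_id\tprotein_id\taffinity_nM\nc\tP1\t999999.0\n")
        assert len(parse_bindingdb_like(path)) == 1

    def test_duplicates_preserved_at_parse(self, tmp_path):
        path = tmp_path / "pc.sif"
        path.write_text("c\trel\tP1\nc\trel\tP1\n")
        assert len(parse_sif_like(path)) == 2


class TestFilter:
    def records(self):
        def stitch(cid, pid, exp, db, pred, tm, comb):
            return InteractionRecord(cid, pid, "stitch_like",
                                     channels={"experimental": exp, "database": db,
                                               "prediction": pred, "textmining": tm},
                                     combined_score=comb)
        return [
            stitch("a", "P1", 0.0, 0.0, 0.0, 0.95, 0.95),   # textmining-only
            stitch("b", "P2", 0.92, 0.0, 0.0, 0.0, 0.92),   # clean keep
            stitch("c", "P3", 0.7, 0.2, 0.0, 0.0, 0.89),    # below 0.9
            InteractionRecord("d", "P4", "pathway_commons_like"),
        ]

    def test_textmining_only_excluded_despite_high_score(self):
        kept = filter_interactions(self.records(), min_score=0.9)
        assert [r.compound_id for r in kept] == ["b", "d"]

    def test_boundary_is_strict_less_than(self):
        kept = filter_interactions(self.records(), min_score=0.89)
        assert "c" in [r.compound_id for r in kept]
        kept = filter_interactions(self.records(), min_score=0.9)
        assert "c" not in [r.compound_id for r in kept]

    def test_relaxed_threshold_is_superset(self):
        records = self.records()
        at_09 = {id(r) for r in filter_interactions(records, min_score=0.9)}
        at_07 = {id(r) for r in filter_interactions(records, min_score=0.7)}
        assert at_09 <= at_07

    def test_monotone_in_min_score(self):
        counts = [len(filter_interactions(self.records(), min_score=s))
                  for s in (0.0, 0.5, 0.7, 0.9, 0.95, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_min_score(self):
        with pytest.raises(ParameterError):
            filter_interactions(self.records(), min_score=1.5)

    def test_nonscored_dialects_pass_vacuously(self):
        records = [InteractionRecord("x", "P9", "bindingdb_like")]
        assert filter_interactions(records, min_score=0.99) == records


class TestMergeAndAnalytics:
    def test_same_pair_two_dialects_one_edge(self):
        a = [InteractionRecord("c1", "P1", "stitch_like")]
        b = [InteractionRecord("c1", "P1", "bindingdb_like")]
        net = merge(a, b)
        assert net.n_edges == 1
        assert net.edges[("c1", "P1")] == frozenset({"stitch_like", "bindingdb_like"})

    def test_disjoint_inputs_add(self):
        a = [InteractionRecord(f"c{i}", "P1", "stitch_like") for i in range(3)]
        b = [InteractionRecord(f"d{i}", "P2", "bindingdb_like") for i in range(4)]
        assert merge(a, b).n_edges == 7

    def test_merge_idempotent(self):
        records = [InteractionRecord("c", "P1", "stitch_like"),
                   InteractionRecord("c", "P2", "stitch_like")]
        once = merge(records)
        twice = merge(records, records)
        assert once.edges == twice.edges

    def test_source_overlap_partitions_nodes(self):
        records = [
            InteractionRecord("c1", "P1", "stitch_like"),
            InteractionRecord("c1", "P1", "bindingdb_like"),
            InteractionRecord("c2", "P2", "stitch_like"),
        ]
        net = merge(records)
        cells = source_overlap(net)
        assert sum(cells["compounds"].values()) == len(net.compounds)
        assert sum(cells["proteins"].values()) == len(net.proteins)
        assert cells["compounds"] == {"bindingdb_like+stitch_like": 1, "stitch_like": 1}

    def test_single_source_single_cell(self):
        records = [InteractionRecord(f"c{i}", f"P{i}", "stitch_like") for i in range(5)]
        cells = source_overlap(merge(records))
        assert cells["compounds"] == {"stitch_like": 5}

    def test_empty_interactome(self):
        net = merge([])
        assert source_overlap(net) == {"compounds": {}, "proteins": {}}
        assert sum(degree_histogram(net, "compound").values()) == 0


class TestDegreeHistogram:
    def test_compound_with_5_edges_in_lowest_bin(self):
        records = [InteractionRecord("c", f"P{i}", "stitch_like") for i in range(5)]
        hist = degree_histogram(merge(records), "compound")
        assert hist["<=10"] == 1 and sum(hist.values()) == 1

    def test_protein_with_exactly_50_partners_goes_higher(self):
        records = [InteractionRecord(f"c{i}", "P", "stitch_like") for i in range(50)]
        hist = degree_histogram(merge(records), "protein")
        assert hist["50-70"] == 1

    def test_matches_brute_force_tally(self):
        import numpy as np
        rng = np.random.default_rng(5)
        records = [
            InteractionRecord(f"c{int(rng.integers(40))}", f"P{int(rng.integers(200))}", "stitch_like")
            for _ in range(600)
        ]
        net = merge(records)
        for side, pos, bins in (
            ("compound", 0, [(">2000", 2000), ("1000-2000", 1000), ("500-1000", 500),
                             ("100-500", 100), ("50-100", 50), ("20-50", 20),
                             ("10-20", 10), ("<=10", 1)]),
            ("protein", 1, [(">70", 70), ("50-70", 50), ("25-50", 25), ("10-25", 10),
                            ("5-10", 5), ("2-5", 2), ("1", 1)]),
        ):
            degrees = {}
            for edge in net.edges:
                degrees[edge[pos]] = degrees.get(edge[pos], 0) + 1
            expected = {label: 0 for label, _ in bins}
            for d in degrees.values():
                for label, lo in bins:  # highest matching lower bound wins
                    if d >= lo:
                        expected[label] += 1
                        break
            assert degree_histogram(net, side) == expected
            assert sum(expected.values()) == len(degrees)

    def test_bad_bins_rejected(self):
        net = merge([InteractionRecord("c", "P", "stitch_like")])
        with pytest.raises(ParameterError):
            degree_histogram(net, "compound", bins=[("a", 5), ("b", 2)])
        with pytest.raises(ParameterError):
            degree_histogram(net, "sideways")


class TestOutputs:
    def test_edge_list_and_graphml_roundtrip(self, tmp_path):
        import networkx as nx
        records = [InteractionRecord("c1", "P1", "stitch_like"),
                   InteractionRecord("c2", "P1", "bindingdb_like")]
        net = merge(records)
        write_edge_list(net, tmp_path / "edges.tsv")
        assert len((tmp_path / "edges.tsv").read_text().splitlines()) == 3
        to_graphml(net, tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == 2
        assert g.nodes["c1"]["kind"] == "compound"
        s = summary(net)
        assert s["n_edges"] == 2 and s["n_compounds"] == 2
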