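"""Hypergeometric over-representation, BH adjustment, and category roll-ups."""

import itertools
import math

import numpy as np
import pytest

from polyphenome import (
    InteractionRecord,
    ParameterError,
    PathwayGeneSet,
    ValidationError,
    bh_adjust,
    category_summary,
    enrich,
    enrich_by_class,
    hypergeometric_p,
    merge,
)
from polyphenome.enrichment import apply_ontology, coverage_matrix, read_gmt, read_ontology, write_gmt
from polyphenome.taxonomy import Classification, ExclusionReason


def enumeration_p(k, K, n, N):
    """Brute-force oracle: count draws of size n with >= k members of the K-set."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


def stepup_bh(p):
    """Brute-force BH step-up from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestHypergeometricP:
    def test_worked_example(self):
        # all C(10,4)=210 draws enumerated by hand: 5 contain >=4 of the 5-set
        assert hypergeometric_p(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_k_zero_is_one(self):
        assert hypergeometric_p(0, 5, 4, 10) == 1.0

    def test_degenerate_universe(self):
        # K = N forces every draw to hit: P[X >= n] = 1
        assert hypergeometric_p(6, 6, 6, 6) == 1.0

    def test_agrees_with_enumeration_small_sweep(self):
        for N in range(1, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        assert hypergeometric_p(k, K, n, N) == pytest.approx(
                            enumeration_p(k, K, n, N), abs=1e-12), (k, K, n, N)

    def test_monotone_in_k(self):
        ps = [hypergeometric_p(k, 20, 15, 100) for k in range(0, 16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("k,K,n,N", [(5, 4, 4, 10), (1, 5, 0, 10), (2, 11, 4, 10)])
    def test_infeasible_counts_rejected(self, k, K, n, N):
        with pytest.raises(ParameterError):
            hypergeometric_p(k, K, n, N)


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.4]) == pytest.approx([0.4])

    def test_ties(self):
        assert bh_adjust([0.5] * 4) == pytest.approx([0.5] * 4)

    def test_agrees_with_stepup_definition(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(stepup_bh(list(p)), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])


def toy_gene_sets():
    universe = [f"G{i:03d}" for i in range(40)]
    return universe, [
        PathwayGeneSet("PW0", "target", frozenset(universe[:10]), "Metabolism", "Lipid Metabolism"),
        PathwayGeneSet("PW1", "bystander", frozenset(universe[10:30]), "Human Diseases", "Cardiovascular Diseases"),
        PathwayGeneSet("PW2", "other", frozenset(universe[30:40]), "Human Diseases", "Endocrine and Metabolic Diseases"),
    ]


class TestEnrich:
    def test_planted_pathway_significant(self):
        universe, gene_sets = toy_gene_sets()
        query = universe[:8]  # 8 of PW0's 10 members
        results = {r.pathway_id: r for r in enrich(query, gene_sets, universe=universe)}
        assert results["PW0"].significant
        assert not results["PW2"].significant
        assert results["PW0"].coverage == pytest.approx(0.8)

    def test_empty_query_nothing_significant(self):
        universe, gene_sets = toy_gene_sets()
        results = enrich([], gene_sets, universe=universe)
        assert all(r.k == 0 and not r.significant for r in results)
        assert all(r.p_raw == 1.0 for r in results)

    def test_coverage_definition(self):
        universe, gene_sets = toy_gene_sets()
        query = universe[:3]
        r = {x.pathway_id: x for x in enrich(query, gene_sets, universe=universe)}["PW0"]
        assert (r.k, r.K) == (3, 10) and r.coverage == pytest.approx(0.3)

    def test_query_outside_universe_dropped(self):
        universe, gene_sets = toy_gene_sets()
        results = enrich(universe[:5] + ["NOT_A_GENE"], gene_sets, universe=universe)
        assert results[0].n == 5

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            enrich(["G1"], [], universe=[])

    def test_significance_thresholds_are_strict(self):
        universe, gene_sets = toy_gene_sets()
        query = universe[:8]
        results = enrich(query, gene_sets, universe=universe, min_coverage=0.8)
        r = {x.pathway_id: x for x in results}["PW0"]
        assert r.coverage == pytest.approx(0.8) and not r.significant  # strict >


def classification(cid, classes):
    return Classification(cid, frozenset(), frozenset(), frozenset(classes),
                          False, ExclusionReason.NONE)


class TestEnrichByClass:
    def network(self, universe):
        records = [InteractionRecord("flav1", p, "stitch_like") for p in universe[:8]]
        records += [InteractionRecord("stilb1", universe[35], "stitch_like")]
        return merge(records)

    def test_class_wired_to_pathway_significant(self):
        universe, gene_sets = toy_gene_sets()
        net = self.network(universe)
        classifications = [classification("flav1", ["flavonoids"]),
                           classification("stilb1", ["stilbenes"])]
        results = enrich_by_class(net, classifications, gene_sets, universe=universe)
        flav = {r.pathway_id: r for r in results["flavonoids"]}
        assert flav["PW0"].significant

    def test_identical_query_sets_identical_tables(self):
        universe, gene_sets = toy_gene_sets()
        records = [InteractionRecord(c, p, "stitch_like")
                   for c in ("a", "b") for p in universe[:6]]
        net = merge(records)
        classifications = [classification("a", ["flavonoids"]),
                           classification("b", ["lignans"])]
        results = enrich_by_class(net, classifications, gene_sets, universe=universe)
        flav = [(r.pathway_id, r.p_bh, r.significant) for r in results["flavonoids"]]
        lign = [(r.pathway_id, r.p_bh, r.significant) for r in results["lignans"]]
        assert flav == lign

    def test_unknown_class_rejected(self):
        universe, gene_sets = toy_gene_sets()
        net = self.network(universe)
        with pytest.raises(ValidationError, match="phenolic acids"):
            enrich_by_class(net, [classification("flav1", ["flavonoids"])],
                            gene_sets, universe=universe, classes=["phenolic acids"])

    def test_class_without_proteins_empty_result(self):
        universe, gene_sets = toy_gene_sets()
        net = self.network(universe)
        classifications = [classification("flav1", ["flavonoids"]),
                           classification("ghost", ["lignans"])]
        results = enrich_by_class(net, classifications, gene_sets, universe=universe)
        assert results["lignans"] == []


class TestCategorySummary:
    def test_percentages_and_cmd_union(self):
        universe, gene_sets = toy_gene_sets()
        query = universe[:8]
        results = enrich(query, gene_sets, universe=universe)
        out = category_summary(results, gene_sets)
        assert out["Metabolism"]["percent_enriched"] == pytest.approx(100.0)
        assert out["Human Diseases"]["percent_enriched"] == pytest.approx(0.0)
        # CMD = cardiovascular + endocrine/metabolic subcategories (2 pathways here)
        assert out["CMD"]["n_pathways"] == 2

    def test_no_significant_all_zero(self):
        universe, gene_sets = toy_gene_sets()
        results = enrich([], gene_sets, universe=universe)
        out = category_summary(results, gene_sets)
        assert all(v["percent_enriched"] == 0.0 for v in out.values())

    def test_unmapped_pathway_rejected(self):
        universe, gene_sets = toy_gene_sets()
        results = enrich(universe[:5], gene_sets, universe=universe)
        with pytest.raises(ValidationError, match="PW2"):
            category_summary(results, gene_sets[:2])

    def test_coverage_matrix_shape(self):
        universe, gene_sets = toy_gene_sets()
        res = enrich(universe[:8], gene_sets, universe=universe, query_label="flavonoids")
        mat = coverage_matrix({"flavonoids": res}, gene_sets)
        assert list(mat.columns) == ["flavonoids"]
        assert mat.loc["PW0", "flavonoids"] == pytest.approx(0.8)


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        universe, gene_sets = toy_gene_sets()
        path = tmp_path / "sets.gmt"
        write_gmt(gene_sets, path)
        back = read_gmt(path)
        assert [gs.pathway_id for gs in back] == ["PW0", "PW1", "PW2"]
        assert back[0].members == gene_sets[0].members

    def test_ontology_attach(self, tmp_path):
        universe, gene_sets = toy_gene_sets()
        path = tmp_path / "ont.tsv"
        path.write_text("pathway_id\tcategory\tsubcategory\n"
                        "PW0\tMetabolism\tLipid Metabolism\n"
                        "PW1\tHuman Diseases\tCardiovascular Diseases\n"
                        "PW2\tHuman Diseases\tEndocrine and Metabolic Diseases\n")
        bare = [PathwayGeneSet(gs.pathway_id, gs.name, gs.members) for gs in gene_sets]
        mapped = apply_ontology(bare, read_ontology(path))
        assert mapped[0].category == "Metabolism"
        with pytest.raises(ValidationError, match="PW2"):
            apply_ontology(bare, {"PW0": ("a", "b"), "PW1": ("a", "b")})
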