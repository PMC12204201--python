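"""Reliability scoring (topological, semantic, STRING) and filtering."""

import math

import networkx as nx
import numpy as np
import pytest

import sigentropy as sg
from sigentropy.correction import (
    ICTable,
    NetworkParseError,
    Ontology,
    filter_network,
    gene_similarity,
    information_content,
    load_string_scores,
    read_obo,
    read_scores,
    semantic_edge_scores,
    term_similarity,
    topological_scores,
    write_annotations,
    write_scores,
)
from sigentropy.synthdata import write_ontology_obo


# ---------------------------------------------------------------------------
# Topological scoring


class TestTopologicalScores:
    def test_dice_identical_inclusive_neighbourhoods(self):
        # i and j both connect to a, b and to each other: Int_i == Int_j
        net = sg.InteractionNetwork.from_edges(
            [("i", "j"), ("i", "a"), ("i", "b"), ("j", "a"), ("j", "b")]
        )
        scores = topological_scores(net, "dice")
        assert scores.get("i", "j") == pytest.approx(1.0)

    def test_jaccard_no_common_neighbours(self):
        net = sg.InteractionNetwork.from_edges([("i", "j"), ("i", "c"), ("j", "d")])
        assert topological_scores(net, "jaccard").get("i", "j") == 0.0

    def test_invlog_unique_maximum_rescaled_to_one(self):
        # edge i-j shares the single neighbour z with k_z = 3 (raw 1/ln 3);
        # extra leaves push i and j to degree 5 so i-z and j-z score lower
        # (raw 1/ln 5) and i-j is the unique maximum
        edges = [("i", "j"), ("i", "z"), ("j", "z"), ("z", "w")]
        edges += [("i", f"li{k}") for k in range(3)]
        edges += [("j", f"lj{k}") for k in range(3)]
        net = sg.InteractionNetwork.from_edges(edges)
        scores = topological_scores(net, "invlog")
        assert scores.get("i", "j") == pytest.approx(1.0)
        assert scores.get("z", "w") == 0.0
        # check the raw ordering that produced the rescale
        assert 1 / math.log(3) > 1 / math.log(5)

    def test_all_scores_within_unit_interval_random(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            g = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(2**31)))
            g.add_edges_from([(0, 1), (1, 2)])
            net = sg.InteractionNetwork(nx.relabel_nodes(g, {v: f"N{v}" for v in g.nodes}))
            for method in ("jaccard", "dice", "invlog"):
                vals = list(topological_scores(net, method).scores.values())
                assert all(0.0 <= v <= 1.0 for v in vals)


# ---------------------------------------------------------------------------
# Information content


def _chain_ontology():
    """root <- a <- b (is_a), plus root <- c (part_of)."""
    dag = nx.DiGraph()
    dag.add_edge("a", "root", relation="is_a")
    dag.add_edge("b", "a", relation="is_a")
    dag.add_edge("c", "root", relation="part_of")
    return Ontology(dag)


class TestInformationContent:
    def test_root_ic_zero(self):
        ont = _chain_ontology()
        ic = information_content(ont, {"g1": {"b"}, "g2": {"c"}})
        assert ic.ic["root"] == 0.0

    def test_half_coverage_ln2(self):
        ont = _chain_ontology()
        ic = information_content(ont, {"g1": {"b"}, "g2": {"c"}})
        assert ic.ic["a"] == pytest.approx(math.log(2), abs=1e-12)

    def test_child_ic_at_least_parent(self, toy_ontology):
        ont, ann = toy_ontology
        ic = information_content(ont, ann)
        for child, parent in ont.dag.edges:
            if child in ic.ic and parent in ic.ic:
                assert ic.ic[child] >= ic.ic[parent] - 1e-12

    def test_unannotated_terms_excluded_with_warning(self, caplog):
        ont = _chain_ontology()
        with caplog.at_level("WARNING"):
            ic = information_content(ont, {"g1": {"b"}})
        assert "c" not in ic.ic


# ---------------------------------------------------------------------------
# Term and gene similarity


class TestTermSimilarity:
    @pytest.fixture
    def chain_ic(self):
        ont = _chain_ontology()
        ic = information_content(ont, {"g1": {"b"}, "g2": {"a"}, "g3": {"c"}, "g4": {"c"}})
        return ont, ic

    @pytest.mark.parametrize("method", ["resnik", "lin", "jiang", "wang"])
    def test_self_similarity_at_max_ic_is_one(self, chain_ic, method):
        ont, ic = chain_ic
        top = max(ic.ic, key=lambda t: ic.ic[t])
        assert term_similarity(ic, ont, top, top, method) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["resnik", "schlicker"])
    def test_root_mica_gives_zero(self, chain_ic, method):
        ont, ic = chain_ic
        assert term_similarity(ic, ont, "b", "c", method) == pytest.approx(0.0)

    def test_wang_chain_self_svalues(self):
        """For root <- a <- b via is_a: S_b = {b: 1, a: 0.8, root: 0.64}."""
        ont = _chain_ontology()
        from sigentropy.correction import _wang_svalues

        s = _wang_svalues(ont, "b", {"is_a": 0.8, "part_of": 0.6})
        assert s == pytest.approx({"b": 1.0, "a": 0.8, "root": 0.64})
        ic = information_content(ont, {"g": {"b"}, "h": {"c"}})
        assert term_similarity(ic, ont, "b", "b", "wang") == pytest.approx(1.0)

    def test_unknown_term_rejected(self, chain_ic):
        ont, ic = chain_ic
        with pytest.raises(KeyError):
            term_similarity(ic, ont, "b", "nope", "lin")

    def test_matches_bruteforce_mica_oracle(self, toy_ontology):
        """IC-based similarities vs explicit enumeration of all common
        ancestors."""
        ont, ann = toy_ontology
        ic = information_content(ont, ann)
        terms = sorted(t for t in ic.ic)
        rng = np.random.default_rng(3)
        for _ in range(50):
            t1, t2 = (terms[i] for i in rng.integers(0, len(terms), 2))
            common = {t for t in ont.ancestors(t1) & ont.ancestors(t2) if t in ic.ic}
            ic_mica = max(ic.ic[t] for t in common) if common else 0.0
            expect_resnik = ic_mica / ic.max_ic
            denom = ic.ic[t1] + ic.ic[t2]
            expect_lin = 2 * ic_mica / denom if denom > 0 else 0.0
            assert term_similarity(ic, ont, t1, t2, "resnik") == pytest.approx(expect_resnik)
            assert term_similarity(ic, ont, t1, t2, "lin") == pytest.approx(expect_lin)


class TestGeneSimilarity:
    @pytest.fixture
    def setup(self, toy_ontology):
        ont, ann = toy_ontology
        return ont, ann, information_content(ont, ann)

    def test_single_term_genes_reduce_to_term_similarity(self, setup):
        ont, ann, ic = setup
        terms = sorted(ic.ic)
        ann2 = {"x": {terms[3]}, "y": {terms[5]}}
        expected = term_similarity(ic, ont, terms[3], terms[5], "lin")
        assert gene_similarity(ann2, ic, ont, "x", "y", "lin") == pytest.approx(expected)

    def test_identical_annotation_sets_lin_one(self, setup):
        ont, ann, ic = setup
        genes = sorted(ann)
        g = genes[0]
        ann2 = {"x": set(ann[g]), "y": set(ann[g])}
        assert gene_similarity(ann2, ic, ont, "x", "y", "lin") == pytest.approx(1.0)

    def test_bma_expansion(self, setup):
        """g1 = {ta}, g2 = {ta, tb}: BMA = (1 + (1 + s_ab)/2) / 2."""
        ont, ann, ic = setup
        leaves = sorted(t for t in ont.terms if not ont.children(t) and t in ic.ic)
        ta, tb = leaves[0], leaves[1]
        s_ab = term_similarity(ic, ont, ta, tb, "lin")
        ann2 = {"x": {ta}, "y": {ta, tb}}
        expected = (1.0 + (1.0 + s_ab) / 2.0) / 2.0
        assert gene_similarity(ann2, ic, ont, "x", "y", "lin") == pytest.approx(expected)

    def test_edge_scores_skip_unannotated(self, setup, caplog):
        ont, ann, ic = setup
        genes = sorted(ann)[:3]
        net = sg.InteractionNetwork.from_edges(
            [(genes[0], genes[1]), (genes[1], "UNANNOTATED")]
        )
        with caplog.at_level("WARNING"):
            scores = semantic_edge_scores(net, ann, ic, ont, "lin")
        assert len(scores) == 1
        assert all(0.0 <= v <= 1.0 for v in scores.scores.values())


# ---------------------------------------------------------------------------
# STRING scores and generic tables


class TestStringScores:
    def test_scale_to_unit(self, tmp_path):
        p = tmp_path / "links.txt"
        p.write_text("protein1 protein2 combined_score\np1 p2 900\n")
        assert load_string_scores(p).get("p1", "p2") == pytest.approx(0.9)

    def test_duplicate_keeps_maximum(self, tmp_path, caplog):
        p = tmp_path / "links.txt"
        p.write_text("protein1 protein2 combined_score\np1 p2 300\np2 p1 700\n")
        with caplog.at_level("WARNING"):
            scores = load_string_scores(p)
        assert scores.get("p1", "p2") == pytest.approx(0.7)

    def test_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "links.txt"
        p.write_text("protein1 protein2 combined_score\np1 p2 1001\n")
        with pytest.raises(NetworkParseError):
            load_string_scores(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "links.txt"
        p.write_text("p1 p2 900\n")
        with pytest.raises(NetworkParseError, match="header"):
            load_string_scores(p)

    def test_score_table_roundtrip(self, tmp_path):
        scores = sg.ReliabilityScores({("a", "b"): 0.25, ("b", "c"): 0.75}, method="string")
        write_scores(scores, tmp_path / "s.tsv")
        back = read_scores(tmp_path / "s.tsv", method="string")
        assert back.scores == pytest.approx(scores.scores)


# ---------------------------------------------------------------------------
# Filtering


class TestFilterNetwork:
    def _scored_net(self):
        net = sg.InteractionNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        scores = sg.ReliabilityScores(
            {("a", "b"): 0.3, ("b", "c"): 0.5, ("c", "d"): 0.9}, method="test"
        )
        return net, scores

    def test_threshold_counting(self):
        net, scores = self._scored_net()
        filtered, stats = filter_network(net, scores, 0.4)
        assert filtered.n_edges == 2
        assert stats.n_removed_scored == 1

    def test_threshold_zero_identity(self):
        net, scores = self._scored_net()
        filtered, _ = filter_network(net, scores, 0.0)
        assert filtered.edges == net.edges

    def test_all_below_threshold_empties_network(self, caplog):
        net, scores = self._scored_net()
        with caplog.at_level("WARNING"):
            filtered, _ = filter_network(net, scores, 0.95)
        assert filtered.n_edges == 0

    def test_missing_scores_removed_at_positive_threshold(self):
        net = sg.InteractionNetwork.from_edges([("a", "b"), ("b", "c")])
        scores = sg.ReliabilityScores({("a", "b"): 0.9}, method="test")
        filtered, stats = filter_network(net, scores, 0.1)
        assert filtered.edges == {("a", "b")}
        assert stats.n_removed_unscored == 1

    def test_edge_count_monotone_in_threshold(self, small_study):
        _, net, _, _ = small_study
        rng = np.random.default_rng(17)
        scores = sg.ReliabilityScores(
            {e: float(rng.random()) for e in net.edges}, method="rand"
        )
        counts = [filter_network(net, scores, t)[0].n_edges for t in np.arange(0.1, 1.0, 0.1)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# Ontology I/O round trip


def test_obo_roundtrip(tmp_path, toy_ontology):
    ont, ann = toy_ontology
    write_ontology_obo(ont, tmp_path / "toy.obo")
    back = read_obo(tmp_path / "toy.obo")
    assert back.terms == ont.terms
    assert back.root == ont.root
    assert set(back.dag.edges) == set(ont.dag.edges)
    for e in ont.dag.edges:
        assert back.dag.edges[e]["relation"] == ont.dag.edges[e]["relation"]


def test_annotation_tsv_roundtrip(tmp_path, toy_ontology):
    ont, ann = toy_ontology
    write_annotations(ann, tmp_path / "ann.tsv")
    back = sg.correction.read_annotations(tmp_path / "ann.tsv", ont)
    assert back == ann


def test_gaf_columns_parsed(tmp_path):
    p = tmp_path / "ann.gaf"
    p.write_text(
        "!gaf-version: 2.2\n"
        "DB\tTP53\tTP53\t\tGO:0001\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
        "DB\tMDM2\tMDM2\t\tGO:0002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
    )
    ann = sg.correction.read_annotations(p)
    assert ann == {"TP53": {"GO:0001"}, "MDM2": {"GO:0002"}}
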