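"""Evaluation pipelines: percentile curves, matching, networking, clusters."""

import math

import networkx as nx
import numpy as np
import pytest

import ms2embed as m


def symmetric_matrix(rng, n, low=0.0, high=1.0):
    a = rng.uniform(low, high, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestTopPercentile:
    def test_perfect_score_reaches_theoretical_maximum(self):
        rng = np.random.default_rng(0)
        structural = symmetric_matrix(rng, 30)
        res = m.top_percentile_structural_means(structural, structural,
                                                fractions=[0.01, 0.1, 0.5])
        assert np.allclose(res["mean_structural"], res["theoretical_maximum"])

    def test_permuted_scores_give_global_mean(self):
        rng = np.random.default_rng(1)
        structural = symmetric_matrix(rng, 60)
        iu = np.triu_indices(60, k=1)
        perm_vals = structural[iu].copy()
        rng.shuffle(perm_vals)
        spectral = np.zeros_like(structural)
        spectral[iu] = perm_vals
        spectral += spectral.T
        res = m.top_percentile_structural_means(spectral, structural,
                                                fractions=[0.1, 0.3])
        global_mean = structural[iu].mean()
        se = structural[iu].std() / math.sqrt(0.1 * len(structural[iu]))
        for value in res["mean_structural"]:
            assert abs(value - global_mean) < 3 * se

    def test_pair_count_ceiling(self):
        # 5 nodes -> 10 unique pairs; fraction 0.2 -> exactly 2 pairs
        spectral = np.zeros((5, 5))
        structural = np.zeros((5, 5))
        spectral[0, 1] = spectral[1, 0] = 0.9
        spectral[0, 2] = spectral[2, 0] = 0.8
        structural[0, 1] = structural[1, 0] = 1.0
        structural[0, 2] = structural[2, 0] = 0.5
        res = m.top_percentile_structural_means(spectral, structural, fractions=[0.2])
        assert res["n_pairs"] == 10
        assert res["mean_structural"][0] == pytest.approx(0.75)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            m.top_percentile_structural_means(np.eye(3), np.eye(4), [0.1])


class TestPrecursorPreselect:
    def _library(self, mzs):
        return [m.Spectrum(mz=[100.0], intensities=[1.0], precursor_mz=p,
                           spectrum_id=f"lib{i}") for i, p in enumerate(mzs)]

    def test_ppm_window_boundaries(self):
        query = m.Spectrum(mz=[100.0], intensities=[1.0], precursor_mz=500.00000)
        hits = m.precursor_preselect(query, self._library([500.00049, 500.00100]))
        assert hits == [0]  # 0.98 ppm in, 2 ppm out

    def test_empty_library(self):
        query = m.Spectrum(mz=[100.0], intensities=[1.0], precursor_mz=500.0)
        assert m.precursor_preselect(query, []) == []

    def test_missing_query_precursor_errors(self):
        with pytest.raises(ValueError):
            m.precursor_preselect(m.Spectrum(mz=[100.0], intensities=[1.0]), [])


class TestLibraryMatch:
    def _spec(self, sid, precursor, mz=None):
        return m.Spectrum(mz=mz or [100.0, 110.0], intensities=[1.0, 0.5],
                          precursor_mz=precursor, spectrum_id=sid)

    def test_exact_duplicate_matched(self):
        query = self._spec("q", 400.0)
        library = [self._spec("dup", 400.0), self._spec("other", 405.0)]
        score_fn = lambda a, b: 1.0 if b.spectrum_id == "dup" else 0.1
        decisions = m.library_match([query], library, score_fn, threshold=0.95)
        assert decisions[0].matched_library_id == "dup"

    def test_no_precursor_candidates_gives_none(self):
        query = self._spec("q", 400.0)
        decisions = m.library_match([query], [self._spec("far", 500.0)],
                                    lambda a, b: 1.0, threshold=0.0)
        assert decisions[0].matched_library_id is None

    def test_score_equal_to_threshold_rejected(self):
        query = self._spec("q", 400.0)
        decisions = m.library_match([query], [self._spec("lib", 400.0)],
                                    lambda a, b: 0.7, threshold=0.7)
        assert decisions[0].matched_library_id is None  # strict >


class TestEvaluateMatches:
    def _decision(self, q, lib, score=0.9):
        return m.MatchDecision(q, lib, score, 0.5)

    def test_all_true_positives(self):
        decisions = [self._decision(f"q{i}", f"l{i}") for i in range(4)]
        truth = {f"q{i}": f"MOL{i}" for i in range(4)}
        annotations = {f"l{i}": f"MOL{i}" for i in range(4)}
        res = m.evaluate_matches(decisions, truth, annotations)
        assert res["accuracy"] == 1.0 and res["retrieval"] == 1.0

    def test_no_matches(self):
        decisions = [self._decision("q0", None)]
        res = m.evaluate_matches(decisions, {"q0": "MOL"}, {})
        assert res["accuracy"] == 0.0 and res["retrieval"] == 0.0

    def test_mixed_counts(self):
        decisions = ([self._decision(f"q{i}", "good") for i in range(8)]
                     + [self._decision(f"q{8 + i}", "bad") for i in range(2)]
                     + [self._decision(f"q{10 + i}", None) for i in range(10)])
        truth = {f"q{i}": "MOL" for i in range(20)}
        annotations = {"good": "MOL", "bad": "OTHER"}
        res = m.evaluate_matches(decisions, truth, annotations)
        assert res["accuracy"] == pytest.approx(0.8)
        assert res["retrieval"] == pytest.approx(0.5)

    def test_unannotated_match_errors(self):
        with pytest.raises(ValueError):
            m.evaluate_matches([self._decision("q", "mystery")], {"q": "MOL"}, {})


def test_threshold_sweep_retrieval_monotone(small_benchmark, small_model):
    model, corpus, lib = small_model
    docs_by_id = {d.source_id: d for d in corpus}
    queries = m.process_spectra(small_benchmark.query_spectra,
                                m.ProcessingConfig(track="embedding"))
    qdocs = {d.source_id: d for d in m.documents_from_spectra(queries)}

    def score_fn(a, b):
        return m.embedding_similarity(model, qdocs[a.spectrum_id],
                                      docs_by_id[b.spectrum_id]).score

    truth = small_benchmark.truth
    annotations = {s.spectrum_id: s.planar_inchikey() for s in lib}
    rows = m.threshold_sweep(queries, lib, score_fn, truth, annotations,
                             thresholds=[0.95, 0.7, 0.4, 0.0])
    retrievals = [row["retrieval"] for row in rows]
    assert retrievals == sorted(retrievals)  # lowering threshold never loses matches
    assert all(0 <= row["accuracy"] <= 1 for row in rows)


class TestTopK:
    def test_k_exceeding_library_ranks_everything(self):
        row = np.array([0.3, 0.9, 0.1])
        ranked = m.top_k_matches(0, row, ["a", "b", "c"], k=10)
        assert [r[0] for r in ranked] == ["b", "a", "c"]

    def test_identical_document_ranks_first(self, small_model):
        model, corpus, _ = small_model
        matrix = m.embedding_similarity_matrix(corpus[:1], corpus[:20], model)
        ranked = m.top_k_matches(0, matrix[0], [d.source_id for d in corpus[:20]], k=5)
        assert ranked[0][0] == corpus[0].source_id
        assert ranked[0][1] == pytest.approx(1.0, abs=1e-9)


class TestBuildNetwork:
    def test_triangle(self):
        matrix = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.85], [0.8, 0.85, 1.0]])
        graph = m.build_network(matrix, threshold=0.5)
        assert set(graph.edges) == {(0, 1), (0, 2), (1, 2)}

    def test_threshold_above_everything_gives_edgeless(self):
        rng = np.random.default_rng(2)
        graph = m.build_network(symmetric_matrix(rng, 6, high=0.4), threshold=0.99)
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 6

    def test_max_links_caps_contributed_edges(self):
        # hub node 0 has 15 qualifying neighbours but contributes only its
        # 10 best; the satellites prefer each other (0.9 > hub's 0.8x), so
        # none of them re-adds a hub edge and the hub degree stays capped
        n = 16
        matrix = np.full((n, n), 0.9)
        np.fill_diagonal(matrix, 1.0)
        matrix[0, 1:] = matrix[1:, 0] = np.linspace(0.80, 0.87, n - 1)
        graph = m.build_network(matrix, threshold=0.5, max_links=10)
        assert graph.degree(0) == 10
        # the hub keeps exactly its ten highest-scoring neighbours
        assert set(graph.neighbors(0)) == set(range(6, 16))

    def test_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(3)
        matrix = symmetric_matrix(rng, 12, high=0.9)
        perm = rng.permutation(12)
        permuted = matrix[np.ix_(perm, perm)]
        g1 = m.build_network(matrix, threshold=0.5, node_ids=[f"n{i}" for i in perm])
        g2 = m.build_network(permuted, threshold=0.5,
                             node_ids=[f"n{i}" for i in range(12)][:12])
        relabeled = {tuple(sorted((f"n{perm[u]}", f"n{perm[v]}")))
                     for u, v in m.build_network(permuted, threshold=0.5).edges}
        original = {tuple(sorted((f"n{u}", f"n{v}")))
                    for u, v in m.build_network(matrix, threshold=0.5).edges}
        assert relabeled == original


class TestLouvainSplit:
    @staticmethod
    def two_cliques():
        graph = nx.Graph()
        for base in (0, 6):
            for i in range(base, base + 6):
                for j in range(i + 1, base + 6):
                    graph.add_edge(i, j, weight=1.0)
        graph.add_edge(0, 6, weight=1.0)  # single bridge
        return graph

    def test_two_cliques_split_matches_modularity_oracle(self):
        graph = self.two_cliques()
        partition = m.split_clusters_louvain(graph, size_cutoff=5, seed=0)
        groups = {}
        for node, cid in partition.items():
            groups.setdefault(cid, set()).add(node)
        # independent oracle: greedy modularity maximization
        oracle = nx.community.greedy_modularity_communities(graph)
        assert {frozenset(g) for g in groups.values()} == {frozenset(c) for c in oracle}
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(range(6)), frozenset(range(6, 12))}

    def test_small_component_kept_whole(self):
        graph = self.two_cliques()
        partition = m.split_clusters_louvain(graph, size_cutoff=30, seed=0)
        assert len(set(partition.values())) == 1  # 12 <= cutoff: untouched

    def test_single_clique_one_community(self):
        graph = nx.complete_graph(6)
        partition = m.split_clusters_louvain(graph, size_cutoff=3, seed=0)
        assert len(set(partition.values())) == 1

    def test_edgeless_graph_all_singletons(self):
        graph = nx.empty_graph(5)
        partition = m.split_clusters_louvain(graph)
        assert len(set(partition.values())) == 5


class TestClusterQuality:
    def test_single_good_cluster(self):
        graph = nx.complete_graph(4)
        structural = np.full((4, 4), 0.9)
        report = m.cluster_quality({n: 0 for n in graph.nodes}, graph, structural)
        assert report.well_clustered_fraction == 1.0
        assert report.unclustered_fraction == 0.0

    def test_edgeless_graph_fully_unclustered(self):
        graph = nx.empty_graph(5)
        report = m.cluster_quality({n: n for n in graph.nodes}, graph, np.eye(5))
        assert report.unclustered_fraction == 1.0

    def test_well_and_poor_split_on_cutoff(self):
        graph = nx.Graph()
        graph.add_edges_from([(0, 1), (2, 3)])
        structural = np.zeros((4, 4))
        structural[0, 1] = structural[1, 0] = 0.6
        structural[2, 3] = structural[3, 2] = 0.3
        partition = {0: 0, 1: 0, 2: 1, 3: 1}
        report = m.cluster_quality(partition, graph, structural, cutoff=0.5)
        assert report.well_clustered_fraction == 0.5
        assert report.poorly_clustered_fraction == 0.5

    def test_fractions_sum_to_one_exactly(self):
        rng = np.random.default_rng(4)
        spectral = symmetric_matrix(rng, 25, high=0.95)
        structural = symmetric_matrix(rng, 25)
        graph = m.build_network(spectral, threshold=0.6)
        partition = m.split_clusters_louvain(graph, seed=0)
        report = m.cluster_quality(partition, graph, structural)
        total = (report.well_clustered_fraction + report.poorly_clustered_fraction
                 + report.unclustered_fraction)
        assert total == 1.0  # exact by rational bookkeeping

    def test_uncovered_partition_errors(self):
        graph = nx.complete_graph(3)
        with pytest.raises(ValueError):
            m.cluster_quality({0: 0, 1: 0}, graph, np.eye(3))
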