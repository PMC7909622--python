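"""Evaluation and application pipelines built on the similarity scores.

Four workflows mirror how spectral similarity is used in practice:

* **top-percentile analysis** — how structurally similar are the
  molecule pairs behind the highest-scoring spectral pairs?
* **library matching** — annotate query spectra by the best-scoring
  library candidate within a precursor m/z window (1 ppm), sweeping the
  acceptance threshold to trade retrieval against accuracy;
* **top-k analog search** — rank an entire library by embedding
  similarity, no precursor prefiltering, and keep the k best;
* **molecular networking** — connect each spectrum to its up-to-10
  highest-scoring neighbours above a threshold, split large components
  with Louvain, and grade clusters by the mean structural similarity of
  their internal edges (well-clustered at >= 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .spectrum import Spectrum

DEFAULT_PPM = 1.0
DEFAULT_MAX_LINKS = 10
DEFAULT_CLUSTER_CUTOFF = 0.5
DEFAULT_LOUVAIN_SIZE_CUTOFF = 30


# ---------------------------------------------------------------------------
# Score-vs-structure top-percentile analysis

def _unique_pairs(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def top_percentile_structural_means(
    spectral: np.ndarray,
    structural: np.ndarray,
    fractions: Sequence[float] = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1),
) -> dict:
    """Mean structural similarity over the top spectral-score percentiles.

    For each fraction f the ceil(f * n_pairs) unique off-diagonal pairs
    with the highest spectral scores are selected and the mean of their
    structural similarities reported, together with the theoretical
    maximum curve (mean of the f highest structural similarities —
    what a perfect score ordering would achieve).
    """
    spectral = np.asarray(spectral)
    structural = np.asarray(structural)
    if spectral.shape != structural.shape:
        raise ValueError("spectral and structural matrices must have equal shape")
    s_pairs = _unique_pairs(spectral)
    t_pairs = _unique_pairs(structural)
    n_pairs = s_pairs.size
    order = np.argsort(-s_pairs, kind="stable")
    t_sorted_by_score = t_pairs[order]
    t_best = np.sort(t_pairs)[::-1]
    curve, maximum = [], []
    for f in fractions:
        k = min(n_pairs, math.ceil(f * n_pairs))
        curve.append(float(t_sorted_by_score[:k].mean()))
        maximum.append(float(t_best[:k].mean()))
    return {"fractions": list(fractions), "mean_structural": curve,
            "theoretical_maximum": maximum, "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# Library matching

@dataclass(frozen=True)
class MatchDecision:
    """Outcome of matching one query against the library."""

    query_id: str
    matched_library_id: Optional[str]
    score: float
    threshold: float


def precursor_preselect(query: Spectrum, library: Sequence[Spectrum],
                        ppm: float = DEFAULT_PPM) -> list[int]:
    """Indices of library spectra within ``ppm`` of the query precursor."""
    if query.precursor_mz is None:
        raise ValueError("precursor preselection requires the query precursor m/z")
    window = ppm * 1e-6 * query.precursor_mz
    hits = []
    for i, ref in enumerate(library):
        if ref.precursor_mz is None:
            continue
        if abs(ref.precursor_mz - query.precursor_mz) <= window:
            hits.append(i)
    return hits


def library_match(queries: Sequence[Spectrum], library: Sequence[Spectrum],
                  score_fn: Callable[[Spectrum, Spectrum], float],
                  threshold: float, ppm: float = DEFAULT_PPM) -> list[MatchDecision]:
    """Best-scoring precursor-window candidate per query, if above threshold.

    ``score_fn`` is any pairwise score in this package returning a
    float.  A query is matched iff its best candidate scores strictly
    above the threshold; ties break on smaller precursor difference,
    then lexicographic spectrum id.
    """
    decisions = []
    for query in queries:
        candidates = precursor_preselect(query, library, ppm)
        best = None
        for idx in candidates:
            ref = library[idx]
            score = float(score_fn(query, ref))
            key = (-score, abs(ref.precursor_mz - query.precursor_mz),
                   str(ref.spectrum_id))
            if best is None or key < best[0]:
                best = (key, ref, score)
        if best is not None and best[2] > threshold:
            decisions.append(MatchDecision(str(query.spectrum_id),
                                           str(best[1].spectrum_id),
                                           best[2], threshold))
        else:
            decisions.append(MatchDecision(str(query.spectrum_id), None,
                                           best[2] if best else float("nan"),
                                           threshold))
    return decisions


def evaluate_matches(decisions: Sequence[MatchDecision],
                     truth: Mapping[str, str],
                     library_annotations: Mapping[str, str]) -> dict:
    """True/false positives, accuracy and retrieval for one threshold.

    A decision is a true positive when the matched library spectrum
    shares the query's planar InChIKey (per ``truth`` /
    ``library_annotations``), a false positive otherwise.  Retrieval is
    the fraction of queries yielding any match; accuracy is
    TP / (TP + FP) (zero when nothing was matched).
    """
    tp = fp = 0
    for decision in decisions:
        if decision.matched_library_id is None:
            continue
        if decision.matched_library_id not in library_annotations:
            raise ValueError(f"matched spectrum {decision.matched_library_id!r} "
                             "has no structure annotation")
        if library_annotations[decision.matched_library_id] == truth[decision.query_id]:
            tp += 1
        else:
            fp += 1
    n_queries = len(decisions)
    matched = tp + fp
    return {
        "true_positives": tp,
        "false_positives": fp,
        "n_queries": n_queries,
        "retrieval": matched / n_queries if n_queries else 0.0,
        "accuracy": tp / matched if matched else 0.0,
    }


def threshold_sweep(queries: Sequence[Spectrum], library: Sequence[Spectrum],
                    score_fn: Callable[[Spectrum, Spectrum], float],
                    truth: Mapping[str, str], library_annotations: Mapping[str, str],
                    thresholds: Optional[Sequence[float]] = None,
                    ppm: float = DEFAULT_PPM) -> list[dict]:
    """Library matching across a threshold grid (default 0.95 down to 0).

    Scores are computed once per (query, candidate) pair and the
    per-threshold decisions derived from the cached argmax.
    """
    if thresholds is None:
        thresholds = [round(0.95 - 0.05 * i, 2) for i in range(20)]
    # cache the best candidate per query once; only the accept step depends
    # on the threshold
    best_per_query = library_match(queries, library, score_fn, threshold=-np.inf, ppm=ppm)
    results = []
    for threshold in thresholds:
        decisions = [
            MatchDecision(d.query_id,
                          d.matched_library_id if (d.matched_library_id is not None
                                                   and d.score > threshold) else None,
                          d.score, threshold)
            for d in best_per_query
        ]
        row = evaluate_matches(decisions, truth, library_annotations)
        row["threshold"] = threshold
        results.append(row)
    return results


# ---------------------------------------------------------------------------
# Top-k analog search

def top_k_matches(query_index: int, similarity_row: np.ndarray,
                  library_ids: Sequence[str], k: int = 10) -> list[tuple[str, float]]:
    """The k highest-similarity library entries for one query row.

    Descending score, ties broken by id.  No precursor prefiltering:
    the point of embedding similarity is that ranking a whole library
    is cheap.
    """
    order = sorted(range(len(library_ids)),
                   key=lambda j: (-float(similarity_row[j]), str(library_ids[j])))
    return [(str(library_ids[j]), float(similarity_row[j])) for j in order[:k]]


# ---------------------------------------------------------------------------
# Molecular networking

def build_network(spectral: np.ndarray, threshold: float,
                  max_links: int = DEFAULT_MAX_LINKS,
                  node_ids: Optional[Sequence] = None) -> nx.Graph:
    """Connect each spectrum to its top-scoring neighbours above a threshold.

    Every node contributes its up-to-``max_links`` highest-scoring
    links with score strictly above ``threshold``; the graph is the
    undirected union, so a node's degree can exceed ``max_links``
    through edges contributed by its neighbours.  All spectra appear as
    nodes, including isolated ones.
    """
    spectral = np.asarray(spectral)
    n = spectral.shape[0]
    if spectral.shape != (n, n):
        raise ValueError("expected a square similarity matrix")
    if node_ids is None:
        node_ids = list(range(n))
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    for i in range(n):
        row = spectral[i].copy()
        row[i] = -np.inf  # no self-loops
        qualifying = np.nonzero(row > threshold)[0]
        if qualifying.size == 0:
            continue
        top = sorted(qualifying, key=lambda j: (-row[j], j))[:max_links]
        for j in top:
            graph.add_edge(node_ids[i], node_ids[j], weight=float(spectral[i, j]))
    return graph


def split_clusters_louvain(graph: nx.Graph,
                           size_cutoff: int = DEFAULT_LOUVAIN_SIZE_CUTOFF,
                           resolution: float = 1.0,
                           seed: int = 0) -> dict:
    """Partition the network, breaking up large components with Louvain.

    Connected components of at most ``size_cutoff`` nodes are kept
    whole (they are already tight, sparse families); larger components
    are replaced by their Louvain modularity communities.  Deterministic
    for a fixed seed.  Returns a node -> cluster id mapping; isolated
    nodes become singletons.
    """
    partition: dict = {}
    cluster_id = 0
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(map(str, c)))
    for component in components:
        if len(component) <= size_cutoff:
            groups = [component]
        else:
            subgraph = graph.subgraph(component)
            groups = nx.community.louvain_communities(
                subgraph, weight="weight", resolution=resolution, seed=seed)
            groups = sorted(groups, key=lambda c: sorted(map(str, c)))
        for group in groups:
            for node in group:
                partition[node] = cluster_id
            cluster_id += 1
    return partition


@dataclass(frozen=True)
class ClusterReport:
    """Partition quality relative to structural ground truth."""

    partition: dict
    cluster_mean_structural: dict
    well_clustered_fraction: float
    poorly_clustered_fraction: float
    unclustered_fraction: float
    n_nodes: int


def cluster_quality(partition: Mapping, graph: nx.Graph, structural: np.ndarray,
                    node_index: Optional[Mapping] = None,
                    cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> ClusterReport:
    """Grade clusters by mean structural similarity of internal edges.

    Nodes in clusters whose internal edges average a structural
    similarity >= ``cutoff`` count as well-clustered, below as poorly
    clustered; nodes without any edge count as unclustered.  The three
    fractions are computed with exact rational arithmetic and sum to 1.
    """
    structural = np.asarray(structural)
    if node_index is None:
        node_index = {node: i for i, node in enumerate(graph.nodes)}
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")

    clusters: dict = {}
    for node, cid in partition.items():
        clusters.setdefault(cid, []).append(node)

    cluster_means: dict = {}
    n_well = n_poor = n_unclustered = 0
    for cid, members in clusters.items():
        edges = [(u, v) for u, v in graph.subgraph(members).edges]
        isolated = [n for n in members if graph.degree(n) == 0]
        connected = [n for n in members if graph.degree(n) > 0]
        n_unclustered += len(isolated)
        if not connected:
            continue
        if edges:
            mean = float(np.mean([structural[node_index[u], node_index[v]]
                                  for u, v in edges]))
            cluster_means[cid] = mean
            if mean >= cutoff:
                n_well += len(connected)
            else:
                n_poor += len(connected)
        else:
            # connected in the graph but no internal edge: the cluster gives
            # these nodes no structural support
            n_poor += len(connected)

    n = graph.number_of_nodes()
    well = Fraction(n_well, n) if n else Fraction(0)
    poor = Fraction(n_poor, n) if n else Fraction(0)
    uncl = Fraction(n_unclustered, n) if n else Fraction(0)
    assert well + poor + uncl == (1 if n else 0)
    return ClusterReport(
        partition=dict(partition),
        cluster_mean_structural=cluster_means,
        well_clustered_fraction=float(well),
        poorly_clustered_fraction=float(poor),
        unclustered_fraction=float(uncl),
        n_nodes=n,
    )


def network_quality_sweep(spectral: np.ndarray, structural: np.ndarray,
                          thresholds: Sequence[float],
                          max_links: int = DEFAULT_MAX_LINKS,
                          cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                          size_cutoff: int = DEFAULT_LOUVAIN_SIZE_CUTOFF,
                          seed: int = 0) -> list[dict]:
    """Networking + Louvain + quality report across a threshold grid."""
    rows = []
    for threshold in thresholds:
        graph = build_network(spectral, threshold, max_links)
        partition = split_clusters_louvain(graph, size_cutoff, seed=seed)
        report = cluster_quality(partition, graph, structural, cutoff=cutoff)
        rows.append({
            "threshold": threshold,
            "well_clustered": report.well_clustered_fraction,
            "poorly_clustered": report.poorly_clustered_fraction,
            "unclustered": report.unclustered_fraction,
            "n_edges": graph.number_of_edges(),
            "n_clusters": len(set(partition.values())),
        })
    return rows
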