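"""Gene-family construction: protein filtering, all-vs-all similarity,
identity/coverage edge gating, and Markov clustering (MCL).

The clustering gate keeps an edge only when identity and the coverage of BOTH
sequences are strictly greater than the thresholds (default 70% each). MCL is
run per connected component of the gated similarity graph with inflation 2 by
default, the granularity classically used for orthologous-family construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import PROTEIN_SCORING, Scoring, align_pair
from .records import Family, Gene, HitRecord, build_census, index_genes

logger = logging.getLogger(__name__)


@dataclass
class SimilarityGraph:
    """Gated, symmetric, weighted similarity graph over gene ids."""

    graph: nx.Graph
    min_identity: float
    min_coverage: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def filter_proteins(genes: list[Gene], min_len: int = 50) -> list[Gene]:
    """Keep genes whose protein is strictly longer than ``min_len`` residues."""
    kept = [g for g in genes if g.protein_length > min_len]
    removed = [g.gene_id for g in genes if g.protein_length <= min_len]
    if removed:
        logger.info("filter_proteins removed %d genes (<= %d aa): %s",
                    len(removed), min_len, ", ".join(removed[:10]))
    return kept


def _edlib_screen(seq_a: str, seq_b: str, max_norm_dist: float) -> bool:
    """Cheap exact-edit-distance screen: True means the pair could still pass
    a 70/70 identity/coverage gate and must be aligned properly."""
    import edlib

    la, lb = len(seq_a), len(seq_b)
    k = int(max_norm_dist * max(la, lb))
    res = edlib.align(seq_a, seq_b, mode="NW", task="distance", k=k)
    return res["editDistance"] != -1


def build_graph_from_alignments(
    genes: list[Gene],
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    scoring: Scoring = PROTEIN_SCORING,
    screen_max_norm_dist: float | None = 0.65,
) -> SimilarityGraph:
    """All-vs-all local alignment of gene proteins, gated into a graph.

    An edge (a, b) is kept iff identity > min_identity and the coverage of
    both a and b is > min_coverage (all strict). Edge weight is the raw
    alignment score; MCL only needs positive weights and is scale-invariant.

    ``screen_max_norm_dist`` skips full alignment of pairs whose global edit
    distance exceeds that fraction of the longer protein — far beyond what any
    70/70 pair can reach — and may be set to None to disable the screen.
    """
    g = nx.Graph()
    for gene in genes:
        g.add_node(gene.gene_id)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genes[i], genes[j]
            if screen_max_norm_dist is not None and not _edlib_screen(
                a.protein, b.protein, screen_max_norm_dist
            ):
                continue
            res = align_pair(a.protein, b.protein, scoring)
            if (
                res.identity > min_identity
                and res.coverage_a > min_coverage
                and res.coverage_b > min_coverage
                and res.score > 0
            ):
                g.add_edge(a.gene_id, b.gene_id, weight=float(res.score))
    return SimilarityGraph(g, min_identity, min_coverage)


def build_graph_from_hits(
    hits: list[HitRecord],
    protein_lengths: dict[str, int],
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> SimilarityGraph:
    """Gate imported 12-column tabular hits into a similarity graph.

    Coverage per side is alignment_length / protein length; reciprocal
    asymmetric hits are merged by keeping the better-scoring direction.
    """
    g = nx.Graph()
    for gid in protein_lengths:
        g.add_node(gid)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        for gid in (h.query_id, h.subject_id):
            if gid not in protein_lengths:
                raise ValueError(f"hit references unknown gene {gid!r}")
        cov_q = 100.0 * h.alignment_length / protein_lengths[h.query_id]
        cov_s = 100.0 * h.alignment_length / protein_lengths[h.subject_id]
        if h.percent_identity > min_identity and cov_q > min_coverage and cov_s > min_coverage:
            u, v = h.query_id, h.subject_id
            w = float(h.bitscore)
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
    return SimilarityGraph(g, min_identity, min_coverage)


# ------------------------------------------------------------------ MCL


def _mcl_component(
    nodes: list[str],
    graph: nx.Graph,
    inflation: float,
    prune: float,
    max_iter: int,
    tol: float,
) -> list[set[str]]:
    """Run canonical MCL on one connected component; return node clusters."""
    n = len(nodes)
    if n == 1:
        return [set(nodes)]
    idx = {node: k for k, node in enumerate(nodes)}
    A = np.zeros((n, n), dtype=np.float64)
    for u, v, data in graph.edges(nodes, data=True):
        if u in idx and v in idx:
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = data["weight"]
    # self-loop = each node's maximum incident edge weight
    for k in range(n):
        m = A[k].max()
        A[k, k] = m if m > 0 else 1.0

    M = A / A.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = np.power(M, inflation)  # inflation
        M /= M.sum(axis=0, keepdims=True)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            break
    else:
        warnings.warn(
            f"MCL did not converge in {max_iter} iterations on a component of {n} nodes; "
            "reading clusters from the current matrix",
            RuntimeWarning,
        )

    # attractors: rows with positive diagonal mass; each attractor row's
    # support is one cluster. Overlapping attractor rows are merged first.
    eps = prune
    attractors = [k for k in range(n) if M[k, k] > eps]
    if not attractors:  # degenerate; fall back to strongest row per column
        attractors = list(set(int(np.argmax(M[:, j])) for j in range(n)))
    supports = [set(np.nonzero(M[k] > eps)[0].tolist()) | {k} for k in attractors]
    # attractor systems: merge supports sharing an attractor node
    raw: list[set[int]] = []
    attractor_set = set(attractors)
    for support in supports:
        hit = None
        for cl in raw:
            if cl & support & attractor_set:
                hit = cl
                break
        if hit is not None:
            hit |= support
        else:
            raw.append(support)

    # Assign every node to exactly one cluster. Nodes appearing in several
    # attractor systems (rare weight ties) go to the cluster with the larger
    # total intra-cluster weight; remaining ties pick the cluster containing
    # the lexicographically smallest node. Nodes whose mass was entirely
    # pruned are assigned the same way over all clusters.
    membership: dict[int, list[int]] = {}
    for ci, cl in enumerate(raw):
        for k in cl:
            membership.setdefault(k, []).append(ci)

    def intra_weight(k: int, ci: int) -> float:
        return sum(A[k, m] for m in raw[ci] if m != k)

    assigned: dict[int, int] = {}
    for k in range(n):
        cands = membership.get(k) or list(range(len(raw)))
        if len(cands) == 1:
            assigned[k] = cands[0]
            continue
        best_w = max(intra_weight(k, ci) for ci in cands)
        tied = [ci for ci in cands if intra_weight(k, ci) == best_w]
        assigned[k] = min(tied, key=lambda ci: min(nodes[m] for m in raw[ci]))

    clusters: dict[int, set[str]] = {}
    for k, ci in assigned.items():
        clusters.setdefault(ci, set()).add(nodes[k])
    return list(clusters.values())


def mcl_cluster(
    simgraph: SimilarityGraph,
    genes: list[Gene] | None = None,
    inflation: float = 2.0,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[Family]:
    """Markov clustering of the similarity graph into gene families.

    Expansion (matrix squaring) alternates with inflation (entrywise power
    then column re-normalization) on the column-stochastic matrix, with
    entries below ``prune`` dropped, until the matrix change falls below
    ``tol``. Families partition the node set; singletons are families of
    size 1. Family ids are assigned zero-padded in order of each family's
    smallest member id, so output is invariant to input order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    g = simgraph.graph
    clusters: list[set[str]] = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        clusters.extend(_mcl_component(nodes, g, inflation, prune, max_iter, tol))

    # check partition
    all_nodes: set[str] = set()
    for cl in clusters:
        if cl & all_nodes:
            raise AssertionError("MCL produced overlapping clusters")
        all_nodes |= cl
    if all_nodes != set(g.nodes):
        raise AssertionError("MCL clusters do not cover all nodes")

    gene_index = index_genes(genes) if genes else None
    families = []
    for i, cl in enumerate(sorted(clusters, key=min), 1):
        members = frozenset(cl)
        census = build_census(set(members), gene_index) if gene_index else {}
        families.append(Family(family_id=f"FAM{i:04d}", members=members, census=census))
    return families


@dataclass
class ClusterResult:
    families: list[Family]
    graph: SimilarityGraph
    log: dict = field(default_factory=dict)


def cluster_pipeline(
    genes: list[Gene],
    min_len: int = 50,
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    inflation: float = 2.0,
    hits: list[HitRecord] | None = None,
) -> ClusterResult:
    """Filter -> all-vs-all similarity (or imported hits) -> gate -> MCL."""
    kept = filter_proteins(genes, min_len)
    if hits is not None:
        lengths = {g.gene_id: g.protein_length for g in kept}
        simgraph = build_graph_from_hits(hits, lengths, min_identity, min_coverage)
    else:
        simgraph = build_graph_from_alignments(kept, min_identity, min_coverage)
    families = mcl_cluster(simgraph, genes=kept, inflation=inflation)
    log = {
        "n_input_genes": len(genes),
        "n_filtered_genes": len(kept),
        "n_edges": simgraph.n_edges,
        "n_families": len(families),
        "params": {
            "min_len": min_len,
            "min_identity": min_identity,
            "min_coverage": min_coverage,
            "inflation": inflation,
        },
    }
    return ClusterResult(families=families, graph=simgraph, log=log)
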