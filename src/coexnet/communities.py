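"""Community detection, modularity, partition comparison and assortativity.

Detection runs through python-igraph with a fixed, sorted vertex ordering and
an explicitly seeded RNG so every algorithm is deterministic under a fixed
seed.  Modularity is re-computed by our own weighted Newman-Girvan sum so the
reported score does not depend on any library's convention.
"""

from __future__ import annotations

import random

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CoexpressionNetwork, CommunityPartition, validate_annotation

ALGORITHMS = ("fast_greedy", "infomap", "leading_eigenvector", "louvain")


def _igraph_from_network(network: CoexpressionNetwork) -> tuple[ig.Graph, list[str]]:
    genes = network.genes  # sorted -> fixed vertex order
    index = {g: i for i, g in enumerate(genes)}
    e = network.edges
    if len(e) == 0:
        raise ValueError("cannot detect communities on an empty network")
    weights = e["score"].to_numpy(dtype=float)
    if (weights <= 0).any():
        raise ValueError("edge weights must be positive for community detection")
    pairs = list(zip(e["gene_a"].map(index), e["gene_b"].map(index)))
    g = ig.Graph(n=len(genes), edges=pairs)
    g.es["weight"] = list(weights)
    return g, genes


def detect_communities(
    network: CoexpressionNetwork, algorithm: str = "louvain", seed: int = 0
) -> CommunityPartition:
    """Partition the network's genes with one of four weighted algorithms.

    Community ids are relabelled to consecutive integers in order of first
    appearance over the sorted gene list, which makes the assignment itself
    seed-stable whenever the underlying clustering is.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    g, genes = _igraph_from_network(network)
    weights = g.es["weight"]
    rng_state = random.getstate()
    random.seed(seed)  # python-igraph draws from the stdlib RNG
    try:
        if algorithm == "louvain":
            clustering = g.community_multilevel(weights=weights)
        elif algorithm == "fast_greedy":
            clustering = g.community_fastgreedy(weights=weights).as_clustering()
        elif algorithm == "leading_eigenvector":
            clustering = g.community_leading_eigenvector(weights=weights)
        else:
            clustering = g.community_infomap(edge_weights=weights)
    finally:
        random.setstate(rng_state)
    raw = clustering.membership
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for gene, cid in zip(genes, raw):
        if cid not in relabel:
            relabel[cid] = len(relabel)
        assignment[gene] = relabel[cid]
    q = modularity(network, assignment)
    return CommunityPartition(algorithm=algorithm, assignment=assignment, modularity=q, seed=seed)


def modularity(network: CoexpressionNetwork, assignment: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity of a partition.

    ``Q = sum_c [ w_in(c)/W - (deg(c)/(2W))^2 ]`` with W the total edge
    weight, w_in the internal weight of community c and deg its weighted
    degree sum.  The all-in-one partition scores exactly 0.
    """
    e = network.edges
    missing = sorted(set(network.genes) - set(assignment))
    if missing:
        raise ValueError(f"genes without community assignment: {missing[:10]}")
    w = e["score"].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total edge weight must be positive")
    ca = e["gene_a"].map(assignment).to_numpy()
    cb = e["gene_b"].map(assignment).to_numpy()
    w_in: dict[int, float] = {}
    deg: dict[int, float] = {}
    for c1, c2, wt in zip(ca, cb, w):
        if c1 == c2:
            w_in[c1] = w_in.get(c1, 0.0) + wt
        deg[c1] = deg.get(c1, 0.0) + wt
        deg[c2] = deg.get(c2, 0.0) + wt
    q = 0.0
    for c in deg:
        q += w_in.get(c, 0.0) / total - (deg[c] / (2.0 * total)) ** 2
    return q


def jaccard_index(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; undefined (raises) when both sets are empty."""
    if not set_a and not set_b:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(set_a & set_b) / len(set_a | set_b)


def compare_partitions(
    partition_a: CommunityPartition, partition_b: CommunityPartition
) -> tuple[pd.DataFrame, float]:
    """Best-match Jaccard for every community of A against B's communities.

    Returns the per-community table and the fraction of A-communities whose
    best match is exact (index == 1).
    """
    comms_a = partition_a.communities()
    comms_b = partition_b.communities()
    rows = []
    for cid in sorted(comms_a):
        best_id, best_j = None, -1.0
        for oid in sorted(comms_b):
            j = jaccard_index(comms_a[cid], comms_b[oid])
            if j > best_j:
                best_id, best_j = oid, j
        rows.append((cid, len(comms_a[cid]), best_id, best_j))
    table = pd.DataFrame(rows, columns=["community_a", "size_a", "best_match_b", "jaccard"])
    frac_exact = float((table["jaccard"] == 1.0).mean()) if len(table) else 0.0
    return table, frac_exact


# ---------------------------------------------------------------------------
# assortativity
# ---------------------------------------------------------------------------

def _internal_edges(network: CoexpressionNetwork, genes: set[str]) -> pd.DataFrame:
    e = network.edges
    return e[e["gene_a"].isin(genes) & e["gene_b"].isin(genes)]


def chromosomal_assortativity(
    internal_edges: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[float, int, int]:
    """(cis - trans) / total over a community's internal edges.

    Returns ``(ass_chr, n_cis, n_trans)``; raises on zero internal edges
    (the statistic is undefined there).
    """
    if len(internal_edges) == 0:
        raise ValueError("chromosomal assortativity undefined without internal edges")
    ann = validate_annotation(annotation)
    chrom_of = dict(zip(ann["gene"], ann["chrom"]))
    ca = internal_edges["gene_a"].map(chrom_of)
    cb = internal_edges["gene_b"].map(chrom_of)
    if ca.isna().any() or cb.isna().any():
        bad = sorted(
            set(internal_edges.loc[ca.isna(), "gene_a"])
            | set(internal_edges.loc[cb.isna(), "gene_b"])
        )
        raise ValueError(f"genes missing from annotation: {bad[:10]}")
    n_cis = int((ca == cb).sum())
    n_trans = len(internal_edges) - n_cis
    return (n_cis - n_trans) / len(internal_edges), n_cis, n_trans


def expression_assortativity(
    internal_edges: pd.DataFrame,
    lfc: pd.Series,
    strict_calls: pd.Series | None = None,
) -> float:
    """(same-LFC-sign links - mixed-sign links) / total internal links.

    Sign is taken from the log2 fold change (zero counts as positive).  With
    ``strict_calls`` given (gene -> over/under/unchanged), edges touching an
    ``unchanged`` gene are excluded before counting.
    """
    e = internal_edges
    if strict_calls is not None:
        sig = strict_calls[strict_calls != "unchanged"].index
        e = e[e["gene_a"].isin(sig) & e["gene_b"].isin(sig)]
    if len(e) == 0:
        raise ValueError("expression assortativity undefined without internal edges")
    sa = e["gene_a"].map(lfc) >= 0
    sb = e["gene_b"].map(lfc) >= 0
    same = int((sa == sb).sum())
    return (same - (len(e) - same)) / len(e)


def name_community(
    genes: set[str], network: CoexpressionNetwork, damping: float = 0.85
) -> str:
    """Name a community by its highest-PageRank member gene.

    PageRank runs on the community's induced weighted subgraph (power
    iteration, tolerance 1e-10); near-ties within 1e-9 resolve to the
    lexicographically first gene.
    """
    if not genes:
        raise ValueError("empty community")
    internal = _internal_edges(network, genes)
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for row in internal.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, weight=float(row.score))
    pr = nx.pagerank(g, alpha=damping, weight="weight", tol=1e-10, max_iter=500)
    best = max(pr.values())
    candidates = sorted(g for g, v in pr.items() if v >= best - 1e-9)
    return candidates[0]


def community_profiles(
    partition: CommunityPartition,
    network: CoexpressionNetwork,
    annotation: pd.DataFrame,
    de_results: pd.DataFrame | None = None,
    strict_dge: bool = False,
) -> pd.DataFrame:
    """Per-community summary table.

    Columns: community_id, name, size, n_internal_edges, n_cis, n_trans,
    ass_chr, ass_dge, is_cis (integer-exact: no trans links and >=1 edge).
    Assortativities are NaN where undefined (no internal edges).
    """
    ann = validate_annotation(annotation)
    lfc = None
    calls = None
    if de_results is not None:
        lfc = pd.Series(de_results["lfc"].values, index=de_results["gene"].values)
        if strict_dge and "call" in de_results.columns:
            calls = pd.Series(de_results["call"].values, index=de_results["gene"].values)
    rows = []
    for cid, genes in sorted(partition.communities().items()):
        internal = _internal_edges(network, genes)
        n_edges = len(internal)
        if n_edges:
            ass_chr, n_cis, n_trans = chromosomal_assortativity(internal, ann)
        else:
            ass_chr, n_cis, n_trans = np.nan, 0, 0
        ass_dge = np.nan
        if lfc is not None and n_edges:
            try:
                ass_dge = expression_assortativity(internal, lfc, calls)
            except ValueError:
                ass_dge = np.nan
        rows.append(
            {
                "community_id": cid,
                "name": name_community(genes, network),
                "size": len(genes),
                "n_internal_edges": n_edges,
                "n_cis": n_cis,
                "n_trans": n_trans,
                "ass_chr": ass_chr,
                "ass_dge": ass_dge,
                "is_cis": bool(n_edges > 0 and n_trans == 0),
            }
        )
    return pd.DataFrame(rows)


def membership_table(partition: CommunityPartition, profiles: pd.DataFrame) -> pd.DataFrame:
    names = dict(zip(profiles["community_id"], profiles["name"]))
    rows = [
        (gene, cid, names.get(cid, ""))
        for gene, cid in sorted(partition.assignment.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "community_id", "community_name"])
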