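"""Downstream analysis of the thresholded network.

Covers community detection (Newman-style modularity clustering on the
undirected IM-weighted projection), betweenness/degree centrality ranking,
Pearson-correlation-based edge signing (positive correlation = activating,
negative = repressive), first-neighbour subcircuit extraction, and
hypergeometric gene-set enrichment of the modules against an annotation
table, with the probe panel as the default universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "ModulePartition",
    "CentralityRecord",
    "EnrichmentResult",
    "pearson_matrix",
    "sign_edges",
    "community_cluster",
    "centrality",
    "first_neighbors",
    "enrich_modules",
    "write_edge_tsv",
    "write_sif",
    "write_graphml",
    "read_gene_sets",
]


@dataclass
class ModulePartition:
    assignment: dict[str, int]  # node -> module id, contiguous from 1
    modularity_q: float
    algorithm: str

    def members(self, module_id: int) -> list[str]:
        return sorted(g for g, mid in self.assignment.items() if mid == module_id)

    @property
    def n_modules(self) -> int:
        return max(self.assignment.values()) if self.assignment else 0

    def frame(self) -> pd.DataFrame:
        nodes = sorted(self.assignment)
        return pd.DataFrame({"node": nodes, "module_id": [self.assignment[n] for n in nodes]})


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    betweenness: float
    out_degree: int
    in_degree: int


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: int
    term: str
    k: int  # term hits in module
    K: int  # term size in universe
    n: int  # module size
    N: int  # universe size
    p_value: float
    enriched: bool


# -- correlation and signing -----------------------------------------------------


def pearson_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene profiles (unit diagonal).

    Zero-variance genes get NaN correlations (flagged with a warning);
    fewer than 3 samples is an error.
    """
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    X = m.values.to_numpy(dtype=float)
    flat = X.std(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance genes have undefined correlations",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    return pd.DataFrame(corr, index=m.genes, columns=m.genes)


def sign_edges(net: nx.DiGraph, corr: pd.DataFrame) -> nx.DiGraph:
    """Annotate each edge with r(regulator, target) and an activation sign.

    r > 0 -> activating, r < 0 -> repressive; r == 0 or undefined -> unsigned
    (warned).  Returns a new graph; IM weights are preserved.
    """
    missing = [n for n in net.nodes if n not in corr.index]
    if missing:
        raise ValueError(f"nodes without correlation entries: {sorted(missing)}")
    out = net.copy()
    n_unsigned = 0
    for u, v, data in out.edges(data=True):
        r = float(corr.loc[u, v])
        if np.isnan(r) or r == 0:
            data["r"] = float("nan") if np.isnan(r) else 0.0
            data["sign"] = "unsigned"
            n_unsigned += 1
        else:
            data["r"] = r
            data["sign"] = "activating" if r > 0 else "repressive"
    if n_unsigned:
        warnings.warn(f"{n_unsigned} edges left unsigned (r zero or undefined)", RuntimeWarning, stacklevel=2)
    return out


# -- community structure ---------------------------------------------------------


def _undirected_projection(net: nx.DiGraph) -> nx.Graph:
    """Undirected projection; antiparallel edge pairs sum their IM weights."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for u, v, data in net.edges(data=True):
        w = float(data.get("im", 1.0))
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


def community_cluster(net: nx.DiGraph | nx.Graph, algorithm: str = "greedy_modularity") -> ModulePartition:
    """Newman-style community detection on the undirected IM-weighted projection.

    ``greedy_modularity`` is agglomerative modularity maximization;
    ``edge_betweenness`` is Girvan-Newman divisive clustering, keeping the
    division of maximal modularity along the dendrogram.  Module ids are
    contiguous from 1, ordered by each module's lexicographically smallest
    node for determinism.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    g = _undirected_projection(net) if net.is_directed() else _weighted_copy(net)
    if g.number_of_edges() == 0:
        communities = [{n} for n in g.nodes]
        q = 0.0
    elif algorithm == "greedy_modularity":
        communities = [set(c) for c in nx.community.greedy_modularity_communities(g, weight="weight")]
        q = nx.community.modularity(g, communities, weight="weight")
    elif algorithm == "edge_betweenness":
        best, best_q = [set(g.nodes)], nx.community.modularity(g, [set(g.nodes)], weight="weight")
        for division in nx.community.girvan_newman(g):
            division = [set(c) for c in division]
            q_div = nx.community.modularity(g, division, weight="weight")
            if q_div > best_q:
                best, best_q = division, q_div
        communities, q = best, best_q
    else:
        raise ValueError(f"unknown community algorithm {algorithm!r}")

    communities = sorted(communities, key=lambda c: min(c))
    assignment = {node: i + 1 for i, c in enumerate(communities) for node in c}
    return ModulePartition(assignment=assignment, modularity_q=float(q), algorithm=algorithm)


def _weighted_copy(g: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, weight=float(data.get("im", data.get("weight", 1.0))))
    return out


# -- centrality ------------------------------------------------------------------


def centrality(net: nx.DiGraph, directed: bool = True) -> list[CentralityRecord]:
    """Betweenness (unnormalized shortest-path counts) plus in/out degree.

    Betweenness is computed on the directed graph by default (ordered node
    pairs); ``directed=False`` uses the undirected projection (unordered
    pairs).  Paths are unweighted.  Degrees always come from the directed
    graph.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    graph = net if directed else _undirected_projection(net)
    btw = nx.betweenness_centrality(graph, normalized=False)
    return [
        CentralityRecord(
            node=n,
            betweenness=float(btw[n]),
            out_degree=int(net.out_degree(n)),
            in_degree=int(net.in_degree(n)),
        )
        for n in sorted(net.nodes)
    ]


def centrality_frame(records: list[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [r.node for r in records],
            "betweenness": [r.betweenness for r in records],
            "out_degree": [r.out_degree for r in records],
            "in_degree": [r.in_degree for r in records],
        }
    )


def first_neighbors(net: nx.DiGraph, gene: str, direction: str = "both") -> nx.DiGraph:
    """Induced subgraph on a gene and its first neighbours.

    ``direction`` selects which neighbours join the subcircuit: regulators
    of the gene (``in``), its targets (``out``), or both.  All edges among
    the selected nodes are retained with their signs and IMs.
    """
    if gene not in net:
        raise ValueError(f"gene {gene!r} not in network")
    if direction not in ("in", "out", "both"):
        raise ValueError(f"direction must be in/out/both, got {direction!r}")
    nodes = {gene}
    if direction in ("out", "both"):
        nodes |= set(net.successors(gene))
    if direction in ("in", "both"):
        nodes |= set(net.predecessors(gene))
    return net.subgraph(nodes).copy()


# -- enrichment ------------------------------------------------------------------


def enrich_modules(
    partition: ModulePartition,
    gene_sets: dict[str, set[str]],
    universe: list[str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in each module.

    For a module of size n in a universe of N genes, a term covering K
    universe genes and hitting k module genes scores
    p = P(X >= k), X ~ Hypergeometric(N, K, n).  Terms with no genes in the
    universe are skipped with a warning.  ``enriched`` flags p < alpha
    (Benjamini-Hochberg adjusted when requested).
    """
    uni = set(universe)
    if not set(partition.assignment) <= uni:
        raise ValueError("universe must contain every partition node")
    N = len(uni)
    results = []
    for term in sorted(gene_sets):
        term_genes = gene_sets[term] & uni
        if not term_genes:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped", RuntimeWarning, stacklevel=2)
            continue
        K = len(term_genes)
        for mid in range(1, partition.n_modules + 1):
            module = set(partition.members(mid))
            n = len(module)
            k = len(module & term_genes)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            results.append(
                EnrichmentResult(module_id=mid, term=term, k=k, K=K, n=n, N=N, p_value=min(p, 1.0), enriched=False)
            )
    if not results:
        return results
    pvals = np.array([r.p_value for r in results])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        flag = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        flag = pvals < alpha
    return [
        EnrichmentResult(r.module_id, r.term, r.k, r.K, r.n, r.N, r.p_value, bool(f))
        for r, f in zip(results, flag)
    ]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [r.module_id for r in results],
            "term": [r.term for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "enriched": [r.enriched for r in results],
        }
    )


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read term->gene sets from a 2-column (term, gene) TSV or a GMT file."""
    path = str(path)
    sets: dict[str, set[str]] = {}
    if path.endswith(".gmt"):
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    sets.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
        return sets
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    term_col, gene_col = df.columns[:2]
    for term, gene in zip(df[term_col], df[gene_col]):
        sets.setdefault(str(term), set()).add(str(gene))
    return sets


# -- exports ---------------------------------------------------------------------


def write_edge_tsv(net: nx.DiGraph, path) -> None:
    rows = [
        {
            "regulator": u,
            "target": v,
            "im": d.get("im", ""),
            "r": d.get("r", ""),
            "sign": d.get("sign", "unsigned"),
        }
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "im", "r", "sign"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_sif(net: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v, d in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{d.get('sign', 'unsigned')}\t{v}\n")


def write_graphml(net: nx.DiGraph, path) -> None:
    clean = net.copy()
    for _, _, d in clean.edges(data=True):
        if "r" in d and isinstance(d["r"], float) and np.isnan(d["r"]):
            d["r"] = "NA"
    nx.write_graphml(clean, path)
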