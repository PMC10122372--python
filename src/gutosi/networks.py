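"""Co-occurrence networks and correlation panels.

Per-group genus co-occurrence networks keep taxon pairs whose Spearman
correlation satisfies |rho| > 0.70 with a Benjamini-Hochberg-adjusted
p < 0.05 (adjustment across all pairs of the group's network).  Network
comparison reports shared edges (same unordered pair, same correlation
sign), per-network unique edges, harmonic closeness (defined on
disconnected graphs) and eigenvector centrality on the largest
component.  The correlation panel relates differential features to a
per-sample target (e.g. plasma OSI) or to pathway abundances, with exact
permutation p-values at small n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import exact

logger = logging.getLogger(__name__)

RHO_MIN = 0.70
ALPHA = 0.05


@dataclass
class CorrelationNetwork:
    group: str
    graph: nx.Graph
    edges: pd.DataFrame  # taxon_a, taxon_b, rho, pvalue, pvalue_bh, sign
    rho_min: float = RHO_MIN
    alpha: float = ALPHA
    excluded: list[str] = field(default_factory=list)

    @property
    def edge_set(self) -> set[tuple[str, str, int]]:
        return {
            (min(a, b), max(a, b), int(s))
            for a, b, s in zip(self.edges["taxon_a"], self.edges["taxon_b"],
                               self.edges["sign"])
        }


@dataclass
class NetworkComparison:
    shared_edges: pd.DataFrame
    unique_a: int
    unique_b: int
    closeness: pd.DataFrame  # per node: closeness + rank in each network
    eigenvector: pd.DataFrame  # shared nodes on each largest component
    empty: bool = False


def cooccurrence_network(
    table: pd.DataFrame,
    group: str = "",
    rho_min: float = RHO_MIN,
    alpha: float = ALPHA,
    node_meta: pd.DataFrame | None = None,
) -> CorrelationNetwork:
    """Build a significant-edge Spearman co-occurrence network.

    All taxon pairs are correlated; p-values (tie-corrected t
    approximation) are BH-adjusted across pairs, and edges require both
    adjusted p < alpha and |rho| > rho_min.  Constant taxa cannot be
    ranked and are excluded (logged).
    """
    if table.shape[0] < 5:
        raise ValueError("need at least 5 samples for a co-occurrence network")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 taxa")
    variances = table.to_numpy(dtype=float).var(axis=0)
    excluded = table.columns[variances == 0].tolist()
    if excluded:
        logger.info("excluding %d constant taxa from network", len(excluded))
    work = table.loc[:, variances > 0]
    cols = list(work.columns)
    rho_mat, p_mat = stats.spearmanr(work.to_numpy(dtype=float))
    if np.ndim(rho_mat) == 0:  # spearmanr collapses the 2-column case to scalars
        rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
        p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
    pairs = list(combinations(range(len(cols)), 2))
    raw_p = np.array([p_mat[i, j] for i, j in pairs])
    rhos = np.array([rho_mat[i, j] for i, j in pairs])
    adj_p = multipletests(raw_p, method="fdr_bh")[1] if len(raw_p) else np.array([])
    rows = []
    G = nx.Graph()
    for col in cols:
        attrs = {}
        if node_meta is not None and col in node_meta.index:
            attrs = node_meta.loc[col].to_dict()
        G.add_node(col, mean_abundance=float(work[col].mean()), **attrs)
    for (i, j), rho, p, q in zip(pairs, rhos, raw_p, adj_p):
        if abs(rho) > rho_min and q < alpha:
            a, b = cols[i], cols[j]
            sign = 1 if rho > 0 else -1
            rows.append({"taxon_a": min(a, b), "taxon_b": max(a, b),
                         "rho": float(rho), "pvalue": float(p),
                         "pvalue_bh": float(q), "sign": sign})
            G.add_edge(a, b, rho=float(rho), sign=sign)
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho",
                                        "pvalue", "pvalue_bh", "sign"])
    return CorrelationNetwork(group=group, graph=G, edges=edges,
                              rho_min=rho_min, alpha=alpha, excluded=excluded)


def _eigenvector_centrality(G: nx.Graph) -> dict:
    """Leading-eigenvector centrality via a dense symmetric
    eigendecomposition (robust on the few-node components co-occurrence
    graphs produce, where sparse iterative solvers fail)."""
    nodes = sorted(G)
    A = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    w, V = np.linalg.eigh(A)
    vec = V[:, int(np.argmax(w))]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return dict(zip(nodes, vec))


def harmonic_closeness(G: nx.Graph) -> dict:
    """Harmonic closeness: mean over other nodes of 1/shortest-path length
    (0 for unreachable pairs).  Defined on disconnected graphs."""
    n = G.number_of_nodes()
    if n <= 1:
        return {v: 0.0 for v in G}
    raw = nx.harmonic_centrality(G)
    return {v: raw[v] / (n - 1) for v in G}


def compare_networks(a: CorrelationNetwork, b: CorrelationNetwork) -> NetworkComparison:
    """Structural comparison of two same-threshold networks.

    Shared edges must match in unordered pair AND correlation sign; an
    edge flipping sign between groups counts as a difference.
    """
    if (a.rho_min, a.alpha) != (b.rho_min, b.alpha):
        raise ValueError("networks were built with different thresholds")
    ea, eb = a.edge_set, b.edge_set
    shared = sorted(ea & eb)
    shared_df = pd.DataFrame(shared, columns=["taxon_a", "taxon_b", "sign"])
    empty = not (ea or eb)

    nodes = sorted(set(a.graph) | set(b.graph))
    ca = harmonic_closeness(a.graph)
    cb = harmonic_closeness(b.graph)
    closeness = pd.DataFrame({
        "closeness_a": pd.Series(ca).reindex(nodes),
        "closeness_b": pd.Series(cb).reindex(nodes),
    })
    closeness["rank_a"] = closeness["closeness_a"].rank(ascending=False)
    closeness["rank_b"] = closeness["closeness_b"].rank(ascending=False)
    closeness["rank_discrepancy"] = (closeness["rank_a"] - closeness["rank_b"]).abs()

    ev = {}
    for label, net in (("a", a), ("b", b)):
        G = net.graph
        cents: dict = {}
        if G.number_of_edges() > 0:
            comp = max(nx.connected_components(G), key=lambda c: (len(c), sorted(c)))
            cents = _eigenvector_centrality(G.subgraph(comp))
        ev[f"eigenvector_{label}"] = pd.Series(cents, dtype=float)
    shared_nodes = sorted(set(a.graph) & set(b.graph))
    eigenvector = pd.DataFrame(ev).reindex(shared_nodes)

    return NetworkComparison(
        shared_edges=shared_df,
        unique_a=len(ea) - len(shared),
        unique_b=len(eb) - len(shared),
        closeness=closeness,
        eigenvector=eigenvector,
        empty=empty,
    )


def feature_phenotype_correlations(
    features: pd.DataFrame,
    target: pd.Series,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman rho and p of every feature against a per-sample target.

    Pairs are aligned on shared samples; features with fewer than
    ``min_n`` paired observations are skipped (logged).  Exact
    permutation p-values at n <= 8, the t approximation above.
    Significance stars: * p<0.05, ** p<0.01, *** p<0.001.
    """
    common = [s for s in features.index if s in target.index]
    rows = []
    for feat in features.columns:
        x = features.loc[common, feat]
        y = target.loc[common]
        mask = x.notna() & y.notna()
        n = int(mask.sum())
        if n < min_n:
            logger.info("feature %s skipped: only %d paired observations", feat, n)
            continue
        xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rho, p = 0.0, 1.0
        elif n <= exact.SPEARMAN_EXACT_LIMIT:
            rho, p = exact.spearman_exact(xv, yv)
        else:
            rho, p = stats.spearmanr(xv, yv)
        stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append({"feature": feat, "rho": float(rho), "pvalue": float(p),
                     "n": n, "stars": stars})
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["rho", "pvalue", "n", "stars"])


def feature_table_correlations(
    features: pd.DataFrame, targets: pd.DataFrame, min_n: int = 5
) -> pd.DataFrame:
    """Feature x target Spearman panel (e.g. taxa vs enriched pathways);
    long format with stars, built from :func:`feature_phenotype_correlations`."""
    frames = []
    for tcol in targets.columns:
        panel = feature_phenotype_correlations(features, targets[tcol], min_n=min_n)
        panel = panel.assign(target=tcol)
        frames.append(panel.reset_index())
    if not frames:
        return pd.DataFrame(columns=["feature", "target", "rho", "pvalue", "n", "stars"])
    return pd.concat(frames, ignore_index=True)


def export_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
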