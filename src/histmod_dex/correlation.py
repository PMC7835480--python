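"""Spearman correlation, clustering and co-occurrence network of marks.

Three analyses, each run separately within the up- and down-regulated
gene classes: (a) Spearman rho between each (mark, bin) signal-change
column and the gene-expression change; (b) the pairwise mark-mark
Spearman matrix on region-level signal changes; (c) agglomerative
clustering of the rho rows (Euclidean distance) and the edge list of
mark pairs whose rho strictly exceeds a threshold (0.6 by default).
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .features import RatioMatrix


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties).

    Returns NaN with a warning when either vector is constant, for
    which the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined, returning NaN", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def change_expression_profile(
    matrix: RatioMatrix,
    expression_ratios: pd.Series,
    gene_class: str,
) -> pd.DataFrame:
    """Mark x bin matrix of rho(signal ratio, expression ratio) in one class."""
    if matrix.mode != "per_bin":
        raise ValueError("change_expression_profile requires a per_bin matrix")
    if gene_class not in ("up", "down"):
        raise ValueError("gene_class must be 'up' or 'down'")
    genes = matrix.y.index[matrix.y == gene_class]
    if len(genes) < 3:
        raise ValueError(f"fewer than 3 genes in class {gene_class!r}")
    expr = expression_ratios.reindex(genes)
    if expr.isna().any():
        raise ValueError("expression_ratios missing genes of the requested class")
    assert matrix.bin_labels is not None
    out = pd.DataFrame(
        index=pd.Index(matrix.hm_names, name="hm"),
        columns=pd.Index(matrix.bin_labels, name="bin"),
        dtype=float,
    )
    ev = expr.to_numpy()
    for hm in matrix.hm_names:
        for b, col in zip(matrix.bin_labels, matrix.columns_for_hm(hm)):
            out.loc[hm, b] = spearman(matrix.X.loc[genes, col].to_numpy(), ev)
    return out


def pairwise_hm_correlation(
    matrix: RatioMatrix,
    gene_class: str,
    raw_signals: "pd.DataFrame | None" = None,
) -> pd.DataFrame:
    """Symmetric mark x mark Spearman matrix within one gene class.

    By default the region-level cancer/normal ratios are correlated;
    pass ``raw_signals`` (a gene x mark frame, e.g. one condition's
    region-level signals) to correlate raw signals instead — the
    source analysis is ambiguous between the two readings.
    """
    if gene_class not in ("up", "down"):
        raise ValueError("gene_class must be 'up' or 'down'")
    genes = matrix.y.index[matrix.y == gene_class]
    if len(genes) < 3:
        raise ValueError(f"fewer than 3 genes in class {gene_class!r}")
    if raw_signals is not None:
        df = raw_signals.reindex(genes)
        if df.isna().any().any():
            raise ValueError("raw_signals missing genes of the requested class")
    elif matrix.mode == "region":
        df = matrix.X.loc[genes]
    else:
        # collapse per-bin columns to the region mean per mark
        df = pd.DataFrame(
            {hm: matrix.X.loc[genes, matrix.columns_for_hm(hm)].mean(axis=1)
             for hm in matrix.hm_names}
        )
    rho = df.corr(method="spearman")
    np.fill_diagonal(rho.values, 1.0)
    return rho


def _newick(node: hierarchy.ClusterNode, labels: Sequence[str], parent_h: float) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}:{parent_h - node.dist:.6g}"
    left = _newick(node.get_left(), labels, node.dist)
    right = _newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{parent_h - node.dist:.6g}"


def cluster_and_network(
    rho: pd.DataFrame,
    threshold: float = 0.6,
    linkage: str = "complete",
) -> tuple[np.ndarray, str, pd.DataFrame]:
    """Cluster the rho rows and emit the above-threshold edge list.

    Returns ``(linkage_matrix, newick, edges)``: a scipy linkage matrix
    from agglomerative clustering on Euclidean distance between rho
    rows, a Newick rendering of the dendrogram, and a DataFrame of
    (hm_a, hm_b, rho) pairs with rho strictly greater than the
    threshold, each unordered pair listed once.
    """
    if rho.isna().any().any():
        bad = [
            (str(r), str(c))
            for r in rho.index
            for c in rho.columns
            if pd.isna(rho.loc[r, c])
        ]
        raise ValueError(f"missing correlations for pairs: {bad[:10]}")
    if not np.allclose(rho.values, rho.values.T):
        raise ValueError("correlation matrix must be symmetric")

    Z = hierarchy.linkage(rho.values, method=linkage, metric="euclidean")
    tree = hierarchy.to_tree(Z)
    labels = list(map(str, rho.index))
    newick = f"({_newick(tree.get_left(), labels, tree.dist)},{_newick(tree.get_right(), labels, tree.dist)});" if not tree.is_leaf() else f"{labels[0]};"

    names = list(rho.index)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            val = float(rho.iloc[i, j])
            if val > threshold:
                rows.append({"hm_a": names[i], "hm_b": names[j], "rho": val})
    edges = pd.DataFrame(rows, columns=["hm_a", "hm_b", "rho"])
    return Z, newick, edges


def edges_to_networkx(edges: pd.DataFrame, nodes: Sequence[str] | None = None):
    """Weighted undirected graph from an edge list (requires networkx)."""
    import networkx as nx

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for _, row in edges.iterrows():
        g.add_edge(row["hm_a"], row["hm_b"], weight=float(row["rho"]))
    return g
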