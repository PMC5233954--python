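"""Gene prioritization within the rewired network.

Four node centralities are computed on the global rewired graph: closeness
and PageRank on the delta-weighted graph (edge distance 1/delta for
closeness, damping 0.85 for PageRank), plus unweighted degree and the local
clustering coefficient (transitivity, 0 for degree < 2).  The composite
centrality ``cs`` averages the four z-standardized centralities, so it is a
dimensionless, mean-zero prioritization score.  The local rewiring score is
the z-standardized sum of incident edge scores delta.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .rewiring import RewiredNetwork


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centralities(net: RewiredNetwork, weighted: bool = True) -> pd.DataFrame:
    """Closeness, transitivity (local clustering), degree and PageRank per
    network gene.  ``weighted=False`` ignores delta weights for closeness
    and PageRank as well."""
    g = net.graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty rewired network")
    dist = "dist" if weighted else None
    wkey = "delta" if weighted else None
    close = nx.closeness_centrality(g, distance=dist)
    pr = nx.pagerank(g, alpha=0.85, weight=wkey)
    clust = nx.clustering(g)  # unweighted local clustering coefficient
    deg = dict(g.degree())
    nodes = sorted(g.nodes())
    return pd.DataFrame(
        {
            "closeness": [close[n] for n in nodes],
            "transitivity": [clust[n] for n in nodes],
            "degree": [deg[n] for n in nodes],
            "pagerank": [pr[n] for n in nodes],
        },
        index=nodes,
    )


def composite_centrality(scores: pd.DataFrame) -> pd.Series:
    """cs = mean of the four z-standardized centralities (population sd;
    a zero-spread centrality contributes 0 for every node)."""
    if len(scores) < 2:
        return pd.Series(np.zeros(len(scores)), index=scores.index, name="cs")
    z = np.column_stack(
        [_zscore(scores[c].to_numpy(dtype=float))
         for c in ("closeness", "transitivity", "degree", "pagerank")]
    )
    return pd.Series(z.mean(axis=1), index=scores.index, name="cs")


def local_rewiring_score(net: RewiredNetwork) -> pd.Series:
    """Z-standardized sum of incident edge scores delta per network gene.

    Genes absent from the rewired network carry no score (reported as NA in
    the gene table downstream).
    """
    sums: dict[str, float] = {}
    for gi, gj, d in zip(net.edges["gene_i"], net.edges["gene_j"], net.edges["delta"]):
        sums[gi] = sums.get(gi, 0.0) + float(d)
        sums[gj] = sums.get(gj, 0.0) + float(d)
    if not sums:
        return pd.Series(dtype=float, name="local_rewiring")
    nodes = sorted(sums)
    raw = np.array([sums[n] for n in nodes])
    z = _zscore(raw) if len(raw) > 1 else np.zeros(1)
    return pd.Series(z, index=nodes, name="local_rewiring")


def gene_table(
    net: RewiredNetwork,
    de: pd.DataFrame,
    affinity: pd.Series | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-gene prioritization table over the universe.

    Combines differential expression with the four centralities, composite
    centrality cs and the local rewiring score; genes outside the rewired
    network carry NA network scores.
    """
    out = pd.DataFrame(index=pd.Index(net.universe, name="gene"))
    out["logFC"] = de["logFC"]
    out["de_adj_p"] = de["adj_p"]
    if net.n_edges:
        cent = centralities(net, weighted=weighted)
        cent["cs"] = composite_centrality(cent)
        out = out.join(cent, how="left")
        out = out.join(local_rewiring_score(net), how="left")
    else:
        for c in ("closeness", "transitivity", "degree", "pagerank", "cs", "local_rewiring"):
            out[c] = np.nan
    if affinity is not None:
        out["affinity"] = affinity
    else:
        out["affinity"] = np.nan
    return out.reset_index()
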