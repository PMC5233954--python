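"""Regulatory overlay: flag rewired edges as TF -> TG regulatory events.

An undirected rewired edge {a, b} is *regulatory* when (a -> b) or (b -> a)
is a known TF -> TG pair in the background regulatory network AND the target
gene is significantly differentially expressed (BH-adjusted p <= de_alpha;
optionally restricted to up-regulated targets).  Both directions may hold
for mutually regulating TFs, in which case both annotations are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import RegulatoryNetwork
from .rewiring import RewiredNetwork


@dataclass
class RegulatoryRewiredSet:
    """Directed regulatory annotations on retained rewired edges.

    ``annotations`` has one row per (TF, TG) direction with columns
    gene_i, gene_j, tf, tg, tg_logfc, tg_adj_p.
    """

    annotations: pd.DataFrame

    def __len__(self) -> int:
        return len(self.annotations)

    @property
    def tgs(self) -> set[str]:
        """Targets carrying at least one regulatory rewired edge."""
        return set(self.annotations["tg"]) if len(self.annotations) else set()

    @property
    def tfs(self) -> set[str]:
        return set(self.annotations["tf"]) if len(self.annotations) else set()

    def edge_keys(self) -> set[tuple[str, str]]:
        """Undirected (gene_i, gene_j) keys of regulatory rewired edges."""
        if self.annotations.empty:
            return set()
        return set(zip(self.annotations["gene_i"], self.annotations["gene_j"]))


_EMPTY = pd.DataFrame(
    columns=["gene_i", "gene_j", "tf", "tg", "tg_logfc", "tg_adj_p"]
)


def annotate_regulatory(
    net: RewiredNetwork,
    grn: RegulatoryNetwork,
    de: pd.DataFrame,
    de_alpha: float = 0.05,
    de_mode: str = "any",
) -> RegulatoryRewiredSet:
    """Annotate rewired edges that realize a known TF -> TG pair with a
    differentially expressed target.

    ``de_mode="any"`` accepts significant DE in either direction (default);
    ``"up"`` additionally requires logFC > 0 for the target.
    """
    if de_mode not in ("any", "up"):
        raise ValueError(f"de_mode must be 'any' or 'up', got {de_mode!r}")
    if net.edges.empty or len(grn) == 0:
        return RegulatoryRewiredSet(_EMPTY.copy())

    rows = []
    grn_edges = grn.edges
    logfc = de["logFC"]
    adj = de["adj_p"]
    for gi, gj in zip(net.edges["gene_i"], net.edges["gene_j"]):
        for tf, tg in ((gi, gj), (gj, gi)):
            if (tf, tg) not in grn_edges or tg not in adj.index:
                continue
            if adj[tg] > de_alpha:
                continue
            if de_mode == "up" and logfc[tg] <= 0:
                continue
            rows.append(
                {
                    "gene_i": gi,
                    "gene_j": gj,
                    "tf": tf,
                    "tg": tg,
                    "tg_logfc": float(logfc[tg]),
                    "tg_adj_p": float(adj[tg]),
                }
            )
    if not rows:
        return RegulatoryRewiredSet(_EMPTY.copy())
    return RegulatoryRewiredSet(pd.DataFrame(rows))
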