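"""Random walk with restart over the rewired network.

Seed (disease) genes receive equal initial probability summing to one; the
walker then iterates

    p <- (1 - r) * W p + r * p0

where W is the column-normalized, delta-weighted adjacency matrix of the
rewired graph and r is the restart probability (default 0.75, the default
of the propagation package the method builds on).  At convergence p is the
steady-state affinity of every network gene to the seed set; an altered
pathway's disease score averages the endpoint affinities of its rewired
intra-pathway connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneList
from .pathways import PathwaySubnetwork
from .rewiring import RewiredNetwork


@dataclass
class AffinityVector:
    """Steady-state visiting probabilities per rewired-network node."""

    affinity: pd.Series
    r_restart: float
    iterations: int
    residual: float

    def __getitem__(self, gene: str) -> float:
        return float(self.affinity[gene])


def column_normalize(adjacency: np.ndarray) -> np.ndarray:
    """Normalize each nonzero column of a nonnegative adjacency matrix to
    sum to one; zero columns are left zero."""
    A = np.asarray(adjacency, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency weights must be nonnegative")
    colsum = A.sum(axis=0)
    W = A.copy()
    nz = colsum > 0
    W[:, nz] = W[:, nz] / colsum[nz]
    return W


def rwr(
    W: np.ndarray,
    p0: np.ndarray,
    r_restart: float = 0.75,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int, float]:
    """Iterate the restart walk to its stationary distribution.

    ``p0`` is the restart distribution (must sum to 1).  Returns the
    affinity vector, the iteration count and the final L1 residual.  The
    result equals the direct linear solution
    r * (I - (1-r) W)^{-1} p0 up to the tolerance.
    """
    if not 0.0 < r_restart < 1.0:
        raise ValueError("restart probability must be in (0, 1)")
    p0 = np.asarray(p0, dtype=float)
    if not np.isclose(p0.sum(), 1.0):
        raise ValueError("restart vector must sum to 1")
    p = p0.copy()
    resid = np.inf
    for it in range(1, max_iter + 1):
        p_new = (1.0 - r_restart) * (W @ p) + r_restart * p0
        resid = float(np.abs(p_new - p).sum())
        p = p_new
        if resid < tol:
            break
    return p, it, resid


def rwr_affinity(
    net: RewiredNetwork,
    seeds: GeneList,
    r_restart: float = 0.75,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> AffinityVector:
    """Run the restart walk on the delta-weighted rewired network.

    Seeds outside the network are ignored; if none maps, this is a hard
    error listing the unmapped IDs.  Components without seeds legitimately
    receive (near-)zero mass.
    """
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValueError("empty rewired network")
    index = {g: k for k, g in enumerate(nodes)}
    mapped = [g for g in seeds if g in index]
    if not mapped:
        raise ValueError(f"no seed gene maps to the rewired network: {list(seeds)}")
    A = np.zeros((len(nodes), len(nodes)))
    for gi, gj, d in zip(net.edges["gene_i"], net.edges["gene_j"], net.edges["delta"]):
        i, j = index[gi], index[gj]
        A[i, j] = A[j, i] = float(d)
    W = column_normalize(A)
    p0 = np.zeros(len(nodes))
    p0[[index[g] for g in mapped]] = 1.0 / len(mapped)
    p, it, resid = rwr(W, p0, r_restart=r_restart, tol=tol, max_iter=max_iter)
    return AffinityVector(pd.Series(p, index=nodes), r_restart, it, resid)


def disease_enrichment_score(
    sub: PathwaySubnetwork, aff: AffinityVector, divisor: str = "m"
) -> float:
    """Seed-affinity score of a pathway's rewired sub-network.

    Sums p_i + p_j over the pathway's intra-pathway rewired edges and
    divides by m (rewired edge count, default) or by M (all possible
    intra-pathway connections), returning 0 when m = 0.
    """
    if divisor not in ("m", "M"):
        raise ValueError("divisor must be 'm' or 'M'")
    if sub.m == 0:
        return 0.0
    total = sum(aff[a] + aff[b] for a, b in sub.intra_edges)
    return float(total / (sub.m if divisor == "m" else sub.M))
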