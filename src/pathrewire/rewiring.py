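"""Construction of the rewired co-expression network.

Given case and control expression matrices over a common gene space, each
gene pair receives a Pearson correlation per condition.  Correlations are
Fisher-transformed (z = arctanh r) and compared with the classical test for
the difference of two independent correlations,

    rewire = (z_case - z_ctrl) / sqrt(1/(n_case - 3) + 1/(n_ctrl - 3)),

which is approximately standard normal when the pair is equally co-expressed
in both conditions.  The scores are standardized against their own empirical
mean and standard deviation, converted to two-tailed p-values, and
Benjamini-Hochberg adjusted; pairs with adjusted p <= alpha form the single
undirected *rewired network*.  Retained edges carry the score
delta = 1 - adj_p in (0, 1].

Differential expression (log fold change plus a Welch two-sample t-test with
BH adjustment) is computed on the same universe and feeds the regulatory
overlay downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_CLAMP = 1.0 - 1e-7


@dataclass
class RewiredNetwork:
    """Undirected graph of significantly rewired gene pairs.

    ``edges`` holds one row per retained pair (gene_i < gene_j under
    lexicographic order) with the full per-edge statistics; ``universe`` is
    the set of genes that survived variance filtering and forms the
    background for enrichment tests.
    """

    edges: pd.DataFrame
    universe: list[str]
    n_pairs_tested: int = 0
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    @property
    def nodes(self) -> set[str]:
        if self.edges.empty:
            return set()
        return set(self.edges["gene_i"]) | set(self.edges["gene_j"])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def graph(self) -> nx.Graph:
        """The delta-weighted networkx view (cached)."""
        if self._graph is None:
            g = nx.Graph()
            for gi, gj, d in zip(
                self.edges["gene_i"], self.edges["gene_j"], self.edges["delta"]
            ):
                g.add_edge(gi, gj, delta=float(d), dist=1.0 / float(d))
            self._graph = g
        return self._graph


def filter_zero_variance(
    case: ExpressionMatrix, control: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Drop genes with zero variance in either condition.

    Constant genes have undefined correlations and would only produce false
    positive interactions.  The intersection of surviving genes across both
    matrices defines the analysis universe (original case order preserved).
    Returns the filtered matrices and the list of removed genes.
    """
    common = [g for g in case.genes if g in set(control.genes)]
    removed = []
    keep = []
    cv = case.values.loc[common].to_numpy()
    kv = control.values.loc[common].to_numpy()
    var_c = cv.var(axis=1)
    var_k = kv.var(axis=1)
    for g, vc, vk in zip(common, var_c, var_k):
        if vc == 0.0 or vk == 0.0:
            removed.append(g)
        else:
            keep.append(g)
    if removed:
        logger.info("removed %d zero-variance gene(s)", len(removed))
    case_f = ExpressionMatrix(case.values.loc[keep])
    ctrl_f = ExpressionMatrix(control.values.loc[keep])
    return case_f, ctrl_f, removed


def differential_expression(
    case: ExpressionMatrix, control: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene log fold change and Welch t-test with BH adjustment.

    Inputs are assumed log-scale, so logFC = mean(case) - mean(control).
    Returns a DataFrame indexed by gene with columns logFC, p, adj_p.
    """
    if case.n_samples < 2 or control.n_samples < 2:
        raise ValueError("differential expression requires >= 2 samples per group")
    if case.genes != control.genes:
        raise ValueError("case and control must share the same gene universe")
    cv = case.values.to_numpy()
    kv = control.values.to_numpy()
    logfc = cv.mean(axis=1) - kv.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(cv, kv, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, adj_p, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"logFC": logfc, "p": p, "adj_p": adj_p}, index=case.genes)


def fisher_z(r):
    """Fisher transformation z = arctanh(r) = 0.5*ln((1+r)/(1-r)).

    Correlations with |r| >= 1 (possible in toy data with perfectly
    collinear genes) are clamped to +/-(1 - 1e-7) with a warning.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation(s) with |r| >= 1 clamped before Fisher transform")
        r = np.clip(r, -_CLAMP, _CLAMP)
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


def rewire_statistic(z_case, z_ctrl, n_case: int, n_ctrl: int):
    """Difference of Fisher-transformed correlations, scaled to unit null
    variance: (z_case - z_ctrl) / sqrt(1/(n_case-3) + 1/(n_ctrl-3)).

    Antisymmetric under swapping case and control.  Requires at least 4
    samples per group so the variance terms are positive and finite.
    """
    if n_case < 4:
        raise ValueError(f"case group has {n_case} samples; need >= 4")
    if n_ctrl < 4:
        raise ValueError(f"control group has {n_ctrl} samples; need >= 4")
    se = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_ctrl - 3))
    out = (np.asarray(z_case, dtype=float) - np.asarray(z_ctrl, dtype=float)) / se
    return out.item() if out.ndim == 0 else out


def standardize_scores(scores, ddof: int = 0):
    """Z-standardize a score vector against its own mean and (population,
    ddof=0) standard deviation.  A zero spread (e.g. identical case and
    control matrices) maps every score to 0 with a warning."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 scores to standardize")
    mu = x.mean()
    sigma = x.std(ddof=ddof)
    if sigma == 0.0:
        warnings.warn("degenerate score set (sigma = 0); all Z set to 0")
        return np.zeros_like(x)
    return (x - mu) / sigma


def edge_significance(Z, alpha: float = 0.05):
    """Two-tailed normal p-values, BH adjustment and edge retention.

    Returns ``(p, adj_p, keep, delta)`` where ``keep`` marks edges with
    adjusted p <= alpha and ``delta = 1 - adj_p`` is the edge score used
    throughout the downstream pathway statistics (defined for every tested
    edge; meaningful on retained ones).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.size == 0:
        raise ValueError("empty Z-score vector")
    p = 2.0 * stats.norm.sf(np.abs(Z))
    _, adj_p, _, _ = multipletests(p, method="fdr_bh")
    keep = adj_p <= alpha
    delta = 1.0 - adj_p
    return p, adj_p, keep, delta


def correlation_matrix(x: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation across samples for every gene pair."""
    return np.corrcoef(x.values.to_numpy())


def build_rewired_network(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    alpha: float = 0.05,
    r_min: float = 0.2,
    sd_ddof: int = 0,
) -> tuple[RewiredNetwork, pd.DataFrame]:
    """Run the full edge-rewiring stage on a case/control pair.

    Stages: zero-variance filter -> per-condition Pearson correlations ->
    optional minimum-correlation floor (pairs with
    max(|r_case|, |r_ctrl|) < r_min are not tested; r_min = 0 disables) ->
    Fisher transform -> difference statistic -> standardization ->
    two-tailed p, BH, retention at adj_p <= alpha.

    Returns the rewired network and the differential-expression table over
    the same universe.  Deterministic for fixed inputs.
    """
    case, control, _ = filter_zero_variance(case, control)
    if case.n_genes == 0:
        raise ValueError("empty universe: all genes removed by variance filter")
    # fixed lexicographic gene order so each undirected pair is stored once
    order = sorted(case.genes)
    case = case.subset_genes(order)
    control = control.subset_genes(order)
    de = differential_expression(case, control)

    rc = correlation_matrix(case)
    rk = correlation_matrix(control)
    iu, ju = np.triu_indices(len(order), k=1)
    r_case = rc[iu, ju]
    r_ctrl = rk[iu, ju]

    # scores for every pair: the standardization scale must come from the
    # full (mostly null) score set; flooring first would select pairs with
    # extreme estimated correlations and inflate sigma, destroying power
    z_case = np.atleast_1d(fisher_z(r_case))
    z_ctrl = np.atleast_1d(fisher_z(r_ctrl))
    rewire = np.atleast_1d(
        rewire_statistic(z_case, z_ctrl, case.n_samples, control.n_samples)
    )
    Z_all = standardize_scores(rewire, ddof=sd_ddof) if rewire.size > 1 else np.zeros(1)

    # the optional floor restricts which pairs enter the testing family
    if r_min > 0:
        tested = np.maximum(np.abs(r_case), np.abs(r_ctrl)) >= r_min
    else:
        tested = np.ones_like(r_case, dtype=bool)
    iu, ju = iu[tested], ju[tested]
    r_case, r_ctrl = r_case[tested], r_ctrl[tested]
    z_case, z_ctrl = z_case[tested], z_ctrl[tested]
    rewire = rewire[tested]
    Z = Z_all[tested]
    n_tested = int(tested.sum())

    empty_cols = {
        "gene_i": [], "gene_j": [], "r_case": [], "r_ctrl": [],
        "z_case": [], "z_ctrl": [], "rewire": [], "Z": [],
        "p": [], "adj_p": [], "delta": [],
    }
    if n_tested == 0:
        return RewiredNetwork(pd.DataFrame(empty_cols), order, 0), de

    p, adj_p, keep, delta = edge_significance(Z, alpha=alpha)

    genes = np.asarray(order, dtype=object)
    edges = pd.DataFrame(
        {
            "gene_i": genes[iu[keep]],
            "gene_j": genes[ju[keep]],
            "r_case": r_case[keep],
            "r_ctrl": r_ctrl[keep],
            "z_case": z_case[keep],
            "z_ctrl": z_ctrl[keep],
            "rewire": rewire[keep],
            "Z": Z[keep],
            "p": p[keep],
            "adj_p": adj_p[keep],
            "delta": delta[keep],
        }
    ).reset_index(drop=True)
    net = RewiredNetwork(edges, order, n_tested)
    logger.info(
        "rewired network: %d/%d tested pairs retained over %d genes",
        net.n_edges, n_tested, len(order),
    )
    return net, de
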