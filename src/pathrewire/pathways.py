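"""Pathway-level scoring on the rewired network.

Each gene set is mapped onto the rewired network.  With T mapped genes there
are M = T(T-1)/2 possible intra-pathway connections, of which m are retained
rewired edges with scores delta.  Pathway statistics:

* enrichment: one-sided Fisher's exact test of rewired-gene overlap against
  the filtered-gene universe, BH-adjusted across pathways;
* rewiring density  R = (sum of intra-pathway delta) / M;
* differential regulation  Dr = mean |logFC| over the t pathway target genes
  that carry at least one regulatory rewired edge (0 when t = 0);
* alteration  Dy = z-standardization of raw = R + Dr across the scored
  collection, so Dy > 0 flags pathways more altered than the average set.

Classification: a pathway is *altered* when its enrichment is significant
and it contains at least one rewired edge (m >= 1); an altered pathway is
*differentially regulated* when Dr exceeds the threshold (default 0.05).
A label-permutation test recomputes the raw alteration score on shuffled
case/control assignments to attach an empirical p-value per pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PathwayCollection, RegulatoryNetwork
from .regulatory import RegulatoryRewiredSet, annotate_regulatory
from .rewiring import RewiredNetwork, build_rewired_network

logger = logging.getLogger(__name__)


@dataclass
class PathwaySubnetwork:
    """A gene set mapped onto the rewired network."""

    pathway_id: str
    T: int                      # pathway genes present in the universe
    M: int                      # possible intra-pathway connections T(T-1)/2
    m: int                      # retained rewired edges with both ends inside
    deltas: np.ndarray          # scores of those m edges
    intra_edges: list[tuple[str, str]]
    # per-target regulatory bookkeeping: tg -> (n_j regulatory edges, logFC)
    targets: dict[str, tuple[int, float]] = field(default_factory=dict)
    local_tfs: set[str] = field(default_factory=set)    # TF inside the gene set
    global_tfs: set[str] = field(default_factory=set)   # TF outside the gene set
    mapped_genes: frozenset[str] = frozenset()

    @property
    def t(self) -> int:
        return len(self.targets)

    @property
    def scoreable(self) -> bool:
        return self.M > 0


def map_pathway(
    net: RewiredNetwork,
    reg: RegulatoryRewiredSet | None,
    pathway_id: str,
    gene_set: frozenset[str] | set[str],
) -> PathwaySubnetwork:
    """Map one gene set onto the rewired network.

    Regulatory rewired edges touching pathway target genes are partitioned
    into local (TF inside the gene set) and global (TF outside) annotations;
    both feed the pathway's target-gene list.
    """
    uni = set(net.universe)
    mapped = frozenset(gene_set) & uni
    T = len(mapped)
    M = T * (T - 1) // 2
    intra = []
    deltas = []
    if T >= 2 and not net.edges.empty:
        gi = net.edges["gene_i"].to_numpy()
        gj = net.edges["gene_j"].to_numpy()
        dl = net.edges["delta"].to_numpy()
        for a, b, d in zip(gi, gj, dl):
            if a in mapped and b in mapped:
                intra.append((a, b))
                deltas.append(d)
    targets: dict[str, tuple[int, float]] = {}
    local_tfs: set[str] = set()
    global_tfs: set[str] = set()
    if reg is not None and len(reg):
        ann = reg.annotations
        for tf, tg, f in zip(ann["tf"], ann["tg"], ann["tg_logfc"]):
            if tg not in mapped:
                continue
            n_j, _ = targets.get(tg, (0, 0.0))
            targets[tg] = (n_j + 1, float(f))
            (local_tfs if tf in mapped else global_tfs).add(tf)
    return PathwaySubnetwork(
        pathway_id=pathway_id,
        T=T,
        M=M,
        m=len(intra),
        deltas=np.asarray(deltas, dtype=float),
        intra_edges=intra,
        targets=targets,
        local_tfs=local_tfs,
        global_tfs=global_tfs,
        mapped_genes=mapped,
    )


def enrichment_test(
    sub: PathwaySubnetwork, rewired_genes: set[str], universe: set[str]
) -> float:
    """One-sided (over-representation) Fisher's exact p-value for the overlap
    of pathway genes with rewired-network genes against the universe."""
    if not universe:
        raise ValueError("empty universe")
    in_path = len(sub.mapped_genes)
    a = len(sub.mapped_genes & rewired_genes)
    b = in_path - a
    c = len(rewired_genes) - a
    d = len(universe) - in_path - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def rewiring_density(sub: PathwaySubnetwork) -> float:
    """R = (sum of intra-pathway edge scores delta) / M, in [0, 1]."""
    if sub.M == 0:
        raise ValueError(f"pathway {sub.pathway_id!r} is unscoreable (M = 0)")
    if sub.m == 0:
        return 0.0
    return float(sub.deltas.sum() / sub.M)


def differential_regulation_score(sub: PathwaySubnetwork, weighted: bool = False) -> float:
    """Dr = mean |logFC| over the t target genes with >= 1 regulatory rewired
    edge (0 when t = 0).  ``weighted=True`` uses the per-target regulatory
    edge counts n_j as weights: sum(n_j |f_j|) / sum(n_j)."""
    if not sub.targets:
        return 0.0
    n = np.array([v[0] for v in sub.targets.values()], dtype=float)
    f = np.abs([v[1] for v in sub.targets.values()])
    if weighted:
        return float((n * f).sum() / n.sum())
    return float(f.mean())


def alteration_scores(
    subs: list[PathwaySubnetwork], dr_weighted: bool = False
) -> pd.DataFrame:
    """Raw and normalized alteration scores for every scoreable pathway.

    raw = R + Dr; Dy = (raw - mean) / sd(raw) with the population sd over
    all scoreable pathways (Dy = 0 for all when the spread is zero or only
    one pathway is scoreable).  Returns a DataFrame indexed by pathway ID
    with columns R, Dr, raw, Dy and in_d (m >= 1 membership flag).
    """
    rows = {}
    for sub in subs:
        if not sub.scoreable:
            continue
        R = rewiring_density(sub)
        Dr = differential_regulation_score(sub, weighted=dr_weighted)
        rows[sub.pathway_id] = {"R": R, "Dr": Dr, "raw": R + Dr, "in_d": sub.m >= 1}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        return pd.DataFrame(columns=["R", "Dr", "raw", "Dy", "in_d"])
    raw = df["raw"].to_numpy()
    sd = raw.std(ddof=0)
    if len(raw) < 2 or sd == 0.0:
        df["Dy"] = 0.0
    else:
        df["Dy"] = (raw - raw.mean()) / sd
    return df[["R", "Dr", "raw", "Dy", "in_d"]]


def classify(
    table: pd.DataFrame,
    enrich_alpha: float = 0.05,
    dr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Label pathways as altered / differentially regulated and rank them.

    altered := enrichment adj_p <= enrich_alpha AND m >= 1;
    differentially_regulated := altered AND Dr > dr_threshold.
    Altered pathways are ranked by Dy descending (rank 1 = most altered).
    """
    out = table.copy()
    out["altered"] = (out["enrich_adj_p"] <= enrich_alpha) & (out["m"] >= 1)
    out["differentially_regulated"] = out["altered"] & (out["Dr"] > dr_threshold)
    out["rank"] = pd.NA
    alt = out.index[out["altered"]]
    if len(alt):
        order = out.loc[alt, "Dy"].sort_values(ascending=False).index
        out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out


def score_pathways(
    net: RewiredNetwork,
    reg: RegulatoryRewiredSet | None,
    collection: PathwayCollection,
    enrich_alpha: float = 0.05,
    dr_threshold: float = 0.05,
    dr_weighted: bool = False,
) -> tuple[dict[str, PathwaySubnetwork], pd.DataFrame]:
    """Map, test and score every pathway in the collection.

    Returns the mapped subnetworks and a per-pathway table (indexed by
    pathway ID) with mapping counts, enrichment p/adj_p, R, Dr, Dy, the
    classification labels, ranks and causal TF/TG lists.
    """
    uni = set(net.universe)
    rewired_genes = net.nodes
    subs = {p.pathway_id: map_pathway(net, reg, p.pathway_id, p.genes) for p in collection}
    rows = []
    for pid, sub in subs.items():
        row = {
            "pathway": pid,
            "T": sub.T,
            "m": sub.m,
            "M": sub.M,
            "t": sub.t,
            "enrich_p": enrichment_test(sub, rewired_genes, uni) if sub.T else 1.0,
            "tfs": ",".join(sorted(sub.local_tfs | sub.global_tfs)),
            "tgs": ",".join(sorted(sub.targets)),
        }
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pathway")
    if table.empty:
        table["enrich_adj_p"] = []
    else:
        _, adj, _, _ = multipletests(table["enrich_p"].to_numpy(), method="fdr_bh")
        table["enrich_adj_p"] = adj
    alt = alteration_scores(list(subs.values()), dr_weighted=dr_weighted)
    table = table.join(alt[["R", "Dr", "raw", "Dy"]], how="left")
    table = classify(table, enrich_alpha=enrich_alpha, dr_threshold=dr_threshold)
    return subs, table


def _raw_scores_for_matrices(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    collection: PathwayCollection,
    grn: RegulatoryNetwork | None,
    alpha: float,
    r_min: float,
    de_alpha: float,
    de_mode: str,
    dr_weighted: bool,
) -> pd.Series:
    """Raw (pre-normalization) alteration score per pathway for one dataset."""
    net, de = build_rewired_network(case, control, alpha=alpha, r_min=r_min)
    reg = None
    if grn is not None and len(grn):
        reg = annotate_regulatory(net, grn, de, de_alpha=de_alpha, de_mode=de_mode)
    raw = {}
    for p in collection:
        sub = map_pathway(net, reg, p.pathway_id, p.genes)
        if not sub.scoreable:
            raw[p.pathway_id] = 0.0
            continue
        raw[p.pathway_id] = rewiring_density(sub) + differential_regulation_score(
            sub, weighted=dr_weighted
        )
    return pd.Series(raw)


def permutation_significance(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    collection: PathwayCollection,
    grn: RegulatoryNetwork | None = None,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    r_min: float = 0.2,
    de_alpha: float = 0.05,
    de_mode: str = "any",
    dr_weighted: bool = False,
) -> pd.DataFrame:
    """Empirical pathway significance from shuffled case/control datasets.

    Sample labels are permuted B times preserving group sizes; the whole
    rewiring + regulatory + pathway pipeline recomputes each pathway's raw
    alteration score per shuffle.  perm_p uses the add-one estimator
    (1 + #{raw_perm >= raw_obs}) / (B + 1), BH-adjusted across pathways.
    The raw (pre-normalization) statistic is used so each pathway's null
    does not depend on the co-shuffled collection.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    kwargs = dict(
        collection=collection, grn=grn, alpha=alpha, r_min=r_min,
        de_alpha=de_alpha, de_mode=de_mode, dr_weighted=dr_weighted,
    )
    obs = _raw_scores_for_matrices(case, control, **kwargs)

    pooled = pd.concat([case.values, control.values], axis=1)
    n_case = case.n_samples
    n_total = pooled.shape[1]
    exceed = pd.Series(0, index=obs.index, dtype=int)
    for _ in range(B):
        perm = rng.permutation(n_total)
        pc = ExpressionMatrix(pooled.iloc[:, perm[:n_case]])
        pk = ExpressionMatrix(pooled.iloc[:, perm[n_case:]])
        raw_b = _raw_scores_for_matrices(pc, pk, **kwargs)
        exceed += (raw_b >= obs).astype(int)
    perm_p = (1.0 + exceed) / (B + 1.0)
    _, adj, _, _ = multipletests(perm_p.to_numpy(), method="fdr_bh")
    return pd.DataFrame(
        {"raw_obs": obs, "perm_p": perm_p, "perm_adj_p": adj}, index=obs.index
    )
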