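"""Simulation benchmark and synthetic expression data.

Benchmark (network-level)
-------------------------
A Barabási–Albert preferential-attachment network of 2000 nodes carries
edge weights drawn Uniform(0.2, 1), standing for co-expression strength.
100 gene sets are sampled: 10 "differentially regulated" (DR) pathways of
100 genes each (mutually disjoint) and 90 null sets of 50–100 genes drawn
from the remaining nodes (null sets may overlap one another but never the
DR sets; a reserve of nodes is kept pathway-free to host regulatory
partners).  Case and control copies of the network are created and, in the
case copy,

* every intra-pathway edge of each DR pathway has its weight replaced by a
  Uniform(0, 1) draw (an edge is added first if a DR pathway has none);
* a gamma proportion of each DR pathway's genes additionally gets an edge
  to a non-pathway partner rewired the same way; the partner is registered
  as the gene's TF and the gene is stamped significantly differentially
  expressed (|logFC| ~ Uniform(0.5, 2), adjusted p = 0.001);
* null-set intra-pathway edges are identical across the two copies.

Rewiring detection reuses the Fisher-difference pipeline by treating each
weight as the population correlation of the pair and drawing the observed
Fisher z per condition from N(arctanh(w), 1/(n_sim - 3)) — the sampling
model the test assumes at a nominal n_sim samples per group (default 50).

Pathways are scored with the standard pathway statistics; following the
benchmark's decision rule, a pathway is *predicted* differentially
regulated when its alteration score Dy exceeds 0, and the prediction is
evaluated as a Mann–Whitney auROC of the 10 DR vs 90 null truth labels
(for a binary predictor this equals (sensitivity + specificity) / 2).

Expression generator
--------------------
:func:`generate_expression_pair` builds matched case/control expression
matrices with planted equicorrelated gene modules (per-condition module
correlation, e.g. 0.8 -> 0.0 for a rewired module), planted TF -> TG pairs
whose targets shift by a chosen logFC in cases, and independent noise
genes, together with the ground truth — the end-to-end fixture for the
whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, Pathway, PathwayCollection, RegulatoryNetwork
from .pathways import score_pathways
from .regulatory import annotate_regulatory
from .rewiring import RewiredNetwork, edge_significance, standardize_scores

_CLAMP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationScenario:
    """One gamma-configuration of the network benchmark."""

    gamma: float
    n_nodes: int = 2000
    m_attach: int = 3
    n_pathways: int = 100
    n_dr: int = 10
    dr_size: int = 100
    null_size_range: tuple[int, int] = (50, 100)
    replicates: int = 200
    n_sim: int = 50           # nominal per-group sample size for detection
    w_low: float = 0.2        # baseline edge-weight range
    w_high: float = 1.0
    alpha: float = 0.05       # edge FDR level
    r_min: float = 0.2        # minimum-correlation floor
    de_alpha: float = 0.05
    reg_edges_per_gene: int = 1
    null_pool_frac: float = 0.85
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.n_dr * self.dr_size >= self.n_nodes:
            raise ValueError("DR pathways need fewer genes than the network has nodes")


@dataclass
class SyntheticTruth:
    """Ground truth of one planted dataset."""

    rewired_edges: set[tuple[str, str]] = field(default_factory=set)
    de_genes: dict[str, float] = field(default_factory=dict)
    regulatory: set[tuple[str, str]] = field(default_factory=set)
    labels: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# benchmark building blocks
# ---------------------------------------------------------------------------

def generate_ba_network(
    n: int = 2000,
    m_attach: int = 3,
    seed: int | np.random.Generator | None = None,
    w_low: float = 0.2,
    w_high: float = 1.0,
) -> nx.Graph:
    """Barabási–Albert graph with Uniform(w_low, w_high) edge weights."""
    if not (isinstance(n, (int, np.integer)) and n > m_attach >= 1):
        raise ValueError("need n > m_attach >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = nx.barabasi_albert_graph(n, m_attach, seed=int(rng.integers(2**31)))
    for u, v in g.edges():
        g.edges[u, v]["weight"] = float(rng.uniform(w_low, w_high))
    return g


def build_pathway_truth(
    graph: nx.Graph, scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[PathwayCollection, dict[str, int]]:
    """Sample the DR and null gene sets and their truth labels.

    DR sets are mutually disjoint and disjoint from every null set; null
    sets are drawn (possibly overlapping one another) from a sub-pool of
    the non-DR nodes so that some nodes stay pathway-free.
    """
    nodes = np.array(sorted(graph.nodes()))
    need = scenario.n_dr * scenario.dr_size
    if need + scenario.null_size_range[1] > len(nodes):
        raise ValueError("insufficient nodes for the requested pathway sets")
    perm = rng.permutation(nodes)
    entries = []
    labels: dict[str, int] = {}
    for k in range(scenario.n_dr):
        genes = perm[k * scenario.dr_size: (k + 1) * scenario.dr_size]
        pid = f"DR{k + 1:03d}"
        entries.append(Pathway(pid, "planted DR pathway", frozenset(int(g) for g in genes)))
        labels[pid] = 1
    rest = perm[need:]
    pool = rest[: max(int(len(rest) * scenario.null_pool_frac), scenario.null_size_range[1])]
    lo, hi = scenario.null_size_range
    for k in range(scenario.n_pathways - scenario.n_dr):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(pool, size=size, replace=False)
        pid = f"NULL{k + 1:03d}"
        entries.append(Pathway(pid, "null gene set", frozenset(int(g) for g in genes)))
        labels[pid] = 0
    return PathwayCollection(entries), labels


def inject_rewiring(
    graph: nx.Graph,
    collection: PathwayCollection,
    labels: dict[str, int],
    scenario: SimulationScenario,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray, RegulatoryNetwork, pd.DataFrame]:
    """Create the case/control weight pair, the simulated regulatory network
    and the simulated differential-expression table.

    Returns ``(edges, w_case, w_ctrl, grn, de)`` where ``edges`` lists the
    (u, v) node pairs (u < v) of the possibly augmented graph.
    """
    g = graph.copy()
    pathway_genes: set[int] = set()
    for p in collection:
        pathway_genes |= {int(x) for x in p.genes}
    non_pathway = sorted(set(g.nodes()) - pathway_genes)
    if not non_pathway:
        raise ValueError("no non-pathway nodes left to host regulatory partners")

    case_w: dict[tuple[int, int], float] = {}
    grn_edges: set[tuple[str, str]] = set()
    targets: dict[int, float] = {}

    def _key(u, v):
        return (u, v) if u < v else (v, u)

    def _rewire(u, v):
        case_w[_key(u, v)] = float(rng.uniform(0.0, 1.0))

    for p in collection:
        if labels[p.pathway_id] != 1:
            continue
        members = sorted(int(x) for x in p.genes)
        mset = set(members)
        intra = [(u, v) for u, v in g.subgraph(members).edges()]
        if not intra:  # guarantee >= 1 rewirable intra-pathway connection
            u, v = rng.choice(members, size=2, replace=False)
            g.add_edge(int(u), int(v), weight=float(rng.uniform(scenario.w_low, scenario.w_high)))
            intra = [(int(u), int(v))]
        for u, v in intra:
            _rewire(u, v)
        n_reg = math.ceil(scenario.gamma * len(members))
        reg_genes = rng.choice(members, size=n_reg, replace=False)
        for gene in reg_genes:
            gene = int(gene)
            partners = [w for w in g.neighbors(gene) if w not in pathway_genes]
            for _ in range(scenario.reg_edges_per_gene):
                if partners:
                    partner = int(partners[int(rng.integers(len(partners)))])
                else:
                    partner = int(non_pathway[int(rng.integers(len(non_pathway)))])
                    if not g.has_edge(gene, partner):
                        g.add_edge(gene, partner,
                                   weight=float(rng.uniform(scenario.w_low, scenario.w_high)))
                _rewire(gene, partner)
                grn_edges.add((str(partner), str(gene)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            targets[gene] = sign * float(rng.uniform(0.5, 2.0))

    edges = [(u, v) if u < v else (v, u) for u, v in g.edges()]
    edges.sort()
    w_ctrl = np.array([g.edges[e]["weight"] for e in edges])
    w_case = np.array([case_w.get(e, g.edges[e]["weight"]) for e in edges])

    nodes = sorted(g.nodes())
    logfc = rng.normal(0.0, 0.1, size=len(nodes))
    adj_p = np.ones(len(nodes))
    de = pd.DataFrame({"logFC": logfc, "p": adj_p, "adj_p": adj_p},
                      index=[str(n) for n in nodes])
    for gene, f in targets.items():
        de.loc[str(gene), "logFC"] = f
        de.loc[str(gene), ["p", "adj_p"]] = 0.001
    return edges, w_case, w_ctrl, RegulatoryNetwork(grn_edges), de


def detect_rewiring_from_weights(
    edges: list[tuple[int, int]],
    w_case: np.ndarray,
    w_ctrl: np.ndarray,
    universe: list[int],
    scenario: SimulationScenario,
    rng: np.random.Generator,
) -> RewiredNetwork:
    """Apply the Fisher-difference pipeline to a case/control weight pair.

    Each weight is the pair's population correlation; the observed Fisher z
    per condition is drawn N(arctanh(w), 1/(n_sim - 3)), matching the
    sampling distribution of a correlation estimated from n_sim samples.
    """
    sd = math.sqrt(1.0 / (scenario.n_sim - 3))
    z_case = np.arctanh(np.clip(w_case, -_CLAMP, _CLAMP)) + rng.normal(0, sd, len(edges))
    z_ctrl = np.arctanh(np.clip(w_ctrl, -_CLAMP, _CLAMP)) + rng.normal(0, sd, len(edges))
    r_case = np.tanh(z_case)
    r_ctrl = np.tanh(z_ctrl)
    stat_all = (z_case - z_ctrl) / math.sqrt(2.0 / (scenario.n_sim - 3))
    # standardize against the full edge-score set, then apply the floor as
    # testing-family eligibility (mirrors build_rewired_network)
    Z_all = standardize_scores(stat_all) if len(stat_all) > 1 else np.zeros(len(stat_all))
    tested = np.maximum(np.abs(r_case), np.abs(r_ctrl)) >= scenario.r_min
    idx = np.flatnonzero(tested)
    stat = stat_all[idx]
    Z = Z_all[idx]
    p, adj_p, keep, delta = edge_significance(Z, alpha=scenario.alpha)
    kept = idx[keep]
    ge = pd.DataFrame(
        {
            "gene_i": [str(edges[k][0]) for k in kept],
            "gene_j": [str(edges[k][1]) for k in kept],
            "r_case": r_case[kept],
            "r_ctrl": r_ctrl[kept],
            "z_case": z_case[kept],
            "z_ctrl": z_ctrl[kept],
            "rewire": stat[keep],
            "Z": Z[keep],
            "p": p[keep],
            "adj_p": adj_p[keep],
            "delta": delta[keep],
        }
    )
    return RewiredNetwork(ge, [str(u) for u in universe], int(tested.sum()))


def run_replicate(
    scenario: SimulationScenario, rng: np.random.Generator
) -> pd.DataFrame:
    """One benchmark replicate: fresh network, truth, injection, detection
    and pathway scoring.  Returns a per-pathway DataFrame with the truth
    label, raw and Dy alteration scores and the Dy > 0 prediction."""
    graph = generate_ba_network(
        scenario.n_nodes, scenario.m_attach, rng, scenario.w_low, scenario.w_high
    )
    collection, labels = build_pathway_truth(graph, scenario, rng)
    edges, w_case, w_ctrl, grn, de = inject_rewiring(graph, collection, labels, scenario, rng)
    universe = sorted({u for e in edges for u in e} | set(graph.nodes()))
    net = detect_rewiring_from_weights(edges, w_case, w_ctrl, universe, scenario, rng)
    str_collection = PathwayCollection(
        [Pathway(p.pathway_id, p.description, frozenset(str(g) for g in p.genes))
         for p in collection]
    )
    reg = annotate_regulatory(net, grn, de, de_alpha=scenario.de_alpha, de_mode="any")
    _, table = score_pathways(net, reg, str_collection)
    out = table[["T", "m", "M", "R", "Dr", "raw", "Dy"]].copy()
    out["label"] = [labels[p] for p in out.index]
    out["predicted"] = (out["Dy"] > 0).astype(float)
    return out.reset_index().rename(columns={"index": "pathway"})


def run_scenario(scenario: SimulationScenario) -> pd.DataFrame:
    """Run all replicates of one gamma scenario (concatenated table)."""
    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.replicates)
    frames = []
    for rep, ss in enumerate(seeds):
        df = run_replicate(scenario, np.random.default_rng(ss))
        df.insert(0, "replicate", rep)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def scenario_auroc(results: pd.DataFrame, score: str = "predicted") -> float:
    """Mean per-replicate auROC of the DR-vs-null discrimination."""
    vals = [
        auroc(g[score].to_numpy(), g["label"].to_numpy())
        for _, g in results.groupby("replicate")
    ]
    return float(np.mean(vals))


def auroc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# synthetic expression generator
# ---------------------------------------------------------------------------

@dataclass
class ModuleSpec:
    """An equicorrelated gene module with per-condition correlation."""

    genes: list[str]
    r_case: float
    r_ctrl: float


@dataclass
class ExpressionSpec:
    """Recipe for a matched case/control expression pair."""

    modules: list[ModuleSpec] = field(default_factory=list)
    regulators: list[tuple[str, str, float]] = field(default_factory=list)  # (tf, tg, logFC)
    noise_genes: list[str] = field(default_factory=list)
    n_case: int = 50
    n_ctrl: int = 50
    baseline: float = 7.0
    gene_sd: float = 1.0


def _module_block(
    genes: list[str], rho: float, n: int, baseline: float, sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Equicorrelated multivariate-normal block via a single shared factor."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"infeasible module correlation {rho}; need 0 <= rho < 1")
    factor = rng.standard_normal(n)
    eps = rng.standard_normal((len(genes), n))
    return baseline + sd * (math.sqrt(rho) * factor + math.sqrt(1.0 - rho) * eps)


def generate_expression_pair(
    spec: ExpressionSpec, seed: int | np.random.Generator | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate matched case/control matrices with planted structure.

    Module genes follow a one-factor equicorrelation model with the
    per-condition correlation from the spec; noise genes are independent
    normals; regulator targets get their case mean shifted by the stated
    logFC.  Returns the two matrices and the planted truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_genes: list[str] = []
    for mod in spec.modules:
        all_genes.extend(mod.genes)
    all_genes.extend(spec.noise_genes)
    if len(set(all_genes)) != len(all_genes):
        raise ValueError("module/noise gene lists must be disjoint")

    truth = SyntheticTruth()
    blocks_case: list[np.ndarray] = []
    blocks_ctrl: list[np.ndarray] = []
    for mod in spec.modules:
        blocks_case.append(
            _module_block(mod.genes, mod.r_case, spec.n_case, spec.baseline, spec.gene_sd, rng)
        )
        blocks_ctrl.append(
            _module_block(mod.genes, mod.r_ctrl, spec.n_ctrl, spec.baseline, spec.gene_sd, rng)
        )
        if mod.r_case != mod.r_ctrl:
            gs = sorted(mod.genes)
            truth.rewired_edges |= {
                (gs[i], gs[j]) for i in range(len(gs)) for j in range(i + 1, len(gs))
            }
    if spec.noise_genes:
        blocks_case.append(
            spec.baseline + spec.gene_sd * rng.standard_normal((len(spec.noise_genes), spec.n_case))
        )
        blocks_ctrl.append(
            spec.baseline + spec.gene_sd * rng.standard_normal((len(spec.noise_genes), spec.n_ctrl))
        )
    case = pd.DataFrame(
        np.vstack(blocks_case), index=all_genes,
        columns=[f"case_{k}" for k in range(spec.n_case)],
    )
    ctrl = pd.DataFrame(
        np.vstack(blocks_ctrl), index=all_genes,
        columns=[f"ctrl_{k}" for k in range(spec.n_ctrl)],
    )
    for tf, tg, logfc in spec.regulators:
        case.loc[tg] += logfc
        truth.de_genes[tg] = logfc
        truth.regulatory.add((tf, tg))
    return ExpressionMatrix(case), ExpressionMatrix(ctrl), truth


def planted_scenario(
    seed: int | None = None,
    module_size: int = 20,
    n_targets: int = 6,
    logfc: float = 1.5,
    n_noise: int = 180,
    n_decoys: int = 20,
    decoy_size: int = 20,
    r_ctrl: float = 0.8,
    r_case: float = 0.0,
    n_per_group: int = 50,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PathwayCollection, RegulatoryNetwork, SyntheticTruth]:
    """Standard end-to-end fixture: one rewired + TF-regulated pathway
    among decoy gene sets drawn from noise genes.

    The planted module loses its co-expression in cases (r_ctrl -> r_case);
    its first gene acts as the TF of ``n_targets`` module genes whose case
    means shift by ``logfc``.  Decoy pathways are random noise-gene sets
    with no planted structure.
    """
    rng = np.random.default_rng(seed)
    module = [f"M{k:03d}" for k in range(module_size)]
    noise = [f"N{k:03d}" for k in range(n_noise)]
    tf = module[0]
    regulators = [(tf, tg, logfc) for tg in module[1: 1 + n_targets]]
    spec = ExpressionSpec(
        modules=[ModuleSpec(module, r_case, r_ctrl)],
        regulators=regulators,
        noise_genes=noise,
        n_case=n_per_group,
        n_ctrl=n_per_group,
    )
    case, ctrl, truth = generate_expression_pair(spec, rng)
    entries = [Pathway("PLANTED", "rewired regulated pathway", frozenset(module))]
    for k in range(n_decoys):
        genes = rng.choice(noise, size=decoy_size, replace=False)
        entries.append(Pathway(f"DECOY{k + 1:02d}", "decoy gene set", frozenset(genes)))
    collection = PathwayCollection(entries)
    grn = RegulatoryNetwork({(tf, tg) for tf, tg, _ in regulators})
    truth.labels = {p.pathway_id: int(p.pathway_id == "PLANTED") for p in collection}
    return case, ctrl, collection, grn, truth
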