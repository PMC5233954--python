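"""Model/Results interface for the full pathway-rewiring analysis.

:class:`PathwayRewiringAnalysis` bundles the inputs (case/control expression,
gene sets, optional regulatory network and disease seeds) with the analysis
parameters; :meth:`~PathwayRewiringAnalysis.fit` runs the pipeline —
variance filter, edge rewiring test, regulatory overlay, pathway scoring,
optional label-permutation significance, optional random-walk disease
propagation, gene prioritization — and returns a
:class:`PathwayRewiringResults` carrying the per-edge, per-pathway and
per-gene tables plus a text ``summary()``.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .centrality import gene_table
from .io import ExpressionMatrix, GeneList, PathwayCollection, RegulatoryNetwork
from .pathways import permutation_significance, score_pathways
from .propagation import disease_enrichment_score, rwr_affinity
from .regulatory import annotate_regulatory
from .rewiring import build_rewired_network

try:  # package version for run provenance
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("pathrewire")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


@dataclass
class AnalysisParams:
    """Tunable parameters of the pipeline (defaults follow the method)."""

    alpha: float = 0.05          # edge FDR level
    r_min: float = 0.2           # minimum-correlation floor (0 disables)
    de_alpha: float = 0.05       # DE significance for regulatory targets
    de_mode: str = "any"         # "any" or "up" (up-regulated targets only)
    enrich_alpha: float = 0.05   # pathway enrichment FDR level
    dr_threshold: float = 0.05   # Dr cutoff for "differentially regulated"
    min_genes: int = 6           # smallest usable gene set after mapping
    restart: float = 0.75        # RWR restart probability
    rwr_tol: float = 1e-10
    dr_weighted: bool = False    # weight Dr by per-target edge counts
    disease_divisor: str = "m"   # "m" or "M" in the disease score
    weighted_centrality: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "de_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.restart < 1.0:
            raise ValueError("restart must be in (0, 1)")


class PathwayRewiringAnalysis:
    """Case/control pathway rewiring analysis.

    Parameters
    ----------
    case, control
        Expression matrices (genes x samples, assumed log scale) in one
        consistent gene-ID space.
    pathways
        Gene sets to score (optional — without them only the rewired
        network, DE table and gene prioritization are produced).
    regulatory
        Background TF -> TG network for the regulatory overlay (optional).
    disease_seeds
        Seed genes for random-walk disease propagation (optional).
    params
        :class:`AnalysisParams`; defaults are the method's standard values.
    """

    def __init__(
        self,
        case: ExpressionMatrix,
        control: ExpressionMatrix,
        pathways: PathwayCollection | None = None,
        regulatory: RegulatoryNetwork | None = None,
        disease_seeds: GeneList | None = None,
        params: AnalysisParams | None = None,
    ):
        if case.n_samples < 4 or control.n_samples < 4:
            raise ValueError("need >= 4 samples per group for the rewiring test")
        self.case = case
        self.control = control
        self.pathways = pathways
        self.regulatory = regulatory
        self.disease_seeds = disease_seeds
        self.params = params or AnalysisParams()

    @classmethod
    def from_files(
        cls,
        case_path,
        control_path,
        pathways_path=None,
        regulatory_path=None,
        seeds_path=None,
        params: AnalysisParams | None = None,
    ) -> "PathwayRewiringAnalysis":
        params = params or AnalysisParams()
        case = pio.read_expression(case_path)
        control = pio.read_expression(control_path)
        pathways = (
            pio.read_gmt(pathways_path, min_genes=params.min_genes)
            if pathways_path else None
        )
        grn = pio.read_regulatory_network(regulatory_path) if regulatory_path else None
        seeds = pio.read_gene_list(seeds_path) if seeds_path else None
        return cls(case, control, pathways, grn, seeds, params)

    def fit(self, permutations: int = 0, seed: int | None = None) -> "PathwayRewiringResults":
        """Run the pipeline.

        ``permutations`` > 0 adds the shuffled-label significance test per
        pathway (seeded by ``seed``); the analytic stages themselves are
        deterministic.
        """
        t0 = time.time()
        p = self.params
        net, de = build_rewired_network(
            self.case, self.control, alpha=p.alpha, r_min=p.r_min
        )
        reg = None
        if self.regulatory is not None and len(self.regulatory):
            reg = annotate_regulatory(
                net, self.regulatory, de, de_alpha=p.de_alpha, de_mode=p.de_mode
            )

        subs, pw_table = {}, None
        collection = None
        if self.pathways is not None:
            collection = self.pathways.subset_to_universe(net.universe, p.min_genes)
            subs, pw_table = score_pathways(
                net, reg, collection,
                enrich_alpha=p.enrich_alpha,
                dr_threshold=p.dr_threshold,
                dr_weighted=p.dr_weighted,
            )

        affinity = None
        if self.disease_seeds is not None and net.n_edges:
            aff = rwr_affinity(
                net, self.disease_seeds, r_restart=p.restart, tol=p.rwr_tol
            )
            affinity = aff.affinity
            if pw_table is not None:
                pw_table["disease_score"] = [
                    disease_enrichment_score(subs[pid], aff, divisor=p.disease_divisor)
                    for pid in pw_table.index
                ]

        if pw_table is not None and permutations > 0 and collection is not None:
            perm = permutation_significance(
                self.case, self.control, collection, self.regulatory,
                B=permutations, seed=seed,
                alpha=p.alpha, r_min=p.r_min,
                de_alpha=p.de_alpha, de_mode=p.de_mode, dr_weighted=p.dr_weighted,
            )
            pw_table = pw_table.join(perm[["perm_p", "perm_adj_p"]], how="left")

        genes = gene_table(net, de, affinity, weighted=p.weighted_centrality)

        # regulatory flag + TF/TG columns on the edge table
        edges = net.edges.copy()
        if reg is not None and len(reg):
            keys = reg.edge_keys()
            first = reg.annotations.drop_duplicates(["gene_i", "gene_j"]).set_index(
                ["gene_i", "gene_j"]
            )
            edges["regulatory"] = [
                (gi, gj) in keys for gi, gj in zip(edges["gene_i"], edges["gene_j"])
            ]
            edges["tf"] = [
                first.loc[(gi, gj), "tf"] if (gi, gj) in keys else pd.NA
                for gi, gj in zip(edges["gene_i"], edges["gene_j"])
            ]
            edges["tg"] = [
                first.loc[(gi, gj), "tg"] if (gi, gj) in keys else pd.NA
                for gi, gj in zip(edges["gene_i"], edges["gene_j"])
            ]
        else:
            edges["regulatory"] = False
            edges["tf"] = pd.NA
            edges["tg"] = pd.NA

        if pw_table is not None:
            pw_table = pw_table.reset_index().rename(columns={"index": "pathway"})

        run_info = {
            "params": asdict(p),
            "permutations": permutations,
            "seed": seed,
            "n_genes_universe": len(net.universe),
            "n_pairs_tested": net.n_pairs_tested,
            "n_rewired_edges": net.n_edges,
            "n_case_samples": self.case.n_samples,
            "n_control_samples": self.control.n_samples,
            "runtime_s": round(time.time() - t0, 3),
            "package_version": _VERSION,
        }
        return PathwayRewiringResults(
            edges=edges, pathways=pw_table, genes=genes, de=de,
            network=net, regulatory_set=reg, run_info=run_info, params=p,
        )


@dataclass
class PathwayRewiringResults:
    """Fitted results: per-edge, per-pathway and per-gene tables."""

    edges: pd.DataFrame
    pathways: pd.DataFrame | None
    genes: pd.DataFrame
    de: pd.DataFrame
    network: object
    regulatory_set: object
    run_info: dict
    params: AnalysisParams

    @property
    def n_rewired_edges(self) -> int:
        return len(self.edges)

    @property
    def altered_pathways(self) -> pd.DataFrame:
        if self.pathways is None:
            return pd.DataFrame()
        alt = self.pathways[self.pathways["altered"].fillna(False)]
        return alt.sort_values("rank")

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the top-ranked altered pathways."""
        ri = self.run_info
        lines = [
            "Pathway rewiring analysis",
            "=" * 60,
            f"universe genes            {ri['n_genes_universe']}",
            f"gene pairs tested         {ri['n_pairs_tested']}",
            f"rewired edges (FDR<={self.params.alpha})  {ri['n_rewired_edges']}",
            f"regulatory rewired edges  {int(self.edges['regulatory'].sum())}",
        ]
        if self.pathways is not None:
            n_alt = int(self.pathways["altered"].sum())
            n_dr = int(self.pathways["differentially_regulated"].sum())
            lines += [
                f"pathways scored           {len(self.pathways)}",
                f"altered pathways          {n_alt}",
                f"differentially regulated  {n_dr}",
            ]
            alt = self.altered_pathways
            if len(alt):
                lines.append("")
                lines.append(f"top {min(top, len(alt))} altered pathways (by Dy):")
                cols = ["pathway", "T", "m", "enrich_adj_p", "R", "Dr", "Dy"]
                if "disease_score" in alt.columns and alt["disease_score"].notna().any():
                    cols.append("disease_score")
                if "perm_p" in alt.columns and alt["perm_p"].notna().any():
                    cols.append("perm_p")
                lines.append(alt.head(top)[cols].to_string(index=False))
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write edges.tsv / pathways.tsv / genes.tsv / run.json."""
        return pio.write_outputs(self, out_dir)
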