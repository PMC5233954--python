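import itertools
import math

import numpy as np
import pytest

from pathrewire.io import ExpressionMatrix
from pathrewire.simulation import (
    ExpressionSpec,
    ModuleSpec,
    SimulationScenario,
    auroc,
    build_pathway_truth,
    generate_ba_network,
    generate_expression_pair,
    inject_rewiring,
    planted_scenario,
    run_replicate,
    run_scenario,
)


def auroc_bruteforce(scores, labels):
    """All-pairs comparison oracle with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestBaNetwork:
    def test_node_count(self):
        g = generate_ba_network(n=2000, m_attach=3, seed=0)
        assert g.number_of_nodes() == 2000

    def test_edge_count_formula(self):
        # preferential attachment adds m edges per incoming node
        g = generate_ba_network(n=500, m_attach=2, seed=1)
        assert g.number_of_edges() == 2 * (500 - 2)

    def test_weights_in_baseline_range(self):
        g = generate_ba_network(n=200, m_attach=3, seed=2)
        w = [d["weight"] for *_, d in g.edges(data=True)]
        assert min(w) >= 0.2 and max(w) <= 1.0

    def test_seed_determinism(self):
        g1 = generate_ba_network(n=300, m_attach=3, seed=7)
        g2 = generate_ba_network(n=300, m_attach=3, seed=7)
        assert set(g1.edges()) == set(g2.edges())

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_ba_network(n=3, m_attach=5)


class TestPathwayTruth:
    def _truth(self, gamma=0.5, seed=0, **kw):
        sc = SimulationScenario(gamma=gamma, **kw)
        rng = np.random.default_rng(seed)
        g = generate_ba_network(sc.n_nodes, sc.m_attach, rng)
        coll, labels = build_pathway_truth(g, sc, rng)
        return sc, g, coll, labels, rng

    def test_counts_and_sizes(self):
        sc, g, coll, labels, _ = self._truth()
        assert len(coll) == 100
        assert sum(labels.values()) == 10
        dr = [p for p in coll if labels[p.pathway_id] == 1]
        null = [p for p in coll if labels[p.pathway_id] == 0]
        assert all(len(p.genes) == 100 for p in dr)
        assert all(50 <= len(p.genes) <= 100 for p in null)

    def test_dr_sets_disjoint_from_everything(self):
        _, _, coll, labels, _ = self._truth(seed=3)
        dr_union = set()
        for p in coll:
            if labels[p.pathway_id] == 1:
                assert not (dr_union & p.genes)
                dr_union |= p.genes
        for p in coll:
            if labels[p.pathway_id] == 0:
                assert not (p.genes & dr_union)

    def test_nonpathway_reserve_exists(self):
        _, g, coll, _, _ = self._truth(seed=4)
        used = set().union(*(p.genes for p in coll))
        assert len(set(g.nodes()) - used) > 50


class TestInjection:
    def _inject(self, gamma, seed=0):
        sc = SimulationScenario(gamma=gamma)
        rng = np.random.default_rng(seed)
        g = generate_ba_network(sc.n_nodes, sc.m_attach, rng)
        coll, labels = build_pathway_truth(g, sc, rng)
        edges, w_case, w_ctrl, grn, de = inject_rewiring(g, coll, labels, sc, rng)
        return sc, coll, labels, edges, w_case, w_ctrl, grn, de

    def test_every_dr_pathway_has_rewired_intra_edge(self):
        _, coll, labels, edges, w_case, w_ctrl, *_ = self._inject(0.25)
        changed = {e for e, wc, wk in zip(edges, w_case, w_ctrl) if wc != wk}
        for p in coll:
            if labels[p.pathway_id] != 1:
                continue
            genes = {int(x) for x in p.genes}
            assert any(u in genes and v in genes for u, v in changed)

    def test_null_intra_edges_identical_across_copies(self):
        _, coll, labels, edges, w_case, w_ctrl, *_ = self._inject(1.0)
        null_genes = set().union(
            *({int(x) for x in p.genes} for p in coll if labels[p.pathway_id] == 0)
        )
        for (u, v), wc, wk in zip(edges, w_case, w_ctrl):
            if u in null_genes and v in null_genes:
                assert wc == wk

    def test_gamma_sets_regulatory_gene_count(self):
        for gamma, expected in ((0.01, 1), (0.25, 25), (1.0, 100)):
            _, coll, labels, _, _, _, grn, de = self._inject(gamma, seed=1)
            tgs_by_pathway = {}
            tg_all = {int(tg) for _, tg in grn.edges}
            for p in coll:
                if labels[p.pathway_id] == 1:
                    members = {int(x) for x in p.genes}
                    tgs_by_pathway[p.pathway_id] = len(members & tg_all)
            assert all(v == expected for v in tgs_by_pathway.values())
            assert math.ceil(gamma * 100) == expected

    def test_targets_stamped_de_significant(self):
        *_, grn, de = self._inject(0.5, seed=2)
        tgs = [tg for _, tg in grn.edges]
        assert (de.loc[tgs, "adj_p"] <= 0.01).all()
        assert (de.loc[tgs, "logFC"].abs() >= 0.5).all()
        non = de.drop(index=set(tgs))
        assert (non["adj_p"] == 1.0).all()


class TestScenario:
    def test_replicate_scores_all_pathways(self):
        sc = SimulationScenario(gamma=0.5, n_nodes=600, n_dr=3, dr_size=40,
                                n_pathways=20, null_size_range=(15, 30))
        out = run_replicate(sc, np.random.default_rng(0))
        assert len(out) == 20 and out["label"].sum() == 3
        assert {"raw", "Dy", "predicted"} <= set(out.columns)

    def test_high_gamma_separates_dr_from_null(self):
        sc = SimulationScenario(gamma=1.0, n_nodes=600, n_dr=3, dr_size=40,
                                n_pathways=20, null_size_range=(15, 30),
                                replicates=3, seed=5)
        res = run_scenario(sc)
        dr = res[res["label"] == 1]
        null = res[res["label"] == 0]
        assert dr["Dy"].mean() > null["Dy"].mean()
        assert dr["predicted"].mean() > 0.8

    def test_fixed_seed_reproduces_scores(self):
        sc = SimulationScenario(gamma=0.5, n_nodes=400, n_dr=2, dr_size=30,
                                n_pathways=10, null_size_range=(10, 20),
                                replicates=2, seed=9)
        a = run_scenario(sc)
        b = run_scenario(sc)
        assert a.equals(b)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            SimulationScenario(gamma=0.0)


class TestAuroc:
    def test_known_values(self):
        assert auroc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)
        assert auroc([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            auroc([1.0, 2.0], [1, 1])

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(4, 200))
            scores = rng.integers(0, 10, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                auroc_bruteforce(scores, labels), abs=1e-12
            )


class TestExpressionGenerator:
    def test_planted_module_correlations(self):
        genes = [f"m{i}" for i in range(15)]
        spec = ExpressionSpec(
            modules=[ModuleSpec(genes, 0.0, 0.8)],
            noise_genes=[f"n{i}" for i in range(5)],
            n_case=400, n_ctrl=400,
        )
        case, ctrl, truth = generate_expression_pair(spec, seed=0)
        rc = np.corrcoef(ctrl.values.loc[genes].to_numpy())
        off = rc[np.triu_indices(15, 1)]
        assert off.mean() == pytest.approx(0.8, abs=0.05)
        ra = np.corrcoef(case.values.loc[genes].to_numpy())
        assert abs(ra[np.triu_indices(15, 1)].mean()) < 0.05
        assert len(truth.rewired_edges) == 15 * 14 // 2

    def test_infeasible_correlation_rejected(self):
        spec = ExpressionSpec(modules=[ModuleSpec(["a", "b"], -0.2, 0.5)])
        with pytest.raises(ValueError, match="infeasible"):
            generate_expression_pair(spec, seed=0)

    def test_target_logfc_planted(self):
        case, ctrl, coll, grn, truth = planted_scenario(seed=2)
        for tg, logfc in truth.de_genes.items():
            observed = case.values.loc[tg].mean() - ctrl.values.loc[tg].mean()
            assert observed == pytest.approx(logfc, abs=0.6)

    def test_no_planted_effects_is_null(self):
        from pathrewire.rewiring import build_rewired_network

        spec = ExpressionSpec(noise_genes=[f"n{i}" for i in range(60)])
        case, ctrl, _ = generate_expression_pair(spec, seed=3)
        net, _ = build_rewired_network(case, ctrl)
        assert net.n_edges <= 2

    def test_planted_de_power(self):
        from pathrewire.rewiring import differential_expression

        hits = trials = 0
        for seed in range(10):
            case, ctrl, _, _, truth = planted_scenario(seed=seed)
            de = differential_expression(*_harmonize(case, ctrl))
            for tg in truth.de_genes:
                trials += 1
                hits += de.loc[tg, "adj_p"] <= 0.05
        assert hits / trials > 0.9


def _harmonize(case, ctrl):
    from pathrewire.rewiring import filter_zero_variance

    c, k, _ = filter_zero_variance(case, ctrl)
    order = sorted(c.genes)
    return c.subset_genes(order), k.subset_genes(order)
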