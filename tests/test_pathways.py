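import math

import numpy as np
import pandas as pd
import pytest

from pathrewire.io import Pathway, PathwayCollection, RegulatoryNetwork
from pathrewire.pathways import (
    PathwaySubnetwork,
    alteration_scores,
    classify,
    differential_regulation_score,
    enrichment_test,
    map_pathway,
    permutation_significance,
    rewiring_density,
)
from pathrewire.regulatory import annotate_regulatory
from pathrewire.simulation import planted_scenario

from test_regulatory import make_de, make_net


def hypergeom_tail_oracle(a, pathway_n, rewired_K, universe_N):
    """P(overlap >= a) by direct hypergeometric summation."""
    total = 0.0
    for k in range(a, min(pathway_n, rewired_K) + 1):
        total += (
            math.comb(rewired_K, k)
            * math.comb(universe_N - rewired_K, pathway_n - k)
            / math.comb(universe_N, pathway_n)
        )
    return total


def make_sub(pathway_id="pw", T=3, m=None, deltas=(), targets=None, mapped=frozenset()):
    deltas = np.asarray(deltas, dtype=float)
    return PathwaySubnetwork(
        pathway_id=pathway_id,
        T=T,
        M=T * (T - 1) // 2,
        m=len(deltas) if m is None else m,
        deltas=deltas,
        intra_edges=[("x", "y")] * len(deltas),
        targets=targets or {},
        mapped_genes=mapped,
    )


class TestMapPathway:
    def test_possible_connection_count(self):
        net = make_net([("a", "b")], universe=[f"g{i}" for i in range(10)] + ["a", "b"])
        sub = map_pathway(net, None, "pw", {f"g{i}" for i in range(10)})
        assert sub.M == 45 and sub.T == 10 and sub.m == 0

    def test_disjoint_pathway_unscoreable(self):
        net = make_net([("a", "b")])
        sub = map_pathway(net, None, "pw", {"q", "r"})
        assert sub.T == 0 and not sub.scoreable
        with pytest.raises(ValueError, match="unscoreable"):
            rewiring_density(sub)

    def test_intra_edges_and_deltas_collected(self):
        net = make_net([("a", "b"), ("b", "c"), ("c", "d")])
        sub = map_pathway(net, None, "pw", {"a", "b", "c"})
        assert sub.m == 2 and sub.T == 3

    def test_external_tf_counted_global(self):
        net = make_net([("b", "t")])  # rewired edge TF(t) -- TG(b)
        grn = RegulatoryNetwork({("t", "b")})
        de = make_de([("b", 1.5, 0.01), ("t", 0.0, 1.0)])
        reg = annotate_regulatory(net, grn, de)
        sub = map_pathway(net, reg, "pw", {"a", "b", "c"})
        assert sub.global_tfs == {"t"} and not sub.local_tfs
        assert sub.targets["b"] == (1, 1.5)


class TestEnrichment:
    def test_matches_hypergeometric_tail(self):
        # pathway 10 genes, 8 rewired; universe 1000 with 50 rewired
        uni = {f"g{i}" for i in range(1000)}
        rewired = {f"g{i}" for i in range(50)}
        pathway = {f"g{i}" for i in range(43, 53)}  # overlap = 7 rewired
        sub = make_sub(T=10, mapped=frozenset(pathway))
        p = enrichment_test(sub, rewired, uni)
        a = len(pathway & rewired)
        assert p == pytest.approx(hypergeom_tail_oracle(a, 10, 50, 1000), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        uni = {f"g{i}" for i in range(100)}
        sub = make_sub(T=5, mapped=frozenset({f"g{i}" for i in range(5)}))
        assert enrichment_test(sub, {f"g{i}" for i in range(50, 60)}, uni) == pytest.approx(1.0)

    def test_pathway_equals_universe_gives_p_one(self):
        uni = {f"g{i}" for i in range(20)}
        sub = make_sub(T=20, mapped=frozenset(uni))
        assert enrichment_test(sub, {f"g{i}" for i in range(4)}, uni) == pytest.approx(1.0)

    def test_exact_oracle_agreement_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            N = int(rng.integers(4, 51))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            a = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            uni = {f"g{i}" for i in range(N)}
            rewired = {f"g{i}" for i in range(K)}
            pathway = {f"g{i}" for i in range(K - a, K - a + n)}
            sub = make_sub(T=n, mapped=frozenset(pathway))
            p = enrichment_test(sub, rewired, uni)
            assert p == pytest.approx(hypergeom_tail_oracle(a, n, K, N), rel=1e-9, abs=1e-12)


class TestScores:
    def test_rewiring_density_examples(self):
        assert rewiring_density(make_sub(T=3, deltas=())) == 0.0
        assert rewiring_density(make_sub(T=3, deltas=(0.9, 0.8))) == pytest.approx(0.5667, abs=1e-4)
        assert rewiring_density(make_sub(T=3, deltas=(1.0, 1.0, 1.0))) == 1.0

    def test_density_monotone_in_added_edges(self):
        base = rewiring_density(make_sub(T=4, deltas=(0.9,)))
        more = rewiring_density(make_sub(T=4, deltas=(0.9, 0.5)))
        assert more > base

    def test_dr_examples_and_set_semantics(self):
        assert differential_regulation_score(make_sub()) == 0.0
        sub = make_sub(targets={"a": (1, 1.0), "b": (1, -2.0)})
        assert differential_regulation_score(sub) == pytest.approx(1.5)
        # a TG regulated by two TFs is one target with n_j = 2
        dup = make_sub(targets={"a": (2, 1.0)})
        assert differential_regulation_score(dup) == pytest.approx(1.0)
        assert differential_regulation_score(dup, weighted=True) == pytest.approx(1.0)

    def test_dr_weighted_variant(self):
        sub = make_sub(targets={"a": (3, 1.0), "b": (1, 2.0)})
        assert differential_regulation_score(sub, weighted=True) == pytest.approx(1.25)

    def test_dr_monotone_when_adding_strong_target(self):
        sub = make_sub(targets={"a": (1, 1.0)})
        grown = make_sub(targets={"a": (1, 1.0), "b": (1, 3.0)})
        assert differential_regulation_score(grown) > differential_regulation_score(sub)


class TestAlterationScores:
    def test_single_pathway_degenerate_normalization(self):
        out = alteration_scores([make_sub(deltas=(0.5,))])
        assert out["Dy"].tolist() == [0.0]

    def test_population_sd_normalization(self):
        subs = [
            make_sub("p1", T=3, deltas=(0.6,)),          # raw 0.2
            make_sub("p2", T=3, deltas=(0.6, 0.6)),      # raw 0.4
            make_sub("p3", T=3, deltas=(0.9, 0.9)),      # raw 0.6
        ]
        out = alteration_scores(subs)
        np.testing.assert_allclose(out["raw"], [0.2, 0.4, 0.6], atol=1e-12)
        np.testing.assert_allclose(out["Dy"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_mean_zero_and_order_preserved(self):
        rng = np.random.default_rng(3)
        subs = [
            make_sub(f"p{i}", T=5, deltas=tuple(rng.uniform(0.5, 1, rng.integers(0, 6))))
            for i in range(15)
        ]
        out = alteration_scores(subs)
        assert abs(out["Dy"].mean()) < 1e-12
        assert (out.sort_values("raw").index == out.sort_values("Dy").index).all()

    def test_m_zero_pathways_scoreable_but_not_in_d(self):
        out = alteration_scores([make_sub("p1", deltas=(0.9,)), make_sub("p2", deltas=())])
        assert bool(out.loc["p1", "in_d"]) and not bool(out.loc["p2", "in_d"])


class TestClassify:
    def _table(self, **over):
        base = dict(enrich_adj_p=0.01, m=2, Dr=0.0, Dy=1.0)
        base.update(over)
        return pd.DataFrame([base], index=["pw"])

    def test_enriched_without_targets_is_altered_not_dr(self):
        out = classify(self._table(Dr=0.0))
        assert bool(out["altered"].iloc[0]) and not bool(out["differentially_regulated"].iloc[0])

    def test_dr_threshold_is_strict_greater(self):
        assert bool(classify(self._table(Dr=0.06))["differentially_regulated"].iloc[0])
        assert not bool(classify(self._table(Dr=0.05))["differentially_regulated"].iloc[0])

    def test_enrichment_gate_precedes_density(self):
        out = classify(self._table(enrich_adj_p=0.5, Dr=2.0, Dy=5.0))
        assert not bool(out["altered"].iloc[0])

    def test_ranking_by_dy_descending(self):
        tab = pd.DataFrame(
            {"enrich_adj_p": [0.01, 0.01, 0.5], "m": [1, 1, 1],
             "Dr": [0, 0, 0], "Dy": [0.5, 2.0, 9.9]},
            index=["a", "b", "c"],
        )
        out = classify(tab)
        assert out.loc["b", "rank"] == 1 and out.loc["a", "rank"] == 2
        assert pd.isna(out.loc["c", "rank"])


class TestPermutation:
    def test_add_one_estimator_bounds(self):
        # direct check of the estimator arithmetic on the planted pathway
        assert (1 + 0) / (19 + 1) == pytest.approx(0.05)
        assert (1 + 19) / (19 + 1) == pytest.approx(1.0)

    def test_planted_pathway_significant_decoys_uniform(self):
        case, ctrl, coll, grn, _ = planted_scenario(seed=5)
        out = permutation_significance(case, ctrl, coll, grn, B=49, seed=9)
        assert out.loc["PLANTED", "perm_p"] <= 0.05
        decoys = out.drop("PLANTED")
        assert (decoys["perm_p"] > 0.2).mean() > 0.7  # roughly uniform nulls

    def test_invalid_b_rejected(self):
        case, ctrl, coll, grn, _ = planted_scenario(seed=5)
        with pytest.raises(ValueError, match="B"):
            permutation_significance(case, ctrl, coll, grn, B=0)
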