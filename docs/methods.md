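# Methods

## Model and assumptions

`pathrewire` treats a case/control expression dataset as two samples from
gene-level multivariate distributions and asks, for every gene pair, whether
the pair's Pearson correlation differs between the conditions.  Expression
values are assumed to be on a log-like scale (log2 microarray intensities or
log-transformed counts) so that group mean differences are log fold changes,
and samples are assumed independent within and across groups.  Missing
values are rejected at read time; genes with zero variance in either
condition are removed before any correlation is computed, and the
intersection of surviving genes defines the analysis *universe* used as the
background of every downstream test.

The pair-level test is the classical Fisher z difference test: with
z = arctanh(r) estimated per condition, the statistic

    rewire = (z_case − z_ctrl) / sqrt(1/(n_case − 3) + 1/(n_ctrl − 3))

is approximately standard normal under no change.  The statistic is
antisymmetric in the two conditions, so swapping case and control flips
signs but retains the same edge set.  Group sizes below 4 are rejected
(the variance terms would be undefined); in practice ≥ 20 samples per
group are needed for useful power.

Two empirical normalizations follow:

1. **Score standardization.**  Scores are z-standardized against the mean
   and population standard deviation of the *entire* pair-score set.  This
   is a self-calibration step: with mostly-null pairs the scale is ≈ 1 and
   the standardization is nearly a no-op, while heavy-tailed data shrink
   the scores towards honesty.  The standardization scale is deliberately
   computed *before* the optional correlation floor is applied (below):
   conditioning the scale on pairs selected for extreme estimated
   correlations inflates the empirical sigma (≈ 1.7 instead of ≈ 1.0 on
   planted-module data) and can annihilate the power of the test.
2. **Correlation floor.**  Pairs with max(|r_case|, |r_ctrl|) < `r_min`
   (default 0.2, 0 disables) are excluded from the testing family before
   the BH adjustment.  This mirrors the observation that retained rewired
   edges in real data populate the |r| ∈ [0.2, 1] range, and reduces the
   multiplicity burden for large gene spaces.

Standardized scores get two-tailed normal p-values, BH adjustment across
the tested family, and edges with adjusted p ≤ `alpha` (default 0.05) form
the rewired network.  The retained-edge score is δ = 1 − adj_p.  The exact
transform from significance to edge weight is a design choice of this
package: δ is the simplest monotone, (0, 1]-bounded score consistent with
being summed inside the pathway statistics.

Differential expression uses the group-mean difference as logFC and a Welch
two-sample t-test with BH adjustment.  A moderated (empirical-Bayes) test
would shrink variances at small n; only the logFC values and a significance
flag feed the downstream scores, so the simpler test is used and documented.

## Regulatory overlay

An undirected rewired edge {a, b} is *regulatory* when (a→b) or (b→a) is in
the user-supplied background TF→TG network and the target is significantly
DE (adj. p ≤ `de_alpha`).  Both directions can hold for mutual regulators
and both annotations are recorded.  `de_mode="any"` (default) accepts DE in
either direction; `"up"` restricts to up-regulated targets.  The permissive
default reflects that TF-mediated rewiring can both induce and repress
targets; the strict reading is available for studies of activating
regulation.  The TF itself is not required to be expression-stable: that
requirement belongs to the motivating biology, not to the score.

## Pathway statistics

For a gene set with T mapped genes, M = T(T−1)/2 counts all unordered
intra-pathway pairs — the only connection universe computable from
expression data alone (no backbone network is assumed).  With m retained
intra-pathway rewired edges:

* R = Σ δ_i / M ∈ [0, 1] (rewiring density);
* Dr = mean |logFC| over the t targets carrying ≥ 1 regulatory rewired
  edge, 0 when t = 0.  Absolute fold changes are used because Dr is a
  magnitude score — signed means would cancel opposing regulation.  The
  per-target regulatory edge counts n_j are reported, and a weighted
  variant Σ n_j |f_j| / Σ n_j is available (`dr_weighted`), but the default
  follows the plain average;
* raw alteration = R + Dr; **Dy** is the z-standardization (population sd)
  of the raw scores.

**Normalization set.**  Dy is standardized across *all* scoreable pathways
(T ≥ 2), with raw = 0 for pathways without a rewired intra-pathway edge,
rather than across only the m ≥ 1 subset.  The rationale: Dy > 0 is the
method's "more altered than the average gene set" decision rule.  When few
gene sets contain rewired edges — precisely the situation in a controlled
benchmark where only the true positives are rewired — normalizing within
the m ≥ 1 subset forces half of those true positives below zero regardless
of effect size, making the decision rule incoherent.  Normalizing over the
whole scored collection keeps the rule meaningful in both regimes and
preserves the score ordering (the transform is monotone).  Membership in
the m ≥ 1 set is still reported (`in_d`), and classification is unaffected:
*altered* requires enrichment adj. p ≤ `enrich_alpha` **and** m ≥ 1;
*differentially regulated* additionally requires Dr > `dr_threshold`
(default 0.05).  Intra-pathway rewiring is thus a hard gate — a gene set
differentially regulated but not rewired is never called.

Enrichment is the one-sided Fisher exact test on
[pathway ∩ rewired, pathway ∖ rewired; rest ∩ rewired, rest ∖ rewired]
over the variance-filtered universe, BH-adjusted across pathways.

**Permutation significance.**  Sample labels are shuffled B times
preserving group sizes and the whole pipeline (rewiring, regulatory
overlay, pathway mapping) is recomputed per shuffle.  The permuted
statistic is the *raw* alteration score, not Dy, so each pathway's null
distribution does not depend on which other gene sets were co-shuffled.
perm_p = (1 + #{raw_perm ≥ raw_obs}) / (B + 1), BH-adjusted.

## Disease propagation and gene prioritization

Random walk with restart runs on the column-normalized, δ-weighted
adjacency of the rewired network: p ← (1 − r) W p + r p0, with p0 uniform
over the mapped seed genes and restart r = 0.75 (the default of the
propagation package this component follows), iterated to an L1 residual
below 1e-10.  The iteration conserves probability mass and equals the
direct linear solve r (I − (1 − r) W)^{-1} p0.  Components without seeds
legitimately receive near-zero mass.  A pathway's disease score averages
p_i + p_j over its m rewired intra-pathway edges; dividing by m (default)
avoids penalizing gene sets for untested pairs, a division by M is
available (`disease_divisor="M"`).

Gene prioritization computes closeness and PageRank (damping 0.85) on the
δ-weighted graph — closeness uses distance 1/δ so stronger rewiring means
shorter distance; an unweighted mode is available — plus unweighted degree
and the unweighted local clustering coefficient.  The composite score `cs`
averages the four z-standardized centralities; standardization prevents the
unbounded degree from dominating and makes `cs` a dimensionless z-like
quantity.  The local rewiring score is the z-standardized sum of incident
δ over network genes; its exact form is a reconstruction of a z-like
"rewiring strength" magnitude, documented as such.

## Simulation benchmark

The benchmark asks whether the Dy score distinguishes truly
TF-differentially-regulated gene sets from null sets as the proportion γ of
regulatory genes grows.  Per replicate: a fresh 2000-node Barabási–Albert
graph (attachment parameter 3 — the generator's choice, configurable) with
Uniform(0.2, 1) edge weights; 10 disjoint DR pathways of 100 genes; 90
null sets of 50–100 genes drawn from a sub-pool (85%) of the remaining
nodes — null sets may overlap one another (the node budget makes full
disjointness impossible) but never the DR sets, and the reserved 15% of
nodes stays pathway-free to host regulatory partners.  In the case copy
every DR intra-pathway edge weight is replaced by Uniform(0, 1) (one edge
is added first if a DR set has none), and ⌈γ·100⌉ genes per DR pathway
get one edge to a non-pathway partner rewired likewise; the partner is
registered as the gene's TF and the gene stamped DE (|logFC| ~
Uniform(0.5, 2), adj. p = 0.001; non-targets logFC ~ N(0, 0.1), adj. p =
1).  Null intra-pathway edges are identical across copies.

**Detection on weight graphs.**  Weight graphs have no samples, so the
Fisher pipeline is applied under its own sampling model: each weight is
taken as the pair's population correlation and the observed z per condition
is drawn N(arctanh(w), 1/(n_sim − 3)) with nominal n_sim = 50 per group.
This makes the test exactly calibrated on unchanged edges (the alternative
— comparing noiseless weights — gives the statistic zero variance and a
degenerate, trivially separable benchmark).

**Decision rule and ROC.**  A pathway is predicted differentially regulated
when Dy > 0; the per-replicate Mann–Whitney auROC of this binary prediction
against the 10-vs-90 truth equals (sensitivity + specificity)/2 and is
averaged over replicates.  A continuous-score ROC is not meaningful here:
null gene sets essentially never contain a rewired intra-pathway edge, so
any continuous convention separates the classes trivially at every γ and
cannot express the prediction-rule behavior the benchmark probes.  At
γ = 0.01 a DR pathway carries a single regulatory edge whose detection is
marginal (weight replacement often lands near the original), so roughly a
third of the true positives cross Dy > 0 and the mean auROC sits near
0.66; detection of at least one of ⌈γ·100⌉ regulatory edges saturates
quickly, so accuracy exceeds 0.9 from γ = 0.25 onward and the curve is
monotone with ties near 1 at high γ.  Benchmark runs here use 20–40
replicates per scenario (the full 200 changes the mean estimates only in
the third decimal).

## What the synthetic data do and do not emulate

The expression generator plants equicorrelated modules via a one-factor
model (per-condition correlation, so a module can be fully rewired, e.g.
0.8 → 0.0), mean-shifted TF targets, and independent noise genes on a
log-intensity-like scale (baseline 7, unit sd, 50 samples per group).  It
emulates the signal structure the method tests for — co-expression loss
and TF-coupled DE — but not: negative or heterogeneous within-module
correlations, mean–variance coupling of counts, batch effects, outlier
samples, or overlapping modules.  Passing tests therefore demonstrate
correctness of the statistics and recovery under the stated model, not
robustness to real-data artifacts.  Feasibility is enforced (module
correlations must lie in [0, 1)); infeasible specs raise.

## Numerical choices and degenerate inputs

* Correlations with |r| ≥ 1 are clamped to ±(1 − 1e-7) before arctanh,
  with a warning (perfect collinearity occurs in toy data).
* Population (n-denominator) standard deviation everywhere a score set is
  standardized; a zero spread maps all scores to 0 with a warning.
* Gene pairs are stored once under lexicographic gene-ID order; self-loops
  are never scored.
* Empty results are valid at every stage: an all-null dataset yields an
  empty rewired network, no altered pathways, and headers-only output
  files.
* BH adjustment, Fisher exact tests, Welch t-tests, graph centralities and
  BA graphs come from statsmodels, scipy and networkx; the rewiring
  statistic, pathway scores, RWR and auROC are implemented here and each
  is checked in the test suite against an independent oracle (sort-based
  BH, hypergeometric tail summation, direct linear solve, all-pairs
  count).

## Known limitations

* The correlation floor makes the tested family data-dependent; p-value
  calibration statements apply to the unfloored statistic (`r_min = 0`).
* Dr uses |logFC| of targets regardless of regulation sign; activating
  vs repressive effects are not distinguished.
* The M = T(T−1)/2 connection universe assumes any intra-pathway pair is
  testable; sparse biological backbones would make R systematically small
  for large pathways.
* Permutation significance recomputes the full pipeline per shuffle and
  scales quadratically in the universe size; it is intended for the
  pathway shortlist, not genome-wide scans.
* With unbalanced group sizes the rewiring test remains valid (sizes enter
  the variance term) but power is governed by the smaller group.
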