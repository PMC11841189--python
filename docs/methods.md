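# Methods

## Experimental logic being modelled

The pipeline analyses a four-condition design: water control, H₂O₂, LaCl₃,
and H₂O₂ + LaCl₃, with three biological replicates per condition.  LaCl₃
blocks plasma-membrane Ca²⁺ channels, suppressing the cytosolic Ca²⁺
transient that H₂O₂ normally evokes, so the difference between a gene's
H₂O₂-alone and H₂O₂+LaCl₃ responses isolates the Ca²⁺-dependent part of
its regulation.  All contrasts are against the water control.

## DEG calling

A gene is differentially expressed for a contrast when FDR < 0.01 (strict
inequality) and |log₂FC| ≥ 0.5 (inclusive).  Everything else — including
genes significant at FDR but below the fold-change gate — is UC
(unchanged).  This two-part complement matters for strictness calls: a
combined-treatment gene at FDR 10⁻⁶ with log₂FC 0.3 counts as UC and hence
as strictly Ca²⁺-dependent if it was an H₂O₂-DEG.  FDR values are
Benjamini–Hochberg (statsmodels' step-up implementation, cross-checked in
the test suite against a naive step-up oracle).

The surrogate two-group test (`de_stats.surrogate_de`) exists so that fully
synthetic count matrices can be pushed end-to-end through the pipeline: it
normalizes by median-of-ratios size factors, reports
log₂((mean_b + 0.5)/(mean_a + 0.5)) with the 0.5 pseudo-count avoiding
log-of-zero, and takes p-values from a Welch t-test on log₂(normalized + 1).
It is deliberately simple — no dispersion shrinkage, no GLM — and with
three replicates it is conservative; it is not a substitute analysis for
real experiments.

## Dependency classification

With Δlog₂FC = log₂FC_H₂O₂ − log₂FC_combined, an H₂O₂-DEG is classified:
STRICT if its combined response is UC; otherwise, if |Δlog₂FC| ≥ 1 (a
twofold difference in fold change), ANTAGONISTIC on a sign flip,
PARTIAL_ADDITIVE if attenuated, ENHANCED if amplified; otherwise
INDEPENDENT.  The Δ gate is applied unsigned so the rule covers up- and
down-regulated genes symmetrically.  Equal-magnitude same-sign responses
cannot pass the Δ gate (their Δ is zero), which the code asserts
unreachable.

Two domain decisions are worth flagging:

* the unique-DEG filter runs in `identity` mode by default — any
  combined-treatment DEG that is also a LaCl₃-alone DEG is excluded,
  regardless of direction (Venn-overlap semantics); a `same_direction`
  mode removing only same-sign overlaps is exposed as an option;
* genes that are DEGs under the combined treatment but UC under H₂O₂ alone
  are outside the classification domain (the analysis classifies
  H₂O₂-responsive genes); they are returned separately, unclassed.

The H₂O₂-DEG reference set defaults to genes passing the gate in the
supplied H₂O₂ table, but an external gene-id list can be given instead,
mirroring a design where that catalogue comes from a prior experiment.

Published tissue-level counts carry one internal inconsistency: the root
component counts sum to 799 + 522 = 1321 while the headline total is
printed as 1320 (and elsewhere 1334).  The package reports exact component
sums (1321, hence 1652 across tissues) and makes no attempt to reproduce
any one of the divergent headline figures.

## Profile clustering

The feature matrix is the per-gene pair (log₂FC_H₂O₂, log₂FC_combined),
unscaled — the clusters should group raw response patterns, and the two
features are already on a common scale.  Optional z-scaling is available.
k-means is scikit-learn's Lloyd algorithm from k-means++ starts, best of
25 restarts, seeded (default 123).  The cluster count comes from the gap
statistic: Gap(k) = E*[log W_k] − log W_k over B = 100 reference datasets
drawn uniformly over each feature's observed range, s_k = sd·√(1 + 1/B),
choosing the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1} and falling back
to argmax Gap if no k qualifies.  Reference fits use 2 restarts (they only
need W_k to first order; this keeps a B = 100 curve under a second per k).
Singleton clusters report SE = 0 with a logged flag so downstream tables
stay numeric.

## Constrained regulatory paths

The knowledge network is a multigraph of typed edges — transcriptional
regulation (always directed), post-translational modification (directed,
actor → substrate), binding (undirected, traversable both ways), other —
each with a reliability rank (0 best).  A valid path from an annotated
source to a target (i) has 1–3 edges, (ii) is simple, (iii) uses only
rank ≤ 2 edges, (iv) contains exactly one transcription-regulation edge,
as the final edge.  The single-TF and terminal-TF conditions are enforced
as two conjoined predicates since either alone admits routes the biology
excludes.  Per target, only paths of the minimal realized length survive
(closest-source reduction), then paths are merged across targets.  Hubs
are ranked by (number of distinct targets whose paths contain the node,
number of path occurrences, node id), descending.

Sources may appear as intermediates of other targets' paths; a target may
appear as an intermediate in other targets' paths but not inside its own
(the simple-path rule).  Annotation matching uses dot-boundary prefix
semantics mirroring hierarchical function bins: query "30.3" matches
"30.3" and "30.3.1" but not "30.31".  Ortholog mapping keeps, per query,
the hit with minimal E-value ≤ 10⁻³⁰, ties broken by bitscore then subject
id.  The edge-table schema (src, dst, etype, rank, directed) is this
package's own dialect; a case-insensitive `etype_map` hook adapts
third-party vocabularies.

Correctness of the search is established against an independent exhaustive
enumerator (all simple node sequences × all parallel-edge combinations ×
the same predicates) on hundreds of random small graphs, not assumed.

## qPCR quantification

2^–ΔΔCt with efficiency 2 assumed: per sample, ΔCt = Ct_target − mean
Ct of the reference genes (arithmetic mean at Ct level, equivalent to the
geometric mean of linear quantities; with equal efficiencies the choice of
averaging scale is immaterial, which the tests verify numerically as the
dual-vs-mean-reference identity).  Rows sharing (gene, sample) — technical
repeats — are averaged at the Ct level first.  ΔΔCt = mean ΔCt_treated −
mean ΔCt_control; per-replicate ratios 2^−(ΔCt_rep − mean ΔCt_control) are
returned for SE bars or ANOVA (a Tukey HSD convenience wrapper is
provided).  Concordance between qPCR and sequencing estimates is ordinary
least squares plus Pearson correlation.  Reporter traces are reduced to
baseline-subtracted peaks: max after injection minus the mean of the 10 s
immediately before it; calibration of raw luminescence to concentration is
out of scope, so traces must arrive calibrated.

## Synthetic data and what it does (not) show

Counts are negative-binomial with gene-wise baseline means
exp(Normal(5.5, 1.0)) (median ≈ 245 counts), a shared dispersion 0.05
(var = μ + 0.05 μ²), and condition means scaled by 2^lfc of the planted
contrast.  DE tables can also be generated directly as planted log₂FC plus
Normal(0, lfc_se) Wald noise with two-sided normal p-values — the default
lfc_se = 0.15 is small relative to the 0.5 DEG gate, representing
well-powered calls.

Each gene gets one of ten true classes (55% null by default).  The
canonical per-class effects — e.g. strict-up (2.0, 0), partial-up
(3.0, 1.2), enhanced-down (−1.2, −3.0), antagonistic (1.5, −1.2),
independent (1.8, 1.8), LaCl₃-artifact (1.5, 1.5, 1.5) — were chosen once
so that every effect sits at least 0.6 log₂ units (≈ 2.8 Wald SEs at the
default noise) from every decision boundary: the classes are separated but
not trivially so, and noiseless tables reproduce the classes exactly.
LaCl₃-artifact genes plant identical effects in the LaCl₃-alone and
combined contrasts, so the uniqueness filter removes them, as intended.

The network generator plants each valid path on its own source, target and
intermediate nodes; decoys add constraint-violating near-paths (two TF
edges, non-terminal TF, length-4 routes, rank-3 parallel edges) plus
rank-3 clutter, constructed from fresh nodes so decoy fragments cannot
splice into new valid rank ≤ 2 routes.  Ct tables place the treated Ct at
control Ct minus the planted log₂FC with condition-invariant references,
making noiseless 2^–ΔΔCt exact.

What passing tests show: the algorithms implement their definitions
correctly, recover planted structure under the stated noise, and control
FDR on null data.  What they do not show: performance on real RNA-seq
(no library-size or batch effects, no per-gene dispersion trends, discrete
rather than continuous effect sizes, no correlated genes) or on a real
curated interaction network (whose degree distribution and annotation
coverage differ greatly from the planted-path generator).

## Benchmark problem sizes

The standard evaluation (`cadep.evaluation`, run by
`scripts/acceptance.py`) uses: 2,000 genes × 10 seeds for classifier
recovery; a 20,000-gene full null for FDR control; 200 random networks for
planted-path recovery and 20 for hub ranking; 20 seeds × B = 100 for each
gap-statistic calibration (60 2-D points per dataset); 200 profiles over
five patterns for clustering recovery; and a 600-gene end-to-end chain
with a 12-gene qPCR panel.  These sizes give stable rates while keeping a
full run around half a minute on one CPU.
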