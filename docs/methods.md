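# Methods

This note documents the statistical procedures, defaults and design
choices in `fflnet`, and what the synthetic-data results do and do not
establish about real data.

## Edge model and prefiltering

Nodes carry exactly one class (gene, miRNA, TF); rosters with a symbol
in two classes are rejected rather than resolved, because no overlap
semantics are defined for the downstream motif classification (a TF
that is also a "gene" would make the self-regulation and exclusivity
rules ambiguous). Gene/TF symbols match case-sensitively; miRNA names
match case-insensitively (miRBase capitalisation varies across
prediction tools) and are reported with the roster spelling.

Prediction-score prefilters are applied exactly as their sources
phrase them: TargetScan total context score strictly *above* a cutoff
(default −0.30), miRanda S strictly above 90 and ΔG strictly below
−17, Match core ≥ 1.00 and matrix ≥ 0.95 (the Match scores are bounded
above by 1.00, so a strict inequality would be vacuous at the
published core cutoff). Because more-negative context scores indicate
stronger predicted repression, "above −0.30" plausibly inverts the
intended direction; the direction is therefore configurable
(`context_direction="lower"`), with the verbatim reading as default.
Edges missing a thresholded score pass by default: the miRNA-target
sources are unioned, not intersected, so absence of one tool's score
is not evidence against an edge.

## FFL classification

For a fixed (miRNA m, TF t, gene g), with presence flags for the four
possible edges, the classifier requires both m⊣g and t→g; the TF–miRNA
arm then decides the category: m⊣t only → miRNA-FFL; t→m only →
TF-FFL; both → composite-FFL. A triple with both regulator→gene edges
but no TF–miRNA arm is **not** an FFL — there is no co-regulation loop.
Exclusivity is enforced by promotion: the reciprocal-arm triple is
composite only. This is the only reading consistent with the
categories being mutually exclusive while the composite motif carries
4 edges. Enumeration walks TF–miRNA arm pairs and intersects the two
regulators' target sets; the test suite proves exact agreement with an
exhaustive triple scan on random typed digraphs.

## Networks and degree

A network is the union of nodes and edges over a set of FFLs —
predicted edges that participate in no FFL never enter. Degree is
undirected incident-edge count; a reciprocal TF↔miRNA pair is two
distinct edges and contributes 2 to each endpoint. Every degree table
satisfies the handshake lemma, and every node in an FFL-derived
network has degree ≥ 2.

## Correlation filter

For each candidate edge the Pearson r is computed pairwise-complete
over the relevant samples, and converted to a one-tailed p via
t = r·√((n−2)/(1−r²)) against Student's t with n−2 df. miRNA-sourced
edges are tested in the negative direction (repression); TF-sourced
edges are tested in the direction of the observed r — the only
interpretation under which a symmetric rule like "r ≥ 0.15 or
r ≤ −0.15" corresponds to a single one-tailed threshold.

Sample alignment: TF→gene pairs use the mRNA assay's samples; any
pair involving a miRNA uses the intersection of the two assays'
sample sets. With the default simulated design this yields the two
reference sizes n = 264 and n = 243, whose analytic one-tailed
p = 0.01 critical correlations are 0.1431 and 0.1492 — the source of
the 0.14/0.15 rule-of-thumb floors.

Multiple testing is controlled by Benjamini–Hochberg within each
edge-type family (each family has its own sample size and sign rule);
a global family is available by configuration. Significance requires
all three of: the sign rule, |r| at or above the fixed floor, and
adjusted p < α (default 0.01). Note a fixed |r| floor and an
FDR-adjusted p rule are not the same constraint — the adjusted-p
critical r is data-dependent and becomes the binding constraint for
large families — so both are applied; with small families the floor
binds, which reproduces the intended behaviour of quoting fixed
cutoffs alongside an FDR rule. r values are compared at full
precision; nothing is rounded before comparison.

An FFL is significant only if *all* of its 3 or 4 constituent edges
are significant; edges with an endpoint absent from its expression
matrix are reported as "unmeasured" and can never support a
significant FFL.

## Hubs

The hub rule is top-fraction-by-degree within node class, fraction
0.20, ties included: the cutoff is the smallest observed degree d such
that the class's nodes with degree ≥ d number at most 20% of the
class. Ties-included means a class with flat degrees yields no hubs
rather than an arbitrary 20%. Manual per-class cutoffs are supported
for imposing externally chosen values. The fraction rule is this
package's choice of a simple, label-invariant degree criterion; no
betweenness or bottleneck variants are computed.

## Survival

Kaplan–Meier estimation and the public two-group log-rank test are
delegated to `lifelines`; the cutpoint scan uses an internal
vectorised log-rank (identical hypergeometric O−E statistic, asserted
equal to lifelines in tests) because a scan evaluates thousands of
splits. Candidate cutpoints are every integer percentile of observed
expression from the 10th to the 90th; each split must leave at least
10% of samples in each group; the minimal-p cutpoint wins, exact ties
going to the cutpoint nearest the median. Because a minimised p is
anti-conservative, the Miller–Siegmund approximation

p_adj ≈ φ(z)(z − 1/z)·ln[(1−ε₁)ε₂ / (ε₁(1−ε₂))] + 4φ(z)/z

with z = Φ⁻¹(1 − p_min/2) and scan bounds (ε₁, ε₂) = (0.10, 0.90) is
reported alongside the raw p; the raw p remains the headline value,
matching how optimum-cutoff survival curves are conventionally
reported. "High risk" names the group with the worse survival (the
sign of the high-group's O−E), irrespective of which expression side
it is. Times are taken in the input unit (days) without conversion.

## Synthetic studies

The generator plants FFLs on node-disjoint triples (so planted
category counts are exact) and rejection-samples decoy edges,
re-checking locally that no candidate decoy completes or promotes any
triple; structural assertions downstream are therefore sharp, not
probabilistic. Optionally, extra miRNA-FFLs sharing one designated
miRNA create a known high-degree hub.

Expression is multivariate Gaussian built from shared latent factors:
each true (regulator, target) pair gets a standard-normal factor that
both endpoints load with √|r| (one side signed), plus independent
noise topping each node up to unit variance, giving corr = r exactly
while letting one node serve several pairs. When a node's loadings
would exceed unit variance (a hub with many correlated partners) they
are rescaled and its pairwise correlations shrink below |r| — a real
limitation worth noting: motifs through strong hubs are the first to
fall below the correlation floor. A pair linked by reciprocal
TF↔miRNA edges is a single pair; the repressive (negative) sign binds.
Defaults: |r| = 0.5 on true pairs, 264 mRNA samples with a 243-sample
miRNA overlap, 5 planted FFLs per category among 50 decoys per edge
type.

Survival times are exponential. Two hazard models are provided:
`linear` (log hazard = baseline + logHR·standardised expression) and
`threshold` (hazard multiplied by e^logHR above a planted expression
percentile, default the 60th). The threshold model is the one used
for cutpoint-recovery benchmarking, since only a change-point hazard
defines a true cutpoint for the scan to recover; defaults are
logHR = 1.5 and 30% censoring. Censoring is independent Uniform(0, c)
with c calibrated by root-finding so the expected censored fraction
equals the configured rate.

What passing synthetic tests shows — and does not. The generator
exercises the pipeline's statistics (correlation power and FDR
behaviour at the study's sample sizes, motif bookkeeping, cutpoint
recovery) but deliberately does not mimic RNA-seq count distributions,
batch effects, shared-factor confounding between unrelated genes, or
real regulatory topology. High sensitivity on Gaussian data with
|r| = 0.5 says the procedure is implemented correctly and well-powered
at these effect sizes, not that real predicted edges are recovered at
that rate.

## Numerical choices and degenerate inputs

* Correlations with n < 3 complete pairs or a zero-variance endpoint
  are undefined and flagged, never silently 0.
* One-tailed p underflow at |r| = 1 returns the smallest positive
  float, keeping p ∈ (0, 1] for BH.
* BH adjustment delegates to `statsmodels` (`fdr_bh`) and is verified
  against an independent step-up implementation.
* Empty FFL lists merge to an empty network with a warning, not an
  error; writing an empty network is an error.
* All generators are deterministic under a fixed seed
  (`numpy.random.default_rng`); pipeline reports are byte-identical
  across reruns of the same configuration.

## Problem sizes used in the bundled benchmarks

The recovery and null benchmarks run 50 and 100 expression replicates
over a fixed 250-edge regulome (15 planted FFLs, 200 decoys) at the
default sample sizes, and 100 survival replicates at n = 300; the
enumeration oracle comparison uses 200 random digraphs of up to ~50
nodes. These sizes give stable rates (binomial standard errors of a
few percent) while keeping the whole suite fast.
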