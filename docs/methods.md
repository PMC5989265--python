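# Methods

This note documents the models, defaults and numerical choices behind
`splicestage`, and what the synthetic generator does and does not show
about real data.

## Ψ quantification and differential splicing

A cassette exon's inclusion isoform spans two exon–exon junctions and
the skipping isoform one, so raw inclusion-junction reads are halved to
put the isoforms on a per-transcript scale: with i = inc_reads/2 and
s = skip_reads,

    Ψ = i / (i + s),   coverage c = i + s.

Cells are masked (missing, never 0) when c < `min_cov` (default 20
effective reads) or when the binomial standard deviation
√(Ψ(1−Ψ)/c) ≥ `max_sd` (default 0.1). The halving convention is a
package choice exposed as `halve_inclusion`; "coverage" here counts
inclusion junctions after halving.

Differential splicing between two conditions pools replicate counts,
builds the 2×2 (inclusion, skipping) table with halved inclusion counts
rounded half-to-even, and applies the standard two-sided Fisher's exact
test (probability-ordering convention, ties included; p = 1 when a
margin is zero). FDR is step-up Benjamini–Hochberg; a call requires
coverage ≥ 20 in both conditions, FDR ≤ 0.05 and |ΔΨ| ≥ 0.2. Over an
ordered stage series, an exon is *regulated* if significant in at
least one pairwise comparison and *monotonic* if every significant
change shares one sign. Replicate-aware GLM testing is out of scope.

## Time axis

Stage labels are converted to log10 post-conception days: E*d* ↦ d,
P*d* ↦ 19.5 + d (mouse gestation 19.5 days, configurable), *n*mo ↦
19.5 + 30.44·n. The nine-point cortex reference axis is E14.5, E16.5,
P0, P4, P7, P15, P30, 4mo, 21mo.

## Co-splicing modules

The detector follows unsigned weighted-correlation-network practice:

1. adjacency a_uv = |pearson(u,v)|^β with β = 3 (a `signed` variant
   ((1+r)/2)^β is available);
2. topological-overlap dissimilarity;
3. average-linkage hierarchical clustering with a **static cut**
   (`cut_height`, default 0.30 on the TOM-dissimilarity scale) and a
   minimum module size of 30;
4. one eigenexon per module — the first principal component of the
   member profiles standardized per exon across time points, unit
   norm, oriented so its mean correlation with member profiles is
   non-negative;
5. iterative merging of the closest module pair while eigenexon
   dissimilarity 1 − |r| < `merge_diss` (default 0.25), recomputing
   eigenexons after every merge; manual merges via `force_merge`;
6. member sign (+/−) from the sign of the exon–eigenexon correlation,
   and core membership where |r| exceeds the two-sided critical value
   at α = 0.001 — r* = t*/√(t*² + n−2) with t* the 1−α/2 quantile of
   the t distribution on n−2 df, ≈ 0.898 for n = 9 time points.

The static cut replaces dynamic tree cutting deliberately: on planted
module structure a fixed height between the within-module and
between-module merge levels recovers membership at 98–100% purity,
whereas height-quantile rules proved unstable (they track the total
number of unclustered background exons rather than the module
separation). Dynamic hybrid tree cutting, soft-threshold selection and
scale-free-topology diagnostics are not reimplemented.

Because the network is unsigned, anti-correlated exon groups
deliberately co-cluster and are separated afterwards by the +/− sign
split; merging uses |r| since eigenexon orientation is arbitrary for
balanced two-sided modules.

## Switch timing

Each exon's trajectory is fit with the four-parameter logistic

    Ψ(t) = a + (k − a) / (1 + e^(−b(t − m))),

a = low and k = high inclusion level (a ≤ k enforced by canonical
orientation; direction carried by sign(b)), m = switch time. Fitting is
bounded trust-region least squares (a, k ∈ [0,1]; |b| ≤ 50; m within
the time range ± 0.5) with multi-start: m initialized at the observed
half-range crossing and the 25/50/75% quantiles of t, b at ±4; the
lowest SSE wins. Fits need ≥ 5 non-missing points. Quality is the
normalized residual

    ε = √( Σ_i (Ψ_i − Ψ̂_i)² / (N (k − a)) ),

N = number of non-missing points (missing points are excluded from N),
with ε = ∞ when k = a. A fit is *reliable* when ε < 0.15, k − a > 0.2
and m > 0; these constants are configurable. Ranking by switch time
uses reliable fits only, ascending m, ties broken by exon id.

## Maturation staging

A query's module-exon Ψ vector y is modeled per exon as
y_i ~ Beta(μ_i, φ) in the mean/precision parameterization
(var = μ(1−μ)/(1+φ)) with the logit link and no intercept:

    logit(μ_i) = Σ_j x_ij β_j,

x_ij = inclusion of exon i in reference time point j. Boundary values
are shrunk by y′ = (y(n−1) + 0.5)/n with n the number of exons used.
The likelihood is maximized over (β, log φ) by L-BFGS-B with analytic
gradients; β is initialized from least squares on the logit scale and
φ by method of moments, with up to 3 damped restarts. The fit requires
≥ 50 exons jointly quantified in query and reference (`min_exons`).

Distances are squared (not rooted), as defined:
D_j = Σ_i (x_ij − μ̂_i)². The stage is the stage of the argmin
reference column (1-NN; E14.5→1 … P7→5, everything from P15 on → 6,
since post-P15 reference profiles are nearly identical), ties broken
toward the younger stage; confidence is S = 1 − min(D)/max(D) ∈ [0,1].
Accuracy is reported both exact and adjacency-tolerant (|Δstage| ≤ 1),
since a sample's true age can fall between reference ages.

Note that the logit-link projection cannot reproduce a reference
column cell-by-cell (logit(x_j) is generally outside the span of the
columns); self-projections still rank their own column nearest, which
is the property staging relies on.

PCA display fits two components on the reference columns only
(exon-wise centered by the reference mean) and projects queries with
missing exons imputed by the reference mean; it never influences the
stage call. Subset staging (e.g., exons targeted by one RNA-binding
protein) refits the same model on the intersection of the subset with
the atlas.

## Enrichment analyses

All enrichment uses the hypergeometric upper tail P(X ≥ k) with the
population N, successes K, draws n counted on *genes* (a gene with
several exons in a window counts once). The sliding-window analysis
walks the switch-time-ranked exon list with window 300 and step 1
(L ranked exons give (L−300)/step + 1 windows; 964 give 665), tests
every term with ≥ 5 background genes, corrects jointly across all
term × window tests by BH, and keeps FDR ≤ 0.005 (the figure-level
0.05 variant is flag-overridable). Per-module enrichment is the same
test per term per module at FDR ≤ 0.05. Significant terms are
clustered on their −log10(FDR) window profiles by average-linkage
hierarchical clustering with a deterministic leaf order. Hexamer
enrichment counts presence/absence per sequence (matching the
hypergeometric sampling model) over all 4096 hexamers, skipping
windows containing N, with fg + bg sequences as the population. GO
graph propagation and motif-model scanning are out of scope.

## Synthetic data

The generator emulates the nine-stage cortex reference with a
module-structured program:

* **M1** (late switches): m ~ U(t(P7)+0.02, t(P15)−0.01); **M2**
  (early): m ~ U(t(P0)±0.03); both split evenly into + (rising) and −
  (mirrored) members. Slopes |b| ~ U(18, 36), i.e. switches complete
  within ~0.12–0.24 log10 days — the sharpness of real developmental
  switches (e.g. birth-time switches completing between E16.5 and P7);
  gentler slopes make the two modules' eigenexons nearly collinear and
  the module structure unidentifiable in principle, not just in
  practice.
* **M3/M4** (non-monotonic): a rising early sigmoid plus a falling
  late sigmoid (independent opposite-direction events), midpoints near
  P0 and P15/P7.
* **null** exons are flat; default mix M1 0.40, M2 0.34, M3 0.08,
  M4 0.08, null 0.10 (the two monotonic modules dominate, ~3/4 of
  regulated exons).
* Levels a ~ U(0.05, 0.25), k ~ U(0.75, 0.95).

Observed data add truncated-normal (reflected into [0,1]) trajectory
noise (SD 0.05 default), then binomial junction-read sampling at
negative-binomial per-cell coverage (mean 100, dispersion 10 —
moderately overdispersed junction depth). Queries evaluate the true
trajectories at any age in range with the same noise model; the
sensory-like query freezes early-switch (M2) exons at their embryonic
values and late-switch (M1) exons at adult values. Gene sets are drawn
uniformly, with optional terms planted into switch-time rank
intervals. All generators are pure functions of (config, seed).

What passing tests on these data do **not** show: real junction counts
are not binomial given a single Ψ (overdispersion across replicates),
trajectories need not be sigmoidal, module exons overlap genes
non-independently, annotation terms are hierarchically nested, and the
real reference is measured, not noise-free. Recovery rates here
characterize the algorithms under their own model assumptions, not
expected performance on tissue data. Problem sizes in the test suite
(600–1000 exons, 100 staging queries, 100 null-control runs) were
chosen as the smallest scales at which the planted structure is
comfortably identifiable.

## Known limitations

* Only cassette exons are modeled (no alt 5′/3′ sites, retained
  introns, mutually exclusive exons).
* Pooled-count Fisher testing ignores replicate variance.
* The static dendrogram cut requires a sensible `cut_height` for
  atypical correlation structures; inspect merge heights when module
  counts look wrong.
* A fully dissociated (sensory-like) profile is off the reference
  manifold: its distance profile is bimodal and the full-profile stage
  call lands at the extreme with the larger mismatch mass, so
  subset-based staging is the meaningful readout for such samples.
* The beta regression assumes a common precision φ across exons.
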