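# Methods

## Scope and inputs

The pipeline starts from a summarized, log2-scale expression matrix
(genes × samples) with each sample labelled `responder`, `nonresponder` or
`untreated`. Probe-level preprocessing (array summarization, probe QC) is
out of scope; the variance filter described below is the in-pipeline
replacement for probe-level informative/non-informative calls, which require
raw probe data. Partial responders are not a valid label: the contrast the
whole analysis is built on is the clean responder/nonresponder dichotomy.

Three further inputs are plain text: a signed directed edge list
(`source  activates|inhibits  target`, optional weight column) standing in
for a curated interaction knowledgebase; a drug-signature database as a
probe × instance matrix in which every column is a permutation of
1..n_probes (rank 1 = most up-regulated), with an instance→drug table; and a
mouse-gene → human-probe ortholog table. Real imports must pre-rank ties
deterministically (average, then first occurrence) because rank columns are
validated as exact permutations.

## Synthetic data: what is planted and what is not

The generator emulates a 30-array design: 10 responders, 10 non-responders,
10 untreated controls, 2000 genes. It is a latent-factor model. Module
*m* has a latent eigengene score per sample, e_mj ~ Normal(μ_mg, 1), where
μ differs by δ_m between responder and non-responder groups (split ±δ_m/2;
untreated at 0). Defaults plant five 100-gene modules with δ = (+2, −2, 0,
0, 0). Gene *i* in module *m* is x_ij = β_i·e_mj + ε_ij with loadings
β ~ Uniform(0.5, 1), ε ~ Normal(0, 1); the first gene of each module is the
designated hub with β = 1. Background genes are Normal(0, 1) noise. Because
a module eigengene is defined as a first principal component, recovery of
the planted scores by the network stage is analytically expected (measured
median |r| ≈ 0.99).

The companion generators plant: one regulator per response module wired to
60% of its genes with edge signs matching the module direction (so a fully
consistent "activated" call is the right answer), among 20 degree-matched
decoy regulators wired to random genes with random signs; and 3 drugs (of
100, 2 instances each, 5000 probes) whose instances place the probes of
responder-up genes at the bottom of the ranking and responder-down probes at
the top, with Gaussian rank jitter (sd 100 positions) before re-ranking.
Decoy instances are uniform permutations. All randomness flows from
per-generator streams derived from one seed; identical (config, seed) gives
byte-identical outputs.

What the generator does **not** emulate: probe-level noise, batch effects,
cell-type composition, correlated background genes, and realistic
between-group separation of the untreated arm (its mean sits at 0 for every
module, midway between the treated groups, so sample-level clustering
separates the three groups only weakly). Passing tests therefore demonstrate
that the machinery recovers planted low-rank structure at realistic noise,
not that any particular biological dataset will yield eight modules.

Two statistical facts about this design are worth knowing before reading
test output. First, the hub's loading (1.0) equals the upper bound of the
competitor loading range, so with 30 samples the hub is the *expected* but
not the guaranteed top of its module's rankings: across seeds its median
within-module rank is ~20 of ~150 on either axis. (Shrinking the noise does
not sharpen the |t| axis: as ε → 0 the per-gene t-statistics become
identical because the loading cancels.) The planted regulator, by contrast,
is recovered at rank 1 essentially always. Second, drugs are ranked on the
reverse-polarity tail when the planted reversers are the target; the
default ranking polarity is `mimic` (drugs positively connected to the
query signature), and `polarity: reverse` flips it.

## Pipeline stages and numerical choices

**Variance filter.** Genes are ranked by across-sample variance (ddof 1);
`keep_fraction` keeps the top fraction (ties broken by input order, so the
count is exact), `min_variance` applies an absolute threshold. Filtering
with a fixed threshold is idempotent.

**Sample clustering.** 1 − Pearson correlation distance, average linkage
(scipy); exported as Newick. Constant samples are an error because their
correlation is undefined.

**Network construction.** Pairwise Pearson correlation; signed adjacency
A = ((1+r)/2)^β by default. Signed, not unsigned, because the two response
modules anti-correlate through the group structure (their latent scores have
population correlation ≈ −0.5 under the default design), and an unsigned
network fuses them into one module in a substantial fraction of datasets;
the signed transform suppresses exactly that cross-module adjacency while
leaving the all-positive within-module correlations intact. `unsigned`
remains available in configuration.

The soft-threshold power is the smallest candidate (1..20) whose scale-free
fit reaches signed R² ≥ 0.8, where the fit regresses log10 frequency on
log10 mean connectivity over 10 equal-width connectivity bins and signs R²
by the negated slope; if none reaches the target, the maximizer wins.

Topological overlap is the standard first-order TOM,
TOM_ij = (ℓ_ij + A_ij) / (min(k_i, k_j) + 1 − A_ij) with
ℓ_ij = Σ_{u≠i,j} A_iu A_uj, computed densely (gene counts capped at 20 000;
TOM is O(n³)). Modules come from average-linkage clustering of 1 − TOM cut
at a static height — the 0.8 quantile of the merge heights — with clusters
below `min_module_size` (30) unassigned. A refinement stage then attaches
each unassigned gene to the module with the smallest average TOM
dissimilarity, provided that distance is below the cut height (the same
refinement dynamic tree cutting applies after core detection; disable with
`pam_stage=False`). The 0.8 quantile was chosen over higher cuts because
merge heights concentrate near 1 for TOM dissimilarities and a 0.99-quantile
cut produces one giant cluster. Modules whose eigengenes correlate above
0.75 (dissimilarity < `merge_cut_height` = 0.25) are merged iteratively,
closest pair first. Labels are 1..M by decreasing size (0 = unassigned),
ties broken by first-gene position, so results are order-independent up to
relabelling.

**Eigengenes.** Per module: standardize genes (mean 0, sd 1 across
samples), take the first right-singular vector over samples (unit norm),
orient its sign so correlation with the module's mean standardized profile
is non-negative; report variance explained.

**Moderated t.** Pooled two-sample variances s_g² (d_g = n_A + n_B − 2 df)
are modelled as s0²·F around a prior with d0 prior df. The hyperparameters
come from closed-form moments of log s_g²: after removing the known digamma
offset, the residual mean estimates log s0² − ψ(d0/2) + log(d0/2) and the
excess variance (beyond the known trigamma term, sample variance with
ddof 1) estimates ψ′(d0/2), inverted by Newton iteration (tolerance 1e-10,
50 iterations, with asymptotic guards). Non-positive excess variance means
no detectable variance heterogeneity and gives d0 = ∞ (all genes share
s0²) — the common outcome on the homoskedastic synthetic data. Then
s̃_g² = (d0 s0² + d_g s_g²)/(d0 + d_g) and
t = logFC / (s̃_g √(1/n_A + 1/n_B)) with d0 + d_g df (normal at d0 = ∞);
d0 = 0 recovers the classical pooled t. FDR control is Benjamini–Hochberg.
Module association reports per-module median/mean t and the fraction of
genes significant at α (default 0.001) per direction; modules are ranked by
|median t| — robust and faithful to the box-plot view this ranking mirrors —
and the top up- and down-modules are flagged as response modules.

**Hub ranking.** Within a module, the coexpression score is
min(percentile kWithin, percentile |t|) (average-rank percentiles): a hub
must be extreme on *both* axes, i.e. sit in the upper-right corner of the
connectivity-vs-differential-expression plane; `product` is available as an
alternative combiner. The prior-knowledge score is the number of distinct
module genes a node touches, counting both edge directions (the edge list
gives no reason to privilege out-edges). The consensus is the intersection
of the two top-k lists ordered by rank sum. Regulator nodes that are not
themselves measured genes can appear in the degree ranking; the consensus
therefore intersects identifiers, not positions.

**Connectivity-map scoring.** Tag sets come from the response-module genes
under either q < α (default 0.05) or top-n by |t| per direction, expanded
through the ortholog map (a gene with k probes contributes k tags; a probe
reachable from both directions goes to the side with larger |t|, logged).
Tag-set sizes are bounded (10–500). Per instance,
ks(tags) uses the two-sided enrichment form: with sorted tag ranks V(j),
a = max_j [j/t − V(j)/n], b = max_j [V(j)/n − (j−1)/t], ks = a if a > b
else −b. The raw score is s = ks_up − ks_down when the two have opposite
signs, else 0; scaling divides positive s by max s and negative s by
|min s|, giving c ∈ [−1, 1]; a drug's score is the mean c of its instances
(a deliberate simplification of the original tool's enrichment-of-instances
aggregation). The permutation p-value draws B ≥ 100 random tag-set pairs of
matching sizes and compares the drug's mean *unclamped* ks_up − ks_down:
the clamp puts an atom at zero and the scaling couples a drug's c to the
database-wide extremes, and either would distort the permutation null away
from uniform (verified: decoy p-values pass a KS uniformity test with the
unclamped statistic and fail badly without).

**Upstream regulators.** The gene universe is the intersection of the
expression genes and the graph nodes (the analysis cannot speak to genes it
has never measured or wired). The DE set is the response-module genes at
q < α (default 0.05, exposed); observed directions are the signs of their
moderated t. Overlap p is the right-tail hypergeometric P(X ≥ k);
activation z uses unit weights unless the edge list carries a weight
column; |z| ≥ 2 predicts activated/inhibited. Regulators with targets but
none in the DE set score p = 1, state undetermined.

**Pipeline.** Stages run in analysis order, write deterministic
tab-separated artifacts (fixed float format, sorted key order) with SHA-256
checksums in the run report, and abort with a stage-named error while
preserving completed artifacts. If the FDR rule yields too few signature
tags, the cmap stage falls back to top-100 by |t| per direction (logged).
Two runs from the same seed are byte-identical.

## Problem sizes

Simulation-based checks use the default design (2000 genes × 30 samples)
over 20 replicate seeds, 50 seeds for null calibration of the per-gene FDR,
and smaller designs (60 genes, 200–300 probes, 5–10 drugs) for
permutation-heavy checks such as p-value uniformity, keeping the full test
suite and the acceptance script each under a minute of compute on one CPU.

## Known limitations

- The static cut + nearest-module refinement is simpler than the full
  dynamic hybrid tree cut; on data with nested or very unequal modules the
  module count is sensitive to `cut_height_quantile` and `min_module_size`.
- Dense TOM limits the network stage to ~20 000 genes; there is no
  block-wise mode.
- The moderated-t model assumes a common residual df across genes (complete
  data, one two-group contrast); there is no design-matrix interface.
- Drug-level aggregation is a mean over instances; the original
  connectivity-map tool's instance-enrichment aggregation is not
  implemented.
- Eight modules on any particular real dataset is a parameter-sensitive
  outcome, not a property the defaults guarantee.
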