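# Methods

This note documents the statistical model behind each stage, the
numerical choices made where the procedure leaves room, and what the
synthetic data generator does and does not emulate.

## Preprocessing

The pipeline takes a probe×sample beta-value matrix (values in [0, 1],
missing allowed) and applies, in a fixed order: (i) removal of features
whose id starts with `rs` (SNP probes) or `ch` (non-CpG `ch.` probes),
matched case-sensitively as prefixes; (ii) removal of features that are
zero in every sample or missing in any sample; (iii) per-probe min–max
scaling x → (x − min)/(max − min); (iv) per-gene averaging of all
probes annotated to that gene symbol, with probes annotated to several
genes contributing to each. Normalization precedes aggregation, so a
gene vector is a mean of [0, 1] rows and itself lies in [0, 1].

A constant probe row has an undefined min–max image; it is mapped to
all zeros and kept by default (`drop_constant_rows` drops it instead).
The accounting identity |input| = |kept| + |removed| holds at every
filter and is recorded in the run summary.

Note that per-probe min–max scaling makes downstream geometry purely
*shape*-based: any affine per-probe transformation of the input leaves
the normalized matrix unchanged. This matters for interpreting the
density stage below.

## Noise removal

**ε calibration.** For each gene vector the distance to its k-th
nearest other vector is computed (Euclidean, k = MinPts − 1 = 4 by
default — the usual kNN-distance-plot convention that excludes the
self-neighbor) and the distances are sorted ascending. Ranks and
distances are each scaled to [0, 1] and the derivative of scaled
distance with respect to scaled rank is estimated by a forward finite
difference over a rank window of max(1, round(0.05 n)). The knee is the
first rank at which this derivative exceeds the threshold (default 1,
i.e. the local slope first exceeds the curve's average slope), and ε is
the **raw** distance at that rank (`eps_scale="scaled"` reports the
[0, 1]-scaled value instead; on min–max-normalized data the two agree
at printed precision, and raw units are what DBSCAN needs).

The window is a numerical-estimation choice, not a change of rule: on
short curves it reduces to the adjacent-rank forward difference, and on
long curves it is required for the rule to be usable at all. At
adjacent-rank resolution the derivative of an empirical quantile curve
is gap·(n−1)/range, and the extreme left tail of *any* continuous
distance distribution contains gaps above range/(n−1) with probability
approaching one as n grows — the unsmoothed rule would therefore fire
within the first few ranks on any realistic input, contradicting the
intended "elbow" reading of the plot. Averaging over 5 % of the curve
suppresses single-gap noise while leaving genuine elbows (which span
many ranks) intact. Curves that never exceed the threshold (linear or
constant curves) raise a dedicated error instructing the caller to
supply ε manually.

**DBSCAN.** A point is *core* if its closed ε-ball contains at least
MinPts points (itself included), *border* if it is not core but within
ε of a core point, and *noise* otherwise. Clusters are connected
components of core points under ε-reachability; a border point joins
the cluster of its lowest-indexed core neighbor (a deterministic
tie-break; the assignment is otherwise ambiguous when a border point
touches two clusters). Labels are assigned in order of each component's
lowest-indexed core point, making the labeling reproducible and
permutation-invariant up to relabeling. Implementation uses exact
neighbor queries (`sklearn.neighbors.NearestNeighbors`); no
approximation is involved.

Core **and border** features are retained and noise features dropped;
the per-cluster core/border counts and the noise total are reported.
Retaining border features follows the reported accounting of the
reference workflow even though the R default `borderPoints = FALSE` is
quoted there; a strict mode (`keep_border=False`) is provided.

## Differential methylation

For a two-group design (n₁ cases, n₂ controls, both ≥ 2) each gene gets
a contrast β̂_g = mean_case − mean_control and a pooled within-group
variance s²_g on d_g = n₁ + n₂ − 2 df. The moderated statistic is

    s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g)
    t̃_g = β̂_g / (s̃_g · √(1/n₁ + 1/n₂))

with two-sided p-values from a Student t on d₀ + d_g df. The prior
(d₀, s₀²) is estimated by marginal moment matching on z_g = log s²_g:
under the scaled-inverse-chi-square hierarchy Var(z) =
trigamma(d_g/2) + trigamma(d₀/2), so d₀ = 2·trigamma⁻¹(Var(e) −
trigamma(d_g/2)) with e_g = z_g − digamma(d_g/2) + log(d_g/2), and
s₀² = exp(mean(e) + digamma(d₀/2) − log(d₀/2)). When the observed
spread of z does not exceed its sampling contribution, d₀ is capped at
10⁶ (complete shrinkage; with identical variances this is the correct
limit). The inverse trigamma is solved by Newton iteration with
asymptotic starts (1/√x for small targets, 1/x for large ones);
a bisection cross-check lives in the test suite.

A gene is called differentially methylated when p < α (default 0.05,
**raw** — deliberately uncorrected, matching the reference workflow;
Benjamini–Hochberg is available behind `fdr="bh"`). Direction is
*hyper* iff β̂_g > 0 (case-minus-control convention).

An optional precision-weighting stage transforms values as
log2(v·10⁶ + 0.5), fits a lowess curve of √(residual SD) against mean
log-intensity, and uses inverse predicted variances as observation
weights in the group fits. Weights are normalized to mean one per gene,
so rescaling all weights changes nothing. The stage was designed for
count data and is applied here to methylation values exactly as the
reference workflow does; it is **off** by default in library calls and
synthetic tests (the moderated t is defined independently of it) and
**on** in the pipeline configuration. With fewer than 10 genes the
trend is unreliable and unit weights are used with a warning.

## Module detection

On the DM genes: unsigned adjacency a_ij = |PCC_ij|^β (Pearson across
all samples; the unsigned form is the historical default of this
construction), topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with a_ii = 0 in the arithmetic and TOM_ii = 1, and average-linkage
agglomeration of 1 − TOM. The exponent β is the smallest candidate
(1–20) whose connectivity distribution fits a scale-free law with
R² ≥ 0.8.

The scale-free fit groups connectivities into 10 equal-occupancy bins
and regresses log₁₀(density) on log₁₀(median k) per bin. Two details
matter: with equal-occupancy bins the raw per-bin *frequency* is
constant by construction, so the density correction (count/width) is
what makes the fit informative; and the fit is *signed* — a positive
slope, or a degree range under half a decade, is reported as no fit
(R² = 0), since neither can evidence scale-free decay. When no
candidate reaches the target, the candidate maximizing R² is used
(with a warning) provided the profile is at all informative
(best R² ≥ 0.3); below that the degree distribution carries no
scale-free signal at any exponent — typical for small, strongly modular
gene sets whose degrees concentrate on a few values — and the
conventional unsigned-network default power 10 is used instead, again
with a warning. An argmax over a flat noise profile would otherwise
select an arbitrary, often tiny, exponent.

Modules are obtained by a simplified tree-style dynamic cut: a static
cut of the dendrogram at `cut_height` (default 0.99) times the maximum
merge height, followed by a minimum-size rule (default 10): branches
below the minimum are merged into the nearest branch by average
inter-branch dissimilarity when that distance is within the cut, and go
to *grey* (unassigned) otherwise. Surviving modules are relabeled by
decreasing size with the fixed palette (turquoise, blue, brown, yellow,
green, red, …) — a pure function of the size list. This is a
deliberate simplification of the full hybrid dynamic-cut algorithm:
module *counts* on real data are data-dependent and not promised.

## Signature selection

Each non-grey module with ≥ 2 genes is scored by the mean Pearson
correlation over all unordered gene pairs. The signature is the module
with the maximum score; scores are compared after rounding to the tie
tolerance (default 10⁻³, i.e. three printed decimals — exact float
comparison would never tie, while reported score tables do), ties are
broken toward the **smaller** module, and any remaining tie toward the
earlier palette position. Singleton modules have no defined score and
are excluded with a warning. Each signature gene carries its hyper/hypo
direction from the differential-methylation stage.

## Evaluation

Classification: stratified k-fold cross-validation (fresh seeded
shuffles per repeat, default 10 repeats) of a 500-tree Random Forest on
the signature genes, with out-of-fold predictions pooled within each
repeat for accuracy, precision, sensitivity, specificity and
class-probability AUC, then averaged over repeats. Stratification is
required rather than optional: with a handful of cases against many
controls, unstratified folds can lack a class entirely. All fold and
forest seeds derive from one master seed sequence, so a report is
exactly reproducible.

Cluster quality: Ball–Hall, Davies–Bouldin, Dunn, G+, the generalized
Dunn indices GDI11/GDI12/GDI31 (Bezdek–Pal δ/Δ numbering — the only
numbering under which GDI11 is the classic Dunn index, an identity the
implementation preserves exactly), and Ray–Turi, computed on the gene
vectors in sample space with Euclidean distances. Indices are reported
raw; no "higher is better" interpretation is encoded (for
Davies–Bouldin, Ball–Hall and Ray–Turi lower is conventionally better).
Degenerate geometry (coincident centroids) yields infinities rather
than errors so that the remaining indices stay available; a single
cluster is rejected. A seeded Lloyd k-means baseline with k equal to
the module count provides the comparison column.

## Synthetic data generator

The generator works at gene level and then expands to probes (default
3 probes per gene plus probe-level noise of SD 0.005, a small fraction
of `rs`/`ch.` decoy ids, all-zero and missing-value probes, and probes
annotated to two genes of the same block).

The gene-level geometry is built to reproduce what per-feature min–max
scaling does to real array data, where most gene vectors are highly
similar in shape:

* **Co-methylation blocks** (sizes 8–45, heavy-tailed ∝ 1/s²): genes in
  a block share a latent per-sample factor; each gene carries its own
  residual share u drawn uniformly from a narrow band
  (u = √(1−ρ) ∈ [0.025, 0.095]), so the sorted 4-NN distance curve has
  a dense, well-covered body. Block factors are built from 12 shared
  archetype sample-profiles; a chance group imbalance in an archetype
  produces correlated false-positive DM calls, as in real data.
* **Duplicate families** (25 % of genes, groups of 5): near-copies of
  one another with residual shares pulled toward zero by a power law —
  the analogue of annotation-overlap families (paralog clusters, genes
  sharing probe sets), which populate the low-distance end of the curve.
* **Stragglers** (1 %): weakly co-methylated singletons
  (u ∈ [0.12, 0.40]) occupying the thinning upper tail of the curve —
  the region where the knee rule places ε, and the features a
  density-based filter legitimately trims.
* **Planted modules** (defaults: sizes 15/20/30 with latent
  correlations 0.9991/0.9982/0.9970) are the tightest blocks and are
  nested inside the DM gene set, because module detection runs on DM
  genes only. Module factors are drawn orthogonal to all archetypes and
  to the group-contrast direction, so module membership is a signal of
  its own and cannot add to or cancel the planted disease effect. The
  tightest module is the smallest, so the score maximum and the
  smaller-module tie-break select the same module. `n_dm` defaults to
  the sum of module sizes; planting additional DM genes is supported
  (they come in small shifted blocks).
* **Planted differential methylation**: a symmetric ±effect_size/2
  group shift (default full effect 0.3 beta units against a total
  per-gene SD of 0.2 — a per-gene noncentrality of ≈ 3.4 at 10 vs 10,
  i.e. detectable but not trivial).
* **Outliers** (1 %, offset 6 SD): near-flat baselines with every
  sample displaced to an extreme with random sign — clipping pins them
  to the beta-value bounds, emulating bimodal artifact features (failed
  or SNP-affected probes), far both from the cloud and from each other.

Values are clipped Gaussians around 0.5 by default; a Beta-marginal
mode (`beta_mode="beta"`) pushes the same latent structure through a
rank-preserving Gaussian copula instead.

What the generator does **not** emulate: probe chemistry (type I/II
design biases), batch and cell-composition effects, genome positional
structure, realistic gene-symbol vocabularies, and the long-range
correlation between methylation level and variance of real beta values.
Passing tests therefore demonstrate that the pipeline's machinery
recovers the structure it targets under controlled conditions — not
that any particular biological dataset will yield a comparable
signature.

## Numerical conventions and degenerate inputs

* Missing tokens accepted on input: empty cell, `NA`, `N/A`, `null`,
  `NaN` (case variants); decimal separators are points only.
* Probe order is preserved from file; gene rows are emitted in sorted
  symbol order; no other implicit sorting.
* The knee window, the derivative threshold, ε, MinPts, α, the power
  candidates, fit target, minimum module size, cut height, tie
  tolerance, CV fold count and repeats are all exposed in `RunConfig`,
  with defaults equal to the reference settings.
* A single master seed fans out to the k-means baseline and the CV
  stage through a fixed `SeedSequence` derivation; reruns with the same
  config and inputs are byte-identical.
* Degenerate inputs fail loudly with typed errors (format, validation,
  configuration, parameter, no-knee) and pipeline failures carry the
  stage name.

## Known limitations

* The knee rule places ε at the first sparse region of the distance
  curve; on data without a dense near-duplicate continuum it can fire
  well inside the bulk (the reference workflow's own runs discard
  2–13 % of features this way). The windowed derivative mitigates but
  cannot remove this sensitivity; an explicit ε override is provided.
* The simplified dynamic cut can absorb satellite genes into modules
  when the soft-threshold exponent is small; module counts are
  data-dependent.
* Raw-p thresholding at α = 0.05 admits ~5 % of null genes by design;
  downstream stages (module detection, scoring) are expected to cope
  with such false positives, and the Benjamini–Hochberg option exists
  for stricter control.
* With very few samples the empirical correlations that drive module
  detection and signature scoring are themselves noisy; nothing in the
  pipeline corrects for that beyond the variance moderation of the
  test statistic.
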