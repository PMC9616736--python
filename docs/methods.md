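# Methods

`thirststate` re-implements, as an integrated and testable pipeline, the
bespoke computations used to characterize the thirst state of the
*Drosophila* brain: single-cell QC and doublet removal, marker-driven
cluster fusion, zero-inflation-aware differential expression, calcium
response classification, and astrocyte–synapse vicinity statistics.
Every stage can be exercised on synthetic data with planted ground
truth, so its statistical behaviour (exact rule recovery, type-I error,
power) is measurable without the original deposited datasets.

## Synthetic data model

**Counts.** Each gene's UMI counts follow a zero-inflated negative
binomial: with probability π the count is zero, otherwise it is
NB(μ, θ) (mean μ, dispersion θ; variance μ + μ²/θ). Baseline per-gene
means are log-uniform on [0.05, 2], θ = 2 and π = 0.1 by default —
values in the range typical of droplet-based fly-brain data, chosen so
that a 2,000-gene simulation yields 400–900 detected features and
~1,000 UMIs per cell, comfortably inside the QC window. Cell classes
(default: cholinergic, glutamatergic, GABAergic, glia, at fractions
0.30/0.25/0.20/0.25) express their marker gene (VAChT, VGlut, Gad1,
nrv2) at NB mean 50 with θ = 20 and no zero inflation; outside the
class the marker is exactly zero. Each class also carries a "program"
of 25 genes at 2^1.5-fold elevated mean, giving classes a
transcriptomic identity beyond the single marker (without it,
DE-count-based fusion would merge genuinely distinct classes — an
artifact of an over-simplified generator, not of the pipeline).
Doublets are sums of the raw counts of two randomly drawn singlets of
different classes — the standard additive assumption that underlies
co-expression doublet detection. Low-quality barcodes are planted by
binomial thinning (keep probability 0.02), which preserves the NB family
while dropping the feature count far below the minimum-features cutoff.
Condition effects multiply μ by 2^log2FC for listed genes in the second
condition.

What the generator does *not* emulate: ambient RNA contamination
(markers are exactly exclusive), library-size and batch structure, UMI
saturation, or correlated gene programs. Exact recovery of planted
doublets therefore demonstrates correctness of the decision rule, not
robustness to contamination; on real data the thresholds must be
re-estimated from each gene's bimodal non-zero distribution.

**Traces.** Fluorescence is Gaussian noise around F₀ = 100 a.u.
(sd 5% of F₀) at 5.92 Hz; activated/inhibited traces add a sustained
±0.25·F₀ step during the drug window (20 s baseline, 25 s drug, 30 s
post). Steps rather than kinetic transients: the classification rule
compares window means and is insensitive to response shape. Category
fractions default to 0.3/0.2/0.5.

**Anatomy.** The skeleton is a seeded branched random walk (500 nodes,
150 nm steps, 8% branch probability); 85% of nodes get "fine" radii
(40–280 nm), the rest "coarse" (350–900 nm) to stand in for somata and
main branches. Only node positions and radii matter downstream.
Synapses of each transmitter are placed at (offset + N(0, 300 nm))
along a random direction from a random fine node; because other nodes
may lie closer, the measured nearest-node distance is attenuated
relative to the planted offset — group *ordering* is preserved, which
is what the vicinity tests assert. Quality scores are uniform above
(or, for a planted failing fraction, below) the CleftScore ≥ 50 /
ConnectionScore ≥ 33 cutoffs; a configurable fraction of synapses list
the astrocyte as a postsynaptic partner (planted tripartite synapses).

All three generators are pure functions of the config, each drawing
from an independent child of the seed, so identical configs produce
byte-identical outputs and changing one spec never perturbs another
stage's data.

## QC and doublet detection

Barcodes are kept iff 300 ≤ features ≤ 4,500, UMIs ≤ 20,000, and
mitochondrial / rRNA / ribosomal-protein fractions ≤ 0.15 / 0.10 /
0.15. Boundary values are kept — the discard conditions are strict
inequalities. Gene families are identified by configurable name
prefixes (defaults `mt:`, `lncRNA:rRNA`, `RpL`/`RpS`).

Per-gene expression thresholds are the local density minimum between
the two highest modes of a Gaussian KDE (Scott's rule, configurable
bandwidth) over the gene's non-zero normalized values; a sample whose
KDE has fewer than two maxima is reported "unimodal" with no
threshold. The estimator needs ≥ 50 non-zero values by default. A cell
is a class doublet when ≥ 2 of {nrv2, VAChT, VGlut, Gad1} strictly
exceed their thresholds (defaults 3 / 1.5 / 2.1 / 2.3 — reference
values from the original data; re-estimate on new data), and a
Kenyon-cell doublet when > 1 of the subtype markers {Ca-alpha1T, ab,
CG8641} (1.5 / 1.5 / 2.2) fire within KC-designated cells. Final calls
are the union with any external (e.g. score-based) doublet list. The
normalized layer the thresholds refer to is whatever layer the caller
passes; `lognormalize` (log1p counts-per-10k) and `zscale` are provided.

## Cluster fusion

Cluster centroids in embedding (PC) space are arranged by
average-linkage hierarchical clustering. For each sibling leaf pair
(most similar, i.e. smallest merge height, first), every protein-coding
gene detected in ≥ 1 cell of the pair is tested with the two-sample
Wilcoxon rank-sum test on the normalized layer and BH-adjusted within
the tested set; if fewer than 10 genes reach adjusted p < 0.05 the pair
is fused, the tree is rebuilt, and the procedure repeats until no pair
fuses. Cluster count is monotone non-increasing and the loop terminates
in at most (initial clusters − 1) rounds. Pairs with a cluster below
`min_cells_per_cluster` (default 3) are skipped and logged. A paired
signed-rank test is not applicable to unmatched cluster comparisons,
hence the rank-sum test.

## Zero-inflation-weighted differential expression

Each gene is fitted per cluster with an independent ZINB by EM: the
E-step assigns each zero a posterior source; the M-step updates π in
closed form, μ as the weighted sample mean (the weighted NB ML mean is
the weighted mean regardless of θ), and θ by profile maximization —
a global bounded search on the first iteration, then damped Newton
steps in log θ with backtracking, so the likelihood is monotone
non-decreasing (asserted). Iteration stops at |Δloglik| < 1e-6 or 200
iterations. When π falls below 1e-5 the fit finishes at the boundary
with a plain NB ML fit; a fit that reaches the iteration cap with a
plateaued likelihood (|Δloglik| < 1e-3, the slow geometric creep of π
toward zero) is still flagged converged, since the remaining likelihood
gain is negligible. All-zero genes are flagged degenerate and never
tested.

Observational weights are 1 for non-zero counts and
w₀ = (1−π)·f_NB(0) / (π + (1−π)·f_NB(0)) with f_NB(0) = (θ/(θ+μ))^θ
for zeros — the posterior probability that the zero is biological
rather than technical. The two-condition test maximizes the weighted NB
log-likelihood with log-library-size offsets under a common-mean null
and a per-group-mean alternative (dispersion profiled within each
model, so the effective sample size entering the dispersion estimate is
the sum of the weights); 2ΔlogLik is referred to χ²(1). With unit
weights this is exactly the ordinary NB likelihood-ratio test (verified
against an independent ML implementation). BH adjustment is applied
within each cluster's tested gene set; a DE event is a (gene, cluster)
pair with |log2FC| > 1 and adjusted p < 0.05, and a gene DE in either
of two supplied result sets counts once.

This is a deliberate reduction of the full ZINB-WaVE factor model to
independent per-gene fits: the weights serve only to downweight excess
zeros, and the simplified posterior has the same contract while being
testable in closed form. Measured on the synthetic conditions (1,000
null ZINB genes, μ=5, θ=2, π=0.3, n=100/arm) the test's type-I error
is ~0.04 at α=0.05 and power at planted log2FC = 2 (μ=10) is ~1.0 with
median estimated log2FC within 0.03 of truth — recomputed on every run
of `scripts/acceptance.py`.

## Calcium traces

F₀ is the mean fluorescence over the 14 s before drug onset
(round(14 × 5.92) = 83 frames); ΔF/F₀ = (F − F₀)/F₀. Second-based
windows are converted to frames by rounding to the nearest frame
(unbiased versus floor/ceil). The response category compares the mean
ΔF/F₀ over the 25 s from onset (148 frames) against the pre-window
mean ± its sample (n−1) standard deviation, with the pre-window mean
normalized to 0 per cell: activated above +σ_pre, inhibited below
−σ_pre, otherwise no change; a zero-variance tie is "no change". The
rule uses raw (unsmoothed) ΔF/F₀ frames. AUC is the trapezoidal
integral at 1/5.92 s spacing with both boundary frames included, so
adjacent windows add exactly; an option shifts the series to 0 at drug
onset.

Paired drug responses are summarized on the activated/inhibited 2×2
(cells with a no-change call under either drug are excluded from the
default "matched versus mismatched" table; a 3×3 agreement mode with a
chi-square test is available). The odds ratio is ad/bc (Haldane 0.5
correction, flagged, when a cross product is zero) and the two-sided
p-value is the exact Fisher/hypergeometric probability. Shifts in
response proportions across satiety states use pairwise Fisher exact
tests collapsed to responsive-vs-not, Bonferroni-corrected by the
number of comparisons and capped at 1.

## Synapse vicinity

Synapses pass quality control at CleftScore ≥ 50 and ConnectionScore ≥
33 (inclusive); records with missing scores are rejected with a
warning. Fine astrocytic processes are skeleton nodes with radius
strictly < 300 nm. Candidate synapses lie inside the union of
axis-aligned boxes of half-width 2 μm centered on fine nodes
(equivalently, Chebyshev distance to the nearest fine node ≤ 2 μm); a
spherical 2 μm mode is provided since figure legends describe a radius
while the procedure text describes a box — the box is the default, and
outputs record the mode. Each candidate's distance is the exact
Euclidean distance to the nearest fine node, computed with a KD-tree
and verified identical to exhaustive search. Distances are node-center
to synapse-point; node radius is not subtracted. Per-transmitter
distance distributions get Gaussian KDEs (Scott's rule).

Significance uses a bootstrap of means: each group is resampled with
replacement 10,000 times at its own size. A literal two-sample t-test
*between* the two 10,000-point bootstrap-mean distributions is
degenerate — its statistic grows like √n_boot, so it rejects almost
surely even when the groups are identical. The primary p-value is
therefore a Welch-style statistic whose numerator is the difference of
the bootstrap-mean centers and whose standard error is the combined
spread of the two bootstrap-mean distributions (each spread is a
bootstrap estimate of the standard error of its group mean), with
Welch–Satterthwaite degrees of freedom from the original group sizes.
This keeps the bootstrap-of-means construction while remaining
calibrated: under equal planted offsets the measured rejection rate is
~5% at α = 0.05, and a planted 100 nm offset (n=500/group, sd 300 nm)
is detected in ≥ 95% of seeds. A plain Welch t-test on the raw
distances is always reported alongside. Degenerate (constant) groups
receive a tiny variance floor so the statistic stays defined.

A tripartite synapse is any synapse listing an astrocyte among its
postsynaptic partners — a deterministic function of the partner lists.
Transmitter ratios report each transmitter's share among TPS synapses
and among all vicinity synapses, plus their ratio (enrichment);
bootstrap resamples pool all astrocytes rather than stratifying.

## Behavioral indices

Preference index: (n_wet − n_dry)/(n_wet + n_dry) ∈ [−1, 1],
antisymmetric under swapping arms; undefined (error) for zero total.
CAFE consumption: sum of capillary volumes minus the mean evaporation
of empty control vials, floored at 0. Per-fly normalization divides by
survivors at the end of the assay (simplest consistent reading of
death re-adjustment); a mean-of-start-and-end mode is provided.

## Pipeline and reproducibility

A YAML config drives the stages simulate → qc → fuse → de and simulate
→ calcium / vicinity. The global seed fans out through SHA-256 into one
sub-seed per stage (all < 2³¹), so stages re-run independently and
byte-identically; the manifest records the config hash, per-stage
output files, and record counts. Schema violations and unknown stages
fail before any stage runs (CLI exit code 2; data errors exit 3).

## Problem sizes

Tests and the acceptance script use: 1,000-cell / 2,000-gene QC
simulations; 2,000-point mixtures over 20 seeds for thresholding;
300-cell / 1,500-gene cluster pairs over 20 seeds; n=2,000 ZINB fits
over 20 seeds; 1,000 null and 200 powered genes at n=100/arm; 400
traces; 50×200 node–synapse brute-force checks; 20 power and 200 null
seeds for the bootstrap comparison. These sizes give Monte-Carlo errors
small enough to resolve the tested properties while keeping a full run
in tens of seconds.

## Known limitations

Independent per-gene ZINB ignores cross-gene and cell-level structure
that the full factor model captures; the χ²(1) reference is asymptotic
(mildly conservative at n=200 in the measured conditions); the
generator's clean marker exclusivity makes doublet detection easier
than on contaminated real data; skeleton geometry is a random walk, so
absolute vicinity distances are not biologically calibrated; upstream
steps (normalization variants, integration, graph clustering, UMAP,
external doublet scorers, transmitter prediction) are out of scope and
assumed done.
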