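# Methods

## Scope and model

The package reconstructs, at desk scale, the transcriptome-network workflow
used to characterize human macrophage activation as a *spectrum* of
programs rather than a bipolar M1/M2 axis. The workflow's stages — sample
coregulation networks, condition correlation clustering with 3-D spectrum
vectors, SOM-based marker discovery, weighted coexpression modules with
eigengene–trait correlation, modules-as-gene-sets GSEA, and
mutual-information reverse network engineering — operate on a gene × sample
matrix of log2 intensities with a sample annotation table (condition, time,
donor, baseline flag). The original study analyzed hundreds of arrays over
~29 stimulation conditions; that dataset is not redistributable here, so
every stage is exercised and validated on synthetic data with planted
ground truth.

## Synthetic data generator

The generator emulates the statistical features the analyses rely on:

* **Per-gene baseline offsets** `offset[g] ~ N(0, gene_sd²)`, shared across
  samples. Real transcriptomes have large between-gene variation relative
  to between-sample variation, which is why any two arrays correlate at
  r ≈ 0.9 and why sample–sample Pearson graphs are meaningful at all.
  Default `gene_sd = 1.0` log2 units.
* **Planted modules**: a gene set shares the latent factor
  `effect · 1[condition ∈ drivers]` with per-gene loading 1 plus independent
  `N(0, noise_sd²)` noise. The within-module gene–gene correlation then has
  the closed form `e²·var(ind) / (e²·var(ind) + σ²)`, used as a test
  oracle. Defaults `effect = 2`, `noise_sd = 0.5` log2 units (effect/noise
  = 4, the regime in which membership is recoverable by correlation
  thresholding); modules of 25–50 genes.
* **Exclusive markers**: one gene elevated by `effect` in exactly one
  condition — the single-stimulus marker situation. Negative effects encode
  repression, which the spectrum fixture uses to build a genuinely
  antagonistic (induced vs repressed) program pair on one gene set.
* **Hub-structured dependency graphs** for reverse engineering: a designated
  hub fraction (default 0.1), every other gene attached to one hub
  (balanced round-robin after a seeded shuffle), hubs chained; edge weights
  (default U(0.9, 1.0)) populate a precision matrix whose diagonal is
  inflated to 1.05× strict dominance, guaranteeing a valid covariance. Data
  are drawn from the implied correlation matrix, and the implied marginal
  correlation of every true edge is returned for oracle tests. Under the
  dominance constraint a hub's diagonal grows with its degree, so edge
  weights near 1.0 are needed for edge correlations in the 0.4–0.7 range;
  weaker weights give edges indistinguishable from noise at desk-scale
  sample counts.
* **Replicate counts** are not prescribed by the source workflow; the
  bundled study uses 6 conditions × 10 replicates (60 arrays, 200 genes),
  large enough for phenotype-permutation GSEA and module detection, small
  enough for second-scale runtimes.

What the generator does **not** emulate: probe-level bead chemistry,
platform batches, donor covariance structure, heavy-tailed (non-Gaussian)
noise, or correlated background genes. Passing tests therefore demonstrate
algorithmic correctness and recoverability under the stated generative
model, not robustness to real-array artifacts.

## Stage-by-stage notes

**Quantile normalization** maps every column onto the mean-of-sorted
reference. Ties are resolved by ordinal (column-position) rank rather than
averaged ranks; this keeps "all sorted columns identical" exact and makes
the operation idempotent to machine precision.

**Detection filter**: the bead-level background of the original platform is
unavailable, so background is the empirical `background_quantile` (default
0.25) of all intensities, and a gene is expressed in a condition when its
condition mean clears background + `min_margin` (default 0.5 log2). The
expressed set is the union over conditions.

**Differential screens** use Welch two-sample t-tests (pairwise) and the
classic equal-variance one-way F-test (across conditions) — deterministic,
vectorized, with constant genes reported at p = 1 and flagged rather than
NaN. Fold change is always `2^(Δ mean log2)`. BH correction is verified
against a brute-force implementation in the tests.

**Sample network (CRA)**: Pearson graph over a chosen gene set with a
configurable threshold (default 0.85; the source workflow does not print
its cutoff). Markov clustering is implemented directly (expansion by matrix
squaring, entrywise inflation, column renormalization, 1e-8 convergence,
200-iteration cap); no MCL package is available in the stack, and the
implementation is cross-checked against an independent straightforward MCL
in the tests. The 3-D layout is a hand-rolled Fruchterman–Reingold with
attraction weighted by edge correlation and a linear cooling schedule.
Library layouts rescale coordinates to a fixed bounding box, which would
destroy both the two-body equilibrium contract (a lone edge settles near
the natural spring length k = 1/√n) and the metric meaning of spectrum
vectors; coordinates here are only centered, never rescaled.

**Condition space**: condition profiles are means over replicates (the
condition-level correlation matrix is displayed at condition blocks);
hierarchical clustering uses average linkage on 1 − r and a count-based cut
(default k = 10 at full scale, clamped to the number of conditions). The
display z-matrix clips at ±2.78 by convention and is never used in
computation. Spectrum vectors subtract the baseline-sample centroid, so a
rigid translation of the layout cancels exactly; the baseline cluster is
the zero vector.

**SOM**: batch training on gene-standardized condition profiles,
PCA-plane initialization (deterministic), Gaussian neighborhood shrinking
linearly from max(w, h)/2 to 0.5, followed by one fine-tuning pass in the
σ → 0 limit (each occupied unit becomes the centroid of its assigned
genes — the k-means step standard in batch SOM practice; without it small
maps retain a visible blend between archetypes). Defaults 10×10, 50
epochs. Marker calling is margin-based — target-condition mean must exceed
every other condition's mean by `margin_min` (default 1 log2) — which makes
marker tables anti-symmetric across conditions by construction; SOM
portraits serve visualization.

**Coexpression modules**: unsigned adjacency |r|^β. The pipeline default is
the conventional unsigned power β = 6; automatic selection by scale-free
fit is available, with the caveat that planted-block covariances are not
scale-free at any power — raising β indefinitely always "improves" the
log-log fit by emptying the network, so the fallback is constrained to
powers keeping mean connectivity ≥ 1. TOM is computed exactly per its
formula (brute-force-verified). Module detection is a static cut (default
height 0.95) of average-linkage trees on 1 − TOM with branches under
`min_size` sent to the unassigned pool, followed by iterative merging of
eigengene pairs correlated above `merge_r` (default 0.8) — a deterministic
stand-in for dynamic tree cutting. Eigengene sign aligns with the module's
mean standardized profile; exact antagonism ties break toward the first
gene. Trait correlation is eigengene vs one-hot condition indicators with
Student-t p-values and BH across the full module × condition grid.

**GSEA**: default ranking metric signal-to-noise with the conventional
0.2·|μ| standard-deviation floor; default weight p = 1. Phenotype
permutation is the default for ≥ 7 samples; below that, a sampled phenotype
null would be too coarse and the engine falls back to gene-set permutation
— unless the requested permutation count covers all distinct label
assignments, in which case the null is enumerated exhaustively and the
nominal p is the exact same-sign tail fraction. In sampled mode the add-one
convention p = (1+k)/(1+m) is used (the unbiased permutation p; the bare
fraction is measurably anticonservative in null calibration). FDR q for
NES follows the original normalized-tail convention, not BH; BH appears
only in ORA. ORA is a plain hypergeometric upper-tail test against a
user-supplied term → gene map — the generic stand-in for GO enrichment,
with no DAG propagation.

**MI network**: the default estimator is the Gaussian copula
(normal-score rank transform, MI = −½ ln(1 − ρ²)) — rank-invariant, fast,
and with a clean closed-form oracle; an equal-frequency binned plug-in
estimator with Miller–Madow bias correction (cube-root bin rule) is
available as a cross-check. The significance cutoff comes from a permuted
null; because the corrected level α/C(n, 2) is far below 1/n_null, the null
tail above its 99th percentile is fit with an exponential and extrapolated,
with fit diagnostics recorded. The full-scale analysis level is a
Bonferroni-corrected 1e-7; at desk scale (tens of samples) that level
corresponds to |ρ| ≈ 0.9 and nothing can pass, so the pipeline default for
the bundled fixture is a Bonferroni-corrected 0.05 (the 50-gene × 1000
sample network analyses keep 1e-7). DPI removes the weakest edge of every
fully connected triplet when it falls below (1 − tolerance)·min(other
two); removals are computed on the input network and applied
simultaneously; default tolerance 0.1. Hubs are the top `fraction`
(default 0.1) of nodes with at least one edge, ranked by degree with a
lexicographic tie-break; average degree is reported over both connected
nodes and all nodes, since the two denominators differ at desk scale.

## Determinism and provenance

Every source of randomness is an explicit seed argument; no stage reads
global random state. The pipeline manifest snapshots the effective
configuration and SHA-256 checksums of all text artifacts (TSV / JSON /
GMT / GraphML); PNG plots are listed by name but not checksummed, so
determinism claims never depend on image-encoder byte stability. TSV floats
are written with a fixed format, making identical runs byte-identical.

## Problem sizes

The validation suite uses: 20 seeds × (350 genes × 60 samples) for module
recovery; 50 genes × 1000 samples for network reverse engineering; 5000
observations × 20 seeds for the MI closed-form check; 200 pure-noise
datasets × 5 gene sets × 400 permutations (plus 2000 ANOVA genes) for null
calibration; exhaustive 20-assignment 3v3 designs for GSEA exactness; and
the 200 × 60 bundled study end-to-end. These sizes keep the whole suite in
the minutes range on a single CPU while leaving each check statistically
meaningful.

## Known limitations

* Static tree cut + eigengene merging approximates, but is not, Dynamic
  Tree Cut; at full scale module boundaries will differ in detail.
* The copula MI estimator saturates on exactly duplicated profiles
  (finite value set by the clipping of ρ) and measures only monotone-
  expressible dependence; the binned estimator is the fallback for
  non-monotone structure.
* The exponential tail extrapolation of the MI null assumes an
  exponentially decaying tail beyond the 99th percentile; the recorded fit
  diagnostics should be inspected on real data.
* Phenotype-permutation GSEA treats samples as exchangeable under the
  null; donor pairing is not modeled.
* No cross-platform harmonization, probe collapsing, or batch correction:
  inputs are assumed to be one platform, gene-level, batch-free.
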