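# Methods

`chromonet` quantifies a structural contrast between the transcriptional
co-expression networks of two phenotypes — typically tumour vs. adjacent
normal tissue: in the healthy network, strong statistical dependencies
connect genes across chromosomes genome-wide, while in the tumour network
they collapse into small, dense clusters of neighbouring genes on a single
chromosome, each cluster coherently over- or under-expressed. This note
documents the models, the estimators, the numerical conventions and the
limits of what the synthetic benchmark shows.

## The synthetic data model

Real inputs at the intended scale (hundreds of RNA-seq samples, ~15k genes)
are not shipped; a generator produces count matrices with the statistical
structure the analysis assumes, plus ground truth for recovery tests.

Per gene g and sample j, log2 expression is a Gaussian copula layer

    L_gj = mu_g + sigma_b * z_gj (+ s_b(g) * delta   in tumour samples)

with per-gene baseline `mu_g ~ N(base_log2_mean, base_log2_sd^2)`
(defaults 7.0, 1.5) and biological scale `sigma_b = 1.0` log2 units. The
latent variable z carries the condition-specific dependence:

* **healthy regime** — `z = rho_inter * F_k(g) + sqrt(1 - rho_inter^2) * eps`,
  where each gene loads on one of `n_inter_factors = 5` genome-wide factors.
  Genes sharing a factor sit on arbitrary chromosomes, which induces
  inter-chromosomal correlation (`rho_inter = 0.6` by default; pairwise
  latent correlation `rho_inter^2 = 0.36`).
* **tumour regime** — `z = rho_intra * G_b(g) + sqrt(1 - rho_intra^2) * eps`,
  one factor per *block*: `block_size = 20` coordinate-contiguous genes on
  one chromosome (`rho_intra = 0.9`, within-block correlation 0.81). Every
  block additionally receives a coherent mean shift `±de_shift` (default
  1.0 log2, sign drawn per block), emulating clusters of neighbouring genes
  that are jointly over- or under-expressed.

Counts are negative-binomial (gamma–Poisson, dispersion 0.1) around
`depth_j * bias_g * 2^L_gj`, with per-sample depth uniform on [0.6, 1.6]
and a multiplicative gene bias `2^(gc_bias*(gc-0.5)) * (len/10kb)^length_bias`
(defaults 2.0 and 0.3) so that the normalization stages face realistic %GC,
length and depth artifacts. The Gaussian layer gives closed-form mutual
information `-0.5 ln(1 - rho^2)` for oracle tests.

No quantitative effect sizes exist for the two regimes in real tissue;
the loadings above are chosen once as plausible and are not calibrated to
any cohort. Default problem sizes for the end-to-end benchmark are 600
genes on 6 chromosomes with 100 samples per condition and a kept edge
fraction of 0.005 — large enough that the kept networks contain hundreds
of edges and tens of components, small enough that a 20-seed replication
finishes in about a minute. The generator does **not** emulate: tumour
heterogeneity/subtypes, copy-number-driven expression, compositional mRNA
effects, outlier samples, or correlated %GC–length structure. Passing the
synthetic benchmark therefore shows the machinery recovers the regimes it
models, not that any particular tissue behaves this way.

Annotation defects (missing symbols, mitochondrial/scaffold chromosome
labels, conflicting duplicate identifiers) are injected only when
`defect_fraction > 0`, with a log of affected identifiers, so integration
filters can be tested against generator bookkeeping.

## Preprocessing

* **Integration** — drop records with missing identifiers/symbols or
  non-conventional chromosomes (outside 1..22, X, Y); join on the primary
  identifier; where duplicate candidates agree in both symbol namespaces the
  lowest-%GC record wins, otherwise the identifier is dropped with a warning
  count. Count values are never altered, only row-subset.
* **Mean-count filter** — keep genes with mean raw count ≥ 10 (strictly-
  below-10 removed).
* **Within-sample full-quantile normalization** — genes are split into 10
  equal-size covariate strata; per sample, each stratum's counts are
  quantile-mapped onto the median-across-strata quantile function (grid of
  the largest stratum size, linear interpolation). Applied sequentially for
  %GC and then gene length. The map is monotone within a stratum; with one
  stratum it is the identity. The bin count (10) follows the common
  convention for covariate full-quantile normalization.
* **TMM** — reference sample: upper-quartile closest to the mean upper
  quartile. Per sample, genes with zero counts in either sample are dropped;
  M = log2 ratio and A = mean log2 abundance are computed on raw counts, the
  top/bottom 30% of M and 5% of A are trimmed, and the factor is
  2^(weighted mean M) with delta-method inverse-variance weights
  1/((N_s-y_s)/(N_s y_s) + (N_r-y_r)/(N_r y_r)); factors are rescaled to
  geometric mean 1. Because M is taken on raw counts, the factor absorbs
  sequencing depth (a sample with every count doubled gets factor 2 relative
  to the reference); normalized values are counts divided by the factor.
* **CPM filter** — after between-sample scaling, keep genes with mean
  CPM ≥ 10. (Whether the historical filter was per-mean or per-all-samples
  is ambiguous; the mean convention matches the companion mean-count filter.)
* **log2** — log2(x + 1).
* **ANOVA + PCA denoising** — X is split into the condition-mean matrix M
  plus residual R; each part is PCA-reconstructed (gene-centered SVD) from
  the leading components reaching 75% cumulative variance, keeping at least
  one; the output is X − (M − M_signal) − R_signal, i.e. the design part's
  reconstruction error and the structured (non-design) residual are removed.

**Where the denoised layer is used.** The denoised matrix feeds the
differential-expression stage only. Co-expression networks are inferred from
the normalized log2 layer: within-condition covariance *is* the quantity MI
estimation measures, and subtracting the residual's leading principal
components would subtract the co-expression signal itself (verified on the
generator: wiring the denoised layer into network inference erases the
healthy/tumour contrast entirely). The denoising step is design-aware and
appropriate for a test of condition means; it is not an appropriate input
for dependence estimation.

## Differential expression

Per gene, the two-group linear model `y_ij = mu + alpha_i + eps_j` is fitted
by OLS; log2FC is the tumour-minus-normal difference of condition means and
s² the pooled residual mean square (n − 2 df). Variances are moderated by
the standard moment-matching empirical-Bayes scheme: with
`e_g = log s²_g − digamma(d/2) + log(d/2)`, the prior degrees of freedom
solve `trigamma(d0/2) = var(e) − trigamma(d/2)` (Newton inversion of the
trigamma; infinite d0 when the excess is non-positive) and
`s0² = exp(mean(e) + digamma(d0/2) − log(d0/2))`. The posterior variance is
`(d0 s0² + d s²)/(d0 + d)` and the moderated t has d0 + d df. P-values are
BH-adjusted (capped cumulative-minimum implementation; ties share their rank
position's value). DEGs require FDR < 1e-5 and |log2FC| > 1; the expected
chance count `n_tested × 1e-5` is reported alongside. Note that under the
generator's defaults a true shift of exactly 1.0 leaves roughly half the
shifted genes below the |log2FC| > 1 cut — sign recovery, not recall, is
the calibrated property.

Null calibration (type-I error 0.05 ± 0.01, uniform p) holds on
depth-normalized data; on raw counts an unbalanced draw of library sizes
shifts every gene's fold change coherently, which is a property of
unnormalized data rather than of the test.

## Mutual-information networks

The binning estimator rank-transforms each gene, folds ranks into
`B = max(2, floor(n^0.4))` equal-frequency bins, and computes plug-in MI
with the Miller–Madow correction, centered at the estimator's
permutation-null mean and clipped at zero. Two numerical choices deserve
note:

* **Bin count.** With a square-root rule the B×B joint table is too sparse
  for the Miller–Madow term to remove the finite-sample bias (measured
  ≈ +0.25 nats at independence, n = 2000); `n^0.4` keeps the table
  populated. The residual cost is a small negative discretization bias at
  strong dependence (≈ −0.035 nats at rho = 0.9, n = 2000) — inside the
  ±0.05-nat accuracy the benchmark demands, and irrelevant for rank-based
  thresholding.
* **Null centering.** For tie-free rank codes the permutation-null mean of
  the estimate depends only on (n, B); it is simulated once per matrix
  (32 permuted pairs) and subtracted, making the estimator unbiased at
  independence by construction. Clipping at zero preserves MI ≥ 0.

Ties in the expression values are broken by a canonical sample order (sorted
sample labels), so the estimate is invariant to column permutations.
The pairwise loop is chunked; results are independent of the chunk size.
The Gaussian-copula estimator (`-0.5 ln(1 - rho²)` on rank-normal scores) is
exact under monotone-transformed Gaussian dependence and serves as a fast
oracle mode. MI is in nats internally and converted to bits on export.

DPI pruning (off by default, since thresholding by top fraction is the
primary selection rule) removes, in every triangle, the strictly weakest
edge when it falls below (1 − epsilon) times the smaller of the other two;
all removals are evaluated on the input matrix and applied at once, and ties
survive.

Thresholding ranks all C(G,2) pair values and keeps the top
`ceil(f × C(G,2))` as edges — the ceiling convention is the only one
consistent with keeping 11,675 of C(15281,2) pairs at f = 1e-4 and 1,168 at
f = 1e-5. Boundary ties break lexicographically by gene pair. Each
condition's network uses its own ranking and records its own MI cut-off.
Which cut-off is higher depends on the effect sizes: under the defaults the
tumour blocks are more strongly co-expressed than the healthy factors, so
the tumour cut-off is higher; when the healthy coupling dominates
(`rho_inter² > rho_intra²` at comparable multiplicity) the ordering
reverses.

## Chromosomal topology

Edges are intra-chromosomal iff both genes share a chromosome label;
intra-edge genomic distance is the absolute difference of interval midpoints
(1-based inclusive coordinates; X/Y included; no strand handling). Network
summaries follow these conventions for disconnected graphs: the diameter is
that of the largest component; the average shortest path is averaged over
connected pairs only; the mean local clustering counts degree-<2 nodes as 0.
Components are profiled (size, internal edges, density = edges/C(size,2),
dominant chromosome, chromosome homogeneity = max per-chromosome member
share, DE-sign homogeneity = larger of the shares with log2FC above/below
zero, TF flag) and ranked by density, ties by size then smallest member.
Subsample robustness redraws sample subsets without replacement and reruns
estimation → thresholding → classification per subset. Concordance with an
external contact-frequency table matches each edge to its chromosome pair's
nearest bin (minimal summed midpoint distance), flags uncovered edges, and
reports the Spearman correlation over covered edges (flagged undefined when
either side is constant).

## Orchestration and determinism

One `PipelineConfig` (JSON/YAML, lossless round-trip) drives
simulate/load → integrate → mean-count filter → full-quantile (%GC, length)
→ TMM → CPM filter → log2 → denoise → DE → per-condition network → topology
→ report. A single seed governs all stochastic stages, stream-split per
stage; identical configs give byte-identical artifacts. Artifacts are TSV
(JSON manifest/report; optional HDF5 for the dense MI matrix), so every
stage can be rerun from its predecessor's files. Stage failures abort with
a stage-tagged error and earlier outputs are kept.

## Known limitations

* Exact equality with the historical normalization runs (EDASeq/ARSyN
  option details) is not claimed; only the stated conventions are.
* The binning MI estimator retains a small negative bias at very strong
  dependence; absolute MI values are estimator-dependent, rankings are the
  robust output.
* Component homogeneity on synthetic tumour networks is slightly below 1
  because occasional spurious inter-chromosomal edges merge blocks.
* The contact-concordance stage consumes pre-computed frequencies; no
  contact-matrix normalization is performed.
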