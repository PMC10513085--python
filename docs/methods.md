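# Methods

This note documents the statistical model behind `cortnet`, the estimator
choices that are not forced by the model, the synthetic-cohort generator's
assumptions, and known limitations.

## Likelihood-ratio tests with a genotype instrument

All tests condition on a categorical genotype E with k observed dosage
categories (k counts observed categories only; categories observed once are
retained, never merged) and operate on supernormalized expression: ranks
(midranks for ties) mapped through the standard-normal quantile function at
(rank − 0.5)/n, centred, and rescaled to unit population variance.  The
transform is idempotent and invariant under monotone maps of the raw data,
so the tests depend on expression only through ranks.

With Gaussian maximum likelihood, every model comparison reduces to a ratio
of residual variances, giving LLR = (n/2)·ln(v_null / v_alt).  For the five
tests of a triple (E, A, B), where A is the candidate regulator with cis
instrument E and B a candidate target:

| test         | alternative            | null                    | v_null / v_alt |
|--------------|------------------------|-------------------------|----------------|
| primary      | E→A                    | E ⊥ A                   | var(A) / within-group var(A) |
| secondary    | E→B                    | E ⊥ B                   | var(B) / within-group var(B) |
| independence | B depends on E given A | B ⊥ E \| A              | resid(B ~ A) / resid(B ~ A + E) |
| relevance    | B depends on (E, A)    | B ⊥ (E, A)              | var(B) / resid(B ~ A + E) |
| controlled   | B depends on A given E | B ⊥ A \| E              | within-group var(B) / resid(B ~ A + E) |

"Within-group" means residuals about group-size-weighted genotype-group
means — the maximum-likelihood estimates.  R² = SS_between/SS_total uses the
weighted between-group sum of squares Σ n_g (ȳ_g − ȳ)²; this weighting is
what makes the analytic null below exact, and R² is defined as 0 when
SS_total vanishes.

**Analytic nulls.**  Writing each LLR as −(n/2)·ln(1 − ρ²) for the
corresponding (partial) coefficient of determination ρ², standard Gaussian
regression theory gives ρ² ~ Beta(d/2, (n − q − d)/2) under the null, where
d regressors are added to a null model with q fitted mean parameters.
Hence the shapes are ((k−1)/2, (n−k)/2) for the primary/secondary tests,
((k−1)/2, (n−k−1)/2) for independence, (k/2, (n−k−1)/2) for relevance and
(1/2, (n−k−1)/2) for controlled.  P-values are upper tails of these Betas.
Supernormalized data are normal scores rather than i.i.d. Gaussians, so the
null is exact under permutation only asymptotically; at n = 200 the
agreement with 10⁴-permutation p-values is within Monte-Carlo error (tested)
and 1,000 null pairs pass Kolmogorov–Smirnov uniformity comfortably.

## Posterior conversion (empirical local FDR)

For one instrument tested against all genes of a tissue (the pooling unit
throughout; at least 100 statistics are required), the LLR ensemble is a
mixture of null and alternative tests.  The posterior probability of the
alternative is 1 − lfdr with lfdr = π₀ f₀ / f:

* π₀ — Storey estimator at λ = 0.5 on the analytic p-values, with a +1
  numerator guard against zero counts;
* the ratio f₀/f — evaluated per histogram bin (Doane-rule bin count on the
  LLR axis) as expected-null-count / observed-count, where the expected
  count integrates the analytic null over the bin.  Evaluating the null
  pointwise against a piecewise-constant density estimate leaks the steep
  within-bin variation of f₀ into the ratio and produces a few percent of
  spurious posterior mass on pure-null ensembles; the bin-integrated form
  cancels it;
* shrinkage — the observed excess over the null expectation is reduced by
  one Poisson standard deviation of that expectation before division.  This
  suppresses sparse-bin noise under the null while leaving far-tail bins,
  where the null expectation vanishes, untouched;
* monotonicity — posteriors are clamped to [0,1] and isotonically
  regressed to be nondecreasing in the LLR (monotone likelihood ratio).

The resulting estimator is slightly conservative: on pure-null ensembles the
mean posterior stays near 1%, and on mixtures the implied global FDR
(1 − mean posterior of a selection) bounds the realized false-discovery
proportion from above.  For the independence test the posterior of interest
is that of the *null* (B ⊥ E | A), reported as 1 minus the alternative's
posterior.

**Composite causal score.**  P(A→B) = ½(P₂·P₅ + P₄), the recommended
combination of the underlying causal-inference framework: the product
P₂·P₅ demands both a SNP→target association and a target–regulator
dependence given the SNP, and P₄ admits targets tied to the instrumented
regulator more loosely, guarding against over-conservatism of the pure
product.  The conservative alternative P₂·P₃ is available via
`combine="conservative"`.

## Selection at global FDR

A selection is the largest posterior-descending prefix whose Bayesian
global FDR, 1 − mean(posterior), stays at or below the nominal threshold;
posterior ties break lexicographically for determinism.  Two properties
matter in practice:

* the trans-eQTL scan selects per tissue at 15% (trans effects are weak,
  and the subsequent biological filter tightens the list);
* network edges are selected **per regulator** at 10% before the
  ≥ 4-target pruning rule.  Per-regulator pooling makes every retained
  subnetwork stand on its own evidence.  Pooling a whole tissue instead
  would let the selection pad roughly thr/(1−thr) × (number of near-certain
  edges) near-zero-posterior edges onto arbitrary regulators — enough to
  carry a 2-target regulator past the pruning rule — which defeats the
  rule's purpose; a `pool_scope="tissue"` switch is provided for the pooled
  variant.  Since each per-regulator selection meets the threshold, the
  pooled network's achieved FDR (a weighted average) does too, and pruning
  whole regulators preserves this; the invariant is still recomputed and
  enforced after pruning.

Records from monomorphic instruments are emitted with NaN statistics and a
`monomorphic` status flag rather than dropped silently, and are never
selectable.

## Synthetic cohorts

The generator produces the structure the analysis assumes, not realistic
genomes:

* **Genotypes** — n_blocks LD blocks (default 4) of n_snps_per_block SNPs
  at one trait locus.  Per block a latent haplotype pair is drawn at a MAF
  uniform in `maf_range` (default (0.1, 0.5)); each SNP copy flips with
  probability (1 − r)/2 (default r = 0.8), giving each SNP correlation ≈ r
  with the latent haplotype and ≈ r² pairwise (less away from MAF 0.5).
  SNPs monomorphic at small n are resampled once, then rejected.
* **Expression** — standardized continuous scale (a surrogate for
  post-normalization data); baseline noise N(0, noise_sd²).
* **Trans effects** — per tissue, n_trans_genes genes receive
  trans_effect_size (default 0.6) per allele of an assigned block SNP.
* **Regulators and instruments** — the first n_regulators trans genes are
  regulators; each gets a dedicated cis SNP 1 kb from the gene with slope
  cis_effect_size (default 1.0).  The cis slope is deliberately larger than
  the trans slope: cis-eQTL effects dominate trans effects in real tissue
  data, and the method's premise is a strong, valid instrument.  At the
  default the instrument explains roughly 8–25% of regulator variance
  across the MAF range.
* **Edges** — a depth-1 linear SEM: each target equals a random-signed
  edge_effect_size (default 0.6) multiple of its regulator's expression
  plus independent noise; targets are disjoint across regulators and from
  trans genes.  `targets_per_regulator` accepts a per-regulator sequence so
  heterogeneous (including sub-threshold "decoy") subnetworks can be
  planted.
* **Replication cohort** — fresh samples, same gene universe, no
  genotypes; edges re-applied with slopes scaled by
  `replication_attenuation` (default 0.7).
* **Summary statistics** — block SNPs get trait p-values 10^−U,
  U ~ Uniform(8, 30), so all pass the 5×10⁻⁸ filter; cis instrument SNPs
  get Uniform(0,1) p-values and are (correctly) excluded by the filter.
* **Evidence catalogs** — a synthetic catalog marks all planted regulators
  (plus decoy null genes) in the TF databases, perturbation sets and the
  murine table, and builds per-regulator predicted-target sets mixing true
  targets with random genes for the enrichment stage.

Defaults (n_samples = 500, 1000 genes, effects 0.6) were chosen so planted
signals are detectable but not trivial at cohort-realistic sample sizes.
What the generator does **not** emulate: realistic recombination and MAF
spectra, population structure, count-based expression noise, shared
technical confounders, multi-level regulatory hierarchies, or genes present
in one cohort only.  Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated model, not performance on real
RNA-seq.

## Numerical and design choices

* Residual variances are floored at 10⁻¹² before forming log ratios, so a
  duplicated gene (B = A) yields a large finite LLR rather than infinity;
  all LLRs are clipped at 0.
* Genes absent from a replication dataset are dropped by intersection (with
  a logged count); the replication background is the discovery∩replication
  gene universe, and one random background set is drawn per comparison by
  default (`n_background_draws` raises it, at the cost of fidelity to the
  single-draw design).
* Hierarchical clustering for heatmap transfer uses average linkage on
  1 − |r| (configurable); the Kruskal–Wallis test uses midrank tie
  correction and the χ²(1) approximation.
* Fisher enrichment is two-sided by default (one-sided available); the
  odds ratio is the conditional MLE, rendered `inf` when a zero cell makes
  it unbounded; a degenerate margin yields p = 1 by convention.
* cis/trans labeling of scan records uses a ±1 Mb window around the SNP.
* Instrument validity requires a primary-linkage posterior ≥ 0.75
  (configurable); among qualifying cis SNPs the argmax is taken, ties
  lexicographic on SNP id.
* The GR score keeps genes with ≥ 1 criterion met; no higher bar is imposed
  before network reconstruction beyond instrument validity.
* The pipeline writes every table with fixed float formatting and sorted
  rows, hashes all artifacts into a manifest (timestamps kept outside the
  hashed content), and is bit-reproducible for a fixed config and seed;
  `--resume` re-runs a stage only if its outputs (or an upstream's) are
  missing.

## Limitations

* Posteriors are ensemble-calibrated: a regulator tested against fewer than
  100 genes cannot be scored (pool tissues or genes first).
* The five tests assume a single categorical instrument and additive
  effects; dominance codings, multi-SNP instruments and latent-confounder
  corrections are out of scope.
* Global-FDR selections by posterior mean deliberately admit a controlled
  fraction of weak edges; interpret individual low-posterior edges
  accordingly.
* The conservative bias of the posterior estimator means achieved FDRs
  typically undershoot the nominal level; power is paid for honesty.
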