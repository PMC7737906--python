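# Methods

## Scope

`omnigene` computes gene-based association tests from GWAS single-variant
summary statistics (z-scores, or effect sizes with standard errors) and an
LD reference panel, stratified by functional annotation class, and combines
them into a per-gene omnibus test. It also ships the summary-level
simulator and the evaluation machinery used to characterize the tests'
calibration, power, and accuracy at identifying causal genes — all runnable
offline against a synthetic fixture panel.

## Statistical model

Under the null hypothesis each single-variant z-score is standard normal
and the vector **Z** over a locus is multivariate normal with correlation
matrix **R** (estimated from the reference panel; "LD matrix"). The five
basic test forms over a variant set with weights w are:

| form | statistic | null |
|------|-----------|------|
| L-type | w′Z / √(w′Rw) | N(0, 1) |
| Q-type | Σₖ wₖZₖ² | Σₖ λₖ χ²₁ₖ, λₖ eigenvalues of diag(w)^½ R diag(w)^½ |
| M-type | maxₖ Zₖ² | MVN rectangle: 1 − P(max |Xₖ| ≤ max |Zₖ|), X ~ MVN(0, R) |
| ACAT | Σₖ wₖ tan((½ − pₖ)π)/Σw | standard Cauchy |
| HMP | Σw / Σ(wₖ/pₖ) | reciprocal ~ Landau(μ, π/2) |

L-type accepts signed weights (burden/TWAS direction hypotheses); Q-type,
ACAT and HMP require nonnegative weights. M-type, ACAT and HMP outputs are
always ≥ the minimum input p-value.

### Annotation classes

- **Coding / UTR** — equal-weight Q-type within each consequence subclass
  (missense, nonsense, synonymous; 3′/5′ UTR), combined across subclasses
  with equal-weight ACAT (HMP selectable).
- **dTSS** — ACAT (or HMP) over single-variant p-values with exponential
  proximity weights w(α) = exp(−α·|pos − TSS|), variants within 500 kb of
  the TSS, for α ∈ {10⁻⁴, 5·10⁻⁵, 10⁻⁵, 5·10⁻⁶}, then equal-weight ACAT
  across the α grid. O(m) per α; no LD needed.
- **Enhancer** — confidence-weighted Q-type T = ΣᵢΣⱼ wᵢ Zᵢⱼ² over enhancer
  elements i linked to the gene with weight wᵢ and member variants j. A
  variant inside several of the gene's enhancers contributes once per
  element, i.e. its effective weight is the sum of the element weights
  (the literal double sum). Tissue-specific element scores are collapsed to
  one confidence weight by the LogSumExp soft maximum.
- **eQTL / cross-tissue TWAS** — per tissue t, S_t = b_t′Z / √(b_t′R b_t)
  with signed predictive weights b_t; cross-tissue aggregation by CT-A
  (ACAT over per-tissue p, the default), CT-H (HMP), CT-Q (ΣS_t² with a
  mixture-χ² null using the eigenvalues of the cross-tissue correlation
  matrix R_S), or CT-M (max |S_t| with an MVN rectangle over tissues).
  Weight variants absent from the GWAS are dropped *without* rescaling the
  remaining weights and the missing fraction is recorded; if more than half
  of the absolute weight mass is missing the tissue result is withheld
  rather than silently biased (configurable).

### Omnibus combination and independent signals

Per gene, the class p-values that exist are combined with equal-weight ACAT
(HMP selectable); absent classes are skipped, never imputed. Trait-level
independent signals are counted greedily: select the most significant gene,
mask every gene any of whose contributing variants lies within 1 Mbp of any
of the selected gene's variants, repeat until nothing unmasked passes the
threshold (Bonferroni 5% over the genes actually tested for the trait — the
denominator is per-trait because a fixed genome-wide count would be
arbitrary for partially annotated inputs). Masking distance is measured
between contributing variant positions, not gene bodies. Ties in p break by
genomic order then gene id, making the procedure deterministic and
input-order invariant.

## Numerical methods

- **Mixture chi-squared tail** (`mixture_chisq_sf`): exact
  characteristic-function inversion (Imhof's formula). The oscillatory
  integrand sin(θ(u))/(u·ρ(u)) is split as sin(η)cos(qu/2) − cos(η)sin(qu/2)
  and the infinite tail handled by Fourier (QAWF) quadrature, which copes
  with the slow u^(−m/2−1) envelope decay at small m; quadrature error
  estimates are propagated (declared bound ≤ 1e-9). The Lugannani–Rice
  saddlepoint takes over for p < 1e-12 or when the quadrature error is too
  large; Liu-style moment matching is the last resort. Eigenvalues below
  1e-10 of the largest are truncated as ridge dust. The method used is
  recorded in the outcome's diagnostics. For replicate batches sharing one
  eigenvalue set, survival values are computed on a 96-node grid (denser
  near zero, where log p curves most) and interpolated monotonically in
  log p (PCHIP); the interpolant is cached per eigenvalue set. Measured
  interpolation error is ≤ 0.2% relative even for 200-eigenvalue sets —
  far below Monte-Carlo noise at the batch sizes involved.
- **MVN rectangle probabilities** (`mvn_rectangle_prob`): Genz sequential
  conditioning on a randomly shifted rank-1 lattice (√prime generators,
  baker transform), vectorized over points; the error estimate is three
  standard errors over the random shifts. The shift stream is seeded, so
  M-type and CT-M p-values are reproducible run to run. With independent
  variables the conditioning factors are constant and the result is exact.
- **Landau distribution**: `landau_cdf(x, μ, σ)` follows the
  integral-density parameterization with the (2u/π)·log(u/σ) phase; it maps
  onto the standard (ROOT-convention) location-scale Landau via
  loc = μ + (2σ/π)·log σ. The HMP null location is
  log m + 1 − γ + log(π/2) ≈ log m + 0.874 (standard convention): this is
  the constant the stable-law limit of the mean of Pareto(1)-tailed
  reciprocals requires, and we verified it by simulation (with it, tail
  rates at α = 0.05/0.005 match nominal to Monte-Carlo error at m = 50; a
  location constant with +γ instead of −γ makes the test roughly half as
  large as nominal). The Landau null is *asymptotic*: its small-p tail is
  accurate already at moderate m, while the bulk of the null distribution
  converges slowly (KS ≈ 0.03 at m = 50 even with the exact asymptotic
  location), so the HMP combiner should be trusted for significance
  testing, not for uniformity of large p-values.
- **ACAT orientation**: quantiles enter as tan((½ − p)π), so small input
  p-values give small outputs; contributions with p < 1e-15 use the tail
  form w/(pπ) to avoid overflow, and p = 1 maps to 1 − 1e-16. Note that
  ACAT's validity argument is a small-α Cauchy-tail argument: under strong
  positive dependence — whether hundreds of LD-correlated variants (the
  dTSS test) or a handful with high pairwise correlation — the empirical
  size at α = 0.05 is mildly inflated (~0.056–0.058 in our calibration),
  while sizes at α ≤ 0.005 are accurate.
- **LD regularization**: every LD matrix used in a denominator or
  eigendecomposition is ridge-regularized as (1 − ε)R + εI with ε = 1e-3 by
  default — reference panels are finite and R̂ is routinely singular. LD is
  computed per variant set on demand (never genome-wide) with an LRU cache
  keyed by the variant-tuple hash.
- **p-value floor**: outputs are clamped to ≥ 1e-300 and flagged in
  diagnostics when clamping occurs.

## Summary-level simulator

Traits are never materialized. For a locus with regularized LD matrix R and
standardized-genotype effects β scaled so β′Rβ = h²_L exactly (the locus
heritability), z-scores are drawn as

    Z = √n · D^(−1/2) R β + E,   E ~ MVN(0, (1 − h²_L)·R)

with D_kk = 1 − α_k², α = Rβ the marginal standardized effects (the
population limit of single-variant regression coefficients). The exact
finite-sample noise covariance is σ²·D^(−1/2)RD^(−1/2); at the locus
heritabilities studied here (h²_L ≤ 0.25%) D ≈ I and the per-entry error of
using σ²·R is O(h²_L). Residual variance is taken as 1 − h²_L;
at these heritabilities the distinction from unit variance is negligible.

Causal scenarios: *coding*/*utr* draw the causal count M* from Poisson(M/4)
truncated to [1, M] (rejection sampling; exact pmf used in tests) and give
the selected variants iid normal effects; *enhancer* draws the causal
element count the same way and selects elements with probability
proportional to confidence weight; *eqtl* picks one causal tissue uniformly
and sets β proportional to that tissue's predictive weights (the iid-normal
magnitude statement cannot apply coordinate-wise when effects are
proportional to a fixed weight vector, so proportionality plus the exact
h²_L rescaling is used); *heterogeneous* draws one of the four classes
uniformly per replicate. All effects are rescaled to β′Rβ = h²_L exactly.
Because real predictive weights are estimated with error, the evaluation
pipeline replaces the causal gene/tissue weight vector with a noisy draw
w̃ ~ N(w, 9/(10·N)·R⁻¹) before computing that TWAS statistic; N defaults to
300, a realistic bulk-expression panel size.

Default study conditions: GWAS sample size n = 50,000; locus heritability
grid h²_L ∈ {0.01%, 0.025%, 0.05%, 0.1%, 0.25%}; evaluation suites run at
h²_L = 0.05%.

## Synthetic fixture panel

The generator emulates an LD reference panel so the whole framework is
testable offline; a loader for a real VCF panel is provided for users who
have one. Haplotypes come from a latent Gaussian autoregression thresholded
at each variant's allele-frequency quantile: within an LD block the latent
correlation between neighbours decays geometrically with distance (0.88 at
one mean spacing of 3 kb), blocks (25–100 kb) are independent. The
frequency spectrum is skewed rare (maf = 0.5u², u ~ U(0.15, 1), floored at
1%). Defaults: 1006 haplotypes (the scale of a 503-sample phased reference
panel), genes every ~350 kb with random strand and 20–100 kb bodies, 3
tissues. Every gene gets coding variants (~35% of body variants outside the
UTR flanks; missense/synonymous/nonsense at 0.5/0.4/0.1), 3′/5′ UTR
variants in 3-kb flanks, 1–4 enhancer elements of 1–3 kb within 300 kb of
the TSS with LogSumExp-aggregated tissue scores, and sparse signed eQTL
weight vectors (2–5 variants within 100 kb of the TSS, drawn from a shared
per-gene pool so cross-tissue statistics are correlated). Ref/alt pairs are
never strand-ambiguous (A/T, C/G), since the default harmonization policy
would otherwise discard simulated signal that a real pipeline would have
pre-excluded.

What the fixture does *not* emulate: realistic MAF–LD coupling, mutation
and recombination-map heterogeneity, population structure, overlapping gene
bodies, annotation errors (enhancer–gene links are always correct), and
genome-scale variant density. Passing tests on this fixture show the
statistics and the pipeline are correct under the stated model, not that
annotation resources for real data are accurate.

## Evaluation

For each simulated locus the causal gene is known and the proximal genes
(other members within 1 Mbp of the causal TSS) are labelled non-causal.
Reported metrics: top-ranked accuracy (fraction of locus-replicates where
the causal gene has the strictly best score; ties count as failures —
conservative), power at p ≤ 2.5e-6 separately for causal and proximal
genes with exact binomial CIs, and ROC/precision-recall over
locus-standardized scores (each gene's −log₁₀ p divided by the locus
maximum, so curves measure within-locus ranking). The TSS-to-top-SNP
baseline ranks genes by distance between TSS and the most significant
single variant (ties to the smallest position); we use the plain most
significant variant rather than an LD-pruned lead. The annotation-agnostic
baseline is an equal-weight Q-type over all variants within 500 kb of the
gene body.

The default suite size is 50 loci × 20 replicates per scenario, which keeps
exact binomial CIs informative while finishing in a few minutes on one CPU;
the same machinery scales to larger designs through configuration. The five
scenario suites reuse one set of loci and share precomputed locus plans.

## Known limitations

- Indels are matched by exact ref/alt strings; no left-normalization.
- The Bonferroni denominator for independent-signal counting is the
  per-trait tested-gene count; analyses mixing traits with very different
  annotation coverage should set an explicit threshold.
- HMP p-values are tail-exact but not bulk-uniform at moderate m (above).
- The dTSS ACAT test is mildly anti-conservative at α = 0.05 under strong
  LD (above); interpretation at genome-wide thresholds is unaffected.
- CT-Q/CT-M require the cross-tissue correlation matrix and cost O(m²n);
  CT-A/CT-H are O(m) and are the default.
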