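# Methods

## The generative model

`tsatwas` simulates, one gene at a time, the full causal chain of a
transcriptome-wide association study (TWAS): genotypes → tissue-resolved eQTL
effects → expression in `P` tissues → a continuous trait driven by expression
in exactly one causal tissue. The point of the model is to control the two
axes of *tissue specificity* — how many tissues express the gene, and how
similar its regulation is across them — and measure what each TWAS method does
as those axes move.

### Genotypes

`M = m_ts·P + m_mt + m_null` independent biallelic SNPs for `n_total`
individuals (default 1,500): per-SNP minor allele frequencies drawn from
U(0.01, 0.5) and dosages from Binomial(2, maf). No linkage disequilibrium is
simulated — each SNP is an independent draw. The cohort is split into an eQTL
training set (first 500 individuals, the scale of a reference expression
panel) and a TWAS test set (1,000). Standardization uses full-panel sample
moments; both splits share the same dosage-to-feature map, so weights trained
on one split apply to the other without rescaling.

### eQTL effects and expression

Each tissue is regulated by `m_eqtl = 30` eQTLs: `m_ts` tissue-specific ones
(a disjoint SNP block per tissue, chosen disjoint for identifiability) and
`m_mt` multi-tissue ones (the same SNPs in all tissues, with tissue-varying
effect sizes). Effects are multivariate normal with per-entry variance
`h2_snp_expr / m_eqtl`, so the genetic variance per tissue sums exactly to the
expression heritability `h2 = 0.3`. Multi-tissue effect rows have pairwise
cross-tissue correlation `cor_tissue`; tissue-specific effects are independent
across tissues. Expression is

    E = X_ts β_ts + X_mt β_mt + ε1,     ε1 ~ N(0, Σe ⊗ I)

with `Σe` exchangeable: diagonal `1 − h2`, off-diagonal `cor_tissue·(1 − h2)`
— non-genetic regulation is assumed to share structure across tissues to the
same degree the genetics does. Two closed forms follow and are verified by the
tests: per-tissue Var(E) → 1, and

    corr(E_p, E_q) → cor_tissue · (h2 · m_mt/m_eqtl + 1 − h2),

which at the default `h2 = 0.3`, `m_mt/m_eqtl = 24/30` is `0.94·cor_tissue`,
i.e. {0, 0.188, 0.376, 0.564, 0.752} across the similarity grid.

A note on the effect-variance scaling: the per-entry variance is
`h2/m_eqtl`, not `h2·m_ts/m_eqtl` (resp. `h2·m_mt/m_eqtl`). The latter would
make the *total* genetic variance quadratic in the component sizes; the former
makes the component totals equal the stated variance proportions and
reproduces the correlation sequence above. We treat the component constants as
totals, which is the only reading consistent with unit expression variance.

### Trait

On the TWAS split, `Y = g_std·b1 + ε2` where `g_std` is the standardized
genetic expression component of one uniformly drawn causal tissue,
`Var(ε2) = 1 − r2_expr_trait`. By default `b1 = sqrt(r2_expr_trait)` (fixed),
so the trait's narrow-sense heritability is exactly `r2_expr_trait`; a
`fixed_effect=False` switch draws `b1 ~ N(0, r2)` per gene-trait pair instead.
The fixed-effect convention is the default because it makes per-scenario power
a deterministic function of the imputation quality rather than a mixture over
random effect sizes, and it is the convention under which the benchmark's
reference operating points (single-tissue power ≈ 51%, omnibus power ≈ 62% on
the ubiquitous-gene scenario; tissue false-positive rates ≈ 77%/84%) are
reproduced. `r2_expr_trait = 0` gives the exact null used for type I error.

### Seeding

One master seed spawns a child stream per (replication, pair, stage) through
`numpy.random.SeedSequence(master, spawn_key=(rep, pair, stage))`. Any single
gene-trait pair is reproducible in isolation; all outputs are pure functions
of (config, seed).

## Weight training and imputation

* **Elastic net** (single-tissue convention): one `ElasticNetCV` per tissue,
  mixing 0.5, a 50-point penalty path spanning 3 decades below the
  data-derived maximum, 5-fold seeded CV. Backed by scikit-learn.
* **Group lasso** (integrative convention): one joint fit minimizing the
  summed squared error plus `α·Σ_j ||W[j,:]||₂` — each SNP's weights across
  tissues are jointly zero or jointly active. This is exactly scikit-learn's
  multi-task lasso, and with one tissue it reduces to the lasso. A pure group
  penalty is used; a sparse-group variant (adding a within-group L1 term)
  exists in the literature but is not implemented.
* Both trainers share fold assignments when given the same `random_state`, so
  method comparisons are paired.
* A tissue whose CV-optimal model keeps no SNP is flagged *unexpressed*; that
  mask drives the TSA routing counts downstream.
* GReX is imputed as standardized dosages × weights.

## Association engines

* **SLR**: OLS of trait on one tissue's GReX (+ covariates); covariates are
  handled by residualizing trait and GReX once, which is equivalent under OLS.
  Zero-variance GReX yields a "not testable" marker, never p = 0.
* **PC regression**: principal components of the standardized GReX matrix;
  components kept while `λ_max/λ_i ≤ 30` (condition threshold, exposed); joint
  F test on the retained components.
* **GBJ**: the Generalized Berk-Jones omnibus test. Per-tissue signed z
  scores come from the SLR p-values; their correlation is estimated as the
  sample correlation of the GReX columns (the regressors), symmetrized and
  PSD-repaired by eigenvalue clipping at 1e-8 with diagonal renormalization.
  Exactly duplicated tissues are collapsed first. The statistic contrasts, at
  each rank k of the ordered |z|, the observed exceedance count with its null
  mean and correlation-inflated variance (bivariate normal orthant
  probabilities via Owen's T), moment-matched to an extended beta-binomial;
  the statistic is the max over ranks inside the rejection region. P-values
  are floored at 1e-15.

### GBJ p-value evaluators

The default evaluator is seeded Monte Carlo from N(0, R̂): stages of
2×10⁴ → 10⁵ → 10⁶ draws (ceiling configurable to 10⁷), stopping early once
100 exceedances are observed or, when a decision threshold α is supplied, once
the 99.9% interval for p excludes it. The benchmark passes its adjusted α so
borderline tests escalate and clear-cut ones stop early.

The optional analytic evaluator computes the boundary-crossing probability of
the ordered |z| exactly for exchangeable correlation: solve per-rank
thresholds `b_k` from the statistic, decompose `Z_i = √ρ·W + √(1−ρ)·ε_i`,
integrate over the shared factor with 80-node Gauss-Hermite quadrature, and
evaluate the conditional non-crossing probability with a dynamic program over
exceedance counts. General correlation matrices are approximated by their mean
off-diagonal equicorrelation. The test suite requires the two evaluators to
agree within Monte-Carlo error on exchangeable grids.

## Benchmark metrics and the multiple-testing convention

Each replication simulates `n_pairs` (default 100) independent gene-trait
systems; `n_reps` (default 20) replications give the distribution of each
point estimate. Power is the fraction of causal genes detected — for
single-tissue tests, detected *in the causal tissue*; for cross-tissue tests,
at gene level. Under the null the same fraction is the type I error. The
tissue false-positive rate is, among significant (gene, tissue) results, the
fraction pointing at non-causal tissues, computed with and without the
tissue-count adjustment.

Each simulated gene-trait pair is treated as its own test family: single-tissue
tests use `α/P_tested`, cross-tissue tests use `α`. This per-pair convention
is the one under which all engines sit at or below the nominal 5% type I rate
while the cross-tissue engines sit *at* it; dividing additionally by the
number of pairs per replication is available (`BonferroniPolicy(genes="panel")`)
but makes every rejection rate collapse toward zero rather than measuring
calibration. Method comparisons use the two-sided Wilcoxon signed-rank test on
paired per-replication rates (exact for n ≤ 25 where ties permit, normal
approximation with continuity correction otherwise).

The mixed-gene-set experiment draws each gene as tissue-specific (P=1) with
probability π and multi-tissue otherwise, and scores three strategies: pure
single-tissue (elastic net + SLR everywhere), pure cross-tissue (group
lasso + GBJ, which *cannot* test single-tissue genes — they count as misses),
and the TSA router. By construction TSA equals the pure cross strategy at
π = 0 and the pure single strategy at π = 1, and never falls below the weaker
pure strategy in between.

## Heritability recovery

The validation study regenerates the whole chain (30 eQTL + 30 null SNPs,
expression heritability 0.3, traits at several `r2_expr_trait` levels and MAF
regimes) and asks a single-component linear mixed model to recover the trait
heritability. The GRM is `K = ZZ'/M` over *all* simulated SNPs (a genome-wide
GRM would be inappropriate for a single-gene design). REML maximizes the
restricted likelihood of `(σ²_g, σ²_e)` by expected-information scoring in the
eigenbasis of K (one eigendecomposition per genotype replicate, O(n) per
iteration afterwards), convergence at relative log-likelihood change < 1e-8,
variance floor 1e-10, non-converged fits excluded and counted. At
`r2_expr_trait = 1%` the recovered mean ĥ² is ≈ 1%; the null level recovers
≈ 0; MAF regime has no detectable effect.

## Problem sizes used by the shipped checks

The acceptance script and the end-to-end tests run at scaled-down replication,
chosen as the package's own verification scale: 500 simulation replicates for
the expression-covariance check; 100 pairs × 5 replications for the power,
type-I and tissue-FPR scenarios (3 representative null cells at P ∈ {1,5,10});
100 pairs × 3 replications per differential cell for the eQTL-method
comparison; N=1,000 with 10 traits × 10 genotype replicates for heritability.
Large grids additionally use a reduced solver profile
(`FAST_TRAINER_OPTIONS`: 16-point penalty path over 1.5 decades, 3-fold CV,
looser tolerances, per-tissue CV scores off), which reproduces the
full-profile GReX-truth correlation to ~0.002 on the default scenarios.

## What the simulator does and does not emulate

It emulates: the cross-tissue sharing structure of eQTL effects, realistic
MAF spectra, the training/testing split of a reference-panel TWAS, weak
expression-trait coupling (trait heritability ≤ 1–5%), and the one-causal-
tissue assumption. It does **not** emulate: linkage disequilibrium (SNPs are
independent, so fine-mapping-style confounding between SNPs is absent), binary
traits, genes whose eQTLs differ in number across tissues, population
structure, or expression measurement noise beyond the Gaussian residual.
Passing benchmarks here therefore speak to method behavior under the stated
architecture, not to LD-driven false sharing in real panels.

## Known limitations

* The GBJ analytic evaluator is exact only for exchangeable correlation; for
  strongly non-exchangeable R it is an approximation and the Monte-Carlo
  evaluator should be preferred (it is the default).
* Monte-Carlo p-values cannot resolve below ~1/max_draws; far-tail p-values
  are reported at the resolution floor, which is irrelevant at benchmark α
  but matters if the output is reused for genome-wide thresholds.
* The group-lasso trainer fits all tissues of a gene jointly and therefore
  declares either all or none expressed in the simulated setting; "expressed
  in k of P tissues" patterns arise in applied mode from user weight tables,
  not from the simulator.
* REML assumes a single variance component plus noise; it is not a general
  GREML implementation.
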