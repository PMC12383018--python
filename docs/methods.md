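# Methods

`stepgen` implements a single-step genomic evaluation for one or two
quantitative traits: pedigree and genomic relationship matrices, variance
components by EM-REML, BLUP/ssGBLUP prediction with iterative SNP
weighting (WssGBLUP), a window-variance association scan (WssGWAS),
evaluation-comparison metrics, and candidate-gene annotation.  A synthetic
generator produces pedigrees, genotypes and bivariate phenotypes with the
statistical structure the analysis assumes, so the whole pipeline is
testable without proprietary records.

## Model

The animal model per trait t is

    y_t = X_t b_t + Z_t a_t + e_t

with one fixed factor (the contemporary group — herd-month-year of birth
in the motivating application), additive genetic effects
`a ~ N(0, G0 ⊗ K)` and residuals `e ~ N(0, R0 ⊗ I)` with trait-wise
deletion of missing records.  `K` is either the pedigree numerator
relationship matrix `A` or the single-step matrix `H` whose inverse is

    H⁻¹ = A⁻¹ + [0 0; 0 τG⁻¹ − ωA22⁻¹]

on the genotyped block, with defaults τ = 1.00 and ω = 0.50.  `G` follows
VanRaden with per-SNP weights:

    G = Z D Z′ / φ,   φ = 2 Σᵢ pᵢ(1 − pᵢ)

where `Z` holds allele counts column-centered at `2pᵢ`, missing calls
mean-imputed to `2pᵢ` beforehand.  Allele frequencies default to observed
post-QC frequencies; base-population frequencies can be supplied.  Because
observed-frequency centering makes G exactly singular (zero row sums), G
is blended with `A22` as `αG + (1−α)A22`, default α = 0.95; α = 1 disables
blending and is used wherever an exact GBLUP/SNP-BLUP identity is needed.

### Pedigree machinery

`A` is built by the tabular recursion; `A⁻¹` directly by the Henderson
rules with inbreeding, where the Mendelian-sampling variance of animal i
is `1 − 0.25(1+F_s) − 0.25(1+F_d)` over the known parents.  Inbreeding
coefficients come from the Meuwissen–Luo ancestor trace, which never
forms the dense matrix.  Pedigrees are recoded canonically — animals
sorted by generation number, then identifier — so the recoded pedigree is
independent of record order in the input file; cycles (an animal its own
ancestor) are a hard error naming an involved animal.

## EM-REML

Variance components are estimated by EM on the mixed-model equations:
`G0` is updated from the BLUP quadratic form `âᵗK⁻¹â` plus the trace of
the corresponding block of the inverse coefficient matrix, `R0` from
expected residual cross-products.  Records missing one trait contribute
through an exact E-step: the unobserved residual components enter via
their conditional moments `B ê_obs` and `R0_mm − B R0_om` with
`B = R0_mo R0_oo⁻¹`, plus the prediction-variance of the fitted values
taken from the inverse coefficient matrix.  The REML log likelihood is
evaluated every iteration and is non-decreasing (a property asserted in
the test suite).

Two computational routes produce identical likelihoods (cross-checked in
the tests to ~1e-11 against a direct dense-V evaluation):

* **eigen** — for balanced data (every phenotyped animal records every
  trait, one record each).  Non-phenotyped animals are marginalized out of
  the likelihood; the phenotyped block `K_pp` is eigendecomposed once and
  every EM quantity reduces to 2×2 operations per eigenvector, making
  iterations cost milliseconds at a few thousand records.  Larger
  simulation studies use this route.
* **mme** — direct dense assembly of the full mixed-model equations with
  one inverse per iteration; handles arbitrary missing-trait patterns and
  is intended for moderate problem sizes (a few hundred animals).

Numerical choices: starting values put half the observed phenotypic
variance in each component with zero covariances; updates are kept
positive definite by an eigenvalue floor at 1e-8 of the largest
eigenvalue; convergence is declared when the maximal parameter change,
normalized by the phenotypic scale `√(P_tt P_uu)`, falls below `tol`
(default 1e-8, iteration cap 500).  EM converges slowly near flat
directions — typical low-heritability fits reach ~1e-5–1e-6 relative
change within 1,000 iterations — so non-convergence is a flagged warning
and the last iterate is returned, never an error.  Per-trait fixed-effect
levels with no observed records are dropped for estimability.

Standard errors come from the observed-information matrix — a central
finite-difference Hessian of the REML log likelihood in the six (or two)
covariance parameters at the optimum — inverted and propagated to h² and
r_g by the delta method with analytic gradients.  The delta-method SEs are
verified against fully numerical Jacobian propagation in the tests.

## Prediction and accuracy

The MME are solved by dense Cholesky factorization; prediction error
variances (PEV) are read off the diagonal of the inverse coefficient
matrix; animals without records receive predictions through the
relationship structure (an unphenotyped, progeny-free animal gets the
parent average).  Per-animal accuracy is

    acc_i = √(1 − PEV_i / ((1 + F_i) σ²_a))

clipped to [0, 1], with F from the pedigree in both the pedigree-only and
single-step evaluations.  Bivariate evaluations solve the two-trait
system jointly.

## WssGBLUP / WssGWAS

SNP effects are back-solved from the genotyped animals' GEBVs as

    ŝ = D Z′ G⁻¹ û / φ

The 1/φ factor (absent in some published statements of the formula) makes
`Z ŝ = û` hold exactly when α = 1; it cancels in every variance-percentage
output, which the tests assert.  Weights are refreshed as
`dᵢ = ŝᵢ² · 2pᵢ(1 − pᵢ)`, renormalized to sum to the number of SNPs, and
the single-step evaluation is rebuilt and re-solved; two weight iterations
are the default (configurable 1–10).  One weight vector enters G, so in a
bivariate model the weights track a designated trait and per-trait scans
rerun the loop.

Association is summarized as the percentage of additive genetic variance
explained by windows of consecutive SNPs: the variance across genotyped
animals of the window genomic value `Σ_k z_k ŝ_k`, divided by the REML
additive variance, × 100.  Windows slide by one SNP by default
(configurable to 5-SNP windows or non-overlapping tiles) and never span
chromosome boundaries; a chromosome shorter than the window becomes a
single whole-chromosome window.  The significance rule is a variance-
proportion threshold (`variance_pct ≥ threshold`), not a p-value.  The
literature quotes thresholds as high as 10% while reporting windows at
1–4%; the pipeline default is therefore 1% and the value is prominently
configurable.

## Evaluation comparison

ABLUP and WssGBLUP evaluations are compared per subset (all animals,
bulls, dams, top 20% by pedigree EBV within sex class, ties broken by
animal id) and trait with three metrics: Pearson CORR between the paired
evaluations (on breeding values by default; an accuracy basis is
available and the report records which was used — published usage is
ambiguous between the two), %Bias Reduction
`(AvgEBV − AvgGEBV)/|AvgEBV| × 100`, and Accuracy Increase
`(AccGEBV − AccEBV)/AccEBV × 100` on subset means.  Zero denominators and
subsets below three animals yield NaN with a warning.  Sexes are inferred
from pedigree roles (sires male, dams female) when no explicit table is
given.

## Candidate-gene annotation

For each significant SNP, all genes on the same chromosome within 50 kb
(inclusive; configurable) are reported.  Distance is 0 when the SNP lies
inside the 1-based inclusive gene span, negative when the gene lies 5′ of
the SNP (lower coordinates), positive when 3′.  A gene hit by significant
SNPs of both traits is flagged pleiotropic.  Annotation is a pure
function of its inputs; coordinates are treated as opaque user input (no
assembly lookups, no network access).

## Quality control

Filter cascade, in order: animal call rate ≥ 0.90 → duplicate genotypes
(pairwise concordance > 0.99 on ≥ 100 shared non-missing calls, the
later-listed animal dropped) → SNP call rate ≥ 0.90 → MAF > 0.05 (strict,
per the "> 5%" convention) → Mendelian conflicts (opposing homozygotes in
known parent–offspring pairs, zero tolerance by default).  Because
removing SNPs changes animal call rates and vice versa, the cascade is
swept to a fixed point, which makes the filter idempotent; removal counts
accumulate per filter so the report stays auditable.

## Synthetic data generator

The generator emulates the data structure of a smallholder
reproductive-trait evaluation, scaled to desk size:

* **Pedigree** — discrete generations; founders alternate sexes; each
  dam of the previous generation mates a random sire from all earlier
  generations.  Defaults (700 founders, 3 generations, 2 offspring per
  mating) give ~2,800 animals; 4.8% of offspring have their parent
  records masked (they become structural founders, and all downstream
  simulation treats the recorded pedigree as truth, keeping the
  generative model self-consistent).
* **Genotypes** — unlinked loci gene-dropped through the recorded
  pedigree; founder frequencies uniform on (0.05, 0.5); 3,000 SNPs on 10
  chromosomes by default (a scaled-down stand-in for a ~30K post-QC
  panel); positions strictly increasing with uniform gaps up to 160 kb;
  missing calls masked at 1%.
* **Phenotypes** — TBV = genomic QTL part + infinitesimal polygenic part.
  The QTL part puts `qtl_variance_fraction` of σ²_a on `n_qtl` markers;
  effects are drawn bivariate-normal with correlation r_g and empirically
  rescaled, either jointly (`gaussian`, variance shares vary across QTL)
  or per-QTL (`equal`, every QTL explains the same share — used by
  detection studies that prescribe per-QTL variance).  The polygenic part
  is bred down the pedigree with Mendelian-sampling variance
  `1 − 0.25(1+F_s) − 0.25(1+F_d)`, so it is distributed exactly as
  `N(0, Σ ⊗ A)` and REML on the same pedigree is correctly specified.
  Phenotype = trait mean + contemporary-group effect (SD = `cg_sd` × the
  trait SD, independent across traits) + TBV + residual with correlation
  `re`.  `trait_sds` parameterize the genetic-plus-residual variance; the
  contemporary-group variance sits on top.  Default trait scales mirror a
  two-trait reproduction study: means 46.31 and 520.87, SDs 10.01 and
  103.68, h² (0.36, 0.051), r_g 0.495, r_e 0.51 (which implies r_p ≈
  0.467).
* **Sampling** — records only for a fraction of non-founders (default
  0.49, ~1,000 records at default scale); genotypes released for a
  fraction of all animals (default 0.16, ~460), selected at random or
  stratified into high/medium/low true-merit thirds.

What the generator does **not** emulate: linkage and LD decay (loci drop
independently; window statistics exist to aggregate signal, not to model
LD), selection across generations, non-additive effects,
genotyping-batch structure, and contemporary-group size imbalance.
Passing tests therefore demonstrate the estimator and pipeline mechanics
under a correctly specified additive model — not robustness to LD,
selection or model misspecification in field data.

When phenotypes use genotypes that already contain missing calls, QTL
columns are mean-imputed before computing genomic values; at the default
1% missingness the distortion of the true architecture is negligible, and
studies that need exact control set `missing_rate = 0`.

## Verification studies (`stepgen.studies`)

The studies the acceptance script reports, with their operating points:

* **Pedigree-inverse oracle** — 50 random looped pedigrees (n ≤ 200);
  `A·A⁻¹ = I` to 1e-8.
* **Single-step degeneracy** — with an empty genotype set, or `G := A22`
  and τ = ω = 1, the H-based evaluation must equal the A-based one
  exactly.
* **GBLUP/SNP-BLUP equivalence** — 50 animals × 200 SNPs, α = 1, d = 1;
  GEBVs equal `Z` times ridge solutions with `λ = φσ²_e/σ²_a` to 1e-6,
  and the back-solve maps onto the GEBVs to 1e-8.  The GBLUP side uses
  the variance-form BLUP identity `û = G(G + λI)⁻¹(y − Xβ̂)`, which is
  valid even for the rank-deficient observed-frequency G.
* **Parameter recovery** — 30 replicates, ~2,000 phenotyped animals in a
  three-generation pedigree, purely polygenic bivariate traits at
  h² = (0.36, 0.051), r_g = 0.495, r_e = 0.513; EM-REML means must land
  within 3 Monte-Carlo SE of truth and the likelihood must be monotone in
  every iteration of every replicate.  REML runs at tol 1e-6 with a
  1,000-iteration cap; replicates stopping at the cap sit at ~1e-5–1e-6
  relative change, far inside the Monte-Carlo tolerance.
* **WssGWAS detection** — 3 QTL, each exactly 15% of σ²_a
  (`qtl_effect_sharing="equal"`), among 2,000 SNPs, two weight
  iterations.  A ~1,200-animal three-generation pedigree is fully
  phenotyped while only ~500 animals are genotyped, so ungenotyped
  relatives sharpen the genotyped animals' GEBVs through H — the setting
  single-step exists for.  Detection is judged on non-overlapping 10-SNP
  windows (each QTL lies in exactly one window; overlapping sliding
  windows of a single QTL would otherwise monopolize the top ranks).
  QTL are common variants (founder MAF 0.15–0.5) on a moderately
  heritable trait (h² = 0.6): power analysis across these open
  dimensions showed rare-variant QTL (MAF down to 0.05) and low-h²
  traits genuinely lack single-window power at this sample size — an
  informative property of the method, not an implementation artifact.
  At the chosen operating point detection runs at 0.90–0.97 across
  independent 30-replicate runs.
* **Accuracy-gain direction** — 30 replicates of a ~480-animal pedigree,
  half genotyped, a 0.36-h² trait with half its additive variance on 20
  QTL; the accuracy-increase metric for the genotyped subset must be
  positive in ≥ 80% of replicates (it is typically +30–45%).
* **QC fixture** — a 10-animal × 12-SNP matrix with exactly one violation
  of every filter; survivors are hand-enumerated and the filter must be
  idempotent.
* **Annotation fixture** — distance boundary at exactly 50,000 vs 50,001
  bp, on-target containment, and the two-trait pleiotropy flag.

Problem sizes throughout are desk-scale choices: dense linear algebra
targets at most ~10k animals, and the simulation studies are sized so the
full suite runs in minutes on a single core.

## Known limitations

* Dense matrices everywhere; no APY or sparse MME for large populations.
* EM-REML without average-information acceleration is slow to fully
  converge on flat likelihoods; the information-matrix SEs and the
  Monte-Carlo studies are insensitive to this, but very tight tolerances
  need many iterations.
* The τ/ω weighting factors are configuration, not estimated; no
  bias-minimization search is implemented.
* Accuracy is PEV-based; validation-based (forward cross-validation)
  accuracy is out of scope.
* The simple-dialect genotype file carries no SNP names; a SNP map file
  is required to carry coordinates.
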