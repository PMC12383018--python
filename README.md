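# stepgen

Single-step genomic evaluation for quantitative traits in livestock
populations with incomplete genotyping — the everyday situation in
smallholder and indigenous-breed programs, where a few hundred animals
are genotyped but thousands of relatives carry pedigree and phenotype
records.  `stepgen` is aimed at animal-breeding researchers who want a
transparent, fully tested reference implementation of the
ssGBLUP/WssGBLUP/WssGWAS stack at desk scale, plus a synthetic-data
generator so every stage can be exercised and validated without access
to proprietary herd records.

## What it computes

For one or two traits the animal model is

    y = Xb + Za + e,    a ~ N(0, G0 ⊗ K),    e ~ N(0, R0 ⊗ I)

with a contemporary-group fixed factor and additive animal effects over
a relationship matrix `K`:

* **ABLUP** — `K = A`, the pedigree numerator relationship matrix
  (tabular method; `A⁻¹` by the Henderson rules with Meuwissen–Luo
  inbreeding).
* **ssGBLUP** — `K = H`, combining pedigree and genomic information:
  `H⁻¹ = A⁻¹ + [0 0; 0 τG⁻¹ − ωA22⁻¹]` with `G = ZDZ′/φ`
  (VanRaden, `φ = 2Σpᵢ(1−pᵢ)`, optional per-SNP weights `D`, A22
  blending for invertibility), defaults τ = 1.00, ω = 0.50.
* **EM-REML** variance components: `σ²a`, `σ²e`, heritability h², the
  genetic correlation r_g and phenotypic correlation r_p, with
  observed-information standard errors; the REML log likelihood is
  monotone across iterations by construction.
* **WssGBLUP / WssGWAS** — SNP effects back-solved as
  `ŝ = DZ′G⁻¹û/φ`, weights refreshed as `dᵢ = ŝᵢ²·2pᵢ(1−pᵢ)`
  (renormalized, two iterations by default), and association summarized
  as the percentage of additive variance per window of consecutive
  SNPs: `100 · Var(Σ z_k ŝ_k)/σ̂²a`.
* **Evaluation comparison** — CORR, %Bias Reduction
  `(AvgEBV − AvgGEBV)/|AvgEBV|·100` and Accuracy Increase
  `(AccGEBV − AccEBV)/AccEBV·100` over standard animal subsets.
* **Candidate genes** — genes within 50 kb of significant SNPs, with
  signed distances and a pleiotropy flag for genes hit by both traits.
* **Quality control** — MAF > 5%, call rate ≥ 90% (animals and
  markers), duplicate genotypes, opposing-homozygote Mendelian
  conflicts; swept to a fixed point so the filter is idempotent.
* **Synthetic data** — multi-generation pedigrees, gene-dropped
  genotypes, and bivariate phenotypes with a configurable QTL +
  infinitesimal-polygenic architecture (defaults emulate a two-trait
  reproduction study: h² ≈ 0.36 and 0.05, r_g ≈ 0.5, ~2,800 animals,
  ~1,000 records, ~460 genotyped).

See `docs/methods.md` for the model details, numerical choices and the
generator's scope.

## Worked example

Run the packaged small simulation (~480 animals, 2,000 SNPs, five QTL)
end to end, lowering the window-significance threshold to 0.3% — at
desk scale BLUP shrinkage keeps per-window variance percentages well
below the 1% default:

```sh
cat > demo.yaml <<EOF
threshold_pct: 0.3
seed: 7
EOF
stepgen run --config demo.yaml --out demo
```

The run writes one directory per stage (simulate, qc, relmat, reml,
predict, gwas, evaluate, annotate) plus a `manifest.json`; re-running
resumes from whatever outputs already exist.  Highlights of this run:

`demo/reml/vc.yaml` (pedigree REML on ~290 records):

```yaml
h2:   [0.558, 0.186]
se_h2: [0.160, 0.146]
rg: 0.917
rp: 0.511
```

With only ~290 records the heritabilities carry standard errors of
~0.15 — the point estimates sit 1–1.3 SE from the generator's truth
(0.36, 0.051), a fair picture of how uncertain desk-scale variance
components are.

`demo/evaluate/comparison.tsv` (ABLUP vs WssGBLUP):

```
subset  trait    n    corr      bias_reduction_pct  accuracy_increase_pct
all     trait1   476  0.988918  24.862              23.8306
all     trait2   476  0.987321  27.4141             28.9239
dams    trait1   247  0.990435  34.4895             21.5886
```

The two evaluations rank animals almost identically (CORR ≈ 0.99)
while genomic information raises the mean PEV-based accuracy of the
predictions by ~20–30% — the qualitative signature of single-step
evaluation when genotypes carry real signal.

`demo/annotate/candidate_genes.tsv` maps the SNPs inside significant
windows onto the simulated gene table:

```
snp      chrom  pos       gene      gene_start  gene_end  distance_bp  trait   pleiotropic
M000327  1      25400775  GENE0003  25372281    25389072  -11703       trait1  False
```

i.e. the window peak on chromosome 1 lies 11.7 kb downstream (negative
= gene 5′ of the SNP) of a simulated gene — the same table shape a
real analysis would hand to functional follow-up.

The library API mirrors the stages (`simulate_dataset`, `qc_filter`,
`build_A_inverse`, `build_G`, `build_H_inverse`, `reml_estimate`,
`solve_mme`, `run_wssgblup`, `window_variance`, `compare_evaluations`,
`annotate_candidates`); every CLI stage is a thin wrapper over these
functions.

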