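# gxegwas

Environment-dependent GWAS of a plastic trait on a pedigreed wild
population, exercised entirely on simulated data.  The pipeline covers:

* **simulate** — multi-generation pedigrees, biallelic SNPs with local LD
  (Markov founder haplotypes + Mendelian gene dropping with recombination),
  daily spring-temperature series, and repeated laying-date records drawn
  from a repeated-measures animal model with class-specific residual
  variances and optional class-specific SNP effects.
* **env_classes** — the March 11 – April 20 temperature window, tercile
  classification of years into cold / intermediate / warm, and
  year-by-area centering of phenotypes.
* **qc** — SNP filters (coordinates, monomorphism, call rate, MAF),
  individual filters (call rate, heterozygosity FDR, IBS near-duplicates)
  and the genotype-by-temperature-class support rule.  Hardy–Weinberg
  deviation is deliberately not a removal criterion.
* **relatedness** — Henderson's pedigree numerator relationship matrix,
  IBS similarity/distance, and classical MDS with robust outlier flagging.
* **mixed_model** — REML for the animal model with permanent-environment
  effects and residual variances stratified by temperature class
  (eigenrotation + Woodbury structure, profiled scale, simplex search with
  an analytic-gradient Newton polish), plus Wald tests, variance-component
  LRTs, per-class heritability with delta-method SEs and adjusted marginal
  r².
* **gwas** — per-SNP scans under main-effect and interaction models
  (null-fixed or per-SNP REML variance components), Bonferroni and
  LD-adjusted (sliding-window Keff) thresholds, genomic inflation, QQ and
  Manhattan tables, and interaction-vs-main model comparison.
* **studies** — the simulation studies behind the acceptance checks
  (heritability recovery, the residual-heteroscedasticity inflation
  demonstration, interaction power, model-comparison direction).

## CLI

Every stage is a subcommand of `gxegwas`; `run-all` chains them from one
declarative YAML config and writes a `manifest.json` next to the outputs:

```sh
gxegwas run-all --config examples/demo.yaml
gxegwas simulate --seed 1 --outdir out/
gxegwas classify --temperatures out/temperatures.csv --out out/classes.csv
gxegwas center --phenotypes out/phenotypes.csv --classes out/classes.csv \
    --out out/centered.csv
gxegwas relatedness --pedigree out/pedigree.csv --out out/amat.tsv
gxegwas gwas --ped out/sim.ped --map out/sim.map --phenotypes out/centered.csv \
    --amatrix out/amat.tsv --residuals het --outdir out/
```

Genotypes are read and written as PLINK 1.07 text `.ped`/`.map`;
phenotypes, pedigree and temperatures as CSV; results as TSV.
Identical configuration (including the root seed) reproduces every output
byte for byte.

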