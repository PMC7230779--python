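# atollconnect

Tools for asking where the spat come from in a pearl-farmed atoll lagoon.

The black-lip pearl oyster *Pinctada margaritifera* industry rests on
collecting wild spat (settled juveniles) in a handful of highly recruiting
lagoons. Whether those spat are produced by the huge exploited stock hanging
on farm lines or by the much smaller natural populations on the lagoon floor
is the central management question: the exploited stock is young and — the
species being a protandrous hermaphrodite — almost entirely male, while the
old natural populations of the lagoon's northeastern corner are
female-biased and genetically distinct.

`atollconnect` implements the full desk-scale analysis chain on synthetic
data, from genotypes to larval trajectories:

- **popsim** — a Balding–Nichols F-model genotype simulator with two genetic
  clusters (northeastern-natural vs southwestern-natural + exploited),
  protandrous demography (0% females at age 1, 27% at 6, 41% past 8),
  sweepstakes-reproductive-success (SRS) spat cohorts parented by a few
  adults, and per-genotype depth/missingness, written out as VCF + CSV.
- **variants** — VCF I/O (pysam) and the GBS post-calling filter cascade
  (genotype depth ≥ 10; biallelic SNPs; complex events; MAF ≥ 0.01; locus
  missingness ≤ 10%; individual missingness ≤ 15%), plus seeded
  within-group binomial imputation.
- **popgen** — multilocus Weir–Cockerham θ (ratio of summed variance
  components) with a 5000-draw percentile bootstrap over loci and the
  "lower 95% CI ≥ 0.001" significance rule; the unadjusted Yang et al.
  genomic relationship A<sub>jk</sub> (≈0 unrelated, ≈1 self); observed /
  expected heterozygosity and F<sub>IS</sub> = 1 − H<sub>O</sub>/H<sub>E</sub>
  with an allele-permutation test; a moment inbreeding estimator with
  bootstrap CIs; Kruskal–Wallis + Dunn group comparisons; and a reduced
  Bayesian F<sub>ST</sub>-outlier scan (logit F<sub>ij</sub> = α<sub>i</sub> + β<sub>j</sub>,
  reversible-jump inclusion of locus effects).
- **structure** — PCA → k-means with an AIC surrogate
  (n·ln(WSS/n) + 2k) for the cluster number → discriminant analysis of
  principal components (DAPC) with k − 1 axes and Gaussian memberships;
  held-out cross-validation for the PC count; projection of spats onto the
  fitted model.
- **lagoonflow** — a divergence-free two-gyre lagoon circulation built from
  a streamfunction, with trade-wind modulation, a weak westward drift and
  depth shear; the desk-scale stand-in for a full hydrodynamic model.
- **dispersal** — Lagrangian larval transport (RK4 + random-walk diffusion
  + diel vertical migration), weekly release cohorts from each source site,
  and an hourly collector census (500 m radius, 25-day pelagic larval
  duration, first-entry counting) building source × collector connectivity
  matrices.
- **integrate** — aggregation of sources into stocks, a multinomial
  log-likelihood score confronting each cohort's connectivity matrix with
  the genetic assignment of collected spats, and the end-to-end pipeline.

## Worked example

```python
from atollconnect import integrate

result = integrate.run_pipeline(integrate.MasterConfig(seed=1), "run1")
print("loci retained:", result.manifest["n_loci_retained"])
print("clusters found:", result.manifest["best_k"])
print("spats assigned to the NE cluster:",
      float((result.spat_assignments == result.ne_cluster).mean()))
print("best-fitting cohort:", result.manifest["best_cohort"])
```

prints

```
loci retained: 993
clusters found: 2
spats assigned to the NE cluster: 1.0
best-fitting cohort: 6
```

meaning: of 1000 simulated loci, 993 survive filtering and the outlier
scan; unsupervised clustering finds the two simulated genetic clusters;
every collected spat (parented, in this scenario, by northeastern natural
adults) is genetically assigned to the northeastern cluster; and weekly
cohort 6 (0-indexed) of the larval-transport model best matches that
observed composition. `run1/` holds the per-stage artifacts: the simulated
VCF and metadata, the filter report, diversity / F<sub>ST</sub> /
relatedness tables, cluster assignments and memberships, per-cohort and
cumulated connectivity matrices, cohort scores and a manifest of seeds and
config hashes.

The same stages are exposed on the command line:

```sh
atollconnect popsim --out-vcf sim.vcf --out-meta meta.csv --seed 1
atollconnect filter --vcf sim.vcf --out-vcf filtered.vcf
atollconnect run --outdir run1 --seed 1
```

## Scope notes

The pipeline starts at a VCF: read processing, mapping and variant calling
are out of scope, as are real hydrodynamic forcing (tides, swell, reef-flat
fluxes) and mortality/growth during drift. See `docs/methods.md` for the
models, defaults and known limitations.
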