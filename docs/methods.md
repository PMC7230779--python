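# Methods

This note documents the models behind each stage, the defaults that matter,
and what the synthetic data do and do not establish.

## Genotype simulation (popsim)

Population divergence follows the hierarchical Balding–Nichols F-model.
Per locus, an ancestral frequency *p* is drawn uniformly on
`ancestral_freq_range` (default (0.05, 0.95), mimicking a MAF-filtered SNP
panel). Each of the two clusters draws a frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) with the between-cluster drift
`cluster_F` (default 0.05); each deme then draws around its cluster
frequency with its own within-cluster drift (default 0.005, i.e. 10×
smaller). F = 0 short-circuits the Beta draw; F = 1 is rejected as
degenerate. Genotypes are Binomial(2, p_deme) — Hardy–Weinberg within
demes, unlinked loci, no mutation or recombination model. Depth is
negative-binomial (mean 40, dispersion 5 — GBS-like overdispersion) and
genotypes are masked missing with probability 0.05, bracketing the ~4–5%
missingness a filtered GBS matrix carries.

Default demes: N2–N7 and E1–E6 (12), with N5–N7 forming cluster 1 (the
northeastern natural group) and everything else cluster 2; 20 individuals
per deme, 1000 loci. These sizes keep every statistic estimable while the
whole pipeline runs in about a minute on one core.

**Demography.** Sex is drawn from the protandry schedule — 0% female at age
1, 27% at 6, 41% from 8 on, linear in between, constant outside — so a
cohort's female fraction is exactly the schedule value in expectation. Ages
are uniform per stock: exploited 2–6 y (grafted near 3, killed between the
pearl harvest at 4.5 and a second-graft harvest at 6), northeastern natural
8–16 y (old, self-recruiting), southwestern natural 2–16 y (mixed). Real
deme age structures are unknown; these are free parameters, not estimates.
Shell length follows a von Bertalanffy curve (L∞ = 19.5 cm, K = 0.35,
t0 = −0.5 y) with 7% multiplicative lognormal noise, clipped to the 6–20 cm
dorso-ventral sampling window; spats are exempt. Exploited individuals are
recorded sex-`undetermined` with probability 0.1 (unreadable gonad
biopsies).

**Sweepstakes (SRS) cohorts.** A spat cohort draws `n_parents` (default 5)
adults from the source deme(s), redrawn (bounded) until both sexes are
present; each offspring takes one allele per locus from a random sire and a
random dam of the subset. Missing parental genotypes fall back to a draw
from the parental-pool frequency. One generation only; no pedigree beyond
it.

A consequence worth stating explicitly: one generation of Mendelian
offspring from *unrelated* parents has E[H_O] = 2pq regardless of how few
parents contribute, so a sweepstakes cohort shows strongly elevated
*relatedness* (mean pairwise A_jk rises from ≈0 to ≈0.2–0.5 as the parent
number falls) but its within-sample F_IS is slightly *negative*
(≈ −1/(2·n_parents), a family-structure artefact of the He reference), not
positive. The high spat F_IS seen in real collector samples reflects
standing relatedness accumulated over generations in the parental pool,
which a single-generation generator cannot produce; tests of the SRS
signature therefore certify the relatedness channel, and the F_IS
comparison against panmictic cohorts fails by design of the model scope.

## Variant filtering and imputation (variants)

The cascade runs in a fixed order: (1) genotypes with depth < 10 are set
missing (skipped with a warning if the VCF has no DP); (2) loci that are
not biallelic single-base SNPs are dropped; (3) loci flagged as complex
caller events are dropped — the flag comes from the VCF INFO `TYPE` field
when present, else from allele lengths, which keeps the stage meaningful
for records whose alleles look simple but whose caller annotation says
otherwise; (4) loci with minor allele frequency < 0.01, computed on
non-missing genotypes *after* depth masking, are dropped; (5) loci with
> 10% missing genotypes are dropped; (6) individuals with > 15% missing
genotypes on the surviving loci are dropped. Boundary values survive every
threshold. The report carries per-stage counts that must reconcile exactly
with input minus output, and the MAF-after-masking convention is stated in
its header notes.

Imputation replaces each missing genotype with a Binomial(2, p̂) draw from
the within-group (default: deme) non-missing allele frequency, falling
back to the global frequency for empty groups, with every imputed call
flagged. This is a deliberate, deterministic substitute for learned
(random-forest) imputation: it preserves group frequencies in expectation,
and a paired run shows multilocus F_ST moves by < 0.005 per pair — the
invariance that justified treating imputed and non-imputed datasets as
interchangeable downstream.

## Population statistics (popgen)

**F_ST.** Per-locus Weir–Cockerham (1984) variance components a (among
populations), b (among individuals within), c (within individuals), with
the multilocus estimate as the ratio of sums Σa / Σ(a+b+c) — not the mean
of ratios. Loci with undefined components (a population without data, mean
sample size ≤ 1, non-positive n_c) are skipped. The CI is a percentile
bootstrap resampling loci with replacement (default 5000 draws), and a
pair is "significantly differentiated" when the lower 95% bound does not
cross 0.001. Fixed differences give θ = 1 exactly; the estimator is
invariant to individual order and to ref/alt relabeling.

**Relatedness.** The unadjusted Yang et al. genomic relationship:
off-diagonal A_jk = mean_i (x_j−2p)(x_k−2p)/(2p(1−p)), diagonal
A_jj = 1 + mean_i (x_j²−(1+2p)x_j+2p²)/(2p(1−p)), frequencies from a
reference set (default: the matrix itself), fixed loci excluded, missing
calls excluded pairwise. Calibration: ≈1 on the diagonal, ≈0 off-diagonal
for unrelated individuals, ≈0.5 for parent–offspring and full sibs.

**Diversity and F_IS.** Per group, H_O is the heterozygote fraction and
H_E = 2p̂q̂·2n/(2n−1) (small-sample corrected — the correction is applied
and noted in output headers); F_IS = 1 − mean(H_O)/mean(H_E) over loci
polymorphic within the group. Significance is a two-sided permutation test
(default 999 draws) that shuffles alleles among the group's individuals
within each locus; with incomplete data the allele pool is first completed
by frequency draws (exact on imputed input, negligible otherwise).

**Individual inbreeding.** The published estimator name in the upstream
toolchain is ambiguous, so the package uses the transparent
method-of-moments form F̂ = 1 − (observed het count)/(Σ 2p̂q̂) over used
loci, with the 1000-draw bootstrap-over-loci percentile CI protocol
retained. Recovers simulated F within ±0.05 at 2000 loci.

**Group tests.** Kruskal–Wallis (scipy, tie-corrected) with hand-computed
Dunn pairwise z statistics (pooled-rank variance with tie term) and
Benjamini–Hochberg adjustment by default (the choice of adjustment is
configurable; none is canonical).

**Outlier scan.** A reduced Beaumont–Balding decomposition: alternate
allele counts per locus × population are beta-binomial with mean the
locus's ancestral frequency and dispersion F_ij, logit(F_ij) = α_i + β_j.
A reversible-jump move includes/excludes each locus effect α_i with prior
odds 10,000 for the neutral model (α ~ N(0,1), β ~ N(−2, 1.8) a priori);
the proposal for a newly included α is its prior, which reduces the
acceptance ratio to the likelihood ratio over the prior odds. Default
desk-scale chain: 5000 burn-in + 10,000 kept, thinned by 10; a split-chain
disagreement over 0.3 in inclusion probabilities flags non-convergence.
Loci at posterior inclusion ≥ 0.76 are flagged and removed before the
downstream statistics. This is a calibration-faithful reimplementation at
desk scale, not a parity port of any released scanner.

## Clustering and DAPC (structure)

PCA centers genotypes per locus (scaling optional) and decomposes by SVD;
axis signs are fixed by forcing each axis's largest-magnitude loading
positive so runs are bit-reproducible. k-means (10 restarts, seeded) runs
on the PCs covering 95% cumulative variance (configurable) for
k = 1..k_max, and the cluster number minimizes the k-means AIC surrogate
AIC(k) = n·ln(WSS_k/n) + 2k — the criterion is named but not specified
upstream, so this standard surrogate is documented in the output table.
DAPC is classical LDA on the first n_pca PC scores with the inferred
labels: at most k−1 discriminant axes, memberships from the
shared-covariance Gaussian posterior, ridge fallback on singular scatter.
The PC count can be chosen by repeated stratified holdout (default 10%
held out, 30 repetitions; ties go to the smaller count). Spats are
projected through the stored centering, loadings and discriminant model;
a locus-panel mismatch is an error, not a silent subset.

In the pipeline the model is fitted on adults only and spats are projected
onto it (train/test separation); the "northeastern" cluster label is
identified post hoc as the majority label among adults of the NE demes.

## Flow field (lagoonflow)

The lagoon is an ellipse (semi-axes 5.6 × 2.7 km) on a 100 m grid. All
velocities derive from a streamfunction by centered differences
(u = ∂ψ/∂y, v = −∂ψ/∂x), so the discrete divergence vanishes identically
(< 1e−10) off land. ψ is the sum of two Gaussian gyre lobes of opposite
sign (centers ±(2.4, 0.8) km, σ = 1.6 km, ψ0 = 250 m²/s) and a westward
drift term (0.03 m/s mid-lagoon), all multiplied by a smoothstep taper
that is exactly zero within one grid cell of land — land velocities are
exactly zero without breaking the divergence identity, and the return flow
of the closed basin concentrates along the shores. Gyre amplitude scales
linearly with the wind series (steady easterly trades, 6 m/s, a 1 m/s diel
component, and seeded episodic events), so doubling the wind doubles the
gyre velocities; speeds exceeding the 1 m/s cap rescale the whole field
with a warning. A multiplicative shear factor (1 at the surface, slope
0.02 per metre, floor 0.3) stands in for vertical structure. The field is
stored compactly (base gyre fields + hourly amplitudes) because it is
linear in the modulation; time interpolation is exactly amplitude
interpolation. NetCDF serialization uses the NetCDF3 (scipy) backend.

This construction keeps the connectivity-relevant features — two
circulation cells, predominantly east-to-west exchange, wind modulation —
and nothing else; tides, swell, reef-flat fluxes, temperature and salinity
are out of scope.

## Larval transport and census (dispersal)

Per source and weekly cohort (default 15 cohorts), larvae are released
uniformly in a 700 m square between 5 and 10 m depth (positions on land
are redrawn, bounded). Advection is RK4 on the sampled flow with a
Gaussian random-walk horizontal diffusion (K_h = 0.1 m²/s — a sub-grid
stirring surrogate, unstated upstream), with substep 6 min by default
(0.5 h in the pipeline default; the integrator order and substep are
implementation choices exposed in config). Depth relaxes toward a diel
target (12 m by day, 5 m by night, 1 h relaxation, 0.5 m noise) — a
parametric surrogate for observed nychthemeral migration. A substep that
would land on the mask is rejected (reflecting-wall at substep
resolution). States are saved hourly to match the census cadence.

The census checks every hourly state: a drifting larva whose age is within
[competency_min, pld_max] (defaults 0 and 25 days; the species' plausible
15–30 d range motivates the configurable floor) and whose horizontal
distance to a collector is ≤ 500 m is counted. Default counting is
first-entry-only — one count per particle, to the first (nearest)
collector reached, after which it is removed — so counts read as settlers
rather than residence time; a snapshot-sum mode that counts every hourly
co-location is provided for sensitivity. Counts accumulate into per-cohort
source × collector matrices; the cumulated matrix is their exact integer
sum. Particle bookkeeping (released = censused + expired + dropped) is
exact.

## Confrontation (integrate)

Sources aggregate into stocks (NE-natural = N5–N7, SW-natural = N1–N4,
exploited = E1–E6; N1 is a release source but was never genotyped, so it
maps to the southwestern group it sits in). Because genetic assignment
cannot distinguish southwestern-natural from exploited adults (they form
one cluster), the cohort fit uses the two-group aggregation cluster 1 =
NE-natural vs cluster 2 = everything else, while the three-group table is
kept for reporting. Each cohort is scored by the multinomial
log-likelihood of the observed per-collector spat assignment counts under
the cohort's predicted group proportions (additive pseudocount 0.5 so
empty routes stay defined); no fit statistic is canonical upstream, so
this simplest proper score is the default, with cosine similarity as an
alternative mode. Ties resolve to the smallest cohort index and are
flagged. Collectors with zero observed spats contribute nothing.

The pipeline runs every stage from one master seed (per-stage seeds are
spawned from it and recorded), writes all artifacts plus a manifest whose
hash changes iff any config field changes, and spreads the synthetic spats
over collectors round-robin before scoring. Desk-scale defaults — 12 demes
× 20 individuals, 1000 loci, 150 larvae per release and 15 weekly cohorts,
0.5 h substeps — complete the full run in about a minute on one core.

## What passing tests show, and what they do not

The synthetic world reproduces the *structure* of the study: two weakly
diverged clusters recoverable by unsupervised clustering, protandrous sex
ratios, SRS relatedness inflation, depth/missingness that exercises every
filter stage, and a two-cell circulation whose first-entry connectivity is
east-to-west biased in every seed. It does not emulate linkage, selection
(outside the spiked-locus checks), age-structured allele frequencies,
multigenerational pedigrees (hence no positive spat F_IS, see above),
larval mortality or behavior beyond diel migration, or real bathymetry and
forcing. Passing tests certify the estimators and the machinery at known
truth, not the field conclusions.

## Numerical choices

Bootstrap and permutation counts follow the stated protocols (5000 / 999 /
1000) except where a test scales them down for speed; percentile CIs
throughout. Genotype codes are int16 with −1 as missing; all estimators
mask rather than drop. Degenerate inputs raise informative errors
(monomorphic groups, empty filter output with the report attached,
all-same-sex parent subsets, locus-panel mismatches) rather than returning
silent NaNs. Every stochastic function takes an explicit seed or
Generator; identical seeds give bit-identical output.
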