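# Methods

This note documents the models, numerical choices and limitations behind
`laiconcord`, in the order the pipeline runs them.

## Synthetic cohort model

**Ancestry tracts.** Each individual draws a global ancestry proportion
vector `pi` once, from a Dirichlet prior attached to their "genetic analysis
group" (the defaults emulate a mainland-like group — high Amerindian — and a
Caribbean-like group — high African, both majority-European, with
concentration chosen so that between-individual proportion SD is roughly
0.1, typical of admixed Hispanic/Latino cohorts). Each haplotype is then a
Markov jump process along genetic distance: switch points arrive as a
Poisson process of rate `g` per Morgan (`g` = generations since admixture,
default 8) and the ancestry after each switch is drawn from `pi`,
self-transitions allowed. Consequences used by the tests:

* inter-switch tract lengths are Exponential(g) in Morgans;
* switch counts per haplotype are Poisson(g·L);
* the stationary ancestry fraction is `pi`.

The panel stores the inter-switch segments (self-transition boundaries are
genuine events of the process); `merge_adjacent_tracts` gives the observable
mosaic, in which runs of equal ancestry collapse. Physical and genetic
distance are related by a constant `cm_per_mb` (default 1); there is no
recombination-map heterogeneity, no interference, and no pedigree structure
in the tract process.

**Observation channels.** The interval channel reports, per haplotype per
fixed-width interval (on the *source* build), the majority-by-length
ancestry, ties broken toward the lowest ancestry index; diploid counts are
the sum over the two haplotypes. The SNP channel reports per-haplotype
ancestry at points on the *target* build (source position plus a constant
`build_shift_bp`), first passed through a row-stochastic relabeling
("leak") matrix — modelling systematic reference-panel effects such as
European calls leaking to Middle Eastern when extra reference populations
are added — and then through the miscall model. The miscall model replaces
a haplotype's label, with the locus's miscall rate, by a uniform draw over
the other K−1 ancestries; declared problem regions raise the rate locally
(emulating blacklist-like territory), and both channels see the same
regions. SNP records carry MAF ~ U(0, 0.5) and an imputation quality R2
drawn from a mixture with 10% missing (directly genotyped), 15% below 0.8
and 75% in [0.8, 1], so the QC filter has work to do. Counts in both
channels always sum to 2 per locus per individual by construction.

What the generator does **not** emulate: genotype/haplotype sequences and
allelic LD (the only dependence is the tract process), reference-panel
construction, inference-method-specific error correlation between the two
channels (channel errors are conditionally independent given the truth),
and X-chromosome dosage. Passing tests therefore demonstrate correctness of
the analysis machinery under a clean admixture model, not accuracy of any
real inference method.

**Phenotypes and design.** `y = X beta + gamma * g_causal + u_household +
u_block + u_kinship + eps`, where `g_causal` is the *true* diploid count of
the causal ancestry at a designated SNP. Covariates mimic a multi-center
cohort: age, sex, recruitment center, eGFR, genetic-analysis group and five
synthetic PCs. Households of size 1–3 nest inside census blocks (10
households per block); households of two or more are full sibships with
probability 0.5, giving a block-diagonal kinship matrix (0.5 diagonal, 0.25
between siblings). Random-effect covariances are `sigma_h^2 Z_h Z_h'`,
`sigma_b^2 Z_b Z_b'`, `sigma_k^2 * 2K` and `sigma_e^2 I`. Note that for
singletons `2K` is the identity, so with few sibships the kinship and
residual components are nearly confounded — an identifiability fact of the
design, visible as a flat REML surface between those two components at
small n, not a defect of the optimizer.

All randomness flows from one seed; each stage draws from a substream
derived as `default_rng([seed, stage_index])`, so stages are individually
reproducible and fixture files are byte-identical under a fixed seed.

## Coordinates, liftover and matching

Internally all coordinates are 0-based half-open; interval TSVs and VCF
positions are 1-based on disk. The liftover map is a list of monotone
equal-length source→target blocks. An interval wholly inside one block is
shifted by the block offset; intervals spanning a block boundary ("mapped
into more than one region"), covered by no block, or inside a block whose
target is a different chromosome are discarded and reported by reason, with
original coordinates retained for audit.

SNP-to-interval matching uses the closed-interval predicate (start ≤ pos ≤
end in 1-based terms). If intervals were to abut at a point the earlier
interval wins; the non-overlap invariant of the container makes this a
formality. QC keeps variants with MAF ≥ 0.005 and, *if imputed*, R2 ≥ 0.8;
variants with missing R2 are treated as directly genotyped and exempt from
the R2 cut (the stricter 0.95 re-run is a parameter change).

Per-pair Pearson correlations across individuals are undefined when either
count vector is constant (common at loci fixed for one ancestry); they are
recorded as missing and excluded from means and SDs — exclusion is the
standard convention. Summaries are per-pair (a SNP-dense interval
contributes many pairs); flagging uses r < 0.9 in *any* considered ancestry,
by default the three majors.

## Annotation enrichment

Distance is edge-to-edge gap on the same chromosome (overlap = 0;
cross-chromosome = infinite); a pair is assigned a class when the gap to the
nearest interval of that class is at most the proximity threshold
(default 0.5 Mb, inclusive — chosen because local ancestry LD extends over
megabases). Controls are sampled uniformly without replacement, at the pair
level, from pairs with r above 0.97 in all considered ancestries, matching
the flagged count. Class percentages use the group's mapped total as
denominator; the overall mapped percentage uses the group size. A 2×2
Fisher exact test (mapped × group) is available as a convenience.

## Null mixed model and score tests

REML estimates the variance components under non-negativity constraints
(L-BFGS-B on the profiled −2 restricted log-likelihood with analytic
gradients; outcome scaled to unit variance internally for conditioning;
`ftol` 1e-14 so refits agree to well below 1e-8). Components estimated at
the boundary (below 1e-6 of the outcome variance) are dropped and the model
refit — standard boundary handling. The combined random-effect covariance
is block-diagonal over the connected components of the household ∪ block ∪
kinship sparsity pattern; the implementation factorizes per component,
which is exact and makes n = 2000 fits take a fraction of a second under
the nested design above. A dense kinship matrix degrades gracefully to one
large block.

The score test needs only the null fit: `U = g' V^-1 (y − X beta_hat)`,
`Var(U) = g' P g` with `P` the REML projection, `U^2/Var(U)` referred to
chi-square with 1 df. Loci whose counts are constant or lie in the span of
the covariates give `Var(U) ≈ 0` and are flagged untestable (relative
tolerance 1e-8) rather than tested. Scans vectorize the solves over loci
and are deterministic. Tested ancestries default to African and Amerindian.

**Multiple testing.** Two simplified substitutes for a full test-statistic
family approximation are provided. (1) `bonferroni_effective`: a greedy walk
along each chromosome counts a new independent locus whenever the
correlation of local ancestry counts with the current anchor falls below
0.1, and the threshold is alpha divided by the count. Counts are first
centered per individual (equivalently, twice the individual's global
proportion is removed): without this, between-individual variation in
genome-wide ancestry keeps arbitrarily distant loci correlated and the
decay never registers — this is the same reason global proportions enter
published threshold methods for admixture mapping. (2) `permutation`:
residuals are permuted on the whitened scale. Writing `V = L L'`, the score
is `U_j = (L' P G_j)' e` with `e = L^{-1}(y − X beta_hat)` exchangeable
under the null, and `P V P = P` guarantees the permutation variance of
`U_j` equals `g_j' P g_j`; the threshold is the alpha-quantile of the
min-p distribution over B ≥ 100 permutations. Permuting *marginal*
residuals would be wrong here — their covariance is V, not exchangeable —
and measurably inflates the permutation statistics when random-effect
variance is present. The greedy rule is intentionally conservative (fewer
effective loci) relative to permutation; the two agree within an order of
magnitude in short-tract regimes and diverge when tracts are long relative
to the map, which is the expected behaviour of an r < 0.1 cut.

**Seven-ancestry scheme.** `collapse_ancestries` keeps the three majors and
sums the remaining ancestries into one "other" class; per-locus totals stay
2, and African/Amerindian test results are bitwise unchanged by collapse.

## Study conditions used by the test suite

Simulation sizes in the tests are chosen to make each law measurable, not
to mimic any particular dataset:

* Tract-law checks use a 20-Morgan chromosome so end-censoring of interior
  tracts is negligible at ≥ 5000 tracts.
* Null calibration uses n = 1000 and 2000 loci decorrelated by wide spacing
  (g = 60, 5 Mb between SNPs on long synthetic chromosomes): p-value
  uniformity and a (0.037, 0.064) band on the 5% type-I error are only
  meaningful for approximately independent tests.
* Parameter recovery fits the correctly specified household + residual
  model at n = 2000 over 50 replicates (true variances 2 and 1).
* Concordance-limit checks use noise-free channels with mean tract length
  250× the interval width, where discretization is the only disagreement.
* Enrichment detection uses a 0.3 miscall rate inside four problem regions
  (totalling about 5 Mb of a 110 Mb genome) against a zero base rate.
* Cross-channel mapping concordance runs 100 replicates at n = 400 on two
  chromosomes with a 0.5-SD-per-count causal effect; "same region" means
  the merged span (1 Mb gap tolerance) of loci passing the analytic
  threshold in either channel contains both channels' minima.

## Known limitations

* The tract process has no recombination-rate variation; genetic and
  physical distance are proportional.
* Channel errors are conditionally independent given the truth, so
  cross-channel correlation under noise is optimistic relative to two real
  inference methods sharing reference-panel biases.
* The effective-loci threshold is a deliberately simple substitute for a
  full extreme-value treatment of the score-statistic family.
* The liftover model is a monotone block map; real chain files with
  inversions or split alignments are out of scope.
* Variance-component SEs are not reported; the package's inferential
  surface is the score test, which needs only point estimates of the
  components.
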