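# laiconcord

Concordance analysis of two generations of local ancestry inference —
interval-based calls (RFMix-style, one diploid ancestry count per genomic
interval) versus SNP-level calls (FLARE-style, per-variant haplotype ancestry
codes) — together with the downstream admixture-mapping comparison, exercised
end-to-end on synthetic admixed cohorts.

## The problem

Admixed populations (for example Hispanic/Latino cohorts) carry genomes that
are mosaics of segments inherited from different ancestral populations. At a
locus, each individual carries 0, 1 or 2 chromosomal copies of a given
ancestry; admixture mapping regresses a phenotype on these diploid local
ancestry counts. When a cohort's local ancestry is re-inferred with a newer
method, a denser variant set, a different reference panel, or a different
genome build, every downstream result potentially changes. This package
provides the machinery to quantify that change:

1. **Global ancestry agreement.** From interval calls, the global proportion
   of ancestry *k* for an individual is length-weighted,
   `pi_k = sum_i len_i * c_ik / (2 * sum_i len_i)`; from SNP calls it is half
   the mean count, `pi_k = mean_j(c_jk) / 2`. Agreement between sources is
   summarized by per-ancestry Pearson correlations.
2. **Per-locus concordance.** Interval calls are lifted to the SNP build
   through a monotone block map (intervals mapped into more than one region,
   or onto a different chromosome, are discarded); each SNP is matched to the
   interval containing it (closed ends); and for every (SNP, interval,
   ancestry) triple the Pearson correlation of the two count vectors across
   individuals is computed. Pairs with r < 0.9 in any ancestry are flagged
   and merged into discordant regions.
3. **Annotation enrichment.** Flagged pairs are mapped — allowing up to
   0.5 Mb of proximity, because local ancestry has very long-range LD — to
   annotation classes (an ENCODE-style blacklist and gene-cluster track), and
   contrasted with an equal number of randomly sampled high-correlation
   (r > 0.97) control pairs.
4. **Admixture mapping.** A null linear mixed model
   `y = X beta + u_household + u_block + u_kinship + eps` is fitted by REML;
   each locus is then tested with the score statistic
   `U = g' V^-1 (y - X beta)`, `U^2 / Var(U) ~ chi2_1`, where `g` is the
   diploid count vector. Genome-wide thresholds come from an effective-loci
   Bonferroni rule (correlation-decay based) or residual permutation, and
   top hits are compared across channels and discovery/replication batches.

Real cohort data of this kind are access-restricted, so the package ships a
first-class synthetic cohort generator: diploid ancestry tracts from a
Poisson switch process (rate *g* per Morgan, *g* = generations since
admixture), two noisy observation channels on two coordinate builds,
region-localized elevated miscall rates, QC fields (MAF, imputation R2), and
phenotypes with household/census-block/kinship random effects.

## Worked example

```python
from laiconcord import *
from laiconcord.simulate import build_liftover_map

cfg = SimulationConfig(
    n_individuals=300, seed=7,
    chrom_lengths_bp=[80_000_000, 60_000_000],
    snp_spacing_bp=25_000, interval_width_bp=50_000,
    miscall_rate_intervals=0.01, miscall_rate_snps=0.01,
    problem_regions=[("chr1", 20_000_000, 22_000_000, 0.3)],
    phenotype=PhenotypeSpec(causal_chrom="chr1", causal_pos_bp=40_499_999,
                            causal_ancestry=1, effect_per_count=0.5),
)
panel = simulate_tracts(cfg)
intervals = observe_intervals(panel, cfg)
snps = observe_snps(panel, cfg)

snps_qc, qc = filter_snps(snps, maf_min=0.005, r2_min=0.8)
lifted, lift = apply_liftover(intervals, build_liftover_map(cfg))
pairs, rate = match_snps_to_intervals(snps_qc, lifted)
corr = pair_correlations(pairs, snps_qc, lifted)
overall, _ = genome_summary(corr)
flagged, frac = flag_low_pairs(corr, low_threshold=0.9)

tab = simulate_phenotype(panel, snps, cfg)
null = fit_null_model(tab)
scan_df = scan(null, snps_qc, ancestries=["African", "Amerindian"])
thr = significance_threshold(snps_qc, "bonferroni_effective")
```

prints (via the objects' reports):

```
kept 4721/5600 variants (84.30%); 61 failed MAF, 829 failed R2
2800 (100.00%) of 2800 intervals converted; 0 mapped into more than one region, ...
match rate 100.00%
  ancestry   mean_r     sd_r  n_pairs
   African 0.959105 0.082221     4721
Amerindian 0.961203 0.080827     4721
  European 0.961433 0.078130     4721
69 pairs (1.46%) below r=0.9 in some ancestry
threshold 3.57e-03 (M_eff=14); top hit chr1_40225000 (Amerindian) p=7.20e-08
```

Reading this: with a 1% per-haplotype miscall rate per channel the two call
sets agree at mean r around 0.96 per ancestry; 1.46% of matched pairs fall
below the r < 0.9 cut (concentrated in the declared problem region); and the
admixture-mapping scan of the SNP channel puts its minimum p-value
(7.2e-08, well past the multiple-testing threshold) about 0.3 Mb from the
simulated causal locus, driven by the simulated Amerindian-ancestry effect.

The same flow is available from the shell:

```bash
laiconcord run --config pipeline.yaml    # simulate -> QC -> liftover -> match
laiconcord report --out <output_dir>     #   -> correlate -> enrich -> map
```

plus per-stage subcommands (`simulate`, `filter`, `liftover`, `global`,
`concord`, `enrich`, `admixmap`).

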