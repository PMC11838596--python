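"""Generator laws and observation-channel behaviour of the synthetic cohort."""

import numpy as np
import pytest
from scipy import stats

import laiconcord.simulate as sim
from laiconcord import (
    ConfigurationError,
    PhenotypeSpec,
    SimulationConfig,
    observe_intervals,
    observe_snps,
    simulate_phenotype,
    simulate_tracts,
    write_fixture_set,
)


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        SimulationConfig(generations_g=0.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(chrom_lengths_bp=[])
    with pytest.raises(ConfigurationError):
        SimulationConfig(group_dirichlet_alphas=[[1.0, -1.0, 1.0]])
    with pytest.raises(ConfigurationError):
        SimulationConfig(snp_spacing_bp=1000, interval_width_bp=500)
    with pytest.raises(ConfigurationError):
        SimulationConfig(problem_regions=[("chr9", 0, 1000, 0.3)])
    with pytest.raises(ConfigurationError):
        SimulationConfig(leak_matrix=np.full((3, 3), 0.5))


def test_degenerate_proportions_give_single_ancestry_mosaic():
    """With all mass on one ancestry, every tract is that ancestry and the
    merged mosaic is a single tract per haplotype per chromosome."""
    cfg = SimulationConfig(
        n_individuals=5, seed=1, chrom_lengths_bp=[50_000_000],
        group_dirichlet_alphas=[[1e8, 1e-300, 1e-300]],
    )
    panel = simulate_tracts(cfg)
    for per_ind in panel.haplotypes["chr1"]:
        for breaks, anc in per_ind:
            assert np.all(anc == 0)
            mb, ma = sim.merge_adjacent_tracts(breaks, anc)
            assert len(mb) == 0 and len(ma) == 1


def test_switch_counts_follow_poisson_law():
    """Switch points per haplotype are Poisson(g * L_morgans): the mean over
    2000 haplotypes falls within 3 standard errors of the rate."""
    g, length = 8.0, 100_000_000  # 1 Morgan at 1 cM/Mb
    cfg = SimulationConfig(n_individuals=1000, seed=2, chrom_lengths_bp=[length],
                           generations_g=g)
    panel = simulate_tracts(cfg)
    counts = sim.switch_counts(panel)["chr1"]
    lam = g * 1.0
    se = np.sqrt(lam / len(counts))
    assert len(counts) == 2000
    assert abs(counts.mean() - lam) < 3 * se


def test_tract_lengths_are_exponential():
    """Interior tract lengths in Morgans pass a KS test against Exp(g)."""
    # long chromosome (20 Morgans) so end-censoring of interior gaps is
    # negligible relative to the mean tract length
    cfg = SimulationConfig(n_individuals=20, seed=3, chrom_lengths_bp=[2_000_000_000],
                           generations_g=8.0)
    panel = simulate_tracts(cfg)
    lengths = sim.tract_lengths_morgans(panel, cfg, interior_only=True)
    assert len(lengths) >= 5000
    res = stats.kstest(lengths, "expon", args=(0, 1 / cfg.generations_g))
    assert res.pvalue > 0.01


def test_stationary_fraction_matches_proportions():
    """Genome-wide ancestry fractions average to the common proportion vector."""
    target = np.array([0.2, 0.3, 0.5])
    cfg = SimulationConfig(
        n_individuals=500, seed=4, chrom_lengths_bp=[100_000_000, 100_000_000],
        generations_g=8.0, group_dirichlet_alphas=[(1e7 * target).tolist()],
    )
    panel = simulate_tracts(cfg)
    frac = sim.true_global_fractions(panel)
    mean = frac.mean(axis=0)
    se = frac.std(axis=0, ddof=1) / np.sqrt(len(frac))
    assert np.all(np.abs(mean - target) < 3 * se + 1e-3)


def test_noise_free_interval_channel_reproduces_spanning_tracts(clean_cohort):
    """Zero miscall: where one tract spans a whole interval on both haplotypes,
    the interval count is 2 for that ancestry; counts always sum to 2."""
    cfg, panel, intervals, _ = clean_cohort
    assert np.all(intervals.counts.sum(axis=2) == 2)
    # individual 0, find an interval fully inside tract 0 of both haplotypes
    chrom = "chr1"
    b0, a0 = panel.haplotypes[chrom][0][0]
    b1, a1 = panel.haplotypes[chrom][0][1]
    first_break = min(b0[0] if len(b0) else np.inf, b1[0] if len(b1) else np.inf)
    rows = np.flatnonzero((intervals.chroms == chrom) & (intervals.ends < first_break))
    assert len(rows) > 0
    expected = np.zeros(3, dtype=int)
    expected[a0[0]] += 1
    expected[a1[0]] += 1
    np.testing.assert_array_equal(intervals.counts[rows[0], 0], expected)


def test_problem_region_inflates_interval_discordance():
    """Inflated miscall inside a declared region raises the per-interval
    discordance vs truth relative to outside (one-sided Monte-Carlo check)."""
    region = ("chr1", 10_000_000, 14_000_000, 0.3)
    cfg = SimulationConfig(n_individuals=200, seed=5, chrom_lengths_bp=[40_000_000],
                           interval_width_bp=200_000, snp_spacing_bp=50_000,
                           miscall_rate_intervals=0.0, problem_regions=[region])
    panel = simulate_tracts(cfg)
    noisy = observe_intervals(panel, cfg)
    cfg_clean = SimulationConfig(**{**cfg.__dict__, "problem_regions": [],
                                    "leak_matrix": None, "group_dirichlet_alphas": None})
    clean = observe_intervals(panel, cfg_clean)
    mismatch = (noisy.counts != clean.counts).any(axis=2).mean(axis=1)
    inside = (noisy.starts >= region[1]) & (noisy.ends <= region[2])
    assert mismatch[inside].mean() > mismatch[~inside].mean()
    assert mismatch[~inside].mean() == 0.0


def test_leak_matrix_shifts_expected_counts():
    """A 10% European -> MiddleEastern leak reduces the mean European count by
    a factor of about 0.9 relative to truth."""
    k = 7
    leak = np.eye(k)
    leak[2, 2], leak[2, 6] = 0.9, 0.1
    cfg = SimulationConfig(
        n_individuals=300, seed=6, n_ancestries=k, chrom_lengths_bp=[30_000_000],
        snp_spacing_bp=100_000, interval_width_bp=100_000, leak_matrix=leak,
    )
    panel = simulate_tracts(cfg)
    snps = observe_snps(panel, cfg)
    cfg_id = SimulationConfig(**{**cfg.__dict__, "leak_matrix": None,
                                 "group_dirichlet_alphas": None})
    truth = observe_snps(panel, cfg_id)
    ratio = snps.counts[:, :, 2].sum() / truth.counts[:, :, 2].sum()
    assert 0.88 < ratio < 0.92
    assert np.all(snps.counts.sum(axis=2) == 2)


def test_noise_free_snp_channel_equals_truth(clean_cohort):
    """Identity leak and zero miscall: SNP counts equal the true ancestry
    at every position."""
    cfg, panel, _, snps = clean_cohort
    rng = np.random.default_rng(0)
    for idx in rng.choice(snps.n_snps, size=20, replace=False):
        chrom = snps.chroms[idx]
        src = snps.positions[idx] - cfg.build_shift_bp
        for ind in (0, 7):
            true = np.zeros(3, dtype=int)
            for hap in (0, 1):
                true[panel.ancestry_at(chrom, np.array([src]), ind, hap)[0]] += 1
            np.testing.assert_array_equal(snps.counts[idx, ind], true)


def test_negative_shift_drops_leading_snps():
    cfg = SimulationConfig(n_individuals=5, seed=7, chrom_lengths_bp=[10_000_000],
                           snp_spacing_bp=50_000, interval_width_bp=50_000,
                           build_shift_bp=-200_000)
    panel = simulate_tracts(cfg)
    snps = observe_snps(panel, cfg)
    assert snps.positions.min() >= 0
    assert snps.n_snps < 10_000_000 // 50_000


def test_phenotype_ols_recovery_in_degenerate_limit():
    """gamma=0 and zero random-effect variances: OLS on the generated design
    recovers the fixed effects within 3 standard errors."""
    import statsmodels.api as smf

    spec = PhenotypeSpec(var_household=0.0, var_block=0.0, var_kinship=0.0,
                         var_residual=1.0)
    cfg = SimulationConfig(n_individuals=1500, seed=8, chrom_lengths_bp=[10_000_000],
                           snp_spacing_bp=100_000, interval_width_bp=100_000,
                           phenotype=spec)
    panel = simulate_tracts(cfg)
    snps = observe_snps(panel, cfg)
    tab = simulate_phenotype(panel, snps, cfg)
    X = np.column_stack([
        np.ones(len(tab.data)), tab.data["age"], tab.data["sex"], tab.data["egfr"],
    ])
    fit = smf.OLS(tab.data["phenotype"].to_numpy(), X).fit()
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)
    for est, se, truth in [
        (params[1], bse[1], spec.beta_age),
        (params[2], bse[2], spec.beta_sex),
        (params[3], bse[3], spec.beta_egfr),
    ]:
        # center/group/pc effects are uncorrelated with these regressors in
        # expectation, so omitting them only inflates the residual
        assert abs(est - truth) < 4 * se


def test_phenotype_deterministic_limit_equals_causal_count():
    """All effects and variances zero except gamma=1: y equals the true
    diploid causal-ancestry count exactly."""
    spec = PhenotypeSpec(
        causal_chrom="chr1", causal_pos_bp=2_599_999, causal_ancestry=1,
        effect_per_count=1.0, beta_age=0, beta_sex=0, beta_egfr=0,
        beta_center=(0.0,), beta_group=(0.0,), beta_pcs=(0, 0, 0, 0, 0),
        var_household=0, var_block=0, var_kinship=0, var_residual=0,
    )
    cfg = SimulationConfig(n_individuals=50, seed=9, chrom_lengths_bp=[5_000_000],
                           snp_spacing_bp=100_000, interval_width_bp=100_000,
                           build_shift_bp=500_000, phenotype=spec)
    panel = simulate_tracts(cfg)
    snps = observe_snps(panel, cfg)
    tab = simulate_phenotype(panel, snps, cfg)
    np.testing.assert_allclose(tab.data["phenotype"], tab.causal_true_count)
    assert set(np.unique(tab.causal_true_count)) <= {0, 1, 2}


def test_household_intraclass_correlation():
    """Household variance 4, residual 1: ICC of household members ~ 0.8."""
    spec = PhenotypeSpec(beta_age=0, beta_sex=0, beta_egfr=0, beta_center=(0.0,),
                         beta_group=(0.0,), beta_pcs=(0, 0, 0, 0, 0),
                         var_household=4.0, var_block=0.0, var_kinship=0.0,
                         var_residual=1.0)
    cfg = SimulationConfig(n_individuals=3000, seed=10, chrom_lengths_bp=[2_000_000],
                           snp_spacing_bp=100_000, interval_width_bp=100_000,
                           phenotype=spec)
    panel = simulate_tracts(cfg)
    snps = observe_snps(panel, cfg)
    tab = simulate_phenotype(panel, snps, cfg)
    df = tab.data
    pairs_a, pairs_b = [], []
    for _, grp in df.groupby("household"):
        vals = grp["phenotype"].to_numpy()
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                pairs_a.append(vals[i])
                pairs_b.append(vals[j])
    r = np.corrcoef(pairs_a + pairs_b, pairs_b + pairs_a)[0, 1]  # symmetrized ICC
    assert abs(r - 0.8) < 0.05


def test_fixture_set_determinism(tmp_path):
    """Same seed -> byte-identical manifest; different seed -> different tracts."""
    def build(seed, where):
        cfg = SimulationConfig(n_individuals=20, seed=seed,
                               chrom_lengths_bp=[5_000_000],
                               snp_spacing_bp=100_000, interval_width_bp=100_000,
                               problem_regions=[("chr1", 1_000_000, 1_500_000, 0.2)])
        panel = simulate_tracts(cfg)
        ints = observe_intervals(panel, cfg)
        snps = observe_snps(panel, cfg)
        tab = simulate_phenotype(panel, snps, cfg)
        return write_fixture_set(where, cfg, ints, snps, tab), ints

    m1, _ = build(42, tmp_path / "a")
    m2, _ = build(42, tmp_path / "b")
    m3, ints3 = build(43, tmp_path / "c")
    assert {k: v["sha256"] for k, v in m1["files"].items()} == \
           {k: v["sha256"] for k, v in m2["files"].items()}
    assert m1["files"]["interval_calls.tsv"]["sha256"] != \
           m3["files"]["interval_calls.tsv"]["sha256"]
    assert m1["files"]["interval_calls.tsv"]["rows"] == 5_000_000 // 100_000
    assert m3["files"]["snp_calls.vcf"]["rows"] == ints3.n_intervals // 1  # same grid
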