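"""Null mixed model, score tests, thresholds and comparison tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laiconcord import (
    PhenotypeSpec,
    SimulationConfig,
    collapse_ancestries,
    compare_top_hits,
    fit_null_model,
    observe_snps,
    scan,
    score_test,
    significance_threshold,
    simulate_phenotype,
    simulate_tracts,
)
from laiconcord.admixmap import ModelError, encode_design

from conftest import make_snp_set, random_counts


def _cohort(seed=0, n=400, **pheno_kwargs):
    spec = PhenotypeSpec(**pheno_kwargs)
    cfg = SimulationConfig(n_individuals=n, seed=seed, chrom_lengths_bp=[20_000_000],
                           snp_spacing_bp=200_000, interval_width_bp=200_000,
                           phenotype=spec)
    panel = simulate_tracts(cfg)
    snps = observe_snps(panel, cfg)
    return cfg, panel, snps, simulate_phenotype(panel, snps, cfg)


def _ols_score_oracle(y, X, g):
    """Classic score test under V = sigma^2 I with REML sigma^2 = RSS/(n-p)."""
    n, p = X.shape
    H = X @ np.linalg.solve(X.T @ X, X.T)
    r = y - H @ y
    sigma2 = (r @ r) / (n - p)
    u = g @ r / sigma2
    var_u = (g @ g - g @ H @ g) / sigma2
    return u * u / var_u


def test_rank_deficient_design_names_collinear_columns():
    df = pd.DataFrame({"sample_id": list("abcd"), "phenotype": [1.0, 2, 3, 4],
                       "x1": [1.0, 2, 3, 4], "x2": [2.0, 4, 6, 8]})
    with pytest.raises(ModelError, match="x2|x1"):
        fit_null_model(df, covariates=["x1", "x2"], kinship=None,
                       household=None, block=None)


def test_non_psd_kinship_rejected():
    rng = np.random.default_rng(0)
    n = 30
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                       "phenotype": rng.normal(size=n), "x": rng.normal(size=n)})
    bad = np.eye(n) * 0.5
    bad[0, 1] = bad[1, 0] = 2.0   # negative eigenvalue
    with pytest.raises(ModelError, match="positive semi-definite"):
        fit_null_model(df, covariates=["x"], kinship=bad, household=None, block=None)


def test_null_fit_degenerates_to_ols_without_random_variance():
    """Data simulated with zero random-effect variances: fitted non-residual
    components vanish relative to the residual and the fixed effects match
    OLS within 1e-6."""
    _, _, _, tab = _cohort(seed=1, n=800, var_household=0.0, var_block=0.0,
                           var_kinship=0.0, var_residual=1.0)
    fit = fit_null_model(tab)
    resid = fit.variance_components["residual"]
    for comp in ("household", "block", "kinship"):
        assert fit.variance_components[comp] < 0.05 * resid
    X = fit._X
    beta_ols = np.linalg.lstsq(X, fit._y, rcond=None)[0]
    # components sit at (or within REML noise of) zero, so GLS ~ OLS; exact
    # 1e-8 agreement of the iid path is covered by the score-oracle test
    np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-4, rtol=1e-3)


def test_reml_refit_is_reproducible():
    _, _, _, tab = _cohort(seed=2, n=300)
    f1 = fit_null_model(tab)
    f2 = fit_null_model(tab)
    for k in f1.variance_components:
        assert abs(f1.variance_components[k] - f2.variance_components[k]) < 1e-8


def test_duplicated_rows_preserve_fixed_effects_in_iid_model():
    """Balanced duplication of all rows leaves the fixed effects of the
    independent-errors model exactly unchanged.  (With group random effects
    the GLS weights depend on group size, so only the iid case is an exact
    invariance.)"""
    _, _, _, tab = _cohort(seed=3, n=250, var_kinship=0.0)
    fit1 = fit_null_model(tab.data, kinship=None, household=None, block=None)
    dup = pd.concat([tab.data, tab.data], ignore_index=True)
    fit2 = fit_null_model(dup, kinship=None, household=None, block=None)
    np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-10)


def test_score_test_matches_ols_oracle_in_degenerate_limit():
    """With variance components at zero the score statistic equals the
    classic OLS score test to 1e-8."""
    rng = np.random.default_rng(4)
    for rep in range(3):
        n = 150
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "phenotype": rng.normal(size=n),
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
        })
        fit = fit_null_model(df, covariates=["x1", "x2"], kinship=None,
                             household=None, block=None)
        g = rng.integers(0, 3, size=n).astype(float)
        res = score_test(fit, g)
        oracle = _ols_score_oracle(df["phenotype"].to_numpy(), fit._X, g)
        assert abs(res.statistic - oracle) < 1e-8
        assert res.p_value == pytest.approx(stats.chi2.sf(oracle, 1))


def test_counts_in_covariate_span_are_untestable():
    rng = np.random.default_rng(5)
    n = 100
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                       "phenotype": rng.normal(size=n), "x1": rng.normal(size=n)})
    fit = fit_null_model(df, covariates=["x1"], kinship=None, household=None,
                         block=None)
    res = score_test(fit, df["x1"].to_numpy())
    assert not res.testable and np.isnan(res.p_value)
    res_const = score_test(fit, np.full(n, 2.0))
    assert not res_const.testable


def test_scan_is_deterministic_and_ordered():
    _, _, snps, tab = _cohort(seed=6, n=200)
    fit = fit_null_model(tab)
    s1 = scan(fit, snps)
    s2 = scan(fit, snps)
    pd.testing.assert_frame_equal(s1, s2)
    for _, grp in s1.groupby("ancestry"):
        assert grp["pos"].is_monotonic_increasing


def test_scan_localizes_causal_locus():
    """A strong causal effect puts the minimum p near the causal position."""
    causal = 10_499_999  # target-build position of a simulated SNP
    cfg, panel, snps, tab = _cohort(seed=7, n=500, causal_chrom="chr1",
                                    causal_pos_bp=causal, causal_ancestry=1,
                                    effect_per_count=1.0)
    fit = fit_null_model(tab)
    s = scan(fit, snps, ancestries=["Amerindian"])
    best = s.loc[s["p_value"].idxmin()]
    assert abs(best["pos"] - causal) <= 1_000_000  # within 1 cM
    assert best["p_value"] < 1e-6


def test_collapse_ancestries_rules():
    counts = np.zeros((2, 1, 7), dtype=np.int8)
    counts[0, 0, 2] = 1   # European
    counts[0, 0, 3] = 1   # CSAsian
    counts[1, 0, 0] = 2   # African
    labels = ["African", "Amerindian", "European", "CSAsian", "EAsian",
              "Oceanian", "MiddleEastern"]
    calls = make_snp_set(counts, ancestry_labels=labels)
    out = collapse_ancestries(calls)
    assert out.ancestry_labels == ["African", "Amerindian", "European", "other"]
    np.testing.assert_array_equal(out.counts[0, 0], [0, 0, 1, 1])
    np.testing.assert_array_equal(out.counts[1, 0], [2, 0, 0, 0])


def test_collapse_conserves_diploid_total_and_major_tests():
    rng = np.random.default_rng(8)
    counts = random_counts(rng, 50, 40, k=7)
    labels = ["African", "Amerindian", "European", "CSAsian", "EAsian",
              "Oceanian", "MiddleEastern"]
    calls = make_snp_set(counts, ancestry_labels=labels)
    out = collapse_ancestries(calls)
    assert np.all(out.counts.sum(axis=2) == 2)
    np.testing.assert_array_equal(out.counts[:, :, 0], calls.counts[:, :, 0])
    # score-test results on African/Amerindian are unchanged by the collapse
    df = pd.DataFrame({"sample_id": calls.sample_ids,
                       "phenotype": rng.normal(size=40), "x": rng.normal(size=40)})
    fit = fit_null_model(df, covariates=["x"], kinship=None, household=None,
                         block=None)
    s_full = scan(fit, calls, ancestries=["African", "Amerindian"])
    s_coll = scan(fit, out, ancestries=["African", "Amerindian"])
    pd.testing.assert_frame_equal(s_full, s_coll)


def test_effective_loci_threshold_in_independence_limit():
    """Independent loci: the effective-loci Bonferroni threshold is within a
    factor 1.5 of alpha / M."""
    rng = np.random.default_rng(9)
    m = 40
    calls = make_snp_set(random_counts(rng, m, 300))
    thr = significance_threshold(calls, "bonferroni_effective", alpha=0.05,
                                 ancestries=["African", "Amerindian"])
    assert 0.05 / (1.5 * m) <= thr.threshold <= 1.5 * 0.05 / m


def test_duplicated_loci_permutation_threshold_near_alpha():
    """Perfect dependence: permutation threshold approaches the single-locus
    alpha."""
    rng = np.random.default_rng(10)
    one = random_counts(rng, 1, 250)
    counts = np.tile(one, (30, 1, 1))
    calls = make_snp_set(counts)
    n = 250
    df = pd.DataFrame({"sample_id": calls.sample_ids,
                       "phenotype": rng.normal(size=n), "x": rng.normal(size=n)})
    fit = fit_null_model(df, covariates=["x"], kinship=None, household=None,
                         block=None)
    thr = significance_threshold(calls, "permutation", alpha=0.05,
                                 ancestries=["African"], null=fit, B=400, seed=1)
    assert 0.02 < thr.threshold < 0.09
    with pytest.raises(ValueError, match="B >= 100"):
        significance_threshold(calls, "permutation", ancestries=["African"],
                               null=fit, B=50)


def test_threshold_bracketing_on_simulated_genome():
    """Permutation and analytic thresholds agree within an order of magnitude
    and both land inside (alpha / M_total, alpha)."""
    # short-tract regime (g=30) where the correlation-decay estimator and the
    # permutation estimator both resolve the dependence structure
    spec = PhenotypeSpec()
    cfg = SimulationConfig(n_individuals=250, seed=11, generations_g=30.0,
                           chrom_lengths_bp=[100_000_000, 100_000_000],
                           snp_spacing_bp=2_000_000, interval_width_bp=2_000_000,
                           phenotype=spec)
    panel = simulate_tracts(cfg)
    snps = observe_snps(panel, cfg)
    tab = simulate_phenotype(panel, snps, cfg)
    fit = fit_null_model(tab)
    t_an = significance_threshold(snps, "bonferroni_effective")
    t_pm = significance_threshold(snps, "permutation", null=fit, B=300, seed=2)
    m_total = 2 * snps.n_snps
    for t in (t_an.threshold, t_pm.threshold):
        assert 0.05 / m_total < t < 0.05
    assert 0.1 < t_an.threshold / t_pm.threshold < 10


def test_compare_top_hits_enumeration_and_untestable_region():
    scan_df = pd.DataFrame({
        "chrom": ["chr1"] * 5 + ["chr2"],
        "pos": [10, 20, 30, 40, 50, 10],
        "end": [11, 21, 31, 41, 51, 11],
        "locus_id": [f"v{i}" for i in range(6)],
        "ancestry": "African",
        "statistic": [1.0, 9.0, 4.0, 9.0, 2.0, np.nan],
        "p_value": [0.3, 0.002, 0.04, 0.002, 0.2, np.nan],
        "direction": 1, "n": 100,
        "testable": [True] * 5 + [False],
    })
    regions = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                            "start": [0, 35, 0], "end": [35, 100, 100]})
    table = compare_top_hits({"snp/b1": scan_df}, regions)
    r0 = table[table["region"] == 0].iloc[0]
    assert r0["top_locus"] == "v1"  # argmin by enumeration
    r1 = table[table["region"] == 1].iloc[0]
    assert r1["top_locus"] == "v3"  # tie on p broken by position within region
    r2 = table[table["region"] == 2].iloc[0]
    assert bool(r2["all_untestable"]) and r2["top_locus"] is None


def test_score_invariant_under_affine_rescaling_of_outcome():
    """Rescaling y -> a*y + b and refitting leaves every score statistic
    unchanged (location-scale equivariance)."""
    _, _, snps, tab = _cohort(seed=12, n=200)
    fit = fit_null_model(tab)
    s1 = scan(fit, snps, ancestries=["African"])
    data2 = tab.data.copy()
    data2["phenotype"] = 3.5 * data2["phenotype"] - 7.0
    fit2 = fit_null_model(data2, kinship=tab.kinship)
    s2 = scan(fit2, snps, ancestries=["African"])
    np.testing.assert_allclose(s1["statistic"], s2["statistic"], rtol=1e-5, atol=1e-7)


def test_encode_design_encodes_categoricals():
    df = pd.DataFrame({"phenotype": [1.0, 2, 3, 4],
                       "center": pd.Categorical(["a", "b", "a", "c"]),
                       "age": [30.0, 40, 50, 60]})
    X, names = encode_design(df, ["age", "center"])
    assert X.shape == (4, 4)  # intercept + age + 2 center dummies
    assert names[0] == "intercept"
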