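import numpy as np
import pytest

from laiconcord import (
    IntervalCallSet,
    SimulationConfig,
    SnpCallSet,
    observe_intervals,
    observe_snps,
    simulate_tracts,
)


def make_interval_set(counts, sample_ids=None, ancestry_labels=None,
                      chrom="chr1", width=1000):
    """Toy interval call set from a (n_intervals, n_samples, K) count array."""
    counts = np.asarray(counts)
    n_int, n_samp, k = counts.shape
    return IntervalCallSet(
        np.full(n_int, chrom, dtype=object),
        np.arange(n_int) * width,
        (np.arange(n_int) + 1) * width,
        counts,
        sample_ids or [f"s{i}" for i in range(n_samp)],
        ancestry_labels or ["African", "Amerindian", "European"][:k],
    )


def make_snp_set(counts, positions=None, maf=None, r2=None, sample_ids=None,
                 ancestry_labels=None, chrom="chr1"):
    counts = np.asarray(counts)
    n_snp, n_samp, k = counts.shape
    positions = np.arange(n_snp) * 100 + 50 if positions is None else np.asarray(positions)
    return SnpCallSet(
        np.full(n_snp, chrom, dtype=object),
        positions,
        np.array([f"v{i}" for i in range(n_snp)], dtype=object),
        counts,
        np.full(n_snp, 0.3) if maf is None else np.asarray(maf, float),
        np.full(n_snp, 0.99) if r2 is None else np.asarray(r2, float),
        sample_ids or [f"s{i}" for i in range(n_samp)],
        ancestry_labels or ["African", "Amerindian", "European"][:k],
    )


def random_counts(rng, n_loci, n_samples, k=3):
    """Random valid diploid count tensor."""
    h1 = rng.integers(0, k, size=(n_loci, n_samples))
    h2 = rng.integers(0, k, size=(n_loci, n_samples))
    counts = np.zeros((n_loci, n_samples, k), dtype=np.int8)
    li = np.arange(n_loci)[:, None]
    si = np.arange(n_samples)[None, :]
    np.add.at(counts, (li, si, h1), 1)
    np.add.at(counts, (li, si, h2), 1)
    return counts


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free dual-channel cohort: tracts much longer than intervals."""
    cfg = SimulationConfig(
        n_individuals=200,
        seed=11,
        chrom_lengths_bp=[80_000_000, 60_000_000],
        generations_g=8.0,
        snp_spacing_bp=25_000,
        interval_width_bp=50_000,
        miscall_rate_intervals=0.0,
        miscall_rate_snps=0.0,
    )
    panel = simulate_tracts(cfg)
    return cfg, panel, observe_intervals(panel, cfg), observe_snps(panel, cfg)
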