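"""Synthetic admixed cohort generator.

Latent truth is a diploid ancestry tract mosaic per individual: each
haplotype is a realization of a Markov jump process along genetic distance,
with ancestry switch points arriving as a Poisson process of rate ``g`` per
Morgan (``g`` = generations since admixture) and each new ancestry drawn from
the individual's global proportion vector (self-transitions allowed).  This
is the standard Poisson-switch ("pool") admixture model assumed by admixture
mapping theory; tract lengths in Morgans are Exponential(g) and the
stationary ancestry fraction equals the individual's proportion vector.

Two noisy observation channels watch the same truth:

* an interval channel (RFMix-flavoured) on the SOURCE coordinate build:
  majority-by-length ancestry per haplotype per fixed-width interval, then a
  symmetric miscall model;
* a SNP channel (FLARE-flavoured) on the TARGET build (source + constant
  shift): per-haplotype ancestry at each SNP passed through an ancestry
  relabeling ("leak") matrix and then the miscall model, with simulated MAF
  and imputation-quality R2 fields so QC filtering is exercised.

Declared problem regions inflate the miscall rate locally in both channels,
emulating genomic territory where real inferences disagree.  Phenotypes add
a local-ancestry effect at a causal locus on top of fixed covariates and
household / census-block / kinship random effects mirroring a multi-center
household-sampled cohort design.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import AnnotationTrack, IntervalCallSet, LiftoverMap, SnpCallSet
from . import io as _io

logger = logging.getLogger(__name__)

MAJOR_ANCESTRIES = ["African", "Amerindian", "European"]
EXTRA_ANCESTRIES = ["CSAsian", "EAsian", "Oceanian", "MiddleEastern"]

# substream indices: every stage derives its generator as
# default_rng([seed, _STREAM[stage]]) so stages are independently reproducible
_STREAM = {"tracts": 0, "intervals": 1, "snps": 2, "phenotype": 3}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def default_ancestry_labels(k: int) -> list[str]:
    labels = MAJOR_ANCESTRIES + EXTRA_ANCESTRIES
    if k <= len(labels):
        return labels[:k]
    return labels + [f"anc{i}" for i in range(len(labels), k)]


@dataclass
class PhenotypeSpec:
    """Trait model: fixed covariates + causal local-ancestry effect + random effects.

    ``causal_pos_bp`` is a TARGET-build (SNP channel) 0-based position and
    must coincide with a simulated SNP; the causal effect acts on the TRUE
    diploid count of ``causal_ancestry`` at that position.  Variances are on
    the phenotype scale (residual variance 1 by default).
    """

    causal_chrom: str | None = None
    causal_pos_bp: int | None = None
    causal_ancestry: int = 1            # Amerindian by default
    effect_per_count: float = 0.0       # gamma, per diploid ancestry count
    intercept: float = 0.0
    beta_age: float = 0.01
    beta_sex: float = 0.3
    beta_egfr: float = -0.005
    beta_center: tuple[float, ...] = (0.0, 0.1, -0.1, 0.05)
    beta_group: tuple[float, ...] = (0.0, 0.2)
    beta_pcs: tuple[float, ...] = (0.1, 0.05, -0.05, 0.02, 0.02)
    var_household: float = 0.2
    var_block: float = 0.1
    var_kinship: float = 0.2
    var_residual: float = 1.0


@dataclass
class SimulationConfig:
    n_individuals: int = 500
    n_ancestries: int = 3
    # one Dirichlet alpha vector per "genetic analysis group": defaults mimic a
    # mainland-like (high Amerindian) and a Caribbean-like (high African) group
    group_dirichlet_alphas: list[list[float]] | None = None
    generations_g: float = 8.0
    chrom_lengths_bp: list[int] = field(default_factory=lambda: [80_000_000, 60_000_000])
    cm_per_mb: float = 1.0
    snp_spacing_bp: int = 20_000
    interval_width_bp: int = 100_000
    miscall_rate_intervals: float = 0.0
    miscall_rate_snps: float = 0.0
    leak_matrix: np.ndarray | None = None   # K x K row-stochastic; identity if None
    problem_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    build_shift_bp: int = 500_000
    mean_household_size: float = 2.0        # household sizes drawn from {1,2,3}
    households_per_block: int = 10
    sib_household_prob: float = 0.5
    phenotype: PhenotypeSpec = field(default_factory=PhenotypeSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_ancestries
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        if k < 2:
            raise ConfigurationError("need at least two ancestries")
        if self.generations_g <= 0:
            raise ConfigurationError("generations_g must be positive")
        if not self.chrom_lengths_bp:
            raise ConfigurationError("chrom_lengths_bp must be non-empty")
        if self.group_dirichlet_alphas is None:
            if k == 3:
                self.group_dirichlet_alphas = [[2.0, 8.0, 10.0], [7.0, 2.0, 11.0]]
            else:
                base = [2.0, 8.0, 10.0] + [0.3] * (k - 3)
                alt = [7.0, 2.0, 11.0] + [0.3] * (k - 3)
                self.group_dirichlet_alphas = [base, alt]
        for alphas in self.group_dirichlet_alphas:
            if len(alphas) != k or any(a <= 0 for a in alphas):
                raise ConfigurationError("each Dirichlet alpha vector must be K positive reals")
        if self.leak_matrix is None:
            self.leak_matrix = np.eye(k)
        self.leak_matrix = np.asarray(self.leak_matrix, dtype=float)
        if self.leak_matrix.shape != (k, k) or not np.allclose(self.leak_matrix.sum(axis=1), 1.0):
            raise ConfigurationError("leak_matrix must be K x K row-stochastic")
        if not (0 <= self.miscall_rate_intervals < 1 and 0 <= self.miscall_rate_snps < 1):
            raise ConfigurationError("miscall rates must lie in [0, 1)")
        if self.interval_width_bp < self.snp_spacing_bp:
            raise ConfigurationError("interval_width_bp must be >= snp_spacing_bp")
        lengths = dict(zip(self.chrom_names, self.chrom_lengths_bp))
        for chrom, start, end, rate in self.problem_regions:
            if chrom not in lengths or start < 0 or end > lengths[chrom] or start >= end:
                raise ConfigurationError(f"problem region {(chrom, start, end)} outside genome")
            if not (0 <= rate < 1):
                raise ConfigurationError("inflated miscall rate must lie in [0, 1)")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths_bp))]

    @property
    def ancestry_labels(self) -> list[str]:
        return default_ancestry_labels(self.n_ancestries)

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stage]])


@dataclass
class TrueAncestryPanel:
    """Latent diploid ancestry tract mosaic both observation channels share.

    ``haplotypes[chrom][ind][hap]`` is a pair ``(breaks_bp, ancestry)``:
    sorted internal tract boundaries (0-based bp) and the per-tract ancestry
    indices (length ``len(breaks_bp) + 1``).  Tracts are contiguous and tile
    each chromosome exactly; coordinates are on the SOURCE build.
    """

    chrom_lengths: dict[str, int]
    haplotypes: dict[str, list[tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]]]
    proportions: np.ndarray       # (n, K) drawn per-individual global proportions
    groups: np.ndarray            # (n,) genetic-analysis-group index
    sample_ids: list[str]
    ancestry_labels: list[str]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def ancestry_at(self, chrom: str, positions: np.ndarray, ind: int, hap: int) -> np.ndarray:
        breaks, anc = self.haplotypes[chrom][ind][hap]
        return anc[np.searchsorted(breaks, positions, side="right")]

    def diploid_count_at(self, chrom: str, position: int, ancestry: int) -> np.ndarray:
        """True diploid count of one ancestry at one position, over individuals."""
        pos = np.asarray([position])
        out = np.zeros(self.n_individuals, dtype=np.int8)
        for ind in range(self.n_individuals):
            for hap in (0, 1):
                out[ind] += self.ancestry_at(chrom, pos, ind, hap)[0] == ancestry
        return out


def simulate_tracts(config: SimulationConfig) -> TrueAncestryPanel:
    """Draw the latent ancestry tract mosaic for the whole cohort."""
    rng = config.stage_rng("tracts")
    n, k = config.n_individuals, config.n_ancestries
    alphas = np.asarray(config.group_dirichlet_alphas, dtype=float)
    groups = rng.integers(0, len(alphas), size=n)
    proportions = np.empty((n, k))
    for g_idx in range(len(alphas)):
        mask = groups == g_idx
        proportions[mask] = rng.dirichlet(alphas[g_idx], size=int(mask.sum()))

    bp_per_morgan = 1e8 / config.cm_per_mb
    haplotypes: dict[str, list] = {}
    for chrom, length in zip(config.chrom_names, config.chrom_lengths_bp):
        length_m = length / bp_per_morgan
        lam = config.generations_g * length_m
        per_chrom = []
        for ind in range(n):
            pi = proportions[ind]
            haps = []
            for _ in range(2):
                n_switch = rng.poisson(lam)
                breaks_m = np.sort(rng.uniform(0.0, length_m, size=n_switch))
                breaks = np.unique((breaks_m * bp_per_morgan).astype(np.int64))
                breaks = breaks[(breaks > 0) & (breaks < length)]
                anc = rng.choice(k, size=len(breaks) + 1, p=pi).astype(np.int8)
                haps.append((breaks, anc))
            per_chrom.append(tuple(haps))
        haplotypes[chrom] = per_chrom

    return TrueAncestryPanel(
        chrom_lengths=dict(zip(config.chrom_names, config.chrom_lengths_bp)),
        haplotypes=haplotypes,
        proportions=proportions,
        groups=groups,
        sample_ids=[f"ind{i:04d}" for i in range(n)],
        ancestry_labels=config.ancestry_labels,
    )


def true_global_fractions(panel: TrueAncestryPanel) -> np.ndarray:
    """Genome-wide length-weighted ancestry fraction per individual from truth."""
    n, k = panel.n_individuals, len(panel.ancestry_labels)
    acc = np.zeros((n, k))
    total = 0
    for chrom, length in panel.chrom_lengths.items():
        total += 2 * length
        for ind in range(n):
            for hap in (0, 1):
                breaks, anc = panel.haplotypes[chrom][ind][hap]
                edges = np.concatenate([[0], breaks, [length]])
                seg = np.diff(edges)
                np.add.at(acc[ind], anc, seg)
    return acc / total


def tract_lengths_morgans(panel: TrueAncestryPanel, config: SimulationConfig,
                          interior_only: bool = True) -> np.ndarray:
    """Pooled tract lengths (Morgans).  Interior tracts exclude the chromosome-end
    censored segments and are Exponential(g) distributed."""
    bp_per_morgan = 1e8 / config.cm_per_mb
    out = []
    for chrom, length in panel.chrom_lengths.items():
        for per_ind in panel.haplotypes[chrom]:
            for breaks, _anc in per_ind:
                edges = np.concatenate([[0], breaks, [length]])
                seg = np.diff(edges)
                out.append(seg[1:-1] if interior_only and len(seg) > 2 else seg[:0])
    return np.concatenate(out) / bp_per_morgan if out else np.empty(0)


def merge_adjacent_tracts(breaks: np.ndarray, anc: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse adjacent tracts sharing an ancestry (self-transition switches
    are genuine events of the jump process but invisible in the mosaic)."""
    if len(anc) <= 1:
        return breaks, anc
    keep = np.flatnonzero(np.diff(anc) != 0)
    return breaks[keep], anc[np.r_[keep, len(anc) - 1]]


def switch_counts(panel: TrueAncestryPanel) -> dict[str, np.ndarray]:
    """Number of ancestry switch points per haplotype, by chromosome."""
    return {
        chrom: np.array([len(hap[0]) for per_ind in panel.haplotypes[chrom] for hap in per_ind])
        for chrom in panel.chrom_lengths
    }


# ---------------------------------------------------------------------------
# observation channels
# ---------------------------------------------------------------------------


def _locus_rates(chroms, starts, ends, base_rate, problem_regions) -> np.ndarray:
    """Per-locus miscall rate: base, or the inflated rate inside a problem region
    (any overlap; the maximum applies when regions overlap each other)."""
    rates = np.full(len(chroms), float(base_rate))
    for chrom, r_start, r_end, r_rate in problem_regions:
        hit = (chroms == chrom) & (starts < r_end) & (ends > r_start)
        rates[hit] = np.maximum(rates[hit], r_rate)
    return rates


def _apply_miscall(labels: np.ndarray, rates: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    """With the locus rate, replace a haplotype label by a uniform draw over the
    other K-1 ancestries.  ``labels``: (n_loci, ...), ``rates``: (n_loci,)."""
    shape = labels.shape
    flip = rng.uniform(size=shape) < rates.reshape((-1,) + (1,) * (labels.ndim - 1))
    if not flip.any():
        return labels
    out = labels.copy()
    shifts = rng.integers(1, k, size=int(flip.sum()))
    out[flip] = (out[flip] + shifts) % k
    return out


def observe_intervals(panel: TrueAncestryPanel, config: SimulationConfig) -> IntervalCallSet:
    """Interval channel: majority-by-length diploid counts on the SOURCE build."""
    rng = config.stage_rng("intervals")
    n, k = panel.n_individuals, config.n_ancestries
    width = config.interval_width_bp

    all_chroms, all_starts, all_ends, all_major = [], [], [], []
    for chrom, length in panel.chrom_lengths.items():
        n_int = length // width
        edges = np.arange(n_int + 1, dtype=np.int64) * width
        majority = np.empty((n_int, n, 2), dtype=np.int8)
        for ind in range(n):
            for hap in (0, 1):
                breaks, anc = panel.haplotypes[chrom][ind][hap]
                pts = np.union1d(edges, breaks[(breaks > 0) & (breaks < edges[-1])])
                seg_len = np.diff(pts)
                seg_int = (pts[:-1] // width).astype(np.int64)
                seg_anc = anc[np.searchsorted(breaks, pts[:-1], side="right")]
                overlap = np.zeros((n_int, k))
                np.add.at(overlap, (seg_int, seg_anc), seg_len)
                majority[:, ind, hap] = np.argmax(overlap, axis=1)  # ties -> lowest index
        all_chroms.append(np.full(n_int, chrom, dtype=object))
        all_starts.append(edges[:-1])
        all_ends.append(edges[1:])
        all_major.append(majority)

    chroms = np.concatenate(all_chroms)
    starts = np.concatenate(all_starts)
    ends = np.concatenate(all_ends)
    majority = np.concatenate(all_major, axis=0)

    rates = _locus_rates(chroms, starts, ends, config.miscall_rate_intervals,
                         config.problem_regions)
    majority = _apply_miscall(majority, rates, k, rng)

    counts = np.zeros((len(chroms), n, k), dtype=np.int8)
    loci = np.arange(len(chroms))[:, None]
    inds = np.arange(n)[None, :]
    for hap in (0, 1):
        np.add.at(counts, (loci, inds, majority[:, :, hap]), 1)
    return IntervalCallSet(chroms, starts, ends, counts, list(panel.sample_ids),
                           list(panel.ancestry_labels))


def _apply_leak(labels: np.ndarray, leak: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if np.allclose(leak, np.eye(len(leak))):
        return labels
    out = labels.copy()
    for a in range(len(leak)):
        mask = labels == a
        if mask.any():
            out[mask] = rng.choice(len(leak), size=int(mask.sum()), p=leak[a])
    return out


def observe_snps(panel: TrueAncestryPanel, config: SimulationConfig) -> SnpCallSet:
    """SNP channel: per-haplotype calls on the TARGET build (source + shift)."""
    rng = config.stage_rng("snps")
    n, k = panel.n_individuals, config.n_ancestries
    spacing, shift = config.snp_spacing_bp, config.build_shift_bp

    all_chroms, all_pos_src, all_haps = [], [], []
    for chrom, length in panel.chrom_lengths.items():
        pos_src = np.arange(1, length // spacing + 1, dtype=np.int64) * spacing - 1
        keep = pos_src + shift >= 0
        if not keep.all():
            logger.warning("%s: dropping %d SNPs shifted below position 1",
                           chrom, int((~keep).sum()))
        pos_src = pos_src[keep]
        haps = np.empty((2, len(pos_src), n), dtype=np.int8)
        for ind in range(n):
            for hap in (0, 1):
                haps[hap, :, ind] = panel.ancestry_at(chrom, pos_src, ind, hap)
        all_chroms.append(np.full(len(pos_src), chrom, dtype=object))
        all_pos_src.append(pos_src)
        all_haps.append(haps)

    chroms = np.concatenate(all_chroms)
    pos_src = np.concatenate(all_pos_src)
    haps = np.concatenate(all_haps, axis=1)

    for hap in (0, 1):
        haps[hap] = _apply_leak(haps[hap], config.leak_matrix, rng)
    rates = _locus_rates(chroms, pos_src, pos_src + 1, config.miscall_rate_snps,
                         config.problem_regions)
    for hap in (0, 1):
        haps[hap] = _apply_miscall(haps[hap], rates, k, rng)

    n_snps = len(chroms)
    counts = np.zeros((n_snps, n, k), dtype=np.int8)
    loci = np.arange(n_snps)[:, None]
    inds = np.arange(n)[None, :]
    for hap in (0, 1):
        np.add.at(counts, (loci, inds, haps[hap]), 1)

    maf = rng.uniform(0.0, 0.5, size=n_snps)
    mix = rng.uniform(size=n_snps)
    r2 = np.where(mix < 0.25, rng.uniform(0.3, 0.8, size=n_snps),
                  rng.uniform(0.8, 1.0, size=n_snps))
    r2[mix < 0.10] = np.nan  # directly genotyped, no imputation quality

    positions = pos_src + shift
    variant_ids = np.array([f"{c}_{p + 1}" for c, p in zip(chroms, positions)], dtype=object)
    return SnpCallSet(chroms, positions, variant_ids, counts, maf, r2,
                      list(panel.sample_ids), list(panel.ancestry_labels), haps=haps)


# ---------------------------------------------------------------------------
# phenotype, design and kinship
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Phenotype + covariates + grouping factors, with the kinship matrix.

    ``kinship`` follows the usual convention (0.5 on the diagonal, 0.25 for
    full siblings); model covariances use 2 x kinship.
    """

    data: pd.DataFrame
    kinship: np.ndarray
    causal_true_count: np.ndarray | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])


def _draw_design(n: int, config: SimulationConfig, rng: np.random.Generator):
    sizes = []
    total = 0
    while total < n:
        s = int(rng.choice([1, 2, 3], p=[0.45, 0.35, 0.20]))
        sizes.append(s)
        total += s
    sizes[-1] -= total - n
    household = np.repeat(np.arange(len(sizes)), sizes)
    block = household // config.households_per_block
    is_sib_household = rng.uniform(size=len(sizes)) < config.sib_household_prob
    kinship = np.eye(n) * 0.5
    start = 0
    for h, s in enumerate(sizes):
        if s >= 2 and is_sib_household[h]:
            idx = np.arange(start, start + s)
            kinship[np.ix_(idx, idx)] = 0.25
            kinship[idx, idx] = 0.5
        start += s
    return household, block, kinship


def simulate_phenotype(panel: TrueAncestryPanel, snps: SnpCallSet,
                       config: SimulationConfig) -> PhenotypeTable:
    """Draw phenotypes for the cohort the SNP channel observes."""
    spec = config.phenotype
    rng = config.stage_rng("phenotype")
    n = panel.n_individuals
    if snps.sample_ids != panel.sample_ids:
        raise ConfigurationError("snp call set and panel carry different samples")

    causal_count = None
    genetic = np.zeros(n)
    if spec.causal_chrom is not None:
        mask = (snps.chroms == spec.causal_chrom) & (snps.positions == spec.causal_pos_bp)
        if not mask.any():
            raise ConfigurationError(
                f"causal locus {spec.causal_chrom}:{spec.causal_pos_bp} not among simulated SNPs"
            )
        src_pos = int(spec.causal_pos_bp) - config.build_shift_bp
        causal_count = panel.diploid_count_at(spec.causal_chrom, src_pos,
                                              spec.causal_ancestry).astype(float)
        genetic = spec.effect_per_count * causal_count

    age = rng.normal(46.0, 14.0, size=n)
    sex = rng.binomial(1, 0.6, size=n).astype(float)
    center = rng.integers(0, len(spec.beta_center), size=n)
    egfr = rng.normal(108.0, 26.6, size=n)
    pcs = rng.normal(0.0, 1.0, size=(n, len(spec.beta_pcs)))
    group = panel.groups % len(spec.beta_group)

    household, block, kinship = _draw_design(n, config, rng)

    fixed = (
        spec.intercept
        + spec.beta_age * age
        + spec.beta_sex * sex
        + spec.beta_egfr * egfr
        + np.asarray(spec.beta_center)[center]
        + np.asarray(spec.beta_group)[group]
        + pcs @ np.asarray(spec.beta_pcs)
    )

    u_house = np.sqrt(spec.var_household) * rng.normal(size=household.max() + 1)
    u_block = np.sqrt(spec.var_block) * rng.normal(size=block.max() + 1)
    # relatedness 2*kinship = 0.5 I + 0.5 J within sibships: simulate as an
    # individual part plus a shared-per-sibship part, both unit variance
    z_ind = rng.normal(size=n)
    z_shared = rng.normal(size=n)
    rel2 = 2 * kinship
    w = z_ind.copy()
    visited = np.zeros(n, bool)
    for i in range(n):
        if visited[i]:
            continue
        members = np.flatnonzero(rel2[i] > 0)
        visited[members] = True
        if len(members) > 1:
            w[members] = np.sqrt(0.5) * z_ind[members] + np.sqrt(0.5) * z_shared[members[0]]
    u_kin = np.sqrt(spec.var_kinship) * w

    eps = np.sqrt(spec.var_residual) * rng.normal(size=n)
    y = fixed + genetic + u_house[household] + u_block[block] + u_kin + eps

    data = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "phenotype": y,
            "age": age,
            "sex": sex,
            "center": pd.Categorical([f"center{c}" for c in center]),
            "group": pd.Categorical([f"group{g}" for g in group]),
            "egfr": egfr,
            **{f"pc{i + 1}": pcs[:, i] for i in range(pcs.shape[1])},
            "household": household,
            "block": block,
        }
    )
    return PhenotypeTable(data=data, kinship=kinship, causal_true_count=causal_count)


# ---------------------------------------------------------------------------
# annotations and liftover map derived from the configuration
# ---------------------------------------------------------------------------


def problem_region_track(config: SimulationConfig) -> AnnotationTrack:
    """Problem regions as a TARGET-build annotation track, classes alternating
    blacklist / gene_cluster in declaration order."""
    chroms, starts, ends, classes = [], [], [], []
    for i, (chrom, start, end, _rate) in enumerate(config.problem_regions):
        chroms.append(chrom)
        starts.append(max(0, start + config.build_shift_bp))
        ends.append(end + config.build_shift_bp)
        classes.append("blacklist" if i % 2 == 0 else "gene_cluster")
    return AnnotationTrack(np.asarray(chroms, object), np.asarray(starts, np.int64),
                           np.asarray(ends, np.int64), np.asarray(classes, object))


def build_liftover_map(config: SimulationConfig, block_bp: int | None = None) -> LiftoverMap:
    """Monotone source->target map shifting every block by ``build_shift_bp``.

    ``block_bp`` splits chromosomes into equal blocks (boundaries that do not
    align with the interval grid produce realistic straddle discards); the
    default single block per chromosome converts everything.
    """
    src_c, src_s, src_e, dst_c, dst_s, dst_e = [], [], [], [], [], []
    shift = config.build_shift_bp
    for chrom, length in zip(config.chrom_names, config.chrom_lengths_bp):
        if block_bp is None:
            bounds = [0, length]
        else:
            bounds = list(range(0, length, block_bp)) + [length]
        for a, b in zip(bounds[:-1], bounds[1:]):
            src_c.append(chrom)
            src_s.append(a)
            src_e.append(b)
            dst_c.append(chrom)
            dst_s.append(a + shift)
            dst_e.append(b + shift)
    return LiftoverMap(np.asarray(src_c, object), np.asarray(src_s), np.asarray(src_e),
                       np.asarray(dst_c, object), np.asarray(dst_s), np.asarray(dst_e))


# ---------------------------------------------------------------------------
# fixture serialization
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["leak_matrix"] = np.asarray(config.leak_matrix).tolist()
    d["problem_regions"] = [list(r) for r in config.problem_regions]
    return d


def write_fixture_set(
    directory: str | os.PathLike,
    config: SimulationConfig,
    intervals: IntervalCallSet,
    snps: SnpCallSet,
    phenotypes: PhenotypeTable,
    annotations: AnnotationTrack | None = None,
    liftover: LiftoverMap | None = None,
) -> dict:
    """Serialize every channel plus config and seed; same seed -> identical bytes."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    if annotations is None:
        annotations = problem_region_track(config)
    if liftover is None:
        liftover = build_liftover_map(config)

    files: dict[str, dict] = {}

    def record(name: str, rows: int) -> None:
        path = os.path.join(directory, name)
        files[name] = {"rows": int(rows), "sha256": _sha256(path)}

    _io.write_interval_calls(intervals, os.path.join(directory, "interval_calls.tsv"))
    record("interval_calls.tsv", intervals.n_intervals)
    _io.write_snp_calls(snps, os.path.join(directory, "snp_calls.vcf"), dialect="vcf")
    record("snp_calls.vcf", snps.n_snps)
    _io.write_annotations(annotations, os.path.join(directory, "annotations.bed"))
    record("annotations.bed", annotations.n_intervals)
    _io.write_liftover_map(liftover, os.path.join(directory, "liftover_map.tsv"))
    record("liftover_map.tsv", liftover.n_blocks)
    phenotypes.data.to_csv(os.path.join(directory, "phenotypes.tsv"), sep="\t", index=False,
                           float_format="%.10g")
    record("phenotypes.tsv", len(phenotypes.data))
    pd.DataFrame(phenotypes.kinship).to_csv(os.path.join(directory, "kinship.tsv"), sep="\t",
                                            index=False, header=False, float_format="%.10g")
    record("kinship.tsv", phenotypes.kinship.shape[0])
    with open(os.path.join(directory, "config.yaml"), "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)
    record("config.yaml", 1)

    manifest = {"seed": config.seed, "files": files}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
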