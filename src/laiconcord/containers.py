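"""Core in-memory containers shared by every pipeline stage.

Diploid local ancestry is represented as an integer count tensor of shape
``(n_loci, n_samples, n_ancestries)`` whose entries lie in {0, 1, 2} and sum
to 2 over the ancestry axis at every (locus, individual) cell — one count per
chromosomal copy.  All genomic coordinates are held 0-based half-open
internally; 1-based closed conventions appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """A file or object violates a structural invariant of the data model."""


def _as_str_array(values) -> np.ndarray:
    return np.asarray(values, dtype=object)


def _check_counts(counts: np.ndarray, what: str) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValidationError(f"{what}: counts must be 3-d (locus, sample, ancestry)")
    if counts.size:
        if counts.min() < 0 or counts.max() > 2:
            bad = np.argwhere((counts < 0) | (counts > 2))[0]
            raise ValidationError(f"{what}: count outside {{0,1,2}} at locus {bad[0]}, sample {bad[1]}")
        sums = counts.sum(axis=2)
        if not np.all(sums == 2):
            bad = np.argwhere(sums != 2)[0]
            raise ValidationError(
                f"{what}: ancestry counts do not sum to 2 at locus {bad[0]}, sample {bad[1]}"
            )
    return counts.astype(np.int8, copy=False)


def _check_sorted_disjoint(chroms, starts, ends, what: str) -> None:
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    if np.any(starts >= ends):
        bad = int(np.argmax(starts >= ends))
        raise ValidationError(f"{what}: empty or inverted interval at row {bad}")
    for chrom in dict.fromkeys(chroms):  # preserves order
        idx = np.flatnonzero(_as_str_array(chroms) == chrom)
        s, e = starts[idx], ends[idx]
        if np.any(np.diff(s) < 0):
            raise ValidationError(f"{what}: intervals not sorted on {chrom}")
        if np.any(s[1:] < e[:-1]):
            raise ValidationError(f"{what}: overlapping intervals on {chrom}")


@dataclass
class IntervalCallSet:
    """Interval-resolution diploid local ancestry calls (RFMix-flavoured)."""

    chroms: np.ndarray          # (n_intervals,) str
    starts: np.ndarray          # (n_intervals,) int, 0-based half-open
    ends: np.ndarray            # (n_intervals,) int
    counts: np.ndarray          # (n_intervals, n_samples, K) int8
    sample_ids: list[str]
    ancestry_labels: list[str]

    def __post_init__(self) -> None:
        self.chroms = _as_str_array(self.chroms)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.counts = _check_counts(self.counts, "interval calls")
        if self.counts.shape != (len(self.chroms), len(self.sample_ids), len(self.ancestry_labels)):
            raise ValidationError("interval calls: counts shape inconsistent with metadata")
        _check_sorted_disjoint(self.chroms, self.starts, self.ends, "interval calls")

    @property
    def n_intervals(self) -> int:
        return len(self.chroms)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestry_labels)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def subset(self, index: np.ndarray) -> "IntervalCallSet":
        index = np.asarray(index)
        return IntervalCallSet(
            self.chroms[index], self.starts[index], self.ends[index],
            self.counts[index], list(self.sample_ids), list(self.ancestry_labels),
        )


@dataclass
class SnpCallSet:
    """SNP-resolution diploid local ancestry calls (FLARE-flavoured).

    ``r2`` is the imputation quality; NaN marks a directly genotyped variant
    (exempt from the R2 QC filter).  ``haps`` optionally carries the two
    per-haplotype ancestry code arrays (shape ``(2, n_snps, n_samples)``)
    from which ``counts`` derive; writers use it to emit AN1/AN2 fields.
    """

    chroms: np.ndarray          # (n_snps,) str
    positions: np.ndarray       # (n_snps,) int, 0-based
    variant_ids: np.ndarray     # (n_snps,) str
    counts: np.ndarray          # (n_snps, n_samples, K) int8
    maf: np.ndarray             # (n_snps,) float
    r2: np.ndarray              # (n_snps,) float, NaN = genotyped
    sample_ids: list[str]
    ancestry_labels: list[str]
    haps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chroms = _as_str_array(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.variant_ids = _as_str_array(self.variant_ids)
        self.counts = _check_counts(self.counts, "snp calls")
        self.maf = np.asarray(self.maf, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        n_snps = len(self.chroms)
        if self.counts.shape != (n_snps, len(self.sample_ids), len(self.ancestry_labels)):
            raise ValidationError("snp calls: counts shape inconsistent with metadata")
        for chrom in dict.fromkeys(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(f"snp calls: positions not sorted on {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.chroms)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestry_labels)

    def subset(self, index: np.ndarray) -> "SnpCallSet":
        index = np.asarray(index)
        return SnpCallSet(
            self.chroms[index], self.positions[index], self.variant_ids[index],
            self.counts[index], self.maf[index], self.r2[index],
            list(self.sample_ids), list(self.ancestry_labels),
            None if self.haps is None else self.haps[:, index],
        )


@dataclass
class LiftoverMap:
    """Ordered monotone source→target coordinate blocks (chain-file stand-in)."""

    src_chroms: np.ndarray
    src_starts: np.ndarray
    src_ends: np.ndarray
    dst_chroms: np.ndarray
    dst_starts: np.ndarray
    dst_ends: np.ndarray

    def __post_init__(self) -> None:
        self.src_chroms = _as_str_array(self.src_chroms)
        self.dst_chroms = _as_str_array(self.dst_chroms)
        for name in ("src_starts", "src_ends", "dst_starts", "dst_ends"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if np.any((self.src_ends - self.src_starts) != (self.dst_ends - self.dst_starts)):
            raise ValidationError("liftover map: src and dst block spans differ in length")
        _check_sorted_disjoint(self.src_chroms, self.src_starts, self.src_ends, "liftover map")

    @property
    def n_blocks(self) -> int:
        return len(self.src_chroms)


@dataclass
class AnnotationTrack:
    """BED-style genomic annotations carrying a class label per interval."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    classes: np.ndarray   # e.g. "blacklist", "gene_cluster"

    def __post_init__(self) -> None:
        self.chroms = _as_str_array(self.chroms)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.classes = _as_str_array(self.classes)
        if np.any(self.starts >= self.ends):
            raise ValidationError("annotation track: start must be < end")

    @property
    def n_intervals(self) -> int:
        return len(self.chroms)

    @property
    def class_labels(self) -> list[str]:
        return sorted(set(self.classes))


@dataclass
class GlobalAncestryTable:
    """Per-individual global ancestry proportions (rows sum to one)."""

    proportions: np.ndarray     # (n_samples, K)
    sample_ids: list[str]
    ancestry_labels: list[str]
    source_label: str = "unknown"

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.size:
            if self.proportions.min() < -1e-9 or self.proportions.max() > 1 + 1e-9:
                raise ValidationError("global ancestry: proportions outside [0, 1]")
            if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError("global ancestry: rows do not sum to 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.ancestry_labels)
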