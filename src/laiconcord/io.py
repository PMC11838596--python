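"""File formats, QC filtering, and interval liftover.

On-disk conventions
-------------------
* interval call TSV: 1-based closed coordinates; columns ``chrom, start, end``
  then one ``<sample>:<ancestry>`` count column per sample × ancestry.
* SNP call TSV: 1-based positions; columns ``chrom, pos, id, maf, r2`` then
  ``<sample>:<ancestry>`` count columns.  Missing R2 (directly genotyped) is
  written as ``.``.
* SNP call VCF: a minimal VCF 4.2 dialect with INFO fields ``MAF``/``R2`` and
  per-sample FORMAT fields ``AN1``/``AN2`` holding haplotype ancestry indices
  (FLARE-style).  Read through pysam.
* annotations: 4-column BED, 0-based half-open, name column = class label.
* liftover map TSV: 0-based half-open columns
  ``chrom, src_start, src_end, dst_start, dst_end, dst_chrom``.

Internally everything is 0-based half-open; the shift happens only here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .containers import (
    AnnotationTrack,
    IntervalCallSet,
    LiftoverMap,
    SnpCallSet,
    ValidationError,
)

# ---------------------------------------------------------------------------
# interval calls (TSV)
# ---------------------------------------------------------------------------


def _parse_count_columns(columns: list[str]) -> tuple[list[str], list[str]]:
    samples: list[str] = []
    ancestries: list[str] = []
    for col in columns:
        if ":" not in col:
            raise ValidationError(f"malformed count column {col!r} (expected 'sample:ancestry')")
        s, a = col.rsplit(":", 1)
        if s not in samples:
            samples.append(s)
        if a not in ancestries:
            ancestries.append(a)
    return samples, ancestries


def write_interval_calls(calls: IntervalCallSet, path: str | os.PathLike) -> None:
    cols = {
        "chrom": calls.chroms,
        "start": calls.starts + 1,  # 1-based closed on disk
        "end": calls.ends,
    }
    for j, sample in enumerate(calls.sample_ids):
        for k, anc in enumerate(calls.ancestry_labels):
            cols[f"{sample}:{anc}"] = calls.counts[:, j, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_interval_calls(path: str | os.PathLike) -> IntervalCallSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        return IntervalCallSet(
            np.empty(0, object), np.empty(0, int), np.empty(0, int),
            np.empty((0, 0, 0), np.int8), [], [],
        )
    count_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    samples, ancestries = _parse_count_columns(count_cols)
    counts = np.empty((len(df), len(samples), len(ancestries)), dtype=np.int64)
    for j, sample in enumerate(samples):
        for k, anc in enumerate(ancestries):
            counts[:, j, k] = df[f"{sample}:{anc}"].to_numpy()
    return IntervalCallSet(
        df["chrom"].to_numpy(object),
        df["start"].to_numpy(np.int64) - 1,
        df["end"].to_numpy(np.int64),
        counts, samples, ancestries,
    )


# ---------------------------------------------------------------------------
# SNP calls (TSV and VCF dialects)
# ---------------------------------------------------------------------------


def _haps_from_counts(counts: np.ndarray) -> np.ndarray:
    """Deterministic haplotype split consistent with diploid counts.

    AN1 takes the lowest ancestry with a positive count; AN2 the highest.
    """
    n_snps, n_samp, K = counts.shape
    rng_idx = np.arange(K)
    pos = counts > 0
    an1 = np.where(pos, rng_idx, K).min(axis=2)
    an2 = np.where(pos, rng_idx, -1).max(axis=2)
    return np.stack([an1, an2]).astype(np.int8)


def write_snp_calls(calls: SnpCallSet, path: str | os.PathLike, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        r2_col = np.array(["." if np.isnan(v) else f"{v:.6g}" for v in calls.r2], dtype=object)
        cols = {
            "chrom": calls.chroms,
            "pos": calls.positions + 1,
            "id": calls.variant_ids,
            "maf": np.round(calls.maf, 6),
            "r2": r2_col,
        }
        for j, sample in enumerate(calls.sample_ids):
            for k, anc in enumerate(calls.ancestry_labels):
                cols[f"{sample}:{anc}"] = calls.counts[:, j, k]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        _write_snp_vcf(calls, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_snp_vcf(calls: SnpCallSet, path: str | os.PathLike) -> None:
    haps = calls.haps if calls.haps is not None else _haps_from_counts(calls.counts)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(calls.chroms):
            mask = calls.chroms == chrom
            length = int(calls.positions[mask].max()) + 2 if mask.any() else 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=AN1,Number=1,Type=Integer,Description="Ancestry of haplotype 1">\n')
        fh.write('##FORMAT=<ID=AN2,Number=1,Type=Integer,Description="Ancestry of haplotype 2">\n')
        for k, anc in enumerate(calls.ancestry_labels):
            fh.write(f"##ANCESTRY=<ID={k},Label={anc}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(calls.sample_ids) + "\n")
        for i in range(calls.n_snps):
            info = f"MAF={calls.maf[i]:.6g}"
            if not np.isnan(calls.r2[i]):
                info += f";R2={calls.r2[i]:.6g}"
            fields = [
                str(calls.chroms[i]), str(calls.positions[i] + 1), str(calls.variant_ids[i]),
                "A", "G", ".", "PASS", info, "AN1:AN2",
            ]
            fields += [f"{haps[0, i, j]}:{haps[1, i, j]}" for j in range(calls.n_samples)]
            fh.write("\t".join(fields) + "\n")


def read_snp_calls(
    path: str | os.PathLike, dialect: str = "tsv", ancestry_labels: list[str] | None = None
) -> SnpCallSet:
    if dialect == "tsv":
        return _read_snp_tsv(path)
    if dialect == "vcf":
        return _read_snp_vcf(path, ancestry_labels)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_snp_tsv(path) -> SnpCallSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str}, na_values=["."])
    meta = ("chrom", "pos", "id", "maf", "r2")
    count_cols = [c for c in df.columns if c not in meta]
    samples, ancestries = _parse_count_columns(count_cols)
    counts = np.empty((len(df), len(samples), len(ancestries)), dtype=np.int64)
    for j, sample in enumerate(samples):
        for k, anc in enumerate(ancestries):
            counts[:, j, k] = df[f"{sample}:{anc}"].to_numpy()
    return SnpCallSet(
        df["chrom"].to_numpy(object), df["pos"].to_numpy(np.int64) - 1,
        df["id"].to_numpy(object), counts,
        df["maf"].to_numpy(float), df["r2"].to_numpy(float),
        samples, ancestries,
    )


def _read_snp_vcf(path, ancestry_labels: list[str] | None) -> SnpCallSet:
    vcf = pysam.VariantFile(os.fspath(path))
    labels = ancestry_labels
    if labels is None:
        labels = []
        for rec in str(vcf.header).splitlines():
            if rec.startswith("##ANCESTRY=") and "Label=" in rec:
                labels.append(rec.split("Label=")[1].rstrip(">").strip())
    samples = list(vcf.header.samples)
    chroms, positions, vids, mafs, r2s, rows1, rows2 = [], [], [], [], [], [], []
    for rec in vcf:
        chroms.append(rec.chrom)
        positions.append(rec.pos - 1)
        vids.append(rec.id or ".")
        def _info(key):
            try:
                return rec.info[key]
            except (KeyError, ValueError):
                return None
        maf = _info("MAF")
        mafs.append(float(maf) if maf is not None else np.nan)
        r2 = _info("R2")
        r2s.append(float(r2) if r2 is not None else np.nan)
        an1 = [rec.samples[s]["AN1"] for s in samples]
        an2 = [rec.samples[s]["AN2"] for s in samples]
        rows1.append(an1)
        rows2.append(an2)
    vcf.close()
    haps = np.stack([np.asarray(rows1, dtype=np.int64), np.asarray(rows2, dtype=np.int64)])
    K = len(labels) if labels else (int(haps.max()) + 1 if haps.size else 0)
    if haps.size and haps.max() >= K:
        bad = np.argwhere(haps.max(axis=(0, 2)) >= K)[0, 0]
        raise ValidationError(
            f"snp calls: ancestry index {int(haps[:, bad].max())} out of range "
            f"(K={K}) at variant {vids[bad]}"
        )
    n_snps, n_samp = haps.shape[1], haps.shape[2]
    counts = np.zeros((n_snps, n_samp, K), dtype=np.int64)
    for h in range(2):
        np.add.at(counts, (np.arange(n_snps)[:, None], np.arange(n_samp)[None, :], haps[h]), 1)
    return SnpCallSet(
        np.asarray(chroms, object), np.asarray(positions, np.int64),
        np.asarray(vids, object), counts,
        np.asarray(mafs, float), np.asarray(r2s, float),
        samples, list(labels), haps=haps.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# annotations (BED) and liftover map (TSV)
# ---------------------------------------------------------------------------


def write_annotations(track: AnnotationTrack, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"chrom": track.chroms, "start": track.starts, "end": track.ends, "name": track.classes}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_annotations(path: str | os.PathLike) -> AnnotationTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    return AnnotationTrack(
        df["chrom"].to_numpy(object), df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64), df["name"].to_numpy(object),
    )


_MAP_COLS = ["chrom", "src_start", "src_end", "dst_start", "dst_end", "dst_chrom"]


def write_liftover_map(lift: LiftoverMap, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "chrom": lift.src_chroms, "src_start": lift.src_starts, "src_end": lift.src_ends,
            "dst_start": lift.dst_starts, "dst_end": lift.dst_ends, "dst_chrom": lift.dst_chroms,
        }
    ).to_csv(path, sep="\t", index=False)


def read_liftover_map(path: str | os.PathLike) -> LiftoverMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "dst_chrom": str})
    missing = [c for c in _MAP_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"liftover map: missing columns {missing}")
    return LiftoverMap(
        df["chrom"].to_numpy(object), df["src_start"].to_numpy(np.int64),
        df["src_end"].to_numpy(np.int64), df["dst_chrom"].to_numpy(object),
        df["dst_start"].to_numpy(np.int64), df["dst_end"].to_numpy(np.int64),
    )


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_total: int
    n_kept: int
    n_fail_maf: int
    n_fail_r2: int

    @property
    def kept_fraction(self) -> float:
        return self.n_kept / self.n_total if self.n_total else 1.0

    def __str__(self) -> str:
        return (
            f"kept {self.n_kept}/{self.n_total} variants "
            f"({100 * self.kept_fraction:.2f}%); "
            f"{self.n_fail_maf} failed MAF, {self.n_fail_r2} failed R2"
        )


def filter_snps(calls: SnpCallSet, maf_min: float = 0.005, r2_min: float = 0.8
                ) -> tuple[SnpCallSet, FilterReport]:
    """Apply the MAF / imputation-quality QC filter.

    Variants with missing R2 are treated as directly genotyped and are exempt
    from the R2 threshold; the MAF threshold applies to every variant.
    """
    if not (0 <= maf_min <= 1 and 0 <= r2_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    maf_ok = calls.maf >= maf_min
    r2_ok = np.isnan(calls.r2) | (calls.r2 >= r2_min)
    keep = maf_ok & r2_ok
    report = FilterReport(
        n_total=calls.n_snps,
        n_kept=int(keep.sum()),
        n_fail_maf=int((~maf_ok).sum()),
        n_fail_r2=int((~r2_ok).sum()),
    )
    return calls.subset(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# liftover
# ---------------------------------------------------------------------------


@dataclass
class LiftoverReport:
    n_total: int
    n_converted: int
    n_multi_region: int      # interval straddles >1 block
    n_cross_chromosome: int  # containing block maps to a different chromosome
    n_unmapped: int          # interval not covered by any block
    discarded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def converted_fraction(self) -> float:
        return self.n_converted / self.n_total if self.n_total else 1.0

    def __str__(self) -> str:
        return (
            f"{self.n_converted} ({100 * self.converted_fraction:.2f}%) of "
            f"{self.n_total} intervals converted; "
            f"{self.n_multi_region} mapped into more than one region, "
            f"{self.n_cross_chromosome} mapped to a different chromosome, "
            f"{self.n_unmapped} unmapped"
        )


def apply_liftover(calls: IntervalCallSet, lift: LiftoverMap
                   ) -> tuple[IntervalCallSet, LiftoverReport]:
    """Shift interval coordinates through a monotone block map.

    An interval wholly inside one block is shifted by that block's offset.
    Intervals spanning block boundaries (mapped into more than one region)
    or whose block maps to a different chromosome are discarded, as are
    intervals not covered by any block; discards are counted by reason and
    retained with their original coordinates for audit.
    """
    n = calls.n_intervals
    new_chroms = np.empty(n, dtype=object)
    new_starts = np.empty(n, dtype=np.int64)
    new_ends = np.empty(n, dtype=np.int64)
    status = np.empty(n, dtype=object)

    for chrom in dict.fromkeys(calls.chroms):
        rows = np.flatnonzero(calls.chroms == chrom)
        blk = np.flatnonzero(lift.src_chroms == chrom)
        bs, be = lift.src_starts[blk], lift.src_ends[blk]
        for i in rows:
            s, e = calls.starts[i], calls.ends[i]
            # block whose src span contains the interval start
            j = np.searchsorted(bs, s, side="right") - 1
            if j < 0 or s >= be[j]:
                # start not inside any block: either unmapped, or straddling a gap edge
                j_end = np.searchsorted(bs, e - 1, side="right") - 1
                inside_end = j_end >= 0 and (e - 1) < be[j_end]
                status[i] = "multi_region" if inside_end else "unmapped"
                continue
            if e > be[j]:
                status[i] = "multi_region"
                continue
            b = blk[j]
            if lift.dst_chroms[b] != chrom:
                status[i] = "cross_chromosome"
                continue
            offset = lift.dst_starts[b] - lift.src_starts[b]
            status[i] = "converted"
            new_chroms[i] = lift.dst_chroms[b]
            new_starts[i] = s + offset
            new_ends[i] = e + offset

    keep = np.flatnonzero(status == "converted")
    converted = IntervalCallSet(
        new_chroms[keep], new_starts[keep], new_ends[keep],
        calls.counts[keep], list(calls.sample_ids), list(calls.ancestry_labels),
    )
    drop = np.flatnonzero(status != "converted")
    discarded = pd.DataFrame(
        {
            "chrom": calls.chroms[drop], "start": calls.starts[drop],
            "end": calls.ends[drop], "reason": status[drop],
        }
    )
    report = LiftoverReport(
        n_total=n,
        n_converted=len(keep),
        n_multi_region=int((status == "multi_region").sum()),
        n_cross_chromosome=int((status == "cross_chromosome").sum()),
        n_unmapped=int((status == "unmapped").sum()),
        discarded=discarded,
    )
    return converted, report
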