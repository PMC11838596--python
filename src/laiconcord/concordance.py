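"""SNP-to-interval matching and genome-wide per-locus agreement profiling.

A SNP matches an interval when its position falls inside the interval with
both ends included (closed-interval predicate, applied on the shared target
build after liftover).  For every matched (SNP, interval) pair and every
ancestry, the Pearson correlation of the two diploid count vectors across
individuals quantifies the agreement of the channels at that locus;
correlations are undefined (NaN) when either vector is constant and are
excluded from summaries.  Pairs whose correlation falls below a threshold in
any considered ancestry are flagged and merged into discordant regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import IntervalCallSet, SnpCallSet


def match_snps_to_intervals(snps: SnpCallSet, intervals: IntervalCallSet
                            ) -> tuple[pd.DataFrame, float]:
    """Match each SNP to at most one interval; returns (pairs, match_rate).

    Intervals must be non-overlapping (enforced by the container).  When
    intervals abut so that a SNP sits on a shared boundary, the earlier
    interval wins (deterministic tie-break).
    """
    pairs = []
    for chrom in dict.fromkeys(snps.chroms):
        snp_rows = np.flatnonzero(snps.chroms == chrom)
        int_rows = np.flatnonzero(intervals.chroms == chrom)
        if len(int_rows) == 0:
            continue
        starts = intervals.starts[int_rows]
        ends = intervals.ends[int_rows]
        pos = snps.positions[snp_rows]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        pairs.append(pd.DataFrame({
            "snp_index": snp_rows[ok],
            "interval_index": int_rows[j[ok]],
            "chrom": chrom,
            "snp_pos": pos[ok],
        }))
    if pairs:
        out = pd.concat(pairs, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["snp_index", "interval_index", "chrom", "snp_pos"])
    match_rate = len(out) / snps.n_snps if snps.n_snps else 0.0
    return out, match_rate


def pair_correlations(pairs: pd.DataFrame, snps: SnpCallSet, intervals: IntervalCallSet,
                      ancestries: list[str] | None = None) -> pd.DataFrame:
    """Across-individual Pearson r per (matched pair, ancestry), long format."""
    if snps.sample_ids != intervals.sample_ids:
        raise ValueError("SNP and interval call sets carry different samples")
    if ancestries is None:
        ancestries = [a for a in snps.ancestry_labels if a in intervals.ancestry_labels]
    si = pairs["snp_index"].to_numpy()
    ii = pairs["interval_index"].to_numpy()
    frames = []
    for anc in ancestries:
        ks = snps.ancestry_labels.index(anc)
        ki = intervals.ancestry_labels.index(anc)
        x = snps.counts[si, :, ks].astype(float)       # (P, n)
        y = intervals.counts[ii, :, ki].astype(float)  # (P, n)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc * xc).sum(axis=1))
        sy = np.sqrt((yc * yc).sum(axis=1))
        denom = sx * sy
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xc * yc).sum(axis=1) / np.where(denom > 0, denom, 1.0),
                         np.nan)
        frames.append(pd.DataFrame({
            "snp_index": si, "interval_index": ii,
            "chrom": pairs["chrom"].to_numpy(), "snp_pos": pairs["snp_pos"].to_numpy(),
            "ancestry": anc, "r": r,
        }))
    return pd.concat(frames, ignore_index=True)


def genome_summary(correlations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unweighted mean/SD of defined correlations per ancestry, and the
    per-chromosome long-format profile table."""
    defined = correlations.dropna(subset=["r"])
    if defined.empty:
        raise ValueError("no defined correlations to summarize")
    overall = (
        defined.groupby("ancestry", sort=True)["r"]
        .agg(mean_r="mean", sd_r=lambda v: v.std(ddof=1), n_pairs="count")
        .reset_index()
    )
    per_chrom = (
        defined.groupby(["chrom", "ancestry"], sort=True)["r"]
        .agg(mean_r="mean", sd_r=lambda v: v.std(ddof=1), n_pairs="count")
        .reset_index()
    )
    return overall, per_chrom


def position_profiles(calls: SnpCallSet | IntervalCallSet) -> pd.DataFrame:
    """Per-locus per-ancestry mean proportion (mean count / 2) and count variance."""
    counts = calls.counts.astype(float)
    n = calls.n_samples
    mean_prop = counts.mean(axis=1) / 2.0
    var = counts.var(axis=1, ddof=1) if n > 1 else np.zeros_like(mean_prop)
    if isinstance(calls, SnpCallSet):
        locus = calls.positions
    else:
        locus = calls.starts
    rows = []
    for k, anc in enumerate(calls.ancestry_labels):
        rows.append(pd.DataFrame({
            "chrom": calls.chroms, "pos": locus, "ancestry": anc,
            "mean_proportion": mean_prop[:, k], "count_variance": var[:, k], "n": n,
        }))
    return pd.concat(rows, ignore_index=True)


def flag_low_pairs(correlations: pd.DataFrame, low_threshold: float = 0.9,
                   ancestries: list[str] | None = None
                   ) -> tuple[pd.DataFrame, float]:
    """Flag pairs with r below the threshold in ANY considered ancestry.

    Undefined correlations never trigger a flag.  Returns the flagged subset
    (one row per pair) and the flagged fraction over all matched pairs.
    """
    if not (0 < low_threshold < 1):
        raise ValueError("low_threshold must lie in (0, 1)")
    df = correlations
    if ancestries is not None:
        df = df[df["ancestry"].isin(ancestries)]
    low = df["r"] < low_threshold   # NaN compares False
    flagged_keys = df.loc[low, ["snp_index", "interval_index", "chrom", "snp_pos"]]
    flagged = flagged_keys.drop_duplicates(subset=["snp_index", "interval_index"])
    flagged = flagged.sort_values(["snp_index"]).reset_index(drop=True)
    n_pairs = correlations[["snp_index", "interval_index"]].drop_duplicates().shape[0]
    fraction = len(flagged) / n_pairs if n_pairs else 0.0
    return flagged, fraction


def merge_regions(flagged: pd.DataFrame, intervals: IntervalCallSet) -> pd.DataFrame:
    """Union of the interval spans of flagged pairs: sorted disjoint regions
    per chromosome, merging overlapping or exactly abutting spans."""
    if flagged.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    idx = flagged["interval_index"].to_numpy()
    spans = pd.DataFrame({
        "chrom": intervals.chroms[idx],
        "start": intervals.starts[idx],
        "end": intervals.ends[idx],
    }).drop_duplicates().sort_values(["chrom", "start"])
    out = []
    for chrom, grp in spans.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])
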