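"""Proximity mapping of discordant pairs to annotation classes, with a
matched high-correlation control group.

Because local ancestry carries very long-range LD, a pair counts as mapped to
an annotation class when its span lies within a proximity window (default
0.5 Mb, inclusive) of any annotation interval of that class; overlap means
distance zero, distance is edge-to-edge gap on the same chromosome, and
cross-chromosome distance is infinite.  A pair may carry several classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .containers import AnnotationTrack


def _gap_to_nearest(qs: np.ndarray, qe: np.ndarray, ann_s: np.ndarray, ann_e: np.ndarray
                    ) -> np.ndarray:
    """Edge-to-edge gap (bp, 0 when overlapping) from half-open query spans to
    the nearest of sorted half-open annotation intervals."""
    if len(ann_s) == 0:
        return np.full(len(qs), np.inf)
    order = np.argsort(ann_s)
    ann_s, ann_e = ann_s[order], ann_e[order]
    cum_e = np.maximum.accumulate(ann_e)
    gaps = np.full(len(qs), np.inf)
    # annotation starting inside the query span -> overlap, distance 0
    j0 = np.searchsorted(ann_s, qs, side="left")
    ok0 = j0 < len(ann_s)
    inside = np.zeros(len(qs), dtype=bool)
    inside[ok0] = ann_s[j0[ok0]] < qe[ok0]
    gaps[inside] = 0.0
    # nearest annotation starting at/after the query end
    j = np.searchsorted(ann_s, qe)
    has_next = j < len(ann_s)
    gaps[has_next] = ann_s[j[has_next]] - (qe[has_next] - 1)
    # nearest annotation ending at/before (or overlapping) the query start
    i = np.searchsorted(ann_s, qs, side="right") - 1
    has_prev = i >= 0
    prev_gap = np.where(has_prev, qs - (cum_e[np.clip(i, 0, None)] - 1), np.inf)
    gaps = np.minimum(gaps, prev_gap)
    return np.maximum(gaps, 0)


def map_pairs_to_annotations(spans: pd.DataFrame, track: AnnotationTrack,
                             proximity_bp: int = 500_000) -> pd.DataFrame:
    """Assign annotation classes to query spans by proximity.

    ``spans`` needs columns ``chrom, start, end`` (a SNP pair is the point
    span ``[pos, pos+1)``).  Returns the input plus one boolean column per
    annotation class, a ``mapped`` column (any class), and the gap distance
    per class.
    """
    if proximity_bp < 0:
        raise ValueError("proximity_bp must be non-negative")
    out = spans.reset_index(drop=True).copy()
    classes = track.class_labels
    for cls in classes:
        gap_col = np.full(len(out), np.inf)
        cls_mask = track.classes == cls
        for chrom in dict.fromkeys(out["chrom"]):
            rows = np.flatnonzero(out["chrom"].to_numpy() == chrom)
            ann = cls_mask & (track.chroms == chrom)
            gap_col[rows] = _gap_to_nearest(
                out["start"].to_numpy()[rows], out["end"].to_numpy()[rows],
                track.starts[ann], track.ends[ann],
            )
        out[f"gap_{cls}"] = gap_col
        out[cls] = gap_col <= proximity_bp
    out["mapped"] = out[classes].any(axis=1) if classes else False
    return out


def pair_spans(flagged: pd.DataFrame) -> pd.DataFrame:
    """Point spans for SNP-level pairs, ready for proximity mapping."""
    return pd.DataFrame({
        "chrom": flagged["chrom"].to_numpy(),
        "start": flagged["snp_pos"].to_numpy(),
        "end": flagged["snp_pos"].to_numpy() + 1,
        "snp_index": flagged["snp_index"].to_numpy(),
        "interval_index": flagged["interval_index"].to_numpy(),
    })


def sample_matched_high_pairs(correlations: pd.DataFrame, n: int,
                              high_threshold: float = 0.97, seed: int = 0,
                              ancestries: list[str] | None = None) -> pd.DataFrame:
    """Uniform sample (without replacement) of n pairs whose correlation
    exceeds the threshold in ALL considered ancestries."""
    df = correlations
    if ancestries is not None:
        df = df[df["ancestry"].isin(ancestries)]
    wide = df.pivot_table(index=["snp_index", "interval_index", "chrom", "snp_pos"],
                          columns="ancestry", values="r")
    eligible = wide[(wide > high_threshold).all(axis=1) & wide.notna().all(axis=1)]
    if len(eligible) < n:
        raise ValueError(
            f"requested {n} high-correlation control pairs but only "
            f"{len(eligible)} are eligible (r > {high_threshold} in all ancestries)"
        )
    keys = eligible.index.to_frame(index=False).sort_values("snp_index").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    take = np.sort(rng.choice(len(keys), size=n, replace=False))
    return keys.iloc[take].reset_index(drop=True)


@dataclass
class EnrichmentReport:
    """Counts and percentages of pairs near each annotation class, for the
    low-correlation group and the matched high-correlation control group.

    Class percentages use the group's mapped total as denominator; the
    overall mapped percentage uses the group size.
    """

    n_low_pairs: int
    n_low_mapped: int
    low_class_counts: dict[str, int]
    n_control_pairs: int
    n_control_mapped: int
    control_class_counts: dict[str, int]
    n_unique_regions_hit: int = 0

    @staticmethod
    def _pct(num: int, denom: int) -> float:
        return round(100.0 * num / denom, 2) if denom else 0.0

    @property
    def low_mapped_pct(self) -> float:
        return self._pct(self.n_low_mapped, self.n_low_pairs)

    @property
    def control_mapped_pct(self) -> float:
        return self._pct(self.n_control_mapped, self.n_control_pairs)

    def low_class_pct(self, cls: str) -> float:
        return self._pct(self.low_class_counts.get(cls, 0), self.n_low_mapped)

    def control_class_pct(self, cls: str) -> float:
        return self._pct(self.control_class_counts.get(cls, 0), self.n_control_mapped)

    def fisher_mapped(self) -> tuple[float, float]:
        """Optional 2x2 Fisher exact test: mapped vs unmapped x low vs control."""
        table = [
            [self.n_low_mapped, self.n_low_pairs - self.n_low_mapped],
            [self.n_control_mapped, self.n_control_pairs - self.n_control_mapped],
        ]
        odds, p = _stats.fisher_exact(table)
        return float(odds), float(p)

    def to_frame(self) -> pd.DataFrame:
        classes = sorted(set(self.low_class_counts) | set(self.control_class_counts))
        rows = [{
            "group": "low", "class": "any", "count": self.n_low_mapped,
            "pct": self.low_mapped_pct, "denominator": self.n_low_pairs,
        }, {
            "group": "control", "class": "any", "count": self.n_control_mapped,
            "pct": self.control_mapped_pct, "denominator": self.n_control_pairs,
        }]
        for cls in classes:
            rows.append({"group": "low", "class": cls,
                         "count": self.low_class_counts.get(cls, 0),
                         "pct": self.low_class_pct(cls), "denominator": self.n_low_mapped})
            rows.append({"group": "control", "class": cls,
                         "count": self.control_class_counts.get(cls, 0),
                         "pct": self.control_class_pct(cls),
                         "denominator": self.n_control_mapped})
        return pd.DataFrame(rows)


def _class_columns(assignments: pd.DataFrame) -> list[str]:
    reserved = {"chrom", "start", "end", "snp_index", "interval_index", "mapped"}
    return [c for c in assignments.columns
            if c not in reserved and not c.startswith("gap_")
            and assignments[c].dtype == bool]


def enrichment_summary(low_assignments: pd.DataFrame,
                       control_assignments: pd.DataFrame,
                       track: AnnotationTrack | None = None,
                       proximity_bp: int = 500_000) -> EnrichmentReport:
    """Tally mapped counts and percentages for the low and control groups."""
    classes = sorted(set(_class_columns(low_assignments))
                     | set(_class_columns(control_assignments)))
    low_counts = {c: int(low_assignments[c].sum()) if c in low_assignments else 0
                  for c in classes}
    ctl_counts = {c: int(control_assignments[c].sum()) if c in control_assignments else 0
                  for c in classes}
    n_unique = 0
    if track is not None and len(low_assignments):
        hit = np.zeros(track.n_intervals, dtype=bool)
        for chrom in dict.fromkeys(low_assignments["chrom"]):
            rows = low_assignments["chrom"].to_numpy() == chrom
            qs = low_assignments["start"].to_numpy()[rows]
            qe = low_assignments["end"].to_numpy()[rows]
            for t in np.flatnonzero(track.chroms == chrom):
                gap = np.maximum(
                    np.maximum(track.starts[t] - (qe - 1), qs - (track.ends[t] - 1)), 0)
                if (gap <= proximity_bp).any():
                    hit[t] = True
        n_unique = int(hit.sum())
    return EnrichmentReport(
        n_low_pairs=len(low_assignments),
        n_low_mapped=int(low_assignments["mapped"].sum()) if len(low_assignments) else 0,
        low_class_counts=low_counts,
        n_control_pairs=len(control_assignments),
        n_control_mapped=int(control_assignments["mapped"].sum()) if len(control_assignments) else 0,
        control_class_counts=ctl_counts,
        n_unique_regions_hit=n_unique,
    )
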