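"""Global ancestry proportions from each channel, and cross-method agreement.

Interval channel: length-weighted — for each individual, sum interval length
times diploid count per ancestry and divide by twice the total interval
length.  SNP channel: half the equally-weighted mean diploid count over SNPs.
Both produce rows summing to one because diploid counts sum to 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GlobalAncestryTable, IntervalCallSet, SnpCallSet


def global_from_intervals(calls: IntervalCallSet) -> GlobalAncestryTable:
    if calls.n_intervals == 0:
        raise ValueError("cannot compute global ancestry from an empty interval set")
    lengths = calls.lengths.astype(float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total interval length is zero")
    weighted = np.einsum("i,ijk->jk", lengths, calls.counts.astype(float))
    return GlobalAncestryTable(weighted / (2.0 * total), list(calls.sample_ids),
                               list(calls.ancestry_labels), source_label="interval")


def global_from_snps(calls: SnpCallSet) -> GlobalAncestryTable:
    if calls.n_snps == 0:
        raise ValueError("cannot compute global ancestry from an empty SNP set")
    props = calls.counts.astype(float).mean(axis=0) / 2.0
    return GlobalAncestryTable(props, list(calls.sample_ids),
                               list(calls.ancestry_labels), source_label="snp")


def compare_global(a: GlobalAncestryTable, b: GlobalAncestryTable,
                   label_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-ancestry Pearson correlation and mean signed difference (a - b).

    ``label_map`` maps ancestry labels of ``a`` onto those of ``b``; labels
    without a counterpart are excluded.  A correlation over a zero-variance
    vector is reported as NaN (undefined).
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("tables cover different individuals")
    rows = []
    for i, label in enumerate(a.ancestry_labels):
        target = label_map.get(label, label) if label_map else label
        if target not in b.ancestry_labels:
            continue
        j = b.ancestry_labels.index(target)
        x, y = a.proportions[:, i], b.proportions[:, j]
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"ancestry": label, "r": r, "mean_signed_diff": float(np.mean(x - y)),
                     "n": len(x)})
    return pd.DataFrame(rows)


def paired_scatter_table(a: GlobalAncestryTable, b: GlobalAncestryTable,
                         label_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Long-format paired proportions, one row per individual x shared ancestry."""
    if a.sample_ids != b.sample_ids:
        raise ValueError("tables cover different individuals")
    frames = []
    for i, label in enumerate(a.ancestry_labels):
        target = label_map.get(label, label) if label_map else label
        if target not in b.ancestry_labels:
            continue
        j = b.ancestry_labels.index(target)
        frames.append(pd.DataFrame({
            "sample_id": a.sample_ids,
            "ancestry": label,
            a.source_label: a.proportions[:, i],
            b.source_label: b.proportions[:, j],
        }))
    return pd.concat(frames, ignore_index=True)
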