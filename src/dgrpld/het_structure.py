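"""Residual-heterozygosity structure across chromosome regions.

Inbred lines should be nearly homozygous, but blocks of residual
heterozygosity persist.  This module builds the lines x regions matrix of
region heterozygosities (H), its Pearson correlation structure with
two-sided p-values (strongly correlated region heterozygosities point to
selection against segregants during inbreeding), and the interval arithmetic
that totals ancestry-labelled sequence inside a region per line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .inversion_typing import region_heterozygosity


def het_matrix(matrix: GenotypeMatrix, regions: pd.DataFrame) -> pd.DataFrame:
    """Lines x regions matrix of region heterozygosities.

    ``regions`` has columns chrom, start, end, name (1-based inclusive) and
    must be non-overlapping within a chromosome.  Each cell is the proportion
    of the line's called sites in the region scored heterozygous (NaN when no
    site is called).
    """
    for chrom, grp in regions.groupby("chrom"):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if (ends[:-1] >= starts[1:]).any():
            raise ValueError(f"overlapping regions on chromosome {chrom}")
    cols = {}
    for name, rows in regions.groupby("name", sort=False):
        cols[name] = region_heterozygosity(matrix, rows)
    return pd.DataFrame(cols, index=matrix.lines)


def het_summary(hmat: pd.DataFrame) -> pd.DataFrame:
    """Per-region mean and SD of H over lines (the 'H +/- SD' column)."""
    return pd.DataFrame(
        {"mean_H": hmat.mean(axis=0), "sd_H": hmat.std(axis=0, ddof=1)}
    )


def het_correlations(hmat: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of region heterozygosities with p-values.

    Correlations are pairwise-complete over lines.  Two-sided p-values come
    from the t transform with n-2 degrees of freedom; the significance class
    is 'b' for P < 0.0001, 'a' for 0.0001 <= P < 0.05, 'ns' otherwise.
    Region pairs with a constant column get NaN r and class 'undefined'.
    """
    if len(hmat) < 3:
        raise ValueError("need at least 3 lines for correlation inference")
    names = list(hmat.columns)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sub = hmat[[a, b]].dropna()
            n = len(sub)
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if n < 3 or x.std() == 0 or y.std() == 0:
                rows.append((a, b, np.nan, n, np.nan, "undefined"))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            cls = "b" if p < 1e-4 else ("a" if p < 0.05 else "ns")
            rows.append((a, b, r, n, p, cls))
    return pd.DataFrame(
        rows, columns=["region_a", "region_b", "r", "n", "p_value", "signif"]
    )


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 1-based inclusive intervals (n x 2 array)."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.argsort(intervals[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def ancestry_overlap(
    intervals: pd.DataFrame, region: tuple[str, int, int]
) -> pd.Series:
    """Per-line total length (bp) of ancestry intervals inside a region.

    ``intervals`` has columns line, chrom, start, end (1-based inclusive);
    overlapping intervals within a line are merged before summing so no base
    is double-counted.  ``region`` is (chrom, start, end), inclusive; overlap
    length counts end - start + 1 bases.  Lines with no interval get 0.
    """
    chrom, rs, re_ = region
    if not (intervals["start"] <= intervals["end"]).all():
        bad = intervals[intervals["start"] > intervals["end"]].iloc[0]
        raise ValueError(
            f"malformed interval for line {bad['line']}: "
            f"{bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    out = {}
    for line, grp in intervals.groupby("line"):
        iv = grp.loc[grp["chrom"] == chrom, ["start", "end"]].to_numpy(dtype=np.int64)
        total = 0
        for s, e in merge_intervals(iv):
            lo, hi = max(s, rs), min(e, re_)
            if hi >= lo:
                total += hi - lo + 1
        out[line] = int(total)
    return pd.Series(out, dtype=np.int64).sort_index()
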