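"""Per-SNP and regional summaries of a high-LD catalogue.

These reproduce the quantities behind the headline panel-wide statistics:
per-site partner counts (overall / distant / other-chromosome), the fraction
of sites with at least one high-LD partner (optionally stratified by MAF
class or inversion membership), mean and median partner counts per MAF class,
the per-100-kb intensity of distant LD along the genome, and the r^2
distribution of random site pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, ld_coded
from .ld_scan import DISTANT_BP


def annotate_inversion(records: pd.DataFrame, regions: pd.DataFrame | None) -> pd.Series:
    """Region name (or NA) for each site that falls inside an inversion region.

    ``regions`` has columns chrom, start, end, name (1-based inclusive).
    """
    out = pd.Series(pd.NA, index=records.index, dtype=object)
    if regions is None:
        return out
    for _, r in regions.iterrows():
        m = (
            (records["chrom"] == r["chrom"])
            & (records["pos"] >= int(r["start"]))
            & (records["pos"] <= int(r["end"]))
        )
        out[m] = r["name"]
    return out


def partner_counts(
    catalog: pd.DataFrame,
    records: pd.DataFrame,
    focal: np.ndarray,
    regions: pd.DataFrame | None = None,
    interchrom_is_distant: bool = True,
) -> pd.DataFrame:
    """Per-focal-site partner degrees from the catalogue.

    Every catalogue pair contributes to the degree of both of its members
    (partners below the focal MAC threshold are counted as partners, but only
    focal sites get an output row).  ``n_partners_distant`` includes
    interchromosomal partners by default; set ``interchrom_is_distant=False``
    to restrict "distant" to same-chromosome pairs > 100 kb apart.

    Returns a DataFrame indexed like the focal subset of ``records`` with
    columns chrom, pos, maf, in_inversion, n_partners_total,
    n_partners_distant, n_partners_other_chrom.
    """
    focal = np.asarray(focal, dtype=bool)
    rec = records.loc[focal, ["chrom", "pos", "maf"]].copy()
    rec["pos"] = rec["pos"].astype(np.int64)
    rec["in_inversion"] = annotate_inversion(rec, regions)
    if len(catalog):
        is_inter = (catalog["pair_class"] == "interchromosomal").to_numpy()
        is_dist = (catalog["pair_class"] == "distant").to_numpy()
        if interchrom_is_distant:
            is_dist = is_dist | is_inter
        ends = []
        for end in ("a", "b"):
            ends.append(
                pd.DataFrame(
                    {
                        "chrom": catalog[f"chrom_{end}"].to_numpy(),
                        "pos": catalog[f"pos_{end}"].to_numpy(dtype=np.int64),
                        "n_partners_total": 1,
                        "n_partners_distant": is_dist.astype(int),
                        "n_partners_other_chrom": is_inter.astype(int),
                    }
                )
            )
        deg = (
            pd.concat(ends, ignore_index=True)
            .groupby(["chrom", "pos"], as_index=False)
            .sum()
        )
        rec = rec.merge(deg, on=["chrom", "pos"], how="left")
    else:
        rec["n_partners_total"] = 0
        rec["n_partners_distant"] = 0
        rec["n_partners_other_chrom"] = 0
    for c in ("n_partners_total", "n_partners_distant", "n_partners_other_chrom"):
        rec[c] = rec[c].fillna(0).astype(np.int64)
    return rec.reset_index(drop=True)


def fraction_with_partner(
    counts: pd.DataFrame, stratify: str | None = None
) -> pd.DataFrame:
    """Proportion of focal sites with >= 1 partner (total / distant / other-chrom).

    ``stratify`` may name a column of ``counts`` (e.g. an in/outside-inversion
    flag or a MAF-class label); None gives a single overall row.  Empty strata
    are omitted.
    """
    def _row(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        return pd.Series(
            {
                "n_sites": n,
                "frac_any_partner": (df["n_partners_total"] > 0).mean(),
                "frac_distant_partner": (df["n_partners_distant"] > 0).mean(),
                "frac_other_chrom_partner": (df["n_partners_other_chrom"] > 0).mean(),
            }
        )

    if stratify is None:
        return _row(counts).to_frame().T
    groups = counts.groupby(counts[stratify].astype(object), dropna=False)
    out = groups.apply(_row, include_groups=False)
    out.index.name = stratify
    return out.reset_index()


def maf_class(maf: np.ndarray, width: float = 0.02) -> np.ndarray:
    """Left edge of the MAF class of width ``width`` starting at 0."""
    maf = np.asarray(maf, dtype=float)
    return np.floor(maf / width) * width


def maf_stratified_summary(
    counts: pd.DataFrame, width: float = 0.02, by_inversion: bool = False
) -> pd.DataFrame:
    """Mean and median partner counts per MAF class (and optionally by inversion).

    Mirrors the "partner count vs MAF" summary: rare variants carry far more
    high-LD partners than common ones, and the mean exceeds the median because
    the degree distribution is strongly right-skewed.
    """
    df = counts.copy()
    df["maf_class"] = maf_class(df["maf"].to_numpy(), width)
    keys = ["maf_class"]
    if by_inversion:
        df["inside_inversion"] = df["in_inversion"].notna()
        keys.append("inside_inversion")
    g = df.groupby(keys)
    out = g.agg(
        n_sites=("n_partners_total", "size"),
        mean_total=("n_partners_total", "mean"),
        median_total=("n_partners_total", "median"),
        mean_distant=("n_partners_distant", "mean"),
        median_distant=("n_partners_distant", "median"),
    ).reset_index()
    return out.sort_values(keys).reset_index(drop=True)


def window_distant_intensity(
    counts: pd.DataFrame, window_bp: int = 100_000
) -> pd.DataFrame:
    """Mean distant-partner count per focal site in non-overlapping genome windows.

    Windows are half-open ``[k*window_bp, (k+1)*window_bp)`` on the 0-based
    coordinate ``pos - 1``.  Windows containing no focal site are absent from
    the output (reported as missing).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = counts.copy()
    df["window_start"] = ((df["pos"].astype(np.int64) - 1) // window_bp) * window_bp + 1
    g = df.groupby(["chrom", "window_start"])
    out = g.agg(
        n_focal_sites=("n_partners_distant", "size"),
        mean_distant=("n_partners_distant", "mean"),
    ).reset_index()
    return out.sort_values(["chrom", "window_start"]).reset_index(drop=True)


def random_pair_r2(
    matrix: GenotypeMatrix,
    focal: np.ndarray,
    n_pairs: int = 1_000_000,
    seed: int = 0,
    r2_cut: float = 0.5,
    chunk: int = 200_000,
) -> tuple[np.ndarray, dict]:
    """r^2 for uniformly random unordered pairs of focal sites.

    Pairs are sampled with replacement (seeded); undefined correlations
    (constant restricted vectors) are returned as NaN and excluded from the
    summary proportions.  Returns ``(r2_sample, summary)`` where the summary
    holds the share of defined pairs with r^2 >= ``r2_cut`` and a histogram
    over [0, 1].
    """
    focal_idx = np.flatnonzero(np.asarray(focal, dtype=bool))
    if len(focal_idx) < 2:
        raise ValueError("need at least two focal sites to sample pairs")
    rng = np.random.default_rng(seed)
    X = ld_coded(matrix).astype(np.float64)
    X[X < 0] = np.nan
    out = np.empty(n_pairs)
    done = 0
    while done < n_pairs:
        m = min(chunk, n_pairs - done)
        i = rng.integers(0, len(focal_idx), size=m)
        j = rng.integers(0, len(focal_idx) - 1, size=m)
        j = np.where(j >= i, j + 1, j)  # uniform over unordered distinct pairs
        xi = X[:, focal_idx[i]]
        xj = X[:, focal_idx[j]]
        ok = np.isfinite(xi) & np.isfinite(xj)
        n = ok.sum(axis=0)
        xi0 = np.where(ok, xi, 0.0)
        xj0 = np.where(ok, xj, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            px = xi0.sum(axis=0) / n
            py = xj0.sum(axis=0) / n
            cov = (xi0 * xj0).sum(axis=0) / n - px * py
            vx = px * (1 - px)
            vy = py * (1 - py)
            r2 = cov * cov / (vx * vy)
        r2[(n < 2) | (vx <= 0) | (vy <= 0)] = np.nan
        out[done : done + m] = r2
        done += m
    defined = out[np.isfinite(out)]
    hist, edges = np.histogram(defined, bins=np.linspace(0, 1, 21))
    summary = {
        "n_pairs": int(n_pairs),
        "n_defined": int(len(defined)),
        "frac_ge_cut": float((defined >= r2_cut).mean()) if len(defined) else float("nan"),
        "hist_counts": hist.tolist(),
        "hist_edges": edges.tolist(),
    }
    return out, summary
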