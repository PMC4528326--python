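"""Genotype-based inversion karyotyping.

SNPs inside an inversion's breakpoints that are in high LD with many distant
sites are characteristic of the arrangement classes.  A PCA of a random
subset of such diagnostic SNPs (dosage-coded, missing calls imputed to the
common allele) separates lines into Standard and Inverted clusters on PC1,
with arrangement heterozygotes scoring in between; the proportion of
heterozygous calls in the region (H) flags lines whose sequence data are
inconsistent with a homozygous karyotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genotype_io import ALT, HET, MISSING, REF, GenotypeMatrix

#: region-heterozygosity level above which a line is flagged "highly heterozygous"
H_THRESHOLD: float = 0.15

KARYOTYPE_COLUMNS = ["line", "region", "pc1", "H", "call", "flag"]


def load_regions(path) -> pd.DataFrame:
    """Read a BED-like region table: chrom, start, end, name[, role].

    Coordinates are 1-based inclusive.  ``role`` defaults to 'inversion';
    rows sharing a name are treated as one region for karyotyping (this is
    how a flanking segment, role='flanking-merged', is merged into its
    inversion), while heterozygosity summaries keep rows separate.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "name"}
    if not required.issubset(df.columns):
        raise ValueError(f"region table needs columns {sorted(required)}")
    if "role" not in df.columns:
        df["role"] = "inversion"
    return df


def region_site_mask(records: pd.DataFrame, region_rows: pd.DataFrame) -> np.ndarray:
    """Boolean site mask for the union of a region's rows (1-based inclusive)."""
    m = np.zeros(len(records), dtype=bool)
    for _, r in region_rows.iterrows():
        m |= (
            (records["chrom"] == r["chrom"])
            & (records["pos"] >= int(r["start"]))
            & (records["pos"] <= int(r["end"]))
        ).to_numpy()
    return m


def prepare_karyotype_matrix(
    matrix: GenotypeMatrix, max_missing: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix for karyotyping from the het-retained call matrix.

    Sites with ``max_missing`` or more missing calls are dropped; remaining
    missing calls are imputed to the common (major) allele.  Dosage coding is
    minor-allele count: common homozygote 0, heterozygote 1, minor homozygote
    2.  Returns ``(dosage, kept)`` where ``kept`` is the boolean site mask of
    retained columns and ``dosage`` is lines x kept-sites.
    """
    calls = matrix.calls
    n_missing = (calls == MISSING).sum(axis=0)
    kept = n_missing < max_missing
    sub = calls[:, kept]
    n_ref = (sub == REF).sum(axis=0)
    n_alt = (sub == ALT).sum(axis=0)
    minor_is_alt = n_alt <= n_ref
    dosage = np.zeros(sub.shape, dtype=np.int8)
    dosage[sub == HET] = 1
    dosage[sub == np.where(minor_is_alt, ALT, REF)[None, :]] = 2
    # imputed MISSING stays at the common-homozygote dosage 0
    return dosage, kept


def select_diagnostic_snps(
    counts: pd.DataFrame,
    region_rows: pd.DataFrame,
    kept_records: pd.DataFrame,
    min_distant_partners: int = 200,
) -> pd.DataFrame:
    """Inversion-diagnostic SNPs: inside the region with many distant partners.

    ``counts`` is a per-site partner-count table (see
    :func:`dgrpld.ld_summary.partner_counts`); ``kept_records`` are the
    (chrom, pos) of sites retained by :func:`prepare_karyotype_matrix`.  The
    default threshold of 200 distant partners is calibrated to a full-size
    panel (millions of sites); scale it down roughly in proportion to the
    number of catalogued sites in the region for smaller panels.
    """
    in_region = region_site_mask(counts, region_rows)
    sel = counts.loc[
        in_region & (counts["n_partners_distant"] >= min_distant_partners),
        ["chrom", "pos"],
    ]
    kept_keys = set(zip(kept_records["chrom"], kept_records["pos"].astype(int)))
    sel = sel[
        [
            (c, int(p)) in kept_keys
            for c, p in zip(sel["chrom"], sel["pos"])
        ]
    ]
    if len(sel) == 0:
        raise ValueError(
            "no diagnostic SNPs selected; lower min_distant_partners "
            "(small or synthetic panels need a smaller threshold)"
        )
    return sel.reset_index(drop=True)


def pca_scores(
    dosage: np.ndarray, n_snps: int = 5000, seed: int = 0
) -> tuple[np.ndarray, float]:
    """PC1 scores of lines from a seeded random subset of diagnostic SNPs.

    Columns (sites) are mean-centred; the sign of PC1 is oriented so that the
    minority cluster — the inverted lines, which are rare — scores positive
    (positive skew).  Returns ``(scores, variance_explained)``.
    """
    dosage = np.asarray(dosage, dtype=float)
    n_lines, n_sites = dosage.shape
    if n_lines < 2 or n_sites < 1:
        raise ValueError("need at least 2 lines and 1 site for PCA")
    rng = np.random.default_rng(seed)
    take = min(n_snps, n_sites)
    cols = np.sort(rng.choice(n_sites, size=take, replace=False))
    sub = dosage[:, cols]
    if np.allclose(sub, sub[0]):
        raise ValueError("all lines identical over the selected SNPs; PCA undefined")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(sub)[:, 0]
    # orient: minority cluster positive => right-skewed score distribution
    dev = scores - np.median(scores)
    skew = np.mean(dev**3)
    if skew < 0 or (skew == 0 and scores.mean() < np.median(scores)):
        scores = -scores
    return scores, float(pca.explained_variance_ratio_[0])


def region_heterozygosity(
    matrix: GenotypeMatrix, region_rows: pd.DataFrame
) -> np.ndarray:
    """Per-line H: proportion of called sites in the region scored heterozygous.

    Lines with no called site in the region get NaN.
    """
    m = region_site_mask(matrix.sites, region_rows)
    sub = matrix.calls[:, m]
    n_het = (sub == HET).sum(axis=1)
    n_called = (sub != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)


def _cluster_scores(
    pc1: np.ndarray, seed: int = 0, rel_gap: float = 0.05
) -> list[np.ndarray]:
    """Partition 1-D PC1 scores into up to three clusters, low to high.

    K-means (k = 3, deterministic geometric initialisation at the score
    minimum, midpoint and maximum — heterozygotes must score midway between
    the homozygote clusters because dosage 1 is the average of 0 and 2) is
    followed by a gap check: adjacent clusters separated by less than
    ``rel_gap`` of the total score range are merged, so an unstructured score
    cloud is not forced into three groups.  Returns index arrays ordered by
    cluster centre.
    """
    uniq = np.unique(pc1)
    if len(uniq) == 1:
        return [np.arange(len(pc1))]
    k = min(3, len(uniq))
    lo, hi = pc1.min(), pc1.max()
    if k == 3:
        init = np.array([[lo], [(lo + hi) / 2.0], [hi]])
    else:
        init = np.array([[lo], [hi]])
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    cluster = km.fit_predict(pc1.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_[:, 0])
    groups = [np.flatnonzero(cluster == c) for c in order if (cluster == c).any()]
    span = hi - lo
    merged = [groups[0]]
    for g in groups[1:]:
        gap = pc1[g].min() - pc1[merged[-1]].max()
        if gap <= rel_gap * span:
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    return [np.sort(g) for g in merged]


def call_karyotypes(
    lines: list[str],
    region: str,
    pc1: np.ndarray,
    H: np.ndarray,
    h_threshold: float = H_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify lines as Std / Inv / Het from PC1 scores plus an H flag.

    Scores are partitioned by deterministic 1-D k-means with a gap-based
    merge (see :func:`_cluster_scores`); the lowest-centre cluster is
    Standard, the highest Inverted, the middle Heterozygous.  When only two
    clusters survive, the minority cluster is labelled Het when its mean H
    exceeds ``h_threshold`` and Inv otherwise.  An independent
    ``flag`` column marks lines whose heterozygosity disagrees with the call
    (H above threshold for a homozygous call, or below it for a Het call).
    """
    pc1 = np.asarray(pc1, dtype=float)
    H = np.asarray(H, dtype=float)
    if len(pc1) < 3:
        raise ValueError("need at least 3 lines to classify karyotypes")
    groups = _cluster_scores(pc1, seed=seed)
    if len(groups) == 1:
        label = np.full(len(pc1), "Std", dtype=object)
    elif len(groups) == 3:
        label = np.full(len(pc1), "Std", dtype=object)
        label[groups[1]] = "Het"
        label[groups[2]] = "Inv"
    else:  # two clusters: majority is Std; minority Het or Inv via its H
        sizes = [len(g) for g in groups]
        minor = int(np.argmin(sizes))
        main = 1 - minor
        minor_h = np.nanmean(H[groups[minor]])
        minor_label = "Het" if minor_h > h_threshold else "Inv"
        label = np.full(len(pc1), "Std", dtype=object)
        if np.mean(pc1[groups[minor]]) > np.mean(pc1[groups[main]]):
            label[groups[minor]] = minor_label
        else:  # minority below the main cluster: main cluster is the rare side
            label[groups[main]] = minor_label
    high_h = H > h_threshold
    flag = np.full(len(pc1), "", dtype=object)
    flag[(label != "Het") & high_h] = "high_H_without_het_call"
    flag[(label == "Het") & ~high_h] = "het_call_without_high_H"
    return pd.DataFrame(
        {
            "line": list(lines),
            "region": region,
            "pc1": pc1,
            "H": H,
            "call": label,
            "flag": flag,
        }
    )


def karyotype_region(
    matrix: GenotypeMatrix,
    records: pd.DataFrame,
    counts: pd.DataFrame,
    region_rows: pd.DataFrame,
    region_name: str,
    min_distant_partners: int = 200,
    n_snps: int = 5000,
    h_threshold: float = H_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Full karyotyping pipeline for one inversion region.

    ``matrix`` must be the het-retained matrix; ``records`` its site table;
    ``counts`` the per-site distant-partner degrees from the LD catalogue.
    """
    dosage, kept = prepare_karyotype_matrix(matrix)
    kept_records = matrix.sites.loc[kept, ["chrom", "pos"]].reset_index(drop=True)
    diag = select_diagnostic_snps(
        counts, region_rows, kept_records, min_distant_partners
    )
    diag_keys = set(zip(diag["chrom"], diag["pos"].astype(int)))
    cols = np.array(
        [
            (c, int(p)) in diag_keys
            for c, p in zip(kept_records["chrom"], kept_records["pos"])
        ]
    )
    scores, _ = pca_scores(dosage[:, cols], n_snps=n_snps, seed=seed)
    H = region_heterozygosity(matrix, region_rows)
    return call_karyotypes(
        matrix.lines, region_name, scores, H, h_threshold=h_threshold, seed=seed
    )


def concordance_table(
    calls: pd.DataFrame, external: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate our karyotype calls against external assignments.

    ``external`` has columns line, region, call with labels in
    {Std, Inv, Het, NA}; NA rows and unknown (line, region) keys are skipped.
    Returns ``(crosstab, discordant)`` where ``discordant`` lists each
    conflicting (line, region) with both labels plus PC1 and H.
    """
    ext = external[external["call"].isin(["Std", "Inv", "Het"])]
    merged = calls.merge(
        ext, on=["line", "region"], how="inner", suffixes=("", "_external")
    )
    crosstab = pd.crosstab(merged["call"], merged["call_external"])
    disc = merged[merged["call"] != merged["call_external"]]
    discordant = disc[["line", "region", "call", "call_external", "pc1", "H"]].copy()
    return crosstab, discordant.reset_index(drop=True)
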