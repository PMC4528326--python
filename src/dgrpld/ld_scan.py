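"""All-pairs high-LD catalogue via MAF binning and MAF-window candidate pruning.

LD is parameterised as r^2, the squared product-moment (Pearson) correlation
between minor-allele-coded genotype vectors, computed over pairwise-complete
lines.  Because two sites can only be strongly correlated when their minor
allele frequencies are similar (for a cutoff c and focal MAF p, a partner must
satisfy c*p < MAF < p/c), the scan bins sites by MAF rounded to the nearest
0.01 and, for each bin, computes correlations only against partner sites
inside an admissible MAF window.  This avoids the quadratic all-pairs cost
while detecting (on complete data, with theoretical windows) exactly the pairs
a brute-force enumeration would find.  With missing data the realised MAFs
shift between pairwise subsets, so a small fraction of qualifying pairs can be
missed; the default window adds an empirically fitted quadratic limit plus a
margin to keep that miss rate small.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, ld_coded

logger = logging.getLogger(__name__)

#: pairs farther apart than this (bp) are "distant"
DISTANT_BP: int = 100_000

#: coefficients (c0, c1, c2) of the empirical quadratic partner-MAF limit
#: hi(p_b) = c0 + c1*p_b + c2*p_b^2 fitted on the DGRP at r^2 > 0.5
EMPIRICAL_LIMIT_COEF: tuple[float, float, float] = (0.01, 1.875, -1.17)

CATALOG_COLUMNS = [
    "chrom_a", "pos_a", "chrom_b", "pos_b",
    "r2", "n_complete", "maf_a", "maf_b", "distance", "pair_class",
]


# ---------------------------------------------------------------------------
# r^2 kernel
# ---------------------------------------------------------------------------

def pairwise_r2(
    X: np.ndarray, Y: np.ndarray | None = None, min_complete: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete squared Pearson correlation between genotype columns.

    ``X`` (and optionally ``Y``) are lines x sites arrays coded 0/1 with any
    other value treated as missing.  Returns ``(r2, n_complete)`` of shape
    (sites_X, sites_Y); entries are NaN where fewer than ``min_complete``
    lines are jointly called or where either restricted vector is constant.

    Implemented with masked matrix products: for 0/1 data the sums of x, x^2
    and xy over the jointly-called lines are all inner products of the
    genotype and mask matrices, so the full block costs three matmuls.
    """
    X = np.asarray(X)
    Y = X if Y is None else np.asarray(Y)
    Mx = ((X == 0) | (X == 1)).astype(np.float64)
    My = ((Y == 0) | (Y == 1)).astype(np.float64)
    Gx = (X == 1).astype(np.float64)
    Gy = (Y == 1).astype(np.float64)
    n = Mx.T @ My
    sx = Gx.T @ My
    sy = Mx.T @ Gy
    sxy = Gx.T @ Gy
    with np.errstate(invalid="ignore", divide="ignore"):
        px = sx / n
        py = sy / n
        cov = sxy / n - px * py
        var_x = px * (1.0 - px)
        var_y = py * (1.0 - py)
        r2 = (cov * cov) / (var_x * var_y)
    bad = (n < min_complete) | (var_x <= 0) | (var_y <= 0)
    r2 = np.where(bad, np.nan, r2)
    return r2, n.astype(np.int64)


def r_squared(x, y, min_complete: int = 2) -> tuple[float, int]:
    """r^2 and joint call count for two call vectors (codes 0/1/missing).

    Returns ``(nan, n_complete)`` when the correlation is undefined (fewer
    than ``min_complete`` jointly-called lines, or a constant restricted
    vector).
    """
    x = np.asarray(x).reshape(-1, 1)
    y = np.asarray(y).reshape(-1, 1)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    r2, n = pairwise_r2(x, y, min_complete=min_complete)
    return float(r2[0, 0]), int(n[0, 0])


# ---------------------------------------------------------------------------
# MAF windows and binning
# ---------------------------------------------------------------------------

def theoretical_maf_window(p: float, r2_cut: float) -> tuple[float, float]:
    """Closed-form admissible partner-MAF interval (r2_cut*p, min(p/r2_cut, 0.5))."""
    if not 0 < p <= 0.5:
        raise ValueError("p must lie in (0, 0.5]")
    if not 0 < r2_cut <= 1:
        raise ValueError("r2_cut must lie in (0, 1]")
    return r2_cut * p, min(p / r2_cut, 0.5)


def empirical_maf_limit(
    p_b: float, coef: tuple[float, float, float] = EMPIRICAL_LIMIT_COEF
) -> float:
    """Quadratic upper partner-MAF limit for a focal bin at frequency ``p_b``."""
    c0, c1, c2 = coef
    return c0 + c1 * p_b + c2 * p_b * p_b


def max_r2_complete(p: float, q: float) -> float:
    """Maximum attainable r^2 between two biallelic sites with folded MAFs p, q.

    On complete data with minor frequencies p <= q <= 0.5, perfect nesting of
    the rarer site's carriers inside the commoner site's carriers maximises
    the correlation at ``p(1-q) / (q(1-p))``.
    """
    p, q = (p, q) if p <= q else (q, p)
    if p <= 0 or q >= 1:
        return 0.0
    return p * (1.0 - q) / (q * (1.0 - p))


def fit_empirical_limit(
    matrix: GenotypeMatrix,
    records: pd.DataFrame,
    r2_cut: float = 0.5,
    min_pairs_per_bin: int = 1,
) -> tuple[float, float, float]:
    """Re-estimate the quadratic partner-MAF limit on a given panel.

    For each focal MAF bin, the maximum partner MAF attaining
    ``r^2 >= r2_cut`` is found by brute-force pair enumeration; a quadratic is
    then least-squares fitted to those per-bin maxima.  Returns the fitted
    (c0, c1, c2).
    """
    X = ld_coded(matrix)
    maf = records["maf"].to_numpy()
    ok = np.isfinite(maf) & (maf > 0)
    idx = np.flatnonzero(ok)
    r2, _ = pairwise_r2(X[:, idx])
    np.fill_diagonal(r2, np.nan)
    hit = r2 >= r2_cut
    bins = bin_of(maf[idx])
    xs, ys = [], []
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        partner_mafs = maf[idx][hit[members].any(axis=0)]
        if len(partner_mafs) >= min_pairs_per_bin:
            xs.append(b / 100.0)
            ys.append(partner_mafs.max())
    if len(xs) < 3:
        raise ValueError("too few populated bins to fit a quadratic limit")
    c2, c1, c0 = np.polyfit(np.asarray(xs), np.asarray(ys), 2)
    return float(c0), float(c1), float(c2)


def bin_of(maf: np.ndarray) -> np.ndarray:
    """Integer MAF bin (frequency x 100) by round-half-up to the nearest 0.01."""
    maf = np.asarray(maf, dtype=float)
    return np.floor(maf * 100.0 + 0.5).astype(int)


def bin_by_maf(records: pd.DataFrame, mask: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Group site indices into MAF bins (keys are frequency x 100, ascending)."""
    maf = records["maf"].to_numpy()
    eligible = np.isfinite(maf)
    if mask is not None:
        eligible &= np.asarray(mask, dtype=bool)
    bins = np.full(len(maf), -1)
    bins[eligible] = bin_of(maf[eligible])
    return {
        int(b): np.flatnonzero(bins == b) for b in np.unique(bins[eligible])
    }


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def classify_pairs(chrom_a, pos_a, chrom_b, pos_b, distant_bp: int = DISTANT_BP):
    """Vectorised pair classification: local / distant / interchromosomal."""
    chrom_a = np.asarray(chrom_a)
    chrom_b = np.asarray(chrom_b)
    pos_a = np.asarray(pos_a, dtype=np.int64)
    pos_b = np.asarray(pos_b, dtype=np.int64)
    same = chrom_a == chrom_b
    dist = np.where(same, np.abs(pos_b - pos_a), -1)
    cls = np.where(
        ~same, "interchromosomal", np.where(dist > distant_bp, "distant", "local")
    )
    return cls, dist


def classify_pair(site_a: tuple[str, int], site_b: tuple[str, int]) -> str:
    """Pair class for two (chrom, pos) keys; 'distant' means > 100 kb apart."""
    cls, _ = classify_pairs([site_a[0]], [site_a[1]], [site_b[0]], [site_b[1]])
    return str(cls[0])


def scan_high_ld(
    matrix: GenotypeMatrix,
    records: pd.DataFrame,
    focal: np.ndarray,
    partner: np.ndarray,
    r2_cut: float = 0.5,
    window: str = "empirical",
    limit_coef: tuple[float, float, float] = EMPIRICAL_LIMIT_COEF,
    window_margin: float = 0.005,
    min_complete: int = 2,
    distant_bp: int = DISTANT_BP,
) -> pd.DataFrame:
    """Catalogue all focal-partner site pairs with ``r^2 >= r2_cut``.

    Proceeds bin by bin in ascending focal MAF.  For a bin at frequency
    ``p_b`` the candidate partners are all partner-eligible sites with MAF in
    ``[r2_cut*(p_b - 0.005), hi]`` where ``hi`` is the theoretical limit
    ``(p_b + 0.005)/r2_cut`` (window='theoretical') or the maximum of that and
    the empirical quadratic limit plus ``window_margin`` (window='empirical',
    the default).  The lower bound extends below the bin so same-bin pairs and
    pairs whose lower-MAF member is partner-only are all examined.  Each
    unordered pair is emitted exactly once: focal-focal pairs only from the
    lower bin (ties broken by (chrom, pos) order), focal-nonfocal pairs from
    the focal member's bin.

    Returns a DataFrame with :data:`CATALOG_COLUMNS`, sorted by
    (chrom_a, pos_a, chrom_b, pos_b); contains no RNG and is deterministic.
    """
    if window not in ("empirical", "theoretical"):
        raise ValueError("window must be 'empirical' or 'theoretical'")
    X = ld_coded(matrix)
    maf = records["maf"].to_numpy()
    chrom = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy(dtype=np.int64)
    focal = np.asarray(focal, dtype=bool)
    partner = np.asarray(partner, dtype=bool)
    poly = maf > 0
    focal = focal & np.isfinite(maf) & poly
    partner = partner & np.isfinite(maf) & poly
    if not focal.any():
        logger.warning("empty focal set: returning empty catalog")
        return pd.DataFrame(columns=CATALOG_COLUMNS)

    bins = bin_of(np.where(np.isfinite(maf), maf, 0.0))
    partner_idx = np.flatnonzero(partner)
    partner_maf = maf[partner_idx]
    order = np.argsort(partner_maf, kind="stable")
    partner_idx = partner_idx[order]
    partner_maf = partner_maf[order]

    focal_bins = bin_by_maf(records, mask=focal)
    out_frames = []
    eps = 1e-12
    for b in sorted(focal_bins):
        members = focal_bins[b]
        p_b = b / 100.0
        lo = r2_cut * (p_b - 0.005) - eps
        hi_theo = (p_b + 0.005) / r2_cut
        if window == "theoretical":
            hi = hi_theo
        else:
            hi = max(hi_theo, empirical_maf_limit(p_b, limit_coef) + window_margin)
        hi = min(hi, 0.5) + eps
        j0 = np.searchsorted(partner_maf, lo, side="left")
        j1 = np.searchsorted(partner_maf, hi, side="right")
        cand = partner_idx[j0:j1]
        if len(cand) == 0:
            continue
        r2, n = pairwise_r2(X[:, members], X[:, cand], min_complete=min_complete)
        with np.errstate(invalid="ignore"):
            hits = r2 >= r2_cut
        if not hits.any():
            continue
        fi, ci = np.nonzero(hits)
        f_sites = members[fi]
        c_sites = cand[ci]
        # dedup: emit focal-focal pairs from the lower bin only (key order in
        # ties); focal-nonfocal always (the focal member owns the pair)
        c_is_focal = focal[c_sites]
        same_site = f_sites == c_sites
        f_key = list(zip(chrom[f_sites], pos[f_sites]))
        c_key = list(zip(chrom[c_sites], pos[c_sites]))
        keep = ~same_site & (
            ~c_is_focal
            | (bins[c_sites] > b)
            | ((bins[c_sites] == b) & np.array([ck > fk for fk, ck in zip(f_key, c_key)]))
        )
        if not keep.any():
            continue
        f_sites, c_sites = f_sites[keep], c_sites[keep]
        r2v = r2[fi[keep], ci[keep]]
        nv = n[fi[keep], ci[keep]]
        swap = np.array(
            [
                (chrom[cs], pos[cs]) < (chrom[fs], pos[fs])
                for fs, cs in zip(f_sites, c_sites)
            ]
        )
        a_sites = np.where(swap, c_sites, f_sites)
        b_sites = np.where(swap, f_sites, c_sites)
        cls, dist = classify_pairs(
            chrom[a_sites], pos[a_sites], chrom[b_sites], pos[b_sites], distant_bp
        )
        out_frames.append(
            pd.DataFrame(
                {
                    "chrom_a": chrom[a_sites],
                    "pos_a": pos[a_sites],
                    "chrom_b": chrom[b_sites],
                    "pos_b": pos[b_sites],
                    "r2": r2v,
                    "n_complete": nv,
                    "maf_a": maf[a_sites],
                    "maf_b": maf[b_sites],
                    "distance": dist,
                    "pair_class": cls,
                }
            )
        )
    if not out_frames:
        return pd.DataFrame(columns=CATALOG_COLUMNS)
    catalog = pd.concat(out_frames, ignore_index=True)
    catalog = catalog.sort_values(
        ["chrom_a", "pos_a", "chrom_b", "pos_b"], kind="stable"
    ).reset_index(drop=True)
    return catalog[CATALOG_COLUMNS]


def brute_force_pairs(
    matrix: GenotypeMatrix,
    records: pd.DataFrame,
    focal: np.ndarray,
    partner: np.ndarray,
    r2_cut: float = 0.5,
    min_complete: int = 2,
) -> set[tuple[str, int, str, int]]:
    """All-pairs reference enumeration (no MAF pruning) of qualifying pairs.

    Considers every unordered pair with at least one focal member and both
    members partner-eligible.  Returns canonical (chrom_a, pos_a, chrom_b,
    pos_b) keys.  Quadratic; intended for validation on small panels.
    """
    X = ld_coded(matrix)
    idx = np.flatnonzero(np.asarray(partner, dtype=bool))
    focal = np.asarray(focal, dtype=bool)
    r2, _ = pairwise_r2(X[:, idx], min_complete=min_complete)
    chrom = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy(dtype=np.int64)
    pairs = set()
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(np.triu(r2 >= r2_cut, k=1))
    for i, j in zip(idx[ii], idx[jj]):
        if not (focal[i] or focal[j]):
            continue
        ka = (str(chrom[i]), int(pos[i]))
        kb = (str(chrom[j]), int(pos[j]))
        if kb < ka:
            ka, kb = kb, ka
        pairs.add((ka[0], ka[1], kb[0], kb[1]))
    return pairs


def catalog_pair_keys(catalog: pd.DataFrame) -> set[tuple[str, int, str, int]]:
    """Canonical pair-key set of a catalog DataFrame."""
    return {
        (str(ca), int(pa), str(cb), int(pb))
        for ca, pa, cb, pb in zip(
            catalog["chrom_a"], catalog["pos_a"], catalog["chrom_b"], catalog["pos_b"]
        )
    }
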