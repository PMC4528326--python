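"""Monte-Carlo false-positive profile for association tests on correlated SNPs.

A causal ("focal") SNP is given a small phenotypic effect on a multivariate
trait and every SNP correlated with it ("its SNP family", r^2 above a family
threshold) is tested with a MANOVA using SNP genotype as the sole predictor.
The rejection probability of the non-causal partners, binned by their r^2
with the focal SNP, quantifies how likely LD is to manufacture significant
associations at each significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, ld_coded


@dataclass
class FPSimConfig:
    """Knobs of the false-positive simulation.

    ``variance_fraction`` is the share of total phenotypic variance (trace of
    the phenotypic covariance) explained by the focal genotype; the trait is
    ``trait_dim``-dimensional with unit-variance isotropic noise and an
    effect direction drawn uniformly on the sphere.  The trait dimension and
    noise model are simulation choices, not estimates of any particular
    study.
    """

    n_focal: int = 100
    per_decile: int = 10
    partner_cap: int = 100
    family_r2_threshold: float = 0.25
    variance_fraction: float = 0.01
    trait_dim: int = 10
    n_reps: int = 5
    alphas: tuple[float, ...] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
    r2_bin_width: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_fraction < 1.0:
            raise ValueError("variance_fraction must lie in [0, 1)")
        if self.trait_dim < 1:
            raise ValueError("trait_dim must be >= 1")
        if any(not 0.0 < a <= 1.0 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1]")


@dataclass
class SNPFamily:
    """A focal site plus the partners correlated with it above the threshold."""

    focal: tuple[str, int]
    partners: list[tuple[str, int]]
    partner_r2: np.ndarray
    maf: float
    decile: int = 0


@dataclass
class ManovaResult:
    wilks_lambda: float
    chi2: float
    df: int
    p_value: float


def build_snp_families(
    catalog: pd.DataFrame, records: pd.DataFrame, config: FPSimConfig
) -> list[SNPFamily]:
    """Sample focal SNPs per MAF decile and collect their capped partner sets.

    Eligible focal SNPs are those appearing in at least one catalogue pair
    (the catalogue must have been computed at the family r^2 threshold).
    ``per_decile`` focal SNPs are drawn from each decile of the eligible MAF
    distribution; deciles with fewer eligible SNPs contribute all of them.
    Families with more than ``partner_cap`` partners are down-sampled.
    """
    rng = np.random.default_rng(config.seed)
    neighbors: dict[tuple[str, int], list[tuple[tuple[str, int], float]]] = {}
    for ca, pa, cb, pb, r2 in zip(
        catalog["chrom_a"], catalog["pos_a"], catalog["chrom_b"],
        catalog["pos_b"], catalog["r2"],
    ):
        a, b = (str(ca), int(pa)), (str(cb), int(pb))
        neighbors.setdefault(a, []).append((b, float(r2)))
        neighbors.setdefault(b, []).append((a, float(r2)))
    maf_of = {
        (str(c), int(p)): float(m)
        for c, p, m in zip(records["chrom"], records["pos"], records["maf"])
    }
    eligible = sorted(k for k in neighbors if k in maf_of)
    if not eligible:
        return []
    mafs = np.array([maf_of[k] for k in eligible])
    edges = np.quantile(mafs, np.linspace(0, 1, 11))
    decile = np.clip(np.searchsorted(edges, mafs, side="right") - 1, 0, 9)
    families = []
    for d in range(10):
        pool = np.flatnonzero(decile == d)
        take = min(config.per_decile, len(pool))
        for i in rng.choice(pool, size=take, replace=False):
            key = eligible[i]
            partners = neighbors[key]
            if len(partners) > config.partner_cap:
                sel = rng.choice(len(partners), size=config.partner_cap, replace=False)
                partners = [partners[j] for j in sel]
            families.append(
                SNPFamily(
                    focal=key,
                    partners=[p for p, _ in partners],
                    partner_r2=np.array([r for _, r in partners]),
                    maf=maf_of[key],
                    decile=d,
                )
            )
    return families


def simulate_phenotypes(
    g: np.ndarray,
    trait_dim: int,
    variance_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multivariate phenotypes with the genotype explaining a set variance share.

    ``g`` is the 0/1 focal genotype over lines (no missing entries).  The
    effect vector has a uniformly random direction and its magnitude is
    scaled against the realised genotype variance so that the genotype
    explains ``variance_fraction`` of the total phenotypic variance (trace
    of signal-plus-noise covariance, unit isotropic noise).
    """
    if trait_dim < 1:
        raise ValueError("trait_dim must be >= 1")
    g = np.asarray(g, dtype=float)
    n = len(g)
    noise = rng.standard_normal((n, trait_dim))
    if variance_fraction == 0.0:
        return noise
    var_g = g.var(ddof=1)
    if var_g <= 0:
        raise ValueError("focal genotype is constant; cannot scale an effect")
    direction = rng.standard_normal(trait_dim)
    direction /= np.linalg.norm(direction)
    f = variance_fraction
    mag = np.sqrt(trait_dim * f / ((1.0 - f) * var_g))
    return np.outer(g, mag * direction) + noise


def manova_wilks(Y: np.ndarray, g: np.ndarray) -> ManovaResult:
    """One-predictor MANOVA via Wilks' Lambda with Bartlett's chi-square approximation.

    Lambda = det(E) / det(E + H) where E is the residual cross-product matrix
    of the model with the genotype predictor and H the hypothesis matrix (the
    reduction from the intercept-only model).  The test statistic is
    ``-(n - 1 - (d + q + 1)/2) * ln(Lambda)`` with d traits and q = 1
    predictor, referred to a chi-square with d*q degrees of freedom.
    """
    Y = np.asarray(Y, dtype=float)
    g = np.asarray(g, dtype=float)
    n, d = Y.shape
    if len(np.unique(g)) < 2:
        raise ValueError("genotype predictor has fewer than 2 levels")
    if n < d + 3:
        raise ValueError("too few lines for the trait dimension")
    Yc = Y - Y.mean(axis=0)
    gc = g - g.mean()
    e_reduced = Yc.T @ Yc
    beta = (gc @ Yc) / (gc @ gc)
    resid = Yc - np.outer(gc, beta)
    e_full = resid.T @ resid
    sign_f, logdet_f = np.linalg.slogdet(e_full)
    sign_t, logdet_t = np.linalg.slogdet(e_reduced)
    if sign_f <= 0 or sign_t <= 0:
        raise ValueError("singular residual matrix: too few lines for trait_dim")
    log_lambda = logdet_f - logdet_t
    lam = float(np.exp(log_lambda))
    q = 1
    factor = n - 1 - (d + q + 1) / 2.0
    chi2 = float(max(-factor * log_lambda, 0.0))
    df = d * q
    p = float(stats.chi2.sf(chi2, df))
    return ManovaResult(wilks_lambda=lam, chi2=chi2, df=df, p_value=p)


def _genotype_lookup(matrix: GenotypeMatrix) -> tuple[np.ndarray, dict]:
    X = ld_coded(matrix)
    index = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(matrix.sites["chrom"], matrix.sites["pos"]))
    }
    return X, index


def fp_profile(
    matrix: GenotypeMatrix,
    families: list[SNPFamily],
    config: FPSimConfig,
) -> pd.DataFrame:
    """Rejection probability per r^2 bin and significance threshold.

    For each family and replicate, phenotypes are simulated from the focal
    genotype and a MANOVA is run at the focal SNP itself (the power estimate,
    reported with role='focal') and at every partner (role='partner', binned
    by the partner's catalogue r^2 with the focal SNP).  Lines missing the
    focal call are dropped from the replicate; lines missing a partner call
    are dropped from that partner's test.

    Returns a tidy DataFrame: role, r2_bin_mid, alpha, n_tests, n_reject,
    rejection_rate, mc_se.
    """
    rng = np.random.default_rng(config.seed + 1)
    X, index = _genotype_lookup(matrix)
    edges = np.arange(
        config.family_r2_threshold, 1.0 + config.r2_bin_width / 2, config.r2_bin_width
    )
    nbins = len(edges) - 1
    alphas = np.asarray(config.alphas)
    rej = np.zeros((nbins, len(alphas)), dtype=np.int64)
    tot = np.zeros(nbins, dtype=np.int64)
    rej_focal = np.zeros(len(alphas), dtype=np.int64)
    tot_focal = 0
    for fam in families:
        jf = index[fam.focal]
        gf = X[:, jf].astype(float)
        keep = gf >= 0
        gfk = gf[keep]
        if len(np.unique(gfk)) < 2:
            continue
        pj = [index[p] for p in fam.partners]
        bins = np.clip(
            np.searchsorted(edges, fam.partner_r2, side="left") - 1, 0, nbins - 1
        )
        for _ in range(config.n_reps):
            Y = simulate_phenotypes(
                gfk, config.trait_dim, config.variance_fraction, rng
            )
            res = manova_wilks(Y, gfk)
            tot_focal += 1
            rej_focal += res.p_value < alphas
            for j, b in zip(pj, bins):
                gp = X[keep, j].astype(float)
                ok = gp >= 0
                if len(np.unique(gp[ok])) < 2 or ok.sum() < config.trait_dim + 3:
                    continue
                res_p = manova_wilks(Y[ok], gp[ok])
                tot[b] += 1
                rej[b] += res_p.p_value < alphas
    rows = []
    mids = (edges[:-1] + edges[1:]) / 2.0
    for b in range(nbins):
        for ai, alpha in enumerate(alphas):
            n = int(tot[b])
            rate = rej[b, ai] / n if n else np.nan
            se = np.sqrt(rate * (1 - rate) / n) if n else np.nan
            rows.append(("partner", mids[b], alpha, n, int(rej[b, ai]), rate, se))
    for ai, alpha in enumerate(alphas):
        n = tot_focal
        rate = rej_focal[ai] / n if n else np.nan
        se = np.sqrt(rate * (1 - rate) / n) if n else np.nan
        rows.append(("focal", 1.0, alpha, n, int(rej_focal[ai]), rate, se))
    return pd.DataFrame(
        rows,
        columns=[
            "role", "r2_bin_mid", "alpha", "n_tests",
            "n_reject", "rejection_rate", "mc_se",
        ],
    )


def null_rejection_rates(
    n_lines: int,
    trait_dim: int,
    n_tests: int,
    alphas: tuple[float, ...],
    seed: int = 0,
    maf: float = 0.3,
) -> pd.DataFrame:
    """Type-I calibration: MANOVA rejection rates with no genotype effect.

    Simulates ``n_tests`` independent datasets of pure-noise phenotypes with
    a random balanced-ish genotype (minor allele frequency ``maf``) and
    reports the rejection proportion at each alpha with its binomial SE.
    """
    rng = np.random.default_rng(seed)
    alphas_arr = np.asarray(alphas)
    rej = np.zeros(len(alphas_arr), dtype=np.int64)
    done = 0
    while done < n_tests:
        g = (rng.random(n_lines) < maf).astype(float)
        if len(np.unique(g)) < 2:
            continue
        Y = rng.standard_normal((n_lines, trait_dim))
        res = manova_wilks(Y, g)
        rej += res.p_value < alphas_arr
        done += 1
    rows = []
    for ai, alpha in enumerate(alphas_arr):
        rate = rej[ai] / n_tests
        se = np.sqrt(alpha * (1 - alpha) / n_tests)
        rows.append((alpha, n_tests, int(rej[ai]), rate, se))
    return pd.DataFrame(
        rows, columns=["alpha", "n_tests", "n_reject", "rejection_rate", "binomial_se"]
    )
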