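"""Genotype containers, VCF input, and the site/line filters applied before LD analysis.

Calls are held as an int8 matrix of lines x sites with the four call codes
``REF``, ``ALT``, ``HET``, ``MISSING``.  Two encodings are used downstream:

* the *LD encoding*, in which heterozygous calls are treated as missing data
  (inbred lines are expected to be homozygous; residual heterozygosity is a
  nuisance for pairwise correlation), and
* the *karyotyping encoding*, which retains heterozygotes as dosage 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REF: int = 0
ALT: int = 1
HET: int = 2
MISSING: int = -1

#: default genotype-quality threshold (phred scale): calls below are set missing
MIN_PHRED: int = 20


@dataclass
class GenotypeMatrix:
    """Lines x sites call matrix with site and line metadata.

    Attributes
    ----------
    lines : list of str
        Ordered sample (inbred line) identifiers.
    sites : pandas.DataFrame
        One row per site with at least ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt`` columns, in matrix column order.
    calls : numpy.ndarray of int8, shape (n_lines, n_sites)
        Call codes ``REF``/``ALT``/``HET``/``MISSING``.
    quals : numpy.ndarray or None
        Optional per-call phred genotype qualities, same shape as ``calls``.
    """

    lines: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    quals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.lines)} lines x {len(self.sites)} sites"
            )
        valid = np.isin(self.calls, (REF, ALT, HET, MISSING))
        if not valid.all():
            raise ValueError("calls contain codes outside {REF, ALT, HET, MISSING}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> list[tuple[str, int]]:
        """(chrom, pos) key per site, in column order."""
        return list(zip(self.sites["chrom"], self.sites["pos"].astype(int)))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.lines),
            self.sites.copy(),
            self.calls.copy(),
            None if self.quals is None else self.quals.copy(),
        )


def read_genotypes(
    vcf_path, min_phred: int = MIN_PHRED, missing_qual_passes: bool = True
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic sites are retained (multiallelic records are dropped and
    logged).  Any call whose genotype quality (GQ) is below ``min_phred`` is
    set to MISSING.  Diploid genotypes map as 0/0 -> REF, 1/1 -> ALT,
    0/1 or 1/0 -> HET, ./. -> MISSING.

    Parameters
    ----------
    vcf_path : str or Path
        VCF 4.x file with GT (and ideally GQ) per genotype.
    min_phred : int
        Phred-scale genotype-quality threshold; calls below become MISSING.
    missing_qual_passes : bool
        If the GQ field is absent, treat calls as passing (with a warning)
        when True; otherwise set them MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    lines = list(vcf.samples)
    rows = []
    call_cols: list[np.ndarray] = []
    qual_cols: list[np.ndarray] = []
    n_multi = 0
    warned_no_gq = False
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gts = variant.genotype.array()  # (n_samples, ploidy+1); last col phasing
        a, b = gts[:, 0], gts[:, 1]
        codes = np.full(len(lines), MISSING, dtype=np.int8)
        codes[(a == 0) & (b == 0)] = REF
        codes[(a == 1) & (b == 1)] = ALT
        codes[((a == 0) & (b == 1)) | ((a == 1) & (b == 0))] = HET
        try:
            gq = variant.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            gq = np.asarray(gq, dtype=float).reshape(len(lines))
            low = np.isfinite(gq) & (gq >= 0) & (gq < min_phred)
            codes[low] = MISSING
            qual_cols.append(gq)
        else:
            if not warned_no_gq:
                if missing_qual_passes:
                    warnings.warn(
                        "VCF has no GQ field; treating all calls as passing quality"
                    )
                warned_no_gq = True
            if not missing_qual_passes:
                codes[:] = MISSING
            qual_cols.append(np.full(len(lines), np.nan))
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        call_cols.append(codes)
    vcf.close()
    if n_multi:
        logger.info("dropped %d multiallelic site(s)", n_multi)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = (
        np.column_stack(call_cols)
        if call_cols
        else np.empty((len(lines), 0), dtype=np.int8)
    )
    quals = np.column_stack(qual_cols) if qual_cols else None
    return GenotypeMatrix(lines, sites, calls, quals)


def encode_for_ld(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy with every HET call recoded as MISSING (LD encoding)."""
    out = matrix.copy()
    out.calls[out.calls == HET] = MISSING
    return out


def site_statistics(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site allele-count statistics.

    Returns a DataFrame aligned with ``matrix.sites`` carrying ``mac`` (minor
    allele count), ``maf`` (minor allele frequency, in [0, 0.5]), ``n_called``,
    ``n_missing``, ``n_het`` and ``minor_is_alt``.  Counts are over
    homozygous calls only; HET calls (if present) are tallied in ``n_het`` and
    excluded from ``n_called``.  Sites with no called genotypes get maf = NaN.

    The minor allele is the rarer of REF/ALT; at an exact tie ALT is
    designated minor so the 0/1 coding is deterministic (r-squared is
    invariant to the choice).
    """
    calls = matrix.calls
    n_ref = (calls == REF).sum(axis=0)
    n_alt = (calls == ALT).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_called = n_ref + n_alt
    n_missing = (calls == MISSING).sum(axis=0)  # HET tallied separately
    minor_is_alt = n_alt <= n_ref  # tie -> ALT minor
    mac = np.where(minor_is_alt, n_alt, n_ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_called > 0, mac / np.maximum(n_called, 1), np.nan)
    out = matrix.sites[["chrom", "pos"]].copy()
    out["mac"] = mac.astype(int)
    out["maf"] = maf
    out["n_called"] = n_called.astype(int)
    out["n_missing"] = n_missing.astype(int)
    out["n_het"] = n_het.astype(int)
    out["minor_is_alt"] = minor_is_alt
    return out


def filter_sites(
    records: pd.DataFrame,
    mac_focal: int = 5,
    mac_partner: int = 3,
    max_missing: int | None = 85,
    max_missing_frac: float | None = None,
    n_lines: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Focal/partner eligibility masks from per-site statistics.

    Focal sites require ``mac >= mac_focal`` (default 5); partner sites
    require ``mac >= mac_partner`` (default 3); both exclude sites with more
    than ``max_missing`` missing calls (default 85, an absolute count chosen
    for a 205-line panel).  ``max_missing_frac`` may be given instead for
    panels of other sizes (requires ``n_lines``).

    Returns ``(focal_mask, partner_mask)`` boolean arrays; focal is always a
    subset of partner.
    """
    if max_missing_frac is not None:
        if n_lines is None:
            raise ValueError("max_missing_frac requires n_lines")
        max_missing = int(np.floor(max_missing_frac * n_lines))
    if max_missing is None:
        raise ValueError("one of max_missing or max_missing_frac is required")
    if mac_partner > mac_focal:
        raise ValueError("mac_partner must be <= mac_focal (focal subset of partner)")
    ok_missing = records["n_missing"].to_numpy() <= max_missing
    mac = records["mac"].to_numpy()
    focal = ok_missing & (mac >= mac_focal)
    partner = ok_missing & (mac >= mac_partner)
    return focal, partner


def ld_coded(matrix: GenotypeMatrix, records: pd.DataFrame | None = None) -> np.ndarray:
    """0/1/-1 minor-allele coding of an LD-encoded matrix.

    ALT homozygotes are 1 and REF 0 regardless of which allele is minor;
    r-squared is invariant to a per-site relabeling, so the plain ALT-count
    coding is used.  HET calls must have been recoded beforehand.
    """
    if (matrix.calls == HET).any():
        raise ValueError("matrix still contains HET calls; apply encode_for_ld first")
    return matrix.calls.astype(np.int8)  # REF=0, ALT=1, MISSING=-1


def write_site_table(records: pd.DataFrame, focal: np.ndarray, path) -> None:
    """Write the filtered site table as TSV with a focal flag column."""
    out = records.copy()
    out["focal_flag"] = np.asarray(focal).astype(int)
    out.to_csv(path, sep="\t", index=False)
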