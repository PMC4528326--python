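"""Synthetic inbred-line panel generator with known LD, inversion and
heterozygosity structure.

The generator emulates a sequenced inbred panel such as the DGRP: ~hundreds of
lines, a rare-skewed folded site-frequency spectrum, haplotype-block local LD,
a few polymorphic inversions at low frequency carrying diverged haplotype
classes (with heterozygous lines), residual-heterozygosity blocks whose
incidence is correlated across regions, missing calls, and per-genotype phred
qualities.  All structure is recorded in a ground-truth manifest.

Design notes
------------
Site frequencies are exact by construction: each site draws a minor allele
count ``k`` from the configured folded spectrum and exactly ``k`` lines carry
the minor allele.  Local LD comes from founder haplotypes: within a haplotype
block each line is assigned one of ``n_founder_haplotypes`` founders and minor
alleles are distributed founder-first along a per-block founder priority
order, so carrier sets of same-block sites are nested and nearby sites are
strongly correlated.  Sites whose ``k`` is below the first founder's carrier
count fall through to individually random carriers, which is what produces
"rarity disequilibrium" among rare variants.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import ALT, HET, MISSING, REF, GenotypeMatrix


@dataclass
class InversionSpec:
    """A polymorphic inversion: two diverged arrangement classes in one region."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    name: str
    frequency: float  # fraction of lines fixed for the inverted arrangement
    divergence: float  # fraction of in-region sites fixed differently between classes
    n_het_lines: int = 0


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults describe a desk-scale DGRP-like panel: 205 lines, two 2-Mb
    chromosome arms with 1500 sites each, folded spectrum with weights
    proportional to 1/k, 10-kb haplotype blocks with 8 founder haplotypes,
    and two low-frequency inversions with heterozygous lines.
    """

    n_lines: int = 205
    chrom_specs: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("2L", 2_000_000, 1500), ("2R", 2_000_000, 1500)]
    )
    maf_spectrum: object = "one_over_k"  # or ("fixed", p) or weight array over k=1..n//2
    block_len: int = 10_000
    n_founder_haplotypes: int = 8
    inversion_specs: list[InversionSpec] = field(
        default_factory=lambda: [
            InversionSpec("2L", 400_001, 1_200_000, "In(2L)sim", 0.07, 0.3, 5),
            InversionSpec("2R", 500_001, 1_300_000, "In(2R)sim", 0.05, 0.3, 3),
        ]
    )
    het_regions: list[tuple[str, int, int, str]] | None = None  # default: whole chroms
    het_block_rate: float = 0.2
    het_block_corr: float = 0.6
    het_block_max_frac: float = 0.2  # max block length as fraction of its region
    missing_rate: float = 0.01
    qual_low_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length, n_sites in self.chrom_specs:
            if n_sites < 1:
                raise ValueError(f"chromosome {name}: n_sites must be >= 1")
            if length < n_sites:
                raise ValueError(f"chromosome {name}: length {length} < n_sites")
        lengths = {name: length for name, length, _ in self.chrom_specs}
        by_chrom: dict[str, list[InversionSpec]] = {}
        for inv in self.inversion_specs:
            if isinstance(inv, (tuple, list)):
                inv = InversionSpec(*inv)
            if inv.chrom not in lengths:
                raise ValueError(f"inversion {inv.name}: unknown chromosome {inv.chrom}")
            if not (1 <= inv.start < inv.end <= lengths[inv.chrom]):
                raise ValueError(f"inversion {inv.name} outside chromosome {inv.chrom}")
            if not 0.0 <= inv.frequency <= 1.0:
                raise ValueError(f"inversion {inv.name}: frequency outside [0, 1]")
            if not 0.0 <= inv.divergence <= 1.0:
                raise ValueError(f"inversion {inv.name}: divergence outside [0, 1]")
            by_chrom.setdefault(inv.chrom, []).append(inv)
        for chrom, invs in by_chrom.items():
            invs = sorted(invs, key=lambda i: i.start)
            for a, b in zip(invs, invs[1:]):
                if a.end >= b.start:
                    raise ValueError(
                        f"overlapping inversion regions {a.name} and {b.name} on {chrom}"
                    )
        self.inversion_specs = [
            InversionSpec(*inv) if isinstance(inv, (tuple, list)) else inv
            for inv in self.inversion_specs
        ]
        if not 0.0 < self.het_block_max_frac <= 1.0:
            raise ValueError("het_block_max_frac must lie in (0, 1]")
        for p in (self.het_block_rate, self.missing_rate, self.qual_low_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 <= self.het_block_corr <= 1.0:
            raise ValueError("het_block_corr must lie in [0, 1]")

    def resolved_het_regions(self) -> list[tuple[str, int, int, str]]:
        if self.het_regions is not None:
            return list(self.het_regions)
        return [(name, 1, length, name) for name, length, _ in self.chrom_specs]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if not isinstance(d["maf_spectrum"], (str, list, tuple)):
            d["maf_spectrum"] = list(np.asarray(d["maf_spectrum"], dtype=float))
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["chrom_specs"] = [tuple(c) for c in d["chrom_specs"]]
        d["inversion_specs"] = [InversionSpec(**i) for i in d["inversion_specs"]]
        if isinstance(d.get("maf_spectrum"), list) and d["maf_spectrum"] and isinstance(
            d["maf_spectrum"][0], str
        ):
            d["maf_spectrum"] = tuple(d["maf_spectrum"])
        if d.get("het_regions") is not None:
            d["het_regions"] = [tuple(r) for r in d["het_regions"]]
        return cls(**d)


@dataclass
class TruthManifest:
    """Ground truth for a synthetic panel.

    ``karyotypes`` maps region name -> per-line labels in {Std, Inv, Het};
    ``diagnostic_sites`` maps region name -> list of (chrom, pos) of sites
    fixed differently between the arrangement classes; ``het_blocks`` maps
    line -> list of (region, start_pos, end_pos) heterozygosity blocks.
    """

    karyotypes: dict[str, dict[str, str]]
    diagnostic_sites: dict[str, list[tuple[str, int]]]
    het_blocks: dict[str, list[tuple[str, int, int]]]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "karyotypes": self.karyotypes,
                "diagnostic_sites": {
                    k: [[c, int(p)] for c, p in v]
                    for k, v in self.diagnostic_sites.items()
                },
                "het_blocks": {
                    k: [[r, int(s), int(e)] for r, s, e in v]
                    for k, v in self.het_blocks.items()
                },
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            karyotypes=d["karyotypes"],
            diagnostic_sites={
                k: [(c, int(p)) for c, p in v]
                for k, v in d["diagnostic_sites"].items()
            },
            het_blocks={
                k: [(r, int(s), int(e)) for r, s, e in v]
                for k, v in d["het_blocks"].items()
            },
            seed=int(d["seed"]),
        )


def _spectrum_weights(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Support (allowed minor allele counts) and weights of the folded spectrum."""
    n = config.n_lines
    kmax = n // 2
    spec = config.maf_spectrum
    if isinstance(spec, str) and spec == "one_over_k":
        ks = np.arange(1, kmax + 1)
        return ks, 1.0 / ks
    if isinstance(spec, (tuple, list)) and len(spec) == 2 and spec[0] == "fixed":
        p = float(spec[1])
        if not 0.0 < p <= 0.5:
            raise ValueError("fixed MAF must lie in (0, 0.5]")
        k = int(round(p * n))
        return np.array([max(k, 1)]), np.array([1.0])
    w = np.asarray(spec, dtype=float)
    if w.ndim != 1 or len(w) != kmax or (w < 0).any() or w.sum() <= 0:
        raise ValueError("maf_spectrum weights must be a nonnegative vector over k=1..n//2")
    return np.arange(1, kmax + 1), w


def _draw_block_genotypes(
    rng: np.random.Generator,
    n_lines: int,
    n_sites: int,
    n_founders: int,
    ks: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Genotypes (0/1) for one haplotype block with nested founder carriers."""
    founder_of = rng.integers(0, n_founders, size=n_lines)
    order = rng.permutation(n_founders)  # per-block founder priority
    # lines sorted founder-priority-first; carriers are taken from this order
    prio = np.argsort(order[founder_of], kind="stable")
    sizes = np.bincount(order[founder_of], minlength=n_founders)
    cum = np.cumsum(sizes)
    calls = np.zeros((n_lines, n_sites), dtype=np.int8)
    k_draws = rng.choice(ks, size=n_sites, p=weights / weights.sum())
    for j, k in enumerate(k_draws):
        # carriers: whole founders along the priority order, then random fill
        n_full = int(np.searchsorted(cum, k, side="right"))
        base = int(cum[n_full - 1]) if n_full > 0 else 0
        carriers = list(prio[:base])
        residual = k - base
        if residual > 0:
            pool = prio[base:]
            carriers.extend(rng.choice(pool, size=residual, replace=False))
        calls[np.asarray(carriers, dtype=int), j] = 1
    return calls


def generate_panel(config: SimConfig) -> tuple[GenotypeMatrix, TruthManifest]:
    """Generate a synthetic panel and its ground-truth manifest.

    The pipeline draws base genotypes per haplotype block, overlays the
    inversion arrangement classes, injects correlated residual-heterozygosity
    blocks, then applies missingness and genotype-quality noise.  Karyotype
    assignment is deterministic: ``round(frequency * n_lines)`` lines become
    inverted homozygotes and ``n_het_lines`` heterozygotes, chosen by a seeded
    shuffle.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_sites, rng_blocks, rng_karyo, rng_het, rng_miss, rng_qual = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    lines = [f"line{i + 1:03d}" for i in range(config.n_lines)]
    ks, weights = _spectrum_weights(config)

    site_rows = []
    call_blocks = []
    for chrom, length, n_sites in config.chrom_specs:
        pos = np.sort(rng_sites.choice(length, size=n_sites, replace=False) + 1)
        site_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        # haplotype blocks partition the chromosome in block_len windows
        block_id = (pos - 1) // config.block_len
        cols = np.empty((config.n_lines, n_sites), dtype=np.int8)
        for b in np.unique(block_id):
            idx = np.flatnonzero(block_id == b)
            cols[:, idx] = _draw_block_genotypes(
                rng_blocks, config.n_lines, len(idx),
                config.n_founder_haplotypes, ks, weights,
            )
        call_blocks.append(cols)
    sites = pd.concat(site_rows, ignore_index=True)
    sites["ref"] = "A"
    sites["alt"] = "T"
    calls = np.concatenate(call_blocks, axis=1)

    # ---- inversions: two diverged haplotype classes ----
    karyotypes: dict[str, dict[str, str]] = {}
    diagnostic_sites: dict[str, list[tuple[str, int]]] = {}
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for inv in config.inversion_specs:
        n_inv = int(np.floor(inv.frequency * config.n_lines + 0.5))
        if inv.frequency > 0 and n_inv == 0:
            warnings.warn(
                f"inversion {inv.name}: frequency x n_lines < 1; zero inverted lines"
            )
        shuffled = rng_karyo.permutation(config.n_lines)
        inv_lines = shuffled[:n_inv]
        het_lines = shuffled[n_inv : n_inv + inv.n_het_lines]
        labels = np.full(config.n_lines, "Std", dtype=object)
        labels[inv_lines] = "Inv"
        labels[het_lines] = "Het"
        karyotypes[inv.name] = {ln: str(lab) for ln, lab in zip(lines, labels)}
        in_region = np.flatnonzero(
            (chrom_arr == inv.chrom) & (pos_arr >= inv.start) & (pos_arr <= inv.end)
        )
        n_diag = int(round(inv.divergence * len(in_region)))
        diag = np.sort(rng_karyo.choice(in_region, size=n_diag, replace=False))
        # diagnostic sites: Std lines carry REF, Inv lines ALT, Het lines HET
        calls[:, diag] = REF
        calls[np.ix_(inv_lines, diag)] = ALT
        calls[np.ix_(het_lines, diag)] = HET
        diagnostic_sites[inv.name] = [
            (inv.chrom, int(p)) for p in pos_arr[diag]
        ]

    matrix = GenotypeMatrix(lines, sites, calls)
    manifest = TruthManifest(karyotypes, diagnostic_sites, {}, config.seed)

    matrix, manifest = inject_heterozygosity(matrix, manifest, config, rng=rng_het)

    # ---- missingness and genotype qualities ----
    if config.missing_rate > 0:
        mask = rng_miss.random(matrix.calls.shape) < config.missing_rate
        matrix.calls[mask] = MISSING
    quals = 20.0 + rng_qual.exponential(scale=30.0, size=matrix.calls.shape)
    if config.qual_low_rate > 0:
        low = rng_qual.random(matrix.calls.shape) < config.qual_low_rate
        quals[low] = rng_qual.uniform(0.0, 20.0, size=matrix.calls.shape)[low]
    matrix.quals = np.floor(quals).astype(np.int32)
    return matrix, manifest


def inject_heterozygosity(
    matrix: GenotypeMatrix,
    manifest: TruthManifest,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthManifest]:
    """Place residual-heterozygosity blocks with cross-region correlated incidence.

    Each line draws one shared latent block (an incidence Bernoulli with the
    configured rate plus a length fraction uniform up to
    ``het_block_max_frac`` of the region); each region
    either copies the shared latent (probability sqrt(het_block_corr)) or
    draws its own independently.  Because both incidence *and* length are
    shared when copied, the Pearson correlation of per-line region
    heterozygosities equals ``het_block_corr``.  Calls inside a placed block
    become HET; placements are recorded in the manifest.
    """
    if not 0.0 <= config.het_block_corr <= 1.0:
        raise ValueError("het_block_corr must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[3])
    if config.het_block_rate == 0:
        return matrix, manifest
    regions = config.resolved_het_regions()
    a = float(np.sqrt(config.het_block_corr))
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    het_blocks: dict[str, list[tuple[str, int, int]]] = dict(manifest.het_blocks)
    for i, line in enumerate(matrix.lines):
        shared_on = rng.random() < config.het_block_rate
        shared_frac = rng.uniform(0.0, 1.0)
        for chrom, start, end, name in regions:
            if rng.random() < a:
                on, frac = shared_on, shared_frac
            else:
                on, frac = rng.random() < config.het_block_rate, rng.uniform(0.0, 1.0)
            if not on:
                continue
            region_len = end - start + 1
            blen = max(1, int(round(frac * config.het_block_max_frac * region_len)))
            bstart = start + int(rng.integers(0, region_len - blen + 1))
            bend = bstart + blen - 1
            in_block = (chrom_arr == chrom) & (pos_arr >= bstart) & (pos_arr <= bend)
            matrix.calls[i, in_block] = HET
            het_blocks.setdefault(line, []).append((name, int(bstart), int(bend)))
    manifest.het_blocks = het_blocks
    return matrix, manifest


_GT = {REF: "0/0", ALT: "1/1", HET: "0/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the panel as a VCF 4.2 file with GT and GQ per genotype.

    Output is byte-deterministic given the matrix.  Missing calls are written
    as ``./.`` with GQ ``.``.
    """
    if matrix.n_sites == 0 or matrix.n_lines == 0:
        raise ValueError("refusing to write an empty panel")
    chrom_order = list(dict.fromkeys(matrix.sites["chrom"]))
    chrom_len = {
        c: int(matrix.sites.loc[matrix.sites["chrom"] == c, "pos"].max())
        for c in chrom_order
    }
    quals = matrix.quals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dgrpld-synthetic\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c},length={chrom_len[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.lines)
            + "\n"
        )
        for j in range(matrix.n_sites):
            row = matrix.sites.iloc[j]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".",
                str(row.get("ref", "A")), str(row.get("alt", "T")),
                ".", "PASS", ".", "GT:GQ",
            ]
            col = matrix.calls[:, j]
            for i in range(matrix.n_lines):
                code = int(col[i])
                if code == MISSING:
                    gq = "."
                elif quals is None:
                    gq = "99"
                else:
                    gq = str(int(quals[i, j]))
                fields.append(f"{_GT[code]}:{gq}")
            fh.write("\t".join(fields) + "\n")
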