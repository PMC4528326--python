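import numpy as np
import pandas as pd
import pytest

from dgrpld import genotype_io as gio
from dgrpld import synthetic_data as sd


def make_matrix(calls, chrom="2L", positions=None, lines=None):
    """GenotypeMatrix from a lines x sites array of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if lines is None:
        lines = [f"L{i}" for i in range(n_lines)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    return gio.GenotypeMatrix(list(lines), sites, calls)


@pytest.fixture(scope="session")
def clean_panel():
    """No-inversion, fully-called panel: 200 lines x 2000 sites."""
    cfg = sd.SimConfig(
        seed=101,
        n_lines=200,
        chrom_specs=[("2L", 2_000_000, 2000)],
        inversion_specs=[],
        het_block_rate=0.0,
        missing_rate=0.0,
        qual_low_rate=0.0,
    )
    matrix, manifest = sd.generate_panel(cfg)
    return matrix, manifest


@pytest.fixture(scope="session")
def default_panel():
    """Default study-condition panel (205 lines, two arms, two inversions)."""
    cfg = sd.SimConfig(seed=42)
    matrix, manifest = sd.generate_panel(cfg)
    return cfg, matrix, manifest


@pytest.fixture(scope="session")
def default_catalog(default_panel):
    """LD encoding, site statistics, filters and r2 >= 0.5 catalog for the default panel."""
    from dgrpld import ld_scan

    _, matrix, _ = default_panel
    ld = gio.encode_for_ld(matrix)
    records = gio.site_statistics(ld)
    focal, partner = gio.filter_sites(records)
    catalog = ld_scan.scan_high_ld(ld, records, focal, partner, r2_cut=0.5)
    return ld, records, focal, partner, catalog


def pandas_corr_pairs(matrix, records, focal, partner, r2_cut=0.5):
    """Independent reference: pairwise-complete Pearson via pandas, all pairs.

    Returns the canonical pair-key set of all unordered pairs with at least
    one focal member, both partner-eligible, and r^2 >= r2_cut.
    """
    X = matrix.calls.astype(float)
    X[X < 0] = np.nan
    idx = np.flatnonzero(np.asarray(partner, dtype=bool))
    df = pd.DataFrame(X[:, idx])
    r = df.corr(min_periods=2).to_numpy()
    r2 = r * r
    chrom = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy()
    focal = np.asarray(focal, dtype=bool)
    pairs = set()
    ii, jj = np.nonzero(np.triu(np.nan_to_num(r2) >= r2_cut, k=1))
    for i, j in zip(idx[ii], idx[jj]):
        if not (focal[i] or focal[j]):
            continue
        ka = (str(chrom[i]), int(pos[i]))
        kb = (str(chrom[j]), int(pos[j]))
        if kb < ka:
            ka, kb = kb, ka
        pairs.add((ka[0], ka[1], kb[0], kb[1]))
    return pairs
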