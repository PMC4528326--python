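"""Shared panel loading for the numbered analysis drivers.

The reference panel is the default synthetic study condition (205 lines, two
2-Mb arms, two low-frequency inversions), seed 42.  Drivers read the VCF
written by 01_simulate_panel.py when present (exercising the real input
path) and regenerate the panel in memory otherwise.
"""

from pathlib import Path

from dgrpld import genotype_io as gio
from dgrpld import synthetic_data as sd

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
PANEL_SEED = 42

SCRATCH.mkdir(exist_ok=True)
RESULTS.mkdir(exist_ok=True)

CONFIG = sd.SimConfig(seed=PANEL_SEED)


def load_panel():
    """(matrix, manifest) for the reference panel, from VCF if available."""
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    vcf = SCRATCH / "panel.vcf"
    truth = SCRATCH / "truth.json"
    if vcf.exists() and truth.exists():
        matrix = gio.read_genotypes(vcf, min_phred=20)
        manifest = sd.TruthManifest.from_json(truth.read_text())
        return matrix, manifest
    return sd.generate_panel(CONFIG)


def ld_view(matrix):
    """LD encoding, site statistics and focal/partner filters."""
    ld = gio.encode_for_ld(matrix)
    records = gio.site_statistics(ld)
    focal, partner = gio.filter_sites(records)
    return ld, records, focal, partner


def inversion_regions():
    import pandas as pd

    return pd.DataFrame(
        [
            {"chrom": i.chrom, "start": i.start, "end": i.end,
             "name": i.name, "role": "inversion"}
            for i in CONFIG.inversion_specs
        ]
    )
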