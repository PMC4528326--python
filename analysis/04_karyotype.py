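"""Inversion karyotyping: diagnostic SNPs -> PCA -> Std/Inv/Het calls.

Selects in-region SNPs with many distant high-LD partners, runs a PCA per
inversion on their dosage matrix, classifies each line from its PC1 score
and region heterozygosity, and cross-tabulates against the generator's
ground truth (standing in for external karyotype assignments).
"""

import pandas as pd

from _common import RESULTS, SCRATCH, inversion_regions, ld_view, load_panel
from dgrpld import inversion_typing as it
from dgrpld import ld_scan, ld_summary

# the 200-distant-partner threshold is full-panel scale; this desk panel has
# ~50x fewer catalogued sites per region, so scale it down accordingly
MIN_DISTANT_PARTNERS = 20

matrix, manifest = load_panel()
ld, records, focal, partner = ld_view(matrix)
cat_path = SCRATCH / "catalog_r2_0.5.tsv"
if cat_path.exists():
    catalog = pd.read_csv(cat_path, sep="\t")
else:
    catalog = ld_scan.scan_high_ld(ld, records, focal, partner, r2_cut=0.5)
counts = ld_summary.partner_counts(catalog, records, focal)

regions = inversion_regions()
all_calls = []
for name, rows in regions.groupby("name", sort=False):
    calls = it.karyotype_region(
        matrix, records, counts, rows, name,
        min_distant_partners=MIN_DISTANT_PARTNERS, seed=0,
    )
    all_calls.append(calls)
    tally = calls["call"].value_counts().to_dict()
    n_flagged = (calls["flag"] != "").sum()
    print(f"{name}: {tally} ({n_flagged} lines H-flagged)")

calls = pd.concat(all_calls, ignore_index=True)
calls.to_csv(RESULTS / "04_karyotype_calls.tsv", sep="\t", index=False)

external = pd.DataFrame(
    [
        {"line": line, "region": region, "call": label}
        for region, karyos in manifest.karyotypes.items()
        for line, label in karyos.items()
    ]
)
crosstab, discordant = it.concordance_table(calls, external)
crosstab.to_csv(RESULTS / "04_concordance_crosstab.tsv", sep="\t")
discordant.to_csv(RESULTS / "04_discordant_calls.tsv", sep="\t", index=False)
agree = int(crosstab.to_numpy().trace()) if not crosstab.empty else 0
total = int(crosstab.to_numpy().sum()) if not crosstab.empty else 0
print(f"concordance with truth manifest: {agree} of {total} "
      f"({100 * agree / max(total, 1):.1f}%); {len(discordant)} in conflict")
print("wrote results/04_*.tsv")
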