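"""Per-SNP partner counts and the panel-wide LD summaries.

Reproduces, at desk scale, the headline quantities of the genome-wide LD
characterisation: the fraction of focal SNPs with at least one highly
correlated partner (overall / distant / other chromosome), partner counts by
MAF class, the 100-kb distant-LD intensity track, and the r^2 distribution of
random focal pairs.
"""

import pandas as pd

from _common import RESULTS, SCRATCH, inversion_regions, ld_view, load_panel
from dgrpld import ld_scan, ld_summary

matrix, _ = load_panel()
ld, records, focal, partner = ld_view(matrix)
cat_path = SCRATCH / "catalog_r2_0.5.tsv"
if cat_path.exists():
    catalog = pd.read_csv(cat_path, sep="\t")
else:
    catalog = ld_scan.scan_high_ld(ld, records, focal, partner, r2_cut=0.5)

regions = inversion_regions()
counts = ld_summary.partner_counts(catalog, records, focal, regions=regions)
counts.to_csv(RESULTS / "03_partner_counts.tsv", sep="\t", index=False)

fr = ld_summary.fraction_with_partner(counts)
print(f"focal SNPs with >=1 high-LD partner: {100 * fr['frac_any_partner'].iloc[0]:.1f}%")
print(f"  with >=1 distant partner:          {100 * fr['frac_distant_partner'].iloc[0]:.1f}%")
print(f"  with >=1 other-chromosome partner: {100 * fr['frac_other_chrom_partner'].iloc[0]:.1f}%")
print(f"mean partners per focal SNP: {counts['n_partners_total'].mean():.1f} "
      f"(median {counts['n_partners_total'].median():.0f})")

counts["inside_inversion"] = counts["in_inversion"].notna()
strat = ld_summary.fraction_with_partner(counts, stratify="inside_inversion")
strat.to_csv(RESULTS / "03_fractions_by_inversion.tsv", sep="\t", index=False)
print("inside vs outside inversions (distant-partner fraction):")
print(strat[["inside_inversion", "frac_distant_partner"]].to_string(index=False))

maf_summary = ld_summary.maf_stratified_summary(counts, width=0.02)
maf_summary.to_csv(RESULTS / "03_partner_counts_by_maf.tsv", sep="\t", index=False)
low = maf_summary[maf_summary["maf_class"] < 0.1]["mean_total"].mean()
high = maf_summary[maf_summary["maf_class"] >= 0.3]["mean_total"].mean()
print(f"mean partners, MAF<0.1: {low:.1f} vs MAF>=0.3: {high:.1f} (rarity disequilibrium)")

wins = ld_summary.window_distant_intensity(counts)
wins.to_csv(RESULTS / "03_window_distant_intensity.tsv", sep="\t", index=False)

_, rp = ld_summary.random_pair_r2(ld, focal, n_pairs=200_000, seed=1)
pd.DataFrame(
    {"r2_bin_lo": rp["hist_edges"][:-1], "r2_bin_hi": rp["hist_edges"][1:],
     "n_pairs": rp["hist_counts"]}
).to_csv(RESULTS / "03_random_pair_r2_hist.tsv", sep="\t", index=False)
print(f"random focal pairs with r^2 >= 0.5: {100 * rp['frac_ge_cut']:.3f}%")
print("wrote results/03_*.tsv")
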