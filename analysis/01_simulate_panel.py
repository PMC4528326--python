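"""Generate the reference synthetic panel and serialise it.

Writes the VCF and ground-truth manifest under scratch/ (they are inputs to
the later drivers, and large), and a small per-site summary under results/.
"""

from _common import CONFIG, RESULTS, SCRATCH, ld_view
from dgrpld import synthetic_data as sd

SCRATCH.mkdir(exist_ok=True)
RESULTS.mkdir(exist_ok=True)

matrix, manifest = sd.generate_panel(CONFIG)
sd.write_vcf(matrix, SCRATCH / "panel.vcf")
(SCRATCH / "truth.json").write_text(manifest.to_json())

ld, records, focal, partner = ld_view(matrix)
summary = records.describe().loc[["mean", "50%", "max"]]
summary.to_csv(RESULTS / "01_site_stats_summary.tsv", sep="\t")

print(f"panel: {matrix.n_lines} lines x {matrix.n_sites} sites "
      f"({len(CONFIG.inversion_specs)} inversions)")
print(f"focal sites (MAC>=5): {int(focal.sum())}; "
      f"partner-eligible (MAC>=3): {int(partner.sum())}")
print(f"median MAF of focal sites: {records.loc[focal, 'maf'].median():.3f}")
print(f"median lines scored: {records['n_called'].median():.0f} of {matrix.n_lines}")
for name, karyos in manifest.karyotypes.items():
    labels = list(karyos.values())
    print(f"  {name}: {labels.count('Inv')} Inv, {labels.count('Het')} Het lines")
print(f"wrote scratch/panel.vcf, scratch/truth.json, "
      f"results/01_site_stats_summary.tsv")
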