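"""Karyotype calling: dosage preparation, PCA separation, classification."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_matrix

from dgrpld import genotype_io as gio
from dgrpld import inversion_typing as it
from dgrpld import ld_scan, ld_summary
from dgrpld import synthetic_data as sd


class TestPrepareKaryotypeMatrix:
    def test_missing_threshold_and_imputation(self):
        # site 0: 5 missing -> dropped; site 1: 4 missing -> kept, imputed
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:5, 0] = gio.MISSING
        calls[:4, 1] = gio.MISSING
        calls[4:7, 1] = gio.ALT
        m = make_matrix(calls)
        dosage, kept = it.prepare_karyotype_matrix(m)
        assert list(kept) == [False, True]
        # ALT is minor (3 of 6 called: tie -> ALT); imputed rows get dosage 0
        assert list(dosage[:, 0]) == [0, 0, 0, 0, 2, 2, 2, 0, 0, 0]

    def test_het_dosage_is_one(self):
        calls = np.array([[gio.REF], [gio.HET], [gio.ALT], [gio.REF]], dtype=np.int8)
        dosage, kept = it.prepare_karyotype_matrix(m := make_matrix(calls))
        assert list(dosage[:, 0]) == [0, 1, 2, 0]


class TestPcaScores:
    def test_two_distinct_groups_separate_exactly(self):
        dosage = np.zeros((10, 20))
        dosage[7:] = 2.0  # minority group differs at every site
        scores, var = it.pca_scores(dosage, seed=0)
        assert var == pytest.approx(1.0)
        assert np.ptp(scores[:7]) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(scores[7:]) == pytest.approx(0.0, abs=1e-9)
        # minority cluster oriented positive
        assert scores[7:].mean() > scores[:7].mean()

    def test_duplicate_lines_share_scores(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(6, 30)).astype(float)
        dosage[3] = dosage[0]
        scores, _ = it.pca_scores(dosage, seed=0)
        assert scores[3] == pytest.approx(scores[0])

    def test_het_line_scores_at_cluster_midpoint(self):
        dosage = np.zeros((11, 40))
        dosage[8:10] = 2.0
        dosage[10] = 1.0  # heterozygous at every diagnostic site
        scores, _ = it.pca_scores(dosage, seed=0)
        mid = (scores[:8].mean() + scores[8:10].mean()) / 2
        assert scores[10] == pytest.approx(mid, abs=1e-8)

    def test_identical_lines_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            it.pca_scores(np.ones((5, 4)), seed=0)

    def test_subsample_is_seeded(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(20, 100)).astype(float)
        s1, _ = it.pca_scores(dosage, n_snps=30, seed=7)
        s2, _ = it.pca_scores(dosage, n_snps=30, seed=7)
        np.testing.assert_allclose(s1, s2)


class TestRegionHeterozygosity:
    def _region(self):
        return pd.DataFrame(
            [{"chrom": "2L", "start": 1, "end": 10_000, "name": "inv"}]
        )

    def test_proportions(self):
        calls = np.array(
            [
                [gio.REF] * 10,
                [gio.HET] * 3 + [gio.REF] * 7,
                [gio.HET] * 10,
            ],
            dtype=np.int8,
        )
        m = make_matrix(calls, positions=np.arange(1, 11) * 100)
        H = it.region_heterozygosity(m, self._region())
        assert H[0] == 0.0
        assert H[1] == pytest.approx(0.3)
        assert H[2] == 1.0

    def test_missing_calls_excluded_from_denominator(self):
        calls = np.array([[gio.HET, gio.MISSING, gio.REF, gio.MISSING]], dtype=np.int8)
        m = make_matrix(calls, positions=[100, 200, 300, 400])
        H = it.region_heterozygosity(m, self._region())
        assert H[0] == pytest.approx(0.5)

    def test_no_called_sites_is_nan(self):
        m = make_matrix(np.full((2, 3), gio.MISSING, dtype=np.int8))
        H = it.region_heterozygosity(m, self._region())
        assert np.isnan(H).all()

    def test_invariant_to_monomorphic_site_inclusion(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([gio.REF, gio.ALT, gio.HET], size=(10, 30)).astype(np.int8)
        extra = np.full((10, 5), gio.REF, dtype=np.int8)
        m1 = make_matrix(calls, positions=np.arange(1, 31) * 10)
        m2 = make_matrix(
            np.hstack([calls, extra]), positions=list(np.arange(1, 31) * 10) + list(range(400, 405))
        )
        h1 = it.region_heterozygosity(m1, self._region())
        # denominators change with extra called sites, so compare counts
        het1 = (calls == gio.HET).sum(axis=1)
        np.testing.assert_allclose(h1 * 30, het1)


class TestCallKaryotypes:
    def test_two_cluster_case_without_hets(self):
        pc1 = np.concatenate([np.full(48, -10.0), np.full(7, 10.0)])
        pc1 += np.linspace(0, 0.1, 55)  # break exact ties
        H = np.zeros(55)
        lines = [f"L{i}" for i in range(55)]
        calls = it.call_karyotypes(lines, "inv", pc1, H)
        assert (calls["call"][:48] == "Std").all()
        assert (calls["call"][48:] == "Inv").all()

    def test_midpoint_line_with_high_h_called_het(self):
        pc1 = np.concatenate([np.full(20, 0.0), [10.0], np.full(4, 20.0)])
        pc1[:20] += np.linspace(0, 0.1, 20)
        H = np.zeros(25)
        H[20] = 0.3
        lines = [f"L{i}" for i in range(25)]
        calls = it.call_karyotypes(lines, "inv", pc1, H)
        assert calls["call"].iloc[20] == "Het"
        assert calls["flag"].iloc[20] == ""

    def test_h_discordance_flags(self):
        pc1 = np.concatenate([np.full(20, 0.0), [10.0], np.full(4, 20.0)])
        pc1[:20] += np.linspace(0, 0.1, 20)
        H = np.zeros(25)
        H[0] = 0.4  # Std call with high heterozygosity
        lines = [f"L{i}" for i in range(25)]
        calls = it.call_karyotypes(lines, "inv", pc1, H)
        assert calls["flag"].iloc[0] == "high_H_without_het_call"
        assert calls["flag"].iloc[20] == "het_call_without_high_H"

    def test_unstructured_scores_all_standard(self):
        rng = np.random.default_rng(5)
        pc1 = rng.normal(size=60)
        calls = it.call_karyotypes([f"L{i}" for i in range(60)], "inv", pc1, np.zeros(60))
        assert (calls["call"] == "Std").all()

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError):
            it.call_karyotypes(["a", "b"], "inv", np.array([0.0, 1.0]), np.zeros(2))


class TestDiagnosticSelection:
    def test_region_and_threshold_boundaries(self):
        counts = pd.DataFrame(
            {
                "chrom": ["2L"] * 3,
                "pos": [100, 200, 900_000],
                "maf": 0.1,
                "in_inversion": None,
                "n_partners_total": [300, 250, 300],
                "n_partners_distant": [199, 200, 300],
                "n_partners_other_chrom": 0,
            }
        )
        region = pd.DataFrame([{"chrom": "2L", "start": 1, "end": 1000, "name": "inv"}])
        kept = pd.DataFrame({"chrom": ["2L"] * 3, "pos": [100, 200, 900_000]})
        sel = it.select_diagnostic_snps(counts, region, kept, min_distant_partners=200)
        assert list(sel["pos"]) == [200]  # 199 partners out; outside region out

    def test_empty_selection_raises_with_guidance(self):
        counts = pd.DataFrame(
            {
                "chrom": ["2L"], "pos": [100], "maf": 0.1, "in_inversion": None,
                "n_partners_total": [0], "n_partners_distant": [0],
                "n_partners_other_chrom": [0],
            }
        )
        region = pd.DataFrame([{"chrom": "2L", "start": 1, "end": 1000, "name": "inv"}])
        kept = pd.DataFrame({"chrom": ["2L"], "pos": [100]})
        with pytest.raises(ValueError, match="min_distant_partners"):
            it.select_diagnostic_snps(counts, region, kept, min_distant_partners=200)

    def test_selection_recovers_truth_diagnostics(self, default_panel, default_catalog):
        cfg, matrix, manifest = default_panel
        _, records, focal, _, catalog = default_catalog
        counts = ld_summary.partner_counts(catalog, records, focal)
        inv = cfg.inversion_specs[0]
        region = pd.DataFrame(
            [{"chrom": inv.chrom, "start": inv.start, "end": inv.end, "name": inv.name}]
        )
        dosage, kept = it.prepare_karyotype_matrix(matrix)
        kept_records = matrix.sites.loc[kept, ["chrom", "pos"]]
        sel = it.select_diagnostic_snps(counts, region, kept_records, min_distant_partners=20)
        selected = set(zip(sel["chrom"], sel["pos"].astype(int)))
        truth = set(manifest.diagnostic_sites[inv.name])
        truth_kept = truth & set(zip(kept_records["chrom"], kept_records["pos"].astype(int)))
        recovered = len(selected & truth_kept) / len(truth_kept)
        assert recovered >= 0.9


class TestConcordance:
    def _calls(self):
        return pd.DataFrame(
            {
                "line": ["a", "b", "c"],
                "region": "inv",
                "pc1": [0.0, 1.0, 10.0],
                "H": [0.0, 0.0, 0.2],
                "call": ["Std", "Std", "Inv"],
                "flag": "",
            }
        )

    def test_identical_tables_fully_concordant(self):
        calls = self._calls()
        ext = calls[["line", "region", "call"]].copy()
        crosstab, disc = it.concordance_table(calls, ext)
        assert len(disc) == 0
        assert np.trace(crosstab.to_numpy()) == 3

    def test_single_flip_detected(self):
        calls = self._calls()
        ext = calls[["line", "region", "call"]].copy()
        ext.loc[ext["line"] == "b", "call"] = "Inv"
        _, disc = it.concordance_table(calls, ext)
        assert len(disc) == 1
        assert disc["line"].iloc[0] == "b"

    def test_na_and_unknown_keys_skipped(self):
        calls = self._calls()
        ext = pd.DataFrame(
            {
                "line": ["a", "b", "zz"],
                "region": "inv",
                "call": ["Std", "NA", "Inv"],
            }
        )
        crosstab, disc = it.concordance_table(calls, ext)
        assert crosstab.to_numpy().sum() == 1 and len(disc) == 0


def test_full_region_pipeline_recovers_karyotypes(default_panel, default_catalog):
    cfg, matrix, manifest = default_panel
    _, records, focal, _, catalog = default_catalog
    counts = ld_summary.partner_counts(catalog, records, focal)
    ok = n = 0
    for inv in cfg.inversion_specs:
        region = pd.DataFrame(
            [{"chrom": inv.chrom, "start": inv.start, "end": inv.end, "name": inv.name}]
        )
        calls = it.karyotype_region(
            matrix, records, counts, region, inv.name,
            min_distant_partners=20, seed=0,
        ).set_index("line")["call"]
        truth = manifest.karyotypes[inv.name]
        ok += sum(calls[l] == truth[l] for l in matrix.lines)
        n += matrix.n_lines
    assert ok / n >= 0.98
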