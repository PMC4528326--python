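"""Catalogue summaries: degrees, fractions, MAF strata, windows, random pairs."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_matrix

from dgrpld import genotype_io as gio
from dgrpld import ld_summary


def _toy_catalog(pairs):
    rows = []
    for (ca, pa), (cb, pb), r2 in pairs:
        cls, dist = (
            ("interchromosomal", -1)
            if ca != cb
            else (("distant", abs(pb - pa)) if abs(pb - pa) > 100_000 else ("local", abs(pb - pa)))
        )
        rows.append((ca, pa, cb, pb, r2, 100, 0.1, 0.1, dist, cls))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom_a", "pos_a", "chrom_b", "pos_b",
            "r2", "n_complete", "maf_a", "maf_b", "distance", "pair_class",
        ],
    )


def _records(keys, maf=0.1):
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in keys],
            "pos": [p for _, p in keys],
            "maf": maf,
        }
    )


class TestPartnerCounts:
    def test_degrees_match_pair_graph(self):
        keys = [("2L", 100), ("2L", 200), ("2L", 300), ("2L", 500_000), ("3R", 100)]
        cat = _toy_catalog(
            [
                (("2L", 100), ("2L", 200), 0.9),
                (("2L", 100), ("2L", 300), 0.8),
                (("2L", 100), ("2L", 500_000), 0.7),
                (("2L", 200), ("3R", 100), 0.6),
            ]
        )
        counts = ld_summary.partner_counts(
            cat, _records(keys), np.ones(5, dtype=bool)
        )
        degree = dict(zip(zip(counts["chrom"], counts["pos"]), counts["n_partners_total"]))
        assert degree == {("2L", 100): 3, ("2L", 200): 2, ("2L", 300): 1,
                          ("2L", 500_000): 1, ("3R", 100): 1}
        distant = dict(zip(zip(counts["chrom"], counts["pos"]), counts["n_partners_distant"]))
        assert distant[("2L", 100)] == 1
        assert distant[("2L", 200)] == 1  # interchromosomal counts as distant
        other = dict(zip(zip(counts["chrom"], counts["pos"]), counts["n_partners_other_chrom"]))
        assert other[("3R", 100)] == 1 and other[("2L", 200)] == 1

    def test_interchrom_excluded_when_flag_off(self):
        keys = [("2L", 100), ("3R", 100)]
        cat = _toy_catalog([(("2L", 100), ("3R", 100), 0.6)])
        counts = ld_summary.partner_counts(
            cat, _records(keys), np.ones(2, dtype=bool), interchrom_is_distant=False
        )
        assert (counts["n_partners_distant"] == 0).all()
        assert (counts["n_partners_other_chrom"] == 1).all()

    def test_absent_focal_site_has_zero_counts(self):
        keys = [("2L", 100), ("2L", 200), ("2L", 900)]
        cat = _toy_catalog([(("2L", 100), ("2L", 200), 0.9)])
        counts = ld_summary.partner_counts(cat, _records(keys), np.ones(3, dtype=bool))
        row = counts[counts["pos"] == 900].iloc[0]
        assert row["n_partners_total"] == 0

    def test_degree_conservation(self):
        """Sum of focal degrees counts intra-focal pairs twice and
        focal-to-partner-only pairs once."""
        keys = [("2L", 100), ("2L", 200), ("2L", 300)]
        cat = _toy_catalog(
            [
                (("2L", 100), ("2L", 200), 0.9),  # both focal
                (("2L", 100), ("2L", 300), 0.8),  # 300 not focal
            ]
        )
        focal = np.array([True, True, False])
        counts = ld_summary.partner_counts(cat, _records(keys), focal)
        assert counts["n_partners_total"].sum() == 2 * 1 + 1


class TestFractions:
    def test_zero_and_partial(self):
        keys = [("2L", 100), ("2L", 200), ("2L", 300), ("2L", 400)]
        cat = _toy_catalog(
            [
                (("2L", 100), ("2L", 200), 0.9),
                (("2L", 100), ("2L", 300), 0.8),
            ]
        )
        counts = ld_summary.partner_counts(cat, _records(keys), np.ones(4, dtype=bool))
        fr = ld_summary.fraction_with_partner(counts)
        assert fr["frac_any_partner"].iloc[0] == pytest.approx(3 / 4)
        empty = ld_summary.partner_counts(
            _toy_catalog([]), _records(keys), np.ones(4, dtype=bool)
        )
        fr0 = ld_summary.fraction_with_partner(empty)
        assert fr0["frac_any_partner"].iloc[0] == 0.0

    def test_stratified_fractions_weight_consistent(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            {
                "chrom": "2L",
                "pos": np.arange(200),
                "maf": rng.uniform(0, 0.5, 200),
                "in_inversion": rng.choice([None, "inv"], 200),
                "n_partners_total": rng.poisson(1, 200),
                "n_partners_distant": 0,
                "n_partners_other_chrom": 0,
            }
        )
        overall = ld_summary.fraction_with_partner(counts)["frac_any_partner"].iloc[0]
        strata = ld_summary.fraction_with_partner(counts, stratify="in_inversion")
        weighted = (
            strata["frac_any_partner"] * strata["n_sites"]
        ).sum() / strata["n_sites"].sum()
        assert weighted == pytest.approx(overall)

    def test_planted_inversion_raises_distant_fraction_inside(self, default_panel, default_catalog):
        cfg, _, _ = default_panel
        _, records, focal, _, catalog = default_catalog
        regions = pd.DataFrame(
            [
                {"chrom": i.chrom, "start": i.start, "end": i.end, "name": i.name}
                for i in cfg.inversion_specs
            ]
        )
        counts = ld_summary.partner_counts(catalog, records, focal, regions=regions)
        counts["inside"] = counts["in_inversion"].notna()
        fr = ld_summary.fraction_with_partner(counts, stratify="inside")
        by = fr.set_index("inside")["frac_distant_partner"]
        assert by[True] > by[False]


class TestMafSummary:
    def test_single_site_bin(self):
        counts = pd.DataFrame(
            {
                "chrom": "2L", "pos": [100], "maf": [0.03],
                "n_partners_total": [5], "n_partners_distant": [2],
                "n_partners_other_chrom": [0], "in_inversion": [None],
            }
        )
        out = ld_summary.maf_stratified_summary(counts)
        assert out["mean_total"].iloc[0] == 5 and out["median_total"].iloc[0] == 5

    def test_skewed_counts_mean_exceeds_median(self):
        counts = pd.DataFrame(
            {
                "chrom": "2L", "pos": [1, 2, 3], "maf": 0.05,
                "n_partners_total": [1, 2, 100], "n_partners_distant": 0,
                "n_partners_other_chrom": 0, "in_inversion": None,
            }
        )
        out = ld_summary.maf_stratified_summary(counts)
        assert out["mean_total"].iloc[0] == pytest.approx(34.33, abs=0.01)
        assert out["median_total"].iloc[0] == 2

    def test_rare_sites_carry_more_partners(self, default_catalog):
        _, records, focal, _, catalog = default_catalog
        counts = ld_summary.partner_counts(catalog, records, focal)
        out = ld_summary.maf_stratified_summary(counts, width=0.1)
        means = out.set_index("maf_class")["mean_total"]
        assert means.loc[0.0] > means.loc[means.index.max()]


class TestWindowIntensity:
    def test_mean_within_window(self):
        counts = pd.DataFrame(
            {
                "chrom": "2L", "pos": [50, 99_000], "maf": 0.1,
                "n_partners_total": [0, 4], "n_partners_distant": [0, 4],
                "n_partners_other_chrom": 0, "in_inversion": None,
            }
        )
        out = ld_summary.window_distant_intensity(counts)
        assert len(out) == 1
        assert out["mean_distant"].iloc[0] == pytest.approx(2.0)

    def test_empty_windows_absent(self):
        counts = pd.DataFrame(
            {
                "chrom": "2L", "pos": [250_000], "maf": 0.1,
                "n_partners_total": [1], "n_partners_distant": [1],
                "n_partners_other_chrom": 0, "in_inversion": None,
            }
        )
        out = ld_summary.window_distant_intensity(counts)
        assert list(out["window_start"]) == [200_001]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            ld_summary.window_distant_intensity(pd.DataFrame(), window_bp=0)

    def test_inversion_windows_hotter_than_outside(self, default_panel, default_catalog):
        cfg, _, _ = default_panel
        _, records, focal, _, catalog = default_catalog
        counts = ld_summary.partner_counts(catalog, records, focal)
        out = ld_summary.window_distant_intensity(counts)
        inv = cfg.inversion_specs[0]
        sub = out[out["chrom"] == inv.chrom]
        inside = sub[
            (sub["window_start"] >= inv.start) & (sub["window_start"] < inv.end)
        ]["mean_distant"]
        outside = sub[
            (sub["window_start"] + 100_000 <= inv.start) | (sub["window_start"] > inv.end)
        ]["mean_distant"]
        assert inside.mean() > outside.mean()


class TestRandomPairs:
    def test_independent_sites_rarely_exceed_cutoff(self):
        rng = np.random.default_rng(8)
        calls = (rng.random((200, 400)) < rng.uniform(0.05, 0.5, 400)).astype(np.int8)
        m = make_matrix(calls)
        records = gio.site_statistics(m)
        focal, _ = gio.filter_sites(records, max_missing=200)
        _, summary = ld_summary.random_pair_r2(m, focal, n_pairs=20_000, seed=0)
        assert summary["frac_ge_cut"] < 0.001

    def test_seeded_reproducibility_and_empty_sample(self):
        rng = np.random.default_rng(9)
        calls = (rng.random((50, 50)) < 0.3).astype(np.int8)
        m = make_matrix(calls)
        focal = np.ones(50, dtype=bool)
        s1, _ = ld_summary.random_pair_r2(m, focal, n_pairs=500, seed=5)
        s2, _ = ld_summary.random_pair_r2(m, focal, n_pairs=500, seed=5)
        np.testing.assert_array_equal(s1, s2)
        s0, summ0 = ld_summary.random_pair_r2(m, focal, n_pairs=0, seed=5)
        assert len(s0) == 0 and summ0["n_defined"] == 0

    def test_too_few_focal_sites_rejected(self):
        m = make_matrix(np.zeros((5, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            ld_summary.random_pair_r2(m, np.array([True, False, False]), 10, 0)
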