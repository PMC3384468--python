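"""Class/category association with chromosomal band types."""

import numpy as np
import pandas as pd
import pytest

from gc3kog.composition import GeneRecord
from gc3kog.band_association import (
    band_coverage,
    band_frequencies,
    category_band_chisq,
    category_band_counts,
    class_proportion_ztest,
    group_band_comparison,
    load_band_map,
)
from gc3kog.butterfly import butterfly_analysis, genome_mean
from gc3kog.synthetic import generate_band_map

BANDS = ("L1+", "L1-", "H3-", "H3+")


def brute_force_chisq(table):
    """Independent Σ(O−E)²/E oracle."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def rec(i, letter, band, gc3=0.5, category=None):
    return GeneRecord(f"g{i}", "sp", 0.5, gc3, 100, kog_class=letter,
                      category=category, band=band)


class TestBandMap:
    def test_load_and_invalid(self, tmp_path):
        p = tmp_path / "bands.tsv"
        p.write_text("g1\tH3+\ng2\tL1-\n")
        assert load_band_map(p) == {"g1": "H3+", "g2": "L1-"}
        p.write_text("g1\tH4\n")
        with pytest.raises(ValueError, match="H4"):
            load_band_map(p)

    def test_coverage(self):
        records = [rec(i, "P", None) for i in range(4)]
        assert band_coverage(records, {"g0": "H3+", "g2": "L1+"}) == 0.5


class TestFrequencies:
    def test_uniform_class_profile(self):
        records = [rec(i, "P", b) for i, b in enumerate(BANDS)]
        table = band_frequencies(records)
        assert np.allclose(table.class_profiles.loc["P"], 0.25)

    def test_profiles_are_probability_vectors(self, rng):
        records = [
            rec(i, rng.choice(["A", "P", "T"]), rng.choice(BANDS)) for i in range(200)
        ]
        table = band_frequencies(records)
        assert np.allclose(table.class_profiles.sum(axis=1), 1.0)
        present = table.counts.sum(axis=0) > 0
        assert np.allclose(table.band_composition.loc[:, present].sum(axis=0), 1.0)

    def test_column_sums_equal_band_totals(self, rng):
        records = [
            rec(i, rng.choice(["A", "P"]), rng.choice(BANDS)) for i in range(100)
        ]
        table = band_frequencies(records)
        for band in BANDS:
            assert table.band_totals[band] == sum(1 for r in records if r.band == band)

    def test_gc3_gradient_yields_monotone_band_means(self, rng):
        records = [
            GeneRecord(f"g{i}", "sp", 0.5, float(g), 100, kog_class="P")
            for i, g in enumerate(rng.uniform(0.2, 0.9, 2000))
        ]
        bmap = generate_band_map(records, slope=12, seed=5)
        for r in records:
            r.band = bmap[r.id]
        mean_gc3 = {
            b: np.mean([r.gc3 for r in records if r.band == b]) for b in BANDS
        }
        values = [mean_gc3[b] for b in BANDS]
        assert values == sorted(values)


class TestChisq:
    def test_hand_computed_toy_table(self):
        chi2, df, _ = category_band_chisq([[10, 20], [20, 10], [15, 15]])
        assert chi2 == pytest.approx(100 / 15, abs=1e-9)
        assert df == 2

    def test_proportional_rows_give_zero(self):
        chi2, _, p = category_band_chisq([[10, 20], [20, 40], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_row_order_invariance(self):
        t = [[12, 3], [7, 19], [4, 4]]
        assert category_band_chisq(t)[0] == pytest.approx(
            category_band_chisq(t[::-1])[0]
        )

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            t = rng.integers(1, 50, size=(3, 2))
            assert category_band_chisq(t)[0] == pytest.approx(brute_force_chisq(t))

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            category_band_chisq([[0, 0], [1, 2], [3, 4]])


class TestProportionZ:
    def test_hand_formula(self):
        z, p = class_proportion_ztest(30, 100, 10, 100, "greater")
        assert z == pytest.approx(0.2 / np.sqrt(0.2 * 0.8 * 0.02), abs=1e-9)
        assert p == pytest.approx(2.0e-4, rel=0.05)

    def test_equal_proportions(self):
        z, p = class_proportion_ztest(25, 100, 50, 200, "greater")
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_swapping_groups_flips_sign(self):
        z1, _ = class_proportion_ztest(30, 100, 10, 100, "greater")
        z2, _ = class_proportion_ztest(10, 100, 30, 100, "greater")
        assert z1 == pytest.approx(-z2)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            class_proportion_ztest(1, 0, 1, 10)


class TestGroupComparison:
    def make_dataset(self, rng, enrich=0.10):
        # positive-group genes drift toward GC-rich bands
        records = []
        i = 0
        for letter, mu in [("P", 0.64), ("K", 0.63), ("A", 0.52), ("V", 0.53)]:
            for _ in range(300):
                records.append(
                    GeneRecord(f"g{i}", "sp", 0.5, float(rng.normal(mu, 0.05)), 100,
                               kog_class=letter)
                )
                i += 1
        bmap = generate_band_map(records, slope=30 * enrich / 0.10, seed=9)
        for r in records:
            r.band = bmap[r.id]
        entries = butterfly_analysis(records, genome_mean(None, records))
        return entries, records

    def test_shares_partition_each_band(self, rng):
        entries, records = self.make_dataset(rng)
        out = group_band_comparison(entries, records)
        assert np.allclose(out.group_shares.sum(axis=0), 1.0)
        assert set(out.positive_classes) == {"P", "K"}

    def test_enriched_positive_group_significant(self, rng):
        entries, records = self.make_dataset(rng)
        out = group_band_comparison(entries, records)
        assert out.p_one_sided < 0.05

    def test_empty_group_errors(self, rng):
        records = [rec(i, "P", "H3+", category="RED") for i in range(10)]
        entries = butterfly_analysis(records + [], 0.0)  # every delta positive
        with pytest.raises(ValueError):
            group_band_comparison(entries, records)


def test_category_band_counts_selects_h3_bands():
    records = [
        rec(0, "A", "H3-", category="BLUE"),
        rec(1, "T", "H3+", category="BLACK"),
        rec(2, "P", "H3+", category="RED"),
        rec(3, "P", "L1+", category="RED"),
    ]
    t = category_band_counts(records)
    assert t.loc["RED", "H3+"] == 1
    assert t.values.sum() == 3  # the L1+ gene is outside the H3 table
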