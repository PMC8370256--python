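"""Peptide-to-site aggregation, normalization and composition summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from phospho_aa_screen import (
    PhosphoPeptideRecord,
    SiteQuantTable,
    composition_summary,
    filter_reliable,
    merge_to_sites,
    normalize,
)
from phospho_aa_screen.site_assembly import NormalizationError, SiteConsistencyError

from conftest import brute_force_merge, make_random_records


def _rec(condition, protein, positions, residues, abundance, reliability=None):
    return PhosphoPeptideRecord(
        condition, "PEPK", protein, tuple(positions), tuple(residues), abundance,
        reliability,
    )


class TestFilterReliable:
    def test_zero_threshold_is_identity(self, handmade_records):
        assert filter_reliable(handmade_records, 0.0) == handmade_records

    def test_threshold_removes_low_scores(self):
        records = [_rec("NT", "p", [1], ["S"], 1.0, r)
                   for r in (0.1, 0.2, 0.5, 0.7, 0.75, 0.8, 0.9, 0.95, 0.99, 1.0)]
        survivors = filter_reliable(records, 0.75)
        assert len(survivors) == 6  # 0.75 itself survives (>= threshold)

    def test_missing_scores_follow_policy(self):
        records = [_rec("NT", "p", [i], ["S"], 1.0, None) for i in (1, 4, 7)]
        assert filter_reliable(records, 0.9, missing_policy="keep") == records
        assert filter_reliable(records, 0.9, missing_policy="drop") == []


class TestMergeToSites:
    def test_same_site_abundances_sum(self):
        table = merge_to_sites(
            [
                PhosphoPeptideRecord("NT", "AAK", "chx:X", (10,), ("S",), 3.0),
                PhosphoPeptideRecord("NT", "CCK", "chx:X", (10,), ("S",), 5.0),
            ]
        )
        assert table.cell("chx:X:S10", "NT") == 8.0

    def test_multi_site_peptide_feeds_every_site(self):
        table = merge_to_sites([_rec("NT", "p", [10, 14], ["S", "T"], 4.0)])
        assert table.cell("p:S10", "NT") == 4.0
        assert table.cell("p:T14", "NT") == 4.0

    def test_exact_duplicates_collapse_before_summing(self):
        record = _rec("NT", "p", [10], ["S"], 3.0)
        table = merge_to_sites([record, record, record])
        assert table.cell("p:S10", "NT") == 3.0

    def test_conflicting_residue_letters_rejected(self):
        with pytest.raises(SiteConsistencyError, match="position 10"):
            merge_to_sites(
                [_rec("NT", "p", [10], ["S"], 1.0), _rec("SS", "p", [10], ["T"], 1.0)]
            )

    def test_mean_statistic(self):
        records = [
            PhosphoPeptideRecord("NT", "AAK", "p", (10,), ("S",), 3.0),
            PhosphoPeptideRecord("NT", "CCK", "p", (10,), ("S",), 5.0),
        ]
        assert merge_to_sites(records, statistic="mean").cell("p:S10", "NT") == 4.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        records = make_random_records(seed)
        table = merge_to_sites(records)
        expected = brute_force_merge(records)
        actual = {
            (site, condition): table.cell(site, condition)
            for site in table.sites
            for condition in table.conditions
            if not math.isnan(table.cell(site, condition))
        }
        assert set(actual) == set(expected)
        for key, value in expected.items():
            assert actual[key] == pytest.approx(value, rel=1e-12)


def _toy_table(values: dict[str, list[float]]) -> SiteQuantTable:
    frame = pd.DataFrame(values, index=[f"p:S{i + 1}" for i in
                                        range(len(next(iter(values.values()))))])
    residues = pd.Series("S", index=frame.index)
    return SiteQuantTable(frame, residues)


class TestNormalize:
    def test_median_scaling_definition(self):
        table = normalize(_toy_table({"NT": [2.0, 4.0, 8.0]}), "median")
        assert list(table.abundance["NT"]) == [0.5, 1.0, 2.0]

    def test_none_is_identity(self):
        table = _toy_table({"NT": [2.0, 4.0, 8.0]})
        assert normalize(table, "none") == table

    def test_median_is_scale_invariant_and_idempotent(self):
        table = _toy_table({"A": [1.0, 3.0, 9.0], "B": [2.0, 6.0, 18.0]})
        normalized = normalize(table, "median")
        assert np.allclose(normalized.abundance["A"], normalized.abundance["B"])
        again = normalize(normalized, "median")
        assert np.allclose(again.abundance.values, normalized.abundance.values)

    def test_total_scaling(self):
        table = normalize(_toy_table({"NT": [1.0, 3.0]}), "total")
        assert list(table.abundance["NT"]) == [0.25, 0.75]

    def test_all_zero_column_is_an_error(self):
        with pytest.raises(NormalizationError, match="NT"):
            normalize(_toy_table({"NT": [0.0, 0.0]}), "median")


class TestComposition:
    def test_single_site_table_is_100_percent(self):
        summary = composition_summary(_toy_table({"NT": [5.0]}), "NT")
        assert summary.percentages["S"] == 100.00
        assert summary.n_sites == 1 and summary.n_proteins == 1

    def test_percentages_sum_to_100_within_rounding(self, default_screen):
        table, _, _ = default_screen
        for condition in table.conditions:
            summary = composition_summary(table, condition)
            assert sum(summary.percentages.values()) == pytest.approx(100.0, abs=0.02)
            assert sum(summary.counts.values()) == summary.n_sites

    def test_residue_class_consistent_with_site_keys(self, default_screen):
        table, _, _ = default_screen
        for site in table.sites[:50]:
            residue = site.rpartition(":")[2][0]
            assert table.residues[site] == residue


def test_site_table_tsv_round_trip(tmp_path, default_screen):
    table, _, _ = default_screen
    path = tmp_path / "sites.tsv"
    table.to_tsv(path)
    loaded = SiteQuantTable.from_tsv(path)
    assert loaded.abundance.shape == table.abundance.shape
    assert np.allclose(loaded.abundance.values, table.abundance.values, equal_nan=True)
    assert (loaded.residues == table.residues).all()
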