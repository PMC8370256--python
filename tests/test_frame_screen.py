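"""Contrast ratios, frame classification and the strict |log10 FC| tier."""

from __future__ import annotations

import pandas as pd
import pytest

from phospho_aa_screen import (
    CONTRAST_AAS_SS,
    CONTRAST_ALLS_AAS,
    CONTRAST_LEUS_AAS,
    ContrastRatio,
    SiteKey,
    SiteQuantTable,
    assign_frames,
    compute_ratios,
    intersect_sites,
    top_subset,
    updown_counts,
)


def _table(columns: dict[str, dict[str, float]]) -> SiteQuantTable:
    frame = pd.DataFrame(columns)
    residues = pd.Series([s.rpartition(":")[2][0] for s in frame.index],
                         index=frame.index)
    return SiteQuantTable(frame, residues)


def _ratio(site_text, contrast, fc):
    return ContrastRatio(SiteKey.from_string(site_text), contrast, fc)


class TestIntersect:
    def test_disjoint_columns_share_nothing(self):
        table = _table({
            "SS": {"p:S1": 1.0, "p:S2": float("nan")},
            "AAS": {"p:S1": float("nan"), "p:S2": 2.0},
        })
        assert intersect_sites(table, "SS", "AAS").sites == frozenset()

    def test_identical_columns_share_everything(self):
        table = _table({"SS": {"p:S1": 1.0, "q:T2": 2.0},
                        "AAS": {"p:S1": 1.0, "q:T2": 2.0}})
        shared = intersect_sites(table, "SS", "AAS")
        assert shared.sites == frozenset({"p:S1", "q:T2"})
        assert shared.n_proteins == 2

    def test_unknown_condition_is_an_error(self):
        table = _table({"SS": {"p:S1": 1.0}})
        with pytest.raises(KeyError):
            intersect_sites(table, "SS", "XX")

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_intersection(self, seed, default_screen):
        table, _, _ = default_screen
        expected = {
            site
            for site in table.sites
            if table.cell(site, "SS") > 0 and table.cell(site, "AAS") > 0
        }
        assert intersect_sites(table, "SS", "AAS").sites == expected


class TestRatios:
    def test_fold_change_is_numerator_over_denominator(self):
        table = _table({"SS": {"p:S722": 1.0}, "AAS": {"p:S722": 2.35}})
        ratios = compute_ratios(table, CONTRAST_AAS_SS)
        assert ratios[0].fc == pytest.approx(2.35)
        assert updown_counts(ratios).n_up == 1

    def test_equal_cells_are_neither_up_nor_down(self):
        table = _table({"SS": {"p:S1": 3.0}, "AAS": {"p:S1": 3.0}})
        ratios = compute_ratios(table, CONTRAST_AAS_SS)
        assert ratios[0].fc == 1.0
        counts = updown_counts(ratios)
        assert (counts.n_up, counts.n_down) == (0, 0)

    def test_zero_denominator_site_is_skipped(self):
        table = _table({"SS": {"p:S1": 0.0, "p:S2": 1.0},
                        "AAS": {"p:S1": 5.0, "p:S2": 2.0}})
        ratios = compute_ratios(table, CONTRAST_AAS_SS)
        assert [str(r.site) for r in ratios] == ["p:S2"]

    def test_reversing_a_contrast_inverts_fc_and_swaps_updown(self, default_screen):
        table, _, _ = default_screen
        forward = {str(r.site): r.fc for r in compute_ratios(table, ("AAS", "SS"))}
        backward = {str(r.site): r.fc for r in compute_ratios(table, ("SS", "AAS"))}
        assert forward.keys() == backward.keys()
        for site, fc in forward.items():
            assert backward[site] == pytest.approx(1.0 / fc, rel=1e-12)
        fwd = updown_counts(compute_ratios(table, ("AAS", "SS")))
        bwd = updown_counts(compute_ratios(table, ("SS", "AAS")))
        assert (fwd.n_up, fwd.n_down) == (bwd.n_down, bwd.n_up)


class TestAssignFrames:
    @pytest.mark.parametrize(
        "fc_by_contrast, expected_frames, expected_top",
        [
            # up under starvation, down under leucine restimulation
            ({CONTRAST_AAS_SS: 2.35, CONTRAST_LEUS_AAS: 0.06}, {1}, False),
            # down under starvation, up under leucine restimulation; the
            # leucine response (6.11x) stays below the strict 10x tier
            ({CONTRAST_AAS_SS: 0.01, CONTRAST_LEUS_AAS: 6.11}, {2}, False),
            # no response at all
            ({CONTRAST_AAS_SS: 1.0, CONTRAST_LEUS_AAS: 0.06}, set(), False),
            # strong all-amino-acid response, passes the 10x tier
            ({CONTRAST_AAS_SS: 0.02, CONTRAST_ALLS_AAS: 113.30}, {4}, True),
            # threshold boundaries are excluded (strict inequalities)
            ({CONTRAST_AAS_SS: 2.0, CONTRAST_LEUS_AAS: 0.5}, set(), False),
            # one site may live in two frames at once
            ({CONTRAST_AAS_SS: 0.01, CONTRAST_LEUS_AAS: 6.11,
              CONTRAST_ALLS_AAS: 23.49}, {2, 4}, True),
        ],
    )
    def test_frame_rules(self, fc_by_contrast, expected_frames, expected_top):
        ratios = [_ratio("p:S1", contrast, fc)
                  for contrast, fc in fc_by_contrast.items()]
        assignments = assign_frames(ratios)
        if not expected_frames:
            assert assignments == []
        else:
            assert assignments[0].frames == frozenset(expected_frames)
            assert assignments[0].top_flag is expected_top

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            assign_frames([], theta_up=0.9)

    def test_frame_counts_bounded_by_updown_counts(self, default_screen):
        """|Frame k| can never exceed the up-count of its up-contrast or the
        down-count of its down-contrast."""
        from phospho_aa_screen import FRAME_RULES

        _, ratios, assignments = default_screen
        for frame, rule in FRAME_RULES.items():
            n_frame = sum(1 for a in assignments if frame in a.frames)
            up = updown_counts(ratios[rule.up]).n_up
            down = updown_counts(ratios[rule.down]).n_down
            assert n_frame <= min(up, down)


class TestTopSubset:
    def test_ten_fold_rule(self):
        keep = assign_frames([_ratio("p:S1", CONTRAST_AAS_SS, 0.05),
                              _ratio("p:S1", CONTRAST_ALLS_AAS, 20.0)])
        drop = assign_frames([_ratio("q:S1", CONTRAST_AAS_SS, 0.4),
                              _ratio("q:S1", CONTRAST_ALLS_AAS, 2.5)])
        subset = top_subset(keep + drop, frame=4)
        assert [str(a.site) for a in subset.assignments] == ["p:S1"]
        assert subset.n_proteins == 1

    def test_fc_pair_at_2x_fails_the_10x_rule(self):
        assignments = assign_frames([_ratio("p:S1", CONTRAST_AAS_SS, 0.4),
                                     _ratio("p:S1", CONTRAST_ALLS_AAS, 2.5)])
        assert assignments[0].frames == {4}
        assert top_subset(assignments, 4).assignments == ()

    def test_subset_of_frame_members_and_matches_brute_force(self, default_screen):
        _, _, assignments = default_screen
        subset = top_subset(assignments, 4, log10_threshold=1.0)
        frame4 = [a for a in assignments if 4 in a.frames]
        oracle = [
            a for a in frame4
            if a.fc_alls_aas > 10.0 and a.fc_aas_ss < 0.1
        ]
        assert list(subset.assignments) == oracle
        assert all(a in frame4 for a in subset.assignments)

    def test_unknown_frame_rejected(self):
        with pytest.raises(ValueError):
            top_subset([], frame=5)
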