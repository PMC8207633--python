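import math
from dataclasses import replace

import numpy as np
import pytest

from convclubs import (ClubConvergence, ClubPartition, ClubSpec,
                       DivergentSpec, FactorModelSpec, PanelData,
                       classify_panel, find_initial_clubs, fit_logt,
                       form_core_group, generate_panel, merge_clubs,
                       recovery_score, sieve_candidates, sort_cross_section)
from convclubs.simulate import study_scale_spec


def _stat(panel, ids):
    res = fit_logt(panel.subset(ids))
    return math.inf if res.degenerate else res.t_b


class TestSortCrossSection:
    def test_final_period_ordering(self):
        values = np.tile([[1.0], [3.0], [2.0]], (1, 5))
        panel = PanelData(values, ids=["A", "B", "C"],
                          years=range(2000, 2005), scale="log")
        assert sort_cross_section(panel) == ["B", "C", "A"]

    def test_already_decreasing_preserved(self):
        values = np.tile([[5.0], [4.0], [3.0]], (1, 5))
        panel = PanelData(values, ids=["x", "y", "z"],
                          years=range(2000, 2005), scale="log")
        assert sort_cross_section(panel) == ["x", "y", "z"]

    def test_ties_break_lexicographically(self):
        values = np.tile([[2.0], [2.0], [1.0]], (1, 5))
        panel = PanelData(values, ids=["b", "a", "c"],
                          years=range(2000, 2005), scale="log")
        assert sort_cross_section(panel) == ["a", "b", "c"]


class TestFormCoreGroup:
    def test_two_convergent_series(self):
        spec = FactorModelSpec(n_periods=15, clubs=(ClubSpec(2, 1.0, 0.02),),
                               seed=1)
        panel, _ = generate_panel(spec)
        order = sort_cross_section(panel)
        assert sorted(form_core_group(panel, order)) == sorted(panel.ids)

    def test_matches_brute_force_argmax(self, two_club_spec):
        """Core = first passing pair extended to the exhaustive-argmax size."""
        panel, _ = generate_panel(two_club_spec)
        order = sort_cross_section(panel)
        core = form_core_group(panel, order)

        n = len(order)
        expected = None
        for k in range(n - 1):
            if not _stat(panel, order[k:k + 2]) > -1.65:
                continue
            stats = [_stat(panel, order[k:k + j + 1]) for j in range(1, n - k)]
            j_star = 1 + int(np.argmax(stats))
            expected = order[k:k + j_star + 1]
            break
        assert core == expected

    def test_mutually_divergent_returns_none(self):
        spec = FactorModelSpec(
            n_periods=20, clubs=(),
            divergent=(DivergentSpec(2.0, 0.05, sigma=0.001),
                       DivergentSpec(1.2, 0.01, sigma=0.001),
                       DivergentSpec(0.5, -0.01, sigma=0.001)),
            seed=2)
        panel, _ = generate_panel(spec)
        order = sort_cross_section(panel)
        assert form_core_group(panel, order) is None


class TestSieveCandidates:
    def test_empty_complement_returns_core(self, two_club_spec):
        panel, _ = generate_panel(two_club_spec)
        core = panel.ids[:6]
        assert sieve_candidates(panel, core, []) == core

    def test_admits_exactly_true_club_mates(self, two_club_spec):
        """With wide separation and c*=0, the sieve recovers the core's club."""
        panel, truth = generate_panel(two_club_spec)
        club1 = [u for u in panel.ids if truth[u] == 1]
        core = club1[:3]
        complement = [u for u in panel.ids if u not in core]
        club = sieve_candidates(panel, core, complement, c_star=0.0)
        assert sorted(club) == sorted(club1)

    def test_failing_joint_fit_falls_back_to_passing_subset(self, two_club_spec):
        """Forcing every unit into the candidate set (c* = -inf) makes the
        joint fit fail; the regrowth fallback must return a strict subset
        that passes its own test."""
        panel, truth = generate_panel(two_club_spec)
        club1 = [u for u in panel.ids if truth[u] == 1]
        core = club1[:3]
        complement = [u for u in panel.ids if u not in core]
        club = sieve_candidates(panel, core, complement, c_star=-1e9)
        assert set(core) <= set(club)
        assert len(club) < len(core) + len(complement)
        assert not _stat(panel, club) < -1.65
        # the best-ranked candidates are exactly the true club-mates
        assert sorted(club) == sorted(club1)


class TestFindInitialClubs:
    def test_fully_convergent_single_club(self, convergent_panel):
        part = find_initial_clubs(convergent_panel)
        assert part.n_clubs == 1
        assert sorted(part.clubs[0]) == sorted(convergent_panel.ids)
        assert part.divergent == []

    def test_planted_three_clubs_recovered(self, study_scale_panel):
        panel, truth = study_scale_panel
        part = find_initial_clubs(panel)
        assert recovery_score(truth, part) == 1.0

    def test_all_divergent_panel(self):
        spec = FactorModelSpec(
            n_periods=20, clubs=(),
            divergent=(DivergentSpec(2.0, 0.05, sigma=0.001),
                       DivergentSpec(1.2, 0.01, sigma=0.001),
                       DivergentSpec(0.5, -0.01, sigma=0.001)),
            seed=3)
        panel, _ = generate_panel(spec)
        part = find_initial_clubs(panel)
        assert part.clubs == []
        assert sorted(part.divergent) == sorted(panel.ids)


class TestMergeClubs:
    def test_single_club_unchanged(self, convergent_panel):
        part = find_initial_clubs(convergent_panel)
        merged = merge_clubs(convergent_panel, part)
        assert merged.n_clubs == 1
        assert sorted(merged.clubs[0]) == sorted(part.clubs[0])
        assert merged.stage == "merged"

    def test_artificially_split_club_remerged(self, convergent_panel):
        ids = sort_cross_section(convergent_panel)
        split = ClubPartition(clubs=[ids[:4], ids[4:]], divergent=[],
                              stage="initial")
        merged = merge_clubs(convergent_panel, split)
        assert merged.n_clubs == 1
        assert sorted(merged.clubs[0]) == sorted(ids)

    def test_separated_clubs_stay_apart(self, study_scale_panel):
        panel, truth = study_scale_panel
        initial = find_initial_clubs(panel)
        merged = merge_clubs(panel, initial)
        assert merged.n_clubs <= initial.n_clubs
        assert recovery_score(truth, merged) == 1.0

    def test_merged_clubs_are_unions_of_consecutive_initial(self, study_scale_panel):
        panel, _ = study_scale_panel
        initial = find_initial_clubs(panel)
        merged = merge_clubs(panel, initial)
        pos = 0
        for club in merged.clubs:
            members = set(club)
            consumed = set()
            while consumed != members:
                assert pos < initial.n_clubs
                nxt = set(initial.clubs[pos])
                assert nxt <= members
                consumed |= nxt
                pos += 1
        assert pos == initial.n_clubs


class TestClassifyPanel:
    def test_convergent_panel_skips_clustering(self, convergent_panel):
        results = classify_panel(convergent_panel)
        assert results.full_decision == "converge"
        assert results.merged.n_clubs == 1
        assert sorted(results.merged.clubs[0]) == sorted(convergent_panel.ids)

    def test_planted_structure_recovered(self, study_scale_panel):
        panel, truth = study_scale_panel
        results = classify_panel(panel)
        assert results.full_decision == "diverge"
        assert results.merged.n_clubs == 3
        assert sorted(len(c) for c in results.merged.clubs) == [12, 14, 14]
        planted_div = {u for u, lab in truth.items() if lab == 0}
        assert len(planted_div & set(results.merged.divergent)) >= 3

    def test_partition_completeness_both_stages(self, study_scale_panel):
        panel, _ = study_scale_panel
        results = classify_panel(panel)
        for part in (results.initial, results.merged):
            assert sorted(part.all_ids()) == sorted(panel.ids)
            assert all(len(c) >= 2 for c in part.clubs)

    def test_self_consistency_of_reported_clubs(self, study_scale_panel):
        """Every reported club refits with t_b >= -1.65 (or exactly)."""
        panel, _ = study_scale_panel
        results = classify_panel(panel)
        for club in results.merged.clubs:
            assert not _stat(panel, club) < -1.65

    def test_deterministic(self, study_scale_panel):
        panel, _ = study_scale_panel
        r1 = classify_panel(panel)
        r2 = classify_panel(panel.copy())
        assert r1.merged.clubs == r2.merged.clubs
        assert r1.merged.divergent == r2.merged.divergent
        assert r1.initial.clubs == r2.initial.clubs

    def test_results_surface(self, study_scale_panel):
        panel, _ = study_scale_panel
        results = ClubConvergence(panel).fit()
        table = results.merged.fit_table()
        assert {"club", "size", "b", "t_b"} <= set(table.columns)
        membership = results.merged.membership()
        assert set(membership.columns) == {"country_id", "club"}
        assert (membership.club == 0).sum() == len(results.merged.divergent)
        assert "classification" in results.summary()


class TestPartitionObject:
    def test_club_of_and_membership(self):
        part = ClubPartition(clubs=[["a", "b"], ["c", "d"]], divergent=["e"])
        assert part.club_of("a") == 1
        assert part.club_of("d") == 2
        assert part.club_of("e") == 0
        with pytest.raises(KeyError):
            part.club_of("zz")
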