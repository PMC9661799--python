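"""Tests of the event model and minimum-event distances."""

import math

import numpy as np
import pytest

from medphylo import fst_core
from medphylo.genome_model import (
    CopyNumberProfile,
    GenomeLayout,
    diploid_profile,
    encode,
)
from medphylo.med_model import (
    EventModelConfig,
    build_event_model,
    extract_events,
    med_asymmetric,
    med_symmetric,
    med_wgd_curve,
    pair_groups,
    pairwise_distances,
    replay_events,
)

from conftest import random_profile
from oracles import oracle_med_asymmetric, oracle_med_symmetric


class TestConfig:
    def test_default_composition_counts_follow_alphabet_size(self):
        cfg = EventModelConfig(cap=8)
        assert cfg.loh_steps == 9  # |Sigma| - 1 with |Sigma| = 10
        assert cfg.seg_steps == 8  # |Sigma| - 2
        assert cfg.max_wgd == 8

    def test_invalid_composition_counts_raise(self):
        with pytest.raises(ValueError):
            EventModelConfig(cap=8, loh_steps=3)
        with pytest.raises(ValueError):
            EventModelConfig(cap=8, seg_steps=2)


class TestOneStepMachines:
    """Single-event semantics, checked on the explicit transducers."""

    def test_gain_run_spanning_three_segments_costs_one(self, model8):
        seq = [1, 1, 1]
        assert fst_core.shortest_distance([model8.t1_gain], seq, [2, 2, 2]) == 1

    def test_gain_run_skips_interior_zero(self, model8):
        assert fst_core.shortest_distance([model8.t1_gain], [1, 0, 1], [2, 0, 2]) == 1
        # but a gain cannot create copies from zero
        assert fst_core.shortest_distance([model8.t1_gain], [1, 0, 1], [2, 1, 2]) == math.inf

    def test_runs_terminate_at_chromosome_separator(self, model8):
        # one run cannot span X: two runs needed
        assert fst_core.shortest_distance([model8.t1_gain], [1, "X", 1], [2, "X", 2]) == 2

    def test_wgd_affects_both_haplotypes_across_separators(self, model8):
        x = [1, 1, "X", 1, 1, "X", 1, 1, "X", 1, 1]
        y = [2, 2, "X", 2, 2, "X", 2, 2, "X", 2, 2]
        assert fst_core.shortest_distance([model8.t1_wgd], x, y) == 1
        # WGD leaves zeros unchanged
        x0 = [1, 0, "X", 1, 1]
        y0 = [2, 0, "X", 2, 2]
        assert fst_core.shortest_distance([model8.t1_wgd], x0, y0) == 1

    def test_loss_cannot_reach_zero_but_loh_can(self, model8):
        assert fst_core.shortest_distance([model8.t1_loss], [1], [0]) == math.inf
        assert fst_core.shortest_distance([model8.t1_loh], [1], [0]) == 1


class TestAsymmetricMed:
    def test_distance_to_self_is_zero(self, model8, layout13):
        d = diploid_profile(layout13)
        assert med_asymmetric(d, d, model8, layout13) == 0

    def test_loh_then_zero_skipping_gain(self, model8, layout13):
        d = diploid_profile(layout13)
        p = CopyNumberProfile("p", np.array([2, 0, 2]), np.array([1, 1, 1]))
        assert med_asymmetric(d, p, model8, layout13) == 2

    def test_zero_segments_cannot_be_regained(self, model8):
        lay = GenomeLayout.uniform(1, 2)
        x = CopyNumberProfile("x", np.array([1, 0]), np.array([1, 1]))
        y = CopyNumberProfile("y", np.array([1, 1]), np.array([1, 1]))
        assert med_asymmetric(x, y, model8, lay) == math.inf
        assert med_asymmetric(y, x, model8, lay) == 1

    def test_engine_and_dp_routes_agree_on_tiny_inputs(self):
        model = build_event_model(cap=2)
        lay = GenomeLayout.uniform(1, 2)
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = random_profile(rng, lay, 2, "x")
            y = random_profile(rng, lay, 2, "y")
            dp = med_asymmetric(x, y, model, lay)
            lazy = fst_core.lazy_shortest_path(
                model.chain(), encode(x, lay).symbols, encode(y, lay).symbols
            ).weight
            assert dp == lazy

    def test_matches_bfs_oracle_with_and_without_wgd(self, model3, model3_nowgd):
        rng = np.random.default_rng(12)
        lay = GenomeLayout.uniform(2, 2)
        for _ in range(25):
            x = random_profile(rng, lay, 3, "x")
            y = random_profile(rng, lay, 3, "y")
            assert med_asymmetric(x, y, model3, lay) == oracle_med_asymmetric(
                x, y, lay, cap=3, wgd=True
            )
            assert med_asymmetric(x, y, model3_nowgd, lay) == oracle_med_asymmetric(
                x, y, lay, cap=3, wgd=False
            )

    def test_wgd_never_increases_the_distance(self, model8, model8_nowgd):
        rng = np.random.default_rng(13)
        lay = GenomeLayout.uniform(2, 3)
        for _ in range(30):
            x = random_profile(rng, lay, 4, "x")
            y = random_profile(rng, lay, 4, "y")
            assert med_asymmetric(x, y, model8, lay) <= med_asymmetric(
                x, y, model8_nowgd, lay
            )


class TestSymmetricMed:
    def test_diploid_pair(self, model8, layout13):
        d = diploid_profile(layout13)
        s, anc = med_symmetric(d, d, model8, layout13, return_ancestor=True)
        assert s == 0
        assert anc.equals(d)

    def test_loh_on_one_side_costs_one_via_the_retained_ancestor(self, model8):
        lay = GenomeLayout.uniform(1, 2)
        x = CopyNumberProfile("x", np.array([1, 0]), np.array([1, 1]))
        y = CopyNumberProfile("y", np.array([1, 1]), np.array([1, 1]))
        s, anc = med_symmetric(x, y, model8, lay, return_ancestor=True)
        assert s == 1
        assert np.array_equal(anc.hapA, [1, 1])

    def test_mirrored_gains_meet_at_the_balanced_ancestor(self, model8):
        lay = GenomeLayout.uniform(1, 2)
        x = CopyNumberProfile("x", np.array([2, 1]), np.array([1, 1]))
        y = CopyNumberProfile("y", np.array([1, 2]), np.array([1, 1]))
        assert med_symmetric(x, y, model8, lay) == 2

    def test_matches_brute_force_ancestor_enumeration(self, model3, model3_nowgd):
        rng = np.random.default_rng(14)
        lay = GenomeLayout.uniform(1, 2)
        for _ in range(8):
            x = random_profile(rng, lay, 3, "x")
            y = random_profile(rng, lay, 3, "y")
            for model, wgd in ((model3, True), (model3_nowgd, False)):
                got = med_symmetric(x, y, model, lay)
                exp, _ = oracle_med_symmetric(x, y, lay, cap=3, wgd=wgd)
                assert got == exp

    def test_symmetry_and_upper_bound_by_asymmetric(self, model8):
        rng = np.random.default_rng(15)
        lay = GenomeLayout.uniform(2, 2)
        for _ in range(20):
            x = random_profile(rng, lay, 3, "x")
            y = random_profile(rng, lay, 3, "y")
            s = med_symmetric(x, y, model8, lay)
            assert s == med_symmetric(y, x, model8, lay)
            bound = min(
                med_asymmetric(x, y, model8, lay), med_asymmetric(y, x, model8, lay)
            )
            if not math.isinf(bound):
                assert s <= bound

    def test_ancestor_witnesses_the_distance(self, model8):
        rng = np.random.default_rng(16)
        lay = GenomeLayout.uniform(2, 2)
        for _ in range(10):
            x = random_profile(rng, lay, 3, "x")
            y = random_profile(rng, lay, 3, "y")
            s, anc = med_symmetric(x, y, model8, lay, return_ancestor=True)
            assert (
                med_asymmetric(anc, x, model8, lay) + med_asymmetric(anc, y, model8, lay)
                == s
            )


class TestWgdCurve:
    def test_increment_model_counts_three_wgds_for_all_fours(self, model8):
        lay = GenomeLayout.uniform(2, 2)
        d = diploid_profile(lay)
        t = CopyNumberProfile("t", np.full(4, 4), np.full(4, 4))
        curve = med_wgd_curve(d, t, model8, lay)
        assert curve[:4] == [12, 9, 6, 3]
        assert curve[-1] == 3

    def test_doubling_model_counts_two_wgds_for_all_fours(self, model8_double):
        lay = GenomeLayout.uniform(2, 2)
        d = diploid_profile(lay)
        t = CopyNumberProfile("t", np.full(4, 4), np.full(4, 4))
        curve = med_wgd_curve(d, t, model8_double, lay)
        assert curve[1] == 9 and curve[2] == 2 and curve[3] == 2

    def test_curve_is_non_increasing(self, model8):
        rng = np.random.default_rng(17)
        lay = GenomeLayout.uniform(2, 2)
        d = diploid_profile(lay)
        for _ in range(10):
            y = random_profile(rng, lay, 5, "y")
            curve = med_wgd_curve(d, y, model8, lay)
            assert all(a >= b for a, b in zip(curve, curve[1:]))


class TestEventExtraction:
    def test_no_events_between_identical_profiles(self, model8, layout13):
        d = diploid_profile(layout13)
        assert extract_events(d, d, model8, layout13) == []

    def test_single_wgd_explains_a_doubled_genome(self, model8):
        lay = GenomeLayout.uniform(22, 2)
        d = diploid_profile(lay)
        t = CopyNumberProfile("t", np.full(44, 2), np.full(44, 2))
        events = extract_events(d, t, model8, lay)
        assert len(events) == 1 and events[0].kind == "wgd"

    def test_loh_and_gain_records_for_the_worked_example(self, model8, layout13):
        d = diploid_profile(layout13)
        p = CopyNumberProfile("p", np.array([2, 0, 2]), np.array([1, 1, 1]))
        events = extract_events(d, p, model8, layout13)
        kinds = sorted((e.kind, e.start_segment, e.end_segment) for e in events)
        assert kinds == [("gain", 0, 2), ("loh_loss", 1, 1)]

    def test_replay_reproduces_target_on_random_pairs(self, model8):
        rng = np.random.default_rng(18)
        lay = GenomeLayout.uniform(2, 3)
        for _ in range(30):
            x = random_profile(rng, lay, 4, "x")
            y = random_profile(rng, lay, 4, "y")
            med = med_asymmetric(x, y, model8, lay)
            if math.isinf(med):
                with pytest.raises(ValueError, match="zero-copy"):
                    extract_events(x, y, model8, lay)
                continue
            events = extract_events(x, y, model8, lay)
            assert len(events) == med
            assert replay_events(x, events, model8, lay).equals(y)

    def test_extraction_is_deterministic(self, model8):
        lay = GenomeLayout.uniform(2, 3)
        rng = np.random.default_rng(19)
        x = random_profile(rng, lay, 3, "x")
        y = CopyNumberProfile("y", np.minimum(x.hapA + 1, 3), x.hapB.copy())
        first = extract_events(x, y, model8, lay)
        again = extract_events(x, y, model8, lay)
        assert first == again


class TestPairwise:
    def test_identical_profiles_give_a_zero_matrix(self, model8):
        lay = GenomeLayout.uniform(1, 3)
        from medphylo.genome_model import Cohort

        p = CopyNumberProfile("a", np.array([2, 1, 1]), np.array([1, 1, 1]))
        cohort = Cohort(lay, [p, CopyNumberProfile("b", p.hapA.copy(), p.hapB.copy())])
        dm = pairwise_distances(cohort, model8)
        assert dm.matrix[0, 1] == 0

    def test_four_taxa_use_six_groups_of_two(self):
        groups = pair_groups(4)
        assert len(groups) == 6
        assert all(len(g) == 2 for g in groups)
        covered = {tuple(sorted(g)) for g in groups}
        assert covered == {(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)}

    def test_scheduled_matrix_equals_serial_double_loop(self, model8):
        from medphylo.genome_model import Cohort

        rng = np.random.default_rng(20)
        lay = GenomeLayout.uniform(2, 3)
        profiles = [random_profile(rng, lay, 3, f"s{i}") for i in range(6)]
        cohort = Cohort(lay, profiles)
        dm = pairwise_distances(cohort, model8, workers=1)
        all_p = cohort.all_profiles()
        for i in range(len(all_p)):
            for j in range(len(all_p)):
                expected = 0 if i == j else med_symmetric(all_p[i], all_p[j], model8, lay)
                assert dm.matrix[i, j] == expected
        dm8 = pairwise_distances(cohort, model8, workers=8)
        assert np.array_equal(dm.matrix, dm8.matrix)
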